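import numpy as np
import pytest

import solvshift as sv
from solvshift.pisa import WINDOWS


@pytest.fixture(scope="session")
def planted_truth():
    """400-protein proteome with eight +3 %AEA targets planted on
    well-covered melters (C_M in [8, 15], > 1 peptide)."""
    truth = sv.generate_proteome(400, seed=7)
    eligible = truth.index[
        truth["sigmoidal"] & (truth["peptides"] > 1)
        & truth["cm"].between(8, 15)
    ]
    return sv.plant_targets(truth, {p: 3.0 for p in eligible[:8]}), list(eligible[:8])


@pytest.fixture(scope="session")
def planted_run(planted_truth):
    """Full SPP shift analysis on the planted proteome."""
    truth, targets = planted_truth
    vehicle, treatment = sv.simulate_spp_tables(truth, seed=7)
    return sv.run_profiling(vehicle, treatment), truth, targets


@pytest.fixture(scope="session")
def pisa_run():
    """PISA analysis of a 1500-protein proteome with 40 planted ±3 %AEA
    targets on window 2."""
    truth = sv.generate_proteome(1500, seed=3)
    eligible = truth.index[
        truth["sigmoidal"] & (truth["peptides"] > 1)
        & truth["cm"].between(8, 15)
    ]
    shifts = {p: (3.0 if i % 2 else -3.0) for i, p in enumerate(eligible[:40])}
    truth = sv.plant_targets(truth, shifts)
    table = sv.simulate_pisa_tables(truth, WINDOWS[2], seed=3)
    results = sv.PisaModel.from_quant_table(table).fit(seed=3)
    return results, truth, shifts
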