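"""Synthetic proteomes and simulated quantification tables.

Generates ground-truth melting curves with the statistical structure the
analyses assume — a right-skewed melting-concentration landscape (sample
median ≈ 10.2 %AEA, support within ≈ 7–21 %AEA), low bottom plateaus, a
configurable fraction of non-sigmoidal proteins, planted target shifts —
and renders them into protein x channel reporter-abundance tables with
multiplicative lognormal channel noise and per-channel pipetting biases.
Everything is deterministic under a single seed, split per stage.

The generator emulates processed protein-level tables, not spectra: no
peptide-to-protein rollup, no missing-value mechanism beyond failed
scaling, and no between-day gradient drift (representable only as a global
gradient offset applied by the caller).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SigmoidParams, melting_point_closed_form, soluble_fraction
from .io import QuantTable
from .pisa import WindowDesign

__all__ = [
    "NoiseModel",
    "generate_proteome",
    "plant_targets",
    "shifted_params",
    "simulate_spp_tables",
    "simulate_pisa_tables",
]

TRUTH_COLUMNS = [
    "protein", "pl", "a", "b", "cm", "delta_cm", "sigmoidal",
    "archetype", "peptides", "base_intensity",
]

_ARCHETYPES = ("flat", "high_plateau", "erratic")


@dataclass
class NoiseModel:
    """Technical-noise settings for table simulation.

    channel_cv : multiplicative lognormal coefficient of variation per
        channel measurement (0.05 = 5%CV, keeping per-group %CVs
        concentrated well below the 15% filter).
    bias_range : half-width of the uniform per-channel pipetting bias
        (0.10 = factors in [0.9, 1.1]); removable by normalization.
    sample_jitter : lognormal CV of a per-sample global scale factor
        (pooled PISA samples only; cancels under reference scaling).
    """

    channel_cv: float = 0.05
    bias_range: float = 0.10
    sample_jitter: float = 0.02

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log(1.0 + self.channel_cv**2))


def _child(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_proteome(
    n: int,
    cm_median: float = 10.2,
    cm_range: tuple[float, float] = (7.0, 21.0),
    frac_nonsigmoid: float = 0.25,
    frac_single_peptide: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a ground-truth proteome of ``n`` proteins.

    Melting concentrations are lognormal above the lower range edge
    (median at ``cm_median``), resampled into ``cm_range``; plateaus are
    beta-distributed below 0.3; curve steepness b ~ N(10, 1.5) clipped to
    [6, 14]; the scale a follows from (C_M, Pl, b).  A ``frac_nonsigmoid``
    fraction is drawn from three degenerate archetypes in equal parts:
    flat solvent-resistant profiles, partial melters with a high plateau,
    and erratic non-monotone profiles.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= frac_nonsigmoid <= 1):
        raise ValueError("frac_nonsigmoid must be in [0, 1]")
    lo, hi = cm_range
    if not (lo < cm_median < hi):
        raise ValueError(f"cm_median {cm_median} outside cm_range {cm_range}")

    rng = _child(seed, 1)
    mu = math.log(cm_median - lo)
    cm = lo + rng.lognormal(mu, 0.45, size=n)
    bad = (cm >= hi) | (cm <= lo)
    while bad.any():
        cm[bad] = lo + rng.lognormal(mu, 0.45, size=int(bad.sum()))
        bad = (cm >= hi) | (cm <= lo)

    pl = 0.28 * rng.beta(1.2, 6.0, size=n)
    b = np.clip(rng.normal(10.0, 1.5, size=n), 6.0, 14.0)
    a = cm * (b - np.log(0.5 / (0.5 - pl)))

    sigmoidal = rng.random(n) >= frac_nonsigmoid
    arche = np.where(sigmoidal, "sigmoid", rng.choice(_ARCHETYPES, size=n))
    # high-plateau partial melters keep a curve but fail the plateau gate
    hp = arche == "high_plateau"
    pl = np.where(hp, rng.uniform(0.35, 0.75, size=n), pl)
    a = np.where(hp, cm * np.maximum(b - np.log(0.5 / np.maximum(0.5 - pl, 1e-3)), 1.0), a)

    peptides = 1 + rng.poisson(7.0, size=n)
    peptides[rng.random(n) < frac_single_peptide] = 1
    base = 10.0 ** rng.uniform(4.0, 7.0, size=n)

    return pd.DataFrame({
        "protein": [f"P{i:05d}" for i in range(n)],
        "pl": pl, "a": a, "b": b,
        "cm": np.where(arche == "sigmoid", cm, np.nan),
        "delta_cm": 0.0,
        "sigmoidal": arche == "sigmoid",
        "archetype": arche,
        "peptides": peptides,
        "base_intensity": base,
    }).set_index("protein")


def shifted_params(row, delta_cm: float) -> SigmoidParams:
    """Treatment-arm parameters: translate the 0.5-crossing by ``delta_cm``
    at fixed plateau and steepness, re-deriving the scale a."""
    params = SigmoidParams(row["pl"], row["a"], row["b"])
    cm = melting_point_closed_form(params)
    if cm is None:
        return params
    new_cm = cm + delta_cm
    if new_cm <= 0:
        raise ValueError(f"shift {delta_cm:+} moves C_M to {new_cm} <= 0")
    return SigmoidParams(params.pl, new_cm * params.a / cm, params.b)


def plant_targets(truth: pd.DataFrame, shifts: dict[str, float]) -> pd.DataFrame:
    """Assign ligand-induced melting-point shifts to target proteins."""
    unknown = [p for p in shifts if p not in truth.index]
    if unknown:
        raise ValueError(f"target ids not in proteome: {unknown}")
    out = truth.copy()
    for prot, delta in shifts.items():
        if not np.isfinite(delta):
            raise ValueError(f"non-finite shift for {prot}")
        shifted_params(out.loc[prot], delta)  # validates domain
        out.loc[prot, "delta_cm"] = delta
    return out


def _true_fractions(truth: pd.DataFrame, gradient: np.ndarray,
                    treated: bool, rng: np.random.Generator) -> np.ndarray:
    """Noise-free soluble-fraction matrix (protein x gradient)."""
    n = len(truth)
    out = np.empty((n, len(gradient)))
    for i, (prot, row) in enumerate(truth.iterrows()):
        arche = row["archetype"]
        if arche == "erratic":
            # non-monotone wander around 1; reference point stays 1
            vals = np.exp(rng.normal(0.0, 0.3, size=len(gradient)))
            vals[0] = 1.0
            out[i] = vals
        elif arche == "flat":
            out[i] = 1.0
        else:
            params = SigmoidParams(row["pl"], row["a"], row["b"])
            if treated and row["delta_cm"] != 0.0:
                params = shifted_params(row, row["delta_cm"])
            out[i] = soluble_fraction(gradient, params)
    return out


def simulate_spp_tables(
    truth: pd.DataFrame,
    gradient: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0),
    replicates: int = 2,
    noise: NoiseModel | None = None,
    seed: int = 0,
    unit: str = "%AEA",
) -> tuple[QuantTable, QuantTable]:
    """Render a truth proteome into vehicle and treatment quantification
    tables (one experiment per replicate, channels = gradient points).

    Abundance = base intensity x soluble fraction x lognormal channel
    noise x per-channel pipetting bias.  Reference channels are strictly
    positive by construction.
    """
    noise = noise or NoiseModel()
    gradient = np.asarray(gradient, dtype=float)
    tables = []
    for ci, cond in enumerate(("vehicle", "treatment")):
        data = {}
        design_rows = []
        for r in range(1, replicates + 1):
            rng = _child(seed, 2, ci, r)
            frac = _true_fractions(truth, gradient, cond == "treatment", _child(seed, 3, ci, r))
            bias = rng.uniform(1.0 - noise.bias_range, 1.0 + noise.bias_range,
                               size=len(gradient))
            eps = rng.lognormal(0.0, noise.sigma, size=frac.shape)
            mat = truth["base_intensity"].to_numpy()[:, None] * frac * eps * bias[None, :]
            for j, g in enumerate(gradient):
                chan = f"{cond}_r{r}_{g:g}"
                data[chan] = mat[:, j]
                design_rows.append((chan, cond, f"r{r}", g, unit))
        df = pd.DataFrame(data, index=truth.index)
        design = pd.DataFrame(design_rows,
                              columns=["channel", "condition", "replicate",
                                       "gradient", "unit"])
        tables.append(QuantTable(data=df, peptides=truth["peptides"].copy(),
                                 design=design))
    return tables[0], tables[1]


def simulate_pisa_tables(
    truth: pd.DataFrame,
    window: WindowDesign,
    n_treated: int = 4,
    n_vehicle: int = 4,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> QuantTable:
    """Render a truth proteome into a pooled PISA quantification table.

    Each sample's value is the window mean of the (shifted, for treated
    samples) soluble fraction, scaled by base intensity, with lognormal
    channel noise and a per-sample global jitter.
    """
    noise = noise or NoiseModel()
    grads = np.asarray(window.gradients)
    data = {}
    design_rows = []
    for cond, n_samp in (("vehicle", n_vehicle), ("treated", n_treated)):
        for r in range(1, n_samp + 1):
            rng = _child(seed, 4, cond == "treated", r)
            frac = _true_fractions(truth, grads, cond == "treated", _child(seed, 5, cond == "treated", r))
            eps = rng.lognormal(0.0, noise.sigma, size=frac.shape)
            pooled = (frac * eps).mean(axis=1)
            jitter = rng.lognormal(0.0, math.sqrt(math.log(1 + noise.sample_jitter**2)))
            chan = f"{cond}_{r}"
            data[chan] = truth["base_intensity"].to_numpy() * pooled * jitter
            design_rows.append((chan, cond, f"r{r}", np.nan, "pooled"))
    df = pd.DataFrame(data, index=truth.index)
    design = pd.DataFrame(design_rows,
                          columns=["channel", "condition", "replicate",
                                   "gradient", "unit"])
    return QuantTable(data=df, peptides=truth["peptides"].copy(), design=design)
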