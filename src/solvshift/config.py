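"""Run configuration with the pipeline's default thresholds."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .curves import SigmoidParams, SPP_START, TPP_START, SPP_ROOT_INTERVAL

__all__ = ["RunConfig"]

_SPP_GRADIENT = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
_TPP_GRADIENT = (38.0, 41.0, 44.0, 48.0, 51.0, 54.0, 58.0, 61.0)


@dataclass
class RunConfig:
    """All tunable thresholds of the profiling and PISA pipelines.

    Defaults: curve-fit starts (Pl=0, a=55, b=10) for solvent and
    (Pl=0, a=550, b=10) for thermal assays; root interval [3, 21] %AEA for
    solvent, the experiment's temperature range for thermal; quality gates
    R² > 0.8 and plateau < 0.3; hit gates adjusted p < 0.001 and > 1
    peptide; PISA gates %CV ≤ 15, permutation FDR 0.05, S0 = 0.1 with 250
    randomizations.
    """

    assay: str = "solvent"  # "solvent" | "thermal"
    gradient: tuple[float, ...] = _SPP_GRADIENT
    start: SigmoidParams | None = None
    root_interval: tuple[float, float] | None = None
    # curve quality
    r2_min: float = 0.8
    plateau_max: float = 0.3
    # hit requirements (per the full-curve shift protocol)
    p_small_max: float = 0.05
    p_large_max: float = 0.1
    min_slope: float = -0.06
    adjusted_p_max: float = 0.001
    min_peptides: int = 2  # "peptides > 1"
    # shift p-value machinery
    bin_size: int = 300
    min_valid_shifts: int = 50
    # PISA
    cv_threshold: float = 15.0
    fdr: float = 0.05
    s0: float = 0.1
    n_perm: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("solvent", "thermal"):
            raise ValueError(f"unknown assay kind {self.assay!r}")
        if self.assay == "thermal" and self.gradient == _SPP_GRADIENT:
            self.gradient = _TPP_GRADIENT
        self.gradient = tuple(float(g) for g in self.gradient)
        if self.start is None:
            self.start = SPP_START if self.assay == "solvent" else TPP_START
        elif not isinstance(self.start, SigmoidParams):
            self.start = SigmoidParams(*self.start)
        if self.root_interval is None:
            if self.assay == "solvent":
                self.root_interval = SPP_ROOT_INTERVAL
            else:
                self.root_interval = (min(self.gradient), max(self.gradient))
        else:
            self.root_interval = tuple(float(v) for v in self.root_interval)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start"] = list(self.start)
        d["gradient"] = list(self.gradient)
        d["root_interval"] = list(self.root_interval)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
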