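"""Reference scaling and joint curve normalization across experiments.

Each protein is first scaled to its reference channel (lowest gradient
value, typically 0 %AEA or the lowest temperature), giving per-experiment
relative-abundance curves that start at 1.  Technical variance between
channels (e.g. pipetting error) is then removed jointly: a normalization
set of well-behaved melters is selected by fixed point-window criteria,
per-experiment median curves over that set are fitted with the sigmoid
model, the experiment with the best median-curve R² becomes the reference,
and every other experiment is corrected channel-wise onto the reference's
fitted curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import MeltCurveModel, SigmoidParams, SPP_START, SPP_ROOT_INTERVAL, melt_model
from .io import QuantTable

__all__ = [
    "FoldChangeMatrix",
    "NormalizationModel",
    "scale_to_reference",
    "select_normalization_set",
    "fit_normalization",
    "apply_normalization",
]

log = logging.getLogger(__name__)

Experiment = tuple[str, str]  # (condition, replicate)

# 1-based positions of the three normalization-set criteria, keyed by the
# number of gradient points: (mid point, late point, last point).
_CRITERIA_POSITIONS = {8: (5, 7, 8), 16: (10, 15, 16)}
_CRITERIA_WINDOWS = ((0.4, 0.6), (0.0, 0.3), (0.0, 0.2))


@dataclass
class FoldChangeMatrix:
    """Per-experiment relative abundances (reference channel = 1).

    ``values`` maps each (condition, replicate) experiment to a protein x
    gradient DataFrame whose columns are the gradient values.  Proteins
    whose reference channel was missing or non-positive are flagged
    ``unscalable`` for that experiment and carry NaN rows there.
    """

    values: dict[Experiment, pd.DataFrame]
    gradient: np.ndarray
    unscalable: dict[Experiment, list[str]] = field(default_factory=dict)

    @property
    def experiments(self) -> list[Experiment]:
        return list(self.values)

    @property
    def n_points(self) -> int:
        return len(self.gradient)

    def copy(self) -> "FoldChangeMatrix":
        return FoldChangeMatrix(
            values={e: df.copy() for e, df in self.values.items()},
            gradient=self.gradient.copy(),
            unscalable={e: list(v) for e, v in self.unscalable.items()},
        )


def scale_to_reference(table: QuantTable) -> FoldChangeMatrix:
    """Divide each protein's channels by its reference (lowest-gradient)
    channel, per experiment."""
    values: dict[Experiment, pd.DataFrame] = {}
    unscalable: dict[Experiment, list[str]] = {}
    gradient = None
    for cond, rep in table.experiments():
        grad = table.gradient(cond, rep)
        if gradient is None:
            gradient = grad
        elif not np.allclose(gradient, grad):
            raise ValueError(
                f"experiment {(cond, rep)} has gradient {grad}, expected {gradient}"
            )
        block = table.abundances(cond, rep)
        ref = block.iloc[:, 0]
        bad = ~(ref > 0) | ref.isna()
        fc = block.div(ref, axis=0)
        fc[bad] = np.nan
        fc.columns = grad
        values[(str(cond), str(rep))] = fc
        unscalable[(str(cond), str(rep))] = [str(p) for p in block.index[bad]]
    if gradient is None:
        raise ValueError("table has no experiments")
    return FoldChangeMatrix(values=values, gradient=gradient, unscalable=unscalable)


def select_normalization_set(fc: FoldChangeMatrix, n_points: int | None = None) -> pd.Index:
    """Proteins eligible for normalization-curve fitting.

    For 8-point curves the 5th point must lie in [0.4, 0.6], the 7th in
    [0, 0.3] and the last in [0, 0.2]; for 16-point curves the 10th, 15th
    and 16th points carry the same windows.  A protein qualifies only if it
    meets all three criteria in every experiment being jointly normalized.
    """
    n_points = fc.n_points if n_points is None else n_points
    if n_points != fc.n_points:
        raise ValueError(f"n_points={n_points} but matrix has {fc.n_points} gradient points")
    try:
        positions = _CRITERIA_POSITIONS[n_points]
    except KeyError:
        raise ValueError(f"no normalization criteria defined for {n_points}-point curves") from None

    keep = None
    for df in fc.values.values():
        ok = pd.Series(True, index=df.index)
        for pos, (lo, hi) in zip(positions, _CRITERIA_WINDOWS):
            col = df.iloc[:, pos - 1]
            ok &= (col >= lo) & (col <= hi)
        keep = ok if keep is None else (keep & ok)
    return keep.index[keep]


@dataclass
class NormalizationModel:
    """Joint-normalization state: membership, median curves, factors."""

    member_ids: pd.Index
    reference_experiment: Experiment
    median_curves: pd.DataFrame  # index gradient, columns experiments
    correction_factors: pd.DataFrame  # same shape
    r_squared: dict[Experiment, float]


def fit_normalization(
    fc: FoldChangeMatrix,
    members: pd.Index,
    start: SigmoidParams = SPP_START,
    root_interval: tuple[float, float] = SPP_ROOT_INTERVAL,
) -> NormalizationModel:
    """Fit per-experiment median curves over the normalization set and
    derive channel correction factors onto the best-fitting experiment."""
    if len(members) == 0:
        raise ValueError("empty normalization set")

    medians = {}
    fits = {}
    r2 = {}
    for exp, df in fc.values.items():
        med = df.loc[df.index.intersection(members)].median(axis=0)
        medians[exp] = med
        grad = med.index.to_numpy(float)
        pos = grad > 0
        fit = MeltCurveModel(grad[pos], med.to_numpy(float)[pos]).fit(
            start=start, root_interval=root_interval
        )
        fits[exp] = fit
        r2[exp] = fit.r_squared if fit.converged else -np.inf

    reference = max(r2, key=r2.__getitem__)
    ref_params = fits[reference].params

    grad = fc.gradient
    factors = {}
    for exp, med in medians.items():
        f = np.ones(len(grad))
        for i, g in enumerate(grad):
            if g <= 0 or i == 0:
                continue  # reference point: factor fixed at 1
            m = med.iloc[i]
            if not np.isfinite(m) or m == 0:
                f[i] = np.nan
                log.warning("invalid median at gradient %s in %s", g, exp)
            else:
                f[i] = melt_model(g, ref_params) / m
        factors[exp] = f

    return NormalizationModel(
        member_ids=pd.Index(members),
        reference_experiment=reference,
        median_curves=pd.DataFrame(medians, index=grad),
        correction_factors=pd.DataFrame(factors, index=grad),
        r_squared=r2,
    )


def apply_normalization(fc: FoldChangeMatrix, model: NormalizationModel) -> FoldChangeMatrix:
    """Multiply each experiment's channels by its correction factors.

    The reference gradient point is untouched (its factor is 1 by
    definition), so every retained protein still starts at 1.
    """
    out = fc.copy()
    for exp, df in out.values.items():
        if exp not in model.correction_factors:
            raise KeyError(f"normalization model lacks factors for experiment {exp}")
        factors = model.correction_factors[exp].to_numpy(float)
        out.values[exp] = df.mul(factors, axis=1)
    return out
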