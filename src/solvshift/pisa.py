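"""PISA analysis: pooled soluble fractions, fold changes, and
permutation-FDR significance.

In a PISA (proteome integral solubility alteration) experiment the soluble
fractions across a gradient window are pooled in equal volumes, so each
sample yields one abundance per protein — a discrete area-under-the-curve
proxy.  Ligand engagement is read as a log2 fold change of each treated
sample against the mean of the vehicle samples, tested with a SAM-style
statistic d = (mean₁ − mean₂) / (s + S0) whose null distribution comes
from group-label permutations.  Later and narrower windows on the melting
curve's back half amplify shift-induced fold changes; the expected fold
change for a window can be predicted from full SPP melting curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .curves import MeltCurveFit, SigmoidParams, soluble_fraction

__all__ = [
    "WindowDesign",
    "WINDOWS",
    "WINDOW2_VARIANT",
    "PisaModel",
    "PisaResults",
    "pool_channels",
    "pisa_fold_changes",
    "cv_filter",
    "sam_permutation_test",
    "predict_window_fc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowDesign:
    """Ordered set of gradient values pooled into one PISA sample."""

    gradients: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        g = tuple(float(v) for v in self.gradients)
        if len(g) < 2 or any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("window needs >= 2 strictly increasing gradient values")
        object.__setattr__(self, "gradients", g)


def _window(lo: float, hi: float, n: int, label: str) -> WindowDesign:
    return WindowDesign(tuple(np.round(np.linspace(lo, hi, n), 6)), label)


#: The four solvent windows (8 points each, %AEA).
WINDOWS: dict[int, WindowDesign] = {
    1: _window(0.0, 21.0, 8, "window 1: 0-21% AEA"),
    2: _window(9.0, 19.5, 8, "window 2: 9-19.5% AEA"),
    3: _window(11.0, 19.75, 8, "window 3: 11-19.75% AEA"),
    4: _window(14.25, 19.5, 8, "window 4: 14.25-19.5% AEA"),
}

#: Alternative spacing of window 2 used in some pooled experiments.
WINDOW2_VARIANT = _window(9.0, 18.625, 8, "window 2 variant: 9-18.625% AEA")


def pool_channels(soluble: np.ndarray | pd.Series, window: WindowDesign | None = None) -> float:
    """Equal-volume pooling of per-gradient soluble abundances: the mean.

    Equivalent to the pooled sample's concentration up to a constant that
    cancels in every fold change.  Any missing value makes the pooled
    value missing (flagged by the caller).
    """
    values = np.asarray(soluble, dtype=float)
    if window is not None and values.shape[-1] != len(window.gradients):
        raise ValueError("abundances must cover every window gradient")
    if np.any(~np.isfinite(values)):
        return float("nan")
    return float(np.mean(values))


def pisa_fold_changes(pooled: pd.DataFrame, vehicle_cols: list[str]) -> pd.DataFrame:
    """log2 fold change of every sample against the vehicle-group mean.

    Proteins whose vehicle mean is not strictly positive are flagged with
    all-missing fold changes.
    """
    if len(vehicle_cols) < 2:
        raise ValueError("need >= 2 vehicle samples")
    vmean = pooled[vehicle_cols].mean(axis=1)
    fc = np.log2(pooled.div(vmean, axis=0).where(vmean > 0))
    return fc.add_prefix("log2fc_")


def cv_filter(
    pooled: pd.DataFrame,
    groups: dict[str, list[str]],
    threshold: float = 15.0,
    peptides: pd.Series | None = None,
    min_peptides: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove proteins whose per-group %CV exceeds ``threshold`` in either
    group (strictly), or that were quantified with fewer than 2 peptides.

    Returns ``(kept pooled table, %CV table for all proteins)``.
    """
    cvs = pd.DataFrame({
        name: 100.0 * pooled[cols].std(axis=1, ddof=1) / pooled[cols].mean(axis=1)
        for name, cols in groups.items()
    })
    keep = ~(cvs > threshold).any(axis=1) & cvs.notna().all(axis=1)
    if peptides is not None:
        keep &= peptides.reindex(pooled.index) >= min_peptides
    return pooled[keep], cvs


def _sam_d(x1: np.ndarray, x2: np.ndarray, s0: float) -> np.ndarray:
    """SAM statistic per row: (mean1 - mean2) / (pooled se + s0).

    With ``s0 = 0`` this is exactly the two-sample pooled-variance
    t statistic.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    sp = np.sqrt(ss / (n1 + n2 - 2))
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    return (m1 - m2) / (se + s0)


def sam_permutation_test(
    treated: pd.DataFrame,
    vehicle: pd.DataFrame,
    s0: float = 0.1,
    fdr: float = 0.05,
    n_perm: int = 250,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """SAM-style two-sample test with permutation-based FDR control.

    Operates on log2-scale pooled abundances (rows = proteins).  The null
    distribution of d comes from ``n_perm`` group-label permutations drawn
    (with replacement, seeded) from the distinct label arrangements.  For a
    candidate cut t, the estimated FDR is the median permutation count of
    |d*| ≥ t divided by the observed count; the cut is the most permissive
    one with estimated FDR ≤ the target, and a per-protein q-value is the
    monotonized estimated FDR at the protein's own |d|.
    """
    x1 = treated.to_numpy(float)
    x2 = vehicle.to_numpy(float)
    n1, n2 = x1.shape[1], x2.shape[1]
    combined = np.hstack([x1, x2])

    arrangements = list(combinations(range(n1 + n2), n1))
    if len(arrangements) - 1 < 2:  # excluding the identity labelling
        raise ValueError("fewer than 2 permutable label arrangements")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = rng.integers(0, len(arrangements), size=n_perm)

    d_obs = _sam_d(x1, x2, s0)
    abs_obs = np.abs(d_obs)

    null_counts = np.empty((n_perm, len(abs_obs)))
    order = np.argsort(abs_obs)[::-1]  # thresholds, most extreme first
    thresholds = abs_obs[order]
    for i, k in enumerate(picks):
        idx1 = list(arrangements[k])
        idx2 = [j for j in range(n1 + n2) if j not in set(idx1)]
        d_null = np.abs(_sam_d(combined[:, idx1], combined[:, idx2], s0))
        d_null = d_null[np.isfinite(d_null)]
        srt = np.sort(d_null)
        # count of null |d| >= each threshold
        null_counts[i] = len(srt) - np.searchsorted(srt, thresholds, side="left")

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.arange(1, len(thresholds) + 1, dtype=float)
        fdr_hat = np.median(null_counts, axis=0) / r
    fdr_hat = np.minimum(fdr_hat, 1.0)
    # q-values: monotone from the most permissive cut upwards
    q_sorted = np.minimum.accumulate(fdr_hat[::-1])[::-1]

    passing = np.nonzero(q_sorted <= fdr)[0]
    if passing.size:
        cut = thresholds[passing.max()]
    else:
        cut = np.inf

    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    sig = abs_obs >= cut
    return pd.DataFrame(
        {"d": d_obs, "q_value": q, "significant": sig}, index=treated.index
    )


def _window_values(obj, window: WindowDesign) -> np.ndarray:
    """Abundances over a window, from fitted curves or explicit values."""
    if isinstance(obj, MeltCurveFit):
        obj = obj.params
    if isinstance(obj, SigmoidParams):
        return soluble_fraction(np.asarray(window.gradients), obj)
    values = np.asarray(obj, dtype=float)
    if values.shape != (len(window.gradients),):
        raise ValueError("abundances must cover every window gradient")
    return values


def predict_window_fc(vehicle, treatment, window: WindowDesign) -> float:
    """Expected log2 fold change of a pooled window, from melting curves.

    Arguments may be fitted curves (``MeltCurveFit`` / ``SigmoidParams``,
    evaluated at the window gradients) or explicit abundance arrays.
    Returns log2( Σ treated / Σ vehicle ) over the window; missing when the
    vehicle sum is not strictly positive.
    """
    v = _window_values(vehicle, window).sum()
    t = _window_values(treatment, window).sum()
    if not v > 0:
        return float("nan")
    return float(np.log2(t / v))


class PisaModel:
    """Pooled-abundance PISA analysis (treated vs vehicle).

    Parameters
    ----------
    pooled : DataFrame
        Protein x sample pooled abundances (raw scale).
    groups : mapping
        ``{"treated": [sample columns], "vehicle": [sample columns]}``.
    peptides : Series, optional
        Per-protein peptide counts, for the >= 2 peptides filter.
    """

    def __init__(self, pooled: pd.DataFrame, groups: dict[str, list[str]],
                 peptides: pd.Series | None = None):
        for key in ("treated", "vehicle"):
            if key not in groups or len(groups[key]) < 2:
                raise ValueError(f"need >= 2 '{key}' samples")
        missing = [c for cols in groups.values() for c in cols if c not in pooled.columns]
        if missing:
            raise ValueError(f"group columns absent from table: {missing}")
        self.pooled = pooled
        self.groups = {k: list(v) for k, v in groups.items()}
        self.peptides = peptides

    @classmethod
    def from_quant_table(cls, table) -> "PisaModel":
        """Build from a QuantTable whose conditions are treated/vehicle
        pooled samples (one channel per sample)."""
        groups: dict[str, list[str]] = {"treated": [], "vehicle": []}
        for _, row in table.design.iterrows():
            cond = str(row["condition"])
            if cond not in groups:
                raise ValueError(f"unexpected condition {cond!r}; want treated/vehicle")
            groups[cond].append(str(row["channel"]))
        return cls(table.data, groups, peptides=table.peptides)

    def fit(
        self,
        s0: float = 0.1,
        fdr: float = 0.05,
        n_perm: int = 250,
        cv_threshold: float = 15.0,
        min_peptides: int = 2,
        seed: int = 0,
    ) -> "PisaResults":
        kept, cvs = cv_filter(
            self.pooled, self.groups, threshold=cv_threshold,
            peptides=self.peptides, min_peptides=min_peptides,
        )
        fc = pisa_fold_changes(kept, self.groups["vehicle"])
        log_pooled = np.log2(kept.where(kept > 0))
        test = sam_permutation_test(
            log_pooled[self.groups["treated"]],
            log_pooled[self.groups["vehicle"]],
            s0=s0, fdr=fdr, n_perm=n_perm, seed=seed,
        )
        mean_fc = fc[[f"log2fc_{c}" for c in self.groups["treated"]]].mean(axis=1)
        result = pd.concat(
            [kept, cvs.loc[kept.index].add_prefix("cv_pct_"), fc,
             mean_fc.rename("mean_log2fc"), test], axis=1
        )
        counts = {
            "quantified": int(len(self.pooled)),
            "retained": int(len(kept)),
            "significant": int(test["significant"].sum()),
        }
        return PisaResults(table=result, cvs=cvs, groups=self.groups,
                           counts=counts, settings={
                               "s0": s0, "fdr": fdr, "n_perm": n_perm,
                               "cv_threshold": cv_threshold,
                               "min_peptides": min_peptides, "seed": seed,
                           })


@dataclass
class PisaResults:
    """Volcano-ready PISA result table plus filter-stage counts."""

    table: pd.DataFrame
    cvs: pd.DataFrame
    groups: dict[str, list[str]]
    counts: dict[str, int] = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            "PISA analysis (SAM permutation FDR "
            f"{self.settings.get('fdr')}, S0 {self.settings.get('s0')})",
            f"  proteins quantified:         {self.counts.get('quantified')}",
            f"  retained after %CV/peptide:  {self.counts.get('retained')}",
            f"  significant:                 {self.counts.get('significant')}",
        ]
        return "\n".join(lines)
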