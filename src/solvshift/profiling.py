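"""End-to-end solvent/thermal profiling: curve fits, melting-point shifts,
and target-engagement hit calling.

The full-curve workflow compares a vehicle (DMSO) arm against a
compound-treated arm, each measured in replicate across the same gradient.
Per replicate, both arms are scaled, jointly normalized, and fitted with
the sigmoid model; the ligand-induced shift is ``ΔC_M = C_M(treatment) −
C_M(vehicle)`` (stabilization positive).  Significance follows the
established full-curve shift protocol: an empirical, slope-binned robust
z-score per replicate with Benjamini–Hochberg adjustment, then four
requirements (replicate p-value thresholds, sign agreement, exceeding the
vehicle-vs-vehicle shift, and a minimum curve steepness) plus adjusted
p < 0.001 and > 1 peptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .curves import MeltCurveModel
from .io import QuantTable
from .normalization import (
    FoldChangeMatrix,
    apply_normalization,
    fit_normalization,
    scale_to_reference,
    select_normalization_set,
)

__all__ = [
    "SppShiftModel",
    "SppShiftResults",
    "CoverageSummary",
    "fit_quant_table",
    "run_profiling",
    "shift_p_values",
    "call_hits",
    "combine_coverage",
]

log = logging.getLogger(__name__)

FIT_COLUMNS = [
    "protein", "condition", "replicate", "pl", "a", "b", "r_squared",
    "plateau", "melting_point", "slope", "converged", "quality_pass",
]


def _normalize(fc: FoldChangeMatrix, config: RunConfig) -> tuple[FoldChangeMatrix, object]:
    members = select_normalization_set(fc)
    model = fit_normalization(
        fc, members, start=config.start, root_interval=config.root_interval
    )
    return apply_normalization(fc, model), model


def _fit_experiments(fc: FoldChangeMatrix, config: RunConfig) -> pd.DataFrame:
    """Fit the sigmoid model to every protein in every experiment."""
    records = []
    for (cond, rep), df in fc.values.items():
        grad = df.columns.to_numpy(float)
        pos = grad > 0  # the origin is the scaling reference, not a fitted point
        x = grad[pos]
        mat = df.to_numpy(float)[:, pos]
        for prot, row in zip(df.index, mat):
            fit = MeltCurveModel(x, row).fit(
                start=config.start,
                root_interval=config.root_interval,
                r2_min=config.r2_min,
                plateau_max=config.plateau_max,
            )
            records.append((
                prot, cond, rep, *fit.params, fit.r_squared, fit.plateau,
                np.nan if fit.melting_point is None else fit.melting_point,
                np.nan if fit.slope is None else fit.slope,
                fit.converged, fit.quality_pass,
            ))
    return pd.DataFrame(records, columns=FIT_COLUMNS)


def fit_quant_table(table: QuantTable, config: RunConfig | None = None):
    """Scale, normalize and fit one quantification table.

    Returns ``(fits, normalization_model)`` where ``fits`` has one row per
    (protein, condition, replicate).
    """
    config = config or RunConfig()
    fc = scale_to_reference(table)
    fc, model = _normalize(fc, config)
    return _fit_experiments(fc, config), model


def shift_p_values(
    delta_cm: pd.Series,
    min_slope: pd.Series,
    bin_size: int = 300,
    min_valid: int = 50,
) -> pd.Series:
    """Empirical two-sided p-values for melting-point shifts in one replicate.

    Proteins with a valid shift are ordered by the steeper of their two
    curve slopes and chunked into bins of ``bin_size``; within each bin a
    robust z-score is formed from the bin median and the half-distance
    between the 84.13th and 15.87th percentiles (a normal-consistent
    spread), and converted to a two-sided normal p-value.
    """
    p = pd.Series(np.nan, index=delta_cm.index, dtype=float)
    valid = delta_cm.notna() & min_slope.notna()
    n = int(valid.sum())
    if n < min_valid:
        log.warning("only %d valid shifts (< %d): p-values not computed", n, min_valid)
        return p

    order = min_slope[valid].sort_values().index
    n_bins = max(1, int(np.ceil(len(order) / bin_size)))
    for chunk in np.array_split(np.asarray(order, dtype=object), n_bins):
        d = delta_cm[chunk].to_numpy(float)
        med = np.median(d)
        spread = (np.percentile(d, 84.13) - np.percentile(d, 15.87)) / 2.0
        if spread <= 0:
            spread = np.nan
        z = (d - med) / spread
        p[chunk] = 2.0 * stats.norm.sf(np.abs(z))
    return p


def _bh_adjust(p: pd.Series) -> pd.Series:
    adj = pd.Series(np.nan, index=p.index, dtype=float)
    ok = p.notna()
    if ok.any():
        adj[ok] = stats.false_discovery_control(p[ok].to_numpy(), method="bh")
    return adj


def call_hits(shifts: pd.DataFrame, replicates: list[str], config: RunConfig) -> pd.DataFrame:
    """Evaluate the four hit requirements plus the adjusted-p and peptide
    gates, in place on the per-protein shift table."""
    reps = replicates
    d = shifts[[f"delta_cm_{r}" for r in reps]]
    p = shifts[[f"p_{r}" for r in reps]]
    adj = shifts[[f"adj_p_{r}" for r in reps]]
    msl = shifts[[f"min_slope_{r}" for r in reps]]

    complete = d.notna().all(axis=1)
    # (1) replicate p-value thresholds: smaller p < 0.05, larger p < 0.1
    req1 = (p.min(axis=1) < config.p_small_max) & (p.max(axis=1) < config.p_large_max)
    # (2) same sign of the shift in all replicates
    sign = np.sign(d)
    req2 = complete & ((sign > 0).all(axis=1) | (sign < 0).all(axis=1))
    # (3) both treatment-vs-vehicle shifts exceed the vehicle-vs-vehicle shift
    if "vehicle_vs_vehicle" in shifts:
        ref = shifts["vehicle_vs_vehicle"].abs()
        req3 = complete & d.abs().gt(ref, axis=0).all(axis=1)
    else:
        req3 = complete  # single vehicle replicate: requirement skipped
    # (4) curve steepness in all replicates
    req4 = msl.lt(config.min_slope).all(axis=1)

    shifts["req_pvalues"] = req1
    shifts["req_same_sign"] = req2
    shifts["req_exceeds_vehicle"] = req3
    shifts["req_steepness"] = req4
    shifts["fulfills_all_4"] = req1 & req2 & req3 & req4
    is_hit = (
        shifts["fulfills_all_4"]
        & adj.lt(config.adjusted_p_max).all(axis=1)
        & (shifts["peptides"] >= config.min_peptides)
    ).astype("boolean")
    is_hit[~complete] = pd.NA  # unfittable: reported, not judged
    shifts["is_hit"] = is_hit
    return shifts


@dataclass
class CoverageSummary:
    """Partition of shared proteins by high-quality-curve status."""

    both: int
    solvent_only: int
    thermal_only: int
    neither: int
    total_shared: int

    @property
    def union(self) -> int:
        return self.both + self.solvent_only + self.thermal_only

    def as_dict(self) -> dict[str, int]:
        return {
            "both": self.both, "solvent_only": self.solvent_only,
            "thermal_only": self.thermal_only, "neither": self.neither,
            "total_shared": self.total_shared, "union": self.union,
        }


def _quality_by_protein(fits: pd.DataFrame, mode: str) -> pd.Series:
    agg = fits.groupby("protein")["quality_pass"]
    return agg.any() if mode == "any" else agg.all()


def combine_coverage(
    solvent_fits: pd.DataFrame,
    thermal_fits: pd.DataFrame,
    mode: str = "any",
) -> CoverageSummary:
    """Cross-tabulate high-quality-curve coverage over proteins quantified
    in both a solvent and a thermal assay.

    ``mode='any'`` counts a protein as covered when at least one replicate
    produced a high-quality curve; ``'all'`` requires every replicate.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    sq = _quality_by_protein(solvent_fits, mode)
    tq = _quality_by_protein(thermal_fits, mode)
    shared = sq.index.intersection(tq.index)
    if len(shared) == 0:
        raise ValueError("no proteins quantified in both assays")
    s, t = sq[shared], tq[shared]
    return CoverageSummary(
        both=int((s & t).sum()),
        solvent_only=int((s & ~t).sum()),
        thermal_only=int((~s & t).sum()),
        neither=int((~s & ~t).sum()),
        total_shared=int(len(shared)),
    )


class SppShiftModel:
    """Vehicle-vs-treatment melting-point shift analysis.

    Parameters
    ----------
    vehicle, treatment : QuantTable
        Quantification tables for the two arms, with matching gradient
        designs and replicate labels.  Condition labels must differ
        between the arms.
    config : RunConfig, optional
    """

    def __init__(self, vehicle: QuantTable, treatment: QuantTable,
                 config: RunConfig | None = None):
        self.vehicle = vehicle
        self.treatment = treatment
        self.config = config or RunConfig()
        v_conds = {c for c, _ in vehicle.experiments()}
        t_conds = {c for c, _ in treatment.experiments()}
        if v_conds & t_conds:
            raise ValueError("vehicle and treatment tables share condition labels")
        v_reps = sorted({r for _, r in vehicle.experiments()})
        t_reps = sorted({r for _, r in treatment.experiments()})
        if v_reps != t_reps:
            raise ValueError(
                f"replicate labels differ: vehicle {v_reps} vs treatment {t_reps}"
            )
        self.replicates = v_reps

    def fit(self) -> "SppShiftResults":
        cfg = self.config
        fc_v = scale_to_reference(self.vehicle)
        fc_t = scale_to_reference(self.treatment)
        if not np.allclose(fc_v.gradient, fc_t.gradient):
            raise ValueError("vehicle and treatment gradient designs differ")
        joint = FoldChangeMatrix(
            values={**fc_v.values, **fc_t.values},
            gradient=fc_v.gradient,
            unscalable={**fc_v.unscalable, **fc_t.unscalable},
        )
        joint, norm_model = _normalize(joint, cfg)
        fits = _fit_experiments(joint, cfg)

        v_cond = self.vehicle.experiments()[0][0]
        t_cond = self.treatment.experiments()[0][0]
        by = fits.set_index(["condition", "replicate", "protein"]).sort_index()

        proteins = self.vehicle.proteins.union(self.treatment.proteins)
        shifts = pd.DataFrame(index=proteins)
        shifts.index.name = "protein"
        for rep in self.replicates:
            cm_v = by.loc[(v_cond, rep)]["melting_point"].reindex(proteins)
            cm_t = by.loc[(t_cond, rep)]["melting_point"].reindex(proteins)
            sl_v = by.loc[(v_cond, rep)]["slope"].reindex(proteins)
            sl_t = by.loc[(t_cond, rep)]["slope"].reindex(proteins)
            q_v = by.loc[(v_cond, rep)]["quality_pass"].reindex(proteins).fillna(False)
            q_t = by.loc[(t_cond, rep)]["quality_pass"].reindex(proteins).fillna(False)
            ok = q_v.astype(bool) & q_t.astype(bool)
            delta = (cm_t - cm_v).where(ok)
            min_slope = pd.concat([sl_v, sl_t], axis=1).min(axis=1).where(ok)
            shifts[f"cm_vehicle_{rep}"] = cm_v
            shifts[f"cm_treatment_{rep}"] = cm_t
            shifts[f"delta_cm_{rep}"] = delta
            shifts[f"min_slope_{rep}"] = min_slope
            shifts[f"p_{rep}"] = shift_p_values(
                delta, min_slope, cfg.bin_size, cfg.min_valid_shifts
            )
            shifts[f"adj_p_{rep}"] = _bh_adjust(shifts[f"p_{rep}"])
            # stabilized past the gradient (or destabilized off it): one arm
            # fits well, the other has no assignable melting point
            shifts[f"inspect_{rep}"] = (q_v & cm_t.isna()) | (q_t & cm_v.isna())

        if len(self.replicates) >= 2:
            r1, r2 = self.replicates[:2]
            vv = (
                by.loc[(v_cond, r1)]["melting_point"].reindex(proteins)
                - by.loc[(v_cond, r2)]["melting_point"].reindex(proteins)
            )
            shifts["vehicle_vs_vehicle"] = vv
        else:
            log.info("single vehicle replicate: vehicle-vs-vehicle requirement skipped")

        pep = pd.concat(
            [self.vehicle.peptides.reindex(proteins),
             self.treatment.peptides.reindex(proteins)], axis=1
        ).min(axis=1)
        shifts["peptides"] = pep
        shifts = call_hits(shifts, self.replicates, cfg)
        return SppShiftResults(
            fits=fits, shifts=shifts, normalization=norm_model,
            replicates=self.replicates, config=cfg,
        )


@dataclass
class SppShiftResults:
    """Fitted shift analysis: per-curve fits, per-protein shifts, hits."""

    fits: pd.DataFrame
    shifts: pd.DataFrame
    normalization: object
    replicates: list[str]
    config: RunConfig

    @property
    def hits(self) -> pd.DataFrame:
        return self.shifts[self.shifts["is_hit"] == True]  # noqa: E712

    @property
    def inspect(self) -> pd.DataFrame:
        """Proteins with a well-fit arm but no melting point in the other
        (e.g. stabilized past the gradient) — for manual inspection."""
        cols = [f"inspect_{r}" for r in self.replicates]
        return self.shifts[self.shifts[cols].any(axis=1)]

    def summary(self) -> str:
        n_prot = len(self.shifts)
        lines = [
            "Melting-point shift analysis",
            f"  proteins quantified:      {n_prot}",
        ]
        for rep in self.replicates:
            n_valid = int(self.shifts[f"delta_cm_{rep}"].notna().sum())
            lines.append(f"  valid shifts, rep {rep}:   {n_valid}")
        q = self.fits.groupby(["condition", "replicate"])["quality_pass"].sum()
        for (cond, rep), n in q.items():
            lines.append(f"  high-quality curves {cond}/{rep}: {int(n)}")
        lines.append(f"  significant hits:         {len(self.hits)}")
        lines.append(f"  flagged for inspection:   {len(self.inspect)}")
        return "\n".join(lines)


def run_profiling(vehicle: QuantTable, treatment: QuantTable,
                  config: RunConfig | None = None) -> SppShiftResults:
    """Functional entry point: ``SppShiftModel(vehicle, treatment).fit()``."""
    return SppShiftModel(vehicle, treatment, config).fit()
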