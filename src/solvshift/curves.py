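"""Sigmoidal denaturation model shared by solvent (SPP) and thermal (TPP) profiling.

The soluble fraction of a protein exposed to an increasing denaturant
gradient x (%AEA v/v, or °C) is modelled as

    f(x) = (1 - Pl) / (1 + exp(-(a / x - b))) + Pl

where ``Pl`` is the bottom plateau (the denaturant-resistant soluble
fraction), and ``a``, ``b`` shape the transition.  For ``a > 0`` the curve
decreases from 1 (at x -> 0+) towards ``Pl + (1 - Pl) / (1 + e^b)``.  The
melting point C_M (or T_M) is the gradient value at which the fitted curve
crosses 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "SigmoidParams",
    "MeltCurveFit",
    "MeltCurveModel",
    "melt_model",
    "soluble_fraction",
    "melting_point",
    "melting_point_closed_form",
    "slope_at",
    "fit_melt_curve",
    "passes_quality",
    "SPP_START",
    "TPP_START",
    "SPP_ROOT_INTERVAL",
]


class SigmoidParams(NamedTuple):
    """Parameters of the sigmoid denaturation curve."""

    pl: float  # bottom plateau, dimensionless, expected in [0, 1)
    a: float  # scale, gradient units x shape
    b: float  # offset, dimensionless


#: Start values for solvent gradients (%AEA) and thermal gradients (°C).
SPP_START = SigmoidParams(pl=0.0, a=55.0, b=10.0)
TPP_START = SigmoidParams(pl=0.0, a=550.0, b=10.0)

#: Root-search interval for the solvent melting concentration, %AEA.
SPP_ROOT_INTERVAL = (3.0, 21.0)

# Optimiser bounds: plateau may overshoot 1 on noisy flat data, a and b are
# kept strictly positive so the curve is non-increasing in x.
_BOUNDS = ([0.0, 1e-8, 1e-8], [1.5, np.inf, np.inf])

# Fallback start values tried when the first fit does not converge.
_RETRY_A = (20.0, 120.0, 300.0, 550.0)
_RETRY_B = (5.0, 10.0, 15.0)


def melt_model(x, params: SigmoidParams):
    """Soluble fraction at gradient value(s) ``x > 0``.

    Raises ``ValueError`` for non-positive ``x``: the model has a pole at
    zero, and the gradient origin is the scaling reference, handled upstream.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("melt_model is undefined at gradient values <= 0")
    pl, a, b = params
    s = 1.0 / (1.0 + np.exp(np.clip(b - a / x, -700, 700)))
    out = pl + (1.0 - pl) * s
    return out if out.ndim else float(out)


def soluble_fraction(x, params: SigmoidParams):
    """Like :func:`melt_model` but maps the gradient origin to 1.

    At zero denaturant the soluble fraction is the scaling reference and
    equals 1 by definition; used when evaluating fitted curves on pooling
    windows that include the origin.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    pos = x > 0
    if np.any(pos):
        out[pos] = melt_model(x[pos], params)
    return out if out.ndim else float(out)


def slope_at(params: SigmoidParams, x: float) -> float:
    """Analytic derivative d f / d x of the melt curve at ``x > 0``.

    Negative for every ``x > 0`` when ``a > 0`` and ``Pl < 1``.
    """
    if x <= 0:
        raise ValueError("slope is undefined at gradient values <= 0")
    pl, a, b = params
    z = a / x - b
    # s(1-s) computed via exp(-|z|) to avoid cancellation in the tails
    ez = math.exp(-abs(z)) if abs(z) < 745 else 0.0
    ds = ez / (1.0 + ez) ** 2
    return -(1.0 - pl) * ds * a / (x * x)


def melting_point_closed_form(params: SigmoidParams) -> float | None:
    """Gradient value where the curve crosses 0.5, in closed form.

    Solving f(x) = 0.5 gives x = a / (b - ln(0.5 / (0.5 - Pl))).  Returns
    ``None`` when the curve never reaches 0.5 (``Pl >= 0.5``) or the root is
    non-positive.
    """
    pl, a, b = params
    if pl >= 0.5:
        return None
    denom = b - math.log(0.5 / (0.5 - pl))
    if denom <= 0:
        return None
    return a / denom


def melting_point(
    params: SigmoidParams,
    root_interval: tuple[float, float] = SPP_ROOT_INTERVAL,
) -> float | None:
    """Melting point found by bracketing root search on ``root_interval``.

    Mirrors the uniroot contract: ``None`` (an invalid melting point) when
    f - 0.5 does not change sign inside the interval; no extrapolation.
    """
    lo, hi = root_interval
    if not (0 < lo < hi):
        raise ValueError(f"invalid root interval {root_interval!r}")

    def g(x: float) -> float:
        return melt_model(x, params) - 0.5

    try:
        glo, ghi = g(lo), g(hi)
    except (OverflowError, FloatingPointError):  # pragma: no cover
        return None
    if not (np.isfinite(glo) and np.isfinite(ghi)) or glo * ghi > 0:
        return None
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


@dataclass(frozen=True)
class MeltCurveFit:
    """Result of fitting the sigmoid model to one protein's curve."""

    params: SigmoidParams
    r_squared: float
    plateau: float
    melting_point: float | None
    slope: float | None
    converged: bool
    quality_pass: bool
    n_points: int = 0

    @property
    def cm(self) -> float | None:
        """Alias for the melting concentration / temperature."""
        return self.melting_point


def passes_quality(
    fit: MeltCurveFit,
    r2_min: float = 0.8,
    plateau_max: float = 0.3,
) -> bool:
    """High-quality curve gate: R² > 0.8, plateau < 0.3, and a valid
    (present, finite, negative) slope and melting point."""
    return bool(
        fit.converged
        and fit.r_squared > r2_min
        and fit.plateau < plateau_max
        and fit.melting_point is not None
        and fit.slope is not None
        and np.isfinite(fit.slope)
        and fit.slope < 0
    )


def _residuals_and_jac(x: np.ndarray, y: np.ndarray):
    def resid(p):
        pl, a, b = p
        s = 1.0 / (1.0 + np.exp(np.clip(b - a / x, -700, 700)))
        return pl + (1.0 - pl) * s - y

    def jac(p):
        pl, a, b = p
        s = 1.0 / (1.0 + np.exp(np.clip(b - a / x, -700, 700)))
        ds = s * (1.0 - s)
        return np.column_stack(
            [1.0 - s, (1.0 - pl) * ds / x, -(1.0 - pl) * ds]
        )

    return resid, jac


_UNFIT = MeltCurveFit(
    params=SigmoidParams(np.nan, np.nan, np.nan),
    r_squared=np.nan,
    plateau=np.nan,
    melting_point=None,
    slope=None,
    converged=False,
    quality_pass=False,
)


class MeltCurveModel:
    """Sigmoid denaturation model for a single (gradient, abundance) series.

    Parameters
    ----------
    gradient : array-like
        Strictly positive, strictly increasing gradient values (%AEA or °C).
    values : array-like
        Relative soluble abundance at each gradient point (reference = 1).
        Non-finite entries are dropped pairwise.
    """

    MIN_POINTS = 5

    def __init__(self, gradient: Sequence[float], values: Sequence[float]):
        x = np.asarray(gradient, dtype=float)
        y = np.asarray(values, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("gradient and values must be equal-length 1-D")
        if np.any(x[np.isfinite(x)] <= 0):
            raise ValueError("gradient values must be positive; the origin "
                             "is the scaling reference, not a fitted point")
        keep = np.isfinite(x) & np.isfinite(y)
        self.x = x[keep]
        self.y = y[keep]

    @property
    def fittable(self) -> bool:
        return self.x.size >= self.MIN_POINTS

    def fit(
        self,
        start: SigmoidParams = SPP_START,
        root_interval: tuple[float, float] = SPP_ROOT_INTERVAL,
        r2_min: float = 0.8,
        plateau_max: float = 0.3,
    ) -> MeltCurveFit:
        """Bounded nonlinear least squares from ``start``, with a small
        retry grid over (a, b) on non-convergence.  Never raises on a bad
        curve: non-convergence is reported via ``converged=False``."""
        if not self.fittable:
            return MeltCurveFit(
                params=_UNFIT.params, r_squared=np.nan, plateau=np.nan,
                melting_point=None, slope=None, converged=False,
                quality_pass=False, n_points=int(self.x.size),
            )

        resid, jac = _residuals_and_jac(self.x, self.y)
        starts = [tuple(start)]
        starts += [(start.pl, a, b) for a in _RETRY_A for b in _RETRY_B]

        best = None
        for i, p0 in enumerate(starts):
            p0 = np.clip(p0, _BOUNDS[0], None)
            try:
                sol = optimize.least_squares(
                    resid, p0, jac=jac, bounds=_BOUNDS,
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=200,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
            if i == 0 and sol.success:
                break  # the recommended start converged; no retries needed

        if best is None or not best.success:
            return MeltCurveFit(
                params=_UNFIT.params, r_squared=np.nan, plateau=np.nan,
                melting_point=None, slope=None, converged=False,
                quality_pass=False, n_points=int(self.x.size),
            )

        params = SigmoidParams(*best.x)
        rss = float(2.0 * best.cost)
        tss = float(np.sum((self.y - self.y.mean()) ** 2))
        if tss > 0:
            r2 = 1.0 - rss / tss
        else:
            r2 = 1.0 if rss == 0 else 0.0

        mp = melting_point(params, root_interval)
        slope = slope_at(params, mp) if mp is not None else None

        fit = MeltCurveFit(
            params=params, r_squared=r2, plateau=float(params.pl),
            melting_point=mp, slope=slope, converged=True,
            quality_pass=False, n_points=int(self.x.size),
        )
        return replace(fit, quality_pass=passes_quality(fit, r2_min, plateau_max))


def fit_melt_curve(
    gradient: Sequence[float],
    values: Sequence[float],
    start: SigmoidParams = SPP_START,
    root_interval: tuple[float, float] = SPP_ROOT_INTERVAL,
    **quality_kwargs,
) -> MeltCurveFit:
    """Convenience wrapper: ``MeltCurveModel(gradient, values).fit(...)``."""
    return MeltCurveModel(gradient, values).fit(
        start=start, root_interval=root_interval, **quality_kwargs
    )
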