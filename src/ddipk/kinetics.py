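"""In vitro enzyme-kinetics analyses.

Michaelis-Menten fitting of substrate-velocity data by unweighted nonlinear
least squares, extra-sum-of-squares F-tests comparing two microsomal
preparations, single-concentration percent-of-control inhibition, and
first-order substrate-depletion (microsomal stability) kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InsufficientDataError, ValidationError
from .profiles import AssayTable


@dataclass(frozen=True)
class MMFitResult:
    """Michaelis-Menten estimates with Gauss-Newton standard errors.

    ``km`` in uM, ``vmax`` in the velocity unit of the input (pmol/min per mg
    protein for microsomal assays).
    """

    km: float
    vmax: float
    km_se: float
    vmax_se: float
    rss: float
    n_points: int
    converged: bool


def _mm_model(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


Weighting = Literal["none", "1/v", "1/v2"]


def _weights(v: np.ndarray, weighting: Weighting) -> np.ndarray:
    """Per-point weights from the observed velocities (fixed across model fits).

    ``1/v`` suits counting-type error, ``1/v2`` constant relative (CV) error;
    zero-velocity points get the weight of the smallest positive observation.
    """
    if weighting == "none":
        return np.ones_like(v)
    vpos = np.where(v > 0, v, np.min(v[v > 0], initial=1.0))
    if weighting == "1/v":
        return 1.0 / vpos
    if weighting == "1/v2":
        return 1.0 / vpos**2
    raise ValidationError(f"weighting must be 'none', '1/v' or '1/v2', got {weighting!r}")


def _default_starts(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Vmax0 = max observed V; Km0 = [S] at half Vmax0, linearly interpolated."""
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise FitError("all velocities are zero; nothing to fit")
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    half = vmax0 / 2.0
    km0 = float(np.interp(half, v_sorted, s_sorted)) if np.any(v_sorted >= half) else float(
        np.median(s_sorted)
    )
    if km0 <= 0:
        km0 = float(np.min(s_sorted[s_sorted > 0], initial=1.0))
    return vmax0, km0


def fit_michaelis_menten(
    assay: AssayTable,
    start: Optional[tuple[float, float]] = None,
    weighting: Weighting = "none",
) -> MMFitResult:
    """Least-squares fit of V = Vmax*[S]/(Km+[S]).

    Unweighted by default (the typical nonlinear-regression default);
    ``weighting="1/v"`` or ``"1/v2"`` applies the corresponding per-point
    weights for data whose error scales with the velocity.  ``start`` is an
    optional ``(vmax0, km0)`` pair; the default start uses the maximum
    observed velocity and the interpolated half-saturation substrate
    concentration.  Standard errors come from the Gauss-Newton covariance at
    the optimum.  Deterministic given data and starts.
    """
    s = assay.substrate_concentrations
    v = assay.velocities
    if assay.n_distinct_substrate < 4:
        raise ValidationError(
            f"need >= 4 distinct substrate concentrations, got {assay.n_distinct_substrate}"
        )
    p0 = start if start is not None else _default_starts(s, v)
    w = _weights(v, weighting)
    sigma = 1.0 / np.sqrt(w)
    try:
        popt, pcov = optimize.curve_fit(
            _mm_model, s, v, p0=p0, sigma=sigma, absolute_sigma=False,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Michaelis-Menten fit failed to converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    if not (km > 0 and vmax > 0):
        raise FitError(f"degenerate optimum: Km={km}, Vmax={vmax}")
    resid = v - _mm_model(s, vmax, km)
    rss = float(resid @ (w * resid))
    ses = np.sqrt(np.diag(pcov))
    return MMFitResult(
        km=km,
        vmax=vmax,
        km_se=float(ses[1]),
        vmax_se=float(ses[0]),
        rss=rss,
        n_points=len(s),
        converged=True,
    )


@dataclass(frozen=True)
class FTestResult:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    shared_preferred: bool  # True when the shared fit is not rejected at alpha
    alpha: float
    mode: str


def _shared_km_rss(
    s_a: np.ndarray, v_a: np.ndarray, s_b: np.ndarray, v_b: np.ndarray,
    p0: tuple[float, float, float], w_a: np.ndarray, w_b: np.ndarray,
) -> float:
    """Weighted RSS of the shared-Km, separate-Vmax joint fit."""

    sqw_a, sqw_b = np.sqrt(w_a), np.sqrt(w_b)

    def resid(p: np.ndarray) -> np.ndarray:
        vmax_a, vmax_b, km = p
        return np.concatenate(
            [
                sqw_a * (v_a - _mm_model(s_a, vmax_a, km)),
                sqw_b * (v_b - _mm_model(s_b, vmax_b, km)),
            ]
        )

    sol = optimize.least_squares(resid, x0=p0, bounds=([0, 0, 0], [np.inf] * 3))
    if not sol.success:
        raise FitError("shared-Km joint fit failed to converge")
    return float(2 * sol.cost)


def compare_fits_f_test(
    assay_a: AssayTable,
    assay_b: AssayTable,
    mode: Literal["both", "km"] = "both",
    alpha: float = 0.05,
    weighting: Weighting = "none",
) -> FTestResult:
    """Extra-sum-of-squares F-test: shared parameters vs separate per-assay fits.

    ``mode="both"`` constrains (Km, Vmax) jointly (one curve for the pooled
    data); ``mode="km"`` constrains Km only, allowing each preparation its own
    Vmax (expression level differs, affinity shared).  In both cases

        F = ((RSS_shared - RSS_sep) / d_df) / (RSS_sep / df_sep)

    with df_sep = n_total - 4.  Identical datasets give F = 0, p = 1.  The
    ``weighting`` choice applies to every fit in the comparison; match it to
    the error structure of the data (``"1/v2"`` for constant-CV error) for the
    test to hold its nominal level.
    """
    fit_a = fit_michaelis_menten(assay_a, weighting=weighting)
    fit_b = fit_michaelis_menten(assay_b, weighting=weighting)
    rss_sep = fit_a.rss + fit_b.rss
    s_a, v_a = assay_a.substrate_concentrations, assay_a.velocities
    s_b, v_b = assay_b.substrate_concentrations, assay_b.velocities
    n_total = len(s_a) + len(s_b)
    df_sep = n_total - 4
    if df_sep <= 0:
        raise InsufficientDataError("too few points for the separate-fits model")
    if mode == "both":
        pooled = AssayTable(np.concatenate([s_a, s_b]), np.concatenate([v_a, v_b]))
        rss_shared = fit_michaelis_menten(pooled, weighting=weighting).rss
        d_df = 2
    elif mode == "km":
        km0 = 0.5 * (fit_a.km + fit_b.km)
        rss_shared = _shared_km_rss(
            s_a, v_a, s_b, v_b, (fit_a.vmax, fit_b.vmax, km0),
            _weights(v_a, weighting), _weights(v_b, weighting),
        )
        d_df = 1
    else:
        raise ValidationError(f"mode must be 'both' or 'km', got {mode!r}")
    # numerical floor: shared model can never beat the separate fits
    extra = max(rss_shared - rss_sep, 0.0)
    if rss_sep == 0.0:
        f_stat = 0.0 if extra == 0.0 else math.inf
    else:
        f_stat = (extra / d_df) / (rss_sep / df_sep)
    p = float(stats.f.sf(f_stat, d_df, df_sep)) if math.isfinite(f_stat) else 0.0
    return FTestResult(
        f_statistic=float(f_stat),
        p_value=p,
        df_num=d_df,
        df_den=df_sep,
        shared_preferred=p >= alpha,
        alpha=alpha,
        mode=mode,
    )


def percent_of_control(activity_inhibited: float, activity_control: float) -> float:
    """Residual activity as percent of the uninhibited control: 100 * inhibited/control."""
    if not activity_control > 0:
        raise ValidationError(f"control activity must be positive, got {activity_control}")
    if activity_inhibited < 0:
        raise ValidationError(f"inhibited activity must be >= 0, got {activity_inhibited}")
    return 100.0 * activity_inhibited / activity_control


@dataclass(frozen=True)
class DepletionResult:
    k_dep: Optional[float]  # 1/min; None when the profile shows no depletion
    half_life: Optional[float]  # min
    slope: float  # raw ln(C/C0)-vs-t slope (diagnostic, any sign)
    stable: bool


def depletion_half_life(times: np.ndarray, concentrations: np.ndarray) -> DepletionResult:
    """First-order substrate depletion: k_dep = -slope of ln(C/C0) vs t.

    A non-negative slope means no measurable depletion (e.g. the no-NADPH
    control); the result is then flagged ``stable`` with no k_dep/half-life.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 3 or len(c) != len(t):
        raise InsufficientDataError("need >= 3 aligned (time, concentration) points")
    if np.any(c <= 0):
        raise ValidationError("depletion concentrations must be positive")
    y = np.log(c / c[0])
    A = np.column_stack([t, np.ones(len(t))])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    if slope >= 0:
        return DepletionResult(k_dep=None, half_life=None, slope=slope, stable=True)
    k = -slope
    return DepletionResult(k_dep=k, half_life=math.log(2) / k, slope=slope, stable=False)
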