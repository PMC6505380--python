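"""Noncompartmental analysis (NCA) of sparse concentration-time profiles.

Implements the classic model-free parameter set — C_max/T_max, AUC to the last
observation (linear trapezoid), terminal elimination rate constant lambda_z by
best-adjusted-R^2 log-linear regression, AUC extrapolated to infinity,
terminal half-life and apparent oral clearance CL/F — plus group AUC ratios.

BLQ policy: a leading BLQ sample (before the first quantifiable concentration)
is imputed as 0 at its nominal time; trailing or embedded BLQ samples are
dropped from both the AUC and the lambda_z regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, TerminalPhaseError, ValidationError
from .profiles import ConcentrationTimeProfile, _UNIT_TO_NG_ML, normalize_unit


@dataclass(frozen=True)
class NCAResult:
    """Noncompartmental parameter set for one profile.

    Concentration-bearing quantities (c_max, auc_all, auc_inf) are in the
    profile's concentration unit; cl_over_f is in ml/h per kg regardless of
    that unit.  ``auc_inf``, ``lambda_z``, ``terminal_half_life`` and
    ``cl_over_f`` are ``None`` when the terminal phase could not be
    characterised (AUC_all remains valid).
    """

    subject_id: str
    analyte: str
    group: str
    conc_unit: str
    c_max: float
    t_max: float
    auc_all: float
    auc_inf: Optional[float]
    lambda_z: Optional[float]
    terminal_half_life: Optional[float]
    cl_over_f: Optional[float]
    n_lambda_points: Optional[int]
    lambda_fit_r2adj: Optional[float]


def _usable_samples(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ policy; return (times, concentrations) of usable samples."""
    t = profile.times
    c = profile.concentrations.copy()
    blq = profile.blq_flags
    quant = np.flatnonzero(~blq)
    if quant.size == 0:
        return np.empty(0), np.empty(0)
    first_quant = quant[0]
    keep = ~blq
    # leading BLQ -> zero at the nominal time
    leading = np.arange(len(t)) < first_quant
    c[leading & blq] = 0.0
    keep |= leading
    return t[keep], c[keep]


def auc_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """AUC from the first to the last usable sample by the linear trapezoid rule."""
    t, c = _usable_samples(profile)
    if len(t) < 2:
        raise InsufficientDataError(
            f"need >= 2 usable samples for AUC, got {len(t)} "
            f"(subject {profile.subject_id!r})"
        )
    return float(np.trapezoid(c, t))


def _loglinear_ols(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(C) on t; returns (slope, intercept, adjusted R^2)."""
    n = len(t)
    A = np.column_stack([t, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, logc, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = logc - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, intercept, r2adj


def fit_lambda_z(
    profile: ConcentrationTimeProfile, min_points: int = 3
) -> tuple[float, float, int]:
    """Terminal elimination rate constant by best-window log-linear regression.

    Candidate windows are the last k usable positive-concentration samples for
    k = ``min_points`` up to all samples strictly after T_max (C_max itself is
    excluded).  The window maximising adjusted R^2 wins, ties broken toward
    more points; lambda_z = -slope must be positive.

    Returns ``(lambda_z, r2_adjusted, n_points)``; raises
    :class:`TerminalPhaseError` when no window gives a positive lambda_z.
    """
    if min_points < 3:
        raise ValidationError("min_points must be >= 3")
    t, c = _usable_samples(profile)
    pos = c > 0
    tp, cp = t[pos], c[pos]
    if len(tp) == 0:
        raise TerminalPhaseError("no positive concentrations for terminal fit")
    i_max = int(np.argmax(cp))  # earliest maximum (argmax takes the first)
    t_after = tp[i_max + 1 :]
    c_after = cp[i_max + 1 :]
    n_avail = len(t_after)
    if n_avail < min_points:
        raise TerminalPhaseError(
            f"need >= {min_points} post-T_max positive samples, have {n_avail}"
        )
    logc = np.log(c_after)
    best: Optional[tuple[float, int, float]] = None  # (r2adj, k, lambda_z)
    for k in range(min_points, n_avail + 1):
        slope, _, r2adj = _loglinear_ols(t_after[-k:], logc[-k:])
        lam = -slope
        if lam <= 0:
            continue
        # ties broken toward more points: >= keeps the larger window
        if best is None or r2adj >= best[0]:
            best = (r2adj, k, lam)
    if best is None:
        raise TerminalPhaseError("no terminal window with positive lambda_z")
    r2adj, k, lam = best
    return lam, r2adj, k


def auc_to_infinity(
    profile: ConcentrationTimeProfile, min_points: int = 3
) -> float:
    """AUC extrapolated to infinity: AUC_all + C_last / lambda_z.

    C_last is the last usable observed concentration; when it is 0 the
    extrapolated tail vanishes and AUC_inf equals AUC_all.
    """
    lam, _, _ = fit_lambda_z(profile, min_points=min_points)
    auc_all = auc_trapezoid(profile)
    _, c = _usable_samples(profile)
    return auc_all + float(c[-1]) / lam


def cl_over_f(dose: float, auc_inf: float, conc_unit: str = "ug/ml") -> float:
    """Apparent oral clearance CL/F in ml/h per kg.

    ``dose`` is in mg/kg; ``auc_inf`` in h * ``conc_unit``.  The dose is
    expressed in the mass unit of the concentration so the result is
    unit-consistent: 10 mg/kg over 76 h*ug/ml gives 10000/76 = 132 ml/h/kg.
    """
    if not (dose > 0 and auc_inf > 0):
        raise ValidationError(f"dose and AUC_inf must be positive, got {dose}, {auc_inf}")
    # mg/kg -> (unit mass)/kg: ug/ml -> x1e3, ng/ml -> x1e6
    dose_in_conc_mass = dose * 1e6 / _UNIT_TO_NG_ML[normalize_unit(conc_unit)]
    return dose_in_conc_mass / auc_inf


def group_aucr(treated: Sequence[float], control: Sequence[float]) -> float:
    """Group AUC ratio: arithmetic mean(treated) / arithmetic mean(control)."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if np.any(treated <= 0) or np.any(control <= 0):
        raise ValidationError("all AUC values must be positive")
    return float(treated.mean() / control.mean())


def run_nca(
    profile: ConcentrationTimeProfile, min_points: int = 3
) -> NCAResult:
    """Full NCA of one profile; terminal-phase parameters are None if undefined."""
    t, c = _usable_samples(profile)
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 usable samples")
    i_max = int(np.argmax(c))  # earliest time wins on ties
    auc_all = auc_trapezoid(profile)
    lam = half_life = auc_inf = clf = r2adj = n_pts = None
    try:
        lam, r2adj, n_pts = fit_lambda_z(profile, min_points=min_points)
    except (TerminalPhaseError, InsufficientDataError):
        pass
    if lam is not None:
        half_life = math.log(2) / lam
        auc_inf = auc_all + float(c[-1]) / lam
        if auc_inf > 0:
            clf = cl_over_f(profile.dose, auc_inf, conc_unit=profile.conc_unit)
    return NCAResult(
        subject_id=profile.subject_id,
        analyte=profile.analyte,
        group=profile.group,
        conc_unit=profile.conc_unit,
        c_max=float(c[i_max]),
        t_max=float(t[i_max]),
        auc_all=auc_all,
        auc_inf=auc_inf,
        lambda_z=lam,
        terminal_half_life=half_life,
        cl_over_f=clf,
        n_lambda_points=n_pts,
        lambda_fit_r2adj=r2adj,
    )
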