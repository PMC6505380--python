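"""Synthetic PK cohorts and enzyme-assay data with known ground truth.

The in vivo generator draws from a one-compartment oral-absorption model

    C(t) = D * (F/V) * ka/(ka - ke) * (exp(-ke*t) - exp(-ka*t))

with first-order absorption ka and elimination ke, multiplicative lognormal
residual noise (concentrations positive by construction), and lognormal
inter-subject variability on ke and F/V.  Drug-drug-interaction cohorts scale
the treated arm's elimination by the static-model clearance factor
(1 - f_m) + f_m/(1 + [I]/Ki) for inhibition, or (1 - f_m) + f_m*fold for
induction, so the expected AUC ratio is analytically known.  All generators
are reproducible bit-for-bit for a fixed seed (per-subject substreams are
spawned deterministically from the single cohort seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .profiles import AssayTable, ConcentrationTimeProfile, _UNIT_TO_NG_ML, normalize_unit

#: sparse oral sampling design typical of a 24 h small-animal PK study
DEFAULT_SAMPLING_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


def _lognormal_sigma(cv: float) -> float:
    """Log-scale sigma giving the requested coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Median-unbiased multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, _lognormal_sigma(cv), size=n))


@dataclass(frozen=True)
class OralPKParams:
    """Ground-truth parameters for one simulated oral profile.

    ``f_over_v`` is bioavailability over apparent volume of distribution in
    1/(ml/kg); with dose in mg/kg the concentration scale is
    dose * F/V (converted to ``conc_unit``).  ``ka`` and ``ke`` are first-order
    rate constants in 1/h; flip-flop kinetics (ka < ke) are permitted and the
    ka = ke degeneracy uses the analytic limit D*(F/V)*ka*t*exp(-ka*t).
    """

    dose: float = 10.0  # mg/kg
    f_over_v: float = 1e-3  # 1/(ml/kg): F/V with V/F = 1000 ml/kg
    ka: float = 3.0  # 1/h
    ke: float = 0.4  # 1/h
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES
    noise_cv: float = 0.0
    seed: int = 0
    conc_unit: str = "ng/ml"

    def __post_init__(self) -> None:
        if not (self.dose > 0 and self.f_over_v > 0 and self.ka > 0 and self.ke > 0):
            raise ValidationError("dose, F/V, ka and ke must all be positive")
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        object.__setattr__(self, "conc_unit", normalize_unit(self.conc_unit))

    @property
    def concentration_scale(self) -> float:
        """dose * F/V expressed in ``conc_unit`` (the hypothetical C at t=0 iv-like)."""
        dose_unit_per_kg = self.dose * 1e6 / _UNIT_TO_NG_ML[self.conc_unit]
        return dose_unit_per_kg * self.f_over_v

    def analytic_auc_inf(self) -> float:
        """Closed-form oral AUC to infinity: D*(F/V)/ke, in h * conc_unit."""
        return self.concentration_scale / self.ke

    def curve(self, times: np.ndarray) -> np.ndarray:
        """Noise-free concentration-time curve at the given times."""
        t = np.asarray(times, dtype=float)
        scale = self.concentration_scale
        if math.isclose(self.ka, self.ke, rel_tol=1e-12):
            return scale * self.ka * t * np.exp(-self.ka * t)
        return (
            scale
            * self.ka
            / (self.ka - self.ke)
            * (np.exp(-self.ke * t) - np.exp(-self.ka * t))
        )


@dataclass(frozen=True)
class DDICohortSpec:
    """Paired control/treated cohort specification.

    Exactly one of ``i_over_ki`` (reversible inhibition arm) or
    ``induction_fold`` (enzyme-induction arm, fold >= 1) must be set; the
    treated arm's elimination rate is scaled by the corresponding static-model
    clearance factor.  ``inter_subject_cv`` applies lognormally to each
    subject's ke and F/V.
    """

    base: OralPKParams = field(default_factory=OralPKParams)
    f_m: float = 0.9
    i_over_ki: Optional[float] = None
    induction_fold: Optional[float] = None
    n_per_group: int = 4
    inter_subject_cv: float = 0.1

    def __post_init__(self) -> None:
        if (self.i_over_ki is None) == (self.induction_fold is None):
            raise ValidationError(
                "exactly one of i_over_ki / induction_fold must be set"
            )
        if not 0 <= self.f_m <= 1:
            raise ValidationError(f"f_m must be in [0, 1], got {self.f_m}")
        if self.i_over_ki is not None and self.i_over_ki < 0:
            raise ValidationError("i_over_ki must be >= 0")
        if self.induction_fold is not None and self.induction_fold < 1:
            raise ValidationError("induction_fold must be >= 1")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.inter_subject_cv < 0:
            raise ValidationError("inter_subject_cv must be >= 0")

    @property
    def clearance_factor(self) -> float:
        """Multiplier on ke in the treated arm (the static-model CL' / CL)."""
        if self.i_over_ki is not None:
            return (1.0 - self.f_m) + self.f_m / (1.0 + self.i_over_ki)
        return (1.0 - self.f_m) + self.f_m * self.induction_fold

    def expected_aucr(self) -> float:
        """Analytic treated/control AUC ratio: 1 / clearance_factor."""
        return 1.0 / self.clearance_factor


def _simulate_with_rng(
    params: OralPKParams,
    rng: np.random.Generator,
    subject_id: str,
    group: str,
    analyte: str,
) -> ConcentrationTimeProfile:
    t = np.asarray(params.sampling_times, dtype=float)
    conc = params.curve(t) * _noise_factors(rng, params.noise_cv, len(t))
    return ConcentrationTimeProfile(
        subject_id=subject_id,
        analyte=analyte,
        group=group,
        dose=params.dose,
        route="oral",
        times=t,
        concentrations=conc,
        conc_unit=params.conc_unit,
        blq_flags=np.zeros(len(t), dtype=bool),
    )


def simulate_profile(
    params: OralPKParams,
    subject_id: str = "S1",
    group: str = "vehicle",
    analyte: str = "probe",
) -> ConcentrationTimeProfile:
    """One noisy oral profile; same seed gives an identical profile."""
    rng = np.random.default_rng(params.seed)
    return _simulate_with_rng(params, rng, subject_id, group, analyte)


def simulate_ddi_cohorts(
    spec: DDICohortSpec,
) -> tuple[list[ConcentrationTimeProfile], list[ConcentrationTimeProfile]]:
    """Paired (control, treated) cohorts with inter-subject variability.

    Each subject gets a deterministic substream spawned from the cohort seed;
    subject-level ke and F/V are lognormally perturbed, and the treated arm's
    ke is additionally multiplied by the static-model clearance factor.
    """
    from dataclasses import replace

    children = np.random.SeedSequence(spec.base.seed).spawn(2 * spec.n_per_group)
    cf = spec.clearance_factor
    sigma = _lognormal_sigma(spec.inter_subject_cv)
    arms: dict[str, list[ConcentrationTimeProfile]] = {"control": [], "treated": []}
    for arm_idx, arm in enumerate(("control", "treated")):
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(children[arm_idx * spec.n_per_group + i])
            ke_mult, fv_mult = (
                np.exp(rng.normal(0.0, sigma, size=2)) if sigma > 0 else (1.0, 1.0)
            )
            subj = replace(
                spec.base,
                ke=spec.base.ke * ke_mult * (cf if arm == "treated" else 1.0),
                f_over_v=spec.base.f_over_v * fv_mult,
            )
            arms[arm].append(
                _simulate_with_rng(
                    subj, rng, subject_id=f"{arm[:3].upper()}{i + 1}", group=arm,
                    analyte="probe",
                )
            )
    return arms["control"], arms["treated"]


def simulate_mm_assay(
    km: float,
    vmax: float,
    s_grid: Sequence[float],
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> AssayTable:
    """Michaelis-Menten assay table: V = Vmax*S/(Km+S) with lognormal noise."""
    if not (km > 0 and vmax > 0):
        raise ValidationError("km and vmax must be positive")
    s = np.asarray(s_grid, dtype=float)
    if s.size == 0:
        raise ValidationError("substrate grid must be non-empty")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    s_all = np.tile(s, n_replicates)
    rep = np.repeat(np.arange(n_replicates), len(s))
    v = vmax * s_all / (km + s_all) * _noise_factors(rng, noise_cv, len(s_all))
    return AssayTable(substrate_concentrations=s_all, velocities=v, replicates=rep)
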