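"""Static reverse-inhibition drug-drug-interaction (DDI) algebra.

The victim drug's exposure ratio under a reversibly inhibiting perpetrator is

    AUCR = 1 / [ (1 - f_m) + f_m / (1 + [I]/K_i) ]

where f_m is the fraction of victim clearance carried by the inhibited enzyme
and [I]/K_i the dimensionless inhibitor potency.  The module provides the
forward model, its exact rearrangement solving for [I]/K_i, the
complete-inhibition limit f_m = 1 - 1/AUCR (equivalently the extensive- vs
poor-metabolizer genotype ratio), and the translational chain that calibrates
[I]/K_i on one victim drug and predicts the AUCR of another sharing the
enzyme.  All computation is unrounded internally; ``round_paper_style``
provides the conventional presentation rounding (f_m two decimals, [I]/K_i
nearest integer, AUCR two decimals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasibleAUCRError, NoInteractionError, ValidationError


def aucr_forward(f_m: float, i_over_ki: float) -> float:
    """AUC ratio from fraction metabolized and inhibitor potency.

    Strictly increasing in both arguments; 1 at f_m = 0 or [I]/Ki = 0;
    approaches the ceiling 1/(1 - f_m) as [I]/Ki -> inf (inf when f_m = 1).
    """
    if not 0 <= f_m <= 1:
        raise ValidationError(f"f_m must be in [0, 1], got {f_m}")
    if not (i_over_ki >= 0 or math.isinf(i_over_ki)):
        raise ValidationError(f"[I]/Ki must be >= 0, got {i_over_ki}")
    if math.isinf(i_over_ki):
        return math.inf if f_m == 1 else 1.0 / (1.0 - f_m)
    denom = (1.0 - f_m) + f_m / (1.0 + i_over_ki)
    if denom == 0.0:
        return math.inf
    return 1.0 / denom


def iki_from_aucr(aucr: float, f_m: float) -> float:
    """Back-solve [I]/Ki from an observed AUC ratio and a known f_m.

    Exact rearrangement of the forward model:
    [I]/Ki = f_m / (1/AUCR - (1 - f_m)) - 1.

    Raises :class:`NoInteractionError` for AUCR <= 1 and
    :class:`InfeasibleAUCRError` when AUCR reaches the complete-inhibition
    ceiling 1/(1 - f_m) for the given f_m.
    """
    if not 0 < f_m <= 1:
        raise ValidationError(f"f_m must be in (0, 1], got {f_m}")
    if aucr <= 1:
        raise NoInteractionError(f"AUCR must exceed 1 to back-solve a potency, got {aucr}")
    ceiling = math.inf if f_m == 1 else 1.0 / (1.0 - f_m)
    if aucr >= ceiling:
        raise InfeasibleAUCRError(
            f"AUCR {aucr} exceeds complete-inhibition ceiling {ceiling:.4g} for f_m {f_m}"
        )
    return f_m / (1.0 / aucr - (1.0 - f_m)) - 1.0


def fm_from_complete_inhibition(aucr: float) -> float:
    """Fraction metabolized from an AUCR under complete inhibition (or EM/PM ratio).

    The [I]/Ki -> inf limit of the forward model: f_m = 1 - 1/AUCR.
    """
    if aucr < 1:
        raise ValidationError(f"AUCR must be >= 1, got {aucr}")
    return 1.0 - 1.0 / aucr


@dataclass(frozen=True)
class TranslatedPrediction:
    """Result of the calibration -> prediction chain, with intermediates."""

    i_over_ki: float          # back-solved potency, unrounded
    i_over_ki_used: float     # value fed into the forward model (maybe rounded)
    predicted_aucr: float


def translate_prediction(
    f_m_cal: float,
    aucr_cal: float,
    victim_f_m: float,
    round_intermediate: bool = False,
) -> TranslatedPrediction:
    """Predict a victim drug's AUCR from a calibration interaction on the same enzyme.

    Back-solves [I]/Ki from ``(f_m_cal, aucr_cal)`` and applies it forward with
    ``victim_f_m``.  With ``round_intermediate=True`` the potency is rounded to
    the nearest integer before the forward step — the conventional hand
    calculation (e.g. potency 21 and victim f_m 0.94 give a predicted 9.73-fold).
    """
    if not 0 <= victim_f_m <= 1:
        raise ValidationError(f"victim f_m must be in [0, 1], got {victim_f_m}")
    if aucr_cal == 1:
        return TranslatedPrediction(0.0, 0.0, 1.0)
    iki = iki_from_aucr(aucr_cal, f_m_cal)
    iki_used = float(round(iki)) if round_intermediate else iki
    return TranslatedPrediction(iki, iki_used, aucr_forward(victim_f_m, iki_used))


def round_paper_style(value: float, kind: str) -> float:
    """Presentation rounding: ``fm`` -> 2 dp, ``iki`` -> nearest int, ``aucr`` -> 2 dp."""
    if kind == "fm":
        return round(value, 2)
    if kind == "iki":
        return float(round(value))
    if kind == "aucr":
        return round(value, 2)
    raise ValidationError(f"unknown rounding kind {kind!r}")
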