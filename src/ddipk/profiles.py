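"""Concentration-time profiles, assay tables and their delimited-text I/O.

The canonical on-disk layout is a flat CSV, one blood sample per row, with
columns ``subject_id, analyte, group, dose_mg_per_kg, route, time_h, conc,
conc_unit, blq``.  A flat layout covers cassette dosing (several analytes per
subject in one file).  Below-limit-of-quantification (BLQ) samples carry the
token ``BLQ`` in the ``conc`` column (and/or a truthy ``blq`` column) and no
numeric value; the downstream handling policy lives in :mod:`ddipk.nca`.

Concentration units are ``ng/ml`` or ``ug/ml`` (``µg``/``μg`` spellings are
accepted) and converted exactly by the factor 1000 on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ROUTES = ("oral", "intraperitoneal")

#: exact scale factors to ng/ml
_UNIT_TO_NG_ML = {"ng/ml": 1.0, "ug/ml": 1000.0}

REQUIRED_COLUMNS = (
    "subject_id",
    "analyte",
    "group",
    "dose_mg_per_kg",
    "route",
    "time_h",
    "conc",
    "conc_unit",
    "blq",
)


def normalize_unit(unit: str) -> str:
    """Map unit spellings (``µg/ml``, ``μg/ml``, case variants) to canonical form."""
    u = unit.strip().lower().replace("µ", "u").replace("μ", "u")
    if u not in _UNIT_TO_NG_ML:
        raise ValidationError(f"unknown concentration unit {unit!r}; expected ng/ml or ug/ml")
    return u


def convert_concentration(values: np.ndarray, from_unit: str, to_unit: str) -> np.ndarray:
    """Exact unit scaling: 1 ug/ml = 1000 ng/ml."""
    factor = _UNIT_TO_NG_ML[normalize_unit(from_unit)] / _UNIT_TO_NG_ML[normalize_unit(to_unit)]
    return values * factor


@dataclass(frozen=True, eq=False)
class ConcentrationTimeProfile:
    """One subject x analyte sparse blood-sampling record with dose metadata.

    Parameters
    ----------
    subject_id, analyte, group
        Free-text labels (e.g. ``"M1"``, ``"midazolam"``, ``"vehicle"``).
    dose
        Administered dose in mg per kg body weight; must be positive.
    route
        ``"oral"`` or ``"intraperitoneal"``.
    times
        Sampling times in hours, strictly increasing, all non-negative.
    concentrations
        Measured concentrations in ``conc_unit``; ``nan`` at BLQ samples.
    conc_unit
        ``"ng/ml"`` or ``"ug/ml"``.
    blq_flags
        Boolean per-sample below-limit-of-quantification markers.
    """

    subject_id: str
    analyte: str
    group: str
    dose: float
    route: str
    times: np.ndarray
    concentrations: np.ndarray
    conc_unit: str = "ng/ml"
    blq_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        blq = (
            np.zeros(t.shape, dtype=bool)
            if self.blq_flags is None
            else np.asarray(self.blq_flags, dtype=bool)
        )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "blq_flags", blq)
        object.__setattr__(self, "conc_unit", normalize_unit(self.conc_unit))
        if self.route not in ROUTES:
            raise ValidationError(f"route must be one of {ROUTES}, got {self.route!r}")
        if t.ndim != 1 or len(t) < 2 or len(c) != len(t) or len(blq) != len(t):
            raise ValidationError(
                f"times/concentrations/blq_flags must be equal-length 1-d with >= 2 samples "
                f"(subject {self.subject_id!r}, analyte {self.analyte!r})"
            )
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"times must be strictly increasing and >= 0 (subject {self.subject_id!r})"
            )
        quantified = ~blq
        if np.any(np.isnan(c[quantified])) or np.any(c[quantified] < 0):
            raise ValidationError(
                f"non-BLQ concentrations must be numeric and >= 0 (subject {self.subject_id!r})"
            )
        if not self.dose > 0:
            raise ValidationError(f"dose must be positive, got {self.dose}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationTimeProfile):
            return NotImplemented
        return (
            (self.subject_id, self.analyte, self.group, self.route, self.conc_unit)
            == (other.subject_id, other.analyte, other.group, other.route, other.conc_unit)
            and self.dose == other.dose
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.concentrations, other.concentrations, equal_nan=True)
            and np.array_equal(self.blq_flags, other.blq_flags)
        )

    def to_unit(self, unit: str) -> "ConcentrationTimeProfile":
        """Return a copy with concentrations expressed in ``unit`` (exact x1000 scaling)."""
        unit = normalize_unit(unit)
        if unit == self.conc_unit:
            return self
        conc = convert_concentration(self.concentrations, self.conc_unit, unit)
        return replace(self, concentrations=conc, conc_unit=unit)


@dataclass(frozen=True, eq=False)
class AssayTable:
    """Substrate-concentration vs velocity table for enzyme-kinetics fitting.

    ``substrate_concentrations`` in uM, ``velocities`` in pmol/min per mg
    protein; ``replicates`` is the replicate index per row.  At least 4
    distinct substrate concentrations are required for a Michaelis-Menten fit.
    """

    substrate_concentrations: np.ndarray
    velocities: np.ndarray
    replicates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_concentrations, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        rep = (
            np.zeros(s.shape, dtype=int)
            if self.replicates is None
            else np.asarray(self.replicates, dtype=int)
        )
        object.__setattr__(self, "substrate_concentrations", s)
        object.__setattr__(self, "velocities", v)
        object.__setattr__(self, "replicates", rep)
        if len(v) != len(s) or len(rep) != len(s):
            raise ValidationError("substrate, velocity and replicate columns must align")
        if np.any(s < 0) or np.any(v < 0):
            raise ValidationError("substrate concentrations and velocities must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssayTable):
            return NotImplemented
        return (
            np.array_equal(self.substrate_concentrations, other.substrate_concentrations)
            and np.array_equal(self.velocities, other.velocities)
            and np.array_equal(self.replicates, other.replicates)
        )

    @property
    def n_distinct_substrate(self) -> int:
        return len(np.unique(self.substrate_concentrations))


def _is_blq_token(value: object) -> bool:
    return isinstance(value, str) and value.strip().upper() == "BLQ"


def read_profiles(path: str | Path, unit_policy: str = "ng/ml") -> list[ConcentrationTimeProfile]:
    """Read a profile CSV, returning one profile per (subject, analyte).

    Concentrations are converted to ``unit_policy``; rows are sorted by time
    within each profile.  Raises :class:`FormatError` for a missing column and
    :class:`ValidationError` (with the offending row number) for negative
    times/concentrations or duplicate (subject, analyte, time) samples.
    """
    unit_policy = normalize_unit(unit_policy)
    df = pd.read_csv(path, dtype={"conc": str, "blq": str}, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    times = pd.to_numeric(df["time_h"], errors="coerce")
    blq = df["blq"].str.strip().str.lower().isin({"1", "true", "yes", "blq"})
    blq |= df["conc"].map(_is_blq_token)
    conc = pd.to_numeric(df["conc"].where(~blq, other=np.nan), errors="coerce")

    for idx in df.index:
        row_no = idx + 2  # header is row 1
        if np.isnan(times[idx]) or times[idx] < 0:
            raise ValidationError(f"row {row_no}: invalid or negative time {df['time_h'][idx]!r}")
        if not blq[idx] and (np.isnan(conc[idx]) or conc[idx] < 0):
            raise ValidationError(
                f"row {row_no}: invalid or negative concentration {df['conc'][idx]!r}"
            )

    dup = df.assign(_t=times).duplicated(subset=["subject_id", "analyte", "_t"], keep=False)
    if dup.any():
        first = dup.idxmax() + 2
        raise ValidationError(f"row {first}: duplicate (subject, analyte, time) sample")

    work = df.assign(_t=times, _c=conc, _blq=blq)
    profiles: list[ConcentrationTimeProfile] = []
    for (subject, analyte), grp in work.groupby(["subject_id", "analyte"], sort=True):
        grp = grp.sort_values("_t")
        units = grp["conc_unit"].map(normalize_unit).to_numpy()
        values = grp["_c"].to_numpy(dtype=float)
        scaled = np.array(
            [
                convert_concentration(np.array([v]), u, unit_policy)[0]
                for v, u in zip(values, units)
            ]
        )
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(subject),
                analyte=str(analyte),
                group=str(grp["group"].iloc[0]),
                dose=float(grp["dose_mg_per_kg"].iloc[0]),
                route=str(grp["route"].iloc[0]),
                times=grp["_t"].to_numpy(dtype=float),
                concentrations=scaled,
                conc_unit=unit_policy,
                blq_flags=grp["_blq"].to_numpy(dtype=bool),
            )
        )
    return profiles


def write_profiles(profiles: Iterable[ConcentrationTimeProfile], path: str | Path) -> None:
    """Write profiles as the flat CSV layout; BLQ samples emit the ``BLQ`` token.

    Round-trip contract: ``read_profiles(write_profiles(x)) == x`` field for field
    (given a common concentration unit).
    """
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.blq_flags):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "analyte": p.analyte,
                    "group": p.group,
                    "dose_mg_per_kg": p.dose,
                    "route": p.route,
                    "time_h": t,
                    "conc": "BLQ" if b else repr(float(c)),
                    "conc_unit": p.conc_unit,
                    "blq": int(bool(b)),
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def read_assay_table(path: str | Path) -> AssayTable:
    """Read an enzyme-assay CSV with columns ``substrate_um, velocity[, replicate]``."""
    df = pd.read_csv(path)
    for col in ("substrate_um", "velocity"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return AssayTable(
        substrate_concentrations=df["substrate_um"].to_numpy(dtype=float),
        velocities=df["velocity"].to_numpy(dtype=float),
        replicates=rep,
    )


def write_assay_table(table: AssayTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "substrate_um": table.substrate_concentrations,
            "velocity": table.velocities,
            "replicate": table.replicates,
        }
    ).to_csv(path, index=False)


def profiles_to_records(profiles: Sequence[ConcentrationTimeProfile]) -> list[dict]:
    """JSON-serializable export of validated profiles (used by the CLI)."""
    out = []
    for p in profiles:
        out.append(
            {
                "subject_id": p.subject_id,
                "analyte": p.analyte,
                "group": p.group,
                "dose_mg_per_kg": p.dose,
                "route": p.route,
                "conc_unit": p.conc_unit,
                "times_h": p.times.tolist(),
                "concentrations": [None if b else float(c) for c, b in zip(p.concentrations, p.blq_flags)],
                "blq_flags": p.blq_flags.astype(bool).tolist(),
            }
        )
    return out
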