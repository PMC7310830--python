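"""Raw anthropometry to analysis-ready variables.

Replicate measurements (two height, two weight, two MUAC readings per
subject, with an optional repeat MUAC pair) are averaged, BMI is derived,
BMI-for-age z-scores are computed against an LMS growth reference, and
subjects are classified as overweight (including obesity, z > +1 SD) or
obese (z > +2 SD) under the WHO school-age convention.

The z-score uses the LMS (Box-Cox power ``L``, median ``M``, coefficient
of variation ``S``) parameterization

    z = ((x / M)**L - 1) / (L * S)          (L != 0)
    z = ln(x / M) / S                        (L == 0)

with the WHO restricted tail: beyond +/-3 the raw z is replaced by a
linear extrapolation in measurement units so extreme BMIs stay finite
and comparable across references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FlaggedRecordError, ValidationError

#: Columns of the subject CSV dialect, in canonical order.
SUBJECT_COLUMNS = [
    "id", "sex", "age_years",
    "height1_cm", "height2_cm",
    "weight1_kg", "weight2_kg",
    "muac1_cm", "muac2_cm",
    "muac_repeat1_cm", "muac_repeat2_cm",
    "bmi_z",
]

#: Default repeat threshold for MUAC replicates, cm.
DEFAULT_REPEAT_THRESHOLD_CM = 0.5

VALID_SEXES = ("male", "female")


@dataclass(frozen=True)
class ReplicatePair:
    """Two replicate readings of the same quantity in the same unit,
    with an optional repeat pair taken when the first two disagreed."""

    first: float
    second: float
    repeat_pair: Optional["ReplicatePair"] = None

    def __post_init__(self):
        if not (self.first > 0 and self.second > 0):
            raise ValidationError(
                f"replicate readings must be strictly positive, got "
                f"({self.first}, {self.second})"
            )

    @property
    def difference(self) -> float:
        return abs(self.first - self.second)

    @property
    def mean(self) -> float:
        return (self.first + self.second) / 2.0


@dataclass(frozen=True)
class LMSReferenceRow:
    """One (sex, age) row of an LMS growth reference."""

    sex: str
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self):
        if self.sex not in VALID_SEXES:
            raise ValidationError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if not (self.M > 0 and self.S > 0):
            raise ValidationError("LMS row requires M > 0 and S > 0")


@dataclass
class SubjectRecord:
    """One adolescent's averaged anthropometry plus derived quantities."""

    id: str
    sex: str
    age_years: float
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    muac_cm: Optional[float] = None
    bmi: Optional[float] = None
    bmi_z: Optional[float] = None
    status_overweight: Optional[bool] = None
    status_obese: Optional[bool] = None

    def __post_init__(self):
        if self.sex not in VALID_SEXES:
            raise ValidationError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        for name in ("height_cm", "weight_kg", "muac_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if self.status_obese and self.status_overweight is False:
            raise ValidationError("obese implies overweight (including obesity)")

    @property
    def complete(self) -> bool:
        """True when MUAC, weight and height are all present (the
        analysis set: subjects missing any of the three are excluded)."""
        return all(
            v is not None and not (isinstance(v, float) and math.isnan(v))
            for v in (self.muac_cm, self.weight_kg, self.height_cm)
        )


# ---------------------------------------------------------------------------
# Replicate handling

def average_replicates(
    pair: ReplicatePair,
    repeat_threshold: float = DEFAULT_REPEAT_THRESHOLD_CM,
    subject_id=None,
) -> float:
    """Average two replicate readings, applying the repeat rule.

    If the two readings agree to within ``repeat_threshold`` their mean is
    returned.  If they disagree by more, the repeat pair (a second set of
    two readings) must be present and its mean is returned instead.

    Raises
    ------
    FlaggedRecordError
        If the readings disagree beyond the threshold and no repeat pair
        was recorded.
    """
    if not repeat_threshold > 0:
        raise ValidationError("repeat_threshold must be > 0")
    if pair.difference <= repeat_threshold:
        return pair.mean
    if pair.repeat_pair is not None:
        return pair.repeat_pair.mean
    raise FlaggedRecordError(
        f"replicates ({pair.first}, {pair.second}) differ by "
        f"{pair.difference:g} > {repeat_threshold:g} and no repeat pair "
        f"was recorded (subject {subject_id!r})",
        subject_id=subject_id,
    )


def technical_error_of_measurement(pairs: Sequence[ReplicatePair]) -> float:
    """TEM = sqrt(sum(d_i^2) / (2n)) over replicate pairs, in the
    measurement unit; the standard measurer-standardization statistic."""
    if len(pairs) == 0:
        raise ValidationError("TEM requires at least one replicate pair")
    d = np.array([p.first - p.second for p in pairs], dtype=float)
    return float(np.sqrt(np.sum(d**2) / (2 * len(d))))


# ---------------------------------------------------------------------------
# BMI and the LMS z-score

def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """BMI in kg/m^2 from weight (kg) and height (cm)."""
    if not (weight_kg > 0 and height_cm > 0):
        raise ValidationError(
            f"weight and height must be strictly positive, got "
            f"({weight_kg}, {height_cm})"
        )
    return weight_kg / (height_cm / 100.0) ** 2


def _lms_raw_z(x: float, L: float, M: float, S: float) -> float:
    if L == 0.0:
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement value at a given z under the (untruncated) LMS model."""
    if L == 0.0:
        return M * math.exp(S * z)
    return M * (1.0 + L * S * z) ** (1.0 / L)


def lms_zscore(x: float, row: LMSReferenceRow, restrict_tails: bool = True) -> float:
    """BMI-for-age z-score under the LMS model with the WHO restricted tail.

    Within +/-3 the raw Box-Cox z is returned.  Beyond, the WHO adjustment
    linearizes the scale in measurement units:

        z = 3 + (x - sd3) / (sd3 - sd2)      above +3
        z = -3 + (x - sd3n) / (sd2n - sd3n)  below -3

    where sdK is the LMS inverse at z = K.  This keeps extreme values
    finite and continuous at the +/-3 joins.
    """
    if not x > 0:
        raise ValidationError(f"measurement must be strictly positive, got {x}")
    z = _lms_raw_z(x, row.L, row.M, row.S)
    if not restrict_tails or -3.0 <= z <= 3.0:
        return z
    if z > 3.0:
        sd3 = lms_inverse(3.0, row.L, row.M, row.S)
        sd2 = lms_inverse(2.0, row.L, row.M, row.S)
        return 3.0 + (x - sd3) / (sd3 - sd2)
    sd3n = lms_inverse(-3.0, row.L, row.M, row.S)
    sd2n = lms_inverse(-2.0, row.L, row.M, row.S)
    return -3.0 + (x - sd3n) / (sd2n - sd3n)


class LMSReference:
    """Sex- and age-indexed LMS lookup table.

    Matches subjects to the nearest ``age_months`` row for their sex by
    default (WHO tables are monthly and this mirrors the common
    implementations); linear interpolation in age is available via
    ``interpolate=True``.
    """

    def __init__(self, table: pd.DataFrame, interpolate: bool = False):
        required = {"sex", "age_months", "L", "M", "S"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"LMS table missing columns: {sorted(missing)}")
        if table.duplicated(["sex", "age_months"]).any():
            raise ValidationError("LMS table has duplicate (sex, age_months) rows")
        if not ((table["M"] > 0).all() and (table["S"] > 0).all()):
            raise ValidationError("LMS table requires M > 0 and S > 0")
        self.interpolate = interpolate
        self._by_sex = {
            sex: grp.sort_values("age_months").reset_index(drop=True)
            for sex, grp in table.groupby("sex")
        }
        for sex in self._by_sex:
            if sex not in VALID_SEXES:
                raise ValidationError(f"unknown sex {sex!r} in LMS table")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LMSReference":
        return cls(pd.read_csv(path), **kwargs)

    def row_for(self, sex: str, age_years: float) -> LMSReferenceRow:
        """LMS parameters for a subject of given sex and age in years."""
        if sex not in self._by_sex:
            raise ValidationError(f"no LMS rows for sex {sex!r}")
        grp = self._by_sex[sex]
        age_months = age_years * 12.0
        ages = grp["age_months"].to_numpy(dtype=float)
        if self.interpolate and ages.min() <= age_months <= ages.max():
            L = float(np.interp(age_months, ages, grp["L"]))
            M = float(np.interp(age_months, ages, grp["M"]))
            S = float(np.interp(age_months, ages, grp["S"]))
            return LMSReferenceRow(sex, age_months, L, M, S)
        i = int(np.argmin(np.abs(ages - age_months)))
        r = grp.iloc[i]
        return LMSReferenceRow(sex, float(r["age_months"]), float(r["L"]),
                               float(r["M"]), float(r["S"]))

    def zscore(self, x: float, sex: str, age_years: float) -> float:
        return lms_zscore(x, self.row_for(sex, age_years))


# ---------------------------------------------------------------------------
# Status classification

def classify_status(bmi_z: float) -> str:
    """WHO school-age nutritional category from the BMI-for-age z-score.

    Overweight (including obesity) is z > +1 SD strictly; obesity is
    z > +2 SD strictly (a subset of the former).
    """
    if not math.isfinite(bmi_z):
        raise ValidationError(f"bmi_z must be finite, got {bmi_z}")
    if bmi_z > 2.0:
        return "obese"
    if bmi_z > 1.0:
        return "overweight_incl_obese"
    return "thin/normal"


# ---------------------------------------------------------------------------
# Subject CSV ingestion

def read_subject_csv(path) -> pd.DataFrame:
    """Read the subject CSV dialect; optional columns may be absent."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = [c for c in SUBJECT_COLUMNS
                if c not in ("muac_repeat1_cm", "muac_repeat2_cm", "bmi_z")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"subject CSV missing columns: {missing}")
    bad = set(df["sex"].dropna().unique()) - set(VALID_SEXES)
    if bad:
        raise ValidationError(f"unknown sex codes in subject CSV: {sorted(bad)}")
    return df


def write_subject_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in SUBJECT_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, lineterminator="\n")


def _pair_from_row(row, a: str, b: str, ra: str = None, rb: str = None):
    v1, v2 = row.get(a), row.get(b)
    if pd.isna(v1) or pd.isna(v2):
        return None
    repeat = None
    if ra and rb and ra in row.index and rb in row.index:
        r1, r2 = row.get(ra), row.get(rb)
        if not (pd.isna(r1) or pd.isna(r2)):
            repeat = ReplicatePair(float(r1), float(r2))
    return ReplicatePair(float(v1), float(v2), repeat)


def build_records(
    df: pd.DataFrame,
    lms: Optional[LMSReference] = None,
    repeat_threshold: float = DEFAULT_REPEAT_THRESHOLD_CM,
) -> list[SubjectRecord]:
    """Turn a subject table into SubjectRecords with derived fields.

    A precomputed ``bmi_z`` column, where present and non-missing, takes
    precedence over the LMS machinery, so the pipeline runs without a
    reference table.  Records missing any of MUAC, weight or height are
    returned with ``complete=False``; callers exclude them and report the
    count (mirroring the exclusion rule of the field protocol).
    """
    records: list[SubjectRecord] = []
    has_bmi_z = "bmi_z" in df.columns
    for _, row in df.iterrows():
        sid = str(row["id"])
        sex = row["sex"]
        age = float(row["age_years"])

        h_pair = _pair_from_row(row, "height1_cm", "height2_cm")
        w_pair = _pair_from_row(row, "weight1_kg", "weight2_kg")
        m_pair = _pair_from_row(row, "muac1_cm", "muac2_cm",
                                "muac_repeat1_cm", "muac_repeat2_cm")

        # height/weight replicates are simply averaged; the >0.5 cm repeat
        # rule applies to MUAC, the index test
        height = h_pair.mean if h_pair else None
        weight = w_pair.mean if w_pair else None
        muac = (average_replicates(m_pair, repeat_threshold, subject_id=sid)
                if m_pair else None)

        bmi = compute_bmi(weight, height) if (weight and height) else None

        bmi_z = None
        if has_bmi_z and not pd.isna(row["bmi_z"]):
            bmi_z = float(row["bmi_z"])
        elif bmi is not None and lms is not None:
            bmi_z = lms.zscore(bmi, sex, age)

        ow = ob = None
        if bmi_z is not None:
            cat = classify_status(bmi_z)
            ob = cat == "obese"
            ow = cat in ("obese", "overweight_incl_obese")

        records.append(SubjectRecord(
            id=sid, sex=sex, age_years=age,
            height_cm=height, weight_kg=weight, muac_cm=muac,
            bmi=bmi, bmi_z=bmi_z,
            status_overweight=ow, status_obese=ob,
        ))
    return records


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Analysis-ready table (one row per record, derived fields included)."""
    return pd.DataFrame([vars(r) for r in records])
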