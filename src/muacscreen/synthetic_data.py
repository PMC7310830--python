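"""Synthetic adolescent cohorts with the study's statistical structure.

Real subject-level data are replaced by a Gaussian-copula generator:
within each sex, (MUAC, BMI z-score) is drawn from a bivariate normal
whose marginals are the published sex-stratified means/SDs and whose
correlation is chosen so the *pooled* rank (Spearman) correlation of the
sex mixture hits the target: via the exact bivariate-normal map
rho = 2 sin(pi * r_s / 6) for a single sex, generalized to a numerically
solved mixture formula when the per-sex means differ.
Overweight prevalence is emergent from the BMI-z marginals, the same way
the real cohort's prevalence arises from its z distribution (a forced-
prevalence mode exists for power experiments).

Measurement realism: height is drawn from a per-sex normal, weight is
back-solved from the BMI z-score through a synthetic LMS reference, and
every quantity is emitted as two replicate readings (true value plus
independent technician noise) rounded to instrument precision (0.1 cm /
0.1 kg), with a repeat MUAC pair whenever the first two readings
disagree by more than the field protocol's 0.5 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .anthropometry import (
    DEFAULT_REPEAT_THRESHOLD_CM,
    LMSReference,
    lms_inverse,
)
from .errors import ValidationError

#: Technician replicate noise, cm / kg, applied to each reading.
DEFAULT_MUAC_REPLICATE_SD_CM = 0.15
_HEIGHT_REPLICATE_SD_CM = 0.2
_WEIGHT_REPLICATE_SD_KG = 0.1


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study's sex-stratified descriptives
    (n 456 males / 395 females; MUAC 25.3+/-3.2 vs 25.7+/-3.4 cm;
    BMI z -0.8+/-1.2 vs -0.05+/-1.1; height 168.7+/-6.8 vs 157.0+/-6.3 cm;
    age 16.7+/-1.1 y) and a Spearman(MUAC, BMI z) target of 0.81.
    """

    n_male: int = 456
    n_female: int = 395
    muac_mean_male: float = 25.3
    muac_sd_male: float = 3.2
    muac_mean_female: float = 25.7
    muac_sd_female: float = 3.4
    bmiz_mean_male: float = -0.8
    bmiz_sd_male: float = 1.2
    bmiz_mean_female: float = -0.05
    bmiz_sd_female: float = 1.1
    height_mean_male: float = 168.7
    height_sd_male: float = 6.8
    height_mean_female: float = 157.0
    height_sd_female: float = 6.3
    age_mean: float = 16.7
    age_sd: float = 1.1
    target_spearman: float = 0.81
    replicate_error_sd: float = DEFAULT_MUAC_REPLICATE_SD_CM
    forced_prevalence: Optional[float] = None
    seed: int = 2019

    def __post_init__(self):
        for name in ("muac_sd_male", "muac_sd_female", "bmiz_sd_male",
                     "bmiz_sd_female", "height_sd_male", "height_sd_female",
                     "age_sd"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not abs(self.target_spearman) < 1:
            raise ValidationError("|target_spearman| must be < 1")
        if self.replicate_error_sd < 0:
            raise ValidationError("replicate_error_sd must be >= 0")
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female == 0:
            raise ValidationError("cohort must contain at least one subject")
        if self.forced_prevalence is not None and not 0 < self.forced_prevalence < 1:
            raise ValidationError("forced_prevalence must lie in (0, 1)")


def spearman_to_pearson(rs: float) -> float:
    """Bivariate-normal Pearson correlation yielding Spearman rs:
    rho = 2 sin(pi * rs / 6)."""
    if not -1.0 <= rs <= 1.0:
        raise ValidationError(f"|rs| must be <= 1, got {rs}")
    return 2.0 * math.sin(math.pi * rs / 6.0)


def _pooled_spearman_of_latent(rho: float, comps) -> float:
    """Population Spearman of a two-variable Gaussian mixture whose
    components share the latent correlation ``rho``.

    ``comps`` is a list of (weight, mean_x, sd_x, mean_y, sd_y).  Uses
    rho_s = 12 E[F(X) G(Y)] - 3 with the pooled marginal CDFs F, G; each
    cross term E[Phi(a+bU) Phi(c+dV)] over a standard bivariate normal
    (U, V) reduces to a bivariate-normal orthant probability.
    """
    from scipy.stats import multivariate_normal

    total = 0.0
    for wk, mxk, sxk, myk, syk in comps:
        for wj, mxj, sxj, _, _ in comps:
            for wl, _, _, myl, syl in comps:
                a, b = (mxk - mxj) / sxj, sxk / sxj
                c, d = (myk - myl) / syl, syk / syl
                sb, sd = math.sqrt(1 + b * b), math.sqrt(1 + d * d)
                r = rho * b * d / (sb * sd)
                p = multivariate_normal(mean=[0.0, 0.0],
                                        cov=[[1.0, r], [r, 1.0]]
                                        ).cdf([a / sb, c / sd])
                total += wk * wj * wl * p
    return 12.0 * total - 3.0


def latent_pearson_for_target(spec: "CohortSpec") -> float:
    """Within-sex latent Pearson correlation such that the *pooled*
    (MUAC, BMI z) Spearman correlation of the sex mixture equals the
    spec's target.

    With one sex this coincides with ``spearman_to_pearson``; with two,
    the differing per-sex means shift the pooled rank correlation, so the
    latent correlation is solved numerically from the exact mixture
    formula.
    """
    from scipy.optimize import brentq

    n = spec.n_male + spec.n_female
    comps = []
    if spec.n_male:
        comps.append((spec.n_male / n, spec.muac_mean_male, spec.muac_sd_male,
                      spec.bmiz_mean_male, spec.bmiz_sd_male))
    if spec.n_female:
        comps.append((spec.n_female / n, spec.muac_mean_female,
                      spec.muac_sd_female, spec.bmiz_mean_female,
                      spec.bmiz_sd_female))
    if len(comps) == 1:
        return spearman_to_pearson(spec.target_spearman)
    lo, hi = -0.9995, 0.9995
    f = lambda r: _pooled_spearman_of_latent(r, comps) - spec.target_spearman
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError(
            f"target_spearman {spec.target_spearman} unreachable for these "
            "marginals")
    return float(brentq(f, lo, hi, xtol=1e-6))


def synthetic_lms_table(age_lo_months: int = 180, age_hi_months: int = 240
                        ) -> pd.DataFrame:
    """SYNTHETIC stand-in LMS reference for late-adolescent BMI-for-age.

    Plausible magnitudes (negative Box-Cox power, median BMI rising
    gently with age, coefficient of variation ~0.13) constructed for
    testing and simulation; NOT the WHO 2007 tables, which this package
    deliberately does not redistribute.
    """
    rows = []
    for age in range(age_lo_months, age_hi_months + 1):
        frac = (age - age_lo_months) / (age_hi_months - age_lo_months)
        rows.append(("male", age, -1.45, 19.5 + 1.4 * frac, 0.130))
        rows.append(("female", age, -1.20, 19.8 + 1.2 * frac, 0.125))
    return pd.DataFrame(rows, columns=["sex", "age_months", "L", "M", "S"])


def synthetic_lms_reference(**kwargs) -> LMSReference:
    return LMSReference(synthetic_lms_table(), **kwargs)


def _lms_inverse_restricted(z: float, L: float, M: float, S: float) -> float:
    """Measurement at a z under the restricted-tail LMS scale (inverse of
    the tail-adjusted z-score, defined for every real z)."""
    if -3.0 <= z <= 3.0:
        return lms_inverse(z, L, M, S)
    if z > 3.0:
        sd3, sd2 = lms_inverse(3.0, L, M, S), lms_inverse(2.0, L, M, S)
        return sd3 + (z - 3.0) * (sd3 - sd2)
    sd3n, sd2n = lms_inverse(-3.0, L, M, S), lms_inverse(-2.0, L, M, S)
    return sd3n + (z + 3.0) * (sd2n - sd3n)


def _replicate(rng, true, sd, decimals=1):
    return np.round(true + rng.normal(0.0, sd, true.shape), decimals) if sd > 0 \
        else np.round(true, decimals)


def _lms_params(lms: LMSReference, sex: str, age_years: float):
    row = lms.row_for(sex, age_years)
    return row.L, row.M, row.S


def generate_cohort(spec: CohortSpec, lms: Optional[LMSReference] = None
                    ) -> pd.DataFrame:
    """Draw a cohort; returns a table in the subject-CSV dialect.

    Columns: id, sex, age_years, two replicate readings each of height,
    weight and MUAC, a repeat MUAC pair where the protocol demands one,
    and the generating bmi_z.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if lms is None:
        lms = synthetic_lms_reference()
    rho = latent_pearson_for_target(spec)

    frames = []
    for sex, n, mu_m, mu_s, bz_m, bz_s, h_m, h_s, prefix in (
        ("male", spec.n_male, spec.muac_mean_male, spec.muac_sd_male,
         spec.bmiz_mean_male, spec.bmiz_sd_male,
         spec.height_mean_male, spec.height_sd_male, "M"),
        ("female", spec.n_female, spec.muac_mean_female, spec.muac_sd_female,
         spec.bmiz_mean_female, spec.bmiz_sd_female,
         spec.height_mean_female, spec.height_sd_female, "F"),
    ):
        if n == 0:
            continue
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        bmiz = bz_m + bz_s * z1
        muac_true = mu_m + mu_s * (rho * z1 + math.sqrt(1 - rho**2) * z2)
        muac_true = np.maximum(muac_true, 10.0)  # physical floor, cm
        height_true = h_m + h_s * rng.standard_normal(n)
        age = np.round(rng.normal(spec.age_mean, spec.age_sd, n), 2)

        bmi = np.array([
            _lms_inverse_restricted(z, *_lms_params(lms, sex, a))
            for z, a in zip(bmiz, age)
        ])
        weight_true = bmi * (height_true / 100.0) ** 2

        m1 = _replicate(rng, muac_true, spec.replicate_error_sd)
        m2 = _replicate(rng, muac_true, spec.replicate_error_sd)
        need_repeat = np.abs(m1 - m2) > DEFAULT_REPEAT_THRESHOLD_CM
        r1 = np.where(need_repeat,
                      _replicate(rng, muac_true, spec.replicate_error_sd), np.nan)
        r2 = np.where(need_repeat,
                      _replicate(rng, muac_true, spec.replicate_error_sd), np.nan)

        frames.append(pd.DataFrame({
            "id": [f"{prefix}{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "age_years": age,
            "height1_cm": _replicate(rng, height_true, _HEIGHT_REPLICATE_SD_CM),
            "height2_cm": _replicate(rng, height_true, _HEIGHT_REPLICATE_SD_CM),
            "weight1_kg": _replicate(rng, weight_true, _WEIGHT_REPLICATE_SD_KG),
            "weight2_kg": _replicate(rng, weight_true, _WEIGHT_REPLICATE_SD_KG),
            "muac1_cm": m1,
            "muac2_cm": m2,
            "muac_repeat1_cm": r1,
            "muac_repeat2_cm": r2,
            "bmi_z": bmiz,
        }))

    df = pd.concat(frames, ignore_index=True)

    if spec.forced_prevalence is not None:
        # shift every z by a common offset so that exactly round(p*n)
        # subjects exceed +1; sacrifices the z marginal by construction
        k = int(round(spec.forced_prevalence * len(df)))
        k = min(max(k, 1), len(df) - 1)
        z_sorted = np.sort(df["bmi_z"].to_numpy())[::-1]
        thresh = (z_sorted[k - 1] + z_sorted[k]) / 2.0
        df["bmi_z"] = df["bmi_z"] + (1.0 - thresh)

    return df


def inject_missingness(cohort: pd.DataFrame, fraction: float, seed: int
                       ) -> pd.DataFrame:
    """Blank one of (MUAC, weight, height) in a seeded random subset.

    Each record is flagged independently with probability ``fraction``;
    a flagged record loses both replicate readings of one field chosen
    uniformly (and the repeat pair, for MUAC).  The analysis pipeline
    must then exclude exactly those records and report the count.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("fraction must lie in [0, 1)")
    out = cohort.copy()
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    flagged = rng.random(len(out)) < fraction
    which = rng.integers(0, 3, len(out))
    field_cols = {
        0: ["muac1_cm", "muac2_cm", "muac_repeat1_cm", "muac_repeat2_cm"],
        1: ["weight1_kg", "weight2_kg"],
        2: ["height1_cm", "height2_cm"],
    }
    for k, cols in field_cols.items():
        mask = flagged & (which == k)
        cols = [c for c in cols if c in out.columns]
        out.loc[mask, cols] = np.nan
    return out
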