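"""Age- and sex-standardised BMI z-scores via the LMS method.

A growth reference summarises, for each sex and age, the distribution of
BMI in a reference population by three parameters: the Box--Cox power
``L`` (skewness), the median ``M`` (kg/m²) and the coefficient of
variation ``S``.  A measurement ``y`` is converted to a standard
deviation score (SDS, z-score scale) by

    z = ((y / M)**L - 1) / (L * S)        for L != 0
    z = ln(y / M) / S                     for L == 0

and the transform is inverted by ``y = M * (1 + L*S*z)**(1/L)`` (or
``M * exp(S*z)`` at L == 0).  The inverse is only defined while
``1 + L*S*z > 0``; for the negative ``L`` typical of child BMI this
bounds how extreme a z-score can be mapped back to a BMI.

The module ships a *synthetic* reference table with smooth, plausible
L/M/S curves over ages 3--14 for both sexes, so the package runs without
any external data.  Real reference tables (for example the UK 1990
tables, which are not redistributable) can be supplied as CSV with
columns ``sex,age,L,M,S`` and sex coded M/F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthReferenceError",
    "AgeOutOfRangeError",
    "InverseRangeError",
    "LMSReferenceTable",
    "Measurement",
    "lms_zscore",
    "lms_inverse",
    "interpolate_lms",
    "bmi_sds",
    "bmi_sds_frame",
    "sds_to_bmi",
    "synthetic_reference",
]

SEXES = ("M", "F")


class GrowthReferenceError(ValueError):
    """Invalid input to an LMS computation."""


class AgeOutOfRangeError(GrowthReferenceError):
    """Requested age lies outside the reference table's coverage."""


class InverseRangeError(GrowthReferenceError):
    """z lies outside the invertible range of the LMS transform."""


def _as_float_arrays(*xs):
    arrs = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in xs))
    scalar = all(np.ndim(x) == 0 for x in xs)
    return arrs, scalar


def lms_zscore(bmi, L, M, S):
    """BMI standard-deviation score for given LMS parameters.

    Accepts scalars or broadcastable arrays.  Continuous in ``L`` at
    L = 0 (the power form is evaluated with ``expm1`` so the L -> 0
    limit equals the log form to machine precision).
    """
    (bmi, L, M, S), scalar = _as_float_arrays(bmi, L, M, S)
    if np.any(bmi <= 0):
        raise GrowthReferenceError("bmi must be positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise GrowthReferenceError("M and S must be positive")
    t = np.log(bmi / M)
    # |L| below ~1e-250 can underflow L*S to zero; use the L -> 0 limit
    tiny = np.abs(L) < 1e-250
    Lsafe = np.where(tiny, 1.0, L)
    z = np.where(tiny, t / S, np.expm1(Lsafe * t) / (Lsafe * S))
    return float(z) if scalar else z


def lms_inverse(z, L, M, S):
    """BMI whose z-score is ``z`` under the given LMS parameters.

    Raises :class:`InverseRangeError` when ``1 + L*S*z <= 0`` (the
    Box--Cox transform is not invertible there).
    """
    (z, L, M, S), scalar = _as_float_arrays(z, L, M, S)
    if np.any(M <= 0) or np.any(S <= 0):
        raise GrowthReferenceError("M and S must be positive")
    t = L * S * z
    bad = (L != 0.0) & (t <= -1.0)
    if np.any(bad):
        raise InverseRangeError(
            "z outside the invertible range for the given L and S"
        )
    # exp(log1p(L*S*z)/L) == (1 + L*S*z)^(1/L) but stays accurate as L -> 0;
    # below ~1e-250 the product L*S*z can underflow, so use the limit form.
    tiny = np.abs(L) < 1e-250
    Lsafe = np.where(tiny, 1.0, L)
    tsafe = np.where(tiny, 0.0, t)
    bmi = np.where(tiny, M * np.exp(S * z),
                   M * np.exp(np.log1p(tsafe) / Lsafe))
    return float(bmi) if scalar else bmi


@dataclass(frozen=True)
class Measurement:
    """One measured child: sex (M/F), decimal age in years, BMI kg/m²."""

    sex: str
    age: float
    bmi: float

    def __post_init__(self):
        if self.sex not in SEXES:
            raise GrowthReferenceError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (2.0 <= self.age <= 18.0):
            raise GrowthReferenceError(f"age {self.age} outside [2, 18] years")
        if not self.bmi > 0:
            raise GrowthReferenceError("bmi must be positive")


@dataclass(frozen=True)
class LMSReferenceTable:
    """Sex/age grid of (L, M, S) with linear interpolation in age.

    Invariants checked on construction: M > 0 and S > 0 everywhere,
    ages strictly increasing within each sex, and coverage of at least
    [4, 12] years for both sexes.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        missing = {"sex", "age", "L", "M", "S"} - set(df.columns)
        if missing:
            raise GrowthReferenceError(f"reference table missing columns {sorted(missing)}")
        if not set(df["sex"].unique()) <= set(SEXES):
            raise GrowthReferenceError("sex must be coded M/F")
        if np.any(df["M"].to_numpy() <= 0) or np.any(df["S"].to_numpy() <= 0):
            raise GrowthReferenceError("M and S must be positive throughout the table")
        for sex in SEXES:
            ages = df.loc[df["sex"] == sex, "age"].to_numpy(dtype=float)
            if ages.size == 0:
                raise GrowthReferenceError(f"no rows for sex {sex}")
            if np.any(np.diff(ages) <= 0):
                raise GrowthReferenceError(f"ages not strictly increasing for sex {sex}")
            if ages.min() > 4.0 or ages.max() < 12.0:
                raise GrowthReferenceError(
                    f"reference for sex {sex} must cover at least ages [4, 12]"
                )

    @classmethod
    def from_csv(cls, path) -> "LMSReferenceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def age_range(self, sex: str) -> tuple[float, float]:
        ages = self.data.loc[self.data["sex"] == sex, "age"]
        return float(ages.min()), float(ages.max())

    def lookup(self, sex, age):
        """(L, M, S) at the given sex/age, linear in age, exact at knots.

        ``sex`` and ``age`` may be arrays of equal length.  Ages outside
        the table raise :class:`AgeOutOfRangeError` — no extrapolation.
        """
        sex_arr = np.atleast_1d(np.asarray(sex))
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        sex_arr, age_arr = np.broadcast_arrays(sex_arr, age_arr)
        L = np.empty(age_arr.shape)
        M = np.empty(age_arr.shape)
        S = np.empty(age_arr.shape)
        for s in SEXES:
            mask = sex_arr == s
            if not mask.any():
                continue
            sub = self.data[self.data["sex"] == s]
            knots = sub["age"].to_numpy(dtype=float)
            a = age_arr[mask]
            if a.min() < knots[0] or a.max() > knots[-1]:
                raise AgeOutOfRangeError(
                    f"age outside reference range [{knots[0]}, {knots[-1]}] for sex {s}"
                )
            for out, col in ((L, "L"), (M, "M"), (S, "S")):
                out[mask] = np.interp(a, knots, sub[col].to_numpy(dtype=float))
        unknown = ~np.isin(sex_arr, SEXES)
        if unknown.any():
            raise GrowthReferenceError(f"unknown sex code {sex_arr[unknown][0]!r}")
        if np.ndim(sex) == 0 and np.ndim(age) == 0:
            return float(L[0]), float(M[0]), float(S[0])
        return L, M, S


def interpolate_lms(table: LMSReferenceTable, sex, age):
    """(L, M, S) for one sex/age — alias for :meth:`LMSReferenceTable.lookup`."""
    return table.lookup(sex, age)


def bmi_sds(m: Measurement, table: LMSReferenceTable) -> float:
    """BMI-SDS of one measurement: interpolate (L, M, S) then z-score."""
    L, M, S = table.lookup(m.sex, m.age)
    return lms_zscore(m.bmi, L, M, S)


def bmi_sds_frame(df: pd.DataFrame, table: LMSReferenceTable,
                  out_col: str = "bmi_sds") -> pd.DataFrame:
    """Return a copy of ``df`` with a BMI-SDS column.

    ``df`` must carry ``sex`` (M/F), ``age`` (years) and ``bmi`` columns.
    """
    L, M, S = table.lookup(df["sex"].to_numpy(), df["age"].to_numpy(dtype=float))
    out = df.copy()
    out[out_col] = lms_zscore(df["bmi"].to_numpy(dtype=float), L, M, S)
    return out


def sds_to_bmi(z, sex, age, table: LMSReferenceTable):
    """Map z-scores back to BMI at the given sexes/ages (simulation support)."""
    L, M, S = table.lookup(sex, age)
    return lms_inverse(z, L, M, S)


def synthetic_reference(age_min: float = 3.0, age_max: float = 14.0,
                        step: float = 0.25) -> LMSReferenceTable:
    """Synthetic LMS reference table with smooth plausible curves.

    The curves mimic the qualitative shape of child BMI references
    (median dipping at the adiposity rebound around age 5-6 then rising;
    increasing spread and left-skew with age) but are *not* the UK 1990
    values; use :meth:`LMSReferenceTable.from_csv` to supply a real
    reference.
    """
    ages = np.round(np.arange(age_min, age_max + step / 2, step), 6)
    rows = []
    for sex in SEXES:
        if sex == "M":
            M = 15.50 + 0.050 * (ages - 5.3) ** 2
            L = -1.10 - 0.050 * (ages - 4.0)
            S = 0.082 + 0.0055 * (ages - 4.0)
        else:
            M = 15.35 + 0.052 * (ages - 5.2) ** 2
            L = -1.30 - 0.040 * (ages - 4.0)
            S = 0.090 + 0.0052 * (ages - 4.0)
        for a, l, m, s in zip(ages, L, M, S):
            rows.append((sex, float(a), float(l), float(m), float(s)))
    df = pd.DataFrame(rows, columns=["sex", "age", "L", "M", "S"])
    return LMSReferenceTable(df)
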