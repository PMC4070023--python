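"""Synthetic multi-year pupil cohorts with crossed school/neighbourhood structure.

Emulates the statistical structure of English National Child Measurement
Programme (NCMP) extracts: repeated cross-sections of Reception
(age 4-5) and Year 6 (age 10-11) pupils, each attending one school and
living in one small-area neighbourhood (LSOA), with school and
neighbourhood catchments crossed rather than nested.  A pupil's true
BMI-SDS is

    z = cohort mean
        + beta_imd * (imd - E[imd]) + ethnicity offsets (centred)
        + u_school(year) + w_school,cohort + v_lsoa + e

where ``u_school`` follows a stationary AR(1) across years with
correlation ``persistence_rho`` and marginal variance ``var_school``,
``v_lsoa`` is constant across years (a neighbourhood is a fixed place),
``w`` is an optional cohort-specific school effect (a true "value-added"
signal; 0 by default) and ``e`` is pupil-level noise.  Covariates are
centred so the configured cohort means are the marginal means of the
generated z-scores.  BMI is obtained from z by inverting the LMS
transform at the pupil's simulated age and sex.

Records from different years are distinct pupils (repeated
cross-sections, not a longitudinal cohort).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .growth_reference import LMSReferenceTable, synthetic_reference, sds_to_bmi

__all__ = [
    "ETHNICITY_CATEGORIES",
    "COHORTS",
    "DEFAULT_YEARS",
    "SimulationConfig",
    "ConfigurationError",
    "PupilDataError",
    "build_crossing",
    "simulate_school_effects",
    "simulate_panel",
    "write_pupils",
    "read_pupils",
]

logger = logging.getLogger(__name__)

ETHNICITY_CATEGORIES = (
    "White-British",
    "Any other White",
    "Chinese/Asian/Asian British",
    "Mixed/Dual",
    "Any other",
)
COHORTS = ("Reception", "Year6")
DEFAULT_YEARS = ("2006/07", "2007/08", "2008/09", "2009/10", "2010/11")

PUPIL_COLUMNS = [
    "pupil_id", "year", "cohort", "sex", "age",
    "school_id", "lsoa_id", "ethnicity", "imd_norm", "bmi",
]

# Cohort age distributions: (mean, sd, low, high), truncated normal by clipping.
_AGE_PARAMS = {"Reception": (5.1, 0.27, 4.2, 5.8), "Year6": (11.1, 0.31, 10.0, 12.0)}

# The LMS inverse is undefined beyond 1 + L*S*z > 0; for the bundled
# reference the bound over ages 4-12 is |z| < ~4.7, so true z-scores are
# clipped at +/-4.4 (affects ~5e-5 of pupils at SD ~1.05).
_Z_CLIP = 4.4


class ConfigurationError(ValueError):
    """Simulation configuration cannot produce a valid crossed design."""


class PupilDataError(ValueError):
    """Malformed pupil-level CSV."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Variance defaults split a total variance of 1.1025 (SD 1.05) into
    shares 0.017 (school), 0.005 (neighbourhood) and 0.978 (pupil).
    """

    n_schools: int = 300
    n_neighbourhoods: int = 500
    pupils_per_school_per_cohort: float = 19.0
    years: tuple[str, ...] = DEFAULT_YEARS
    var_school: float = 0.0187425
    var_neighbourhood: float = 0.0055125
    var_residual: float = 1.078245
    persistence_rho: float = 0.5
    cohort_effect_sd: float = 0.0
    beta_imd: float = 0.44
    beta_ethnicity: tuple[float, ...] = (0.0, 0.04, -0.07, -0.04, -0.16)
    ethnicity_freqs: tuple[float, ...] = (0.9561, 0.0206, 0.0051, 0.0124, 0.0057)
    imd_beta_params: tuple[float, float] = (3.5, 15.0)
    mean_sds_reception: float = 0.35
    mean_sds_year6: float = 0.45
    p_male: float = 0.518
    seed: int = 0

    def __post_init__(self):
        if self.n_schools < 2 or self.n_neighbourhoods < 2:
            raise ConfigurationError("need at least 2 schools and 2 neighbourhoods")
        for name in ("var_school", "var_neighbourhood", "var_residual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.persistence_rho <= 1.0:
            raise ConfigurationError("persistence_rho must lie in [0, 1]")
        if self.cohort_effect_sd < 0:
            raise ConfigurationError("cohort_effect_sd must be >= 0")
        if len(self.ethnicity_freqs) != len(ETHNICITY_CATEGORIES):
            raise ConfigurationError("ethnicity_freqs must have 5 entries")
        if abs(sum(self.ethnicity_freqs) - 1.0) > 0.01:
            raise ConfigurationError("ethnicity_freqs must sum to 1")
        if len(self.beta_ethnicity) != len(ETHNICITY_CATEGORIES):
            raise ConfigurationError("beta_ethnicity must have 5 entries")
        a, b = self.imd_beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError("imd_beta_params must be positive")
        if len(self.years) < 1:
            raise ConfigurationError("at least one year required")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("years", "beta_ethnicity", "ethnicity_freqs", "imd_beta_params"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()},
                fh, sort_keys=True)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _ids(prefix: str, n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)])


def build_crossing(n_schools: int, n_neighbourhoods: int, seed: int,
                   links_per_school: int = 4) -> dict[str, np.ndarray]:
    """School -> neighbourhood catchment map with crossed (not nested) factors.

    Schools and neighbourhoods are placed at random positions on a
    circle; each school's catchment is its ``links_per_school`` nearest
    neighbourhoods, and any neighbourhood left unlinked is attached to
    its nearest school.  Overlapping catchments of adjacent schools make
    the school x neighbourhood incidence graph connected, so the two
    factors are genuinely crossed.
    """
    if n_schools < 2 or n_neighbourhoods < 2:
        raise ConfigurationError("need at least 2 schools and 2 neighbourhoods")
    if n_neighbourhoods < n_schools / 2:
        raise ConfigurationError(
            "crossing requires n_neighbourhoods >= n_schools / 2")
    k = min(max(2, links_per_school), n_neighbourhoods)
    rng = np.random.default_rng(seed)
    school_pos = np.sort(rng.uniform(0.0, 1.0, size=n_schools))
    lsoa_pos = np.sort(rng.uniform(0.0, 1.0, size=n_neighbourhoods))
    school_ids = _ids("S", n_schools)
    lsoa_ids = _ids("L", n_neighbourhoods)

    # circular distance matrix, school x lsoa
    d = np.abs(school_pos[:, None] - lsoa_pos[None, :])
    d = np.minimum(d, 1.0 - d)
    catchment = {}
    linked = np.zeros(n_neighbourhoods, dtype=bool)
    for i in range(n_schools):
        nearest = np.argsort(d[i])[:k]
        catchment[i] = set(nearest.tolist())
        linked[nearest] = True
    # consecutive schools around the circle share one neighbourhood so
    # the incidence graph is a single connected component (fully crossed)
    for i in range(n_schools):
        nxt = (i + 1) % n_schools
        catchment[i].add(int(np.argmin(d[nxt])))
    for j in np.flatnonzero(~linked):
        catchment[int(np.argmin(d[:, j]))].add(int(j))
    return {school_ids[i]: lsoa_ids[sorted(catchment[i])] for i in range(n_schools)}


def simulate_school_effects(rng: np.random.Generator, n_schools: int,
                            n_years: int, var: float, rho: float) -> np.ndarray:
    """Stationary AR(1) school effects, shape (n_years, n_schools).

    Marginal variance ``var`` in every year; corr(u_t, u_{t+1}) = rho.
    """
    sd = np.sqrt(var)
    u = np.empty((n_years, n_schools))
    u[0] = rng.normal(0.0, sd, size=n_schools)
    innov_sd = sd * np.sqrt(max(0.0, 1.0 - rho ** 2))
    for t in range(1, n_years):
        u[t] = rho * u[t - 1] + rng.normal(0.0, innov_sd, size=n_schools)
    return u


def simulate_panel(config: SimulationConfig,
                   reference: LMSReferenceTable | None = None,
                   return_effects: bool = False):
    """Generate the full multi-year, two-cohort pupil panel.

    Returns a DataFrame with the pupil CSV columns plus the
    generator-only ``true_sds``; with ``return_effects=True`` also
    returns a dict holding the realised school/cohort/neighbourhood
    effects and neighbourhood deprivation for recovery studies.
    """
    if reference is None:
        reference = synthetic_reference()
    ss = np.random.SeedSequence(config.seed)
    s_cross, s_area, s_effects, s_pupils = ss.spawn(4)
    crossing_seed = int(s_cross.generate_state(1)[0] % (2 ** 31))
    crossing = build_crossing(config.n_schools, config.n_neighbourhoods,
                              seed=crossing_seed)
    school_ids = np.array(sorted(crossing))
    lsoa_ids = _ids("L", config.n_neighbourhoods)

    rng_area = np.random.default_rng(s_area)
    a, b = config.imd_beta_params
    imd = rng_area.beta(a, b, size=config.n_neighbourhoods)
    imd_mean = a / (a + b)
    lsoa_eff = rng_area.normal(0.0, np.sqrt(config.var_neighbourhood),
                               size=config.n_neighbourhoods)
    imd_by_lsoa = pd.Series(imd, index=lsoa_ids)
    eff_by_lsoa = pd.Series(lsoa_eff, index=lsoa_ids)

    rng_eff = np.random.default_rng(s_effects)
    n_years = len(config.years)
    u = simulate_school_effects(rng_eff, config.n_schools, n_years,
                                config.var_school, config.persistence_rho)
    w = rng_eff.normal(0.0, 1.0, size=(config.n_schools, 2)) * config.cohort_effect_sd

    freqs = np.asarray(config.ethnicity_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    beta_eth = np.asarray(config.beta_ethnicity, dtype=float)
    eth_offsets = beta_eth - float(freqs @ beta_eth)  # centred
    cohort_means = {"Reception": config.mean_sds_reception,
                    "Year6": config.mean_sds_year6}

    year_streams = s_pupils.spawn(n_years)
    frames = []
    counter = 0
    for t, (year, stream) in enumerate(zip(config.years, year_streams)):
        rng = np.random.default_rng(stream)
        for c_idx, cohort in enumerate(COHORTS):
            counts = rng.poisson(config.pupils_per_school_per_cohort,
                                 size=config.n_schools)
            n_tot = int(counts.sum())
            if n_tot == 0:
                continue
            school_idx = np.repeat(np.arange(config.n_schools), counts)
            # pupil's LSOA drawn uniformly from the school's catchment
            lsoa_choice = np.empty(n_tot, dtype=object)
            pos = 0
            for i, sid in enumerate(school_ids):
                ni = counts[i]
                if ni == 0:
                    continue
                cat = crossing[sid]
                lsoa_choice[pos:pos + ni] = cat[rng.integers(0, len(cat), size=ni)]
                pos += ni
            sex = np.where(rng.random(n_tot) < config.p_male, "M", "F")
            mu, sd_a, lo, hi = _AGE_PARAMS[cohort]
            age = np.clip(rng.normal(mu, sd_a, size=n_tot), lo, hi)
            eth_idx = rng.choice(len(ETHNICITY_CATEGORIES), size=n_tot, p=freqs)
            imd_p = imd_by_lsoa.loc[lsoa_choice].to_numpy()
            z = (cohort_means[cohort]
                 + config.beta_imd * (imd_p - imd_mean)
                 + eth_offsets[eth_idx]
                 + u[t, school_idx]
                 + w[school_idx, c_idx]
                 + eff_by_lsoa.loc[lsoa_choice].to_numpy()
                 + rng.normal(0.0, np.sqrt(config.var_residual), size=n_tot))
            z = np.clip(z, -_Z_CLIP, _Z_CLIP)
            bmi = sds_to_bmi(z, sex, age, reference)
            pid = np.array([f"{year[:4]}-{counter + i:06d}" for i in range(n_tot)])
            counter += n_tot
            frames.append(pd.DataFrame({
                "pupil_id": pid,
                "year": year,
                "cohort": cohort,
                "sex": sex,
                "age": np.round(age, 4),
                "school_id": school_ids[school_idx],
                "lsoa_id": lsoa_choice.astype(str),
                "ethnicity": np.array(ETHNICITY_CATEGORIES, dtype=object)[eth_idx],
                "imd_norm": imd_p,
                "bmi": bmi,
                "true_sds": z,
            }))
    panel = pd.concat(frames, ignore_index=True)
    if not return_effects:
        return panel
    effects = {
        "school": pd.DataFrame(u, index=list(config.years), columns=school_ids),
        "cohort": pd.DataFrame(w, index=school_ids, columns=list(COHORTS)),
        "lsoa": eff_by_lsoa,
        "imd": imd_by_lsoa,
    }
    return panel, effects


def write_pupils(records: pd.DataFrame, path, truth_path=None) -> None:
    """Write the pupil CSV; generator-only columns go to ``truth_path`` if given."""
    records[PUPIL_COLUMNS].to_csv(path, index=False, float_format="%.10g")
    if truth_path is not None and "true_sds" in records.columns:
        records[["pupil_id", "true_sds"]].to_csv(path_or_buf=truth_path,
                                                 index=False, float_format="%.10g")


def read_pupils(path) -> pd.DataFrame:
    """Read a pupil CSV, validating required fields.

    A row with a missing required field raises :class:`PupilDataError`
    naming the (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(path, dtype={"pupil_id": str, "year": str, "cohort": str,
                                  "sex": str, "school_id": str, "lsoa_id": str,
                                  "ethnicity": str})
    missing_cols = [c for c in PUPIL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PupilDataError(f"missing columns: {missing_cols}")
    for col in PUPIL_COLUMNS:
        nulls = df[col].isna()
        if nulls.any():
            line = int(np.flatnonzero(nulls.to_numpy())[0]) + 2
            raise PupilDataError(f"line {line}: missing value in column {col!r}")
    if (df["bmi"] <= 0).any():
        line = int(np.flatnonzero((df["bmi"] <= 0).to_numpy())[0]) + 2
        raise PupilDataError(f"line {line}: non-positive bmi")
    bad_imd = (df["imd_norm"] < 0) | (df["imd_norm"] > 1)
    if bad_imd.any():
        line = int(np.flatnonzero(bad_imd.to_numpy())[0]) + 2
        raise PupilDataError(f"line {line}: imd_norm outside [0, 1]")
    return df[PUPIL_COLUMNS]
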