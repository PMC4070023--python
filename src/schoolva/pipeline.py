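"""End-to-end orchestration of the five-step value-added analysis.

Given pupil records (real CSV or a synthetic-cohort configuration) the
pipeline:

1. converts BMI to BMI-SDS against the growth reference;
2. per year, fits the null cross-classified model (for ICCs), the
   adjusted pooled-cohort model, and the two cohort-specific models —
   optionally repeating the pooled fit without the neighbourhood factor
   as a sensitivity check;
3. builds the Observed, Expected and Value-added rankings;
4. compares the three rankings within each year (Lin's rho_c and
   Pearson's r);
5. compares each ranking type across years and tracks quintile
   membership (kappa, proportion constant).

All intermediates are persisted as CSV/JSON under the output directory
and the aggregate report is returned as a plain dict (written as
``report.json``).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crossclassified import ModelSpec, fit_reml, icc
from .growth_reference import LMSReferenceTable, bmi_sds_frame, synthetic_reference
from .league_tables import (SchoolRanking, expected_ranking, observed_ranking,
                            value_added_ranking, wide_rank_table)
from .plots import caterpillar_plot
from .stability import (AgreementError, between_year_table, pearson,
                        quintile_track, within_year_table)
from .synthetic_cohort import (COHORTS, ETHNICITY_CATEGORIES, SimulationConfig,
                               read_pupils, simulate_panel, write_pupils)

__all__ = ["RunConfig", "run_pipeline", "sample_summary"]

logger = logging.getLogger(__name__)

RANKING_TYPES = ("observed", "expected", "value_added")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``pupil_csv`` (real data) or ``simulation``
    (synthetic cohort) must be provided.  ``seed`` overrides the
    simulation seed so one flag controls all randomness.
    """

    outdir: Path
    pupil_csv: Path | None = None
    simulation: SimulationConfig | None = None
    reference_csv: Path | None = None
    seed: int = 0
    min_pupils: int = 1
    alpha: float = 0.05
    compare_on: str = "rank"          # 'rank' or 'score'
    include_neighbourhood: bool = True
    cohort_indicator: bool = False
    sensitivity: bool = True          # repeat pooled fit without neighbourhood
    make_plots: bool = True

    def __post_init__(self):
        if (self.pupil_csv is None) == (self.simulation is None):
            raise ValueError("provide exactly one of pupil_csv or simulation")
        self.outdir = Path(self.outdir)


def sample_summary(records: pd.DataFrame, *, response: str = "bmi_sds") -> dict:
    """Per-year descriptive statistics of the analysed sample.

    Counts, sex and ethnicity percentages, cohort age mean/SD,
    deprivation median (IQR) and BMI-SDS mean/SD and median (IQR).
    """
    out = {}
    for year, sub in records.groupby("year"):
        entry = {
            "n_pupils": int(len(sub)),
            "n_schools": int(sub["school_id"].nunique()),
            "n_neighbourhoods": int(sub["lsoa_id"].nunique()),
            "pct_male": float(100.0 * (sub["sex"] == "M").mean()),
            "pct_female": float(100.0 * (sub["sex"] == "F").mean()),
        }
        for cohort in COHORTS:
            ages = sub.loc[sub["cohort"] == cohort, "age"]
            entry[f"age_mean_{cohort}"] = float(ages.mean()) if len(ages) else None
            entry[f"age_sd_{cohort}"] = float(ages.std(ddof=1)) if len(ages) > 1 else None
        eth = sub["ethnicity"].value_counts(normalize=True) * 100.0
        entry["ethnicity_pct"] = {cat: float(eth.get(cat, 0.0))
                                  for cat in ETHNICITY_CATEGORIES}
        q = sub["imd_norm"].quantile([0.25, 0.5, 0.75])
        entry["imd_median"] = float(q[0.5])
        entry["imd_iqr"] = [float(q[0.25]), float(q[0.75])]
        if response in sub.columns:
            z = sub[response]
            zq = z.quantile([0.25, 0.5, 0.75])
            entry["bmi_sds_mean"] = float(z.mean())
            entry["bmi_sds_sd"] = float(z.std(ddof=1))
            entry["bmi_sds_median"] = float(zq[0.5])
            entry["bmi_sds_iqr"] = [float(zq[0.25]), float(zq[0.75])]
        out[year] = entry
    return out


def _agreement_rows(df: pd.DataFrame) -> list[dict]:
    return [
        {k: (v if not isinstance(v, (np.floating, np.bool_)) else
             (bool(v) if isinstance(v, np.bool_) else float(v)))
         for k, v in row.items()}
        for row in df.to_dict(orient="records")
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole analysis; returns (and writes) the stability report."""
    out = Path(config.outdir)
    for sub in ("fits", "rankings", "agreement", "plots"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    if config.reference_csv is not None:
        reference = LMSReferenceTable.from_csv(config.reference_csv)
    else:
        reference = synthetic_reference()

    if config.simulation is not None:
        sim = config.simulation.with_seed(config.seed)
        records = simulate_panel(sim, reference=reference)
        write_pupils(records, out / "pupils.csv", truth_path=out / "pupils_truth.csv")
        records = records.drop(columns=["true_sds"])
    else:
        records = read_pupils(config.pupil_csv)

    records = bmi_sds_frame(records, reference)
    years = sorted(records["year"].unique())
    spec_pooled = ModelSpec(adjusted=True,
                            include_neighbourhood=config.include_neighbourhood,
                            cohort_indicator=config.cohort_indicator)

    report: dict = {
        "seed": int(config.seed),
        "years": years,
        "n_records": int(len(records)),
        "sample_summary": sample_summary(records),
        "icc": {}, "fixed_effects": {}, "within_year": {},
        "between_year": {}, "tracking": {}, "sensitivity": {},
        "files": [],
    }

    def _save(path: Path):
        report["files"].append(str(path.relative_to(out)))

    rankings: dict[str, dict[str, SchoolRanking]] = {}
    for year in years:
        sub = records[records["year"] == year]
        null_spec = ModelSpec(adjusted=False,
                              include_neighbourhood=config.include_neighbourhood)
        null_fit = fit_reml(sub, null_spec)
        report["icc"][year] = {k: float(v) for k, v in icc(null_fit).items()}
        with open(out / "fits" / f"{year.replace('/', '-')}_null.json", "w") as fh:
            json.dump(null_fit.summary_dict(), fh, indent=1, sort_keys=True)
        _save(out / "fits" / f"{year.replace('/', '-')}_null.json")

        pooled = fit_reml(sub, spec_pooled)
        report["fixed_effects"][year] = pooled.summary_dict()["fixed_effects"]
        tag = year.replace("/", "-")
        with open(out / "fits" / f"{tag}_adjusted.json", "w") as fh:
            json.dump(pooled.summary_dict(), fh, indent=1, sort_keys=True)
        pooled.blups["school"].reset_index().to_csv(
            out / "fits" / f"{tag}_adjusted_blups.csv", index=False,
            float_format="%.10g")
        _save(out / "fits" / f"{tag}_adjusted.json")
        _save(out / "fits" / f"{tag}_adjusted_blups.csv")

        yr = {
            "observed": observed_ranking(sub, year, min_pupils=config.min_pupils),
            "expected": expected_ranking(sub, year, fitted=pooled,
                                         min_pupils=config.min_pupils),
            "value_added": value_added_ranking(
                sub, year, spec_pooled,
                min_pupils_per_cohort=config.min_pupils),
        }
        rankings[year] = yr
        for rtype, ranking in yr.items():
            path = out / "rankings" / f"{tag}_{rtype}.csv"
            ranking.to_csv(path)
            _save(path)
            if config.make_plots:
                ppath = out / "plots" / f"caterpillar_{tag}_{rtype}.png"
                caterpillar_plot(ranking, ppath, alpha=config.alpha)
                _save(ppath)

        wt = within_year_table(yr, use=config.compare_on, alpha=config.alpha)
        wt.to_csv(out / "agreement" / f"within_{tag}.csv", index=False,
                  float_format="%.10g")
        _save(out / "agreement" / f"within_{tag}.csv")
        report["within_year"][year] = _agreement_rows(wt)

        if config.sensitivity and config.include_neighbourhood:
            spec_nonb = ModelSpec(adjusted=True, include_neighbourhood=False,
                                  cohort_indicator=config.cohort_indicator)
            exp_nonb = expected_ranking(sub, year, spec_nonb,
                                        min_pupils=config.min_pupils)
            common = yr["expected"].table.index.intersection(exp_nonb.table.index)
            try:
                rc_value = pearson(yr["expected"].table.loc[common, "rank"],
                                   exp_nonb.table.loc[common, "rank"]).value
            except AgreementError as exc:
                logger.warning("sensitivity comparison degenerate in %s: %s",
                               year, exc)
                rc_value = float("nan")
            report["sensitivity"][year] = {
                "expected_rank_correlation_without_neighbourhood": rc_value,
                "n": int(len(common)),
            }

    wide = wide_rank_table(rankings)
    wide.to_csv(out / "rankings" / "wide_rank_table.csv", float_format="%.10g")
    _save(out / "rankings" / "wide_rank_table.csv")

    if len(years) >= 2:
        for rtype in RANKING_TYPES:
            per_year = {y: rankings[y][rtype] for y in years}
            bt = between_year_table(per_year, use=config.compare_on,
                                    alpha=config.alpha)
            bt.to_csv(out / "agreement" / f"between_{rtype}.csv", index=False,
                      float_format="%.10g")
            _save(out / "agreement" / f"between_{rtype}.csv")
            report["between_year"][rtype] = _agreement_rows(bt)
            try:
                track = quintile_track(per_year)
            except AgreementError as exc:
                logger.warning("tracking skipped for %s: %s", rtype, exc)
                continue
            track.labels.to_csv(out / "agreement" / f"quintiles_{rtype}.csv")
            _save(out / "agreement" / f"quintiles_{rtype}.csv")
            report["tracking"][rtype] = {
                "kappa": track.kappa.value,
                "kappa_p": track.kappa.p_value,
                "kappa_ci": [track.kappa.ci_lower, track.kappa.ci_upper],
                "proportion_constant": track.proportion_constant,
                "n_schools": track.kappa.n,
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
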