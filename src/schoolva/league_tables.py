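"""Per-year school rankings: Observed, Expected and Value-added.

Three league tables are built for each academic year:

* **Observed** — schools ranked on their raw mean pupil BMI-SDS, both
  cohorts combined.  Rank 1 is the lowest (leanest) mean.
* **Expected** — schools ranked on how far their mean departs from the
  value expected given pupil ethnicity and deprivation: the school BLUP
  from the adjusted cross-classified model fitted to the pooled cohorts.
* **Value-added** — the Year 6 school residual minus the Reception
  school residual, from cohort-specific fits of the same model.  As
  Reception pupils are largely unexposed to the school, the difference
  reads as the school's net effect on weight status during schooling;
  rank 1 is the most negative score (the most "slimming" school).

Ties share averaged ranks throughout so rank-based agreement statistics
stay well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossclassified import (FittedModel, ModelSpec, NotConvergedError,
                              fit_reml, school_blups)

__all__ = [
    "SchoolRanking",
    "RankingError",
    "rank_scores",
    "observed_ranking",
    "expected_ranking",
    "value_added_ranking",
    "wide_rank_table",
]

logger = logging.getLogger(__name__)

RANKING_TYPES = ("observed", "expected", "value_added")


class RankingError(ValueError):
    """Ranking cannot be built from the given inputs."""


def rank_scores(scores) -> np.ndarray:
    """Ascending averaged ranks (rank 1 = lowest score; ties share means)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 1:
        raise RankingError("need at least one score to rank")
    if not np.all(np.isfinite(arr)):
        raise RankingError("scores must be finite")
    return stats.rankdata(arr, method="average")


@dataclass
class SchoolRanking:
    """One league table: per-school score, SE, averaged rank and size."""

    year: str
    ranking_type: str
    table: pd.DataFrame = field(repr=False)  # index school_id; score, se, rank, n_pupils

    def __post_init__(self):
        if self.ranking_type not in RANKING_TYPES:
            raise RankingError(f"ranking_type must be one of {RANKING_TYPES}")
        if self.table.index.has_duplicates:
            raise RankingError("a school appears more than once in the ranking")

    @property
    def n_schools(self) -> int:
        return len(self.table)

    def ranks(self) -> pd.Series:
        return self.table["rank"]

    def scores(self) -> pd.Series:
        return self.table["score"]

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, year: str, ranking_type: str) -> "SchoolRanking":
        df = pd.read_csv(path, dtype={"school_id": str}).set_index("school_id")
        return cls(year=year, ranking_type=ranking_type, table=df)


def _finalise(year: str, ranking_type: str, df: pd.DataFrame,
              min_pupils: int) -> SchoolRanking:
    kept = df[df["n_pupils"] >= min_pupils].copy()
    dropped = len(df) - len(kept)
    if dropped:
        logger.info("%s ranking %s: excluded %d schools below size threshold %d",
                    ranking_type, year, dropped, min_pupils)
    if kept.empty:
        raise RankingError(f"no eligible schools for {ranking_type} ranking in {year}")
    kept["rank"] = rank_scores(kept["score"].to_numpy())
    kept = kept.sort_index().sort_values("rank", kind="stable")
    return SchoolRanking(year=year, ranking_type=ranking_type,
                         table=kept[["score", "se", "rank", "n_pupils"]])


def _year_records(records: pd.DataFrame, year: str) -> pd.DataFrame:
    sub = records[records["year"] == year]
    if sub.empty:
        raise RankingError(f"no records for year {year!r}")
    return sub


def observed_ranking(records: pd.DataFrame, year: str, *,
                     response: str = "bmi_sds",
                     min_pupils: int = 1) -> SchoolRanking:
    """Rank schools on observed mean BMI-SDS, both cohorts combined."""
    sub = _year_records(records, year)
    grp = sub.groupby("school_id")[response]
    df = pd.DataFrame({
        "score": grp.mean(),
        "se": grp.std(ddof=1) / np.sqrt(grp.count()),
        "n_pupils": grp.count(),
    })
    df["se"] = df["se"].fillna(0.0)  # single-pupil schools
    return _finalise(year, "observed", df, min_pupils)


def expected_ranking(records: pd.DataFrame, year: str,
                     spec: ModelSpec | None = None, *,
                     fitted: FittedModel | None = None,
                     response: str = "bmi_sds",
                     min_pupils: int = 1) -> SchoolRanking:
    """Rank schools on the adjusted-model expected residual (school BLUP).

    ``fitted`` may supply a pre-computed pooled-cohort fit for the year;
    otherwise the model given by ``spec`` (default: adjusted, with the
    neighbourhood factor) is fitted here.  A non-converged fit is
    refused.
    """
    sub = _year_records(records, year)
    if fitted is None:
        fitted = fit_reml(sub, spec or ModelSpec(), response=response)
    if not fitted.converged:
        raise NotConvergedError(
            f"expected ranking {year}: REML fit did not converge")
    df = school_blups(fitted).rename(columns={"residual": "score"})
    return _finalise(year, "expected", df, min_pupils)


def value_added_ranking(records: pd.DataFrame, year: str,
                        spec: ModelSpec | None = None, *,
                        fitted_reception: FittedModel | None = None,
                        fitted_year6: FittedModel | None = None,
                        response: str = "bmi_sds",
                        min_pupils_per_cohort: int = 1) -> SchoolRanking:
    """Rank schools on Year 6 minus Reception expected residuals.

    Cohort-specific fits of the same adjusted model produce two sets of
    school BLUPs; their difference is the value-added score.  Schools
    lacking pupils in either cohort that year are excluded (logged).
    """
    sub = _year_records(records, year)
    base = spec or ModelSpec()
    fits = {}
    for cohort, pre in (("Reception", fitted_reception), ("Year6", fitted_year6)):
        if pre is None:
            cspec = ModelSpec(adjusted=base.adjusted,
                              include_neighbourhood=base.include_neighbourhood,
                              cohort=cohort)
            pre = fit_reml(sub, cspec, response=response)
        if not pre.converged:
            raise NotConvergedError(
                f"value-added ranking {year}: {cohort} fit did not converge")
        fits[cohort] = school_blups(pre)
    rec, y6 = fits["Reception"], fits["Year6"]
    common = rec.index.intersection(y6.index)
    rec = rec.loc[common]
    y6 = y6.loc[common]
    ok = (rec["n_pupils"] >= min_pupils_per_cohort) & \
         (y6["n_pupils"] >= min_pupils_per_cohort)
    excluded = int((~ok).sum()) + (len(rec.index.symmetric_difference(y6.index)))
    if len(common) < len(set(rec.index) | set(y6.index)) or (~ok).any():
        logger.info("value-added ranking %s: excluded %d schools without both "
                    "cohorts at the size threshold", year, excluded)
    df = pd.DataFrame({
        "score": y6.loc[ok, "residual"] - rec.loc[ok, "residual"],
        "se": np.sqrt(y6.loc[ok, "se"] ** 2 + rec.loc[ok, "se"] ** 2),
        "n_pupils": y6.loc[ok, "n_pupils"] + rec.loc[ok, "n_pupils"],
    })
    df.index.name = "school_id"
    return _finalise(year, "value_added", df, min_pupils=1)


def wide_rank_table(rankings: dict[str, dict[str, SchoolRanking]]) -> pd.DataFrame:
    """Combined wide table of ranks: one row per school, (year, Ob/Exp/VA) columns."""
    short = {"observed": "Ob", "expected": "Exp", "value_added": "VA"}
    pieces = {}
    for year in sorted(rankings):
        for rtype, ranking in rankings[year].items():
            pieces[(year, short.get(rtype, rtype))] = ranking.ranks()
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["year", "ranking"])
    out.index.name = "school_id"
    return out.sort_index()
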