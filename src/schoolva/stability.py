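"""Agreement between rankings and their stability across years.

Within a year, pairs of league tables (Observed / Expected /
Value-added) are compared with Lin's concordance correlation
coefficient

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

which penalises both imperfect correlation and location/scale shift
(so |rho_c| <= |r|, the Pearson correlation, with equality only when
the two vectors share mean and variance).  Confidence intervals and
p-values use the inverse-hyperbolic-tangent transform with Lin's
asymptotic standard error.

Across years, each ranking type is compared pairwise between years with
the same statistics, and "tracking" is quantified by splitting each
year's ranking into quintiles and computing a multi-occasion
chance-corrected kappa (Fleiss construction, treating years as
interchangeable raters of each school's quintile), together with the
proportion of schools staying in the same quintile in every year.

By default agreement is computed on rank vectors, since league tables
are compared as rankings; ``use='score'`` switches to the raw scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .league_tables import SchoolRanking

__all__ = [
    "AgreementResult",
    "AgreementError",
    "lin_ccc",
    "pearson",
    "quintiles",
    "tracking_kappa",
    "proportion_constant_quintile",
    "within_year_table",
    "between_year_table",
    "QuintileTrack",
    "quintile_track",
]

logger = logging.getLogger(__name__)

N_QUINTILES = 5


class AgreementError(ValueError):
    """Agreement statistic undefined for the given inputs."""


@dataclass(frozen=True)
class AgreementResult:
    statistic: str
    value: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int

    def __post_init__(self):
        if np.isfinite(self.value) and not -1.0 - 1e-12 <= self.value <= 1.0 + 1e-12:
            raise AgreementError(f"{self.statistic} = {self.value} outside [-1, 1]")

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < alpha)


def _paired(x, y, min_n: int):
    # two Series over the same schools are paired by index, not position
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if len(x.index) == len(y.index) and x.index.sort_values().equals(
                y.index.sort_values()):
            y = y.reindex(x.index)
        else:
            raise AgreementError("Series inputs must share the same index")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("x and y must be equal-length 1-d vectors")
    if x.size < min_n:
        raise AgreementError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AgreementError("inputs must be finite")
    return x, y


def lin_ccc(x, y) -> AgreementResult:
    """Lin's concordance correlation coefficient with CI and p-value.

    Moments use the population (1/n) convention.  The CI is the Fisher
    z-transform interval with Lin's asymptotic variance; the p-value
    tests rho_c = 0 two-sided.  Degenerate inputs with zero variance in
    both vectors raise :class:`AgreementError`.
    """
    x, y = _paired(x, y, min_n=3)
    n = x.size
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    sx2 = float(np.mean(dx * dx))
    sy2 = float(np.mean(dy * dy))
    sxy = float(np.mean(dx * dy))
    d2 = (mx - my) ** 2
    denom = sx2 + sy2 + d2
    if denom == 0.0:
        raise AgreementError("concordance undefined: zero variance in both "
                             "vectors and equal means")
    ccc = 2.0 * sxy / denom

    if sx2 == 0.0 or sy2 == 0.0 or abs(ccc) >= 1.0 - 1e-14:
        # exact agreement/reversal or a degenerate axis: no sampling CI
        p = 0.0 if abs(ccc) >= 1.0 - 1e-14 else np.nan
        return AgreementResult("lin_ccc", float(ccc), float(ccc), float(ccc), p, n)

    r = sxy / np.sqrt(sx2 * sy2)
    u2 = d2 / np.sqrt(sx2 * sy2)  # squared location-shift, scale-free
    one_m = 1.0 - ccc ** 2
    if r == 0.0:
        var_z = 1.0 / (n - 3)  # fallback: Fisher variance for r
    else:
        var_z = ((1.0 - r ** 2) * ccc ** 2 / (one_m * r ** 2)
                 + 4.0 * ccc ** 3 * (1.0 - ccc) * u2 / (r * one_m ** 2)
                 - 2.0 * ccc ** 4 * u2 ** 2 / (r ** 2 * one_m ** 2)) / (n - 2)
    var_z = max(var_z, 0.0)
    se_z = np.sqrt(var_z)
    z = np.arctanh(ccc)
    lo, hi = np.tanh(z - 1.959963984540054 * se_z), np.tanh(z + 1.959963984540054 * se_z)
    p = 2.0 * stats.norm.sf(abs(z) / se_z) if se_z > 0 else 0.0
    return AgreementResult("lin_ccc", float(ccc), float(lo), float(hi), float(p), n)


def pearson(x, y) -> AgreementResult:
    """Pearson product-moment correlation with CI and p-value."""
    x, y = _paired(x, y, min_n=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AgreementError("Pearson correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    try:
        ci = res.confidence_interval()
        lo, hi = float(ci.low), float(ci.high)
    except ValueError:
        lo = hi = float(res.statistic)
    return AgreementResult("pearson", float(res.statistic), lo, hi,
                           float(res.pvalue), x.size)


def quintiles(ranking) -> pd.Series:
    """Quintile label (1-5) per school, from a ranking or a rank vector.

    Schools ordered by rank are cut into 5 contiguous groups with sizes
    as equal as possible; with remainder r, the first r groups take one
    extra school.  Requires n >= 5.
    """
    if isinstance(ranking, SchoolRanking):
        ranks = ranking.ranks()
    elif isinstance(ranking, pd.Series):
        ranks = ranking
    else:
        ranks = pd.Series(np.asarray(ranking, dtype=float))
    n = len(ranks)
    if n < N_QUINTILES:
        raise AgreementError(f"need at least {N_QUINTILES} schools, got {n}")
    base, rem = divmod(n, N_QUINTILES)
    sizes = [base + (1 if i < rem else 0) for i in range(N_QUINTILES)]
    labels = np.repeat(np.arange(1, N_QUINTILES + 1), sizes)
    order = np.argsort(ranks.to_numpy(), kind="stable")
    out = np.empty(n, dtype=int)
    out[order] = labels
    return pd.Series(out, index=ranks.index, name="quintile")


def _complete_label_matrix(labels: pd.DataFrame) -> pd.DataFrame:
    complete = labels.dropna()
    dropped = len(labels) - len(complete)
    if dropped:
        logger.info("tracking: dropped %d schools not present in all years", dropped)
    return complete.astype(int)


def tracking_kappa(labels: pd.DataFrame) -> AgreementResult:
    """Multi-occasion chance-corrected quintile agreement (Fleiss kappa).

    ``labels`` is a schools x years matrix of quintile labels; years are
    treated as interchangeable raters of each school's quintile.  Rows
    with any missing year are dropped (logged).  The p-value tests the
    no-agreement null with the Fleiss asymptotic variance.
    """
    if labels.shape[1] < 2:
        raise AgreementError("tracking needs at least 2 years")
    mat = _complete_label_matrix(labels)
    n_subj = len(mat)
    if n_subj < 2:
        raise AgreementError("too few schools present in all years")
    m = mat.shape[1]
    cats = np.arange(1, N_QUINTILES + 1)
    counts = np.stack([(mat.to_numpy() == c).sum(axis=1) for c in cats], axis=1)

    p_i = (np.sum(counts ** 2, axis=1) - m) / (m * (m - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_subj * m)
    p_e = float(np.sum(p_j ** 2))
    if p_e >= 1.0:
        raise AgreementError("degenerate category distribution")
    kappa = (p_bar - p_e) / (1.0 - p_e)

    q_j = 1.0 - p_j
    s = float(np.sum(p_j * q_j))
    num = s ** 2 - float(np.sum(p_j * q_j * (q_j - p_j)))
    se0 = np.sqrt(2.0 / (n_subj * m * (m - 1))) * np.sqrt(max(num, 0.0)) / s
    if se0 > 0:
        zstat = kappa / se0
        p = float(2.0 * stats.norm.sf(abs(zstat)))
        lo, hi = kappa - 1.959963984540054 * se0, kappa + 1.959963984540054 * se0
    else:
        p, lo, hi = np.nan, kappa, kappa
    return AgreementResult("kappa", float(kappa), float(lo), float(hi), p, n_subj)


def proportion_constant_quintile(labels: pd.DataFrame) -> float:
    """Share of schools keeping the same quintile label in every year."""
    if labels.shape[1] < 2:
        raise AgreementError("need at least 2 years")
    mat = _complete_label_matrix(labels)
    if mat.empty:
        raise AgreementError("no schools present in all years")
    same = (mat.nunique(axis=1) == 1)
    return float(same.mean())


@dataclass
class QuintileTrack:
    """Quintile labels per school/year plus tracking summaries."""

    labels: pd.DataFrame
    kappa: AgreementResult
    proportion_constant: float

    def __post_init__(self):
        if not 0.0 <= self.proportion_constant <= 1.0:
            raise AgreementError("proportion_constant outside [0, 1]")


def quintile_track(rankings: dict[str, SchoolRanking]) -> QuintileTrack:
    """Quintile tracking of one ranking type across years."""
    if len(rankings) < 2:
        raise AgreementError("tracking needs rankings from at least 2 years")
    cols = {}
    for year in sorted(rankings):
        cols[year] = quintiles(rankings[year])
    labels = pd.DataFrame(cols)
    labels.index.name = "school_id"
    return QuintileTrack(labels=labels,
                         kappa=tracking_kappa(labels),
                         proportion_constant=proportion_constant_quintile(labels))


def _vectors(a: SchoolRanking, b: SchoolRanking, use: str):
    common = a.table.index.intersection(b.table.index)
    if len(common) < 3:
        raise AgreementError("fewer than 3 schools common to both rankings")
    col = "rank" if use == "rank" else "score"
    return (a.table.loc[common, col].to_numpy(),
            b.table.loc[common, col].to_numpy())


def _pairwise(a: SchoolRanking, b: SchoolRanking, use: str):
    """rho_c and r for a ranking pair; a degenerate statistic becomes NaN.

    A fully tied ranking (e.g. all school effects shrunk to zero) has a
    zero-variance rank vector: Pearson's r is then undefined while
    rho_c may still be.  Such cases are recorded as NaN, not errors.
    """
    x, y = _vectors(a, b, use)
    out = []
    for func, name in ((lin_ccc, "lin_ccc"), (pearson, "pearson")):
        try:
            out.append(func(x, y))
        except AgreementError as exc:
            logger.warning("%s undefined for %s/%s %s: %s", name,
                           a.ranking_type, b.ranking_type, a.year, exc)
            out.append(AgreementResult(name, np.nan, np.nan, np.nan,
                                       np.nan, len(x)))
    return out


def within_year_table(rankings: dict[str, SchoolRanking], *,
                      use: str = "rank", alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise agreement of the three ranking types within one year.

    Returns tidy rows ``pair, statistic, value, ci_lower, ci_upper, p,
    significant`` for the Observed/Expected, Observed/Value-added and
    Expected/Value-added pairs (rho_c and r each).
    """
    missing = [t for t in ("observed", "expected", "value_added")
               if t not in rankings]
    if missing:
        raise AgreementError(f"missing ranking types {missing}")
    rows = []
    for t1, t2 in combinations(("observed", "expected", "value_added"), 2):
        ccc, r = _pairwise(rankings[t1], rankings[t2], use)
        for res in (ccc, r):
            rows.append({"pair": f"{t1}/{t2}", "statistic": res.statistic,
                         "value": res.value, "ci_lower": res.ci_lower,
                         "ci_upper": res.ci_upper, "p": res.p_value,
                         "n": res.n, "significant": res.significant(alpha)})
    return pd.DataFrame(rows)


def between_year_table(rankings: dict[str, SchoolRanking], *,
                       use: str = "rank", alpha: float = 0.05) -> pd.DataFrame:
    """Year x year agreement of one ranking type on the schools common to each pair.

    Returns tidy rows for every ordered pair (year_a <= year_b),
    including the self-concordant diagonal (rho_c = 1 by construction).
    """
    years = sorted(rankings)
    if len(years) < 2:
        raise AgreementError("between-year comparison needs at least 2 years")
    rows = []
    for i, ya in enumerate(years):
        for yb in years[i:]:
            x, y = _vectors(rankings[ya], rankings[yb], use)
            try:
                res = lin_ccc(x, y)
            except AgreementError as exc:
                logger.warning("lin_ccc undefined for %s vs %s: %s", ya, yb, exc)
                res = AgreementResult("lin_ccc", np.nan, np.nan, np.nan,
                                      np.nan, len(x))
            rows.append({"year_a": ya, "year_b": yb,
                         "pair": f"{ya}/{yb}", "statistic": res.statistic,
                         "value": res.value, "ci_lower": res.ci_lower,
                         "ci_upper": res.ci_upper, "p": res.p_value,
                         "n": res.n, "significant": res.significant(alpha)})
    return pd.DataFrame(rows)
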