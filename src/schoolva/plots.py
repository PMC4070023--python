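"""Caterpillar plots of school rankings with 95% prediction whiskers."""

from __future__ import annotations

import logging
import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .league_tables import SchoolRanking

__all__ = ["caterpillar_plot"]

logger = logging.getLogger(__name__)

_TITLES = {
    "observed": "Observed mean BMI-SDS",
    "expected": "Expected residual (school BLUP)",
    "value_added": "Value-added score (Year 6 − Reception residual)",
}


def caterpillar_plot(ranking: SchoolRanking, out_path, *,
                     alpha: float = 0.05, dpi: int = 120) -> str:
    """Schools in rank order with score ± z·SE whiskers and a zero line.

    Rankings without usable standard errors are plotted as points only,
    with a warning.
    """
    tab = ranking.table.sort_values("rank")
    x = np.arange(1, len(tab) + 1)
    scores = tab["score"].to_numpy()
    fig, ax = plt.subplots(figsize=(9, 4))
    se = tab["se"].to_numpy() if "se" in tab.columns else None
    if se is None or not np.all(np.isfinite(se)):
        warnings.warn("ranking has no usable standard errors; "
                      "plotting without whiskers")
        logger.warning("caterpillar plot %s %s: missing SEs, no whiskers",
                       ranking.year, ranking.ranking_type)
        ax.plot(x, scores, ".", ms=3, color="tab:blue")
    else:
        from scipy.stats import norm
        zq = norm.ppf(1 - alpha / 2)
        ax.errorbar(x, scores, yerr=zq * se, fmt=".", ms=3, lw=0.5,
                    color="tab:blue", ecolor="0.7")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("school (rank order)")
    ax.set_ylabel("BMI-SDS")
    ax.set_title(f"{_TITLES.get(ranking.ranking_type, ranking.ranking_type)}"
                 f" — {ranking.year}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return str(out_path)
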