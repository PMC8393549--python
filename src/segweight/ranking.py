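"""Rank scoring of competing losses via pairwise Wilcoxon signed-rank tests.

The input is a long-form metric table with columns ``metric``, ``loss``,
``class``, ``case``, ``value`` (and optionally ``dataset``).  For every
(metric, class) cell, all loss pairs are compared with a two-sided
Wilcoxon signed-rank test on the paired per-case differences; the
significance score ``s(metric, class, loss)`` counts how many competitors
perform significantly worse (p < alpha, no multiplicity adjustment) than
the loss, "worse" being decided by the orientation-adjusted median
difference (DSC/SDSC higher-better, ASD/95HD lower-better).  The rank
score of a loss is the mean of its significance scores over all metrics
and classes; losses are ranked by descending rank score.

Conventions: zero differences are dropped before ranking (Wilcoxon's
original treatment); the exact null distribution is used for n <= 25
without ties, otherwise the normal approximation with continuity
correction.  Pairs with missing values (undefined surface metrics) are
deleted pairwise; comparisons with fewer than 6 complete pairs are
treated as missing and never add to a significance score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_ORIENTATIONS

__all__ = [
    "RankReport",
    "wilcoxon_pair",
    "pairwise_test",
    "significance_scores",
    "rank_scores",
    "rank_benchmark",
]

MIN_PAIRS = 6


def wilcoxon_pair(x, y, higher_better: bool = True):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(p_value, winner)`` with ``winner`` in {0, 1, None}: the
    index of the sample favoured by the orientation-adjusted median
    difference (mean difference on a zero median; None if both vanish).
    All-zero differences give ``p = 1`` and no winner; fewer than
    ``MIN_PAIRS`` complete pairs give ``(nan, None)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < MIN_PAIRS:
        return float("nan"), None
    d = x - y
    dnz = d[d != 0]
    if dnz.size == 0:
        return 1.0, None
    exact = dnz.size <= 25 and np.unique(np.abs(dnz)).size == dnz.size
    res = stats.wilcoxon(dnz, alternative="two-sided",
                         method="exact" if exact else "approx",
                         correction=not exact)
    shift = np.median(d)
    if shift == 0:
        shift = d.mean()
    if shift == 0:
        return float(res.pvalue), None
    oriented = shift if higher_better else -shift
    return float(res.pvalue), (0 if oriented > 0 else 1)


def _orientation(metric: str, orientations) -> bool:
    table = METRIC_ORIENTATIONS if orientations is None else orientations
    if metric not in table:
        raise ValueError(f"no orientation declared for metric {metric!r}")
    return table[metric] > 0


def _paired(cell: pd.DataFrame, loss_a: str, loss_b: str):
    wide = cell.pivot(index="case", columns="loss", values="value")
    for loss in (loss_a, loss_b):
        if loss not in wide.columns:
            raise ValueError(f"loss {loss!r} absent from table")
    return wide[loss_a].to_numpy(), wide[loss_b].to_numpy()


def pairwise_test(table: pd.DataFrame, metric: str, class_id, loss_a: str,
                  loss_b: str, orientations: Optional[dict] = None):
    """Wilcoxon test between two losses on one (metric, class) cell.

    Returns ``(p_value, better_loss)``; ``better_loss`` is ``None`` on a
    tie or a missing comparison (p is then ``nan``).
    """
    cell = table[(table["metric"] == metric) & (table["class"] == class_id)]
    x, y = _paired(cell, loss_a, loss_b)
    p, winner = wilcoxon_pair(x, y, _orientation(metric, orientations))
    better = {0: loss_a, 1: loss_b, None: None}[winner]
    return p, better


def significance_scores(table: pd.DataFrame, alpha: float = 0.05,
                        orientations: Optional[dict] = None) -> pd.DataFrame:
    """Significance score matrix ``s(metric, class, loss)``.

    ``s`` counts, per (metric, class), the competitors each loss beats at
    ``p < alpha``; values lie in ``[0, J-1]`` for J losses.  Returned as
    a frame indexed by (metric, class) with one column per loss.
    """
    losses = sorted(table["loss"].unique())
    rows = {}
    for (metric, class_id), cell in table.groupby(["metric", "class"]):
        higher_better = _orientation(metric, orientations)
        s = dict.fromkeys(losses, 0)
        for i, la in enumerate(losses):
            for lb in losses[i + 1:]:
                x, y = _paired(cell, la, lb)
                p, winner = wilcoxon_pair(x, y, higher_better)
                if winner is not None and not np.isnan(p) and p < alpha:
                    s[la if winner == 0 else lb] += 1
        rows[(metric, class_id)] = s
    out = pd.DataFrame.from_dict(rows, orient="index").loc[:, losses]
    out.index = pd.MultiIndex.from_tuples(out.index, names=["metric", "class"])
    return out


def rank_scores(s: pd.DataFrame) -> pd.DataFrame:
    """Rank scores from a significance matrix: per-loss mean of ``s`` over
    all (metric, class) cells, ranked descending (ties share the best
    position)."""
    scores = s.mean(axis=0)
    ranks = scores.rank(ascending=False, method="min").astype(int)
    out = pd.DataFrame({"rank_score": scores, "rank": ranks})
    out.index.name = "loss"
    return out.sort_values(["rank", "loss"])


@dataclass
class RankReport:
    """Ranked losses with per-dataset breakdown.

    ``scores`` is indexed by loss with one rank-score column per dataset,
    an ``All`` aggregate (mean over every (dataset, metric, class) cell)
    and the final integer ``rank``; ``significance`` holds the underlying
    per-dataset significance matrices.
    """

    scores: pd.DataFrame
    significance: pd.DataFrame

    def __str__(self):
        return self.scores.to_string(float_format=lambda v: f"{v:.2f}")


def rank_benchmark(table: pd.DataFrame, alpha: float = 0.05,
                   orientations: Optional[dict] = None) -> RankReport:
    """End-to-end ranking of a metric table (optionally dataset-stratified).

    Statistical tests are run within each dataset; the aggregate score is
    the mean significance score over all (dataset, metric, class) cells.
    """
    if table["loss"].nunique() < 2:
        raise ValueError("ranking needs at least 2 losses")
    if "dataset" in table.columns:
        groups = dict(tuple(table.groupby("dataset")))
    else:
        groups = {"All": table}
    mats = {}
    for name, sub in groups.items():
        mats[name] = significance_scores(sub, alpha=alpha,
                                         orientations=orientations)
    per_ds = pd.DataFrame({name: m.mean(axis=0) for name, m in mats.items()})
    pooled = pd.concat(mats.values(), axis=0)
    per_ds["All"] = pooled.mean(axis=0)
    per_ds["rank"] = per_ds["All"].rank(ascending=False, method="min").astype(int)
    per_ds.index.name = "loss"
    significance = pd.concat(mats, names=["dataset"])
    return RankReport(scores=per_ds.sort_values(["rank", "loss"]),
                      significance=significance)
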