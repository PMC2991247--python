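"""Metric-comparison bench: alternative association measures and their agreement
with statistical significance.

Beyond the F score, marker-vs-sites association can be summarized by ROC AUC,
area under the precision-recall curve (with the same normalized false-positive
count the F score uses), odds ratio, Shannon mutual information, and difference
of proportions.  To compare them, markers are ranked under each measure by
filling a strict-inequality N x N matrix; the similarity D of a metric's matrix
to the matrix built from -log10 p quantifies how well the metric tracks
significance (D = 1: identical strict ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import InputError, PeakSet, SiteSet
from .association import (ContingencyTable, DEFAULT_BETA, DEFAULT_WINDOW, LOG10_FLOOR,
                          _coerce_sites, distance_to_nearest, f_score, fisher_pvalue,
                          table_from_distances)

__all__ = [
    "auc_roc", "aupr", "odds_ratio", "smi", "dop",
    "RankingMatrix", "SimilarityReport", "ranking_matrix", "similarity_D",
    "rank_bench", "BenchResult", "METRICS",
]


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def auc_roc(site_d: np.ndarray, ctrl_d: np.ndarray) -> float:
    """P(random site distance < random control distance), ties counted 1/2.

    The rank (Mann-Whitney) formulation; identical to the area under the ROC
    curve obtained by sweeping the window threshold over all distances.
    """
    site_d = np.asarray(site_d, dtype=float)
    ctrl_d = np.asarray(ctrl_d, dtype=float)
    if site_d.size == 0 or ctrl_d.size == 0:
        raise InputError("AUC needs non-empty distance sets")
    from scipy.stats import rankdata
    combined = np.concatenate([site_d, ctrl_d])
    ranks = rankdata(combined)  # average ranks handle ties (incl. inf)
    r_sites = ranks[:site_d.size].sum()
    u = r_sites - site_d.size * (site_d.size + 1) / 2
    # U counts (site > control) pairs under ascending ranks; smaller distance wins
    return float(1.0 - u / (site_d.size * ctrl_d.size))


def aupr(site_d: np.ndarray, ctrl_d: np.ndarray) -> float:
    """Area under the precision(recall) curve swept over distance thresholds.

    Precision uses the normalized false-positive count fp' = fp*V/C so the
    curve lives on the same scale as the F score.  Trapezoidal integration
    over recall, anchored at recall 0 with the first threshold's precision.
    """
    site_d = np.asarray(site_d, dtype=float)
    ctrl_d = np.asarray(ctrl_d, dtype=float)
    if site_d.size == 0 or ctrl_d.size == 0:
        raise InputError("AUPR needs non-empty distance sets")
    V, C = site_d.size, ctrl_d.size
    thresholds = np.unique(np.concatenate([site_d, ctrl_d]))
    thresholds = thresholds[np.isfinite(thresholds)]
    if thresholds.size == 0:
        return 0.0
    tp = np.searchsorted(np.sort(site_d), thresholds, side="right")
    fp = np.searchsorted(np.sort(ctrl_d), thresholds, side="right")
    recall = tp / V
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp * V / C > 0, tp / (tp + fp * V / C), 1.0)
    # anchor the curve at recall 0
    recall = np.concatenate([[0.0], recall])
    prec = np.concatenate([[prec[0]], prec])
    return float(np.trapezoid(prec, recall))


def odds_ratio(t: ContingencyTable) -> tuple[float, bool]:
    """(tp*tn)/(fn*fp); Haldane-Anscombe +0.5 on all cells when any is zero."""
    cells = [t.tp, t.fn, t.fp, t.tn]
    corrected = any(c == 0 for c in cells)
    tp, fn, fp, tn = [c + 0.5 for c in cells] if corrected else cells
    return float(tp * tn / (fn * fp)), corrected


def smi(t: ContingencyTable) -> float:
    """Shannon mutual information (bits) between class and window membership."""
    n = t.V + t.C
    if n == 0:
        raise InputError("empty table")
    joint = t.as_array() / n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def dop(t: ContingencyTable) -> float:
    """Difference of proportions: tp/V - fp/C."""
    if t.V == 0 or t.C == 0:
        raise InputError("DOP requires V > 0 and C > 0")
    return float(t.tp / t.V - t.fp / t.C)


# ---------------------------------------------------------------------------
# ranking matrices and D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankingMatrix:
    """Strict pairwise-outranking indicator over an ordered marker list."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # (N, N) 0/1; (i, j) = 1 iff score_i > score_j

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.shape != (len(self.labels), len(self.labels)):
            raise InputError("ranking matrix shape mismatch")
        object.__setattr__(self, "matrix", m)


def ranking_matrix(labels, values) -> RankingMatrix:
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise InputError("duplicate marker labels")
    if len(labels) < 2:
        raise InputError("ranking needs at least 2 markers")
    v = np.asarray(values, dtype=float)
    m = (v[:, None] > v[None, :]).astype(np.int8)
    np.fill_diagonal(m, 0)
    return RankingMatrix(labels, m)


@dataclass(frozen=True)
class SimilarityReport:
    metric: str
    D: float
    discordant: tuple[tuple[str, str], ...]  # ordered pairs where the matrices differ


def similarity_D(m_x: RankingMatrix, s: RankingMatrix, metric: str = "") -> SimilarityReport:
    """D = 1 - (sum |M_X - S| over off-diagonal pairs) / (N(N-1)); 1 = identical."""
    if m_x.labels != s.labels:
        raise InputError("ranking matrices cover different marker sets")
    n = len(m_x.labels)
    diff = np.abs(m_x.matrix.astype(int) - s.matrix.astype(int))
    np.fill_diagonal(diff, 0)
    discordant = tuple((m_x.labels[i], m_x.labels[j])
                       for i, j in zip(*np.nonzero(diff)))
    return SimilarityReport(metric, float(1.0 - diff.sum() / (n * (n - 1))), discordant)


# ---------------------------------------------------------------------------
# the bench
# ---------------------------------------------------------------------------

METRICS = ("auc", "aupr", "f0.5", "f1", "f2", "or", "smi", "dop")


@dataclass
class BenchResult:
    scores: "object"                       # DataFrame: marker x metric (+ significance)
    matrices: dict[str, RankingMatrix] = field(default_factory=dict)
    similarity: dict[str, SimilarityReport] = field(default_factory=dict)


def _metric_value(name: str, t: ContingencyTable, site_d, ctrl_d) -> float:
    if name == "auc":
        return auc_roc(site_d, ctrl_d)
    if name == "aupr":
        return aupr(site_d, ctrl_d)
    if name.startswith("f"):
        return f_score(t, beta=float(name[1:]))[2]
    if name == "or":
        return odds_ratio(t)[0]
    if name == "smi":
        return smi(t)
    if name == "dop":
        return dop(t)
    raise InputError(f"unknown metric {name!r}")


def rank_bench(sites: SiteSet, controls, markers: list[PeakSet],
               w: float = DEFAULT_WINDOW, metrics=METRICS, mode: str = "summit",
               method: str = "auto") -> BenchResult:
    """Score every marker under every metric and compare rankings to significance.

    Significance ranking uses raw -log10 p capped at 350 (the reporting floor);
    the per-metric D values and discordant pairs feed discordance-grid plots.
    """
    import pandas as pd

    if len(markers) < 2:
        raise InputError("bench needs at least 2 markers")
    labels = [m.label for m in markers]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate marker labels")
    for name in metrics:
        if name not in METRICS:
            raise InputError(f"unknown metric {name!r}")
    controls_s = _coerce_sites(controls)

    rows = {}
    neglog = []
    for marker in markers:
        site_d = distance_to_nearest(sites, marker, mode)
        ctrl_d = distance_to_nearest(controls_s, marker, mode)
        t = table_from_distances(site_d, ctrl_d, w)
        rows[marker.label] = {name: _metric_value(name, t, site_d, ctrl_d)
                              for name in metrics}
        p = fisher_pvalue(t, method)
        neglog.append(min(-p.log10, -LOG10_FLOOR))
    frame = pd.DataFrame(rows).T
    frame["neglog10_p"] = neglog

    s_matrix = ranking_matrix(labels, neglog)
    result = BenchResult(scores=frame)
    for name in metrics:
        m_x = ranking_matrix(labels, frame[name].to_numpy())
        result.matrices[name] = m_x
        result.similarity[name] = similarity_D(m_x, s_matrix, metric=name)
    result.matrices["significance"] = s_matrix
    return result


def plot_discordance_grid(result: BenchResult, out_path) -> None:
    """Discordance grid: one row per metric, markers ordered by significance;
    red cells mark ordered pairs where the metric disagrees with significance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = result.matrices["significance"]
    order = np.argsort(-result.scores["neglog10_p"].to_numpy())
    labels = [sig.labels[i] for i in order]
    metric_names = [m for m in result.matrices if m != "significance"]
    n = len(labels)
    fig, axes = plt.subplots(1, len(metric_names),
                             figsize=(3.2 * len(metric_names), 3.2), squeeze=False)
    for ax, name in zip(axes[0], metric_names):
        diff = np.abs(result.matrices[name].matrix.astype(int) - sig.matrix.astype(int))
        diff = diff[np.ix_(order, order)]
        ax.imshow(diff, cmap="Reds", vmin=0, vmax=1)
        ax.set_title(f"{name} (D={result.similarity[name].D:.2f})", fontsize=9)
        ax.set_xticks(range(n), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(n), labels, fontsize=6)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
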