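"""Hierarchical clustering of molecule time series.

Each molecule's binned intensity record is z-transformed (mean 0, SD 1
across bins) and the standardized rows are clustered agglomeratively
with Euclidean distance and Ward linkage. The tree is cut into two
top-level clusters — an *anthropogenic* cluster whose mean series rises
across the record and a *natural* cluster that is stationary to
declining — and the anthropogenic branch is cut once more into
subcluster 1A (present throughout, rising after the industrial ramp)
and 1B (absent before the industrial onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .trends import BinnedSeries

__all__ = ["ZScoreMatrix", "ClusterResult", "zscore", "hca", "summarize_cluster", "cluster_share"]

DESCRIPTOR_SUMMARY_COLUMNS = ("oc", "osc", "dbe", "chi_c", "nC")


@dataclass
class ZScoreMatrix:
    """Row-standardized molecules × bins matrix.

    Rows are standardized with the sample SD (ddof=1) over that
    molecule's non-missing bins; constant rows become all-zero and are
    flagged in ``degenerate``. Bins that are missing for the whole
    record are dropped (clustering needs complete vectors)."""

    values: pd.DataFrame
    row_mean: pd.Series
    row_sd: pd.Series
    degenerate: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    """Tree, flat labels and per-cluster series/summaries."""

    linkage: np.ndarray
    labels: dict[str, str]
    cluster_mean_series: pd.DataFrame
    summaries: dict[str, dict] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)

    def members(self, cluster: str) -> list[str]:
        return [m for m, c in self.labels.items() if c == cluster]

    def top_level(self) -> dict[str, str]:
        """Labels collapsed to anthropogenic ('1') vs natural ('2')."""
        return {m: ("1" if c in ("1A", "1B") else "2") for m, c in self.labels.items()}


def zscore(binned: BinnedSeries) -> ZScoreMatrix:
    """z-transform each molecule's binned record.

    The transform is invariant to affine rescaling of the raw row;
    degenerate rows (SD = 0) are set to zero and flagged."""
    mat = binned.matrix.dropna(axis=1, how="all")
    if mat.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 populated bins")
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    # constant rows: allow for float accumulation error in the SD
    tiny = 1e-10 * (mean.abs() + 1.0)
    flat = (sd <= tiny) | sd.isna()
    degenerate = list(mat.index[flat])
    safe_sd = sd.mask(flat, np.nan)
    z = mat.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = 0.0
    return ZScoreMatrix(values=z, row_mean=mean, row_sd=sd, degenerate=degenerate)


def _ramp_correlation(series: np.ndarray) -> float:
    ramp = np.arange(series.size, dtype=float)
    if np.ptp(series) == 0:
        return 0.0
    return float(np.corrcoef(series, ramp)[0, 1])


def hca(z: ZScoreMatrix) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering with a 2 + 2 cut.

    The top cut (k = 2) separates the anthropogenic from the natural
    cluster; the anthropogenic branch is identified proxy-free as the
    cluster whose mean z-score series correlates more positively with a
    monotone ramp. Its subtree's own two children give subclusters 1A
    and 1B, 1B being the child with the more depressed early-record
    mean (molecules absent before the industrial onset). Degenerate
    rows are excluded from clustering and reported separately.
    """
    active = z.values.drop(index=z.degenerate)
    ids = list(active.index)
    if len(ids) < 3:
        raise ValueError("clustering needs at least 3 non-degenerate molecules")
    X = active.to_numpy(dtype=float)
    if np.isnan(X).any():
        # complete rows on the common grid: fill per-row missing bins
        # with that row's mean (0 after standardization)
        X = np.nan_to_num(X, nan=0.0)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    root = hierarchy.to_tree(Z)
    left = set(root.get_left().pre_order())
    right = set(root.get_right().pre_order())

    def mean_series(idx: set[int]) -> np.ndarray:
        return X[sorted(idx)].mean(axis=0)

    if _ramp_correlation(mean_series(left)) >= _ramp_correlation(mean_series(right)):
        anthro_node, natural_idx = root.get_left(), right
    else:
        anthro_node, natural_idx = root.get_right(), left

    anthro_idx = set(anthro_node.pre_order())
    labels: dict[str, str] = {ids[i]: "2" for i in natural_idx}
    if anthro_node.is_leaf() or len(anthro_idx) < 2:
        for i in anthro_idx:
            labels[ids[i]] = "1A"
    else:
        sub_a = set(anthro_node.get_left().pre_order())
        sub_b = set(anthro_node.get_right().pre_order())
        n_early = max(1, X.shape[1] // 3)

        def early_mean(idx: set[int]) -> float:
            return float(X[sorted(idx), :n_early].mean())

        if early_mean(sub_a) <= early_mean(sub_b):
            b_idx, a_idx = sub_a, sub_b
        else:
            b_idx, a_idx = sub_b, sub_a
        for i in a_idx:
            labels[ids[i]] = "1A"
        for i in b_idx:
            labels[ids[i]] = "1B"

    order = [c for c in ("1A", "1B", "2") if c in set(labels.values())]
    mean_rows = {
        c: X[[i for i, mid in enumerate(ids) if labels[mid] == c]].mean(axis=0) for c in order
    }
    cluster_mean = pd.DataFrame(mean_rows, index=active.columns).T
    return ClusterResult(
        linkage=Z,
        labels=labels,
        cluster_mean_series=cluster_mean,
        degenerate=list(z.degenerate),
    )


def summarize_cluster(result: ClusterResult, descriptors: pd.DataFrame) -> dict[str, dict]:
    """Per-cluster member count, class tally and descriptor mean ± SD.

    SDs use ddof=1 (NaN for singleton clusters). The summaries are also
    stored on the result."""
    summaries: dict[str, dict] = {}
    for cluster in sorted(set(result.labels.values())):
        members = result.members(cluster)
        d = descriptors.loc[members]
        stats = {
            col: (float(d[col].mean()), float(d[col].std(ddof=1)))
            for col in DESCRIPTOR_SUMMARY_COLUMNS
        }
        summaries[cluster] = {
            "n": len(members),
            "class_counts": d["compound_class"].value_counts().to_dict(),
            "descriptors": stats,
        }
    result.summaries = summaries
    return summaries


def cluster_share(result: ClusterResult, binned: BinnedSeries) -> pd.DataFrame:
    """Per-bin percentage of total intensity carried by each cluster.

    The denominator runs over the labeled molecules only; shares sum to
    100 within each populated bin."""
    labeled = [m for m in binned.matrix.index if m in result.labels]
    mat = binned.matrix.loc[labeled]
    lab = pd.Series({m: result.labels[m] for m in labeled})
    sums = mat.groupby(lab).sum(min_count=1)
    tot = sums.sum(axis=0)
    return 100.0 * sums.div(tot.where(tot > 0), axis=1)
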