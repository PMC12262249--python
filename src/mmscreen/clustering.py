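"""Dynamic-phenotype clustering: Z-score timeseries, soft-DTW distances,
Leiden community detection and jackknife stability.

Each sgRNA's response is summarised as a 6-channel x 20-timepoint matrix of
Z-scores against the per-window distribution of control sgRNAs.  Pairwise
dissimilarities between these multichannel timeseries use soft dynamic time
warping (a soft-minimum relaxation of DTW with smoothing gamma), clusters
come from Leiden modularity optimisation on a kNN affinity graph, and their
robustness is scored by 10 % jackknife resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ZSeriesSet",
    "StabilityReport",
    "zscore_timeseries",
    "weak_phenotype_filter",
    "softdtw",
    "softdtw_matrix",
    "cluster",
    "jackknife_stability",
    "gene_assignment",
]


@dataclass
class ZSeriesSet:
    """Z-score timeseries for a set of sgRNAs.

    values[i] is the (n_channels, n_timepoints) matrix for sgrna_ids[i];
    channels follow ``phenotypes.PARAMETERS`` order.
    """

    sgrna_ids: list[str]
    channels: list[str]
    values: np.ndarray  # (n_sgrna, n_channels, n_timepoints)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("Z-series must be finite")

    def __len__(self) -> int:
        return len(self.sgrna_ids)

    def to_long(self) -> pd.DataFrame:
        n, c, t = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.sgrna_ids, self.channels, range(t)],
            names=["sgrna_id", "channel", "timepoint"],
        )
        return pd.DataFrame({"z": self.values.reshape(-1)}, index=idx).reset_index()


def zscore_timeseries(
    lineages: pd.DataFrame,
    control_sgrnas: list[str],
    channels: list[str],
    n_windows: int = 20,
) -> ZSeriesSet:
    """Bin the experiment into ``n_windows`` equal windows and express each
    sgRNA's per-window mean as a Z-score against the control-sgRNA distribution.

    Z = (sgRNA window mean - mean of control sgRNA window means) / SD across
    control sgRNA window means.  A zero control SD in any window is an error.
    """
    controls = set(control_sgrnas)
    t = lineages["time_min"].to_numpy()
    t_max = t.max() + 1e-9
    window = np.minimum((t / (t_max / n_windows)).astype(int), n_windows - 1)
    df = lineages.assign(_window=window)

    per_sgrna = df.groupby(["sgrna_id", "_window"])[channels].mean()
    sgrna_ids = sorted(df["sgrna_id"].unique())
    ctrl = per_sgrna.loc[per_sgrna.index.get_level_values(0).isin(controls)]
    ctrl_mean = ctrl.groupby("_window").mean()
    ctrl_sd = ctrl.groupby("_window").std(ddof=1)
    ctrl_n = ctrl.groupby("_window").count()
    informative = ctrl_n >= 2
    if (ctrl_sd[informative] <= 0).any().any():
        raise ValueError("control SD is zero in at least one window")
    ctrl_sd = ctrl_sd.where(informative)

    values = np.zeros((len(sgrna_ids), len(channels), n_windows))
    for i, sg in enumerate(sgrna_ids):
        m = per_sgrna.loc[sg].reindex(range(n_windows))
        z = (m - ctrl_mean) / ctrl_sd
        # windows without data (an arrested lineage, or too few control
        # observations to define the null scale) carry no evidence
        values[i] = z.fillna(0.0).to_numpy().T
    return ZSeriesSet(sgrna_ids=sgrna_ids, channels=list(channels), values=values)


def weak_phenotype_filter(z: np.ndarray, threshold: float = 1.0) -> bool:
    """Keep (True) iff the series exceeds the threshold somewhere: max|Z| > 1.

    A maximum of exactly 1.0 is dropped (the criterion is strict).
    """
    return bool(np.max(np.abs(z)) > threshold)


def _softmin(vals: np.ndarray, gamma: float) -> float:
    return float(-gamma * logsumexp(-vals / gamma))


def softdtw(x: np.ndarray, y: np.ndarray, gamma: float = 1.0) -> float:
    """Soft dynamic time warping between multichannel series.

    ``x`` and ``y`` are (n_channels, T) arrays (T may differ); the local cost
    is the squared Euclidean distance across channels, and the recursion is
    D(i,j) = cost(i,j) + softmin_gamma{D(i-1,j), D(i,j-1), D(i-1,j-1)}.
    Symmetric in its arguments; converges to exact DTW as gamma -> 0.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("series must share the channel count")
    # cost[i, j] = ||x[:, i] - y[:, j]||^2
    diff = x[:, :, None] - y[:, None, :]
    cost = np.einsum("cij,cij->ij", diff, diff)
    n, m = cost.shape
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = np.array([D[i - 1, j], D[i, j - 1], D[i - 1, j - 1]])
            D[i, j] = cost[i - 1, j - 1] + _softmin(prev, gamma)
    return float(D[n, m])


def softdtw_matrix(series: list[np.ndarray] | np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Symmetric pairwise soft-DTW distance matrix with a zero diagonal.

    Self-distances are set to zero (raw soft-DTW self-scores are negative for
    small gamma; only relative dissimilarities feed the graph).
    """
    n = len(series)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = softdtw(series[i], series[j], gamma)
    return D


def cluster(
    distances: np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a kNN affinity graph of the distance matrix.

    Edges connect each point to its ``k_neighbors`` nearest neighbours with
    affinity exp(-d / sigma_i), sigma_i the median distance to those k
    neighbours (local scaling); Leiden optimises RB-configuration modularity
    at the given resolution and is deterministic under the seed.
    """
    import igraph as ig
    import leidenalg

    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if k_neighbors >= n:
        warnings.warn(f"k_neighbors={k_neighbors} >= n={n}; reducing to {n - 1}")
        k_neighbors = max(n - 1, 1)

    order = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1)
    knn_d = np.take_along_axis(D, order[:, :k_neighbors], axis=1)
    sigma = np.maximum(np.median(knn_d, axis=1), np.finfo(float).tiny)
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in order[i, :k_neighbors]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            w = float(np.exp(-D[i, j] / sigma[i]))
            edges[(a, b)] = max(edges.get((a, b), 0.0), w)
    graph = ig.Graph(n=n, edges=list(edges), edge_attrs={"weight": list(edges.values())})
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


@dataclass
class StabilityReport:
    """Mean jackknife Jaccard and recall per original cluster."""

    table: pd.DataFrame  # cluster, jaccard, recall
    n_resamples: int


def jackknife_stability(
    distances: np.ndarray,
    labels: np.ndarray,
    cluster_fn=None,
    drop_frac: float = 0.10,
    n_resamples: int = 50,
    seed: int = 0,
    **cluster_kwargs,
) -> StabilityReport:
    """Cluster robustness under repeated 10 % jackknife resampling.

    Each resample drops ``drop_frac`` of points, reclusters the remaining
    distance submatrix and matches every original cluster (restricted to the
    retained points) to its best-overlapping resampled cluster.  Scores are
    Jaccard |A&B|/|A|B| and recall |A&B|/|A|, averaged over resamples; a
    cluster entirely dropped in a resample scores 0 in that resample.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if cluster_fn is None:
        cluster_fn = lambda d, s: cluster(d, seed=s, **cluster_kwargs)  # noqa: E731
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    n = labels.size
    clusters = np.unique(labels)
    jac = {c: [] for c in clusters}
    rec = {c: [] for c in clusters}
    n_drop = max(int(round(drop_frac * n)), 1)
    for r in range(n_resamples):
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))
        sub_labels = cluster_fn(distances[np.ix_(keep, keep)], int(rng.integers(2**31)))
        for c in clusters:
            A = set(np.flatnonzero(labels == c)) & set(keep)
            if not A:
                jac[c].append(0.0)
                rec[c].append(0.0)
                continue
            best_j = best_r = 0.0
            for c2 in np.unique(sub_labels):
                B = set(keep[sub_labels == c2])
                inter = len(A & B)
                if inter == 0:
                    continue
                j = inter / len(A | B)
                if j > best_j:
                    best_j = j
                    best_r = inter / len(A)
            jac[c].append(best_j)
            rec[c].append(best_r)
    table = pd.DataFrame(
        {
            "cluster": clusters,
            "jaccard": [float(np.mean(jac[c])) for c in clusters],
            "recall": [float(np.mean(rec[c])) for c in clusters],
        }
    )
    return StabilityReport(table=table, n_resamples=n_resamples)


def gene_assignment(sgrna_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene to the cluster holding the plurality of its sgRNAs.

    ``sgrna_table`` needs columns ``gene`` and ``cluster``.  Exact ties for
    the plurality assign all tied clusters (two for a two-way tie).
    """
    rows = []
    for gene, grp in sgrna_table.groupby("gene"):
        counts = grp["cluster"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index.tolist())
        rows.append({"gene": gene, "clusters": winners, "n_sgrnas": len(grp)})
    return pd.DataFrame(rows)
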