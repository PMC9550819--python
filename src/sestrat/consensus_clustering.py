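"""Consensus K-means clustering of seRNA activity with PAC-based k selection.

Tumors are grouped by resampled K-means: for each candidate k, samples are
repeatedly subsampled without replacement, clustered, and the consensus
matrix entry (i, j) is the fraction of resamples containing both i and j in
which they co-clustered. Final labels come from average-linkage hierarchical
clustering of 1 - consensus. The number of clusters is chosen by minimizing
the proportion of ambiguous clustering (PAC): the mass of the consensus-CDF
between two quantile bounds (defaults 0.1 and 0.9); low PAC means most
pairs are either always or never co-clustered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io_formats import ExprMatrix, logger


@dataclass
class ConsensusResult:
    """Consensus clustering output for one value of k."""

    k: int
    consensus: np.ndarray          # n x n in [0, 1]
    cosample_counts: np.ndarray    # n x n integers
    labels: np.ndarray             # 1..k per sample
    cdf_values: np.ndarray         # sorted upper-triangle consensus values
    pac: float
    delta_area: float = float("nan")

    def validate(self) -> None:
        c = self.consensus
        assert np.allclose(c, c.T), "consensus matrix must be symmetric"
        assert ((c >= 0) & (c <= 1)).all(), "consensus entries must lie in [0, 1]"
        diag_defined = np.diag(self.cosample_counts) > 0
        assert np.allclose(np.diag(c)[diag_defined], 1.0), "unit diagonal where defined"
        assert set(np.unique(self.labels)) == set(range(1, self.k + 1))


def prepare_features(
    matrix: ExprMatrix, top_n: int = 2000
) -> np.ndarray:
    """Samples x features array for clustering: top-``top_n`` features by
    median absolute deviation on the log2 scale, each z-scored."""
    log = matrix.to_log2().values
    med = np.median(log, axis=1, keepdims=True)
    mad = np.median(np.abs(log - med), axis=1)
    order = np.argsort(mad, kind="stable")[::-1][: min(top_n, len(mad))]
    sel = log[np.sort(order)]
    sd = sel.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sel - sel.mean(axis=1, keepdims=True)) / sd
    return z.T


def kmeans(
    X: np.ndarray, k: int, seed: int | None = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means (k-means++ initialization, best of ``n_init`` restarts).

    Returns (labels, centers, inertia); labels are 0-based.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds n={X.shape[0]} samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def consensus_cluster(
    X: np.ndarray,
    k: int,
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    pac_lower: float = 0.1,
    pac_upper: float = 0.9,
) -> ConsensusResult:
    """Resampled K-means consensus for one k (X: samples x features)."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    n = X.shape[0]
    n_sub = int(np.ceil(subsample_frac * n))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_resamples * 2, dtype=np.uint32).reshape(-1, 2)

    cocluster = np.zeros((n, n), dtype=np.int64)
    cosample = np.zeros((n, n), dtype=np.int64)
    for r in range(n_resamples):
        rng = np.random.default_rng(child_seeds[r, 0])
        idx = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        labels, _, _ = kmeans(X[idx], k, seed=int(child_seeds[r, 1] % (2**31)), n_init=n_init)
        onehot = np.zeros((n_sub, k), dtype=np.int64)
        onehot[np.arange(n_sub), labels] = 1
        cocluster[np.ix_(idx, idx)] += onehot @ onehot.T
        cosample[np.ix_(idx, idx)] += 1

    consensus = np.zeros((n, n), dtype=float)
    sampled = cosample > 0
    consensus[sampled] = cocluster[sampled] / cosample[sampled]
    never = ~sampled
    np.fill_diagonal(never, False)
    if never.any():
        logger.warning(
            "%d sample pairs never co-sampled; their consensus is set to 0",
            int(never.sum()) // 2,
        )
    consensus = (consensus + consensus.T) / 2.0
    np.fill_diagonal(consensus, np.where(np.diag(cosample) > 0, 1.0, 0.0))

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # fcluster can merge groups in degenerate geometry; relabel to 1..k' contiguous
    uniq = np.unique(labels)
    remap = {u: i + 1 for i, u in enumerate(uniq)}
    labels = np.array([remap[u] for u in labels])

    iu = np.triu_indices(n, k=1)
    vals = np.sort(consensus[iu])
    pac = _ecdf(vals, pac_upper) - _ecdf(vals, pac_lower)
    return ConsensusResult(
        k=k,
        consensus=consensus,
        cosample_counts=cosample,
        labels=labels,
        cdf_values=vals,
        pac=float(pac),
    )


def _ecdf(sorted_vals: np.ndarray, x: float) -> float:
    return float(np.searchsorted(sorted_vals, x, side="right")) / len(sorted_vals)


def _cdf_area(sorted_vals: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values over [0, 1]."""
    grid = np.concatenate([[0.0], sorted_vals, [1.0]])
    heights = np.arange(len(sorted_vals) + 1) / len(sorted_vals)
    return float(np.sum(heights * np.diff(grid)))


def run_consensus_sweep(
    X: np.ndarray,
    k_range: range | list[int],
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    pac_lower: float = 0.1,
    pac_upper: float = 0.9,
) -> dict[int, ConsensusResult]:
    """Consensus clustering for each k; fills in delta_area across k."""
    results: dict[int, ConsensusResult] = {}
    prev_area = None
    for i, k in enumerate(sorted(k_range)):
        res = consensus_cluster(
            X, k, n_resamples, subsample_frac, seed=seed + 7919 * i,
            n_init=n_init, pac_lower=pac_lower, pac_upper=pac_upper,
        )
        area = _cdf_area(res.cdf_values)
        res.delta_area = area if prev_area is None else (area - prev_area) / prev_area
        prev_area = area
        results[k] = res
    return results


def select_k(results: dict[int, ConsensusResult], flat_tol: float = 0.02) -> int:
    """Choose k by PAC minimization; ties and flat profiles go to smaller k.

    When the PAC profile is flat (max - min < ``flat_tol``) there is no
    evidence of structure and the smallest k is returned with a warning.
    """
    ks = sorted(results)
    if len(ks) == 1:
        logger.warning("single k in range; returning k=%d without selection", ks[0])
        return ks[0]
    pacs = np.array([results[k].pac for k in ks])
    if pacs.max() - pacs.min() < flat_tol:
        logger.warning("PAC profile flat (no cluster structure); returning k=%d", ks[0])
        return ks[0]
    return ks[int(np.argmin(pacs))]


def adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (chance-corrected, in [-1, 1])."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))
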