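"""One-vs-rest differential expression by Wilcoxon rank-sum.

Each feature is tested cluster-vs-rest on log2(x+1) values with a two-sided
Wilcoxon rank-sum test: exact enumeration when both groups have <= 8
samples and the values are tie-free, otherwise the tie-corrected normal
approximation with continuity correction. The fold change is the difference
of group means on the log2 scale. p-values are BH-adjusted across features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExprMatrix


@dataclass
class DEResult:
    feature_id: str
    cluster: int
    log2fc: float
    p: float
    q: float = float("nan")

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-values must lie in (0, 1]; got {bad}")
    return multipletests(p, method="fdr_bh")[1]


def _use_exact(a: np.ndarray, b: np.ndarray) -> bool:
    if len(a) > 8 or len(b) > 8:
        return False
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) == len(pooled)


def de_test(
    matrix: ExprMatrix,
    labels: Sequence[int],
    cluster: int,
    min_group: int = 3,
) -> list[DEResult]:
    """Wilcoxon rank-sum DE of ``cluster`` vs the rest, per feature."""
    labels = np.asarray(labels)
    if len(labels) != len(matrix.sample_ids):
        raise ValueError("labels length must match number of samples")
    in_c = labels == cluster
    n_in, n_out = int(in_c.sum()), int((~in_c).sum())
    if n_in < min_group:
        raise ValueError(f"cluster {cluster} has only {n_in} samples (< {min_group})")
    if n_out < min_group:
        raise ValueError(f"rest of cohort for cluster {cluster} has only {n_out} samples")
    log = matrix.to_log2().values
    A = log[:, in_c]
    B = log[:, ~in_c]
    lfc = A.mean(axis=1) - B.mean(axis=1)

    # vectorized asymptotic branch; exact branch per-feature where applicable;
    # constant features carry no rank information and get p = 1
    const = log.max(axis=1) == log.min(axis=1)
    exact_mask = np.array([_use_exact(A[i], B[i]) for i in range(log.shape[0])])
    exact_mask &= ~const
    approx_mask = ~exact_mask & ~const
    pvals = np.ones(log.shape[0])
    if approx_mask.any():
        res = stats.mannwhitneyu(
            A[approx_mask], B[approx_mask], axis=1,
            alternative="two-sided", method="asymptotic", use_continuity=True,
        )
        pvals[approx_mask] = res.pvalue
    for i in np.flatnonzero(exact_mask):
        pvals[i] = stats.mannwhitneyu(
            A[i], B[i], alternative="two-sided", method="exact"
        ).pvalue
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    qvals = bh_adjust(pvals)
    return [
        DEResult(fid, cluster, float(lfc[i]), float(pvals[i]), float(qvals[i]))
        for i, fid in enumerate(matrix.feature_ids)
    ]


def deg_sets(
    results: Iterable[DEResult], q_max: float = 0.05, lfc_min: float = 1.0
) -> tuple[set[str], set[str]]:
    """(up, down) feature sets at the q and |log2FC| gates."""
    up, down = set(), set()
    for r in results:
        if r.q <= q_max:
            if r.log2fc >= lfc_min:
                up.add(r.feature_id)
            elif r.log2fc <= -lfc_min:
                down.add(r.feature_id)
    return up, down
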