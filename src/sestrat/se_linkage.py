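"""SE -> target-gene linkage by windowed expression correlation.

An SE and a gene are candidates when the gene's TSS lies within a fixed
window (default 500 kb, boundary inclusive) of the SE interval on the same
chromosome; the distance is TSS-to-interval, zero when the TSS falls inside
the SE. Candidates are scored by Spearman (default) or Pearson correlation
of seRNA and mRNA across samples on the log2 scale, with BH correction over
all tested pairs jointly. SE-regulated potential genes (SPGs) are the genes
with at least one link passing the correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .diffexpr import bh_adjust, de_test, deg_sets
from .io_formats import ExprMatrix, SERegion, TssRecord, logger


@dataclass
class SpgLink:
    """One SE-gene link with its correlation screen statistics."""

    se_id: str
    gene_id: str
    distance_bp: int
    rho: float
    p: float
    q: float = float("nan")


def candidate_pairs(
    se_regions: Sequence[SERegion],
    tss_table: Sequence[TssRecord],
    window_bp: int = 500_000,
) -> list[tuple[str, str, int]]:
    """All (se_id, gene_id, distance_bp) with TSS within ``window_bp`` of the SE.

    Distance is from the TSS to the SE interval (0 if contained); the window
    boundary is inclusive.
    """
    if not tss_table:
        logger.warning("empty TSS table; no candidate pairs")
        return []
    by_chrom: dict[str, list[TssRecord]] = {}
    for rec in tss_table:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    pairs: list[tuple[str, str, int]] = []
    for se in se_regions:
        for rec in by_chrom.get(se.chrom, ()):
            if se.start <= rec.tss < se.end:
                d = 0
            elif rec.tss < se.start:
                d = se.start - rec.tss
            else:
                d = rec.tss - se.end
            if d <= window_bp:
                pairs.append((se.se_id, rec.gene_id, d))
    return pairs


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (n <= 9)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def correlate_links(
    pairs: Iterable[tuple[str, str, int]],
    se_rna: ExprMatrix,
    mrna: ExprMatrix,
    method: str = "spearman",
) -> list[SpgLink]:
    """Correlation screen of candidate pairs on the log2 scale.

    p-values come from the t-approximation, or exact permutation when
    n <= 9; BH adjustment is applied jointly across all tested pairs.
    Zero-variance vectors make the correlation undefined; such pairs are
    skipped with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    mrna = mrna.align_samples(se_rna.sample_ids)
    n = len(se_rna.sample_ids)
    if n < 3:
        raise ValueError("need >= 3 samples to correlate")
    se_log = se_rna.to_log2()
    m_log = mrna.to_log2()
    se_arr = se_log.values
    m_arr = m_log.values
    se_idx = {f: i for i, f in enumerate(se_log.feature_ids)}
    m_idx = {f: i for i, f in enumerate(m_log.feature_ids)}

    pair_list = list(pairs)
    if not pair_list:
        return []
    x_rows = np.array([se_idx[p[0]] for p in pair_list])
    y_rows = np.array([m_idx[p[1]] for p in pair_list])
    X = se_arr[x_rows]
    Y = m_arr[y_rows]
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        Y = stats.rankdata(Y, axis=1)
    xsd = X.std(axis=1)
    ysd = Y.std(axis=1)
    ok = (xsd > 0) & (ysd > 0)
    if not ok.all():
        for i in np.flatnonzero(~ok):
            logger.warning(
                "pair (%s, %s) skipped: zero-variance vector",
                pair_list[i][0], pair_list[i][1],
            )
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc * Yc).sum(axis=1) / (n * xsd * ysd)
    rho = np.clip(rho, -1.0, 1.0)

    links: list[SpgLink] = []
    pvals: list[float] = []
    for i, (sid, gid, d) in enumerate(pair_list):
        if not ok[i]:
            continue
        r = float(rho[i])
        if n <= 9:
            p = _spearman_exact_p(X[i], Y[i], r) if method == "spearman" else \
                stats.permutation_test(
                    (se_arr[x_rows[i]],),
                    lambda x: np.corrcoef(x, m_arr[y_rows[i]])[0, 1],
                    permutation_type="pairings", n_resamples=np.inf,
                ).pvalue
            p = float(p)
        else:
            # t-approximation: t = r sqrt((n-2)/(1-r^2))
            if abs(r) >= 1.0:
                p = np.finfo(float).tiny
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        links.append(SpgLink(sid, gid, int(d), r, p))
        pvals.append(p)
    if links:
        qvals = bh_adjust(np.array(pvals))
        for link, q in zip(links, qvals):
            link.q = float(q)
    return links


def define_spgs(
    links: Iterable[SpgLink],
    rho_min: float = 0.3,
    q_max: float = 0.05,
    sign: str = "positive",
) -> set[str]:
    """Genes with at least one link passing the correlation screen.

    ``sign`` is "positive" (default), "negative" or "both"; the magnitude
    gate is |rho| >= rho_min in all cases.
    """
    if sign not in ("positive", "negative", "both"):
        raise ValueError(f"unknown sign constraint {sign!r}")
    out: set[str] = set()
    for link in links:
        if np.isnan(link.q) or link.q > q_max or abs(link.rho) < rho_min:
            continue
        if sign == "positive" and link.rho <= 0:
            continue
        if sign == "negative" and link.rho >= 0:
            continue
        out.add(link.gene_id)
    return out


def cluster_specific_ses(
    se_rna: ExprMatrix,
    labels: Sequence[int],
    cluster: int,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
) -> set[str]:
    """SEs specifically activated in ``cluster``: one-vs-rest up-regulated
    (q <= q_max and log2 fold change >= lfc_min)."""
    results = de_test(se_rna, labels, cluster)
    up, _ = deg_sets(results, q_max=q_max, lfc_min=lfc_min)
    return up
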