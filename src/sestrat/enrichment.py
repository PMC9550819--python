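"""Gene-set overlap and promoter motif enrichment.

SE-regulated genes are the SPGs that are also differentially expressed in
the matching direction; the SPG/DEG overlap is tested one-sided against the
expressed-gene universe with Fisher's exact test. Candidate transcription
factors are then nominated by scanning SE-regulated-gene promoters with a
PWM library (log2-odds vs a uniform background, hits called at a fraction
of the maximum achievable score, both strands) and testing each motif's
foreground-vs-background hit counts with a one-sided Fisher test, BH
adjusted across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import ALPHABET, Pwm, logger

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    odds_ratio: float
    p: float
    genes: frozenset[str]


@dataclass
class MotifEnrichment:
    motif_id: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    odds_ratio: float
    p: float
    q: float = float("nan")


def _table_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio of a 2x2 table with Haldane 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """One-sided (greater) Fisher's exact test of the overlap of two gene
    sets drawn from a common universe: P(X >= observed overlap) under the
    hypergeometric null."""
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    stray = (set_a | set_b) - universe
    if stray:
        raise ValueError(f"sets not contained in universe: {sorted(stray)[:5]}")
    N, na, nb = len(universe), len(set_a), len(set_b)
    if N == 0:
        raise ValueError("empty universe")
    overlap = set_a & set_b
    x = len(overlap)
    p = float(stats.hypergeom.sf(x - 1, N, na, nb))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    odds = _table_odds_ratio(x, na - x, nb - x, N - na - nb + x)
    return OverlapResult(N, na, nb, x, float(odds), p, frozenset(overlap))


def se_regulated_genes(
    spgs: Iterable[str],
    deg_up: Iterable[str],
    deg_down: Iterable[str],
    cluster_direction: str,
    universe: Iterable[str],
) -> tuple[set[str], OverlapResult]:
    """SPGs intersected with the directed DEG set (up- or down-regulated,
    per cluster), with the overlap tested against the expressed universe."""
    if cluster_direction not in ("up", "down"):
        raise ValueError(f"cluster_direction must be 'up' or 'down', got {cluster_direction!r}")
    degs = set(deg_up) if cluster_direction == "up" else set(deg_down)
    res = fisher_overlap(set(spgs), degs, universe)
    return set(res.genes), res


def _encode(sequence: str) -> np.ndarray:
    """Sequence -> integer codes; N (or any non-ACGT) -> 4."""
    return np.array([_BASE_INDEX.get(b, 4) for b in sequence.upper()], dtype=np.int8)


def pwm_scan(
    sequence: str, pwm: Pwm, threshold_frac: float = 0.8
) -> list[tuple[int, str, float]]:
    """Scan both strands with a PWM; return (offset, strand, score) hits.

    Scores are log2-odds against a uniform background; N positions
    contribute 0. A hit requires score >= threshold_frac * maximum
    achievable score. Offsets are 0-based on the forward strand.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    L = len(pwm)
    if L > len(sequence):
        return []
    fwd_scores, rev_scores, threshold = _scan_scores(sequence, pwm, threshold_frac)
    hits: list[tuple[int, str, float]] = []
    for off in np.flatnonzero(fwd_scores >= threshold - 1e-12):
        hits.append((int(off), "+", float(fwd_scores[off])))
    for off in np.flatnonzero(rev_scores >= threshold - 1e-12):
        hits.append((int(off), "-", float(rev_scores[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _scan_scores(
    sequence: str, pwm: Pwm, threshold_frac: float
) -> tuple[np.ndarray, np.ndarray, float]:
    L = len(pwm)
    logodds = np.log2(pwm.probs / 0.25)               # L x 4
    logodds = np.hstack([logodds, np.zeros((L, 1))])  # N column scores 0
    max_score = float(logodds[:, :4].max(axis=1).sum())
    threshold = threshold_frac * max_score
    codes = _encode(sequence)
    # minus-strand scan == forward scan with the reverse-complemented PWM
    rc_logodds = logodds[::-1][:, [3, 2, 1, 0, 4]]
    n_off = len(sequence) - L + 1
    windows = codes[np.arange(n_off)[:, None] + np.arange(L)[None, :]]  # n_off x L
    rows = np.arange(L)[None, :]
    fwd_scores = logodds[rows, windows].sum(axis=1)
    rev_scores = rc_logodds[rows, windows].sum(axis=1)
    return fwd_scores, rev_scores, threshold


def has_motif_hit(sequence: str, pwm: Pwm, threshold_frac: float = 0.8) -> bool:
    """Whether the sequence has >= 1 scan hit on either strand."""
    if len(pwm) > len(sequence):
        return False
    fwd, rev, thr = _scan_scores(sequence, pwm, threshold_frac)
    return bool((fwd >= thr - 1e-12).any() or (rev >= thr - 1e-12).any())


def motif_enrichment(
    fg_genes: Iterable[str],
    promoters: Mapping[str, str],
    pwms: Sequence[Pwm],
    bg_genes: Iterable[str] | None = None,
    threshold_frac: float = 0.8,
) -> list[MotifEnrichment]:
    """Per-motif over-representation of promoter hits in foreground genes.

    A gene counts as a hit when its promoter has >= 1 scan hit. Background
    defaults to all non-foreground promoters. One-sided Fisher per motif,
    BH across motifs.
    """
    fg = [g for g in fg_genes]
    missing = [g for g in fg if g not in promoters]
    if missing:
        logger.warning("%d foreground genes lack promoters; dropped", len(missing))
        fg = [g for g in fg if g in promoters]
    if bg_genes is None:
        bg = [g for g in promoters if g not in set(fg)]
    else:
        bg = [g for g in bg_genes if g in promoters]
        overlap = set(fg) & set(bg)
        if overlap:
            raise ValueError(f"foreground and background overlap: {sorted(overlap)[:5]}")
    results: list[MotifEnrichment] = []
    for pwm in pwms:
        fg_hits = sum(1 for g in fg if has_motif_hit(promoters[g], pwm, threshold_frac))
        bg_hits = sum(1 for g in bg if has_motif_hit(promoters[g], pwm, threshold_frac))
        table = [[fg_hits, len(fg) - fg_hits], [bg_hits, len(bg) - bg_hits]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        p = min(max(p, np.finfo(float).tiny), 1.0)
        odds = _table_odds_ratio(fg_hits, len(fg) - fg_hits, bg_hits, len(bg) - bg_hits)
        results.append(
            MotifEnrichment(pwm.motif_id, fg_hits, len(fg), bg_hits, len(bg), odds, p)
        )
    if results:
        qvals = bh_adjust([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results
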