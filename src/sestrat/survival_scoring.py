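"""Kaplan-Meier estimation, k-group log-rank testing and signature scoring.

Survival validation of a stratification: per-group product-limit curves and
the k-group log-rank chi-square (observed-minus-expected event counts with
hypergeometric covariance summed over event times, df = k-1). Single-sample
signature scoring (e.g. a glycolysis gene set) is the mean of per-gene
z-scores on the log2 scale. Ties between censored and event times follow
the standard convention: censored observations are removed after events at
the same time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io_formats import ExprMatrix, SurvivalRecord, logger


@dataclass
class KmCurve:
    """A product-limit survival curve."""

    event_times: np.ndarray     # ascending distinct event times
    survival_probs: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray         # n at risk just before each event time
    n_events: np.ndarray        # events at each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


@dataclass
class SignatureScore:
    sample_id: str
    score: float
    n_genes_used: int


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit estimate from right-censored records."""
    if not records:
        raise ValueError("no survival records")
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter().fit(times, events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    probs = np.array([float(sf.loc[t]) for t in event_times])
    return KmCurve(
        event_times=event_times,
        survival_probs=probs,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
    )


def logrank_test(
    records: Sequence[SurvivalRecord], groups: Sequence
) -> LogrankResult:
    """k-group log-rank test (chi-square with k-1 degrees of freedom)."""
    if len(records) != len(groups):
        raise ValueError("records and groups must have equal length")
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 non-empty groups")
    times, events = _to_arrays(records)
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(
        chi2=float(res.test_statistic), df=len(uniq) - 1, p=float(res.p_value)
    )


def signature_score(
    expr: ExprMatrix, gene_set: Iterable[str]
) -> list[SignatureScore]:
    """Mean per-gene z-score (log2 scale) over the signature genes present.

    Zero-variance genes are dropped with a warning and excluded from
    ``n_genes_used``.
    """
    genes = [g for g in gene_set if g in expr.feature_ids]
    if not genes:
        raise ValueError("no signature gene present in expression matrix")
    log = expr.subset_features(genes).to_log2().values
    sds = log.std(axis=1, ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("zero-variance signature genes dropped: %s", dropped[:5])
    if not keep.any():
        raise ValueError("all signature genes have zero variance")
    z = (log[keep] - log[keep].mean(axis=1, keepdims=True)) / sds[keep][:, None]
    scores = z.mean(axis=0)
    n_used = int(keep.sum())
    return [
        SignatureScore(s, float(v), n_used)
        for s, v in zip(expr.sample_ids, scores)
    ]


def median_split(index: Mapping[str, float]) -> dict[str, str]:
    """Dichotomize a per-sample index at the cohort median (high/low)."""
    vals = np.array(list(index.values()), dtype=float)
    med = float(np.median(vals))
    return {s: ("high" if v > med else "low") for s, v in index.items()}


def stratified_km_report(
    records: Sequence[SurvivalRecord],
    groups: Mapping[str, object] | None = None,
    index: Mapping[str, float] | None = None,
    cut_rule: str = "median",
) -> tuple[dict, LogrankResult]:
    """Per-group KM curves plus the k-group log-rank test.

    Groups come either directly from ``groups`` (sample -> label) or from a
    scalar ``index`` dichotomized by ``cut_rule`` (only "median" supported).
    """
    if (groups is None) == (index is None):
        raise ValueError("provide exactly one of groups or index")
    if index is not None:
        if cut_rule != "median":
            raise ValueError(f"unknown cut rule {cut_rule!r}")
        groups = median_split(index)
    by_sample = dict(groups)
    missing = [r.sample_id for r in records if r.sample_id not in by_sample]
    extra = set(by_sample) - {r.sample_id for r in records}
    if missing or extra:
        raise ValueError(
            f"unmatched sample ids: records without group {missing[:5]}, "
            f"groups without record {sorted(extra)[:5]}"
        )
    labels = [by_sample[r.sample_id] for r in records]
    curves = {
        g: km_estimate([r for r, l in zip(records, labels) if l == g])
        for g in sorted(set(labels), key=str)
    }
    lr = logrank_test(records, labels)
    return curves, lr
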