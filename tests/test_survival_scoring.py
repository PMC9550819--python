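import numpy as np
import pandas as pd
import pytest

from sestrat import (
    ExprMatrix,
    SurvivalRecord,
    km_estimate,
    logrank_test,
    median_split,
    signature_score,
    stratified_km_report,
)


def recs(times, events, prefix="S"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def test_km_all_censored_stays_at_one():
    curve = km_estimate(recs([1, 2, 3], [0, 0, 0]))
    assert len(curve.event_times) == 0
    assert curve.survival_at(99) == 1.0


def test_km_single_event_first_time():
    curve = km_estimate(recs([1, 2, 3, 4], [1, 0, 0, 0]))
    assert curve.survival_at(1) == pytest.approx(0.75)
    assert curve.survival_at(10) == pytest.approx(0.75)


def test_km_hand_product_limit():
    """times [1,2,3,4], events [1,0,1,0]: S=3/4 after t=1, then 3/4 * 1/2."""
    curve = km_estimate(recs([1, 2, 3, 4], [1, 0, 1, 0]))
    np.testing.assert_allclose(curve.event_times, [1, 3])
    np.testing.assert_allclose(curve.survival_probs, [0.75, 0.375])
    np.testing.assert_array_equal(curve.at_risk, [4, 2])


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    times = rng.exponential(5, size=50)
    curve = km_estimate(recs(times, np.ones(50)))
    for t in curve.event_times:
        assert curve.survival_at(t) == pytest.approx(np.mean(times > t))


def test_km_empty_errors():
    with pytest.raises(ValueError):
        km_estimate([])


def logrank_oracle_two_group(times, events, groups):
    """Textbook O-E/V two-group log-rank, computed independently."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_identical_groups_null():
    r = recs([1, 2, 3, 4], [1, 1, 0, 1]) + recs([1, 2, 3, 4], [1, 1, 0, 1], "T")
    res = logrank_test(r, [1] * 4 + [2] * 4)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_df_is_k_minus_one():
    r = recs(range(1, 10), [1] * 9)
    res = logrank_test(r, [1, 1, 1, 2, 2, 2, 3, 3, 3])
    assert res.df == 2


def test_logrank_matches_textbook_oracle():
    times = [1, 2, 3, 4]
    events = [1, 1, 1, 1]
    groups = [1, 1, 2, 2]
    res = logrank_test(recs(times, events), groups)
    expected = logrank_oracle_two_group(times, events, groups)
    assert res.chi2 == pytest.approx(expected, abs=1e-10)


def test_logrank_oracle_on_random_censored_data():
    rng = np.random.default_rng(3)
    for _ in range(5):
        n = 40
        times = np.round(rng.exponential(5, n), 1) + 0.1
        events = (rng.random(n) < 0.7).astype(int)
        groups = rng.integers(1, 3, n)
        if len(set(groups)) < 2:
            continue
        res = logrank_test(recs(times, events), groups)
        expected = logrank_oracle_two_group(times, events, groups)
        assert res.chi2 == pytest.approx(expected, abs=1e-10)


def test_logrank_relabel_invariance_and_late_censor_oracle():
    rng = np.random.default_rng(1)
    times = rng.exponential(5, 30)
    events = (rng.random(30) < 0.8).astype(int)
    groups = rng.integers(1, 3, 30)
    base = logrank_test(recs(times, events), groups)
    swapped = logrank_test(recs(times, events), 3 - groups)
    assert swapped.chi2 == pytest.approx(base.chi2, abs=1e-12)
    # a censored sample beyond all event times still enters every at-risk
    # set, so the statistic changes; it must keep matching the O-E/V oracle
    extra = recs(list(times) + [1e6], list(events) + [0], "X")
    with_late = logrank_test(extra, list(groups) + [1])
    expected = logrank_oracle_two_group(
        list(times) + [1e6], list(events) + [0], list(groups) + [1]
    )
    assert with_late.chi2 == pytest.approx(expected, abs=1e-10)


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        logrank_test(recs([1, 2], [1, 1]), [1, 1])


def log2_matrix(values, features, samples):
    return ExprMatrix(
        pd.DataFrame(values, index=features, columns=samples), "log2"
    )


def test_signature_single_gene_is_zscore():
    m = log2_matrix([[1.0, 3.0, 5.0]], ["G1"], ["a", "b", "c"])
    scores = signature_score(m, ["G1"])
    vals = np.array([s.score for s in scores])
    np.testing.assert_allclose(vals, (np.array([1, 3, 5]) - 3) / np.std([1, 3, 5]))
    assert all(s.n_genes_used == 1 for s in scores)


def test_signature_shift_invariance():
    rng = np.random.default_rng(0)
    vals = rng.normal(5, 1, size=(3, 10))
    m1 = log2_matrix(vals, ["G1", "G2", "G3"], [f"S{i}" for i in range(10)])
    shifted = vals.copy()
    shifted[1] += 100.0
    m2 = log2_matrix(shifted, ["G1", "G2", "G3"], [f"S{i}" for i in range(10)])
    s1 = [s.score for s in signature_score(m1, ["G1", "G2", "G3"])]
    s2 = [s.score for s in signature_score(m2, ["G1", "G2", "G3"])]
    np.testing.assert_allclose(s1, s2)


def test_signature_zero_variance_dropped_and_missing_error():
    m = log2_matrix([[1.0, 2.0], [5.0, 5.0]], ["G1", "G2"], ["a", "b"])
    scores = signature_score(m, ["G1", "G2"])
    assert scores[0].n_genes_used == 1
    with pytest.raises(ValueError):
        signature_score(m, ["NOPE"])


def test_signature_recovery_on_planted_cohort(cohort300, truth_labels300):
    """Planted signature (effect 1 SD) separates the worst-prognosis cluster."""
    from scipy.stats import mannwhitneyu

    truth = cohort300.truth
    scores = signature_score(cohort300.mrna, truth["signature_genes"])
    by = {s.sample_id: s.score for s in scores}
    sig_c = truth["signature_cluster"]
    in_c = [by[s] for s, l in zip(cohort300.mrna.sample_ids, truth_labels300) if l == sig_c]
    out_c = [by[s] for s, l in zip(cohort300.mrna.sample_ids, truth_labels300) if l != sig_c]
    assert np.mean(in_c) > np.mean(out_c)
    p = mannwhitneyu(in_c, out_c, alternative="greater").pvalue
    assert p <= 0.01


def test_median_split_balanced():
    groups = median_split({f"S{i}": float(i) for i in range(10)})
    assert sum(g == "high" for g in groups.values()) == 5


def test_stratified_report_planted_hazards(cohort300, truth_labels300):
    """Hazards (0.02, 0.02, 0.08): cluster 3 separates at p <= 0.01 and its
    curve is lowest beyond the first decile of event times."""
    groups = dict(zip(cohort300.mrna.sample_ids, (int(l) for l in truth_labels300)))
    curves, lr = stratified_km_report(cohort300.survival, groups=groups)
    assert lr.p <= 0.01
    all_events = np.sort(np.concatenate([c.event_times for c in curves.values()]))
    decile = np.quantile(all_events, 0.1)
    grid = [t for t in all_events if t > decile]
    for t in grid:
        s3 = curves[3].survival_at(t)
        assert s3 <= curves[1].survival_at(t) + 1e-12
        assert s3 <= curves[2].survival_at(t) + 1e-12


def test_stratified_report_input_validation(cohort300):
    with pytest.raises(ValueError, match="exactly one"):
        stratified_km_report(cohort300.survival)
    groups = {r.sample_id: 1 for r in cohort300.survival}
    with pytest.raises(ValueError):
        stratified_km_report(cohort300.survival, groups=groups)  # single group
    del groups[cohort300.survival[0].sample_id]
    groups[cohort300.survival[1].sample_id] = 2
    with pytest.raises(ValueError, match="unmatched"):
        stratified_km_report(cohort300.survival, groups=groups)
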