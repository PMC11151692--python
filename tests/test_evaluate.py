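"""ROC/Youden analysis, contingency metrics, and the integer
count-reconstruction oracle, each validated against brute-force references."""

import numpy as np
import pytest

from pfmap.evaluate import (
    ContingencyTable,
    NoConsistentCountsError,
    UndefinedMetricError,
    contingency_metrics,
    reconstruct_counts,
    roc_analysis,
    round_report,
    run_phase2,
    youden_cutoff,
)
from pfmap.synthgen import BLOCK, GAP

# published four-criterion accuracy rows (SE, SP, PPV, NPV in %) against
# 37 gap segments, in order: V_bi, V_omni, PF_bi, PF_omni
TABLE_ROWS = [
    (16.2, 96.1, 50.0, 82.8),
    (10.8, 97.4, 50.0, 82.1),
    (51.4, 96.8, 79.2, 89.3),
    (54.1, 95.5, 74.1, 89.7),
]
N_GAP = 37


def brute_force_auc(scores, labels):
    """Pair-concordance probability: P(gap score > block score) + half ties."""
    s = np.asarray(scores, float)
    g = np.asarray([lab == GAP for lab in labels])
    num = n = 0.0
    for a in s[g]:
        for b in s[~g]:
            num += 1.0 if a > b else (0.5 if a == b else 0.0)
            n += 1
    return num / n


def brute_force_youden(scores, labels):
    """Max of SE+SP-1 over all candidate thresholds (>= direction)."""
    s = np.asarray(scores, float)
    g = np.asarray([lab == GAP for lab in labels])
    best = -np.inf
    for t in np.concatenate([[-np.inf], np.unique(s), [np.inf]]):
        se = np.mean(s[g] >= t)
        sp = np.mean(s[~g] < t)
        best = max(best, se + sp - 1.0)
    return best


def test_rounding_is_half_away_from_zero():
    assert round_report(82.75) == 82.8
    assert round_report(51.35135) == 51.4
    assert round_report(-0.05) == -0.1
    assert round_report(100.0 * 26 / 88) == 29.5


def test_contingency_metrics_reproduce_published_pf_row():
    t = ContingencyTable(tp=19, fp=5, fn=18, tn=150)
    m = {k: round_report(v) for k, v in contingency_metrics(t).items()}
    assert m == {"se": 51.4, "sp": 96.8, "ppv": 79.2, "npv": 89.3}


def test_contingency_metrics_undefined_denominators_raise():
    t = ContingencyTable(tp=1, fp=1, fn=0, tn=0)
    # se and ppv defined; sp = 0/1 is defined (one true block); npv = 0/0 is not
    assert contingency_metrics(t, ("se", "ppv", "sp")) == {"se": 100.0, "ppv": 50.0, "sp": 0.0}
    with pytest.raises(UndefinedMetricError):
        contingency_metrics(t, ("npv",))
    t2 = ContingencyTable(tp=0, fp=0, fn=0, tn=5)
    assert contingency_metrics(t2, ("sp", "npv")) == {"sp": 100.0, "npv": 100.0}
    with pytest.raises(UndefinedMetricError):
        contingency_metrics(t2, ("se",))


def test_reconstruct_counts_recovers_unique_minimal_tables():
    sols = reconstruct_counts(TABLE_ROWS, n_gap=N_GAP)
    s = sols[0]
    assert s.n_block == 155
    assert [(t.tp, t.fp) for t in s.tables] == [(6, 6), (4, 4), (19, 5), (20, 7)]
    # the reconstructed tables reproduce every printed percentage cell
    for table, row in zip(s.tables, TABLE_ROWS):
        m = contingency_metrics(table)
        assert tuple(round_report(m[k]) for k in ("se", "sp", "ppv", "npv")) == row


def test_reconstruct_counts_perfect_row_matches_any_n_block():
    sols = reconstruct_counts([(100.0, 100.0, 100.0, 100.0)], n_gap=2, n_block_max=10)
    assert all(s.tables[0].tp == 2 and s.tables[0].fp == 0 for s in sols)
    assert [s.n_block for s in sols] == list(range(1, 11))


def test_reconstruct_counts_inconsistent_row_raises():
    # PPV 50% requires fp > 0, contradicting SP 100%
    with pytest.raises(NoConsistentCountsError):
        reconstruct_counts([(100.0, 100.0, 50.0, 100.0)], n_gap=1, n_block_max=50)


def test_roc_trivial_cases():
    assert roc_analysis([2, 3, 0, 1], [GAP, GAP, BLOCK, BLOCK]).auc == 1.0
    assert roc_analysis([5, 5, 5, 5], [GAP, GAP, BLOCK, BLOCK]).auc == 0.5
    # brute force over the 4 label pairs: only (3,2) concordant -> 0.25
    assert roc_analysis([1, 3, 2, 4], [GAP, GAP, BLOCK, BLOCK]).auc == 0.25


def test_auc_equals_pair_concordance_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(50):
        n = rng.integers(4, 50)
        scores = rng.choice(np.round(rng.normal(0, 1, 8), 2), size=n)
        labels = np.where(rng.random(n) < 0.5, GAP, BLOCK)
        if len(set(labels)) < 2:
            continue
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


def test_auc_cross_checked_against_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    for _ in range(10):
        scores = rng.normal(0, 1, 40)
        labels = np.where(rng.random(40) < 0.4, GAP, BLOCK)
        if len(set(labels)) < 2:
            continue
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(
            roc_auc_score([lab == GAP for lab in labels], scores), abs=1e-12
        )


def test_youden_matches_brute_force_on_random_scores():
    rng = np.random.default_rng(17)
    for _ in range(20):
        scores = np.round(rng.normal(100, 30, 20), 1)
        labels = np.where(rng.random(20) < 0.5, GAP, BLOCK)
        if len(set(labels)) < 2:
            continue
        res = roc_analysis(scores, labels)
        assert res.youden_j == pytest.approx(brute_force_youden(scores, labels), abs=1e-12)


def test_youden_cutoff_midpoint_convention():
    res = roc_analysis([200.0, 300.0, 50.0, 100.0], [GAP, GAP, BLOCK, BLOCK])
    assert res.youden_j == 1.0
    assert res.youden_threshold == 200.0
    assert res.youden_cutoff == 150.0  # midpoint of (100, 200)
    assert youden_cutoff(res, interpolate=False) == 200.0


def test_youden_degenerate_single_scores():
    res = roc_analysis([10.0, 1.0], [GAP, BLOCK])
    assert res.youden_j == 1.0
    assert 1.0 < res.youden_cutoff < 10.0


def test_se_curve_non_increasing_with_threshold():
    rng = np.random.default_rng(8)
    scores = rng.normal(0, 1, 60)
    labels = np.where(rng.random(60) < 0.5, GAP, BLOCK)
    res = roc_analysis(scores, labels)
    assert (np.diff(res.se_curve) <= 1e-12).all()
    assert (np.diff(res.sp_curve) >= -1e-12).all()


def test_roc_rejects_single_class_and_nonfinite():
    with pytest.raises(ValueError):
        roc_analysis([1.0, 2.0], [GAP, GAP])
    with pytest.raises(ValueError):
        roc_analysis([np.nan, 2.0], [GAP, BLOCK])


def _segment_universe():
    truth = {i: GAP for i in range(N_GAP)}
    truth.update({N_GAP + i: BLOCK for i in range(155)})
    return truth


def test_phase2_with_reconstructed_counts_reproduces_published_table():
    truth = _segment_universe()
    sols = reconstruct_counts(TABLE_ROWS, n_gap=N_GAP)
    names = ["v_bi", "v_omni", "pf_bi", "pf_omni"]
    calls = {}
    for name, table in zip(names, sols[0].tables):
        c = {}
        for i in range(N_GAP):
            c[i] = GAP if i < table.tp else BLOCK
        for i in range(155):
            c[N_GAP + i] = GAP if i < table.fp else BLOCK
        calls[name] = c
    results = run_phase2(calls, truth)
    for name, row in zip(names, TABLE_ROWS):
        _, m = results[name]
        assert tuple(round_report(m[k]) for k in ("se", "sp", "ppv", "npv")) == row


def test_phase2_ordering_pf_beats_voltage_on_se_and_ppv():
    # the reconstructed tables show the headline ordering: PF criteria have
    # strictly higher SE and PPV than voltage criteria, while SP stays within
    # 4 points and NPV within its printed 8-point spread ("similar SP/NPV")
    sols = reconstruct_counts(TABLE_ROWS, n_gap=N_GAP)
    metrics = [contingency_metrics(t) for t in sols[0].tables]
    v_rows, pf_rows = metrics[:2], metrics[2:]
    for pf in pf_rows:
        for v in v_rows:
            assert pf["se"] > v["se"]
            assert pf["ppv"] > v["ppv"]
    sp = [m["sp"] for m in metrics]
    npv = [m["npv"] for m in metrics]
    assert max(sp) - min(sp) < 4.0
    assert max(npv) - min(npv) < 8.0


def test_phase2_perfect_and_degenerate_calls():
    truth = {0: GAP, 1: GAP, 2: BLOCK, 3: BLOCK}
    table, m = run_phase2({"crit": dict(truth)}, truth)["crit"]
    assert all(v == 100.0 for v in m.values()) and len(m) == 4
    assert (table.tp, table.fp, table.fn, table.tn) == (2, 0, 0, 2)
    # all-block calls: SE defined (0.0), SP/NPV defined, PPV undefined/omitted
    _, m0 = run_phase2({"crit": {k: BLOCK for k in truth}}, truth)["crit"]
    assert m0["se"] == 0.0 and m0["sp"] == 100.0 and "ppv" not in m0


def test_phase2_mismatched_segment_sets_raise():
    with pytest.raises(ValueError):
        run_phase2({"crit": {0: GAP}}, {0: GAP, 1: BLOCK})
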