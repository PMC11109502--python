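"""The statistical battery, checked against independent oracles.

Fisher's two-sided p is verified against a from-scratch enumeration of the
hypergeometric family at fixed margins; the exact Mann-Whitney p against a
brute-force enumeration of all group-label assignments.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from vftrial.scoring import OutcomeRecord
from vftrial.stats import (
    ContingencyTable,
    analyze_trial,
    chi_square_2x2,
    fisher_exact_2x2,
    flow_summary,
    format_p,
    independent_t,
    mann_whitney_u,
    paired_t,
    shapiro_wilk_gate,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Oracles


def fisher_enumeration_p(table) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins:
    sum of hypergeometric probabilities no larger than the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p_k = hypergeom.pmf(k, n, r1, c1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(1.0, total)


def mwu_enumeration_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = list(a) + list(b)
    n1, n = len(a), len(pooled)

    def u_stat(idx_a):
        xs = [pooled[i] for i in idx_a]
        ys = [pooled[i] for i in range(n) if i not in set(idx_a)]
        return sum(
            (x > y) + 0.5 * (x == y) for x in xs for y in ys
        )

    u_obs = u_stat(tuple(range(n1)))
    u_hi = max(u_obs, n1 * (n - n1) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = u_stat(idx)
        total += 1
        if u >= u_hi or u <= n1 * (n - n1) - u_hi:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Gate


def test_gate_routes_normal_data_parametric():
    x = np.random.default_rng(1).normal(0, 1, 50)
    assert shapiro_wilk_gate(x) == "parametric"


def test_gate_routes_exponential_data_nonparametric():
    x = np.random.default_rng(1).exponential(1.0, 50)
    assert shapiro_wilk_gate(x) == "nonparametric"


def test_gate_rejects_degenerate_samples():
    with pytest.raises(ValueError):
        shapiro_wilk_gate([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk_gate([3.0] * 10)


# ---------------------------------------------------------------------------
# 2x2 tables


def test_chi_square_reproduces_trial_baseline_rows():
    # defect side by arm and sex by arm from the baseline table
    assert chi_square_2x2([[22, 18], [20, 15]]).p_value == pytest.approx(
        0.85, abs=0.005
    )
    assert chi_square_2x2([[26, 14], [18, 17]]).p_value == pytest.approx(
        0.23, abs=0.005
    )


def test_chi_square_no_association_is_p_one():
    res = chi_square_2x2([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_chi_square_invariant_under_row_and_column_swap():
    t = [[7, 12], [3, 21]]
    p0 = chi_square_2x2(t).p_value
    assert chi_square_2x2([t[1], t[0]]).p_value == pytest.approx(p0)
    assert chi_square_2x2([row[::-1] for row in t]).p_value == pytest.approx(p0)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [5, 5]])


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(counts=((0, 0), (0, 0)))
    with pytest.raises(ValueError):
        ContingencyTable(counts=((-1, 2), (3, 4)))


def test_fisher_exact_known_values():
    assert fisher_exact_2x2([[1, 40], [3, 35]]).p_value == pytest.approx(
        0.35, abs=0.005
    )
    assert fisher_exact_2x2([[3, 37], [2, 33]]).p_value > 0.99
    assert fisher_exact_2x2([[0, 5], [5, 0]]).p_value == pytest.approx(
        2 / 252, rel=1e-9
    )


def test_fisher_matches_enumeration_over_random_tables(rng):
    for _ in range(60):
        counts = rng.integers(0, 16, size=4)
        if counts.sum() == 0 or counts.sum() > 60:
            continue
        t = [[int(counts[0]), int(counts[1])], [int(counts[2]), int(counts[3])]]
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_enumeration_p(t), rel=1e-8, abs=1e-12
        )


# ---------------------------------------------------------------------------
# Rank and t tests


def test_mwu_identical_samples_p_is_one():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert mann_whitney_u(a, a).p_value == pytest.approx(1.0, abs=1e-9)
    big = list(np.arange(20.0))
    assert mann_whitney_u(big, big).p_value > 0.95


def test_mwu_exact_mode_matches_permutation_enumeration():
    cases = [
        ([1.2, 3.4, 2.2, 5.1], [4.0, 6.3, 7.7, 0.5, 8.8]),
        ([10.0, 11.5, 9.1], [12.0, 13.3, 14.1, 15.9]),
        ([0.1, 0.2, 0.3, 0.4, 0.5], [0.6, 0.7, 0.8]),
    ]
    for a, b in cases:
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mwu_enumeration_p(a, b), abs=1e-9
        )


def test_mwu_invariant_under_monotone_transform(rng):
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
    p0 = mann_whitney_u(a, b).p_value
    assert mann_whitney_u(np.exp(a), np.exp(b)).p_value == pytest.approx(p0)
    assert mann_whitney_u(3 * a + 7, 3 * b + 7).p_value == pytest.approx(p0)


def test_wilcoxon_all_zero_differences_rejected():
    pre = [1.0, 2.0, 3.0, 4.0]
    with pytest.raises(ValueError, match="zero"):
        wilcoxon_signed_rank(pre, pre)


def test_wilcoxon_drops_zero_differences():
    pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    post = [1.0, 2.0, 4.0, 5.5, 6.5, 7.5]  # two zero diffs dropped
    res = wilcoxon_signed_rank(pre, post)
    assert res.n == 4
    assert 0 < res.p_value <= 1


def test_paired_and_independent_t_agree_with_closed_form():
    pre = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
    post = pre + np.array([1.0, 2.0, 0.5, 1.5, 1.0])
    res = paired_t(pre, post)
    d = post - pre
    t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    assert res.statistic == pytest.approx(t_manual)
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0]
    assert 0 <= independent_t(a, b).p_value <= 1


def test_p_value_formatting():
    assert format_p(0.0004) == "<.001"
    assert format_p(0.995) == ">.99"
    assert format_p(0.85) == ".85"
    assert format_p(0.034) == ".03"


# ---------------------------------------------------------------------------
# Trial-level analysis


def _outcome(pid, arm, delta, area=72.0, pre=-20.0):
    return OutcomeRecord(
        patient_id=pid, arm=arm, vfd_side="left", vfd_type="hemianopia",
        improved_area_hemi_deg2=area, improved_area_whole_deg2=area,
        mtd_pre_hemi=pre, mtd_post_hemi=pre + delta, mtd_delta_hemi=delta,
        mtd_pre_whole=pre / 2, mtd_post_whole=pre / 2 + delta / 2,
        mtd_delta_whole=delta / 2,
        responder_hemi=delta > 0, responder_whole=delta / 2 > 0,
    )


def test_analyze_trial_identical_arms_give_null_p():
    outcomes = []
    deltas = [0.5, -0.3, 1.2, -0.8, 0.1, 0.9, -1.1, 0.4, 1.4, -0.2]
    for arm in ("NV", "NV-C"):
        outcomes += [
            _outcome(f"{arm}{i}", arm, d, area=36.0 * i)
            for i, d in enumerate(deltas)
        ]
    report = analyze_trial(outcomes)
    for region in ("hemifield", "whole"):
        sec = report["regions"][region]
        assert sec["improved_area_between"]["p_value"] == pytest.approx(
            1.0, abs=0.05
        )
        assert sec["mtd_delta_between"]["p_value"] == pytest.approx(1.0, abs=0.05)


def test_analyze_trial_detects_programmed_single_arm_effect():
    """An NV-only MTD gain of +3 dB (sd 1) at n=40/35 is essentially always
    detected within-arm, while the unaffected arm stays null."""
    rng = np.random.default_rng(11)
    outcomes = [
        _outcome(f"NV{i}", "NV", float(rng.normal(3.0, 1.0)))
        for i in range(40)
    ] + [
        _outcome(f"NVC{i}", "NV-C", float(rng.normal(0.0, 1.0)))
        for i in range(35)
    ]
    report = analyze_trial(outcomes)
    sec = report["regions"]["hemifield"]
    assert sec["mtd_within"]["NV"]["p_value"] < 0.05
    assert sec["mtd_within"]["NV-C"]["p_value"] > 0.05
    assert sec["mtd_delta_between"]["p_value"] < 0.001


def test_analyze_trial_responder_percentages():
    outcomes = [
        _outcome(f"NV{i}", "NV", d)
        for i, d in enumerate([1.0, 1.0, -1.0, 0.5, -0.5])
    ] + [
        _outcome(f"NVC{i}", "NV-C", d)
        for i, d in enumerate([1.0, -1.0, -2.0, 0.1])
    ]
    report = analyze_trial(outcomes)
    resp = report["regions"]["hemifield"]["responders"]
    assert resp["NV"]["count"] == 3 and resp["NV"]["pct"] == pytest.approx(60.0)
    assert resp["NV-C"]["count"] == 2 and resp["NV-C"]["pct"] == pytest.approx(50.0)


def test_analyze_trial_rejects_tiny_arm():
    with pytest.raises(ValueError, match="fewer than 2"):
        analyze_trial([_outcome("a", "NV", 1.0), _outcome("b", "NV-C", 1.0)])


def test_flow_summary_trial_counts():
    s = flow_summary((41, 38), (1, 3))
    assert s["completed"] == {"NV": 40, "NV-C": 35}
    assert s["completion_pct"] == 94.9
    assert s["dropout_test"]["p_value"] == pytest.approx(0.35, abs=0.005)


def test_flow_summary_no_dropout():
    s = flow_summary((10, 10), (0, 0))
    assert s["completion_pct"] == 100.0
    assert s["dropout_test"]["p_value"] == 1.0


def test_flow_summary_validation():
    with pytest.raises(ValueError):
        flow_summary((5, 5), (6, 0))
    with pytest.raises(ValueError):
        flow_summary((5, -1), (0, 0))
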