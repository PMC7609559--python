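"""Paired cohort statistics: routing, Wilcoxon, percent change, thresholds."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from coarctflow.stats import (
    classify_threshold,
    paired_compare,
    percent_change,
    summarize_cohort,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank vs brute-force enumeration
# ---------------------------------------------------------------------------

def _wilcoxon_exact_bruteforce(diff):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    stat_obs = abs(w_obs - mean_w)
    count = 0
    total = 2 ** n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / total


@pytest.mark.parametrize("n", [4, 6, 8])
def test_wilcoxon_matches_enumeration_for_all_sign_patterns(n):
    """Exact signed-rank p equals the brute-force null enumeration for every
    sign pattern over fixed distinct magnitudes."""
    mags = np.arange(1.0, n + 1.0)
    for signs in itertools.product((-1.0, 1.0), repeat=n):
        d = mags * np.array(signs)
        assert wilcoxon_signed_rank(d) == pytest.approx(
            _wilcoxon_exact_bruteforce(d), abs=1e-12)


def test_wilcoxon_handles_zeros_and_ties():
    assert wilcoxon_signed_rank(np.zeros(5)) == 1.0
    d = np.array([1.0, 1.0, -1.0, 2.0, 3.0, 0.0, 2.0, -2.0])  # ties + a zero
    p = wilcoxon_signed_rank(d)
    assert 0.0 < p <= 1.0


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def test_identical_vectors_are_degenerate():
    c = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert c.test == "degenerate"
    assert c.p_value == 1.0
    assert c.pct_change == 0.0


def test_normal_differences_route_to_paired_t(rng):
    rest = rng.normal(10, 2, 20)
    ex = rest + rng.normal(1, 1, 20)
    c = paired_compare(rest, ex)
    assert c.test == "paired t"
    assert c.p_value == pytest.approx(sps.ttest_rel(ex, rest).pvalue)


def test_heavy_tailed_differences_route_to_wilcoxon(rng):
    rest = rng.normal(10, 2, 50)
    ex = rest + rng.standard_cauchy(50)
    c = paired_compare(rest, ex)
    assert c.test == "wilcoxon"


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        paired_compare([1, 2, 3], [1, 2])


# ---------------------------------------------------------------------------
# percent change and threshold classification
# ---------------------------------------------------------------------------

def test_percent_change_examples():
    assert percent_change([10.0, 20.0], [20.0, 20.0]) == pytest.approx(50.0)
    assert percent_change([5.0, 7.0], [5.0, 7.0]) == 0.0
    with pytest.raises(ValueError, match="index 1"):
        percent_change([2.0, 0.0], [3.0, 1.0])


def test_threshold_counts_partition():
    rest = [25.0, 10.0, 5.0, 30.0, 20.0]
    ex = [30.0, 25.0, 8.0, 15.0, 20.0]
    counts = classify_threshold(rest, ex, 20.0)
    assert counts == {"both_above": 1, "both_below": 2, "crossed": 1,
                      "reverse_crossed": 1}
    assert sum(counts.values()) == 5
    zero = classify_threshold(np.zeros(7), np.zeros(7))
    assert zero["both_below"] == 7


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def test_summary_permutation_invariant(reference_cohort):
    import copy
    s1 = summarize_cohort(reference_cohort)
    shuffled = copy.deepcopy(reference_cohort)
    order = np.random.default_rng(5).permutation(len(shuffled.patients))
    shuffled.patients = [shuffled.patients[i] for i in order]
    s2 = summarize_cohort(shuffled)
    for name in s1.comparisons:
        assert s1.comparisons[name].mean_rest == pytest.approx(
            s2.comparisons[name].mean_rest, rel=1e-12)
        assert s1.comparisons[name].p_value == pytest.approx(
            s2.comparisons[name].p_value, rel=1e-9)
    assert s1.threshold_counts == s2.threshold_counts


def test_summary_headline_significances(reference_cohort):
    """The cohort's pressure gradient and WSS rise significantly during
    exercise; SFD and NFD do not."""
    s = summarize_cohort(reference_cohort)
    assert s.comparisons["pressure_gradient"].p_value < 0.001
    assert s.comparisons["wss"].p_value < 0.05
    assert s.comparisons["sfd_ascending"].p_value > 0.05
    assert s.comparisons["nfd_ascending"].p_value > 0.05
    assert s.comparisons["stroke_volume_index"].p_value > 0.05
    rep = s.to_report()
    assert rep["n"] == 20
    assert set(rep["threshold_counts"]) == {"both_above", "both_below",
                                            "crossed", "reverse_crossed"}
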