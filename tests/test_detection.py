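import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from imputebench import (DetectionParams, InputError, detect, discrimination_scores,
                         filter_complete, percent_present, wilcoxon_one_sided_p)
from imputebench.detection import ABSENT, MARGINAL, PRESENT


def brute_force_signed_rank_p(scores, tau):
    """Independent oracle: enumerate all 2^n sign assignments explicitly."""
    d = np.asarray(scores, dtype=float) - tau
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** len(d)


class TestDiscriminationScores:
    def test_equal_intensities_score_zero(self):
        np.testing.assert_allclose(discrimination_scores([50, 120, 7], [50, 120, 7]), 0.0)

    def test_worked_ratios(self):
        np.testing.assert_allclose(discrimination_scores([300], [100]), [0.5])
        np.testing.assert_allclose(discrimination_scores([100], [300]), [-0.5])

    def test_rejects_nonpositive_and_mismatched(self):
        with pytest.raises(InputError):
            discrimination_scores([1.0, -2.0], [1.0, 1.0])
        with pytest.raises(InputError):
            discrimination_scores([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(1e-3, 1e6), min_size=1, max_size=20),
           st.lists(st.floats(1e-3, 1e6), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_scores_bounded_open_interval(self, pm, mm):
        n = min(len(pm), len(mm))
        s = discrimination_scores(pm[:n], mm[:n])
        assert np.all(s > -1) and np.all(s < 1)


class TestWilcoxonExact:
    def test_three_positive_differences(self):
        assert wilcoxon_one_sided_p([0.5, 0.4, 0.3], 0.015) == pytest.approx(0.125)

    def test_symmetric_pair_distinct_magnitudes(self):
        # differences +0.2 and -0.1: two of four sign assignments reach the
        # observed positive-rank sum
        assert wilcoxon_one_sided_p([0.015 + 0.2, 0.015 - 0.1], 0.015) == pytest.approx(0.5)

    def test_all_below_tau_gives_one(self):
        p = wilcoxon_one_sided_p([-0.5, -0.4, -0.3, -0.2, -0.1], 0.015)
        assert p == pytest.approx(1.0)

    def test_all_equal_tau_returns_one(self):
        assert wilcoxon_one_sided_p([0.015, 0.015], 0.015) == 1.0

    def test_matches_brute_force_enumeration(self):
        """Exact-null DP equals full 2^n enumeration, including ties and
        zero-differences, over 200 random score vectors with n <= 12."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            scores = np.round(rng.normal(0.0, 0.3, n), 2)  # rounding makes ties
            p_fast = wilcoxon_one_sided_p(scores, 0.015)
            p_slow = brute_force_signed_rank_p(scores, 0.015)
            assert p_fast == pytest.approx(p_slow, abs=1e-12)

    def test_agrees_with_scipy_on_tie_free_vectors(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(5, 13))
            scores = rng.normal(0.1, 0.3, n)
            d = scores - 0.015
            if len(np.unique(np.abs(d))) < n or np.any(d == 0):
                continue
            p_ours = wilcoxon_one_sided_p(scores, 0.015)
            p_ref = scipy_wilcoxon(d, alternative="greater", mode="exact").pvalue
            assert p_ours == pytest.approx(p_ref, abs=1e-12)

    def test_raising_pm_cannot_raise_p(self):
        rng = np.random.default_rng(8)
        pm = rng.uniform(100, 400, 11)
        mm = rng.uniform(50, 200, 11)
        p0 = wilcoxon_one_sided_p(discrimination_scores(pm, mm), 0.015)
        pm2 = pm.copy()
        pm2[4] *= 2.0
        p1 = wilcoxon_one_sided_p(discrimination_scores(pm2, mm), 0.015)
        assert p1 <= p0 + 1e-12


class TestCallsAndThresholds:
    @pytest.mark.parametrize("p,call", [(0.03, PRESENT), (0.039999, PRESENT),
                                        (0.04, MARGINAL), (0.05, MARGINAL),
                                        (0.06, ABSENT), (0.07, ABSENT)])
    def test_half_open_thresholds(self, p, call):
        assert DetectionParams().call(p) == call

    def test_detect_covers_every_probe_set_sample_pair(self, tiny_dataset):
        calls = detect(tiny_dataset)
        n_sets = tiny_dataset.probes["probe_set_id"].nunique()
        assert len(calls) == n_sets * len(tiny_dataset.samples)
        assert calls["p_value"].between(0, 1).all()
        assert set(calls["call"]) <= {PRESENT, MARGINAL, ABSENT}


def _toy_calls():
    """Enumerated calls for one site x pool cell with 5 replicates."""
    reps = [f"site1_A_r{i}" for i in range(1, 6)]
    rows = []
    patterns = {"ps1": "PPPPP", "ps2": "PPPPA", "ps3": "PPMPP"}
    for ps, pat in patterns.items():
        for r, c in zip(reps, pat):
            rows.append((ps, r, 0.01 if c == "P" else (0.05 if c == "M" else 0.5), c))
    calls = pd.DataFrame(rows, columns=["probe_set_id", "sample_id", "p_value", "call"])
    samples = pd.DataFrame({"sample_id": reps, "site": "site1", "pool": "A",
                            "replicate": range(1, 6)})
    return calls, samples


class TestFilterAndPercentPresent:
    def test_filter_retains_only_all_present(self):
        calls, samples = _toy_calls()
        assert filter_complete(calls, samples, "site1", "A") == ["ps1"]

    def test_filter_unknown_cell_raises(self):
        calls, samples = _toy_calls()
        with pytest.raises(InputError):
            filter_complete(calls, samples, "site9", "A")

    def test_percent_present_hand_arithmetic(self):
        # one array, 200 probe sets, 110 Present -> 55.0%
        rows = [(f"ps{i}", "a1", 0.01, PRESENT) for i in range(110)]
        rows += [(f"ps{i}", "a1", 0.5, ABSENT) for i in range(110, 200)]
        calls = pd.DataFrame(rows, columns=["probe_set_id", "sample_id", "p_value", "call"])
        samples = pd.DataFrame({"sample_id": ["a1"], "site": ["s1"], "pool": ["A"],
                                "replicate": [1]})
        per_array, per_cell = percent_present(calls, samples)
        assert per_array["percent_present"].iloc[0] == pytest.approx(55.0)
        assert per_cell["mean_percent_present"].iloc[0] == pytest.approx(55.0)

    def test_cell_mean_over_replicates(self):
        reps = [f"r{i}" for i in range(1, 6)]
        pcts = [50, 52, 54, 56, 58]
        rows = []
        for rep, pct in zip(reps, pcts):
            rows += [(f"ps{i}", rep, 0.01, PRESENT) for i in range(pct)]
            rows += [(f"ps{i}", rep, 0.5, ABSENT) for i in range(pct, 100)]
        calls = pd.DataFrame(rows, columns=["probe_set_id", "sample_id", "p_value", "call"])
        samples = pd.DataFrame({"sample_id": reps, "site": "s1", "pool": "A",
                                "replicate": range(1, 6)})
        _, per_cell = percent_present(calls, samples)
        assert per_cell["mean_percent_present"].iloc[0] == pytest.approx(54.0)

    def test_percent_present_in_plausible_window_on_synthetic_data(self, tiny_dataset):
        """Stochastic smoke check: defaults land percent-present in 45-65%."""
        calls = detect(tiny_dataset)
        per_array, _ = percent_present(calls, tiny_dataset.samples)
        assert 40 < per_array["percent_present"].mean() < 70
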