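"""Three-step misclassification analysis: logs, ratios, CDVs, recovery."""

import numpy as np
import pytest

from gpcrnoise.detector import (
    DetectorConfig,
    classify_magnitude,
    cumulative_dv,
    detect_candidates,
    profile_errors,
    select_frequent,
    voting_ratio,
)

from conftest import make_blobs, make_profile

FAST = DetectorConfig(n_iterations=10, n_folds=5, seed=0)


@pytest.fixture(scope="module")
def clean_run():
    X, y = make_blobs(4, 15, spread=0.3, seed=2)
    ids = [f"s{i}" for i in range(len(y))]
    profiles, iters = profile_errors(X, y, ids, C_opt=10.0, gamma_opt=0.5, config=FAST)
    return profiles, iters


@pytest.fixture(scope="module")
def flipped_run():
    """Three labels flipped to a distant class on separable blobs."""
    X, y = make_blobs(4, 15, spread=0.3, seed=2)
    y = y.copy()
    flips = {0: 3, 20: 4, 45: 1}  # index -> wrong class (original 1, 2, 4)
    for idx, wrong in flips.items():
        y[idx] = wrong
    ids = [f"s{i}" for i in range(len(y))]
    result = detect_candidates(
        X, y, ids, FAST, C_opt=10.0, gamma_opt=0.5
    )
    return result, flips, y


class TestProfileErrors:
    def test_separable_classes_have_zero_error_rates(self, clean_run):
        profiles, iters = clean_run
        assert all(p.er == 0.0 for p in profiles)
        assert np.allclose(iters["accuracy_overall"], 1.0)
        assert np.allclose(iters["mcc_multiclass"], 1.0)

    def test_each_sequence_tested_once_per_iteration(self, clean_run):
        profiles, _ = clean_run
        for p in profiles:
            assert p.pred_log.shape == (FAST.n_iterations,)
            assert np.all(p.pred_log >= 1)  # a prediction was logged every time
            assert np.all(p.votes_log.sum(axis=1) == 4 * 3 // 2)

    def test_votes_true_bounded_by_pairs_involving_true_class(self, clean_run):
        profiles, _ = clean_run
        for p in profiles:
            assert p.votes_true <= (4 - 1) * FAST.n_iterations

    def test_dv_pairs_involving_true_class_logged_every_iteration(self, clean_run):
        profiles, _ = clean_run
        for p in profiles[:5]:
            others = [c for c in range(1, 5) if c != p.true_class]
            # well inside its class: every pair with the true class favors it
            for c in others:
                signs = np.sign(p.dv_true[:, c - 1])
                expected = 1.0 if p.true_class < c else -1.0
                assert np.all(signs == expected)

    def test_tiny_class_rejected(self):
        X, y = make_blobs(2, 3, seed=0)
        with pytest.raises(ValueError, match="smallest class"):
            profile_errors(X, y, [str(i) for i in range(len(y))], 1.0, 0.1, FAST)


class TestSelectFrequent:
    def test_boundary_is_inclusive(self):
        at = make_profile(1, [2] * 3 + [1] * 1, np.tile([1, 2, 0], (4, 1)))
        assert at.er == 75.0
        below = make_profile(1, [2] * 2 + [1] * 2, np.tile([1, 2, 0], (4, 1)))
        kept = select_frequent([at, below], 75.0)
        assert kept == [at]

    def test_zero_threshold_keeps_everything(self):
        profiles = [
            make_profile(1, [1] * 4, np.tile([2, 1, 0], (4, 1))),
            make_profile(2, [1] * 4, np.tile([2, 1, 0], (4, 1))),
        ]
        assert select_frequent(profiles, 75.0) == profiles[1:]
        # zero is excluded from valid configs but the selector itself
        # accepts any cutoff; ER >= 0 keeps all
        assert select_frequent(profiles, 0.0) == profiles

    def test_raising_threshold_never_grows_the_subset(self, flipped_run):
        result, _, _ = flipped_run
        sizes = [len(select_frequent(result.profiles, e)) for e in (0.0, 50.0, 75.0, 100.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestVotingRatio:
    def test_printed_vote_totals_reproduce_ratios(self):
        # 100 iterations; true class 2, always misclassified as 1;
        # votes per occasion chosen so the totals are VT=91, VP=600
        votes = np.zeros((100, 7), dtype=int)
        votes[:, 0] = 6
        votes[:91, 1] = 1
        votes[91:, 2] = 1
        extra = 21 - votes[0].sum()
        votes[:, 6] = extra
        p = make_profile(2, [1] * 100, votes)
        vr = voting_ratio(p)
        assert (vr["VT"], vr["VP"], vr["predicted_class"]) == (91, 600, 1)
        assert round(vr["R"], 2) == 0.15

    def test_half_ratio(self):
        votes = np.zeros((100, 7), dtype=int)
        votes[:, 4] = 6  # predicted class 5 sweeps its pairs
        votes[:50, 3] = 6
        votes[50:, 3] = 0
        p = make_profile(4, [5] * 100, votes)
        vr = voting_ratio(p)
        assert vr["R"] == pytest.approx(300 / 600) == 0.5

    def test_equal_votes_give_unit_ratio(self):
        votes = np.tile([3, 3, 0], (10, 1))
        p = make_profile(1, [2] * 10, votes)
        assert voting_ratio(p)["R"] == 1.0

    def test_never_misclassified_has_no_ratio(self):
        p = make_profile(1, [1] * 10, np.tile([2, 1, 0], (10, 1)))
        with pytest.raises(ValueError, match="never misclassified"):
            voting_ratio(p)

    def test_recount_from_vote_logs_matches(self, flipped_run):
        """Brute-force recount of the per-iteration vote logs."""
        result, _, y = flipped_run
        for p in result.profiles:
            if p.n_misclassified == 0:
                continue
            vr = voting_ratio(p)
            vt = sum(int(row[p.true_class - 1]) for row in p.votes_log)
            vp = sum(int(row[vr["predicted_class"] - 1]) for row in p.votes_log)
            assert (vr["VT"], vr["VP"]) == (vt, vp)

    def test_misclassified_only_variant_counts_subset(self):
        votes = np.tile([2, 4, 0], (10, 1))
        pred = [2] * 6 + [1] * 4
        p = make_profile(1, pred, votes)
        full = voting_ratio(p)
        sub = voting_ratio(p, misclassified_only=True)
        assert (full["VT"], full["VP"]) == (20, 40)
        assert (sub["VT"], sub["VP"]) == (12, 24)


class TestCumulativeDV:
    def test_zero_log_gives_zero(self):
        p = make_profile(1, [2] * 10, np.tile([1, 2, 0], (10, 1)))
        assert cumulative_dv(p, 2) == 0.0

    def test_consistent_preference_for_higher_class_gives_negative_sum(self):
        # true class 4, predicted 5; the (4,5) classifier favors 5 with
        # magnitude 1 on every occasion -> CDV = -100 (true index < predicted)
        n, k = 100, 7
        dv = np.zeros((n, k))
        dv[:, 4] = -1.0
        p = make_profile(4, [5] * n, np.tile([0, 0, 0, 1, 6, 0, 14], (n, 1)), dv_true=dv)
        assert cumulative_dv(p, 5) == -100.0

    def test_matches_independent_resummation(self):
        rng = np.random.default_rng(0)
        dv = rng.normal(size=(50, 3))
        p = make_profile(3, [1] * 50, np.tile([2, 0, 1], (50, 1)), dv_true=dv)
        assert cumulative_dv(p, 1) == pytest.approx(sum(dv[i, 0] for i in range(50)))

    def test_pair_with_itself_rejected(self):
        p = make_profile(1, [2] * 5, np.tile([1, 2, 0], (5, 1)))
        with pytest.raises(ValueError):
            cumulative_dv(p, 1)


class TestClassifyMagnitude:
    config = DetectorConfig(n_iterations=100)

    def test_low_ratio_is_large(self):
        out = classify_magnitude(0.15, 0.0, self.config)
        assert out["large_R"] and out["magnitude"] == "large"

    def test_large_cdv_magnitude(self):
        out = classify_magnitude(0.83, -96.0, self.config)
        assert out["large_CDV"] and out["magnitude"] == "large"

    def test_moderate_values_are_small(self):
        out = classify_magnitude(0.67, 45.0, self.config)
        assert out["magnitude"] == "small"

    def test_thresholds_scale_with_iteration_count(self):
        short = DetectorConfig(n_iterations=10)
        assert short.theta_CDV_effective == 6.0
        assert classify_magnitude(0.9, -7.0, short)["large_CDV"]

    def test_lowering_theta_r_never_shrinks_the_large_set(self):
        rs = [0.1, 0.4, 0.5, 0.7, 1.0]
        sets = []
        for theta in (0.7, 0.5, 0.3):
            cfg = DetectorConfig(theta_R=theta)
            sets.append({r for r in rs if classify_magnitude(r, 0, cfg)["large_R"]})
        assert sets[2] <= sets[1] <= sets[0]


class TestDetectCandidates:
    def test_clean_separable_data_yields_no_candidates(self):
        X, y = make_blobs(3, 10, spread=0.3, seed=4)
        ids = [f"s{i}" for i in range(len(y))]
        result = detect_candidates(X, y, ids, FAST, C_opt=10.0, gamma_opt=0.5)
        assert result.candidates == []

    def test_flipped_labels_recovered_with_original_class_predicted(self, flipped_run):
        result, flips, _ = flipped_run
        found = {c.id: c for c in result.candidates}
        originals = {"s0": 1, "s20": 2, "s45": 4}
        for idx in flips:
            cid = f"s{idx}"
            assert cid in found
            assert found[cid].er == 100.0
            assert found[cid].predicted_class == originals[cid]

    def test_candidates_are_exactly_the_large_magnitude_frequent_ones(self, flipped_run):
        result, _, _ = flipped_run
        assert all(c.magnitude == "large" for c in result.candidates)
        large_ids = {c.id for c in result.frequent if c.magnitude == "large"}
        assert {c.id for c in result.candidates} == large_ids

    def test_cdv_sign_tracks_class_index_order(self, flipped_run):
        """When the pair classifier favored the predicted class in >= 90%
        of iterations, the CDV sign must be positive for true > predicted
        and negative for true < predicted."""
        result, _, _ = flipped_run
        checked = 0
        for c in result.candidates:
            p = next(pr for pr in result.profiles if pr.id == c.id)
            dvs = p.dv_true[:, c.predicted_class - 1]
            favored = (
                (dvs < 0) if c.true_class < c.predicted_class else (dvs > 0)
            )
            if favored.mean() >= 0.9:
                checked += 1
                expected = 1.0 if c.true_class > c.predicted_class else -1.0
                assert np.sign(c.cdv) == expected
        assert checked > 0

    def test_same_seed_reproduces_report_exactly(self):
        X, y = make_blobs(3, 10, spread=0.5, seed=6)
        y = y.copy()
        y[0] = 2
        ids = [f"s{i}" for i in range(len(y))]
        a = detect_candidates(X, y, ids, FAST, C_opt=10.0, gamma_opt=0.5)
        b = detect_candidates(X, y, ids, FAST, C_opt=10.0, gamma_opt=0.5)
        assert a.candidates_frame().to_csv() == b.candidates_frame().to_csv()
        assert a.iteration_metrics.to_csv() == b.iteration_metrics.to_csv()
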