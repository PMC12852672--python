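import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import audiophen as ap
from audiophen.stability import clusterwise_match, jaccard

index_sets = st.sets(st.integers(min_value=0, max_value=30), max_size=12)


def brute_force_match(original, comparison):
    """Independent oracle: set arithmetic over every cluster pair."""
    original = list(original)
    comparison = list(comparison)
    scores = {}
    for c in sorted(set(original)):
        members = {i for i, l in enumerate(original) if l == c}
        best = -1.0
        for d in sorted(set(comparison)):
            other = {i for i, l in enumerate(comparison) if l == d}
            inter = len(members & other)
            union = len(members | other)
            score = inter / union if union else 0.0
            if score > best:
                best = score
        scores[c] = best
    return scores


class TestJaccard:
    def test_identical_sets_score_one(self):
        assert jaccard({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert jaccard({1, 2}, {3, 4}) == 0.0

    def test_half_overlap(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_defined_as_zero(self):
        assert jaccard(set(), set()) == 0.0

    def test_duplicated_indices_count_once(self):
        assert jaccard([1, 1, 2], [1, 2, 2]) == 1.0

    @settings(max_examples=300, deadline=None)
    @given(index_sets, index_sets)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        s = jaccard(a, b)
        assert s == jaccard(b, a)
        assert 0.0 <= s <= 1.0
        if a or b:
            assert (s == 1.0) == (a == b)


class TestClusterwiseMatch:
    def test_identical_labelings_score_one(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        match = clusterwise_match(labels, labels)
        assert np.allclose(match.values(), 1.0)

    def test_merged_clusters_score_their_relative_sizes(self):
        original = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        merged = np.array([0, 0, 0, 0, 0, 1, 1, 1])  # clusters 0 and 1 merged
        match = clusterwise_match(original, merged)
        assert match.values()[0] == pytest.approx(3 / 5)
        assert match.values()[1] == pytest.approx(2 / 5)
        assert match.values()[2] == 1.0

    def test_tie_breaks_toward_lower_comparison_index(self):
        original = np.array([0, 0])
        comparison = np.array([0, 1])  # both comparison clusters score 1/2
        match = clusterwise_match(original, comparison)
        assert match.scores.loc[0, "best_match"] == 0

    def test_restricted_to_shared_indices(self):
        original = np.array([0, 0, 1, 1])
        comparison = np.array([0, 1])  # defined on indices 1 and 2 only
        match = clusterwise_match(original, comparison, indices=np.array([1, 2]))
        assert match.values()[0] == 1.0  # {1} vs {1}
        assert match.values()[1] == 1.0  # {2} vs {2}

    def test_cluster_absent_from_shared_set_is_undefined(self):
        original = np.array([0, 1, 1])
        match = clusterwise_match(original, np.array([0, 0]),
                                  indices=np.array([1, 2]))
        assert np.isnan(match.values()[0])
        assert match.scores.loc[0, "best_match"] == -1

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(min_value=1, max_value=8).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 2), min_size=n, max_size=n),
                st.lists(st.integers(0, 2), min_size=n, max_size=n),
            )
        )
    )
    def test_agrees_with_brute_force_oracle(self, labelings):
        original, comparison = (np.array(l) for l in labelings)
        match = clusterwise_match(original, comparison)
        oracle = brute_force_match(original, comparison)
        for c, score in oracle.items():
            assert match.values()[c] == pytest.approx(score)

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(2)
        original = rng.integers(0, 3, 60)
        comparison = rng.integers(0, 3, 60)
        base = np.sort(clusterwise_match(original, comparison).values())
        perm_orig = np.array([2, 0, 1])[original]
        perm_comp = np.array([1, 2, 0])[comparison]
        permuted = np.sort(clusterwise_match(perm_orig, perm_comp).values())
        np.testing.assert_allclose(base, permuted)

    def test_one_to_one_mode_never_reuses_a_comparison_cluster(self):
        original = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        merged = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        match = clusterwise_match(original, merged, one_to_one=True)
        used = match.scores["best_match"].tolist()
        assert len(set(used)) == len(used)


class TestBootstrapStability:
    def test_separated_mixture_is_stable(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 600, seed=1)
        cfg = ap.GmmConfig(n_components=2, seed=0)
        fit = ap.fit_gmm(X, cfg)
        report = ap.bootstrap_stability(X, cfg, fit.labels, n_bootstrap=15, seed=0)
        assert np.all(report.per_cluster["mean_jaccard"] >= 0.95)

    def test_distinct_index_fraction_near_one_minus_inv_e(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 1000, seed=1)
        cfg = ap.GmmConfig(n_components=2, seed=0)
        fit = ap.fit_gmm(X, cfg)
        report = ap.bootstrap_stability(X, cfg, fit.labels, n_bootstrap=20, seed=3)
        frac = report.replicate_scores["shared_fraction"].mean()
        assert abs(frac - (1 - np.exp(-1))) < 0.01

    def test_report_counts_match_configuration(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 300, seed=4)
        cfg = ap.GmmConfig(n_components=2, seed=0)
        fit = ap.fit_gmm(X, cfg)
        report = ap.bootstrap_stability(X, cfg, fit.labels, n_bootstrap=7, seed=0)
        assert report.n_replicates == 7
        assert report.replicate_scores["replicate"].nunique() == 7 - report.n_failed


class TestInitializationStability:
    def test_excludes_original_seed_from_pool(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 300, seed=5)
        cfg = ap.GmmConfig(n_components=2, seed=7)
        fit = ap.fit_gmm(X, cfg)
        report = ap.initialization_stability(X, cfg, fit.labels, seed_pool=range(21))
        assert report.n_replicates == 20
        assert 7 not in report.seeds

    def test_seed_invariant_fit_scores_one(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 500, seed=6)
        cfg = ap.GmmConfig(n_components=2, seed=0)
        fit = ap.fit_gmm(X, cfg)
        report = ap.initialization_stability(X, cfg, fit.labels, seed_pool=range(6))
        assert np.allclose(report.per_cluster["mean_jaccard"], 1.0)


class TestSubsampleCurve:
    def test_fraction_grid_has_nine_entries(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 400, seed=7)
        cfg = ap.GmmConfig(n_components=2, seed=0)
        fit = ap.fit_gmm(X, cfg)
        report = ap.subsample_curve(X, cfg, fit.labels, n_replicates=2, seed=0)
        assert len(report.per_fraction) == 9

    def test_full_fraction_with_deterministic_fit_scores_one(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 400, seed=8)
        cfg = ap.GmmConfig(n_components=2, seed=0)
        fit = ap.fit_gmm(X, cfg)
        report = ap.subsample_curve(
            X, cfg, fit.labels, fractions=[1.0], n_replicates=1, seed=0
        )
        assert report.per_fraction.loc[0, "mean_jaccard"] == 1.0

    def test_too_small_fraction_skipped_and_counted(self, separated_pair):
        X, _ = ap.generate_mixture(separated_pair, 100, seed=9)
        cfg = ap.GmmConfig(n_components=2, seed=0)
        fit = ap.fit_gmm(X, cfg)
        report = ap.subsample_curve(
            X, cfg, fit.labels, fractions=[0.01], n_replicates=3, seed=0
        )
        assert report.n_failed == 3
        assert report.replicate_scores.empty
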