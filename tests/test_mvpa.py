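"""Per-depth decoding, accuracy shapes, similarity and the exact sign test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lamfmri.laminar import N_DEPTHS
from lamfmri.mvpa import (ATTENTION_PAIRS, STIMULUS_PAIRS, DecodingProfile,
                          PatternDataset, decode_per_depth,
                          exact_sign_permutation, fisher_z,
                          fit_accuracy_shape, make_pattern_dataset,
                          pattern_similarity)


def _pattern_data(rng, n_features=20, separation=0.0, n_runs=4,
                  samples_per_class_run=6, y=None):
    n = 2 * samples_per_class_run * n_runs
    runs = np.repeat(np.arange(1, n_runs + 1), 2 * samples_per_class_run)
    if y is None:
        y = np.tile(np.repeat([0, 1], samples_per_class_run), n_runs)
    x = rng.normal(size=(n, N_DEPTHS, n_features))
    x[y == 1] += separation
    return PatternDataset(patterns=x, y=y, runs=runs,
                          class_names=("c0", "c1"), comparison="c0 vs c1")


class TestDecoding:
    def test_separable_classes_reach_ceiling_at_every_depth(self):
        rng = np.random.default_rng(0)
        data = _pattern_data(rng, separation=10.0)
        prof = decode_per_depth(data)
        assert np.allclose(prof.accuracies, 1.0)

    def test_permuted_labels_decode_at_chance(self):
        # 60 label-shuffled datasets, accuracy averaged over depths
        accs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            data = _pattern_data(rng, separation=3.0)
            y_perm = rng.permutation(data.y)
            # re-permute until every run keeps both classes
            while any(len(set(y_perm[data.runs == r])) < 2
                      for r in np.unique(data.runs)):
                y_perm = rng.permutation(data.y)
            shuffled = PatternDataset(patterns=data.patterns, y=y_perm,
                                      runs=data.runs, class_names=data.class_names,
                                      comparison="perm")
            accs.append(decode_per_depth(shuffled).accuracies.mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.02)

    def test_identical_class_distributions_not_decodable(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(24, N_DEPTHS, 15))
        x = np.concatenate([base, base])          # class 1 duplicates class 0
        y = np.repeat([0, 1], 24)
        runs = np.tile(np.repeat(np.arange(1, 5), 6), 2)
        data = PatternDataset(patterns=x, y=y, runs=runs,
                              class_names=("a", "b"), comparison="dup")
        prof = decode_per_depth(data)
        assert np.all(prof.accuracies <= 0.5 + 1e-9)   # ties go to class 0

    def test_single_class_fold_rejected(self):
        rng = np.random.default_rng(2)
        y = np.tile(np.repeat([0, 1], 6), 4)
        y[:12] = 0                                  # run 1 has one class only
        with pytest.raises(ValueError, match="run 1"):
            _pattern_data(rng, y=y)

    def test_training_ignores_test_fold(self):
        # Cross-validation hygiene: an artifact injected into the held-out
        # run must leave that fold's trained weights unchanged.
        from lamfmri.mvpa import _center, _fit_fold
        rng = np.random.default_rng(3)
        data = _pattern_data(rng, separation=1.0)
        test = data.runs == 1
        d = 2
        clf_before = _fit_fold(data.patterns[~test, d, :], data.y[~test], 1.0)
        corrupted = data.patterns.copy()
        corrupted[test] += 100.0
        clf_after = _fit_fold(corrupted[~test, d, :], data.y[~test], 1.0)
        assert np.array_equal(clf_before.coef_, clf_after.coef_)
        assert clf_before.intercept_ == clf_after.intercept_

    def test_pooled_attention_comparison_stacks_24_vs_24(self, noisy_dataset):
        data = make_pattern_dataset(noisy_dataset, "A1", ("AV", "A"), by="stim")
        assert data.patterns.shape[0] == 48
        assert (data.y == 0).sum() == 24 and (data.y == 1).sum() == 24
        assert data.n_runs == 4


class TestAccuracyShape:
    def test_chance_profile_gives_zero_shape(self):
        prof = DecodingProfile(accuracies=np.full(6, 0.5),
                               fold_accuracies=None, comparison="x")
        p = fit_accuracy_shape(prof)
        assert p.C == pytest.approx(0.0) and p.L == pytest.approx(0.0)

    def test_linear_profile(self):
        prof = DecodingProfile(accuracies=np.linspace(0.5, 1.0, 6),
                               fold_accuracies=None, comparison="x")
        p = fit_accuracy_shape(prof)
        assert p.C == pytest.approx(0.25) and p.L == pytest.approx(0.1)

    def test_matches_shape_glm_oracle(self):
        rng = np.random.default_rng(4)
        acc = rng.uniform(0.3, 1.0, size=6)
        prof = DecodingProfile(accuracies=acc, fold_accuracies=None,
                               comparison="x")
        p = fit_accuracy_shape(prof)
        x = np.arange(6) - 2.5
        assert p.C == pytest.approx((acc - 0.5).mean())
        assert p.L == pytest.approx(((acc - 0.5) * x).sum() / (x**2).sum())


class TestSimilarity:
    def test_identical_patterns_clip_to_finite_z(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-12))

    def test_null_rho_for_independent_patterns(self):
        rhos = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            rhos.append(stats.spearmanr(rng.normal(size=1000),
                                        rng.normal(size=1000)).statistic)
        assert abs(np.mean(rhos)) < 0.07

    def test_rank_invariance_under_monotone_transform(self, noisy_dataset):
        r1 = pattern_similarity(noisy_dataset, "A1", ATTENTION_PAIRS,
                                STIMULUS_PAIRS)
        # Spearman is rank-based, so any strictly monotone transform of one
        # pattern leaves rho unchanged; verified directly:
        from lamfmri.mvpa import condition_mean_patterns
        means = condition_mean_patterns(noisy_dataset, "A1")
        a, b = means["A_AttA"], means["A_AttV"]
        assert stats.spearmanr(a, b).statistic == pytest.approx(
            stats.spearmanr(np.exp(a), b).statistic)
        assert set(r1.rho) == {"A_AttV|A_AttA", "AV_AttV|AV_AttA",
                               "A_AttA|AV_AttA", "A_AttV|AV_AttV"}

    def test_constant_pattern_rejected(self, noisy_dataset):
        ds = noisy_dataset
        flat = ds.betas.copy()
        flat[ds.roi_mask("A1")] = 1.0
        import dataclasses
        broken = dataclasses.replace(ds, betas=flat)
        with pytest.raises(ValueError, match="constant pattern"):
            pattern_similarity(broken, "A1", ATTENTION_PAIRS, STIMULUS_PAIRS)


class TestExactSignPermutation:
    def test_all_same_sign_n11(self):
        assert exact_sign_permutation(np.ones(11)) == 2.0 / 2048.0

    def test_zero_mean_gives_p_one(self):
        assert exact_sign_permutation(np.array([1.0, -1.0])) == 1.0

    def test_matches_bruteforce_oracle(self):
        # independent oracle: explicit enumeration via itertools
        def oracle(v):
            v = np.asarray(v, float)
            obs = abs(v.mean())
            hits = sum(abs(np.mean([s * x for s, x in zip(signs, v)])) >= obs - 1e-12
                       for signs in itertools.product((-1, 1), repeat=len(v)))
            return hits / 2 ** len(v)

        rng = np.random.default_rng(7)
        for n in range(2, 11):
            for _ in range(12):
                v = rng.normal(size=n)
                assert exact_sign_permutation(v) == pytest.approx(oracle(v))

    def test_scale_invariance_and_granularity(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=9)
        p = exact_sign_permutation(v)
        assert exact_sign_permutation(3.7 * v) == p
        # p is a multiple of 2^(1-n) (sign symmetry pairs assignments)
        assert (p * 2**8) == pytest.approx(round(p * 2**8))
        assert 0 < p <= 1

    def test_large_n_suggests_monte_carlo(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            exact_sign_permutation(np.ones(25))
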