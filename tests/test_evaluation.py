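"""Bootstrap AUC evaluation, Welch testing, ranking and tiering."""

import numpy as np
import pytest

import rpcascade as rp


def mann_whitney_auc(scores, y):
    """O(n^2) concordant-pair count with half-credit ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocPrAuc:
    def test_perfect_and_inverted_ordering(self):
        y = [0, 0, 1, 1]
        assert rp.roc_pr_auc([0.1, 0.2, 0.8, 0.9], y) == (1.0, 1.0)
        assert rp.roc_pr_auc([0.9, 0.8, 0.2, 0.1], y)[0] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            rp.roc_pr_auc([0.1, 0.2], [1, 1])

    def test_matches_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 41))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            roc, _ = rp.roc_pr_auc(scores, y)
            assert roc == pytest.approx(mann_whitney_auc(scores, y))

    def test_pr_conventions_differ_but_agree_on_perfect(self):
        rng = np.random.default_rng(1)
        scores, y = rng.random(200), rng.integers(0, 2, 200)
        _, step = rp.roc_pr_auc(scores, y, pr_convention="step")
        _, trap = rp.roc_pr_auc(scores, y, pr_convention="trapezoid")
        assert step != trap
        assert rp.roc_pr_auc([0.1, 0.9], [0, 1], pr_convention="trapezoid")[1] == 1.0


class TestBootstrap:
    def test_constant_scores_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            rp.bootstrap_auc(np.full(40, 0.5), np.r_[np.zeros(20), np.ones(20)], 10, seed=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        scores, y = rng.random(100), rng.integers(0, 2, 100)
        b1 = rp.bootstrap_auc(scores, y, 50, seed=5)
        b2 = rp.bootstrap_auc(scores, y, 50, seed=5)
        assert np.array_equal(b1["roc"], b2["roc"]) and np.array_equal(b1["pr"], b2["pr"])

    def test_bootstrap_mean_consistent_with_point_auc(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.zeros(150), np.ones(150)].astype(int)
        scores = np.where(y == 1, rng.normal(1, 1, 300), rng.normal(0, 1, 300))
        point, _ = rp.roc_pr_auc(scores, y)
        boot = rp.bootstrap_auc(scores, y, 1000, seed=3)
        assert abs(boot["roc"].mean() - point) < 2 * boot["roc"].std()

    def test_sigma_shrinks_with_test_set_size(self):
        rng = np.random.default_rng(4)
        sds = []
        for n in (200, 800, 3200):
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
            scores = np.where(y == 1, rng.normal(0.8, 1, n), rng.normal(0, 1, n))
            sds.append(rp.bootstrap_auc(scores, y, 200, seed=4)["roc"].std())
        assert sds[0] > sds[1] > sds[2]

    def test_paired_mapping_shares_resamples(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        boot = rp.bootstrap_auc({"a": s, "b": s}, y, 50, seed=6)
        assert np.array_equal(boot["a"]["roc"], boot["b"]["roc"])


class TestWelch:
    def test_identical_samples_give_p_one(self):
        assert rp.welch_test([0.8, 0.9, 0.85], [0.8, 0.9, 0.85]) == pytest.approx(1.0)

    def test_separated_normals_highly_significant(self):
        rng = np.random.default_rng(6)
        p = rp.welch_test(rng.normal(0, 1, 1000), rng.normal(5, 1, 1000))
        assert p < 1e-10

    def test_matches_scipy_satterthwaite(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 30), rng.normal(0.2, 2, 50)
        assert rp.welch_test(a, b) == pytest.approx(stats.ttest_ind(a, b, equal_var=False).pvalue)

    def test_type_i_error_rate_near_alpha(self):
        rng = np.random.default_rng(8)
        rejections = sum(
            rp.welch_test(rng.normal(0, 1, 40), rng.normal(0, 1, 40)) < 0.05 for _ in range(400)
        )
        # binomial(400, 0.05): mean 20, sd ~4.36; allow ~3 sd
        assert 7 <= rejections <= 34

    def test_degenerate_variance(self):
        with pytest.raises(ValueError, match="variance"):
            rp.welch_test([1.0, 1.0], [2.0, 2.0])


class TestCombinedScore:
    def test_printed_arithmetic(self):
        assert rp.combined_score([0.4], [0.8], 0.5)[0] == pytest.approx(0.08)

    def test_boundary_lambdas_collapse_to_zero(self):
        m, r = np.array([0.3, 0.9]), np.array([0.5, 0.7])
        assert np.all(rp.combined_score(m, r, 0.0) == 0)
        assert np.all(rp.combined_score(m, r, 1.0) == 0)

    def test_lambda_invariant_ranking_equals_plain_product(self):
        rng = np.random.default_rng(9)
        m, r = rng.random(500), rng.random(500)
        ref = np.argsort(-m * r)
        for lam in (0.1, 0.5, 0.9):
            assert np.array_equal(np.argsort(-rp.combined_score(m, r, lam)), ref)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            rp.combined_score([0.5], [0.5], 1.5)

    def test_normalized_batch_spans_unit_interval(self):
        s = rp.combined_score([0.1, 0.5, 0.9], [0.2, 0.6, 0.8], 0.5, normalize=True)
        assert s.min() == 0.0 and s.max() == 1.0


class TestDosCandidates:
    def test_threshold_filtering(self):
        pairs = [("m1", "g1"), ("m2", "g2")]
        by_dos, by_ref = rp.dos_candidates(pairs, [0.9, 0.6], [0.3, 0.2])
        assert len(by_dos) == 1 and by_dos.iloc[0]["entity_a"] == "m1"
        by_dos, by_ref = rp.dos_candidates(pairs, [0.5, 0.5], [0.2, 0.3])
        assert len(by_dos) == 0 and len(by_ref) == 0

    def test_both_orderings_match_sort_oracle(self):
        rng = np.random.default_rng(10)
        pairs = [(f"m{i}", f"g{i}") for i in range(100)]
        refined, original = rng.random(100), rng.random(100) * 0.3
        by_dos, by_ref = rp.dos_candidates(pairs, refined, original)
        dos = refined - original
        surv = [i for i in range(100) if dos[i] >= 0.5]
        assert list(by_dos["dos"]) == sorted((dos[i] for i in surv), reverse=True)
        assert list(by_ref["refined"]) == sorted((refined[i] for i in surv), reverse=True)


class TestTiers:
    def test_exact_fractions_at_n_100(self):
        scores = np.linspace(1, 0, 100)
        tiers = rp.tier_assignment(scores)
        from collections import Counter

        counts = Counter(tiers)
        assert counts == {"top1": 1, "top5": 4, "top10": 5, "top33": 23, "bottom66": 67}

    def test_small_n_ceiling_rule(self):
        assert rp.tier_assignment([0.9, 0.5, 0.1])[0] == "top1"

    def test_partition_and_order_statistics(self):
        rng = np.random.default_rng(11)
        scores = rng.random(1000)
        tiers = np.array(rp.tier_assignment(scores))
        assert len(tiers) == 1000
        top = scores[tiers != "bottom66"]
        bottom = scores[tiers == "bottom66"]
        assert top.min() >= bottom.max()
        assert (tiers == "top1").sum() == 10
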