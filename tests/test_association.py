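"""Unit tests for standardization, correlation, meta-analysis, permutations
and the empirical-FDR machinery."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from vima import association
from vima.association import (
    cluster_baseline_test,
    contingency_log_odds,
    correlate,
    global_statistic,
    global_test,
    local_test,
    mat_pca,
    meta_local,
    permute_phenotype,
    standardize_mat,
)
from vima.types import SampleMetadata

from conftest import make_metadata


def random_mat(n=10, p=30, e=2, seed=0):
    return np.random.default_rng(seed).standard_normal((n, p, e))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class TestStandardizeMat:
    def test_population_convention(self):
        Q = np.zeros((3, 1, 1))
        Q[:, 0, 0] = [0.0, 1.0, 2.0]
        Q_std, valid = standardize_mat(Q)
        np.testing.assert_allclose(Q_std[:, 0, 0], [-1.22474487, 0, 1.22474487])
        assert valid.all()

    def test_constant_column_flagged_and_zeroed(self):
        Q = random_mat(8, 5, 2)
        Q[:, 2, 1] = 7.0
        Q_std, valid = standardize_mat(Q)
        assert not valid[2, 1]
        assert np.all(Q_std[:, 2, 1] == 0)

    def test_contract_on_random_input(self):
        Q_std, _ = standardize_mat(random_mat(20, 40, 3))
        assert np.abs(Q_std.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Q_std.std(axis=0), 1.0, atol=1e-10)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_mat(np.ones((5, 3, 2)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            standardize_mat(random_mat(2, 3, 1))


# ---------------------------------------------------------------------------
# correlation and meta-analysis
# ---------------------------------------------------------------------------

class TestCorrelate:
    def test_column_equal_to_phenotype(self):
        y = np.array([0.0, 1, 0, 1, 1, 0])
        Q = np.stack([y, -y], axis=1)[:, :, None]
        Q_std, _ = standardize_mat(Q)
        C = correlate(Q_std, y)
        assert C[0, 0] == pytest.approx(1.0)
        assert C[0, 1] == pytest.approx(-1.0)

    def test_independent_column_small_correlation(self):
        r = np.random.default_rng(11)
        n = 200
        Q_std, _ = standardize_mat(r.standard_normal((n, 1, 1)))
        C = correlate(Q_std, r.standard_normal(n))
        assert abs(C[0, 0]) < 0.2

    def test_constant_phenotype_rejected(self):
        Q_std, _ = standardize_mat(random_mat(6, 3, 1))
        with pytest.raises(ValueError, match="constant"):
            correlate(Q_std, np.ones(6))

    def test_covariate_residualization_kills_confounded_signal(self):
        r = np.random.default_rng(12)
        n = 60
        cov = r.standard_normal(n)
        y = cov + 0.01 * r.standard_normal(n)
        Q = cov[:, None, None] + 0.01 * r.standard_normal((n, 4, 1))
        Q_std, _ = standardize_mat(Q)
        raw = correlate(Q_std, y)
        adj = correlate(Q_std, y, covariates=cov[:, None])
        assert abs(raw).min() > 0.9
        assert abs(adj).max() < 0.5


class TestMetaLocal:
    def test_identical_correlations_yield_that_value(self):
        C = np.full((10, 4), 0.37)
        np.testing.assert_allclose(meta_local(C), 0.37)

    def test_odd_symmetry_cancels(self):
        C = np.array([[0.5], [-0.5]])
        assert meta_local(C)[0] == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        C = np.array([[0.9], [0.1]])
        expected = (0.9**3 + 0.1**3) / (0.9**2 + 0.1**2)
        assert meta_local(C)[0] == pytest.approx(expected)
        assert meta_local(C)[0] == pytest.approx(0.8902439024390244)

    def test_zero_denominator_gives_zero(self):
        assert meta_local(np.zeros((5, 3)))[0] == 0.0

    def test_bounded_by_extreme_correlations(self):
        r = np.random.default_rng(13)
        C = r.uniform(-1, 1, size=(10, 50))
        rho = meta_local(C)
        assert np.all(rho <= C.max(axis=0) + 1e-12)
        assert np.all(rho >= C.min(axis=0) - 1e-12)
        assert np.all(np.abs(rho) <= np.abs(C).max(axis=0) + 1e-12)


class TestGlobalStatistic:
    def test_equal_correlations_give_c_squared(self):
        C = np.full((10, 7), 0.3)
        assert global_statistic(C) == pytest.approx(0.09)

    def test_zero_matrix_gives_zero(self):
        assert global_statistic(np.zeros((10, 5))) == 0.0

    def test_single_encoder_equals_mean_square(self):
        r = np.random.default_rng(14)
        C = r.uniform(-1, 1, size=(1, 40))
        assert global_statistic(C) == pytest.approx(float((C[0] ** 2).mean()))

    def test_bounded_unit_interval(self):
        r = np.random.default_rng(15)
        C = r.uniform(-1, 1, size=(5, 100))
        assert 0.0 <= global_statistic(C) <= 1.0


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

class TestPermutePhenotype:
    def test_singleton_donors_permute_values(self):
        meta = make_metadata(6)
        rng = np.random.default_rng(0)
        perm = permute_phenotype(meta, rng)
        assert sorted(perm) == sorted(meta.phenotype)

    def test_same_donor_shares_value(self):
        meta = SampleMetadata(
            sample_ids=np.array(["a", "b", "c", "d", "e"]),
            donor_ids=np.array(["d0", "d0", "d0", "d1", "d2"]),
            phenotype=np.array([1.0, 1, 1, 0, 0]),
        )
        rng = np.random.default_rng(1)
        for _ in range(20):
            perm = permute_phenotype(meta, rng)
            assert perm[0] == perm[1] == perm[2]

    def test_donor_arrangements_equally_likely(self):
        # 3 donors with distinct values -> 6 arrangements, uniform
        meta = SampleMetadata(
            sample_ids=np.array(["a", "b", "c"]),
            donor_ids=np.array(["d0", "d1", "d2"]),
            phenotype=np.array([0.0, 1.0, 2.0]),
        )
        rng = np.random.default_rng(2)
        counts = {p: 0 for p in itertools.permutations([0.0, 1.0, 2.0])}
        n = 6000
        for _ in range(n):
            counts[tuple(permute_phenotype(meta, rng))] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_inconsistent_donor_phenotype_rejected(self):
        meta = SampleMetadata(
            sample_ids=np.array(["a", "b"]),
            donor_ids=np.array(["d0", "d0"]),
            phenotype=np.array([0.0, 1.0]),
        )
        with pytest.raises(ValueError, match="inconsistent"):
            permute_phenotype(meta, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# local test / empirical FDR
# ---------------------------------------------------------------------------

def brute_force_fdr(rho, null_rho, thr):
    """Reference implementation: mean null exceedances / observed exceedances."""
    obs = (rho >= thr).sum()
    if obs == 0:
        return 0.0
    return float(np.mean([(nr >= thr).sum() for nr in null_rho]) / obs)


class TestLocalTest:
    def test_fdr_estimator_matches_bruteforce_recount(self):
        r = np.random.default_rng(20)
        n, p, e = 12, 20, 2
        meta = make_metadata(n, seed=3)
        Q_std, valid = standardize_mat(r.standard_normal((n, p, e)))
        res = local_test(Q_std, meta, n_perm=50, seed=5, valid=valid)
        # recompute the raw estimates for the positive tail independently
        rng = np.random.default_rng(5)
        C = correlate(Q_std, meta.phenotype, valid=valid)
        rho = meta_local(C)
        null_C = association._null_correlations(Q_std, meta, 50,
                                                np.random.default_rng(5), valid, None)
        null_rho = np.stack([meta_local(c) for c in null_C])
        pos = res.fdr_table[res.fdr_table["tail"] == "pos"]
        for _, row in pos.iterrows():
            expected = min(1.0, brute_force_fdr(rho, null_rho, row.threshold))
            assert row.fdr_raw == pytest.approx(expected)

    def test_fdr_isotonized_monotone_in_threshold(self):
        r = np.random.default_rng(21)
        meta = make_metadata(10, seed=4)
        Q_std, valid = standardize_mat(r.standard_normal((10, 40, 2)))
        res = local_test(Q_std, meta, n_perm=60, seed=6, valid=valid)
        for tail, sign in (("pos", 1), ("neg", -1)):
            sub = res.fdr_table[res.fdr_table["tail"] == tail]
            if len(sub) > 1:
                # walk from the loosest to the strictest cutoff of the tail:
                # the isotonized estimate must never increase
                ordered = sub.sort_values("threshold", ascending=(sign > 0))
                assert np.all(np.diff(ordered.fdr.to_numpy()) <= 1e-12)

    def test_significant_sets_disjoint(self):
        r = np.random.default_rng(22)
        meta = make_metadata(10, seed=5)
        Q = r.standard_normal((10, 30, 2))
        Q[:, :5, :] += 3 * meta.phenotype[:, None, None]
        Q_std, valid = standardize_mat(Q)
        res = local_test(Q_std, meta, n_perm=100, seed=7, valid=valid)
        assert set(res.significant_pos).isdisjoint(res.significant_neg)

    def test_planted_signal_enriched_and_fdr_controlled(self):
        r = np.random.default_rng(23)
        n, p = 30, 200
        n_signal = 30
        meta = make_metadata(n, seed=6)
        y = meta.phenotype
        Q = r.standard_normal((n, p, 2))
        Q[:, :n_signal, :] += 2.0 * y[:, None, None]
        Q_std, valid = standardize_mat(Q)
        res = local_test(Q_std, meta, n_perm=150, seed=8, valid=valid,
                         fdr_level=0.10)
        called = np.concatenate([res.significant_pos, res.significant_neg])
        assert len(called) > 0
        true_hits = (called < n_signal).sum()
        # planted columns dominate the calls
        assert true_hits / len(called) > 0.7

    def test_null_rarely_calls_patches(self):
        r = np.random.default_rng(24)
        frac = []
        for i in range(10):
            meta = make_metadata(12, seed=100 + i)
            Q_std, valid = standardize_mat(r.standard_normal((12, 50, 2)))
            res = local_test(Q_std, meta, n_perm=80, seed=i, valid=valid,
                             fdr_level=0.10)
            frac.append(res.n_significant / 50)
        assert np.mean(frac) < 0.1


# ---------------------------------------------------------------------------
# global test
# ---------------------------------------------------------------------------

class TestGlobalTest:
    def test_pvalue_floor(self):
        r = np.random.default_rng(30)
        meta = make_metadata(10, seed=7)
        Q = r.standard_normal((10, 20, 2)) + 5 * meta.phenotype[:, None, None] * np.sign(
            r.standard_normal((10, 20, 2))
        ) * 0  # no modification; only check the floor bound
        Q_std, valid = standardize_mat(Q)
        res = global_test(Q_std, meta, n_perm=99, seed=9, valid=valid)
        assert res.p_value >= 1 / 100

    def test_sign_symmetry_of_phenotype(self):
        r = np.random.default_rng(31)
        n = 12
        meta = make_metadata(n, seed=8)
        Q_std, valid = standardize_mat(r.standard_normal((n, 25, 2)))
        res_pos = global_test(Q_std, meta, n_perm=60, seed=10, valid=valid)
        meta_neg = SampleMetadata(sample_ids=meta.sample_ids,
                                  donor_ids=meta.donor_ids,
                                  phenotype=-meta.phenotype)
        res_neg = global_test(Q_std, meta_neg, n_perm=60, seed=10, valid=valid)
        assert res_pos.R == pytest.approx(res_neg.R, abs=1e-12)
        assert res_pos.p_value == res_neg.p_value
        C_pos = correlate(Q_std, meta.phenotype, valid=valid)
        C_neg = correlate(Q_std, -meta.phenotype, valid=valid)
        np.testing.assert_allclose(meta_local(C_pos), -meta_local(C_neg), atol=1e-12)

    def test_null_pvalues_uniform(self):
        """Permutation P-values under a true null follow the uniform
        distribution on the achievable grid (KS test over replicates)."""
        from scipy.stats import kstest

        r = np.random.default_rng(32)
        pvals = []
        for i in range(200):
            meta = make_metadata(10, seed=500 + i)
            if meta.phenotype.std() == 0:
                continue
            Q_std, valid = standardize_mat(r.standard_normal((10, 15, 2)))
            res = global_test(Q_std, meta, n_perm=49, seed=i, valid=valid)
            pvals.append(res.p_value)
        # compare against the discrete uniform achievable with 49 permutations
        stat, p = kstest(pvals, "uniform")
        # the add-one estimator makes p-values slightly conservative; allow
        # one-sided deviation toward conservatism only
        assert np.mean(pvals) > 0.45
        assert p > 0.01 or np.mean(np.array(pvals) < 0.05) <= 0.05


# ---------------------------------------------------------------------------
# auxiliary operations
# ---------------------------------------------------------------------------

class TestMatPca:
    def test_block_structure_separated_by_pc1(self):
        r = np.random.default_rng(40)
        n, p = 12, 40
        Q = 0.05 * r.standard_normal((n, p, 2))
        Q[:6, :20, :] += 1.0
        Q[6:, 20:, :] += 1.0
        scores, evr = mat_pca(Q)
        side = np.sign(scores[:, 0])
        assert len(set(side[:6])) == 1 and len(set(side[6:])) == 1
        assert side[0] != side[6]

    def test_duplicate_samples_identical_scores(self):
        r = np.random.default_rng(41)
        Q = r.standard_normal((6, 10, 2))
        Q[3] = Q[0]
        scores, _ = mat_pca(Q)
        np.testing.assert_allclose(scores[0], scores[3], atol=1e-10)

    def test_scores_orthogonal(self):
        Q = np.random.default_rng(42).standard_normal((10, 30, 2))
        scores, _ = mat_pca(Q, n_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestClusterBaseline:
    def test_bonferroni_and_floor(self):
        r = np.random.default_rng(43)
        n, p = 12, 90
        meta = make_metadata(n, seed=9)
        # embedding with 3 clear clusters; cluster 0 abundance tracks y
        centers = np.array([[5, 0], [0, 5], [-5, -5]])
        labels = r.integers(0, 3, size=p)
        emb = centers[labels] + 0.1 * r.standard_normal((p, 2))
        codes = r.integers(0, n, size=p)
        out = cluster_baseline_test(emb, codes, meta, n_perm=60, seed=1)
        assert out["n_clusters"] >= 2
        assert out["global_bonferroni_p"] == pytest.approx(
            min(1.0, out["n_clusters"] * out["per_cluster_p"].min())
        )
        assert out["per_cluster_p"].min() >= 1 / 61
        assert len(out["patch_scores"]) == p


class TestContingencyLogOdds:
    def test_balanced_table(self):
        res = contingency_log_odds(10, 10, 10, 10)
        assert res["log_or"] == pytest.approx(0.0)
        assert res["se"] == pytest.approx(np.sqrt(0.4))
        assert res["se"] == pytest.approx(0.6324555, abs=1e-6)

    def test_fourfold_odds(self):
        res = contingency_log_odds(20, 10, 10, 20)
        assert res["log_or"] == pytest.approx(np.log(4.0))

    def test_ci_contains_zero_iff_insignificant(self):
        for cells in [(20, 10, 10, 20), (11, 10, 10, 11), (30, 5, 6, 28)]:
            res = contingency_log_odds(*cells)
            contains = res["ci95"][0] < 0 < res["ci95"][1]
            assert contains == (abs(res["log_or"]) < 1.96 * res["se"])

    def test_zero_cell_directs_to_continuity_correction(self):
        with pytest.raises(ValueError, match="continuity"):
            contingency_log_odds(0, 5, 5, 5)
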