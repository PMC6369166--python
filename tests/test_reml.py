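"""Variance-component machinery: stacked covariance construction, EM-REML and
the restricted likelihood."""

import numpy as np
import pytest

from mvftest.data import GRM
from mvftest.reml import (
    MissingPattern,
    VarianceComponents,
    build_Vm,
    em_reml,
    restricted_loglik,
)

from conftest import make_phenotypes


def random_psd(d, rng, scale=1.0):
    R = rng.standard_normal((d, d))
    return scale * (R @ R.T / d + 0.1 * np.eye(d))


def identity_grm(n):
    return GRM(A=np.eye(n), sample_ids=[f"s{i + 1}" for i in range(n)])


def two_group_pattern(n):
    """First half observed for variate 1 only, second half for variate 2 only."""
    mask = np.zeros((n, 2), dtype=bool)
    mask[: n // 2, 0] = True
    mask[n // 2:, 1] = True
    return MissingPattern(mask)


class TestMissingPattern:
    def test_stacking_is_variate_major(self):
        mask = np.array([[True, True], [True, False], [False, True]])
        pattern = MissingPattern(mask)
        values = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        # stacked order: variate 1 of s1, s2, then variate 2 of s1, s3
        np.testing.assert_allclose(pattern.stack(values), [1.0, 2.0, 10.0, 30.0])
        np.testing.assert_array_equal(pattern.rec_variate, [0, 0, 1, 1])
        np.testing.assert_array_equal(pattern.rec_individual, [0, 1, 0, 2])

    def test_design_is_block_diagonal(self):
        mask = np.array([[True, True], [True, False]])
        pattern = MissingPattern(mask)
        X = np.array([[1.0, 5.0], [1.0, 7.0]])
        D = pattern.design(X)
        np.testing.assert_allclose(D, [
            [1, 5, 0, 0],
            [1, 7, 0, 0],
            [0, 0, 1, 5],
        ])

    def test_rejects_empty_row(self):
        with pytest.raises(ValueError, match="at least one"):
            MissingPattern(np.array([[True, True], [False, False]]))


class TestBuildVm:
    def test_full_observation_matches_kronecker_oracle(self):
        rng = np.random.default_rng(1)
        n, d = 4, 3
        A = random_psd(n, rng)
        Su, Se = random_psd(d, rng), random_psd(d, rng)
        vc = VarianceComponents(sigma_u=Su, sigma_e=Se)
        grm = GRM(A=A, sample_ids=[f"s{i}" for i in range(n)])
        pattern = MissingPattern(np.ones((n, d), dtype=bool))
        V = build_Vm(vc, grm, pattern)
        oracle = np.kron(Su, A) + np.kron(Se, np.eye(n))
        np.testing.assert_allclose(V, oracle, atol=1e-12)

    def test_missing_rows_are_deleted_from_kronecker(self):
        rng = np.random.default_rng(2)
        n, d = 5, 2
        A = random_psd(n, rng)
        vc = VarianceComponents(sigma_u=random_psd(d, rng), sigma_e=random_psd(d, rng))
        grm = GRM(A=A, sample_ids=[f"s{i}" for i in range(n)])
        mask = rng.random((n, d)) < 0.6
        mask[~mask.any(axis=1), 0] = True
        pattern = MissingPattern(mask)
        full = np.kron(vc.sigma_u, A) + np.kron(vc.sigma_e, np.eye(n))
        keep = pattern.flat_obs
        np.testing.assert_allclose(build_Vm(vc, grm, pattern),
                                   full[np.ix_(keep, keep)], atol=1e-12)

    def test_univariate_formula(self):
        rng = np.random.default_rng(3)
        n = 6
        A = random_psd(n, rng)
        grm = GRM(A=A, sample_ids=[f"s{i}" for i in range(n)])
        vc = VarianceComponents(sigma_u=[[2.5]], sigma_e=[[0.7]])
        V = build_Vm(vc, grm, MissingPattern(np.ones((n, 1), dtype=bool)))
        np.testing.assert_allclose(V, 2.5 * A + 0.7 * np.eye(n), atol=1e-12)

    def test_zero_genetic_identity_residual(self):
        n, d = 4, 2
        vc = VarianceComponents(sigma_u=np.zeros((d, d)), sigma_e=np.eye(d))
        V = build_Vm(vc, identity_grm(n), MissingPattern(np.ones((n, d), dtype=bool)))
        np.testing.assert_allclose(V, np.eye(n * d), atol=1e-12)

    def test_maximal_missingness_residual_ignores_correlation(self):
        """With one variate per individual the residual part is block diagonal
        and the residual correlation parameter drops out exactly."""
        rng = np.random.default_rng(4)
        n = 8
        A = random_psd(n, rng)
        grm = GRM(A=A, sample_ids=[f"s{i}" for i in range(n)])
        pattern = two_group_pattern(n)
        Su = random_psd(2, rng)
        Se_diag = np.diag([0.9, 1.7])
        for off in (0.0, 0.3, -0.6, 1.2):
            Se = Se_diag + off * (np.ones((2, 2)) - np.eye(2))
            V = build_Vm(VarianceComponents(sigma_u=Su, sigma_e=Se), grm, pattern)
            V0 = build_Vm(VarianceComponents(sigma_u=Su, sigma_e=Se_diag), grm, pattern)
            np.testing.assert_array_equal(V, V0)
        # and the residual part is diag(I_X se1, I_Y se2)
        resid = V0 - Su[pattern.rec_variate][:, pattern.rec_variate] * A[
            np.ix_(pattern.rec_individual, pattern.rec_individual)]
        np.testing.assert_allclose(
            resid, np.diag([0.9] * (n // 2) + [1.7] * (n // 2)), atol=1e-12)

    def test_non_psd_components_fatal(self):
        n = 3
        vc = VarianceComponents(sigma_u=[[1.0]], sigma_e=[[-0.5]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            build_Vm(vc, identity_grm(n), MissingPattern(np.ones((n, 1), dtype=bool)))

    def test_dimension_mismatch_fatal(self):
        vc = VarianceComponents(sigma_u=np.eye(2), sigma_e=np.eye(2))
        with pytest.raises(ValueError):
            build_Vm(vc, identity_grm(3), MissingPattern(np.ones((3, 1), dtype=bool)))


class TestVarianceComponents:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            VarianceComponents(sigma_u=[[1.0, 0.4], [0.1, 1.0]], sigma_e=np.eye(2))

    def test_scalar_promoted(self):
        vc = VarianceComponents(sigma_u=2.0, sigma_e=1.0)
        assert vc.d == 1 and vc.sigma_u.shape == (1, 1)


def model_phenotypes(grm, Su, Se, rng):
    """Draw one n x d phenotype table from the mixed model itself."""
    n, d = grm.n_samples, Su.shape[0]
    La = np.linalg.cholesky(grm.A + 1e-8 * np.eye(n))
    U = La @ rng.standard_normal((n, d)) @ np.linalg.cholesky(Su).T
    E = rng.standard_normal((n, d)) @ np.linalg.cholesky(Se).T
    return make_phenotypes(U + E, sample_ids=grm.sample_ids)


class TestEmReml:
    def test_monotone_loglik_and_convergence(self, small_grm):
        rng = np.random.default_rng(8)
        Su = np.array([[1.0, 0.5], [0.5, 0.8]])
        ph = model_phenotypes(small_grm, Su, Su, rng)
        vc = em_reml(ph, small_grm)
        assert vc.converged
        assert np.all(np.diff(vc.loglik_path) >= -1e-6)
        assert vc.is_psd()

    def test_loglik_path_matches_restricted_loglik(self, small_grm):
        rng = np.random.default_rng(9)
        Su = np.array([[1.0, 0.3], [0.3, 0.6]])
        ph = model_phenotypes(small_grm, Su, Su, rng)
        vc = em_reml(ph, small_grm)
        assert vc.loglik_path[-1] <= restricted_loglik(vc, ph, small_grm) + 1e-4

    def test_rotated_and_direct_paths_agree(self, small_grm):
        rng = np.random.default_rng(10)
        Su = np.array([[1.2, 0.4], [0.4, 0.9]])
        ph = model_phenotypes(small_grm, Su, Su, rng)
        a = em_reml(ph, small_grm, method="rotated")
        b = em_reml(ph, small_grm, method="direct")
        np.testing.assert_allclose(a.sigma_u, b.sigma_u, atol=1e-8)
        np.testing.assert_allclose(a.sigma_e, b.sigma_e, atol=1e-8)

    def test_mask_plumbing_does_not_change_estimates(self, small_grm):
        # complete data passed as "missing-capable" (direct path) must match
        # the complete-data path; the all-true mask is pure plumbing
        rng = np.random.default_rng(11)
        ph = model_phenotypes(small_grm, np.eye(2), np.eye(2), rng)
        assert ph.mask.all()
        auto = em_reml(ph, small_grm, method="auto")
        direct = em_reml(ph, small_grm, method="direct")
        np.testing.assert_allclose(auto.sigma_u, direct.sigma_u, atol=1e-8)

    def test_rotated_requires_complete_records(self, small_grm):
        rng = np.random.default_rng(12)
        ph = model_phenotypes(small_grm, np.eye(2), np.eye(2), rng)
        mask = ph.mask.copy()
        mask[0, 1] = False
        ph_m = make_phenotypes(ph.values, mask=mask, sample_ids=ph.sample_ids)
        with pytest.raises(ValueError, match="complete"):
            em_reml(ph_m, small_grm, method="rotated")

    def test_null_heritability_recovery(self, sim_grm):
        # d = 1, pure i.i.d. noise against a real relationship matrix:
        # estimated h2 < 0.2 in >= 90% of replicates.  (With A = I the two
        # components are confounded -- V = (su + se) I -- so a non-trivial A
        # is required for the split to be identifiable at all.)
        reps = 20
        n = sim_grm.n_samples
        rng = np.random.default_rng(100)
        low = 0
        for _ in range(reps):
            ph = make_phenotypes(rng.standard_normal((n, 1)),
                                 sample_ids=sim_grm.sample_ids)
            vc = em_reml(ph, sim_grm)
            h2 = float(vc.sigma_u[0, 0] / (vc.sigma_u[0, 0] + vc.sigma_e[0, 0]))
            low += h2 < 0.2
        assert low >= 0.9 * reps

    def test_identity_grm_components_confounded(self):
        # A = I: V = (su + se) I, so only the total variance is identified;
        # EM from the symmetric start leaves the split at its initial ratio.
        n = 60
        rng = np.random.default_rng(101)
        ph = make_phenotypes(rng.standard_normal((n, 1)))
        vc = em_reml(ph, identity_grm(n))
        y = ph.values[:, 0]
        total = float(vc.sigma_u[0, 0] + vc.sigma_e[0, 0])
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.1)
        assert vc.sigma_u[0, 0] == pytest.approx(vc.sigma_e[0, 0], rel=1e-3)

    def test_inestimable_fatal(self):
        grm = identity_grm(2)
        ph = make_phenotypes(np.array([[1.0, 2.0], [0.5, 1.5]]),
                             mask=[[True, False], [False, True]])
        with pytest.raises(ValueError, match="observed records"):
            em_reml(ph, grm)

    def test_iteration_cap_reports_nonconvergence(self, small_grm):
        rng = np.random.default_rng(13)
        ph = model_phenotypes(small_grm, np.eye(2), np.eye(2), rng)
        vc = em_reml(ph, small_grm, max_iter=4)
        assert not vc.converged
        assert vc.n_iter <= 4


class TestRestrictedLoglik:
    @staticmethod
    def scalar_oracle(y, X, V):
        """Independent textbook REML likelihood with explicit inverses."""
        n, q = X.shape
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        resid = y - X @ beta
        return -0.5 * (
            np.log(np.linalg.det(V))
            + np.log(np.linalg.det(XtViX))
            + resid @ Vi @ resid
            + (n - q) * np.log(2 * np.pi)
        )

    def test_matches_hand_coded_scalar_reml(self):
        rng = np.random.default_rng(20)
        n = 10
        y = rng.standard_normal(n)
        vc = VarianceComponents(sigma_u=[[0.8]], sigma_e=[[1.3]])
        grm = identity_grm(n)
        ph = make_phenotypes(y[:, None])
        want = self.scalar_oracle(y, np.ones((n, 1)),
                                  0.8 * np.eye(n) + 1.3 * np.eye(n))
        assert restricted_loglik(vc, ph, grm) == pytest.approx(want, abs=1e-10)

    def test_permutation_invariance(self, small_grm):
        rng = np.random.default_rng(21)
        ph = model_phenotypes(small_grm, np.eye(2), np.eye(2), rng)
        vc = VarianceComponents(sigma_u=np.array([[0.9, 0.2], [0.2, 0.7]]),
                                sigma_e=np.eye(2))
        perm = rng.permutation(small_grm.n_samples)
        ll = restricted_loglik(vc, ph, small_grm)
        ll_p = restricted_loglik(vc, ph.subset_samples(perm),
                                 small_grm.subset_samples(perm))
        assert ll_p == pytest.approx(ll, abs=1e-8)

    def test_doubling_scaling_identity(self, small_grm):
        rng = np.random.default_rng(22)
        Su = np.array([[1.0, 0.4], [0.4, 0.8]])
        ph = model_phenotypes(small_grm, Su, Su, rng)
        vc1 = VarianceComponents(sigma_u=Su, sigma_e=Su)
        vc2 = VarianceComponents(sigma_u=2 * Su, sigma_e=2 * Su)
        # ll(2V) - ll(V) = -(1/2)[(N - q) log 2 - qf/2] with qf the GLS
        # quadratic form under V (brute-force below)
        pattern = MissingPattern(ph.mask)
        V = build_Vm(vc1, small_grm, pattern)
        X = pattern.design(np.ones((small_grm.n_samples, 1)))
        y = pattern.stack(ph.values)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        qf = (y - X @ beta) @ Vi @ (y - X @ beta)
        N, q = len(y), X.shape[1]
        want = -0.5 * ((N - q) * np.log(2.0) - qf / 2.0)
        got = restricted_loglik(vc2, ph, small_grm) - restricted_loglik(vc1, ph, small_grm)
        assert got == pytest.approx(want, abs=1e-8)

    def test_singular_covariance_fatal(self):
        n = 4
        vc = VarianceComponents(sigma_u=[[0.0]], sigma_e=[[0.0]])
        ph = make_phenotypes(np.zeros((n, 1)))
        with pytest.raises(Exception, match="singular|positive"):
            restricted_loglik(vc, ph, identity_grm(n))
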