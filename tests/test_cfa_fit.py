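import dataclasses

import numpy as np
import pytest

import hbmscore as hs
from hbmscore import cfa
from hbmscore.model import DEFAULT_SPEC, ITEM_COLUMNS, HBMModelSpec

ITEMS = list(ITEM_COLUMNS)

ONE_FACTOR_3 = HBMModelSpec(
    item_factor_map=("F", "F", "F"), factors=("F",), structural_paths=()
)


class TestFitBasics:
    def test_just_identified_three_item_closed_form(self, rng):
        """A one-factor, 3-item model is just identified: F_ML reaches 0 and
        the standardized loadings equal sqrt(r12 r13 / r23) etc."""
        lam = np.array([0.6, 0.7, 0.8])
        pop = np.outer(lam, lam)
        np.fill_diagonal(pop, 1.0)
        X = rng.multivariate_normal(np.zeros(3), pop, size=400)
        S = np.cov(X, rowvar=False, ddof=1)
        result = hs.fit(S, n=400, spec=ONE_FACTOR_3)
        assert result.fml == pytest.approx(0.0, abs=1e-10)
        d = np.sqrt(np.diag(S))
        r = S / np.outer(d, d)
        closed = np.array(
            [
                np.sqrt(r[0, 1] * r[0, 2] / r[1, 2]),
                np.sqrt(r[0, 1] * r[1, 2] / r[0, 2]),
                np.sqrt(r[0, 2] * r[1, 2] / r[0, 1]),
            ]
        )
        np.testing.assert_allclose(np.abs(result.loadings_std), closed, atol=1e-6)

    def test_large_sample_recovery_of_reference_solution(self, large_continuous_fit):
        """Fitting n = 50,000 continuous responses generated under the
        reference standardized solution recovers every second-order
        coefficient, the BAR->CTA coefficient, the loadings and the total
        effects within +/-0.02."""
        result = large_continuous_fit
        assert result.converged and not result.heywood
        np.testing.assert_allclose(result.gamma_std, hs.REFERENCE_GAMMA, atol=0.02)
        assert result.beta_std[0] == pytest.approx(hs.REFERENCE_BETA, abs=0.02)
        np.testing.assert_allclose(
            result.loadings_std, hs.reference_loadings(), atol=0.02
        )
        np.testing.assert_allclose(
            result.total_effects, hs.REFERENCE_TOTAL_EFFECTS, atol=0.02
        )
        assert result.df == 203

    def test_location_shift_leaves_estimates_unchanged(self, ref_config_continuous):
        """Mean structure does not enter the covariance fit."""
        tab = hs.generate_cohort(ref_config_continuous, "pre", 1500, 0.0)
        shifted = tab.copy()
        shifted[ITEMS] = shifted[ITEMS] + 2.5
        a = hs.fit(tab, n_starts=1)
        b = hs.fit(shifted, n_starts=1)
        np.testing.assert_allclose(a.loadings_std, b.loadings_std, atol=1e-8)
        np.testing.assert_allclose(a.gamma_std, b.gamma_std, atol=1e-8)
        assert a.fml == pytest.approx(b.fml, abs=1e-10)

    def test_start_jitter_does_not_move_the_solution(self, ref_config_continuous):
        tab = hs.generate_cohort(ref_config_continuous, "pre", 2000, 0.0)
        a = hs.fit(tab, seed=1)
        b = hs.fit(tab, seed=999)
        np.testing.assert_allclose(a.gamma_std, b.gamma_std, atol=1e-6)
        np.testing.assert_allclose(a.loadings_std, b.loadings_std, atol=1e-6)

    def test_scale_equivariance_of_standardized_solution(self, ref_config_continuous):
        """Rescaling one item by 10 changes nothing in the standardized
        metric."""
        tab = hs.generate_cohort(ref_config_continuous, "pre", 1500, 0.0)
        scaled = tab.copy()
        scaled["item_07"] = scaled["item_07"] * 10.0
        a = hs.fit(tab, n_starts=2)
        b = hs.fit(scaled, n_starts=2)
        np.testing.assert_allclose(a.loadings_std, b.loadings_std, atol=1e-6)
        np.testing.assert_allclose(a.gamma_std, b.gamma_std, atol=1e-6)
        np.testing.assert_allclose(a.beta_std, b.beta_std, atol=1e-6)

    def test_freeing_the_structural_path_cannot_worsen_fit(
        self, ref_config_continuous
    ):
        tab = hs.generate_cohort(ref_config_continuous, "pre", 1200, 0.0)
        no_path = HBMModelSpec(structural_paths=())
        with_path = hs.fit(tab, n_starts=2)
        without = hs.fit(tab, spec=no_path, n_starts=2)
        assert with_path.fml <= without.fml + 1e-10
        assert with_path.df == without.df - 1

    def test_non_pd_covariance_rejected(self):
        bad = np.ones((22, 22))
        with pytest.raises(cfa.NotPositiveDefiniteError):
            hs.fit(bad, n=100)

    def test_covariance_without_n_rejected(self):
        sigma = hs.population_item_covariance(hs.reference_config())
        with pytest.raises(ValueError, match="n is required"):
            hs.fit(sigma)


class TestStandardizeAndTotalEffects:
    def _reference_fit(self) -> cfa.CFAFit:
        """A CFAFit holding the reference solution in the standardized
        metric (raw == standardized because all variances are 1)."""
        cfg = hs.reference_config()
        lam = np.array(cfg.loadings)
        gamma = np.array(cfg.gamma)
        beta = np.array(cfg.beta)
        from hbmscore.simulate import disturbance_variances

        psi = disturbance_variances(cfg)
        theta = 1.0 - lam**2
        return cfa.CFAFit(
            spec=DEFAULT_SPEC,
            loadings=lam, gamma=gamma, beta=beta, psi=psi, theta=theta,
            loadings_std=lam, gamma_std=gamma, beta_std=beta,
            chi_square=0.0, df=203, n_used=0, fml=0.0,
            sample_cov=np.eye(22), fit_indices=None,
            total_effects=np.zeros(22), converged=True, n_iterations=0,
            final_gradient_norm=0.0, heywood=False,
        )

    def test_standardize_is_idempotent_on_standardized_solution(self):
        fit0 = self._reference_fit()
        out = cfa.standardize(fit0)
        np.testing.assert_allclose(out.loadings_std, fit0.loadings, atol=1e-10)
        np.testing.assert_allclose(out.gamma_std, fit0.gamma, atol=1e-10)
        np.testing.assert_allclose(out.beta_std, fit0.beta, atol=1e-10)
        again = cfa.standardize(out)
        np.testing.assert_allclose(again.loadings_std, out.loadings_std, atol=1e-12)

    def test_cta_total_effect_adds_the_mediated_route(self):
        """TE(HB -> CTA) = gamma_CTA + beta * gamma_BAR
        = 0.60 + 0.35 * (-0.18) = 0.537."""
        out = cfa.standardize(self._reference_fit())
        te_factor = np.linalg.solve(
            np.eye(5) - DEFAULT_SPEC.structural_matrix(out.beta_std), out.gamma_std
        )
        assert te_factor[4] == pytest.approx(0.537, abs=1e-12)
        # item-level weights on CTA
        lam = np.array(hs.reference_loadings())
        np.testing.assert_allclose(
            out.total_effects[18:], lam[18:] * 0.537, atol=1e-12
        )

    def test_zero_beta_reduces_to_pure_second_order_weights(self):
        fit0 = self._reference_fit()
        fit0 = dataclasses.replace(fit0, beta=np.array([0.0]))
        # psi no longer sums variances to 1 exactly for CTA, but the weight
        # identity W_i = lambda*_i gamma*_k is what is under test
        out = cfa.standardize(fit0)
        expected = out.loadings_std * out.gamma_std[DEFAULT_SPEC.item_factor_indices]
        np.testing.assert_allclose(cfa.total_effects(out), expected, atol=1e-12)

    def test_weight_signs_follow_loading_and_factor_effect(self):
        out = cfa.standardize(self._reference_fit())
        te_factor = np.linalg.solve(
            np.eye(5) - DEFAULT_SPEC.structural_matrix(out.beta_std), out.gamma_std
        )
        expected_sign = np.sign(
            out.loadings_std * te_factor[DEFAULT_SPEC.item_factor_indices]
        )
        np.testing.assert_array_equal(np.sign(out.total_effects), expected_sign)
        # barrier weights are negative
        assert (out.total_effects[14:18] < 0).all()


class TestSamplingCalibration:
    def test_estimator_bias_and_rmse_over_replicates(self):
        """100 continuous-mode replicates at n = 5,000: every standardized
        estimate has |bias| < 0.01 and RMSE < 0.02."""
        est_gamma, est_beta = [], []
        for rep in range(100):
            cfg = hs.reference_config(
                response_scale="continuous", seed=40_000 + rep
            )
            tab = hs.generate_cohort(
                cfg, "post", 5000, 0.0, np.random.default_rng(50_000 + rep)
            )
            result = hs.fit(tab, n_starts=1, compute_indices=False)
            est_gamma.append(result.gamma_std)
            est_beta.append(result.beta_std[0])
        est_gamma = np.array(est_gamma)
        est_beta = np.array(est_beta)
        bias = est_gamma.mean(axis=0) - np.array(hs.REFERENCE_GAMMA)
        rmse = np.sqrt(((est_gamma - np.array(hs.REFERENCE_GAMMA)) ** 2).mean(axis=0))
        assert np.all(np.abs(bias) < 0.01)
        assert np.all(rmse < 0.02)
        assert abs(est_beta.mean() - hs.REFERENCE_BETA) < 0.01
        assert np.sqrt(((est_beta - hs.REFERENCE_BETA) ** 2).mean()) < 0.02

    def test_chi_square_mean_matches_df_under_true_model(self):
        """Under a correctly specified model the ML chi-square has mean df;
        200 replicates at n = 5,000 pin the mean within 3 standard errors."""
        chis = []
        for rep in range(200):
            cfg = hs.reference_config(
                response_scale="continuous", seed=60_000 + rep
            )
            tab = hs.generate_cohort(
                cfg, "post", 5000, 0.0, np.random.default_rng(70_000 + rep)
            )
            result = hs.fit(tab, n_starts=1, compute_indices=False)
            chis.append(result.chi_square)
        df = 203
        tol = 3.0 * np.sqrt(2.0 * df / 200.0)
        assert abs(np.mean(chis) - df) < tol

    def test_ordinal_loadings_attenuated_relative_to_continuous(self):
        """Treating 1-5 scores as continuous attenuates standardized
        loadings relative to the underlying continuous responses; it never
        inflates them beyond sampling error."""
        n = 20_000
        cont = hs.generate_cohort(
            hs.reference_config(response_scale="continuous", seed=81), "post", n, 0.0
        )
        ordi = hs.generate_cohort(
            hs.reference_config(response_scale="ordinal", seed=81), "post", n, 0.0
        )
        fc = hs.fit(cont, n_starts=1, compute_indices=False)
        fo = hs.fit(ordi, n_starts=1, compute_indices=False)
        tol = 3.0 / np.sqrt(n)
        assert np.all(np.abs(fo.loadings_std) <= np.abs(fc.loadings_std) + tol)
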