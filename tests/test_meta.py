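import numpy as np
import pandas as pd
import pytest
from scipy import stats

from steeprank.meta import (
    DesignError,
    DesignSpec,
    build_design,
    fit,
    fit_at_sigma2,
    lrt,
    omnibus_qm,
    phylo_signal,
    profile_loglik,
    qe_test,
    records_to_frame,
    small_study_test,
    time_lag_test,
)
from steeprank.phylo import PhyloCorrelation
from steeprank.synthetic_data import simulate_effect_records

FULL = DesignSpec.full()
CONTROL = DesignSpec.control()
STEEP_ONLY = DesignSpec(predictors=("steepness",))
INTERCEPT = DesignSpec.intercept_only()


@pytest.fixture(scope="module")
def records():
    df, A, truth = simulate_effect_records(
        n_species=20, groups_per_species=2, records_per_group=2,
        seed=99, with_moderators=True, beta_steep=0.3,
    )
    return df, A, truth


def tiny_frame(y, v, species=None, groups=None, steep=None):
    k = len(y)
    return pd.DataFrame(
        {
            "z_r": y,
            "v": v,
            "species": species or [f"s{i}" for i in range(k)],
            "group": groups or [f"g{i}" for i in range(k)],
            "steepness": steep if steep is not None else np.linspace(0, 1, k),
            "n": 10,
        }
    )


def identity_corr(ids):
    return PhyloCorrelation(ids=tuple(ids), matrix=np.eye(len(ids)))


class TestBuildDesign:
    def test_full_model_has_13_columns(self, records):
        df, A, _ = records
        assert build_design(df, FULL).p == 13

    def test_control_model_has_12_columns(self, records):
        df, A, _ = records
        assert build_design(df, CONTROL).p == 12

    def test_centered_dummies_sum_to_zero(self, records):
        df, _, _ = records
        d = build_design(df, FULL)
        for j, name in enumerate(d.columns):
            if "[" in name:
                assert abs(d.x[:, j].sum()) < 1e-9

    def test_standardized_continuous(self, records):
        df, _, _ = records
        d = build_design(df, FULL)
        j = list(d.columns).index("steepness")
        assert d.x[:, j].mean() == pytest.approx(0.0, abs=1e-12)
        assert d.x[:, j].std(ddof=1) == pytest.approx(1.0)

    def test_rank_deficiency_lists_aliased(self, records):
        df, _, _ = records
        df2 = df.copy()
        df2["setting"] = "wild"  # single level -> all-zero centered dummies
        with pytest.raises(DesignError, match="setting"):
            build_design(df2, FULL)

    def test_interaction_columns(self, records):
        df, _, _ = records
        spec = DesignSpec(predictors=("steepness",) + CONTROL.predictors,
                          interaction="setting")
        d = build_design(df, spec)
        prods = [c for c in d.columns if c.startswith("steepness:")]
        assert len(prods) == 2

    def test_unknown_level_rejected(self, records):
        df, _, _ = records
        df2 = df.copy()
        df2.loc[df2.index[0], "setting"] = "urban"
        with pytest.raises(DesignError, match="urban"):
            build_design(df2, FULL)


class TestFitBasics:
    def test_pooled_inverse_variance_mean(self):
        df = tiny_frame([0.0, 1.0], [1.0, 1.0])
        f = fit_at_sigma2(df, INTERCEPT, identity_corr(df["species"]), (0, 0, 0))
        assert f.beta[0] == pytest.approx(0.5)

    def test_weighted_pooling(self):
        df = tiny_frame([0.0, 1.0], [1.0, 3.0])
        f = fit_at_sigma2(df, INTERCEPT, identity_corr(df["species"]), (0, 0, 0))
        assert f.beta[0] == pytest.approx((0 / 1 + 1 / 3) / (1 + 1 / 3))

    def test_gls_equals_ols_when_no_heterogeneity(self, rng):
        k = 12
        df = tiny_frame(rng.normal(size=k), np.ones(k), steep=rng.normal(size=k))
        f = fit_at_sigma2(df, STEEP_ONLY, identity_corr(df["species"]), (0, 0, 0))
        d = build_design(df, STEEP_ONLY)
        beta_ols = np.linalg.lstsq(d.x, d.y, rcond=None)[0]
        np.testing.assert_allclose(f.beta, beta_ols, atol=1e-10)

    def test_reml_and_ml_betas_agree_at_fixed_sigma2(self, records):
        df, A, _ = records
        s2 = (0.05, 0.02, 0.01)
        f_ml = fit_at_sigma2(df, FULL, A, s2, method="ML")
        f_reml = fit_at_sigma2(df, FULL, A, s2, method="REML")
        np.testing.assert_allclose(f_ml.beta, f_reml.beta, atol=1e-10)

    def test_k_less_than_p_rejected(self):
        df = tiny_frame([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="k ="):
            fit(df, STEEP_ONLY, identity_corr(df["species"]))

    def test_permutation_invariance(self, records):
        df, A, _ = records
        f1 = fit(df, STEEP_ONLY, A, n_starts=2)
        perm = np.random.default_rng(0).permutation(len(df))
        f2 = fit(df.iloc[perm].reset_index(drop=True), STEEP_ONLY, A, n_starts=2)
        np.testing.assert_allclose(np.sort(f1.beta), np.sort(f2.beta), atol=1e-5)
        np.testing.assert_allclose(f1.sigma2, f2.sigma2, atol=1e-4)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)

    def test_deterministic(self, records):
        df, A, _ = records
        f1 = fit(df, STEEP_ONLY, A, n_starts=2)
        f2 = fit(df, STEEP_ONLY, A, n_starts=2)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.beta, f2.beta)


class TestLikelihoodOracle:
    def _dense_oracle_ll(self, df, spec, A, sigma2):
        """Independent dense multivariate-normal evaluation."""
        d = build_design(df, spec)
        sp = pd.Categorical(d.species)
        gr = pd.Categorical([f"{s}//{g}" for s, g in zip(d.species, d.groups)])
        zs = np.eye(len(sp.categories))[sp.codes]
        zg = np.eye(len(gr.categories))[gr.codes]
        asub = A.reorder(list(sp.categories)).matrix
        V = (
            sigma2[0] * zs @ zs.T
            + sigma2[1] * zg @ zg.T
            + sigma2[2] * zs @ asub @ zs.T
            + np.diag(d.v)
        )
        vinv = np.linalg.inv(V)
        beta = np.linalg.solve(d.x.T @ vinv @ d.x, d.x.T @ vinv @ d.y)
        return stats.multivariate_normal(mean=d.x @ beta, cov=V).logpdf(d.y)

    @pytest.mark.parametrize("seed", range(5))
    def test_profile_matches_dense_mvn(self, seed):
        df, A, _ = simulate_effect_records(
            n_species=5, groups_per_species=2, records_per_group=2,
            seed=seed, beta_steep=0.2,
        )
        gen = np.random.default_rng(seed)
        sigma2 = gen.uniform(0.01, 0.3, size=3)
        ours = profile_loglik(df, STEEP_ONLY, A, sigma2, method="ML")
        oracle = self._dense_oracle_ll(df, STEEP_ONLY, A, sigma2)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_optimum_dominates_grid(self):
        df, A, _ = simulate_effect_records(
            n_species=10, groups_per_species=2, records_per_group=1,
            seed=3, beta_steep=0.0,
        )
        best = fit(df, STEEP_ONLY, A, method="ML").loglik
        grid = np.concatenate([[1e-9], np.geomspace(1e-4, 1.0, 9)])
        worst_violation = -np.inf
        for a in grid:
            for b in grid:
                for c in grid:
                    ll = profile_loglik(df, STEEP_ONLY, A, (a, b, c))
                    worst_violation = max(worst_violation, ll - best)
        assert worst_violation < 1e-4


class TestLRT:
    def test_identical_models_chi2_zero(self, records):
        df, A, _ = records
        f = fit(df, STEEP_ONLY, A, n_starts=2)
        res = lrt(f, f, df=0)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_requires_ml(self, records):
        df, A, _ = records
        f = fit_at_sigma2(df, STEEP_ONLY, A, (0.1, 0.1, 0.1), method="REML")
        c = fit_at_sigma2(df, INTERCEPT, A, (0.1, 0.1, 0.1), method="REML")
        with pytest.raises(ValueError, match="ML"):
            lrt(f, c)

    def test_non_nested_rejected(self, records):
        df, A, _ = records
        f1 = fit(df, DesignSpec(predictors=("duration_months",)), A, n_starts=1)
        f2 = fit(df, STEEP_ONLY, A, n_starts=1)
        with pytest.raises(ValueError, match="nested"):
            lrt(f1, f2)

    def test_signal_detected_with_effect(self, records):
        df, A, _ = records  # generated with beta_steep = 0.3
        f = fit(df, STEEP_ONLY, A, n_starts=2)
        c = fit(df, INTERCEPT, A, n_starts=2)
        res = lrt(f, c)
        assert res.df == 1
        assert res.p < 0.05

    def test_invariant_to_response_shift(self, records):
        df, A, _ = records
        f = fit(df, STEEP_ONLY, A, n_starts=2)
        c = fit(df, INTERCEPT, A, n_starts=2)
        df2 = df.copy()
        df2["z_r"] = df2["z_r"] + 5.0
        f2 = fit(df2, STEEP_ONLY, A, n_starts=2)
        c2 = fit(df2, INTERCEPT, A, n_starts=2)
        assert lrt(f, c).chi2 == pytest.approx(lrt(f2, c2).chi2, abs=1e-4)


class TestQM:
    def test_single_coefficient_wald_identity(self, records):
        df, A, _ = records
        f = fit(df, STEEP_ONLY, A, n_starts=2)
        j = list(f.columns).index("steepness")
        assert f.qm == pytest.approx((f.beta[j] / f.se[j]) ** 2, rel=1e-10)
        assert f.qm_df == 1

    def test_intercept_only_rejected(self, records):
        df, A, _ = records
        f = fit(df, INTERCEPT, A, n_starts=1)
        with pytest.raises(ValueError, match="intercept-only"):
            omnibus_qm(f)

    def test_null_p_values_uniform(self):
        # moderator unrelated to the response: Q_M p ~ U(0,1)
        pvals = []
        for s in range(200):
            df, A, _ = simulate_effect_records(
                n_species=10, groups_per_species=2, records_per_group=1,
                sigma2=(0.05, 0.02, 0.0), seed=20000 + s, beta_steep=0.0,
            )
            f = fit(df, STEEP_ONLY, A, n_starts=1)
            pvals.append(f.qm_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestQE:
    def test_exact_fit_zero(self):
        x = np.linspace(0, 1, 8)
        df = tiny_frame(2.0 + 3.0 * x, np.ones(8), steep=x)
        qe, dof, p = qe_test(df, STEEP_ONLY)
        assert qe == pytest.approx(0.0, abs=1e-18)
        assert dof == 6

    def test_homogeneous_mean_matches_df(self):
        gen = np.random.default_rng(5)
        qes = []
        for _ in range(300):
            k = 20
            v = gen.uniform(0.02, 0.2, size=k)
            y = 0.3 + gen.normal(scale=np.sqrt(v))
            qes.append(qe_test(tiny_frame(y, v), INTERCEPT)[0])
        assert np.mean(qes) == pytest.approx(19, rel=0.1)

    def test_heterogeneity_inflates_qe(self):
        gen = np.random.default_rng(6)
        k = 20
        v = np.full(k, 0.05)
        y0 = gen.normal(scale=np.sqrt(v))
        y1 = y0 + gen.normal(scale=0.5, size=k)
        assert (
            qe_test(tiny_frame(y1, v), INTERCEPT)[0]
            > qe_test(tiny_frame(y0, v), INTERCEPT)[0]
        )


class TestPhyloSignal:
    def test_null_phylo_small_lambda(self):
        lams, ps = [], []
        for s in range(10):
            df, A, _ = simulate_effect_records(
                n_species=20, groups_per_species=2, records_per_group=1,
                sigma2=(0.05, 0.02, 0.0), seed=300 + s,
            )
            sig = phylo_signal(df, STEEP_ONLY, A, n_starts=2)
            lams.append(sig.lambda_hat)
            ps.append(sig.p)
        assert np.median(lams) < 0.25
        assert np.median(ps) > 0.1

    def test_dominant_phylo_large_lambda(self):
        lams = []
        for s in range(10):
            df, A, _ = simulate_effect_records(
                n_species=20, groups_per_species=2, records_per_group=1,
                sigma2=(0.03, 0.03, 0.3), seed=400 + s,
            )
            lams.append(phylo_signal(df, STEEP_ONLY, A, n_starts=2).lambda_hat)
        assert np.mean(np.array(lams) > 0.5) > 0.5

    def test_all_zero_variances_lambda_zero(self):
        df = tiny_frame([0.1, 0.2, 0.15, 0.12], np.full(4, 0.04))
        f = fit_at_sigma2(df, INTERCEPT, identity_corr(df["species"]), (0, 0, 0))
        total = f.sigma2.sum()
        lam = f.sigma2[2] / total if total > 0 else 0.0
        assert lam == 0.0

    def test_boundary_mixture_halves_p(self, records):
        df, A, _ = records
        plain = phylo_signal(df, STEEP_ONLY, A, n_starts=1)
        mix = phylo_signal(df, STEEP_ONLY, A, boundary_mixture=True, n_starts=1)
        if plain.chi2 > 0:
            assert mix.p == pytest.approx(plain.p / 2)
        else:
            assert mix.p == 1.0


class TestBiasTests:
    def _published_frame(self, gen, k=60, shrink=0.0):
        n = gen.integers(10, 100, size=k)
        v = 1.0 / (n - 3)
        z = shrink * np.sqrt(1.0 / n) * 10 + gen.normal(scale=np.sqrt(v))
        df = tiny_frame(z, v)
        df["n"] = n
        df["pub_year"] = gen.integers(1980, 2022, size=k).astype(float)
        df["origin"] = "published"
        return df

    def test_small_study_directional(self):
        gen = np.random.default_rng(8)
        df = self._published_frame(gen, shrink=1.0)
        z, p = small_study_test(df, identity_corr(df["species"]))
        assert z > 1.96 and p < 0.05

    def test_no_effect_usually_nonsignificant(self):
        gen = np.random.default_rng(9)
        df = self._published_frame(gen, shrink=0.0)
        z, p = small_study_test(df, identity_corr(df["species"]))
        assert abs(z) < 3

    def test_time_lag_constant_year_rejected(self):
        gen = np.random.default_rng(10)
        df = self._published_frame(gen)
        df["pub_year"] = 2000.0
        with pytest.raises(DesignError, match="zero-variance"):
            time_lag_test(df, identity_corr(df["species"]))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            small_study_test(pd.DataFrame(), None)


def test_records_to_frame_round_trip():
    from steeprank.effect_sizes import EffectSizeRecord

    rec = EffectSizeRecord(
        z_r=0.2, v=0.05, r=0.19, n=23, rank_basis="cardinal", method="NDS_Dij",
        group="g1", species="sp1", benefit_category="direct",
        duration_months=12.0, setting="wild", sex="female",
        dispersal="none", social_org="MMG", origin="published",
        steepness=0.5, pub_year=2001.0,
    )
    df = records_to_frame([rec])
    assert df.loc[0, "z_r"] == 0.2
    assert df.loc[0, "species"] == "sp1"
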