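import math

import numpy as np
import pandas as pd
import pytest

from nhnet import glmm
from nhnet import synthetic_data as synth
from nhnet.glmm import (
    DesignBundle,
    DesignError,
    MCMCSettings,
    ModelSpec,
    SettingsError,
    compute_icc,
    format_pmcmc,
    hpdi,
    pmcmc,
)


class TestSettings:
    def test_default_schedule_bookkeeping(self):
        s = MCMCSettings()
        assert (s.n_iter, s.burn_in, s.thin) == (115_000, 15_000, 10)
        assert s.n_kept == 10_000

    def test_reduced_schedule(self):
        assert MCMCSettings(n_iter=11_500, burn_in=1_500, thin=10).n_kept == 1_000

    def test_inconsistent_schedule_rejected(self):
        with pytest.raises(SettingsError):
            MCMCSettings(n_iter=1001, burn_in=500, thin=10)
        with pytest.raises(SettingsError):
            MCMCSettings(n_iter=100, burn_in=500)

    def test_unknown_prior_rejected(self):
        with pytest.raises(SettingsError):
            MCMCSettings(variance_prior="flat")


class TestBuildDesign:
    def test_one_facility_all_dates_share_index(self, small_synth):
        frame = small_synth.model_frame()
        one = frame[frame.provider_id == frame.provider_id.iloc[0]]
        spec = ModelSpec(
            variant="model1",
            continuous=("staffing_cna_hrd",),
            booleans=(),
            include_ownership_type=False,
            include_affiliation=False,
            include_interaction=False,
            include_quality=False,
            hrr_level=(),
        )
        bundle = glmm.build_design(one, spec)
        assert bundle.n == len(one) > 1
        assert len(set(bundle.factor_codes["facility"])) == 1
        assert len(set(bundle.factor_codes["obs"])) == len(one)

    def test_centering_makes_columns_mean_zero(self, small_synth):
        bundle = glmm.build_design(small_synth.model_frame(), synth.RECOVERY_SPEC)
        for j, name in enumerate(bundle.colnames):
            if name in bundle.centering_means:
                assert abs(bundle.X[:, j].mean()) < 1e-10

    def test_model2_has_mds_columns_not_five_star(self, small_synth):
        panel = small_synth.assemble(required_mds_codes=synth.MDS_CODES)
        from nhnet import hrr_aggregation as agg

        networks = agg.derive_hrr_networks(panel, seed=1)
        metrics = agg.compute_hrr_metrics(networks)
        frame = glmm.assemble_model_frame(panel, networks, metrics)
        bundle = glmm.build_design(frame, ModelSpec(variant="model2"))
        mds_cols = [c for c in bundle.colnames if c.startswith("mds_")]
        assert len(mds_cols) == 21
        assert not any(c.startswith("five_star") for c in bundle.colnames)

    def test_rank_deficiency_names_aliased_column(self, small_synth):
        frame = small_synth.model_frame()
        frame["affiliation"] = "single"  # collinear with the intercept
        with pytest.raises(DesignError, match="affiliation_single"):
            glmm.build_design(frame, synth.RECOVERY_SPEC)


class TestHpdi:
    def test_uniform_ladder(self):
        lo, hi = hpdi(np.arange(1, 101, dtype=float), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_point_mass(self):
        assert hpdi(np.full(150, 3.0)) == (3.0, 3.0)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(123)
        lo, hi = hpdi(rng.standard_normal(100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(50))

    def test_exp_preserves_interval_ordering(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            draws = rng.normal(rng.normal(), rng.uniform(0.1, 2), 500)
            lo, hi = hpdi(draws)
            assert lo < hi
            assert math.exp(lo) < math.exp(hi)


class TestPmcmc:
    def test_half_and_half_is_one(self):
        assert pmcmc(np.concatenate([np.ones(500), -np.ones(500)])) == 1.0

    def test_tail_fraction(self):
        s = np.concatenate([np.ones(9750), -np.ones(250)])
        assert pmcmc(s) == pytest.approx(0.05)

    def test_floor_and_label(self):
        s = np.ones(10_000)
        p = pmcmc(s)
        assert p == pytest.approx(1 / 10_000)
        assert format_pmcmc(p, 10_000).startswith("<")
        assert format_pmcmc(0.23, 10_000) == "0.230"


class TestIcc:
    def test_equal_components(self):
        draws = {k: np.ones(200) for k in ("state", "hrr", "facility", "obs")}
        icc = compute_icc(draws)
        assert np.allclose(icc["icc"], 0.25)

    def test_single_nonzero_component(self):
        draws = {
            "state": np.full(200, 2.0),
            "hrr": np.zeros(200),
        }
        icc = compute_icc(draws).set_index("component")
        assert icc.loc["state", "icc"] == pytest.approx(1.0)
        assert icc.loc["hrr", "icc"] == pytest.approx(0.0)

    def test_iccs_sum_to_one(self):
        rng = np.random.default_rng(0)
        draws = {k: rng.uniform(0.01, 1, 300) for k in ("a", "b", "c")}
        icc = compute_icc(draws)
        assert icc["icc"].sum() == pytest.approx(1.0)


def _intercept_bundle(y, factors=False):
    n = len(y)
    codes = {"obs": np.arange(n)} if factors else {}
    levels = {"obs": list(range(n))} if factors else {}
    return DesignBundle(
        y=np.asarray(y),
        X=np.ones((n, 1)),
        colnames=["intercept"],
        factor_codes=codes,
        factor_levels=levels,
        centering_means={},
    )


SHORT = dict(n_iter=4000, burn_in=1000, thin=5)


class TestSampler:
    def test_constant_data_recovers_log_mean(self):
        y = np.full(300, 54)
        out = glmm.fit_poisson_glmm(
            _intercept_bundle(y), MCMCSettings(seed=3, **SHORT)
        )
        assert out.beta[:, 0].mean() == pytest.approx(math.log(54), abs=0.05)

    def test_constant_data_with_observation_term(self):
        y = np.full(300, 54)
        out = glmm.fit_poisson_glmm(
            _intercept_bundle(y, factors=True), MCMCSettings(seed=3, **SHORT)
        )
        assert out.beta[:, 0].mean() == pytest.approx(math.log(54), abs=0.08)

    def test_seeded_determinism(self):
        y = np.random.default_rng(1).poisson(20, 200)
        s = MCMCSettings(seed=11, **SHORT)
        a = glmm.fit_poisson_glmm(_intercept_bundle(y, factors=True), s)
        b = glmm.fit_poisson_glmm(_intercept_bundle(y, factors=True), s)
        assert np.array_equal(a.beta, b.beta)
        assert all(np.array_equal(a.sigma2[k], b.sigma2[k]) for k in a.sigma2)

    def test_doubling_covariate_halves_coefficient(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 1500)
        y = rng.poisson(np.exp(2.0 + 0.3 * x))

        def bundle(scale):
            return DesignBundle(
                y=y,
                X=np.column_stack([np.ones(len(y)), scale * x]),
                colnames=["intercept", "x"],
                factor_codes={},
                factor_levels={},
                centering_means={},
            )

        s = MCMCSettings(seed=5, **SHORT)
        b1 = glmm.fit_poisson_glmm(bundle(1.0), s).beta[:, 1].mean()
        b2 = glmm.fit_poisson_glmm(bundle(2.0), s).beta[:, 1].mean()
        assert b1 == pytest.approx(2 * b2, rel=1e-6)

    def test_prior_variance_insensitivity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 800)
        y = rng.poisson(np.exp(1.5 - 0.2 * x))
        bundle = DesignBundle(
            y=y,
            X=np.column_stack([np.ones(len(y)), x]),
            colnames=["intercept", "x"],
            factor_codes={},
            factor_levels={},
            centering_means={},
        )
        a = glmm.fit_poisson_glmm(bundle, MCMCSettings(seed=8, beta_prior_var=1e8, **SHORT))
        b = glmm.fit_poisson_glmm(bundle, MCMCSettings(seed=8, beta_prior_var=2e8, **SHORT))
        mc_se = a.beta[:, 1].std() / math.sqrt(len(a.beta))
        assert abs(a.beta[:, 1].mean() - b.beta[:, 1].mean()) < mc_se

    def test_invgamma_prior_option_runs(self):
        y = np.random.default_rng(4).poisson(10, 200)
        out = glmm.fit_poisson_glmm(
            _intercept_bundle(y, factors=True),
            MCMCSettings(seed=4, variance_prior="invgamma", **SHORT),
        )
        assert out.beta[:, 0].mean() == pytest.approx(math.log(10), abs=0.15)

    def test_overdispersion_variance_recovered(self):
        """Planted state/HRR variance ratio is recovered within 50%."""
        cfg = synth.GeneratorConfig(
            n_facilities=1200,
            n_hrrs=48,
            n_states=24,
            n_dates=3,
            sigma2_state=0.168,
            sigma2_hrr=0.07,
        )
        data = synth.generate(cfg, 21)
        bundle = glmm.build_design(data.model_frame(), synth.RECOVERY_SPEC)
        out = glmm.fit_poisson_glmm(
            bundle, MCMCSettings(n_iter=6500, burn_in=1500, thin=5, seed=22)
        )
        ratio = out.sigma2["state"].mean() / out.sigma2["hrr"].mean()
        true_ratio = 0.168 / 0.07
        assert abs(ratio - true_ratio) / true_ratio < 0.5


class TestSummaries:
    def test_zero_coefficient_gives_unit_pr(self):
        samples = glmm.PosteriorSamples(
            beta=np.zeros((200, 1)),
            colnames=["x"],
            sigma2={"obs": np.full(200, 0.1)},
            u_draws={},
            u_mean={"obs": np.zeros(5)},
            factor_levels={"obs": list(range(5))},
            settings=MCMCSettings(seed=1, **SHORT),
        )
        summary = glmm.summarize(samples)
        row = summary.fixed.iloc[0]
        assert row.pr == 1.0 and row.l95_hpdi == 1.0 and row.u95_hpdi == 1.0

    def test_pr_is_exponentiated_mean(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(-0.23, 0.01, 500)
        samples = glmm.PosteriorSamples(
            beta=draws[:, None],
            colnames=["rn"],
            sigma2={"obs": np.full(500, 0.1)},
            u_draws={},
            u_mean={},
            factor_levels={},
            settings=MCMCSettings(seed=1, **SHORT),
        )
        summary = glmm.summarize(samples)
        assert summary.fixed.iloc[0].pr == pytest.approx(math.exp(draws.mean()))
        assert summary.fixed.iloc[0].pr == pytest.approx(0.795, abs=0.01)

    def test_random_effect_prs_exported(self, small_synth):
        bundle = glmm.build_design(small_synth.model_frame(), synth.RECOVERY_SPEC)
        out = glmm.fit_poisson_glmm(
            bundle, MCMCSettings(n_iter=1500, burn_in=500, thin=10, seed=2)
        )
        summary = glmm.summarize(out)
        assert set(summary.random_pr) == {"state", "hrr", "facility"}
        state_tbl = summary.random_pr["state"]
        assert len(state_tbl) == len(bundle.factor_levels["state"])
        assert (state_tbl.pr > 0).all()
        assert {"state", "hrr", "facility", "obs"} == set(
            summary.icc.component
        )
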