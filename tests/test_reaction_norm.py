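"""Two-step reaction-norm pipeline: gradient, sire model, EBV diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rngxe.mmecore import GibbsConfig, PosteriorSamples
from rngxe.mmecore import _TermInfo
from rngxe.reaction_norm import (
    EnvironmentGradient,
    ReactionNormFit,
    compare_rankings,
    ebv_accuracy,
    ebv_at_environment,
    fit_reaction_norm,
    fit_step1,
    sire_h2,
    variance_ratios,
)
from rngxe.synthdata import SimulationConfig, simulate_dataset


def mock_fit(g0_draws, htd=1.865, pe=5.632, resid=6.650, sire_locs=None,
             with_gxe=True, n_keep=None):
    """Assemble a ReactionNormFit from hand-picked chains."""
    g0_draws = np.asarray(g0_draws, dtype=float)
    if g0_draws.ndim == 2:
        g0_draws = np.repeat(g0_draws[None], 8, axis=0)
    k = len(g0_draws) if n_keep is None else n_keep
    if sire_locs is None:
        sire_locs = np.zeros((k, 4))
    sire_locs = np.asarray(sire_locs, dtype=float)
    n_sires = sire_locs.shape[1] // 2
    terms = [_TermInfo("sire", "rr", 0, n_sires, 2,
                       levels=np.arange(1, n_sires + 1))]
    vc = {"htd": np.full(k, htd), "pe": np.full(k, pe)}
    for c in range(5):
        vc[f"residual_class_{c}"] = np.full(k, resid)
    samples = PosteriorSamples(
        variance_chains=vc,
        g0_chains={"sire": g0_draws},
        location_chain=sire_locs,
        terms=terms,
        level_labels={"sire": np.arange(1, n_sires + 1)},
        n_retained=k,
    )
    grad = EnvironmentGradient(
        pd.DataFrame({"heg_level": ["a", "b"], "solution": [0.0, 1.0],
                      "scaled_x": [-1.0, 1.0], "n_records": [1, 1]}),
        {}, {}, {})
    return ReactionNormFit(samples, with_gxe, "MT", grad,
                           np.arange(1, n_sires + 1))


TABLE2_MILK = np.array([[0.756, -0.23], [-0.23, 2.697]])


class TestVarianceRatios:
    def test_published_milk_components_reproduce_ratios(self):
        # htd 1.865 + pe 5.632 + G 0.756 + GxE 2.697 + 2(-0.23) + e 6.650
        fit = mock_fit(TABLE2_MILK)
        out = variance_ratios(fit)
        assert out["sigma2_P"]["mean"] == pytest.approx(17.14, abs=0.01)
        assert out["GxE_over_P"]["mean"] == pytest.approx(0.157, abs=0.001)
        assert out["G_over_P"]["mean"] == pytest.approx(0.756 / 17.14, abs=1e-4)

    def test_zero_components_give_zero_ratios(self):
        fit = mock_fit(np.zeros((2, 2)), htd=0.0, pe=0.0, resid=1.0)
        out = variance_ratios(fit)
        assert out["G_over_P"]["mean"] == 0.0
        assert out["GxE_over_P"]["mean"] == 0.0

    def test_zero_covariance_makes_p_a_simple_sum(self):
        fit = mock_fit(np.array([[0.5, 0.0], [0.0, 0.3]]), htd=1.0, pe=2.0,
                       resid=3.0)
        out = variance_ratios(fit)
        assert out["sigma2_P"]["mean"] == pytest.approx(1 + 2 + 0.5 + 0.3 + 3)

    def test_requires_gxe_fit(self):
        fit = mock_fit(TABLE2_MILK)
        fit.with_gxe = False
        with pytest.raises(ValueError):
            variance_ratios(fit)


class TestSireH2:
    def test_published_milk_row(self):
        out = sire_h2(mock_fit(TABLE2_MILK))
        assert out["mean"] == pytest.approx(4 * 0.756 / 17.14, abs=1e-3)

    def test_boundary_cases(self):
        # sigma2_G = sigma2_P / 4 gives h2 = 1
        fit = mock_fit(np.array([[1.0, 0.0], [0.0, 0.0]]), htd=0.0, pe=0.0,
                       resid=3.0)
        assert sire_h2(fit)["mean"] == pytest.approx(1.0)
        fit0 = mock_fit(np.array([[0.0, 0.0], [0.0, 0.0]]), htd=1.0, pe=0.0,
                        resid=1.0)
        assert sire_h2(fit0)["mean"] == 0.0


class TestEbv:
    def _fit_two_sires(self):
        k = 8
        # sires: (intercept 1, slope 0.5), (0.5, 1.0); layout [i1 i2 s1 s2]
        locs = np.tile([1.0, 0.5, 0.5, 1.0], (k, 1))
        return mock_fit(np.eye(2) * 0.2, sire_locs=locs)

    def test_midpoint_returns_intercept(self):
        fit = self._fit_two_sires()
        assert ebv_at_environment(fit, 1, 0.0) == pytest.approx(1.0)

    def test_linear_in_environment(self):
        fit = self._fit_two_sires()
        assert ebv_at_environment(fit, 1, 1.0) == pytest.approx(1.5)
        assert ebv_at_environment(fit, 1, -1.0) == pytest.approx(0.5)

    def test_reranking_between_extremes(self):
        k = 8
        locs = np.tile([1.0, 0.5, -1.0, 1.0], (k, 1))  # (1,-1) and (0.5,1)
        fit = mock_fit(np.eye(2) * 0.2, sire_locs=locs)
        lo = [ebv_at_environment(fit, s, -1.0) for s in (1, 2)]
        hi = [ebv_at_environment(fit, s, 1.0) for s in (1, 2)]
        assert np.argmax(lo) != np.argmax(hi)

    def test_unknown_sire_rejected(self):
        with pytest.raises(KeyError):
            ebv_at_environment(self._fit_two_sires(), 99, 0.0)

    def test_accuracy_limits(self):
        k = 4
        # intercept chain with ddof=1 SD exactly s: values m +/- s/sqrt(...)
        s2_g = 0.16
        for pev_frac, expected in [(0.0, 1.0), (1.0, 0.0), (0.75, 0.5)]:
            sd = np.sqrt(pev_frac * s2_g)
            base = np.array([-1.0, 1.0, -1.0, 1.0]) * sd * np.sqrt(3 / 4)
            locs = np.column_stack([base, np.zeros(k), np.zeros(k), np.zeros(k)])
            fit = mock_fit(np.eye(2) * s2_g, sire_locs=locs, n_keep=k)
            out = ebv_accuracy(fit, 1)
            assert out["accuracy"] == pytest.approx(expected, abs=1e-9)

    def test_literal_squared_ebv_variant_available(self):
        fit = self._fit_two_sires()
        out = ebv_accuracy(fit, 1, pev_mode="ebv_squared")
        assert out["pev"] == pytest.approx(1.0)  # EBV^2 with intercept 1


class TestCompareRankings:
    def test_identical_vectors(self):
        e = pd.Series([3.0, 2.0, 1.0], index=[1, 2, 3])
        assert compare_rankings(e, e)["spearman_r"] == pytest.approx(1.0)

    def test_reversed_vectors(self):
        a = pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3])
        b = pd.Series([3.0, 2.0, 1.0], index=[1, 2, 3])
        assert compare_rankings(a, b)["spearman_r"] == pytest.approx(-1.0)

    def test_single_swap_toy(self):
        # 1 - 6*2/(5*24) = 0.9
        a = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        b = pd.Series([2, 1, 3, 4, 5.0], index=list("abcde"))
        assert compare_rankings(a, b)["spearman_r"] == pytest.approx(0.9)

    def test_topk_turnover_reported(self):
        a = pd.Series(np.arange(10.0), index=range(10))
        b = a.copy()
        b[0] = 99.0  # enters the top 3
        out = compare_rankings(a, b, top_k=3)
        assert 0 in out["entered_top_k"]

    def test_disjoint_sets_rejected(self):
        a = pd.Series([1.0], index=[1])
        b = pd.Series([1.0], index=[2])
        with pytest.raises(ValueError):
            compare_rankings(a, b)


class TestTwoStepOnSimulatedData:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SimulationConfig(seed=21)  # 60 herds, ~8,000 records
        pop, pheno = simulate_dataset(cfg)
        grad = fit_step1(pheno, pop.pedigree, "MT",
                         GibbsConfig(6000, 1000, 5, seed=1))
        return cfg, pop, pheno, grad

    def test_gradient_recovers_true_herd_ordering(self, fitted):
        cfg, pop, pheno, grad = fitted
        h = pop.herd_env.copy()
        h["heg_level"] = h["herd_id"].astype(str) + ":" + h["eg_label"]
        m = grad.table.merge(h[["heg_level", "env_effect"]], on="heg_level")
        rho = spearmanr(m["solution"], m["env_effect"]).statistic
        assert rho >= 0.9

    def test_gradient_spans_unit_interval(self, fitted):
        _, _, _, grad = fitted
        assert grad.table["scaled_x"].min() == pytest.approx(-1.0)
        assert grad.table["scaled_x"].max() == pytest.approx(1.0)
        assert np.isfinite(grad.diagnostics["p_normal"])

    def test_step1_h2_formula(self, fitted):
        _, _, _, grad = fitted
        vc = {k: v["mean"] for k, v in grad.components.items()}
        expected = vc["animal"] / (vc["htd"] + vc["pe"] + vc["animal"]
                                   + vc["residual"])
        assert grad.h2["mean"] == pytest.approx(expected, rel=0.05)

    def test_single_record_kind_uses_hyc_and_no_pe(self):
        cfg = SimulationConfig(n_herds=20, n_sires=20, daughters_per_sire=5,
                               records_per_cow=1, sigma2_pe=0.0, seed=31)
        pop, pheno = simulate_dataset(cfg)
        grad = fit_step1(pheno, pop.pedigree, "FS",
                         GibbsConfig(1500, 300, 4, seed=1))
        assert "hyc" in grad.components and "pe" not in grad.components
        fit = fit_reaction_norm(pheno, grad, pop.pedigree, True,
                                dataset_kind="FS",
                                config=GibbsConfig(1500, 300, 4, seed=2))
        assert "hyc" in fit.samples.variance_chains
        assert "pe" not in fit.samples.variance_chains
        assert fit.g0_chain.shape[1:] == (2, 2)

    def test_without_gxe_fit_has_no_slopes(self, fitted):
        cfg, pop, pheno, grad = fitted
        fit = fit_reaction_norm(pheno, grad, pop.pedigree, with_gxe=False,
                                config=GibbsConfig(2500, 500, 4, seed=2))
        tab = fit.ebv_table()
        assert "slope" not in tab.columns
        with pytest.raises(ValueError):
            _ = fit.g0_chain
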