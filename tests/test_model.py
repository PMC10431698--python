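"""PC priors, WAIC, the mixed-model engine, and RW2 smoothers."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from spatiophylo.errors import AlignmentError
from spatiophylo.model import (
    SENSITIVITY_ALPHAS,
    LMMResults,
    PCPrior,
    SpatioPhyloLMM,
    pc_prior_rate,
    rw2_structure,
    second_difference_matrix,
    waic,
)
from spatiophylo.synthetic import simulate_dataset


class TestPCPrior:
    @pytest.mark.parametrize(
        "alpha,expected", [(0.1, 2.302585), (0.5, 0.693147)]
    )
    def test_closed_form_rate(self, alpha, expected):
        assert pc_prior_rate(PCPrior(1.0, alpha)) == pytest.approx(expected, abs=1e-6)

    def test_monte_carlo_tail(self, rng):
        p = PCPrior(1.0, 0.1)
        draws = p.sample(rng, 100_000)
        assert (draws > 1.0).mean() == pytest.approx(0.10, abs=0.01)

    @pytest.mark.parametrize("alpha", SENSITIVITY_ALPHAS)
    def test_sensitivity_grid_calibrated(self, alpha, rng):
        """Prior-predictive check across the sensitivity settings."""
        draws = PCPrior(1.0, alpha).sample(rng, 60_000)
        se = 3 * np.sqrt(alpha * (1 - alpha) / 60_000)
        assert (draws > 1.0).mean() == pytest.approx(alpha, abs=max(se, 5e-3))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PCPrior(0.0, 0.1)
        with pytest.raises(ValueError):
            PCPrior(1.0, 1.0)


class TestWAIC:
    def test_identical_draws_zero_penalty(self):
        ll = np.tile([[-1.2, -0.7, -2.0]], (5, 1))
        res = waic(ll)
        assert res.p_eff == pytest.approx(0.0, abs=1e-12)
        assert res.waic == pytest.approx(-2 * ll[0].sum(), abs=1e-10)

    def test_matches_brute_force_definition(self):
        ll = np.array([[-1.0, -2.0], [-1.5, -1.0], [-0.5, -3.0]])
        expected = -2 * sum(
            logsumexp(ll[:, i]) - np.log(3) - ll[:, i].var(ddof=1)
            for i in range(2)
        )
        assert waic(ll).waic == pytest.approx(expected, abs=1e-10)

    def test_ordering_invariant_to_constant_shift(self, rng):
        a = rng.normal(-1, 0.3, size=(50, 10))
        b = rng.normal(-1.2, 0.3, size=(50, 10))
        base = waic(a).waic < waic(b).waic
        shifted = waic(a + 5.0).waic < waic(b + 5.0).waic
        assert base == shifted

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            waic(np.array([[0.0, -np.inf]]))


def _fake_results(beta_draws, sd_draws, sd_names, terms):
    model = SpatioPhyloLMM(np.zeros(3))
    model.term_names = terms
    return LMMResults(
        model=model,
        beta_draws=beta_draws,
        sd_draws=sd_draws,
        sd_names=sd_names,
        pointwise_loglik=np.zeros((len(beta_draws), 3)),
        theta_mode=np.zeros(len(sd_names)),
        grid_nodes=np.zeros((1, len(sd_names))),
        grid_weights=np.ones(1),
        diagnostics={"mode_converged": True, "boundary_mass": 0.0},
    )


class TestEffectSummaries:
    def test_constant_draws_substantial(self):
        r = _fake_results(np.full((20, 1), 0.5), np.ones((20, 1)), ["resid"],
                          ["Intercept"])
        e = r.summarize_effect("Intercept")
        assert (e.q025, e.q50, e.q975) == (0.5, 0.5, 0.5)
        assert e.substantial

    def test_symmetric_draws_not_substantial(self, rng):
        d = rng.standard_normal(4000)[:, None]
        r = _fake_results(d, np.ones((4000, 1)), ["resid"], ["Intercept"])
        assert not r.summarize_effect("Intercept").substantial

    def test_normal_quantiles(self, rng):
        d = rng.standard_normal(10_000)[:, None]
        r = _fake_results(d, np.ones((10_000, 1)), ["resid"], ["Intercept"])
        e = r.summarize_effect("Intercept")
        assert e.q025 == pytest.approx(-1.96, abs=0.05)
        assert e.q50 == pytest.approx(0.0, abs=0.05)
        assert e.q975 == pytest.approx(1.96, abs=0.05)

    def test_unknown_term_rejected(self):
        r = _fake_results(np.zeros((5, 1)), np.ones((5, 1)), ["resid"],
                          ["Intercept"])
        with pytest.raises(KeyError):
            r.summarize_effect("nope")


class TestVariancePartition:
    def test_equal_sds_give_thirds(self):
        sd = np.ones((50, 3))
        r = _fake_results(np.zeros((50, 1)), sd,
                          ["phylo", "spatial", "resid"], ["Intercept"])
        fr = r.variance_partition()
        assert fr == pytest.approx(
            {"phylo": 1 / 3, "spatial": 1 / 3, "residual": 1 / 3}
        )
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-6)

    def test_zero_component_gives_zero_fraction(self):
        sd = np.column_stack([np.ones(50), np.zeros(50), np.ones(50)])
        r = _fake_results(np.zeros((50, 1)), sd,
                          ["phylo", "spatial", "resid"], ["Intercept"])
        assert r.variance_partition()["spatial"] == 0.0


class TestFitting:
    def test_collapses_to_ols_without_structures(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + 0.3 * rng.standard_normal(n)
        res = SpatioPhyloLMM(pd.Series(y), X=pd.DataFrame({"x": x})).fit(
            seed=0, draws=400
        )
        X = np.column_stack([np.ones(n), x])
        bols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ bols
        se = np.sqrt(
            resid.var(ddof=2) * np.linalg.inv(X.T @ X)[1, 1]
        )
        e = res.summarize_effect("x")
        assert abs(e.q50 - bols[1]) < 2 * se

    def test_intercept_only_on_standardized_response(self, rng):
        y = rng.standard_normal(150)
        y = (y - y.mean()) / y.std(ddof=1)
        res = SpatioPhyloLMM(pd.Series(y)).fit(seed=0, draws=300)
        assert abs(res.summarize_effect("Intercept").q50) < 0.1

    def test_posterior_contracts_with_n(self, rng):
        """Quadrupling n roughly halves the posterior SD of beta."""
        widths = {}
        for n in (250, 1000):
            x = rng.standard_normal(n)
            y = 0.8 * x + 0.5 * rng.standard_normal(n)
            res = SpatioPhyloLMM(pd.Series(y), X=pd.DataFrame({"x": x})).fit(
                seed=1, draws=400
            )
            widths[n] = res.beta_draws[:, 1].std()
        assert widths[1000] < widths[250] / 1.6

    def test_seed_reproducibility(self):
        ds = simulate_dataset(n_taxa=60, seed=5)
        y = ds.scores.set_index("taxon")["z_score"]
        kw = dict(structures=[ds.structures["phylo"]])
        r1 = SpatioPhyloLMM(y, **kw).fit(seed=9, draws=150)
        r2 = SpatioPhyloLMM(y, **kw).fit(seed=9, draws=150)
        assert np.array_equal(r1.beta_draws, r2.beta_draws)
        assert np.array_equal(r1.pointwise_loglik, r2.pointwise_loglik)

    def test_misaligned_taxa_rejected(self):
        ds = simulate_dataset(n_taxa=30, seed=5)
        y = ds.scores.set_index("taxon")["z_score"]
        bad = ds.structures["phylo"].subset(y.index[:-2].tolist())
        with pytest.raises(AlignmentError):
            SpatioPhyloLMM(y, structures=[bad])

    def test_true_structure_beats_intercept_only_waic(self):
        ds = simulate_dataset(n_taxa=150, seed=21)
        y = ds.scores.set_index("taxon")["z_score"]
        with_struct = SpatioPhyloLMM(
            y, structures=[ds.structures["phylo"], ds.structures["spatial_local"]]
        ).fit(seed=0, draws=300)
        plain = SpatioPhyloLMM(y).fit(seed=0, draws=300)
        assert with_struct.waic.waic < plain.waic.waic


class TestRW2:
    def test_second_difference_rank(self):
        assert np.linalg.matrix_rank(second_difference_matrix(5)) == 3

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            rw2_structure(np.repeat([1.0, 2.0, 3.0], 10), n_bins=5)

    def test_linear_truth_within_band(self, rng):
        n = 150
        x = rng.uniform(0, 10, n)
        y = 0.3 * x + 0.2 * rng.standard_normal(n)
        term = rw2_structure(x, n_bins=10, name="rw2x")
        res = SpatioPhyloLMM(pd.Series(y), rw2=[term]).fit(seed=0, draws=300)
        curve = res.rw2_curve("rw2x")
        line = 0.3 * (curve["bin_mid"] - np.average(x))
        inside = (line >= curve["q025"] - 0.1) & (line <= curve["q975"] + 0.1)
        assert inside.all()

    def test_constant_truth_shrinks(self, rng):
        n = 150
        x = rng.uniform(0, 10, n)
        y = 0.2 * rng.standard_normal(n)
        term = rw2_structure(x, n_bins=10, name="rw2x")
        res = SpatioPhyloLMM(pd.Series(y), rw2=[term]).fit(seed=0, draws=300)
        assert res.summarize_effect("rw2x").q50 < 0.1
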