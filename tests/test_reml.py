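import itertools

import numpy as np
import pandas as pd
import pytest

import nmrherit as nh
from nmrherit.reml import (
    RemlError,
    build_bivariate,
    build_design,
    reml_fit,
    reml_fit_bivariate,
    restricted_loglik,
    restricted_loglik_bivariate,
)


@pytest.fixture(scope="module")
def oneway_model():
    """Balanced one-way layout: 2 groups x 3 reps, y = 1,2,3,7,8,9.

    REML on a single i.i.d. group effect equals the balanced ANOVA
    estimators: sigma_e^2 = MS_within = 1, sigma_group^2 =
    (MS_between - MS_within)/r = (54 - 1)/3.
    """
    df = pd.DataFrame(
        {
            "plot": [f"p{i}" for i in range(6)],
            "line": ["A"] * 3 + ["B"] * 3,
            "location": "L1",
            "year": "Y1",
            "trial": "T1",
            "batch": "B1",
        }
    )
    design = nh.PlotDesign(df)
    G = nh.GenomicRelationship(np.array(["A", "B"]), np.eye(2), np.zeros(0))
    y = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
    return build_design(design, G, y, term_names=("l",))


class TestUnivariateOracles:
    def test_balanced_anova_estimators(self, oneway_model):
        vc = reml_fit(oneway_model)
        assert vc["e"] == pytest.approx(1.0, abs=1e-6)
        assert vc["l"] == pytest.approx(53.0 / 3.0, abs=1e-5)

    def test_closed_form_restricted_likelihood(self, oneway_model):
        # textbook REML likelihood of a balanced one-way layout:
        # -2l = (n-g) log se + g log(se + r sg) + SSW/se + SSB/(se + r sg)
        #        + log(g) - log(n) ... compare through the generic kernel
        y = oneway_model.y
        se, sg, r, g = 2.0, 5.0, 3, 2
        means = np.array([y[:3].mean(), y[3:].mean()])
        ssw = float(((y[:3] - means[0]) ** 2).sum() + ((y[3:] - means[1]) ** 2).sum())
        lam = se + r * sg
        grand = y.mean()
        ssb = r * float(((means - grand) ** 2).sum())
        n = 6
        # with X = 1_n: log|X'V^-1X| = log(g r / lam)
        ll_closed = -0.5 * (
            (n - g) * np.log(se)
            + g * np.log(lam)
            + np.log(g * r / lam)
            + ssw / se
            + ssb / lam
            + (n - 1) * np.log(2 * np.pi)
        )
        ll = restricted_loglik(oneway_model, np.array([sg, se]))
        assert ll == pytest.approx(ll_closed, abs=1e-10)

    def test_tiny_model1_matches_grid_search(self, tiny_design, tiny_grm):
        # 12 plots, 4 lines, 2 environments, known G; grid over the free
        # components of a g + il + e model
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(tiny_grm.G + 1e-9 * np.eye(4))
        idx = {l: i for i, l in enumerate(tiny_grm.line_ids)}
        li = np.array([idx[l] for l in tiny_design.line_ids])
        g = L @ rng.standard_normal(4)
        y = g[li] + 0.5 * rng.standard_normal(12)
        model = build_design(tiny_design, tiny_grm, y, term_names=("g", "il"))
        vc = reml_fit(model)
        grid = np.linspace(0.0, 2.0, 41)  # resolution 0.05
        best_ll, best = -np.inf, None
        for sg, si, se in itertools.product(grid, grid[:21], grid[1:]):
            ll = restricted_loglik(model, np.array([sg, si, se]))
            if ll > best_ll:
                best_ll, best = ll, (sg, si, se)
        assert vc.loglik >= best_ll - 1e-8
        np.testing.assert_allclose(vc.estimates, best, atol=0.051)

    def test_solution_beats_random_perturbations(self, small_sim):
        rel, design = small_sim["grm"], small_sim["design"]
        y = small_sim["features"].values[:, 0]
        model = build_design(design, rel, y)
        vc = reml_fit(model)
        rng = np.random.default_rng(0)
        for _ in range(100):
            pert = vc.estimates + rng.uniform(-0.05, 0.05, vc.estimates.size)
            pert = np.clip(pert, 1e-6, None)
            assert restricted_loglik(model, pert) <= vc.loglik + 1e-6


class TestUnivariateProperties:
    def test_scale_equivariance(self, oneway_model):
        vc1 = reml_fit(oneway_model)
        vc2 = reml_fit(oneway_model.with_response(10.0 * oneway_model.y))
        np.testing.assert_allclose(vc2.estimates, 100.0 * vc1.estimates, rtol=1e-4)

    def test_translation_invariance_of_loglik(self, oneway_model):
        theta = np.array([2.0, 1.0])
        ll0 = restricted_loglik(oneway_model, theta)
        ll1 = restricted_loglik(oneway_model.with_response(oneway_model.y + 7.5), theta)
        assert ll1 == pytest.approx(ll0, abs=1e-9)

    def test_constant_response_raises(self, oneway_model):
        with pytest.raises(RemlError, match="constant|degenerate"):
            reml_fit(oneway_model.with_response(np.zeros(6)))

    def test_estimates_nonnegative_and_converged(self, small_sim):
        rel, design, fm = small_sim["grm"], small_sim["design"], small_sim["features"]
        model = build_design(design, rel, fm.values[:, 4])  # a null feature
        vc = reml_fit(model)
        assert vc.converged
        assert (vc.estimates >= 0).all()


class TestBuildDesign:
    def test_ig_block_structure_per_environment(self, tiny_design, tiny_grm):
        model = build_design(tiny_design, tiny_grm, np.zeros(12))
        k = model.term_names.index("ig")
        S = model.structures[k]
        env = tiny_design.environment().to_numpy()
        li = tiny_design.line_ids
        idx = {l: i for i, l in enumerate(tiny_grm.line_ids)}
        for a in range(12):
            for b in range(12):
                expect = tiny_grm.G[idx[li[a]], idx[li[b]]] if env[a] == env[b] else 0.0
                assert S[a, b] == pytest.approx(expect)

    def test_missing_responses_dropped(self, tiny_design, tiny_grm):
        y = np.arange(12.0)
        y[3] = np.nan
        model = build_design(tiny_design, tiny_grm, y)
        assert model.n == 11
        assert 3 not in model.plot_index

    def test_unknown_line_raises(self, tiny_design):
        G = nh.GenomicRelationship(np.array(["A", "B", "C"]), np.eye(3), np.zeros(0))
        with pytest.raises(KeyError, match="D"):
            build_design(tiny_design, G, np.zeros(12))

    def test_single_trial_aliased_with_environment(self, tiny_design, tiny_grm):
        # one trial per environment: trial cells = environments; the X of
        # cells has exactly n_env independent columns
        model = build_design(tiny_design, tiny_grm, np.zeros(12))
        assert model.X.shape[1] == tiny_design.n_environments()

    def test_single_batch_flagged_inestimable(self, tiny_grm):
        df = pd.DataFrame(
            {
                "plot": [f"p{i}" for i in range(8)],
                "line": ["A", "B", "C", "D"] * 2,
                "location": "L1",
                "year": "Y1",
                "trial": "T1",
                "batch": "B1",
            }
        )
        model = build_design(nh.PlotDesign(df), tiny_grm, np.zeros(8))
        assert "t" in model.inestimable


class TestBivariate:
    def test_identical_responses_have_unit_correlations(self, small_sim):
        rel, design, fm = small_sim["grm"], small_sim["design"], small_sim["features"]
        order = {p: i for i, p in enumerate(design.plot_ids)}
        rows = np.array([order[p] for p in fm.plot_ids])
        y = np.full(design.n_plots, np.nan)
        y[rows] = fm.values[:, 0]
        fit = reml_fit_bivariate(build_bivariate(design, rel, y, y.copy()))
        for k, name in enumerate(fit.term_names):
            v1, c, v2 = fit.blocks[k, 0, 0], fit.blocks[k, 0, 1], fit.blocks[k, 1, 1]
            if v1 > 1e-6 and v2 > 1e-6:
                assert c / np.sqrt(v1 * v2) == pytest.approx(1.0, abs=1e-3), name

    def test_tiny_instance_matches_grid_over_residual_block(self, tiny_design, tiny_grm):
        # grid-search oracle over (v1, v2, c12) of the residual block with
        # all other terms fixed at the fitted values
        rng = np.random.default_rng(3)
        z = rng.standard_normal(12)
        y1 = z + 0.3 * rng.standard_normal(12)
        y2 = 0.8 * z + 0.3 * rng.standard_normal(12)
        model = build_bivariate(tiny_design, tiny_grm, y1, y2)
        fit = reml_fit_bivariate(model)
        e = fit.term_names.index("e")
        f1, f2 = fit.blocks[e, 0, 0], fit.blocks[e, 1, 1]
        # grid brackets the fitted point so the argmax is resolvable
        grid1 = np.linspace(0.25 * f1, 2.0 * f1, 26)
        grid2 = np.linspace(0.25 * f2, 2.0 * f2, 26)
        best_ll = -np.inf
        best = None
        for v1, v2 in itertools.product(grid1, grid2):
            cmax = np.sqrt(v1 * v2)
            for c in np.linspace(-0.9995 * cmax, 0.9995 * cmax, 161):
                blocks = fit.blocks.copy()
                blocks[e] = [[v1, c], [c, v2]]
                ll = restricted_loglik_bivariate(model, blocks)
                if ll > best_ll:
                    best_ll, best = ll, (v1, c, v2)
        # the two maximizations agree to within the grid's own resolution:
        # near the (boundary) optimum adjacent grid points differ by more
        # than 0.01 log-likelihood units
        assert fit.loglik >= best_ll - 0.01
        assert best_ll >= fit.loglik - 0.05
        # both agree the residual covariance is positive (shared signal)
        assert best[1] > 0 and fit.blocks[e, 0, 1] > 0

    def test_psd_blocks_at_solution(self, small_sim):
        rel, design, fm = small_sim["grm"], small_sim["design"], small_sim["features"]
        traits = small_sim["traits"]
        order = {p: i for i, p in enumerate(design.plot_ids)}
        rows = np.array([order[p] for p in fm.plot_ids])
        yf = np.full(design.n_plots, np.nan)
        yf[rows] = fm.values[:, 0]
        yt = traits["BG"].to_numpy(float)
        fit = reml_fit_bivariate(build_bivariate(design, rel, yf, yt))
        for k in range(fit.blocks.shape[0]):
            w = np.linalg.eigvalsh(fit.blocks[k])
            assert w.min() >= -1e-10

    def test_constant_response_raises(self, tiny_design, tiny_grm):
        y1 = np.arange(12.0)
        with pytest.raises(ValueError, match="constant"):
            build_bivariate(tiny_design, tiny_grm, y1, np.ones(12))

    def test_missing_records_use_unequal_plot_sets(self, small_sim):
        rel, design, traits = small_sim["grm"], small_sim["design"], small_sim["traits"]
        fm = small_sim["features"]
        order = {p: i for i, p in enumerate(design.plot_ids)}
        rows = np.array([order[p] for p in fm.plot_ids])
        yf = np.full(design.n_plots, np.nan)
        yf[rows] = fm.values[:, 1]
        yt = traits["BG"].to_numpy(float)  # has ~2% missing plots
        assert np.isnan(yt).any()
        model = build_bivariate(design, rel, yf, yt)
        assert model.n2 == np.isfinite(yt).sum() < model.n1
        fit = reml_fit_bivariate(model)
        assert fit.converged
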