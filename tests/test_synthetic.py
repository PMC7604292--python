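import numpy as np
import pandas as pd
import pytest

import nmrherit as nh
from nmrherit.synthetic import (
    SimulationConfig,
    TraitSpec,
    default_feature_components,
    simulate_design,
    simulate_genotypes,
    simulate_phenotypes,
)


def _cfg(**kw):
    kw.setdefault("n_lines", 30)
    kw.setdefault("n_markers", 120)
    kw.setdefault("reps_per_line", 3.0)
    kw.setdefault("n_batches", 4)
    kw.setdefault("ppm_grid", (1.0, 4.0, 2))
    kw.setdefault("feature_components", np.tile([0.3, 0.1, 0.1, 0.1, 0.1, 0.3], (2, 1)))
    return SimulationConfig(**kw)


class TestGenotypes:
    def test_dosage_domain(self):
        cfg = _cfg(n_lines=2, n_markers=1, maf_range=(0.5, 0.5), seed=1)
        m = simulate_genotypes(cfg)
        assert m.dosages.shape == (2, 1)
        assert np.isin(m.dosages, [0.0, 1.0, 2.0]).all()

    def test_seeded_determinism(self):
        a = simulate_genotypes(_cfg(seed=9))
        b = simulate_genotypes(_cfg(seed=9))
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_relatedness_raises_offdiagonal_G(self):
        # founder crossing must induce more relationship than independent
        # Hardy-Weinberg draws of the same size
        kw = dict(n_lines=200, n_markers=2000, n_founders=10, seed=4)
        rel = nh.build_grm(simulate_genotypes(_cfg(related=True, **kw)))
        unrel = nh.build_grm(simulate_genotypes(_cfg(related=False, **kw)))
        off = ~np.eye(200, dtype=bool)
        assert np.abs(rel.G[off]).mean() > np.abs(unrel.G[off]).mean()

    def test_degenerate_maf_range_raises(self):
        with pytest.raises(ValueError, match="maf_range"):
            _cfg(maf_range=(0.0, 0.0))

    def test_missing_rate_produces_nans(self):
        m = simulate_genotypes(_cfg(marker_missing_rate=0.1, seed=2))
        frac = np.isnan(m.dosages).mean()
        assert 0.05 < frac < 0.15


class TestDesign:
    def test_two_locations_three_years_gives_six_environments(self):
        design = simulate_design(_cfg(n_locations=2, n_years=3))
        assert design.n_environments() == 6

    def test_paper_scale_mean_replicates(self):
        cfg = SimulationConfig(n_lines=565, n_plots=2628, ppm_grid=(0.7, 9.0, 1),
                               feature_components=np.array([[0, 0, 0, 0, 0, 1.0]]))
        design = simulate_design(cfg)
        assert design.n_plots == 2628
        assert round(design.mean_replicates(), 2) == 4.65

    def test_single_line_single_plot(self):
        cfg = SimulationConfig(
            n_lines=1, reps_per_line=1.0, n_locations=1, n_years=1,
            trials_per_env=1, n_batches=1, ppm_grid=(1.0, 2.0, 1),
            feature_components=np.array([[0, 0, 0, 0, 0, 1.0]]),
        )
        design = simulate_design(cfg)
        assert design.n_plots == 1
        assert design.table.nunique().max() == 1 or design.n_plots == 1

    def test_every_line_gets_a_plot(self):
        design = simulate_design(_cfg(reps_per_line=1.2))
        assert design.table["line"].nunique() == 30

    def test_more_trials_than_plots_raises(self):
        with pytest.raises(ValueError, match="trials"):
            simulate_design(_cfg(n_lines=2, reps_per_line=1.0, trials_per_env=10))

    def test_trials_nested_in_environment(self):
        design = simulate_design(_cfg(trials_per_env=2))
        cells = design.table.groupby(["location", "year"])["trial"].nunique()
        assert (cells <= 2).all()


class TestPhenotypes:
    def test_pure_noise_when_only_residual(self):
        comps = np.array([[0, 0, 0, 0, 0, 1.0]])
        cfg = _cfg(ppm_grid=(1.0, 2.0, 1), feature_components=comps,
                   cell_effect_sd=0.0, dilution_sd=0.0, baseline_scale=0.0, seed=3)
        mk = simulate_genotypes(cfg)
        des = simulate_design(cfg)
        spectra, _, truth = simulate_phenotypes(mk, des, cfg)
        y = spectra.intensities[:, 0]
        assert truth.true_h2[0] == 0.0
        assert np.var(y, ddof=1) == pytest.approx(1.0, rel=0.25)
        # no line structure: within-line spread comparable to overall spread
        df = pd.DataFrame({"line": des.line_ids, "y": y})
        within = df.groupby("line")["y"].var(ddof=1).mean()
        assert within == pytest.approx(np.var(y, ddof=1), rel=0.5)

    def test_pure_genomic_effect_repeats_within_line(self):
        # only sigma_g^2 > 0 and no nuisance effects: two plots of the same
        # line in the same environment/trial get identical values
        comps = np.array([[1.0, 0, 0, 0, 0, 0]])
        cfg = _cfg(ppm_grid=(1.0, 2.0, 1), feature_components=comps,
                   cell_effect_sd=0.0, dilution_sd=0.0, seed=5,
                   n_locations=1, n_years=1, trials_per_env=1, n_batches=1)
        mk = simulate_genotypes(cfg)
        des = simulate_design(cfg)
        spectra, _, _ = simulate_phenotypes(mk, des, cfg)
        df = pd.DataFrame({"line": des.line_ids, "y": spectra.intensities[:, 0]})
        assert (df.groupby("line")["y"].nunique() == 1).all()

    def test_full_determinism_under_seed(self):
        cfg = _cfg(seed=7)
        a = simulate_phenotypes(simulate_genotypes(cfg), simulate_design(cfg), cfg)
        b = simulate_phenotypes(simulate_genotypes(cfg), simulate_design(cfg), cfg)
        np.testing.assert_array_equal(a[0].intensities, b[0].intensities)

    def test_perfect_genetic_covariance_gives_unit_true_correlation(self):
        comps = np.array([[0.3, 0.1, 0.1, 0.1, 0.1, 0.3]])
        spec = TraitSpec("T", [0.3, 0.1, 0.1, 0.1, 0.1, 0.3],
                         feature_gen_cov=[np.sqrt(0.3 * 0.3)],
                         feature_res_cov=[0.0], missing_rate=0.0)
        cfg = _cfg(ppm_grid=(1.0, 2.0, 1), feature_components=comps,
                   trait_specs=[spec], seed=6)
        _, traits, truth = simulate_phenotypes(
            simulate_genotypes(cfg), simulate_design(cfg), cfg
        )
        assert truth.true_r_g[0, 0] == pytest.approx(1.0)
        assert (np.abs(truth.true_r_g) <= 1).all()
        assert (truth.true_h2 >= 0).all() and (truth.true_h2 <= 1).all()

    def test_non_psd_trait_block_raises_with_block_name(self):
        comps = np.array([[0.1, 0.1, 0.1, 0.1, 0.1, 0.5]])
        spec = TraitSpec("T", [0.1, 0.1, 0.1, 0.1, 0.1, 0.5],
                         feature_gen_cov=[0.5], feature_res_cov=[0.0])
        cfg = _cfg(ppm_grid=(1.0, 2.0, 1), feature_components=comps,
                   trait_specs=[spec], seed=1)
        with pytest.raises(ValueError, match="genomic"):
            simulate_phenotypes(simulate_genotypes(cfg), simulate_design(cfg), cfg)

    def test_realized_genomic_variance_matches_plot_scale_target(self):
        # across many independent features the average realized variance of
        # line genomic values equals the configured plot-scale sigma_g^2
        nf = 300
        comps = np.tile([0.5, 0.0, 0.0, 0.0, 0.0, 0.5], (nf, 1))
        cfg = _cfg(n_lines=80, n_markers=600, ppm_grid=(1.0, 4.0, nf),
                   feature_components=comps, seed=12)
        _, _, truth = simulate_phenotypes(
            simulate_genotypes(cfg), simulate_design(cfg), cfg
        )
        realized = np.mean(truth.line_genomic_feature**2)
        assert realized == pytest.approx(0.5, rel=0.1)


def test_default_feature_components_unit_variance_and_h2_range():
    comps = default_feature_components(200, seed=0)
    np.testing.assert_allclose(comps.sum(axis=1), 1.0, atol=1e-12)
    h2 = comps[:, 0] / comps.sum(axis=1)
    assert h2.min() >= 0.0 and h2.max() <= 0.4
    assert (h2 == 0).mean() > 0.3  # a sizable null fraction
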