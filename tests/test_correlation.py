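import numpy as np
import pandas as pd
import pytest

from nmrherit.correlation import (
    CorrelationResult,
    CorrEstimate,
    compute_descriptives,
    correlation_from_fit,
    genetic_correlation,
    phenotypic_correlation,
    summarize_trait,
    z_test,
    z_threshold,
)
from nmrherit.reml import TERM_NAMES, BivariateComponents


def _biv(blocks, cov=None):
    blocks = np.asarray(blocks, float)
    K = blocks.shape[0]
    cov = np.zeros((3 * K, 3 * K)) if cov is None else cov
    return BivariateComponents(
        term_names=TERM_NAMES, blocks=blocks, cov=cov, loglik=0.0,
        converged=True, n_iter=1, pinned=np.zeros(3 * K, bool), n_obs=(10, 10),
    )


def _blocks(g=(1.0, 0.0, 1.0), e=(1.0, 0.0, 1.0), rest=(0.1, 0.0, 0.1)):
    out = np.zeros((6, 2, 2))
    for k in range(6):
        v1, c, v2 = {0: g, 5: e}.get(k, rest)
        out[k] = [[v1, c], [c, v2]]
    return out


class TestZTest:
    def test_threshold_value_two_sided_one_percent(self):
        assert z_threshold(0.01) == 2.326

    def test_clear_significance(self):
        assert z_test(0.5, 0.2)  # z = 2.5

    def test_zero_estimate_never_significant(self):
        assert not z_test(0.0, 0.3)

    def test_strict_inequality_at_threshold(self):
        assert not z_test(0.465, 0.2)  # z = 2.325 exactly below 2.326

    def test_nonpositive_se_raises(self):
        with pytest.raises(ValueError, match="positive"):
            z_test(0.5, 0.0)


class TestGeneticCorrelation:
    def test_zero_covariance_gives_zero(self):
        est = genetic_correlation(_biv(_blocks(g=(0.4, 0.0, 0.2))))
        assert est.value == 0.0 and est.defined

    def test_boundary_covariance_flags(self):
        c = np.sqrt(0.4 * 0.2)
        est = genetic_correlation(_biv(_blocks(g=(0.4, -c, 0.2))))
        assert est.value == pytest.approx(-1.0)
        assert est.boundary

    def test_zero_variance_is_reason_coded_not_zero(self):
        est = genetic_correlation(_biv(_blocks(g=(0.0, 0.0, 0.2))))
        assert not est.defined
        assert "boundary" in est.reason
        assert est.value is None

    def test_se_matches_numeric_delta_method(self):
        rng = np.random.default_rng(1)
        A = rng.random((18, 18)) * 0.01
        cov = A @ A.T
        blocks = _blocks(g=(0.4, 0.1, 0.3))
        est = genetic_correlation(_biv(blocks, cov))

        def r_of(p3):
            v1, c, v2 = p3
            return c / np.sqrt(v1 * v2)

        base = np.array([0.4, 0.1, 0.3])
        grad = np.zeros(18)
        for i in range(3):
            d = np.zeros(3)
            d[i] = 1e-7
            grad[i] = (r_of(base + d) - r_of(base - d)) / 2e-7
        assert est.se == pytest.approx(np.sqrt(grad @ cov @ grad), rel=1e-5)


class TestPhenotypicCorrelation:
    def test_all_covariances_zero(self):
        est = phenotypic_correlation(_biv(_blocks()), g_bar=1.3)
        assert est.value == 0.0

    def test_identical_responses_give_one(self):
        blocks = np.zeros((6, 2, 2))
        for k, v in enumerate([0.3, 0.1, 0.1, 0.1, 0.1, 0.3]):
            blocks[k] = [[v, v], [v, v]]
        est = phenotypic_correlation(_biv(blocks), g_bar=1.7)
        assert est.value == pytest.approx(1.0)
        assert est.boundary

    def test_residual_only_covariance_closed_form(self):
        # only the residual block carries covariance c; the phenotypic
        # correlation must equal c / sqrt(sigma_P1^2 sigma_P2^2) with the
        # Gbar-weighted variance sums
        g_bar = 1.4
        blocks = _blocks(g=(0.2, 0.0, 0.3), e=(0.5, 0.21, 0.4))
        est = phenotypic_correlation(_biv(blocks), g_bar=g_bar)
        sp1 = g_bar * 0.2 + 0.1 + g_bar * 0.1 + 0.1 + 0.1 + 0.5
        sp2 = g_bar * 0.3 + 0.1 + g_bar * 0.1 + 0.1 + 0.1 + 0.4
        assert est.value == pytest.approx(0.21 / np.sqrt(sp1 * sp2), abs=1e-12)


class TestSummaries:
    def _result(self, trait, rg, sig_se):
        return CorrelationResult(
            feature_id="f", trait_id=trait,
            r_g=CorrEstimate(rg, sig_se), r_p=CorrEstimate(0.0, 1.0),
        )

    def test_one_of_four_significant(self):
        results = [
            self._result("BG", 0.5, 0.1),  # z = 5, significant
            self._result("BG", 0.5, 0.5),
            self._result("BG", -0.2, 0.5),
            self._result("BG", 0.1, 0.5),
        ]
        s = summarize_trait(results, "BG")
        assert s["r_g_pct_significant"] == 25.0
        assert s["r_g_min"] == -0.2 and s["r_g_max"] == 0.5

    def test_all_nonsignificant_gives_zero_pct(self):
        results = [self._result("WV", 0.1, 1.0) for _ in range(3)]
        assert summarize_trait(results, "WV")["r_g_pct_significant"] == 0.0

    def test_undefined_excluded_from_denominator(self):
        results = [
            self._result("BG", 0.5, 0.1),
            CorrelationResult("f2", "BG", CorrEstimate(None, None, reason="x"),
                              CorrEstimate(0.0, 1.0)),
        ]
        s = summarize_trait(results, "BG")
        assert s["r_g_n_defined"] == 1 and s["r_g_n_undefined"] == 1
        assert s["r_g_pct_significant"] == 100.0

    def test_row_order_invariance(self):
        results = [self._result("BG", v, 0.1) for v in (0.5, -0.3, 0.2)]
        a = summarize_trait(results, "BG")
        b = summarize_trait(results[::-1], "BG")
        assert a == b


class TestDescriptives:
    def test_hand_example_two_values(self):
        out = compute_descriptives(pd.DataFrame({"T": [1.0, 3.0]}))
        row = out.iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(np.sqrt(2), abs=1e-10)
        assert row["cv_pct"] == 70.71

    def test_cv_from_given_mean_and_sd(self):
        # two points constructed to have mean 224.75 and SD 133.65 exactly;
        # the coefficient of variation then prints as 59.47%
        half = 133.65 / np.sqrt(2.0)
        out = compute_descriptives(
            pd.DataFrame({"BG": [224.75 - half, 224.75 + half]})
        )
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(224.75)
        assert row["sd"] == pytest.approx(133.65)
        assert row["cv_pct"] == 59.47

    def test_constant_trait_cv_zero(self):
        out = compute_descriptives(pd.DataFrame({"T": [2.0, 2.0, 2.0]}))
        assert out.iloc[0]["sd"] == 0.0 and out.iloc[0]["cv_pct"] == 0.0

    def test_missing_trait_raises_with_name(self):
        with pytest.raises(ValueError, match="WCL"):
            compute_descriptives(pd.DataFrame({"WCL": [np.nan, np.nan]}))

    def test_missing_values_excluded_from_count(self):
        out = compute_descriptives(pd.DataFrame({"T": [1.0, np.nan, 3.0, 2.0]}))
        assert out.iloc[0]["n"] == 3


def test_correlation_from_fit_labels(small_sim):
    import nmrherit as nh

    rel, design, fm = small_sim["grm"], small_sim["design"], small_sim["features"]
    order = {p: i for i, p in enumerate(design.plot_ids)}
    rows = np.array([order[p] for p in fm.plot_ids])
    yf = np.full(design.n_plots, np.nan)
    yf[rows] = fm.values[:, 0]
    yt = small_sim["traits"]["BG"].to_numpy(float)
    fit = nh.reml_fit_bivariate(nh.build_bivariate(design, rel, yf, yt))
    res = correlation_from_fit(fit, rel.g_bar, "1.000000", "BG")
    assert res.feature_id == "1.000000" and res.trait_id == "BG"
    row = res.to_row()
    assert set(["r_g", "r_g_se", "r_g_z", "r_g_sig", "r_p", "r_p_se"]) <= set(row)
    if res.r_g.defined:
        assert -1.0 <= res.r_g.value <= 1.0
    assert -1.0 <= res.r_p.value <= 1.0
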