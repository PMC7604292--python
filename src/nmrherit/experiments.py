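"""Calibration experiments: oracle checks, parameter recovery and null
false-positive rate, run end to end on synthetic data.

These are the package's own quality-control experiments.  They are used by
the test suite and by ``scripts/acceptance.py`` and always recompute their
numbers from scratch.  Problem sizes are chosen so the full battery runs
on a desktop in minutes: recovery uses 200 lines with ~3 plots each over
six environments, null calibration uses a 100-line design (the
false-positive rate of the percentile cutoff does not depend on design
size, only its power does).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import grm as grm_mod
from .correlation import genetic_correlation
from .heritability import compute_h2, null_cutoff
from .preprocess import preprocess_spectra
from .reml import build_bivariate, build_design, reml_fit, reml_fit_bivariate
from .synthetic import (
    SimulationConfig,
    TraitSpec,
    simulate_design,
    simulate_genotypes,
    simulate_phenotypes,
)

#: the reference component vector used in recovery experiments
#: (g, l, ig, il, t, e) on the plot scale; true plot h2 = 0.3
RECOVERY_COMPONENTS = (0.3, 0.1, 0.1, 0.1, 0.1, 0.3)


def anova_oracle() -> dict:
    """REML on a balanced one-way layout (2 groups x 3 reps, y = 1..3, 7..9)
    against the closed-form ANOVA estimators sigma_e^2 = 1 and
    sigma_group^2 = (54 - 1)/3."""
    from .design import PlotDesign
    from .grm import GenomicRelationship

    df = pd.DataFrame(
        {
            "plot": [f"p{i}" for i in range(6)],
            "line": ["A"] * 3 + ["B"] * 3,
            "location": "L1", "year": "Y1", "trial": "T1", "batch": "B1",
        }
    )
    design = PlotDesign(df)
    G = GenomicRelationship(np.array(["A", "B"]), np.eye(2), np.zeros(0))
    y = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
    vc = reml_fit(build_design(design, G, y, term_names=("l",)))
    return {"sigma_group": vc["l"], "sigma_e": vc["e"]}


def hwe_grm_mean_diagonal(n_lines: int = 500, n_markers: int = 5000, seed: int = 0) -> float:
    """Average diagonal of the VanRaden G for an unrelated Hardy-Weinberg
    population (expected ~ 1 under the method-1 scaling)."""
    cfg = SimulationConfig(
        n_lines=n_lines, n_markers=n_markers, related=False,
        ppm_grid=(1.0, 2.0, 1),
        feature_components=np.array([[0, 0, 0, 0, 0, 1.0]]), seed=seed,
    )
    return grm_mod.build_grm(simulate_genotypes(cfg)).g_bar


#: pure-noise buckets simulated alongside every target feature so that the
#: probabilistic quotient normalization sees a realistic quotient
#: distribution.  The count matters quantitatively, not just cosmetically:
#: the PQN dilution factor is a median over bucket quotients, and its
#: estimation error injects extra plot-level variance of order 1/n_buckets
#: into every normalized feature, attenuating h2.  Real spectra have
#: thousands of buckets; 127 fillers keep that artifact below half a
#: Monte-Carlo SE while staying cheap.
N_FILLER_BUCKETS = 127


def _recovery_setup(n_lines: int, n_markers: int, reps: float, seed: int,
                    trait_specs=None):
    """One independent replicate: related genotypes, 6-environment design
    and the G matrix; bucket 0 is the target feature, the rest are noise."""
    comps = np.vstack(
        [RECOVERY_COMPONENTS]
        + [[0.0, 0.0, 0.0, 0.0, 0.0, 1.0]] * N_FILLER_BUCKETS
    )
    cfg = SimulationConfig(
        n_lines=n_lines, n_markers=n_markers, reps_per_line=reps,
        n_batches=max(4, round(n_lines * reps / 60)),
        ppm_grid=(1.0, 4.5, comps.shape[0]), feature_components=comps,
        trait_specs=trait_specs or [], seed=seed,
    )
    markers = simulate_genotypes(cfg)
    design = simulate_design(cfg)
    filtered, _ = grm_mod.filter_markers(markers)
    relationship = grm_mod.build_grm(filtered)
    return cfg, markers, design, relationship


@dataclass
class RecoveryResult:
    estimates: np.ndarray
    truth: float

    @property
    def mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def mc_se(self) -> float:
        return float(self.estimates.std(ddof=1) / np.sqrt(len(self.estimates)))

    @property
    def within_2se(self) -> bool:
        return abs(self.mean - self.truth) <= 2.0 * self.mc_se


def recover_h2(
    n_features: int = 50, n_lines: int = 200, n_markers: int = 2000,
    reps: float = 3.0, seed: int = 0,
) -> RecoveryResult:
    """Simulate features at true plot h2 = 0.3 on 6-environment designs,
    run the full preprocess + REML + h2 chain, and collect the estimates.

    Every feature is a fully independent replicate (own genotypes, design
    and G), so the Monte-Carlo standard error of the mean is honest; the
    mean estimate should sit within two such SEs of the truth
    (unbiasedness at the study scale).
    """
    h2s = np.empty(n_features)
    truth_h2 = 0.0
    for f in range(n_features):
        cfg, markers, design, relationship = _recovery_setup(
            n_lines, n_markers, reps, seed + 1000 * f
        )
        spectra, _, truth = simulate_phenotypes(markers, design, cfg)
        truth_h2 = float(truth.true_h2[0])
        features, _ = preprocess_spectra(spectra)
        template = build_design(design, relationship, np.zeros(design.n_plots))
        order = {p: i for i, p in enumerate(design.plot_ids)}
        rows = np.array([order[p] for p in features.plot_ids])
        y = np.full(design.n_plots, np.nan)
        y[rows] = features.values[:, 0]
        vc = reml_fit(template.with_response(y[template.plot_index]))
        h2s[f] = compute_h2(vc, relationship.g_bar).h2
    return RecoveryResult(h2s, truth=truth_h2)


def recover_genetic_correlation(
    n_pairs: int = 30, n_lines: int = 200, n_markers: int = 2000,
    reps: float = 3.0, true_rg: float = -0.6, seed: int = 0,
) -> RecoveryResult:
    """Simulate feature-trait pairs at a known genetic correlation and
    collect the bivariate REML estimates (genotypes and design are shared
    across pairs; phenotypes are redrawn per pair)."""
    sg = RECOVERY_COMPONENTS[0]
    gen_cov = np.zeros(1 + N_FILLER_BUCKETS)
    gen_cov[0] = true_rg * sg
    spec = TraitSpec(
        "trait", np.array(RECOVERY_COMPONENTS),
        feature_gen_cov=gen_cov,
        feature_res_cov=np.zeros(1 + N_FILLER_BUCKETS), missing_rate=0.02,
    )
    estimates = []
    for k in range(n_pairs):
        cfg, markers, design, relationship = _recovery_setup(
            n_lines, n_markers, reps, seed + 1000 * k, trait_specs=[spec]
        )
        spectra, traits, _ = simulate_phenotypes(markers, design, cfg)
        features, _ = preprocess_spectra(spectra)
        order = {p: i for i, p in enumerate(design.plot_ids)}
        rows = np.array([order[p] for p in features.plot_ids])
        yf = np.full(design.n_plots, np.nan)
        yf[rows] = features.values[:, 0]
        yt = traits["trait"].to_numpy(float)
        fit = reml_fit_bivariate(build_bivariate(design, relationship, yf, yt))
        est = genetic_correlation(fit)
        if est.defined:
            estimates.append(est.value)
    return RecoveryResult(np.asarray(estimates), truth=true_rg)


@dataclass
class NullCalibrationResult:
    cutoff: float
    n_features: int
    n_flagged: int
    alpha: float

    @property
    def flag_rate(self) -> float:
        return self.n_flagged / self.n_features

    def binomial_interval(self, level: float = 0.95) -> tuple[int, int]:
        from scipy import stats

        lo, hi = stats.binom.interval(level, self.n_features, self.alpha)
        return int(lo), int(hi)

    @property
    def within_binomial_95(self) -> bool:
        lo, hi = self.binomial_interval()
        return lo <= self.n_flagged <= hi


def calibrate_null(
    n_replicates: int = 500, n_features: int = 500, alpha: float = 0.01,
    n_lines: int = 100, n_markers: int = 1000, reps: float = 2.5,
    seed: int = 0,
) -> NullCalibrationResult:
    """Type-I error of the percentile-cutoff procedure.

    The cutoff is derived from ``n_replicates`` pure-noise refits on the
    design; a fresh batch of ``n_features`` null responses is then flagged
    against it.  The flagged fraction must be statistically compatible
    with ``alpha``.
    """
    cfg = SimulationConfig(
        n_lines=n_lines, n_markers=n_markers, reps_per_line=reps,
        n_batches=max(4, round(n_lines * reps / 60)), ppm_grid=(1.0, 2.0, 1),
        feature_components=np.array([[0, 0, 0, 0, 0, 1.0]]), seed=seed,
    )
    design = simulate_design(cfg)
    relationship = grm_mod.build_grm(simulate_genotypes(cfg))
    model = build_design(design, relationship, np.zeros(design.n_plots))
    null = null_cutoff(
        design, relationship, n_replicates=n_replicates, alpha=alpha,
        seed=seed, model=model,
    )
    rng = np.random.default_rng([seed, 777])
    n_flagged = 0
    for _ in range(n_features):
        y = rng.standard_normal(model.n)
        vc = reml_fit(model.with_response(y))
        if compute_h2(vc, relationship.g_bar).h2 > null.cutoff:
            n_flagged += 1
    return NullCalibrationResult(
        cutoff=null.cutoff, n_features=n_features, n_flagged=n_flagged, alpha=alpha
    )
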