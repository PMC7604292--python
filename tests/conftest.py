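import numpy as np
import pandas as pd
import pytest

import nmrherit as nh
from nmrherit.synthetic import (
    SimulationConfig,
    TraitSpec,
    simulate_design,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def tiny_design() -> nh.PlotDesign:
    """12 plots, 4 lines, 2 environments, 2 batches; hand-enumerable."""
    rows = []
    plot = 0
    for env, (loc, year) in enumerate([("Loc1", "Y1"), ("Loc1", "Y2")]):
        for line in ["A", "B", "C", "D"]:
            for rep in range(1 if line in ("C", "D") else 2):
                rows.append(
                    {
                        "plot": f"p{plot:02d}",
                        "line": line,
                        "location": loc,
                        "year": year,
                        "trial": "T1",
                        "batch": f"B{env + 1}",
                    }
                )
                plot += 1
    return nh.PlotDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_grm() -> nh.GenomicRelationship:
    """Hand-built PSD relationship for 4 lines (A,B related; C,D related)."""
    G = np.array(
        [
            [1.2, 0.6, 0.1, 0.1],
            [0.6, 1.1, 0.1, 0.1],
            [0.1, 0.1, 1.3, 0.7],
            [0.1, 0.1, 0.7, 1.0],
        ]
    )
    return nh.GenomicRelationship(np.array(["A", "B", "C", "D"]), G, np.zeros(0))


@pytest.fixture(scope="session")
def small_sim():
    """Shared small simulation: 60 related lines, 8 features, 2 traits.

    Feature 0-2 are heritable (plot h2 = 0.3); the rest are null.  Trait
    'BG' shares genomic covariance with feature 0 (true r_g = -0.6) and
    trait 'WV' is independent of all features.
    """
    nf = 8
    comps = np.tile([0.0, 0.05, 0.0, 0.05, 0.05, 0.85], (nf, 1))
    comps[:3] = [0.3, 0.1, 0.1, 0.1, 0.1, 0.3]
    gen_cov = np.zeros(nf)
    gen_cov[0] = -0.6 * np.sqrt(0.3 * 0.3)
    specs = [
        TraitSpec("BG", [0.3, 0.1, 0.1, 0.1, 0.1, 0.3], gen_cov, np.zeros(nf), 0.02),
        TraitSpec("WV", [0.2, 0.1, 0.1, 0.1, 0.1, 0.4], np.zeros(nf), np.zeros(nf), 0.0),
    ]
    cfg = SimulationConfig(
        n_lines=60,
        n_markers=500,
        reps_per_line=3.0,
        n_batches=6,
        ppm_grid=(1.0, 4.5, nf),
        feature_components=comps,
        trait_specs=specs,
        seed=42,
    )
    markers = simulate_genotypes(cfg)
    design = simulate_design(cfg)
    spectra, traits, truth = simulate_phenotypes(markers, design, cfg)
    filtered, _ = nh.filter_markers(markers)
    rel = nh.build_grm(filtered)
    features, _ = nh.preprocess_spectra(spectra)
    return {
        "config": cfg,
        "markers": markers,
        "design": design,
        "spectra": spectra,
        "traits": traits,
        "truth": truth,
        "grm": rel,
        "features": features,
    }
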