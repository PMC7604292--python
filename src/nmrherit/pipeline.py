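"""End-to-end orchestration: preprocessing, GRM, per-feature heritability
scan, null calibration, and bivariate correlations for significant
features, driven by one config and one master seed.

Stage order: preprocess -> GRM -> univariate REML per feature -> null
cutoff -> significance flags -> bivariate fits (significant features x
traits only) -> trait summaries.  Every artifact is a TSV with a header;
a JSON manifest records seeds, counts and versions so a rerun with the
same config reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, correlation, grm as grm_mod, heritability, preprocess, reml
from .design import read_design_tsv, write_design_tsv
from .synthetic import (
    SimulationConfig,
    TraitSpec,
    default_feature_components,
    simulate_design,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of ``inputs`` (paths) or ``simulation`` must be set."""

    output_dir: str = "nmrherit_out"
    inputs: dict | None = None  # genotypes, design, spectra (TSV paths)
    simulation: dict | None = None  # kwargs of SimulationConfig (+ n_features)
    maf_min: float = 0.05
    missing_max: float = 0.20
    excluded_regions: tuple = preprocess.DEFAULT_EXCLUDED_REGIONS
    align_max_shift: int = 0
    null_replicates: int = 1000
    alpha: float = 0.01
    z_threshold: float = correlation.Z_THRESHOLD_1PCT
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("config must set exactly one of inputs / simulation")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _simulation_config(block: dict) -> SimulationConfig:
    block = dict(block)
    n_features = block.pop("n_features", None)
    trait_specs = block.pop("trait_specs", [])
    seed = block.get("seed", 0)
    cfg = SimulationConfig(**block)
    if cfg.feature_components is None:
        if n_features is None:
            raise ValueError("simulation block needs n_features or feature_components")
        cfg.feature_components = default_feature_components(n_features, seed=seed)
    cfg.trait_specs = [
        ts if isinstance(ts, TraitSpec) else TraitSpec(**ts) for ts in trait_specs
    ]
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    A stage failure aborts with the stage name; artifacts of completed
    stages remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}
    stage = "load"
    try:
        if config.simulation is not None:
            stage = "simulate"
            sim = _simulation_config(config.simulation)
            markers = simulate_genotypes(sim)
            design = simulate_design(sim)
            spectra, traits, truth = simulate_phenotypes(markers, design, sim)
            grm_mod.write_genotypes_tsv(markers, out / "genotypes.tsv")
            write_design_tsv(design, out / "design_traits.tsv", traits)
            from .synthetic import write_ground_truth_tsv

            write_ground_truth_tsv(truth, out / "ground_truth.tsv")
        else:
            markers = grm_mod.read_genotypes_tsv(config.inputs["genotypes"]) \
                if not str(config.inputs["genotypes"]).endswith(".vcf") \
                else grm_mod.read_genotypes_vcf(config.inputs["genotypes"])
            design, traits = read_design_tsv(config.inputs["design"])
            spectra = preprocess.read_spectra_tsv(config.inputs["spectra"])
        manifest["stages"].append(stage)
        manifest["n_plots"] = design.n_plots
        manifest["n_lines"] = int(design.table["line"].nunique())
        manifest["n_environments"] = design.n_environments()
        manifest["mean_replicates"] = round(design.mean_replicates(), 2)

        stage = "preprocess"
        features, prep_report = preprocess.preprocess_spectra(
            spectra, regions=config.excluded_regions, max_shift=config.align_max_shift
        )
        preprocess.write_preprocess_sidecar(prep_report, out / "preprocess.json")
        manifest["stages"].append(stage)
        manifest["n_features"] = features.n_features

        stage = "grm"
        filtered, qc_report = grm_mod.filter_markers(
            markers, config.maf_min, config.missing_max
        )
        relationship = grm_mod.build_grm(filtered)
        grm_mod.write_grm_tsv(relationship, out / "grm.tsv")
        manifest["stages"].append(stage)
        manifest["marker_qc"] = qc_report
        manifest["g_bar"] = round(relationship.g_bar, 6)

        stage = "h2scan"
        order = {p: i for i, p in enumerate(design.plot_ids)}
        rows = np.array([order[p] for p in features.plot_ids])
        if len(rows) != design.n_plots:
            raise ValueError("spectra plots do not cover the design")
        template = reml.build_design(design, relationship, np.zeros(design.n_plots))
        h2_results = []
        for f in range(features.n_features):
            y = np.full(design.n_plots, np.nan)
            y[rows] = features.values[:, f]
            vc = reml.reml_fit(template.with_response(y[template.plot_index]))
            h2_results.append(
                heritability.compute_h2(vc, relationship.g_bar, features.feature_ids()[f])
            )
        manifest["stages"].append(stage)

        stage = "nullcut"
        null = heritability.null_cutoff(
            design, relationship, n_replicates=config.null_replicates,
            alpha=config.alpha, seed=config.seed, model=template,
        )
        heritability.write_null_tsv(null, out / "null_h2.tsv", out / "null_h2.json")
        manifest["stages"].append(stage)
        manifest["null_cutoff"] = null.cutoff

        stage = "significance"
        h2_results, sig_summary = heritability.flag_significant(h2_results, null)
        heritability.write_results_tsv(h2_results, out / "heritability.tsv")
        manifest["stages"].append(stage)
        manifest["significance"] = sig_summary

        stage = "corr"
        trait_names = list(traits.columns)
        pair_results = []
        significant = [r for r in h2_results if r.significant]
        for r in significant:
            f = [i for i, fid in enumerate(features.feature_ids()) if fid == r.feature_id][0]
            yf = np.full(design.n_plots, np.nan)
            yf[rows] = features.values[:, f]
            for tname in trait_names:
                yt = traits.reindex(design.plot_ids)[tname].to_numpy(float)
                model = reml.build_bivariate(design, relationship, yf, yt)
                fit = reml.reml_fit_bivariate(model)
                pair_results.append(
                    correlation.correlation_from_fit(
                        fit, relationship.g_bar, r.feature_id, tname
                    )
                )
        if pair_results:
            correlation.results_to_frame(pair_results, config.z_threshold).to_csv(
                out / "correlations.tsv", sep="\t", index=False, float_format="%.8g"
            )
        summaries = [
            correlation.summarize_trait(pair_results, t, config.z_threshold)
            for t in trait_names
        ]
        pd.DataFrame(summaries).to_csv(
            out / "trait_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if trait_names:
            correlation.compute_descriptives(traits).to_csv(
                out / "trait_descriptives.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
        manifest["stages"].append(stage)
        manifest["n_pairs"] = len(pair_results)
        manifest["pairs_expected"] = len(significant) * len(trait_names)

        if config.make_plots:
            stage = "report"
            _plots(h2_results, null, pair_results, out)
            manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _plots(h2_results, null, pair_results, out: Path) -> None:
    """Histogram exports of the h2 scan and correlation distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.hist([r.h2 for r in h2_results], bins=30, color="tab:red", alpha=0.7)
    ax.axvline(null.cutoff, ls="--", color="k", label=f"cutoff {null.cutoff:.3f}")
    ax.set_xlabel("plot-level genomic heritability")
    ax.set_ylabel("features")
    ax.legend()
    fig.savefig(out / "h2_hist.png", dpi=120)
    plt.close(fig)
    rg = [p.r_g.value for p in pair_results if p.r_g.defined]
    if rg:
        fig, ax = plt.subplots()
        ax.hist(rg, bins=30, color="tab:blue", alpha=0.7)
        ax.set_xlabel("additive genetic correlation")
        ax.set_ylabel("feature-trait pairs")
        fig.savefig(out / "rg_hist.png", dpi=120)
        plt.close(fig)
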