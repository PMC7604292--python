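"""Synthetic genotypes, field designs, spectra-like feature tables and
trait phenotypes with known ground truth.

The generator emulates the structure of a multi-environment malting-barley
breeding trial: a few hundred related inbred lines (founder crossing with
several selfing generations, so the genomic relationship matrix has
non-trivial off-diagonals), plots laid out over location x year
environments with trials and malting batches, bucketed NMR-like spectra
whose signal component follows the plot-level mixed model, and quality
traits sharing genomic and residual covariance with chosen features.

Defaults mirror the motivating study's design: 565 lines, 3,889 SNPs with
MAF >= 5%, 2 locations x 3 years, ~4.65 plots per line (2,628 plots),
spectra on a 0.70-9.00 ppm grid, and feature heritabilities in [0, ~0.4].
Every draw flows from one master seed through named substreams, so output
is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import grm as grm_mod
from .design import PlotDesign
from .grm import MarkerMatrix
from .preprocess import SpectrumSet

#: component order used throughout (residual last)
COMPONENT_NAMES = ("g", "l", "ig", "il", "t", "e")

_STREAMS = {"genotypes": 1, "design": 2, "features": 3, "traits": 4, "noise": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class TraitSpec:
    """One quality trait: its six variance components plus its genomic and
    residual covariances with each feature."""

    name: str
    components: np.ndarray  # (6,) in COMPONENT_NAMES order
    feature_gen_cov: np.ndarray  # (n_features,)
    feature_res_cov: np.ndarray  # (n_features,)
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, float)
        self.feature_gen_cov = np.asarray(self.feature_gen_cov, float)
        self.feature_res_cov = np.asarray(self.feature_res_cov, float)
        if self.components.shape != (6,) or (self.components < 0).any():
            raise ValueError(f"trait {self.name}: need 6 nonnegative variances")


@dataclass
class SimulationConfig:
    """Study-design constants and ground-truth dispersion parameters."""

    n_lines: int = 565
    n_markers: int = 3889
    maf_range: tuple = (0.05, 0.5)
    n_locations: int = 2
    n_years: int = 3
    trials_per_env: int = 2
    reps_per_line: float = 4.65
    n_plots: int | None = None  # overrides n_lines * reps_per_line when set
    n_batches: int = 28  # ~96-well malting batches for the default plot count
    ppm_grid: tuple = (0.70, 9.00, 24018)
    n_founders: int = 16
    selfing_generations: int = 4
    marker_missing_rate: float = 0.0
    related: bool = True
    feature_components: np.ndarray | None = None  # (n_features, 6)
    trait_specs: list = field(default_factory=list)
    cell_effect_sd: float = 0.5  # fixed location x year x trial effects
    baseline_scale: float = 10.0  # spectra baseline in feature-SD units
    dilution_sd: float = 0.1  # log-normal per-plot dilution (removed by PQN)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_lines < 1 or self.n_markers < 1:
            raise ValueError("need n_lines >= 1 and n_markers >= 1")
        if self.reps_per_line <= 0:
            raise ValueError("reps_per_line must be positive")
        if self.feature_components is not None:
            fc = np.asarray(self.feature_components, float)
            if fc.ndim != 2 or fc.shape[1] != 6 or (fc < 0).any():
                raise ValueError("feature_components must be (n_features, 6), nonnegative")
            self.feature_components = fc

    @property
    def n_features(self) -> int:
        if self.feature_components is None:
            return int(self.ppm_grid[2])
        return self.feature_components.shape[0]

    def total_plots(self) -> int:
        return self.n_plots if self.n_plots is not None else round(
            self.n_lines * self.reps_per_line
        )


def default_feature_components(
    n_features: int, seed: int = 0, h2_max: float = 0.4, frac_null: float = 0.6
) -> np.ndarray:
    """Per-feature true components with total variance 1: a fraction of
    near-null features and the rest with plot heritability up to h2_max."""
    rng = np.random.default_rng([seed, 97])
    comps = np.zeros((n_features, 6))
    null = rng.random(n_features) < frac_null
    h2 = np.where(null, 0.0, rng.uniform(0.02, h2_max, n_features))
    comps[:, 0] = h2
    for j in (1, 2, 3, 4):  # l, ig, il, t share a modest slice
        comps[:, j] = 0.05
    comps[:, 5] = 1.0 - comps[:, :5].sum(axis=1)
    if (comps[:, 5] <= 0).any():
        raise ValueError("h2_max too large for unit total variance")
    return comps


@dataclass
class GroundTruth:
    """Realized effects and true population parameters of one simulation."""

    feature_components: np.ndarray  # (n_features, 6)
    trait_components: np.ndarray  # (n_traits, 6)
    g_bar: float
    true_h2: np.ndarray  # per feature, Gbar sigma_g^2 / sigma_P^2
    true_r_g: np.ndarray  # (n_traits, n_features)
    true_r_p: np.ndarray  # (n_traits, n_features)
    line_genomic_feature: np.ndarray  # (n_lines, n_features)
    line_genomic_trait: np.ndarray  # (n_lines, n_traits)
    env_interaction_feature: np.ndarray  # (n_env, n_lines, n_features)
    batch_effects: np.ndarray  # (n_batches, n_features + n_traits)

    def sigma_p2(self, components: np.ndarray) -> np.ndarray:
        # components are plot-level variances, so sigma_P^2 is their plain sum
        return np.asarray(components, float).sum(axis=-1)


# ------------------------------------------------------------- genotypes


def simulate_genotypes(config: SimulationConfig) -> MarkerMatrix:
    """Dosage matrix in {0,1,2} (missing optional) for related inbred lines.

    Founders are drawn in Hardy-Weinberg proportions at per-marker allele
    frequencies from ``maf_range``; each line descends from a founder cross
    followed by recombination-free selfing generations, which induces
    off-diagonal genomic relatedness.  With ``related=False`` every line is
    an independent Hardy-Weinberg draw (useful as a contrast).
    """
    if config.n_lines < 2:
        raise ValueError("genotype simulation needs n_lines >= 2")
    rng = _rng(config.seed, "genotypes")
    m = config.n_markers
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - p, p)

    if config.related:
        founders = (rng.random((config.n_founders, m, 2)) < p[None, :, None]).astype(
            np.int8
        )
        dams = rng.integers(0, config.n_founders, config.n_lines)
        sires = rng.integers(0, config.n_founders, config.n_lines)
        alleles = np.empty((config.n_lines, m, 2), dtype=np.int8)
        pick1 = rng.integers(0, 2, (config.n_lines, m))
        pick2 = rng.integers(0, 2, (config.n_lines, m))
        cols = np.arange(m)[None, :]
        alleles[:, :, 0] = founders[dams[:, None], cols, pick1]
        alleles[:, :, 1] = founders[sires[:, None], cols, pick2]
        for _ in range(config.selfing_generations):
            pick1 = rng.integers(0, 2, (config.n_lines, m))
            pick2 = rng.integers(0, 2, (config.n_lines, m))
            rows = np.arange(config.n_lines)[:, None]
            cols = np.arange(m)[None, :]
            new0 = alleles[rows, cols, pick1]
            new1 = alleles[rows, cols, pick2]
            alleles[:, :, 0], alleles[:, :, 1] = new0, new1
        dos = alleles.sum(axis=2).astype(float)
    else:
        dos = (
            (rng.random((config.n_lines, m)) < p).astype(float)
            + (rng.random((config.n_lines, m)) < p).astype(float)
        )

    if config.marker_missing_rate > 0:
        mask = rng.random(dos.shape) < config.marker_missing_rate
        dos[mask] = np.nan
    line_ids = np.array([f"L{i:04d}" for i in range(config.n_lines)])
    marker_ids = np.array([f"M{j:05d}" for j in range(m)])
    return MarkerMatrix(line_ids, marker_ids, dos)


# ----------------------------------------------------------------- design


def simulate_design(config: SimulationConfig) -> PlotDesign:
    """Field layout: lines split into year cohorts, grown in every location
    of their year, trials nested in each environment, consecutive plots
    grouped into equal-size malting batches."""
    n_plots = config.total_plots()
    n_lines = config.n_lines
    if n_plots < n_lines:
        raise ValueError("fewer plots than lines; every line needs >= 1 plot")
    n_env = config.n_locations * config.n_years
    if config.trials_per_env * n_env > n_plots:
        raise ValueError("more trials than plots")

    base, extra = divmod(n_plots, n_lines)
    reps = np.full(n_lines, base)
    reps[:extra] += 1

    years = [f"Y{y + 1}" for y in range(config.n_years)]
    locs = [f"Loc{l + 1}" for l in range(config.n_locations)]
    line_year = [years[i % config.n_years] for i in range(n_lines)]

    rows = []
    for i in range(n_lines):
        for r in range(reps[i]):
            rows.append(
                {"line": f"L{i:04d}", "location": locs[r % config.n_locations],
                 "year": line_year[i]}
            )
    df = pd.DataFrame(rows)
    # trials nested in each location x year environment, filled in order
    df["trial"] = ""
    for (_, _), idx in df.groupby(["location", "year"]).groups.items():
        idx = np.sort(np.asarray(idx))
        size = int(np.ceil(len(idx) / config.trials_per_env))
        for j, start in enumerate(range(0, len(idx), size)):
            df.loc[idx[start : start + size], "trial"] = f"T{j + 1}"
    df = df.sort_values(["year", "location", "trial", "line"], kind="stable")
    df = df.reset_index(drop=True)
    batch_size = int(np.ceil(len(df) / config.n_batches))
    df["batch"] = [f"B{i // batch_size + 1:03d}" for i in range(len(df))]
    df.insert(0, "plot", [f"P{i:05d}" for i in range(len(df))])
    return PlotDesign(df)


# -------------------------------------------------------------- phenotypes


def _draw_effects(
    rng: np.random.Generator,
    Lg: np.ndarray,
    design: PlotDesign,
    line_code: np.ndarray,
    env_code: np.ndarray,
    batch_code: np.ndarray,
    cell_code: np.ndarray,
    comps: np.ndarray,
    cell_effect_sd: float,
    genomic_line: np.ndarray | None = None,
    resid: np.ndarray | None = None,
):
    """Realize one response on all plots from its six components.

    ``genomic_line`` / ``resid`` override the corresponding draws (used to
    impose genetic and residual covariance between responses).  All six
    components are *plot-level* variances: genomic effects are drawn with
    covariance (G / Gbar) * sigma^2, so the average variance of a plot's
    genomic value equals sigma_g^2 whatever the inbreeding level of the
    simulated population, and the true plot heritability is simply
    sigma_g^2 over the plain sum of the six components.  ``Lg`` must be the
    factor of G / Gbar.  Returns (values, realized effect arrays).
    """
    n_lines = Lg.shape[0]
    n_env = env_code.max() + 1
    n_plots = design.n_plots
    sg, sl, sig_, sil, st, se = comps

    g = genomic_line if genomic_line is not None else (
        Lg @ rng.standard_normal(n_lines) * np.sqrt(sg)
    )
    l = rng.standard_normal(n_lines) * np.sqrt(sl)
    ig = np.stack(
        [Lg @ rng.standard_normal(n_lines) * np.sqrt(sig_) for _ in range(n_env)]
    )
    il = rng.standard_normal((n_env, n_lines)) * np.sqrt(sil)
    t = rng.standard_normal(batch_code.max() + 1) * np.sqrt(st)
    e = resid if resid is not None else rng.standard_normal(n_plots) * np.sqrt(se)
    b = rng.standard_normal(cell_code.max() + 1) * cell_effect_sd
    y = (
        b[cell_code]
        + g[line_code]
        + l[line_code]
        + ig[env_code, line_code]
        + il[env_code, line_code]
        + t[batch_code]
        + e
    )
    return y, {"g": g, "l": l, "ig": ig, "il": il, "t": t, "e": e}


def simulate_phenotypes(
    markers: MarkerMatrix, design: PlotDesign, config: SimulationConfig
) -> tuple[SpectrumSet, pd.DataFrame, GroundTruth]:
    """Spectra-like bucket table, trait table and ground truth.

    Feature signal follows the plot-level mixed model with the per-feature
    true components; traits share genomic and residual covariance with
    features per ``trait_specs`` (a trait's genomic effect is a linear
    combination of feature genomic effects plus an independent remainder,
    which reproduces the requested covariances when feature genomic effects
    are mutually independent).  All configured variances and covariances
    are on the plot scale (genomic draws use G / Gbar, see
    :func:`_draw_effects`), so true h2 = sigma_g^2 / sum(components) and
    the REML estimate of Gbar*sigma_g^2 targets the configured sigma_g^2.
    Bucket intensities add a positive baseline and a per-plot
    multiplicative dilution, both removed again by PQN and standardization
    downstream.
    """
    if config.feature_components is None:
        raise ValueError("config.feature_components must be set (see "
                         "default_feature_components)")
    comps_f = config.feature_components
    n_features = comps_f.shape[0]

    relationship = grm_mod.build_grm(grm_mod.impute_missing(markers))
    order = {l: i for i, l in enumerate(relationship.line_ids)}
    line_code = np.array([order[l] for l in design.line_ids])
    env = design.environment().to_numpy()
    _, env_code = np.unique(env, return_inverse=True)
    _, batch_code = np.unique(design.table["batch"].to_numpy(), return_inverse=True)
    _, cell_code = np.unique(design.cell().to_numpy(), return_inverse=True)
    g_bar = relationship.g_bar
    Lg = relationship.factor(clip=0.0) / np.sqrt(g_bar)  # factor of G / Gbar
    n_lines = len(relationship.line_ids)
    n_env = env_code.max() + 1

    rng_f = _rng(config.seed, "features")
    Y = np.empty((design.n_plots, n_features))
    g_lines = np.empty((n_lines, n_features))
    e_resid = np.empty((design.n_plots, n_features))
    ig_all = np.empty((n_env, n_lines, n_features))
    t_all = []
    for f in range(n_features):
        y, eff = _draw_effects(
            rng_f, Lg, design, line_code, env_code, batch_code, cell_code,
            comps_f[f], config.cell_effect_sd,
        )
        Y[:, f] = y
        g_lines[:, f] = eff["g"]
        e_resid[:, f] = eff["e"]
        ig_all[:, :, f] = eff["ig"]
        t_all.append(eff["t"])

    # traits with imposed genomic / residual covariances
    specs = config.trait_specs
    rng_t = _rng(config.seed, "traits")
    n_traits = len(specs)
    traits = pd.DataFrame(index=design.plot_ids)
    comps_t = np.zeros((n_traits, 6))
    g_traits = np.zeros((n_lines, n_traits))
    true_rg = np.zeros((n_traits, n_features))
    true_rp = np.zeros((n_traits, n_features))
    sp2_f = comps_f.sum(axis=1)
    for k, spec in enumerate(specs):
        if len(spec.feature_gen_cov) != n_features or len(spec.feature_res_cov) != n_features:
            raise ValueError(f"trait {spec.name}: covariance vectors must have "
                             f"{n_features} entries")
        comps_t[k] = spec.components
        sg_t, se_t = spec.components[0], spec.components[5]
        for nm, cov, var_f, var_t in (
            ("genomic", spec.feature_gen_cov, comps_f[:, 0], sg_t),
            ("residual", spec.feature_res_cov, comps_f[:, 5], se_t),
        ):
            bad = np.flatnonzero((cov != 0) & (var_f == 0))
            if bad.size:
                raise ValueError(
                    f"trait {spec.name}: {nm} block with feature {bad[0]} is not PSD "
                    "(covariance against a zero variance)"
                )
            if ((cov**2) > var_f * var_t + 1e-12).any():
                raise ValueError(
                    f"trait {spec.name}: a {nm} 2x2 block is not positive semi-definite"
                )
        wg = np.divide(spec.feature_gen_cov, comps_f[:, 0],
                       out=np.zeros(n_features), where=comps_f[:, 0] > 0)
        rem_g = sg_t - float(wg @ spec.feature_gen_cov)
        we = np.divide(spec.feature_res_cov, comps_f[:, 5],
                       out=np.zeros(n_features), where=comps_f[:, 5] > 0)
        rem_e = se_t - float(we @ spec.feature_res_cov)
        if rem_g < -1e-10 or rem_e < -1e-10:
            raise ValueError(
                f"trait {spec.name}: requested covariances exceed the trait's "
                "own variance (joint covariance matrix not PSD)"
            )
        g_t = g_lines @ wg + Lg @ rng_t.standard_normal(n_lines) * np.sqrt(max(rem_g, 0.0))
        e_t = e_resid @ we + rng_t.standard_normal(design.n_plots) * np.sqrt(max(rem_e, 0.0))
        y_t, _ = _draw_effects(
            rng_t, Lg, design, line_code, env_code, batch_code, cell_code,
            spec.components, config.cell_effect_sd,
            genomic_line=g_t, resid=e_t,
        )
        if spec.missing_rate > 0:
            miss = rng_t.random(design.n_plots) < spec.missing_rate
            y_t = np.where(miss, np.nan, y_t)
        traits[spec.name] = y_t
        g_traits[:, k] = g_t
        sp2_t = float(spec.components.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rg = spec.feature_gen_cov / np.sqrt(comps_f[:, 0] * sg_t)
            rp = (spec.feature_gen_cov + spec.feature_res_cov) / np.sqrt(
                sp2_f * sp2_t
            )
        true_rg[k] = np.where(np.isfinite(rg), rg, np.nan)
        true_rp[k] = np.where(np.isfinite(rp), rp, np.nan)

    # wrap features into a spectra-like bucket table
    lo, hi, _ = config.ppm_grid
    ppm = np.linspace(lo, hi, n_features)
    rng_n = _rng(config.seed, "noise")
    sd_f = np.sqrt(np.maximum(sp2_f, 1e-12))
    baseline = config.baseline_scale * sd_f
    dilution = np.exp(rng_n.normal(0.0, config.dilution_sd, design.n_plots))
    intensities = dilution[:, None] * (baseline[None, :] + Y)
    spectra = SpectrumSet(design.plot_ids, ppm, intensities)

    truth = GroundTruth(
        feature_components=comps_f,
        trait_components=comps_t,
        g_bar=g_bar,
        true_h2=comps_f[:, 0] / sp2_f,
        true_r_g=true_rg,
        true_r_p=true_rp,
        line_genomic_feature=g_lines,
        line_genomic_trait=g_traits,
        env_interaction_feature=ig_all,
        batch_effects=np.stack(t_all) if t_all else np.empty((0, 0)),
    )
    return spectra, traits, truth


def write_ground_truth_tsv(truth: GroundTruth, path) -> None:
    rows = []
    for f in range(truth.feature_components.shape[0]):
        row = {"feature": f}
        row.update(
            {f"true_var_{n}": truth.feature_components[f, j]
             for j, n in enumerate(COMPONENT_NAMES)}
        )
        row["true_h2"] = truth.true_h2[f]
        for k in range(truth.true_r_g.shape[0]):
            row[f"true_r_g_trait{k}"] = truth.true_r_g[k, f]
            row[f"true_r_p_trait{k}"] = truth.true_r_p[k, f]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")
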