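"""Plot-level genomic heritability and its simulation-based null calibration.

The phenotypic variance of a single-plot measurement decomposes as

    sigma_P^2 = Gbar*sigma_g^2 + sigma_l^2 + Gbar*sigma_ig^2
                + sigma_il^2 + sigma_t^2 + sigma_e^2

with Gbar the average diagonal of the genomic relationship matrix, and the
plot-level genomic heritability is h2 = Gbar*sigma_g^2 / sigma_P^2 (the
heritability of one plot, not of a line mean).  Relative variance
components (RVCs) are each component's Gbar-weighted share of sigma_P^2.

Because h2 estimates pile up at the zero boundary, significance is
calibrated empirically: standard-normal responses are simulated on the
exact experimental design (all components null except the residual), the
model is refitted per replicate, and the upper alpha quantile of the
resulting null h2 values is the significance cutoff.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PlotDesign
from .grm import GenomicRelationship
from .reml import ModelSpec, RemlError, VarianceComponents, build_design, reml_fit

logger = logging.getLogger(__name__)

#: Gbar applies to the genomic terms only
_GENOMIC_TERMS = ("g", "ig")


def _weights(term_names, g_bar: float) -> np.ndarray:
    return np.array([g_bar if t in _GENOMIC_TERMS else 1.0 for t in term_names])


@dataclass
class HeritabilityResult:
    feature_id: str
    components: dict
    sigma_p2: float
    h2: float
    se: float
    rvc: dict
    significant: bool | None = None
    converged: bool = True

    def to_row(self) -> dict:
        row = {"feature": self.feature_id}
        row.update({f"var_{k}": v for k, v in self.components.items()})
        row.update(
            sigma_p2=self.sigma_p2, h2=self.h2, h2_se=self.se,
            significant=self.significant,
        )
        row.update({f"rvc_{k}": v for k, v in self.rvc.items()})
        return row


def compute_rvc(components: VarianceComponents | np.ndarray, g_bar: float,
                term_names=None) -> dict:
    """Relative variance components: Gbar-weighted share of each term in
    sigma_P^2 (they sum to 1)."""
    if isinstance(components, VarianceComponents):
        term_names = components.term_names
        est = components.estimates
    else:
        est = np.asarray(components, float)
        if term_names is None:
            raise ValueError("term_names required with a raw estimate vector")
    w = _weights(term_names, g_bar)
    weighted = w * est
    total = float(weighted.sum())
    if total <= 0.0:
        raise ValueError("sigma_P^2 is zero; RVCs undefined")
    return {t: float(v / total) for t, v in zip(term_names, weighted)}


def compute_h2(
    components: VarianceComponents, g_bar: float, feature_id: str = ""
) -> HeritabilityResult:
    """Plot-level genomic heritability with a delta-method standard error.

    The SE propagates the inverse-AI covariance of the component estimates
    through h2 = Gbar*sigma_g^2 / sigma_P^2 (an extension beyond the core
    point estimate, useful for diagnostics).
    """
    est = components.estimates
    if not np.isfinite(est).all():
        raise ValueError("non-finite variance components")
    names = components.term_names
    w = _weights(names, g_bar)
    sigma_p2 = float(w @ est)
    if sigma_p2 <= 0.0:
        raise ValueError("sigma_P^2 is zero; heritability undefined")
    gi = names.index("g")
    h2 = g_bar * est[gi] / sigma_p2
    # delta method: dh/dtheta_k = [k==g]*Gbar/sigma_P2 - Gbar*sigma_g2*w_k/sigma_P2^2
    grad = -g_bar * est[gi] * w / sigma_p2**2
    grad[gi] += g_bar / sigma_p2
    se = float(np.sqrt(max(grad @ components.cov @ grad, 0.0)))
    return HeritabilityResult(
        feature_id=feature_id,
        components=components.as_dict(),
        sigma_p2=sigma_p2,
        h2=float(h2),
        se=se,
        rvc=compute_rvc(components, g_bar),
        converged=components.converged,
    )


@dataclass
class NullDistribution:
    """Empirical null distribution of h2 on a fixed experimental design."""

    h2_values: np.ndarray
    cutoff: float
    alpha: float
    seed: int
    n_failed: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.h2_values)

    def to_json(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


def null_cutoff(
    design: PlotDesign,
    grm: GenomicRelationship,
    n_replicates: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    model: ModelSpec | None = None,
) -> NullDistribution:
    """Simulate the null distribution of h2 on the exact design.

    Each replicate draws i.i.d. standard-normal responses for all plots
    (only residual variation under the null), refits the full model and
    records h2; the cutoff is the empirical upper-``alpha`` quantile
    (linear interpolation).  A failed replicate fit is retried with the
    next substream; more than 5% failures aborts.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if model is None:
        model = build_design(design, grm, np.zeros(design.n_plots))
    rng_root = np.random.default_rng(seed)
    streams = rng_root.spawn(n_replicates + max(100, n_replicates // 2))
    h2s = np.empty(n_replicates)
    failed = 0
    next_stream = 0
    for i in range(n_replicates):
        while True:
            if next_stream >= len(streams):
                raise RemlError("exhausted retry streams in null simulation")
            rng = streams[next_stream]
            next_stream += 1
            y = rng.standard_normal(model.n)
            try:
                vc = reml_fit(model.with_response(y))
            except RemlError:
                failed += 1
                if failed > 0.05 * n_replicates:
                    raise RemlError(
                        f"more than 5% of null replicates failed ({failed})"
                    )
                continue
            h2s[i] = compute_h2(vc, grm.g_bar).h2
            break
    cutoff = float(np.quantile(h2s, 1.0 - alpha))
    logger.info(
        "null distribution from %d replicates: cutoff(h2, alpha=%g) = %.5f",
        n_replicates, alpha, cutoff,
    )
    return NullDistribution(h2s, cutoff, alpha, seed, failed)


def flag_significant(
    results: list[HeritabilityResult], null: NullDistribution
) -> tuple[list[HeritabilityResult], dict]:
    """Flag features with h2 strictly above the null cutoff; a value exactly
    at the cutoff is not significant."""
    flagged = 0
    for r in results:
        r.significant = r.h2 > null.cutoff
        flagged += int(r.significant)
    total = len(results)
    pct = 100.0 * flagged / total if total else 0.0
    summary = {"n_significant": flagged, "n_total": total, "pct_significant": round(pct, 2)}
    logger.info(
        "%d of %d features significant (%.2f%%) at cutoff %.5f",
        flagged, total, pct, null.cutoff,
    )
    return results, summary


# ---------------------------------------------------------------- I/O

def results_to_frame(results: list[HeritabilityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def write_results_tsv(results: list[HeritabilityResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_null_tsv(null: NullDistribution, path, meta_path=None) -> None:
    pd.DataFrame({"h2_null": null.h2_values}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump(null.to_json(), fh, indent=2)
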