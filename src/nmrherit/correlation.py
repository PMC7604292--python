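"""Genetic and phenotypic correlations between features and quality traits.

From a bivariate fit the additive genetic correlation is

    r_g = sigma_g12 / sqrt(sigma_g1^2 * sigma_g2^2)

and the phenotypic correlation sums all covariance components with the
same Gbar weighting as the univariate phenotypic-variance identity:

    r_p = (Gbar*c_g + c_l + Gbar*c_ig + c_il + c_t + c_e)
          / sqrt(sigma_P1^2 * sigma_P2^2).

Standard errors come from the delta method on the inverse-AI parameter
covariance, and each estimate is tested with z = estimate/SE against the
two-sided 1% normal threshold |z| > 2.326.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import _weights
from .reml import BivariateComponents

#: two-sided 1% normal threshold, Phi^-1(0.99) to three decimals
Z_THRESHOLD_1PCT = 2.326


def z_threshold(alpha_per_side: float = 0.01, decimals: int = 3) -> float:
    """Normal quantile for a test at ``alpha_per_side`` on each side."""
    return float(np.round(stats.norm.ppf(1.0 - alpha_per_side), decimals))


def z_test(estimate: float, se: float, threshold: float = Z_THRESHOLD_1PCT) -> bool:
    """Significant iff |estimate/se| strictly exceeds the threshold."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return abs(estimate / se) > threshold


@dataclass
class CorrEstimate:
    value: float | None
    se: float | None
    boundary: bool = False
    reason: str | None = None  # set when the correlation is undefined

    @property
    def defined(self) -> bool:
        return self.reason is None

    @property
    def z(self) -> float | None:
        if not self.defined or self.se is None or self.se <= 0:
            return None
        return self.value / self.se

    def significant(self, threshold: float = Z_THRESHOLD_1PCT) -> bool | None:
        z = self.z
        return None if z is None else abs(z) > threshold


def _clamped_ratio(c: float, v1: float, v2: float, grad: np.ndarray, cov: np.ndarray):
    r = c / np.sqrt(v1 * v2)
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    boundary = abs(r) >= 1.0 - 1e-10
    return CorrEstimate(float(np.clip(r, -1.0, 1.0)), se, boundary=boundary)


def genetic_correlation(blocks: BivariateComponents) -> CorrEstimate:
    """Additive genetic correlation from the genomic 2x2 block.

    Undefined (reason-coded, never silently zero) when either genomic
    variance is pinned at the zero boundary.
    """
    B = blocks.block("g")
    v1, c, v2 = B[0, 0], B[0, 1], B[1, 1]
    if v1 <= 0.0 or v2 <= 0.0:
        return CorrEstimate(None, None, reason="genomic variance at zero boundary")
    # d r / d(v1, c, v2) for r = c / sqrt(v1 v2)
    s = np.sqrt(v1 * v2)
    grad3 = np.array([-c / (2.0 * v1 * s), 1.0 / s, -c / (2.0 * v2 * s)])
    sl = blocks.param_slice("g")
    grad = np.zeros(blocks.cov.shape[0])
    grad[sl] = grad3
    return _clamped_ratio(c, v1, v2, grad, blocks.cov)


def phenotypic_correlation(blocks: BivariateComponents, g_bar: float) -> CorrEstimate:
    """Phenotypic correlation from the Gbar-weighted sum of all covariance
    blocks over the product of the two phenotypic standard deviations."""
    w = _weights(blocks.term_names, g_bar)
    v1 = float(w @ blocks.blocks[:, 0, 0])
    v2 = float(w @ blocks.blocks[:, 1, 1])
    c = float(w @ blocks.blocks[:, 0, 1])
    if v1 <= 0.0 or v2 <= 0.0:
        return CorrEstimate(None, None, reason="phenotypic variance at zero boundary")
    s = np.sqrt(v1 * v2)
    npar = blocks.cov.shape[0]
    grad = np.zeros(npar)
    for k, wk in enumerate(w):
        grad[3 * k] = -c * wk / (2.0 * v1 * s)      # d/d v1_k
        grad[3 * k + 1] = wk / s                    # d/d c_k
        grad[3 * k + 2] = -c * wk / (2.0 * v2 * s)  # d/d v2_k
    return _clamped_ratio(c, v1, v2, grad, blocks.cov)


@dataclass
class CorrelationResult:
    feature_id: str
    trait_id: str
    r_g: CorrEstimate
    r_p: CorrEstimate

    def to_row(self, threshold: float = Z_THRESHOLD_1PCT) -> dict:
        def cols(prefix, est: CorrEstimate):
            return {
                prefix: est.value,
                f"{prefix}_se": est.se,
                f"{prefix}_z": est.z,
                f"{prefix}_sig": est.significant(threshold),
                f"{prefix}_boundary": est.boundary if est.defined else None,
                f"{prefix}_reason": est.reason,
            }

        row = {"feature": self.feature_id, "trait": self.trait_id}
        row.update(cols("r_g", self.r_g))
        row.update(cols("r_p", self.r_p))
        return row


def correlation_from_fit(
    blocks: BivariateComponents, g_bar: float, feature_id: str, trait_id: str
) -> CorrelationResult:
    return CorrelationResult(
        feature_id=feature_id,
        trait_id=trait_id,
        r_g=genetic_correlation(blocks),
        r_p=phenotypic_correlation(blocks, g_bar),
    )


def summarize_trait(
    results: list[CorrelationResult],
    trait_id: str,
    threshold: float = Z_THRESHOLD_1PCT,
) -> dict:
    """Per-trait range of r_g / r_p and percentage significant.

    Percentages are computed over defined estimates only (undefined,
    reason-coded correlations are excluded and their count reported);
    row order does not matter.
    """
    rows = [r for r in results if r.trait_id == trait_id]
    out: dict = {"trait": trait_id, "n_pairs": len(rows)}
    for key in ("r_g", "r_p"):
        ests = [getattr(r, key) for r in rows]
        defined = [e for e in ests if e.defined]
        out[f"{key}_n_defined"] = len(defined)
        out[f"{key}_n_undefined"] = len(ests) - len(defined)
        if defined:
            vals = np.array([e.value for e in defined])
            sig = [e.significant(threshold) for e in defined]
            n_sig = sum(bool(s) for s in sig if s is not None)
            out[f"{key}_min"] = float(vals.min())
            out[f"{key}_max"] = float(vals.max())
            out[f"{key}_pct_significant"] = round(100.0 * n_sig / len(defined), 2)
        else:
            out[f"{key}_min"] = out[f"{key}_max"] = np.nan
            out[f"{key}_pct_significant"] = np.nan
    return out


def compute_descriptives(traits: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per trait column: record count, mean, SD
    (divisor n-1), min, max and CV = SD/mean*100 (rounded to 2 decimals)."""
    rows = []
    for col in traits.columns:
        x = traits[col].dropna().to_numpy(float)
        if x.size == 0:
            raise ValueError(f"trait {col!r} is entirely missing")
        if x.size < 2:
            raise ValueError(f"trait {col!r} has fewer than 2 records")
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        rows.append(
            {
                "trait": col,
                "n": int(x.size),
                "mean": mean,
                "sd": sd,
                "min": float(x.min()),
                "max": float(x.max()),
                "cv_pct": round(100.0 * sd / mean, 2) if mean != 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(
    results: list[CorrelationResult], threshold: float = Z_THRESHOLD_1PCT
) -> pd.DataFrame:
    return pd.DataFrame([r.to_row(threshold) for r in results])
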