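"""Preprocessing of plot x chemical-shift NMR bucket tables.

The pipeline starts from a frequency-domain bucket table (intensities
integrated over small ppm intervals).  Standard wort-metabolomics
preprocessing is applied: exclusion of the water and reference-standard
regions, probabilistic quotient normalization (PQN) against a median
reference spectrum, segment-wise integer-shift alignment by
cross-correlation, and per-bucket centering/standardization to mean 0 and
standard deviation 1.  The standardized buckets are the metabolomic
features analyzed by the variance-component models.

The ppm grid is stored ascending internally; display order (NMR convention
is descending) is left to writers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default exclusion windows: residual water and the DSS reference standard
DEFAULT_EXCLUDED_REGIONS = ((4.7, 4.9), (-0.2, 0.2))


@dataclass
class SpectrumSet:
    """A set of 1D spectra on a common ppm grid (one row per plot)."""

    plot_ids: np.ndarray
    ppm: np.ndarray
    intensities: np.ndarray  # plots x buckets

    def __post_init__(self) -> None:
        self.plot_ids = np.asarray(self.plot_ids)
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.plot_ids), len(self.ppm)):
            raise ValueError("intensity matrix does not match plot/ppm dimensions")
        if len(set(self.plot_ids.tolist())) != len(self.plot_ids):
            raise ValueError("duplicate plot ids")
        d = np.diff(self.ppm)
        if len(self.ppm) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm grid must be strictly monotone")
        if len(self.ppm) > 1 and d[0] < 0:  # canonical ascending storage
            self.ppm = self.ppm[::-1].copy()
            self.intensities = self.intensities[:, ::-1].copy()

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_buckets(self) -> int:
        return len(self.ppm)


@dataclass
class FeatureMatrix:
    """Standardized plot x feature matrix; feature ids are ppm centers."""

    plot_ids: np.ndarray
    feature_ppm: np.ndarray
    values: np.ndarray
    pre_mean: np.ndarray
    pre_sd: np.ndarray
    dropped_ppm: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_features(self) -> int:
        return len(self.feature_ppm)

    def feature_ids(self) -> list[str]:
        return [f"{p:.6f}" for p in self.feature_ppm]


def exclude_regions(spectra: SpectrumSet, regions=DEFAULT_EXCLUDED_REGIONS) -> SpectrumSet:
    """Remove buckets whose ppm center lies inside any closed interval."""
    keep = np.ones(spectra.n_buckets, dtype=bool)
    for lo, hi in regions:
        if lo > hi:
            raise ValueError(f"region ({lo}, {hi}) is not an ordered pair")
        keep &= ~((spectra.ppm >= lo) & (spectra.ppm <= hi))
    if not keep.any():
        raise ValueError("all buckets removed by region exclusion")
    removed = int((~keep).sum())
    if removed:
        logger.info("excluded %d buckets in %s", removed, list(regions))
    return SpectrumSet(spectra.plot_ids, spectra.ppm[keep], spectra.intensities[:, keep])


def pqn_normalize(spectra: SpectrumSet, reference: np.ndarray | None = None) -> SpectrumSet:
    """Probabilistic quotient normalization.

    Each spectrum is divided by the median of its bucket-wise quotients to a
    reference spectrum (default: the bucket-wise median across plots),
    correcting overall dilution differences.  Quotients at buckets where the
    reference is <= 0 are skipped.
    """
    X = spectra.intensities
    if not np.isfinite(X).all():
        raise ValueError("intensities must be finite for PQN")
    ref = np.median(X, axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (spectra.n_buckets,):
        raise ValueError("reference length does not match bucket count")
    valid = ref > 0
    if not valid.any():
        raise ValueError("reference spectrum has no positive buckets")
    quotients = X[:, valid] / ref[valid]
    factors = np.median(quotients, axis=1)
    bad = ~np.isfinite(factors) | (factors == 0)
    if bad.any():
        raise ValueError(
            f"no valid quotient for plots: {list(spectra.plot_ids[bad][:5])}"
        )
    return SpectrumSet(spectra.plot_ids, spectra.ppm, X / factors[:, None])


def _best_shift(segment: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Integer shift in [-max_shift, max_shift] maximizing the inner product
    of the shifted segment with the reference (edge-value padding).
    Ties break toward the smallest |shift|, then the negative one."""
    best, best_score = None, 0.0
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        score = float(np.dot(_apply_shift(segment, s), ref))
        if best is None or score > best_score + 1e-12 * max(1.0, abs(best_score)):
            best, best_score = s, score
    return best


def _apply_shift(x: np.ndarray, s: int) -> np.ndarray:
    """Shift right by s buckets (left for negative s), padding with edge values."""
    if s == 0:
        return x
    out = np.empty_like(x)
    if s > 0:
        out[s:] = x[:-s]
        out[:s] = x[0]
    else:
        out[:s] = x[-s:]
        out[s:] = x[-1]
    return out


def align_segments(
    spectra: SpectrumSet,
    reference: np.ndarray | None = None,
    segment_bounds=None,
    max_shift: int = 10,
) -> tuple[SpectrumSet, list[dict]]:
    """Segment-wise spectral alignment by integer-shift cross-correlation.

    Each ppm segment of each spectrum is shifted by the integer bucket
    offset (within ±max_shift) that maximizes its cross-correlation with
    the reference segment; vacated positions take the segment's edge value.
    With no segment bounds the whole spectrum is one segment.  Returns the
    aligned spectra and a per-plot record of the applied shifts.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    ref = np.median(spectra.intensities, axis=0) if reference is None else np.asarray(reference, float)
    if segment_bounds is None:
        segs = [(0, spectra.n_buckets)]
    else:
        segs = []
        for lo, hi in segment_bounds:
            mask = (spectra.ppm >= lo) & (spectra.ppm <= hi)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            segs.append((int(idx[0]), int(idx[-1]) + 1))
        segs.sort()
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            if b0 < a1:
                raise ValueError("segments overlap")
    for a, b in segs:
        if b - a < 2 * max_shift + 1:
            raise ValueError(
                f"segment of {b - a} buckets shorter than 2*max_shift+1 = {2 * max_shift + 1}"
            )
    out = spectra.intensities.copy()
    records: list[dict] = []
    for i, pid in enumerate(spectra.plot_ids):
        shifts = []
        for a, b in segs:
            s = 0
            if max_shift > 0:
                s = _best_shift(out[i, a:b], ref[a:b], max_shift)
                out[i, a:b] = _apply_shift(out[i, a:b], s)
            shifts.append(s)
        records.append({"plot": str(pid), "shifts": shifts})
    return SpectrumSet(spectra.plot_ids, spectra.ppm, out), records


def standardize(spectra: SpectrumSet) -> FeatureMatrix:
    """Column-wise (x - mean) / sd with divisor n-1; constant columns are
    dropped with a warning and recorded."""
    if spectra.n_plots < 2:
        raise ValueError("standardization needs at least 2 plots")
    X = spectra.intensities
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant buckets", int((~keep).sum()))
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        plot_ids=spectra.plot_ids,
        feature_ppm=spectra.ppm[keep],
        values=Z,
        pre_mean=mean[keep],
        pre_sd=sd[keep],
        dropped_ppm=spectra.ppm[~keep],
    )


def preprocess_spectra(
    spectra: SpectrumSet,
    regions=DEFAULT_EXCLUDED_REGIONS,
    max_shift: int = 0,
    segment_bounds=None,
) -> tuple[FeatureMatrix, dict]:
    """Full chain: exclusion -> PQN -> (optional) alignment -> standardize.

    Alignment is off by default (max_shift=0) because synthetic bucket
    tables are generated on a common grid; set max_shift > 0 for real
    spectra with chemical-shift drift.
    """
    s = exclude_regions(spectra, regions)
    s = pqn_normalize(s)
    shift_records: list[dict] = []
    if max_shift > 0:
        s, shift_records = align_segments(s, segment_bounds=segment_bounds, max_shift=max_shift)
    fm = standardize(s)
    report = {
        "excluded_regions": [list(r) for r in regions],
        "n_buckets_in": spectra.n_buckets,
        "n_features_out": fm.n_features,
        "dropped_constant": [float(p) for p in fm.dropped_ppm],
        "alignment_max_shift": max_shift,
        "shifts": shift_records,
    }
    return fm, report


# ---------------------------------------------------------------- I/O

def read_spectra_tsv(path) -> SpectrumSet:
    """TSV with a header row of ppm values and one row per plot (first column
    the plot id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SpectrumSet(
        df.index.to_numpy(dtype=str),
        df.columns.to_numpy(dtype=float),
        df.to_numpy(float),
    )


def write_spectra_tsv(spectra: SpectrumSet, path, descending: bool = False) -> None:
    ppm, X = spectra.ppm, spectra.intensities
    if descending:
        ppm, X = ppm[::-1], X[:, ::-1]
    df = pd.DataFrame(X, index=spectra.plot_ids, columns=[f"{p:.6f}" for p in ppm])
    df.index.name = "plot"
    df.to_csv(path, sep="\t", float_format="%.8g")


def write_preprocess_sidecar(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
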