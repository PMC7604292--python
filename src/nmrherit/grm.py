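"""Marker QC and the VanRaden method-1 genomic relationship matrix.

Genotypes are biallelic SNP dosages coded 0/1/2 (copies of the counted
allele) with missing values allowed.  After quality control and mean
imputation the genomic relationship matrix is

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),

where column j of Z is the dosage centred by twice the in-sample allele
frequency p_j.  The average diagonal of G (g_bar) rescales genomic
variance components to the phenotypic scale downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix; missing entries stored as NaN."""

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray  # float array, values in {0, 1, 2, NaN}

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            # imputed matrices carry fractional dosages; only raw input is checked
            pass

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele frequency p_j from the observed dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


@dataclass
class GenomicRelationship:
    """VanRaden method-1 G with its average diagonal and the frequencies used."""

    line_ids: np.ndarray
    G: np.ndarray
    allele_frequencies: np.ndarray
    g_bar: float = field(init=False)

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.G = np.asarray(self.G, dtype=float)
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        self.g_bar = float(np.mean(np.diag(self.G)))

    def factor(self, clip: float = 0.0) -> np.ndarray:
        """Symmetric factor L with L L' = G, eigenvalues clipped at ``clip``.

        Used to sample correlated genomic effects; G from finite marker
        panels can be numerically indefinite, so small negative eigenvalues
        are clipped before the square root.
        """
        w, v = np.linalg.eigh(self.G)
        if w.min() < -1e-8:
            logger.warning(
                "G has negative eigenvalues (min %.3e); clipping for factorization",
                w.min(),
            )
        w = np.clip(w, clip, None)
        return v * np.sqrt(w)

    def submatrix(self, line_ids) -> "GenomicRelationship":
        idx = {l: i for i, l in enumerate(self.line_ids)}
        missing = [str(l) for l in line_ids if l not in idx]
        if missing:
            raise KeyError(f"lines absent from G: {missing[:5]}")
        sel = np.array([idx[l] for l in line_ids])
        return GenomicRelationship(
            np.asarray(line_ids), self.G[np.ix_(sel, sel)], self.allele_frequencies
        )


def filter_markers(
    markers: MarkerMatrix, maf_min: float = 0.05, missing_max: float = 0.20
) -> tuple[MarkerMatrix, dict]:
    """Keep markers with MAF strictly above ``maf_min`` and missing fraction
    strictly below ``missing_max``.

    Both inequalities are strict: a marker at exactly 5% MAF or exactly 20%
    missingness is removed.  Returns the filtered matrix and a report of
    removals per rule.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError("missing_max must be in [0, 1]")
    p = markers.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    miss = markers.missing_fraction()
    entirely_missing = np.isnan(p)
    maf_ok = ~entirely_missing & (maf > maf_min)
    miss_ok = miss < missing_max
    keep = maf_ok & miss_ok
    if not keep.any():
        raise ValueError("no markers survive QC")
    report = {
        "n_input": markers.n_markers,
        "n_kept": int(keep.sum()),
        "removed_maf": int((~maf_ok).sum()),
        "removed_missing": int((~miss_ok).sum()),
        "removed_total": int((~keep).sum()),
    }
    logger.info(
        "marker QC: kept %d of %d (%d failed MAF>%g, %d failed missing<%g)",
        report["n_kept"], report["n_input"], report["removed_maf"], maf_min,
        report["removed_missing"], missing_max,
    )
    return (
        MarkerMatrix(markers.line_ids, markers.marker_ids[keep], markers.dosages[:, keep]),
        report,
    )


def impute_missing(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing dosages by the marker mean 2 p_j (observed entries kept)."""
    dos = markers.dosages.copy()
    nan_mask = np.isnan(dos)
    if not nan_mask.any():
        return MarkerMatrix(markers.line_ids, markers.marker_ids, dos)
    fully_missing = nan_mask.all(axis=0)
    if fully_missing.any():
        bad = markers.marker_ids[fully_missing]
        raise ValueError(f"markers entirely missing (filter first): {list(bad[:5])}")
    col_mean = np.nanmean(dos, axis=0)
    dos[nan_mask] = np.broadcast_to(col_mean, dos.shape)[nan_mask]
    logger.info("imputed %d missing dosages with marker means", int(nan_mask.sum()))
    return MarkerMatrix(markers.line_ids, markers.marker_ids, dos)


def build_grm(markers: MarkerMatrix) -> GenomicRelationship:
    """VanRaden method-1 genomic relationship matrix.

    Missing dosages are mean-imputed first; allele frequencies come from the
    analyzed lines themselves.  Raises if the denominator 2*sum p(1-p) is
    zero (all markers monomorphic).
    """
    markers = impute_missing(markers)
    p = markers.dosages.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    Z = markers.dosages - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # exact symmetry against rounding
    w = np.linalg.eigvalsh(G)
    if w.min() < -1e-8:
        logger.warning("G indefinite (min eigenvalue %.3e); factor() will clip", w.min())
    return GenomicRelationship(markers.line_ids, G, p)


# ---------------------------------------------------------------- I/O

def read_genotypes_tsv(path) -> MarkerMatrix:
    """Lines x markers TSV: first column line id, header row marker ids;
    missing entries empty or NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    return MarkerMatrix(
        df.index.to_numpy(dtype=str), df.columns.to_numpy(dtype=str), df.to_numpy(float)
    )


def write_genotypes_tsv(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(markers.dosages, index=markers.line_ids, columns=markers.marker_ids)
    df.index.name = "line"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes_vcf(path) -> MarkerMatrix:
    """Read dosages of the ALT allele from the GT field of a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = np.asarray(vcf.samples)
    marker_ids, cols = [], []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
    if not marker_ids:
        raise ValueError(f"no variants in {path}")
    return MarkerMatrix(line_ids, np.asarray(marker_ids), np.column_stack(cols))


def write_grm_tsv(grm: GenomicRelationship, path) -> None:
    df = pd.DataFrame(grm.G, index=grm.line_ids, columns=grm.line_ids)
    df.index.name = "line"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_grm_tsv(path) -> GenomicRelationship:
    df = pd.read_csv(path, sep="\t", index_col=0)
    G = df.to_numpy(float)
    G = 0.5 * (G + G.T)
    return GenomicRelationship(
        df.index.to_numpy(dtype=str), G, np.full(0, np.nan)
    )
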