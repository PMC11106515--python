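"""A/B compartment calling from the leading eigenvector (PC1) of the
observed/expected correlation matrix, orientation by gene density, and
tumour/normal switch classification.

Compartments are megabase-scale chromatin states: A (active, gene-dense)
and B (inactive).  Per chromosome, the balanced cis matrix is divided by
its distance expectation, bin-row Pearson correlations form a plaid
pattern, and the sign of the leading eigenvector of that (mean-centered)
correlation matrix separates the two states.  The eigenvector sign is
arbitrary, so it is oriented to correlate positively with gene density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_core import ContactMatrix, expected_by_separation

CATEGORIES = ("A-to-A", "B-to-B", "A-to-B", "B-to-A")


def oe_transform(M: ContactMatrix, chrom: str) -> np.ndarray:
    """Observed/expected cis block: each pixel divided by the mean value at
    its separation.  Masked bins are NaN rows/columns."""
    block = M.cis_block(chrom, balanced=True)
    exp = expected_by_separation(M, chrom, balanced=True)
    if not np.any(np.isfinite(exp)):
        raise ValueError(f"no expected values for {chrom}")
    n = block.shape[0]
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = block / exp[sep]
    invalid = ~M.mask[M.spec.chrom_slice(chrom)]
    oe[invalid, :] = np.nan
    oe[:, invalid] = np.nan
    return oe


def correlation_matrix(oe: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation between bin rows of an O/E
    block; zero-variance valid bins are masked (NaN)."""
    n = oe.shape[0]
    valid = ~np.all(np.isnan(oe), axis=1)
    vidx = np.flatnonzero(valid)
    if vidx.size < 3:
        raise ValueError("fewer than 3 valid bins")
    sub = oe[np.ix_(vidx, vidx)]
    sub = np.nan_to_num(sub, nan=np.nanmean(sub))
    sd = sub.std(axis=1)
    keep = sd > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 bins with nonzero variance")
    vidx = vidx[keep]
    sub = sub[np.ix_(keep, keep)]
    corr = np.corrcoef(sub)
    out = np.full((n, n), np.nan)
    out[np.ix_(vidx, vidx)] = corr
    return out


def compartment_eigenvector(C: np.ndarray, max_iter: int = 5000, tol: float = 1e-12) -> np.ndarray:
    """Leading eigenvector (largest eigenvalue) of the column-mean-centered
    correlation matrix, restricted to valid bins; unit norm, NaN at masked
    bins, sign provisional.

    Uses shifted power iteration; a dense eigendecomposition serves as the
    cross-check in the test suite.
    """
    if C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    valid = ~np.all(np.isnan(C), axis=1)
    vidx = np.flatnonzero(valid)
    sub = C[np.ix_(vidx, vidx)]
    if not np.allclose(sub, sub.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    centered = sub - sub.mean(axis=0, keepdims=True)
    centered = 0.5 * (centered + centered.T)  # keep symmetric after centering
    # shift so the algebraically largest eigenvalue is also largest in magnitude
    shift = np.abs(centered).sum(axis=1).max()
    B = centered + shift * np.eye(centered.shape[0])
    rng = np.random.default_rng(0)
    v = rng.standard_normal(centered.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        nv = B @ v
        nrm = np.linalg.norm(nv)
        if nrm == 0:
            raise ValueError("power iteration collapsed to zero vector")
        nv /= nrm
        if np.linalg.norm(nv - v) < tol or np.linalg.norm(nv + v) < tol:
            v = nv
            break
        v = nv
    else:
        raise ValueError("eigen-iteration did not converge")
    out = np.full(C.shape[0], np.nan)
    out[vidx] = v
    return out


@dataclass
class CompartmentTrack:
    chrom: str
    resolution: int
    pc1: np.ndarray  # NaN on masked bins
    labels: np.ndarray  # 'A', 'B', or '' (unassigned)
    orientation_corr: float

    def to_bedgraph(self, path, mode: str = "w") -> None:
        with open(path, mode) as fh:
            for i, v in enumerate(self.pc1):
                if np.isfinite(v):
                    fh.write(
                        f"{self.chrom}\t{i * self.resolution}\t{(i + 1) * self.resolution}\t{v:.6g}\n"
                    )


def classify_compartments(
    pc1: np.ndarray, gene_density: np.ndarray, chrom: str, resolution: int
) -> CompartmentTrack:
    """Orient PC1 by gene density (flip if negatively correlated) and label
    bins A (PC1 > 0), B (PC1 < 0), unassigned at NaN or exactly 0."""
    if pc1.shape != gene_density.shape:
        raise ValueError("pc1 and gene_density must share the grid")
    ok = np.isfinite(pc1)
    if ok.sum() >= 2 and np.std(gene_density[ok]) > 0 and np.std(pc1[ok]) > 0:
        r = float(np.corrcoef(pc1[ok], gene_density[ok])[0, 1])
    else:
        r = 0.0
    if r == 0.0:
        raise ValueError("orientation undecidable: zero correlation with gene density")
    oriented = pc1 if r > 0 else -pc1
    labels = np.full(pc1.shape, "", dtype=object)
    labels[np.isfinite(oriented) & (oriented > 0)] = "A"
    labels[np.isfinite(oriented) & (oriented < 0)] = "B"
    return CompartmentTrack(chrom, resolution, oriented, labels, abs(r))


def call_compartments(
    M: ContactMatrix, gene_density: dict[str, np.ndarray]
) -> dict[str, CompartmentTrack]:
    """Full per-chromosome compartment calling: O/E -> correlation -> PC1 ->
    gene-density orientation."""
    tracks = {}
    for chrom in M.spec.chroms:
        oe = oe_transform(M, chrom)
        corr = correlation_matrix(oe)
        pc1 = compartment_eigenvector(corr)
        tracks[chrom] = classify_compartments(
            pc1, gene_density[chrom], chrom, M.spec.resolution
        )
    return tracks


@dataclass
class SwitchTable:
    per_bin: pd.DataFrame  # chrom, bin, category
    percentages: pd.Series  # over assigned bins, sums to 100

    def category_bins(self, category: str) -> pd.DataFrame:
        return self.per_bin[self.per_bin["category"] == category]


def switch_classification(
    normal: dict[str, CompartmentTrack], tumour: dict[str, CompartmentTrack]
) -> SwitchTable:
    """Per-bin switch category between two samples: A-to-A, B-to-B, A-to-B,
    B-to-A (normal -> tumour), or unassigned when either label is missing."""
    rows = []
    for chrom, tn in normal.items():
        if chrom not in tumour:
            raise ValueError(f"{chrom} missing from tumour tracks")
        tt = tumour[chrom]
        if tn.pc1.shape != tt.pc1.shape:
            raise ValueError(f"grid mismatch on {chrom}")
        for i, (a, b) in enumerate(zip(tn.labels, tt.labels)):
            cat = f"{a}-to-{b}" if a and b else "unassigned"
            rows.append((chrom, i, cat))
    per_bin = pd.DataFrame(rows, columns=["chrom", "bin", "category"])
    assigned = per_bin[per_bin["category"] != "unassigned"]
    if len(assigned):
        pct = assigned["category"].value_counts(normalize=True) * 100
    else:
        pct = pd.Series(dtype=float)
    pct = pct.reindex(CATEGORIES, fill_value=0.0)
    return SwitchTable(per_bin, pct)
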