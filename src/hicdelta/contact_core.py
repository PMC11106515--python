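"""Binned Hi-C contact matrices: data model, triplet-text I/O, iterative
correction (ICE), distance-decay statistics, and cis/trans summaries.

The contact matrix is stored as a sparse upper triangle over a genome-wide
bin grid defined by a :class:`GenomeSpec`.  Queries are symmetric.  Balancing
weights are multiplicative per-bin factors: the balanced value of pixel
(i, j) is ``count * w[i] * w[j]``; masked bins carry NaN weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

TRIPLET_HEADER = "#chromA\tbinA\tchromB\tbinB\tcount"


class BalanceWarning(UserWarning):
    """ICE reached max_iter without meeting the row-sum CV tolerance."""


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names, lengths (bp) and a bin resolution (bp).

    Bins are 0-based half-open: bin ``i`` covers ``[i*res, (i+1)*res)``.
    """

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    resolution: int

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("duplicate chromosome names")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def n_chroms(self) -> int:
        return len(self.chroms)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.lengths[self.chrom_index(chrom)] / self.resolution)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chroms.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    @property
    def bins_per_chrom(self) -> np.ndarray:
        return np.array([math.ceil(l / self.resolution) for l in self.lengths])

    @property
    def offsets(self) -> np.ndarray:
        """Global bin offset of each chromosome (cumulative bin counts)."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)])

    @property
    def total_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    def global_bin(self, chrom: str, b: int) -> int:
        ci = self.chrom_index(chrom)
        nb = self.bins_per_chrom[ci]
        if not 0 <= b < nb:
            raise ValueError(f"bin {b} out of range for {chrom} ({nb} bins)")
        return int(self.offsets[ci]) + int(b)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index of a genomic position (floor division)."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.resolution

    def chrom_slice(self, chrom: str) -> slice:
        ci = self.chrom_index(chrom)
        off = self.offsets
        return slice(int(off[ci]), int(off[ci + 1]))

    @classmethod
    def from_chromsizes(cls, path, resolution: int) -> "GenomeSpec":
        """Read a two-column ``name<TAB>length`` chrom.sizes file."""
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                names.append(name)
                lengths.append(int(length))
        return cls(tuple(names), tuple(lengths), resolution)

    def write_chromsizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chroms, self.lengths):
                fh.write(f"{name}\t{length}\n")


@dataclass
class ContactMatrix:
    """Symmetric genome-wide contact counts with optional balancing weights.

    Only the upper triangle (in global bin order) is stored; ``query`` is
    symmetric.  ``mask`` marks valid bins; ``weights`` are NaN on masked bins.
    """

    spec: GenomeSpec
    counts: sp.csr_matrix  # upper triangle, global bins
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None  # True = valid
    balance_converged: bool | None = None
    balance_iterations: int | None = None

    def __post_init__(self) -> None:
        n = self.spec.total_bins
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match genome spec")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative contact counts")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)

    # -- construction / I/O ------------------------------------------------

    @classmethod
    def from_pixels(cls, spec: GenomeSpec, rows, cols, vals) -> "ContactMatrix":
        """Build from global-bin pixel triplets; folds entries into the upper
        triangle (symmetric duplicates are summed once)."""
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        vals = np.asarray(vals, dtype=float)
        lo = np.minimum(rows, cols)
        hi = np.maximum(rows, cols)
        n = spec.total_bins
        m = sp.coo_matrix((vals, (lo, hi)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        return cls(spec, m)

    @classmethod
    def load(cls, path, spec: GenomeSpec) -> "ContactMatrix":
        """Read tab-separated triplet text: chromA binA chromB binB count."""
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{ln}: expected 5 fields")
                ca, ba, cb, bb, c = parts
                count = float(c)
                if count < 0:
                    raise ValueError(f"{path}:{ln}: negative count")
                rows.append(spec.global_bin(ca, int(ba)))
                cols.append(spec.global_bin(cb, int(bb)))
                vals.append(count)
        return cls.from_pixels(spec, rows, cols, vals)

    def write(self, path) -> None:
        coo = self.counts.tocoo()
        off = self.spec.offsets
        chrom_of = np.searchsorted(off, coo.row, side="right") - 1
        chrom_of_c = np.searchsorted(off, coo.col, side="right") - 1
        with open(path, "w") as fh:
            fh.write(TRIPLET_HEADER + "\n")
            for r, c, v, ci, cj in zip(coo.row, coo.col, coo.data, chrom_of, chrom_of_c):
                fh.write(
                    f"{self.spec.chroms[ci]}\t{r - off[ci]}\t"
                    f"{self.spec.chroms[cj]}\t{c - off[cj]}\t{v:g}\n"
                )

    # -- queries -----------------------------------------------------------

    def query(self, chromA: str, binA: int, chromB: str, binB: int) -> float:
        i = self.spec.global_bin(chromA, binA)
        j = self.spec.global_bin(chromB, binB)
        if i > j:
            i, j = j, i
        return float(self.counts[i, j])

    def cis_block(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Dense symmetric cis matrix of one chromosome.

        Balanced values are ``count * w_i * w_j`` with NaN on masked bins.
        """
        sl = self.spec.chrom_slice(chrom)
        block = self.counts[sl, sl].toarray()
        block = block + np.triu(block, 1).T
        if balanced:
            if self.weights is None:
                raise ValueError("matrix is not balanced")
            w = self.weights[sl]
            block = block * np.outer(w, w)
        return block

    def trans_block(self, chromA: str, chromB: str, balanced: bool = False) -> np.ndarray:
        ia = self.spec.chrom_index(chromA)
        ib = self.spec.chrom_index(chromB)
        sa, sb = self.spec.chrom_slice(chromA), self.spec.chrom_slice(chromB)
        if ia <= ib:
            block = self.counts[sa, sb].toarray()
        else:
            block = self.counts[sb, sa].toarray().T
        if balanced:
            if self.weights is None:
                raise ValueError("matrix is not balanced")
            block = block * np.outer(self.weights[sa], self.weights[sb])
        return block

    # -- mass bookkeeping --------------------------------------------------

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())

    def _pair_masses(self) -> np.ndarray:
        """(n_chrom, n_chrom) symmetric matrix of total mass per chrom pair."""
        off = self.spec.offsets
        nc = self.spec.n_chroms
        coo = self.counts.tocoo()
        ci = np.searchsorted(off, coo.row, side="right") - 1
        cj = np.searchsorted(off, coo.col, side="right") - 1
        m = np.zeros((nc, nc))
        np.add.at(m, (ci, cj), coo.data)
        return m + np.triu(m, 1).T

    def scaled(self, factor: float) -> "ContactMatrix":
        return replace(self, counts=self.counts * factor)

    def coverage(self) -> np.ndarray:
        """Per-bin marginal count sum (diagonal counted once)."""
        sym = self.counts + sp.triu(self.counts, k=1).T
        return np.asarray(sym.sum(axis=1)).ravel()


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_balance(
    M: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_quantile: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: multiplicative bin weights equalising row sums.

    Bins with zero coverage, plus nonzero-coverage bins below the
    ``mask_quantile`` quantile of nonzero coverage, are masked before
    iteration.  Returned weights have mean 1 on valid bins; convergence is
    declared when the coefficient of variation of balanced row sums over
    valid bins drops below ``tol``.  Non-convergence emits a
    :class:`BalanceWarning`, not an error.
    """
    if not 0 <= mask_quantile < 1:
        raise ValueError("mask_quantile must be in [0, 1)")
    if M.counts.nnz == 0:
        raise ValueError("cannot balance an empty matrix")
    cov = M.coverage()
    mask = cov > 0
    nz = cov[mask]
    if mask_quantile > 0 and nz.size:
        cut = np.quantile(nz, mask_quantile)
        mask &= cov > cut
    if not mask.any():
        raise ValueError("all bins masked")

    sym = (M.counts + sp.triu(M.counts, k=1).T).tocsr()
    n = sym.shape[0]
    b = np.ones(n)
    b[~mask] = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = b * sym.dot(b)  # balanced row sums
        sv = s[mask]
        mean_s = sv.mean()
        cv = sv.std() / mean_s if mean_s > 0 else np.inf
        if cv < tol:
            converged = True
            break
        upd = np.ones(n)
        upd[mask] = sv / mean_s
        b /= np.where(upd > 0, upd, 1.0)
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (CV={cv:.2e})",
            BalanceWarning,
        )
    w = np.full(n, np.nan)
    w[mask] = b[mask] / b[mask].mean()
    return replace(
        M, weights=w, mask=mask, balance_converged=converged, balance_iterations=it
    )


# ---------------------------------------------------------------------------
# Distance decay
# ---------------------------------------------------------------------------

@dataclass
class DecayProfile:
    """Mean contact value per genomic separation, per chromosome or pooled."""

    scope: str  # chromosome name or "pooled"
    resolution: int
    separations: np.ndarray  # bp, strictly increasing, >= resolution
    values: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    fit_range: tuple[int, int] | None = None


def expected_by_separation(M: ContactMatrix, chrom: str, balanced: bool = True) -> np.ndarray:
    """expected[s] = mean (balanced) value over valid pixels at bin separation
    s, for s = 0..n-1.  Masked bins are excluded from numerator and
    denominator."""
    block = M.cis_block(chrom, balanced=balanced)
    sl = M.spec.chrom_slice(chrom)
    valid = M.mask[sl]
    n = block.shape[0]
    exp = np.full(n, np.nan)
    vb = block[np.ix_(valid, valid)]
    vidx = np.flatnonzero(valid)
    if vidx.size == 0:
        return exp
    sep = np.abs(vidx[:, None] - vidx[None, :])
    sums = np.zeros(n)
    cnts = np.zeros(n)
    iu = np.triu_indices(vidx.size)
    np.add.at(sums, sep[iu], np.nan_to_num(vb[iu]))
    np.add.at(cnts, sep[iu], 1.0)
    with np.errstate(invalid="ignore"):
        exp = np.where(cnts > 0, sums / cnts, np.nan)
    return exp


def compute_expected(
    M: ContactMatrix, scope: str = "per-chrom", balanced: bool = True
) -> list[DecayProfile]:
    """Distance-decay profiles; ``scope`` is ``per-chrom`` or ``pooled``.

    Separation 0 (the main diagonal) is excluded from the profile.
    """
    res = M.spec.resolution
    per = {}
    for chrom in M.spec.chroms:
        exp = expected_by_separation(M, chrom, balanced=balanced)
        per[chrom] = exp
    if all(e[1:].size == 0 or np.nansum(e[1:]) == 0 for e in per.values()):
        raise ValueError("no cis contacts")
    if scope == "per-chrom":
        out = []
        for chrom, exp in per.items():
            s = np.arange(1, exp.size) * res
            out.append(DecayProfile(chrom, res, s, exp[1:]))
        return out
    if scope == "pooled":
        nmax = max(e.size for e in per.values())
        sums = np.zeros(nmax)
        cnts = np.zeros(nmax)
        for chrom, exp in per.items():
            block_n = M.spec.n_bins(chrom)
            # re-weight by pixel counts: recompute counts per stratum
            sl = M.spec.chrom_slice(chrom)
            vidx = np.flatnonzero(M.mask[sl])
            sep = np.abs(vidx[:, None] - vidx[None, :])
            iu = np.triu_indices(vidx.size)
            c = np.zeros(nmax)
            np.add.at(c, sep[iu], 1.0)
            ok = np.isfinite(exp)
            sums[: exp.size][ok] += exp[ok] * c[: exp.size][ok]
            cnts[: exp.size][ok] += c[: exp.size][ok]
        with np.errstate(invalid="ignore"):
            pooled = np.where(cnts > 0, sums / cnts, np.nan)
        s = np.arange(1, nmax) * res
        return [DecayProfile("pooled", res, s, pooled[1:])]
    raise ValueError(f"unknown scope: {scope!r}")


def fit_decay_exponent(
    D: DecayProfile, s_min: int = 50_000, s_max: int = 10_000_000
) -> float:
    """Interaction decay exponent: OLS slope of log10 expected vs log10
    separation over [s_min, s_max].  Requires >= 3 positive strata."""
    sel = (D.separations >= s_min) & (D.separations <= s_max) & (D.values > 0)
    sel &= np.isfinite(D.values)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 positive strata in fit range")
    x = np.log10(D.separations[sel].astype(float))
    y = np.log10(D.values[sel])
    slope, intercept = np.polyfit(x, y, 1)
    D.slope, D.intercept = float(slope), float(intercept)
    D.fit_range = (s_min, s_max)
    return float(slope)


# ---------------------------------------------------------------------------
# Cis/trans and inter-chromosomal comparisons
# ---------------------------------------------------------------------------

@dataclass
class CisTransSummary:
    total_cis: float
    total_trans: float
    overall_cis_fraction: float
    per_chrom: pd.DataFrame  # chrom, cis, trans, cis_fraction


def cis_trans_fraction(M: ContactMatrix) -> CisTransSummary:
    """Per-chromosome and overall fraction of contact mass that is cis."""
    pm = M._pair_masses()
    if pm.sum() == 0:
        raise ValueError("matrix has zero total mass")
    cis = np.diag(pm)
    trans = pm.sum(axis=1) - cis
    with np.errstate(invalid="ignore"):
        frac = np.where(cis + trans > 0, cis / (cis + trans), np.nan)
    total_cis = float(cis.sum())
    total_trans = float(np.triu(pm, 1).sum())
    df = pd.DataFrame(
        {"chrom": M.spec.chroms, "cis": cis, "trans": trans, "cis_fraction": frac}
    )
    overall = total_cis / (total_cis + total_trans)
    return CisTransSummary(total_cis, total_trans, overall, df)


def depth_normalize(A: ContactMatrix, B: ContactMatrix) -> tuple[ContactMatrix, ContactMatrix]:
    """Scale both matrices to the same total genome-wide mass (their mean)."""
    ta, tb = A.total_mass, B.total_mass
    if ta == 0 or tb == 0:
        raise ValueError("cannot depth-normalize an empty matrix")
    target = 0.5 * (ta + tb)
    return A.scaled(target / ta), B.scaled(target / tb)


def log2_ratio_map(
    A: ContactMatrix,
    B: ContactMatrix,
    pseudocount: float = 1.0,
    balanced: bool = True,
) -> sp.csr_matrix:
    """log2((a + pc) / (b + pc)) on the union of nonzero pixels.

    Both matrices are depth-normalized to equal total mass first; values are
    balanced when ``balanced`` and weights are available on both.
    """
    if A.spec != B.spec:
        raise ValueError("mismatched genome specs")
    An, Bn = depth_normalize(A, B)

    def _values(m: ContactMatrix) -> sp.csr_matrix:
        c = m.counts.tocsr().copy()
        if balanced:
            if m.weights is None:
                raise ValueError("balanced=True but matrix not balanced")
            w = np.nan_to_num(m.weights)
            dw = sp.diags(w)
            c = dw @ c @ dw
        return c

    a = _values(An).tocoo()
    b = _values(Bn).tocoo()
    keys = {}
    for coo, which in ((a, 0), (b, 1)):
        for r, c, v in zip(coo.row, coo.col, coo.data):
            keys.setdefault((r, c), [0.0, 0.0])[which] = v
    rows, cols, vals = [], [], []
    for (r, c), (va, vb) in keys.items():
        rows.append(r)
        cols.append(c)
        vals.append(math.log2((va + pseudocount) / (vb + pseudocount)))
    n = A.spec.total_bins
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def interchrom_oe(M: ContactMatrix, top_k: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromosome-pair trans observed/expected matrix plus the top-k trans
    pixels by count.

    Expected trans mass for pair (i, j) is proportional to the product of
    valid-bin counts, normalized so total expected equals total observed
    trans mass.
    """
    if M.spec.n_chroms < 2:
        raise ValueError("need at least 2 chromosomes")
    pm = M._pair_masses()
    obs = np.triu(pm, 1)
    total_trans = obs.sum()
    if total_trans == 0:
        raise ValueError("zero trans mass")
    nb = np.array(
        [int(M.mask[M.spec.chrom_slice(c)].sum()) for c in M.spec.chroms]
    )
    prod = np.outer(nb, nb).astype(float)
    prod = np.triu(prod, 1)
    exp = prod / prod.sum() * total_trans
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, obs / exp, 0.0)
    oe = oe + oe.T  # symmetric view
    oe[(prod + prod.T) == 0] = np.nan
    np.fill_diagonal(oe, np.nan)
    oe_df = pd.DataFrame(oe, index=M.spec.chroms, columns=M.spec.chroms)

    coo = M.counts.tocoo()
    off = M.spec.offsets
    ci = np.searchsorted(off, coo.row, side="right") - 1
    cj = np.searchsorted(off, coo.col, side="right") - 1
    is_trans = ci != cj
    order = np.argsort(coo.data[is_trans])[::-1][:top_k]
    tr, tc, tv = coo.row[is_trans][order], coo.col[is_trans][order], coo.data[is_trans][order]
    tci, tcj = ci[is_trans][order], cj[is_trans][order]
    top = pd.DataFrame(
        {
            "chromA": [M.spec.chroms[i] for i in tci],
            "binA": tr - off[tci],
            "chromB": [M.spec.chroms[j] for j in tcj],
            "binB": tc - off[tcj],
            "count": tv,
        }
    )
    return oe_df, top
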