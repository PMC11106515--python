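"""Stratum-adjusted correlation coefficient (SCC) between two Hi-C maps.

The SCC is a distance-stratified, variance-weighted Pearson correlation:
after 2-D mean smoothing, each diagonal stratum k contributes a correlation
r_k with weight ``N_k * sqrt(var_A,k * var_B,k)``.  By HiCRep convention it
is computed on raw counts; a flag allows balanced values instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .contact_core import ContactMatrix


def smooth_matrix(block: np.ndarray, h: int) -> np.ndarray:
    """Mean filter over a (2h+1) x (2h+1) window, truncated at edges."""
    if h < 0:
        raise ValueError("h must be >= 0")
    if h == 0:
        return block.copy()
    size = 2 * h + 1
    vals = uniform_filter(block, size=size, mode="constant", cval=0.0)
    ones = uniform_filter(np.ones_like(block), size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return vals / ones


@dataclass
class SCCResult:
    per_chrom: pd.DataFrame  # chrom, scc, n_strata, total_weight
    pooled: float
    h: int
    s_max: int
    strata: dict  # chrom -> (r_k array, w_k array)


def _chrom_scc(a: np.ndarray, b: np.ndarray, h: int, max_k: int):
    sa = smooth_matrix(np.nan_to_num(a), h)
    sb = smooth_matrix(np.nan_to_num(b), h)
    n = sa.shape[0]
    rs, ws = [], []
    for k in range(1, min(max_k, n - 1) + 1):
        x = np.diagonal(sa, k)
        y = np.diagonal(sb, k)
        if x.size < 2:
            continue
        vx, vy = x.var(), y.var()
        if vx == 0 or vy == 0:
            continue  # constant stratum carries no correlation signal
        r = float(np.corrcoef(x, y)[0, 1])
        rs.append(r)
        ws.append(x.size * np.sqrt(vx * vy))
    return np.array(rs), np.array(ws)


def scc(
    A: ContactMatrix,
    B: ContactMatrix,
    chroms: list[str] | None = None,
    h: int = 1,
    s_max: int = 5_000_000,
    balanced: bool = False,
) -> SCCResult:
    """Stratum-adjusted correlation between two maps on the same grid.

    The pooled genome-wide value weights each chromosome by its total
    stratum weight.
    """
    if A.spec != B.spec:
        raise ValueError("mismatched genome specs")
    if s_max < A.spec.resolution:
        raise ValueError("s_max must be at least one bin")
    if chroms is None:
        chroms = list(A.spec.chroms)
    max_k = s_max // A.spec.resolution
    rows = []
    strata = {}
    num = den = 0.0
    for chrom in chroms:
        a = A.cis_block(chrom, balanced=balanced)
        b = B.cis_block(chrom, balanced=balanced)
        rs, ws = _chrom_scc(a, b, h, max_k)
        strata[chrom] = (rs, ws)
        if ws.size == 0 or ws.sum() == 0:
            rows.append((chrom, np.nan, 0, 0.0))
            continue
        s = float(np.sum(rs * ws) / ws.sum())
        rows.append((chrom, s, len(rs), float(ws.sum())))
        num += np.sum(rs * ws)
        den += ws.sum()
    if den == 0:
        raise ValueError("no valid strata in any chromosome")
    per = pd.DataFrame(rows, columns=["chrom", "scc", "n_strata", "total_weight"])
    return SCCResult(per, float(num / den), h, s_max, strata)
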