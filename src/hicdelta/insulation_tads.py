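"""Diamond insulation scores, TAD boundary calling, cross-sample boundary
matching, the high-confidence/differential boundary rules, and
boundary-centred pileups.

The insulation score at bin i is the mean balanced contact value in the
w x w diamond just off the diagonal (rows i-w..i-1 against columns
i+1..i+w).  Scores are reported as log2 of the chromosome-normalised value,
so a matrix scaled by any constant gives identical tracks.  TAD boundaries
are local minima of the log2 insulation score whose prominence exceeds a
calling threshold; lower log2IS means stronger insulation.

Differential classification between a normal and a tumour track follows
two rules: positions where the log2 insulation score is greater than 0 in
both samples are excluded (not high-confidence boundaries), and the
remainder are classified by the difference tumour - normal against a
threshold of 0.4 — below -0.4 the boundary is enhanced in tumour (more
insulating), above +0.4 weakened, otherwise unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .contact_core import ContactMatrix, GenomeSpec

DELTA_THRESHOLD = 0.4  # |delta log2IS| above which a boundary is differential


@dataclass
class InsulationTrack:
    spec: GenomeSpec
    window: int  # bp
    raw: dict[str, np.ndarray] = field(default_factory=dict)
    log2: dict[str, np.ndarray] = field(default_factory=dict)

    def to_bedgraph(self, path) -> None:
        res = self.spec.resolution
        with open(path, "w") as fh:
            for chrom in self.spec.chroms:
                for i, v in enumerate(self.log2.get(chrom, [])):
                    if np.isfinite(v):
                        fh.write(f"{chrom}\t{i * res}\t{(i + 1) * res}\t{v:.6g}\n")


def insulation_track(M: ContactMatrix, window: int = 500_000) -> InsulationTrack:
    """Diamond insulation score per bin at the matrix resolution.

    ``window`` is the diamond arm in bp; bins within the window of a
    chromosome edge, masked bins, and diamonds with under half their cells
    valid are NaN.
    """
    res = M.spec.resolution
    if window % res != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // res
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    if all(M.spec.n_bins(c) <= 2 * w for c in M.spec.chroms):
        raise ValueError("window too large for every chromosome")
    track = InsulationTrack(M.spec, window)
    for chrom in M.spec.chroms:
        n = M.spec.n_bins(chrom)
        raw = np.full(n, np.nan)
        if n > 2 * w:
            block = M.cis_block(chrom, balanced=True)
            valid = M.mask[M.spec.chrom_slice(chrom)]
            block = block.copy()
            block[~valid, :] = np.nan
            block[:, ~valid] = np.nan
            for i in range(w, n - w):
                if not valid[i]:
                    continue
                diamond = block[i - w : i, i + 1 : i + w + 1]
                n_ok = np.isfinite(diamond).sum()
                if n_ok >= 0.5 * diamond.size:
                    raw[i] = np.nanmean(diamond)
        ok = np.isfinite(raw)
        log2 = np.full(n, np.nan)
        if ok.any() and np.nanmean(raw[ok]) > 0:
            with np.errstate(divide="ignore"):
                log2[ok] = np.log2(raw[ok] / raw[ok].mean())
        track.raw[chrom] = raw
        track.log2[chrom] = log2
    return track


@dataclass
class BoundarySet:
    spec: GenomeSpec
    table: pd.DataFrame  # chrom, bin, log2_is, strength

    def positions(self) -> list[tuple[str, int]]:
        return list(zip(self.table["chrom"], self.table["bin"]))

    def to_bed(self, path) -> None:
        res = self.spec.resolution
        with open(path, "w") as fh:
            for _, r in self.table.iterrows():
                fh.write(
                    f"{r.chrom}\t{r.bin * res}\t{(r.bin + 1) * res}\t"
                    f"boundary\t{r.strength:.4g}\t.\n"
                )


def _fill_short_gaps(y: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap.

    Strongly insulating boundaries often lose their centre bin to the
    low-coverage mask; without filling, the minimum sits at a segment edge
    and no peak can be called there.
    """
    out = y.copy()
    finite = np.isfinite(y)
    idx = np.flatnonzero(~finite)
    if idx.size == 0:
        return out
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= y.size or run.size > max_gap:
            continue
        if np.isfinite(y[lo]) and np.isfinite(y[hi]):
            out[run] = np.interp(run, [lo, hi], [y[lo], y[hi]])
    return out


def call_boundaries(
    T: InsulationTrack,
    min_strength: float = 0.1,
    max_gap: int = 2,
    max_log2: float = 0.0,
) -> BoundarySet:
    """Local minima of the log2 insulation score with prominence at least
    ``min_strength`` (log2 units) and score below ``max_log2`` — a minimum
    that is still less insulating than the chromosome average is not a
    boundary.  Interior NaN runs of up to ``max_gap`` bins are interpolated
    before peak finding.  An empty set is a valid result."""
    rows = []
    for chrom in T.spec.chroms:
        y = T.log2.get(chrom)
        if y is None:
            continue
        y = _fill_short_gaps(y, max_gap)
        finite = np.isfinite(y)
        # scan each contiguous finite segment independently
        idx = np.flatnonzero(finite)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        segments = np.split(idx, breaks + 1)
        for seg in segments:
            if seg.size < 3:
                continue
            vals = y[seg]
            peaks, props = find_peaks(-vals, prominence=min_strength)
            for p, prom in zip(peaks, props["prominences"]):
                if vals[p] < max_log2:
                    rows.append((chrom, int(seg[p]), float(vals[p]), float(prom)))
    table = pd.DataFrame(rows, columns=["chrom", "bin", "log2_is", "strength"])
    table = table.sort_values(["chrom", "bin"]).reset_index(drop=True)
    return BoundarySet(T.spec, table)


@dataclass
class TADSet:
    table: pd.DataFrame  # chrom, start (bp), end (bp)
    n_tads: int
    mean_adjacent_distance: float  # bp, mean gap between consecutive boundaries


def tads_from_boundaries(B: BoundarySet, min_bins: int = 3) -> TADSet:
    """One TAD per consecutive boundary pair on a chromosome (half-open bp
    intervals); TADs shorter than ``min_bins`` bins are dropped."""
    res = B.spec.resolution
    rows = []
    gaps = []
    for chrom, grp in B.table.groupby("chrom", sort=False):
        bins = np.sort(grp["bin"].to_numpy())
        if bins.size < 2:
            continue
        d = np.diff(bins)
        gaps.extend(d * res)
        for b0, b1 in zip(bins[:-1], bins[1:]):
            if b1 - b0 >= min_bins:
                rows.append((chrom, int(b0) * res, int(b1) * res))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    mean_gap = float(np.mean(gaps)) if gaps else float("nan")
    return TADSet(table, len(table), mean_gap)


@dataclass
class BoundaryMatch:
    conserved: pd.DataFrame  # chrom, bin_a, bin_b
    a_specific: pd.DataFrame  # chrom, bin
    b_specific: pd.DataFrame  # chrom, bin


def match_boundaries(A: BoundarySet, B: BoundarySet, tol_bins: int = 1) -> BoundaryMatch:
    """Greedy nearest matching of boundary positions within ``tol_bins``;
    every boundary lands in exactly one of conserved / A-specific /
    B-specific."""
    if A.spec != B.spec:
        raise ValueError("mismatched genome specs")
    cons, a_only, b_only = [], [], []
    chroms = set(A.table["chrom"]) | set(B.table["chrom"])
    for chrom in sorted(chroms):
        pa = np.sort(A.table.loc[A.table["chrom"] == chrom, "bin"].to_numpy())
        pb = np.sort(B.table.loc[B.table["chrom"] == chrom, "bin"].to_numpy())
        pairs = [
            (abs(int(x) - int(y)), i, j)
            for i, x in enumerate(pa)
            for j, y in enumerate(pb)
            if abs(int(x) - int(y)) <= tol_bins
        ]
        pairs.sort()
        used_a, used_b = set(), set()
        for _, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            cons.append((chrom, int(pa[i]), int(pb[j])))
        a_only.extend((chrom, int(x)) for i, x in enumerate(pa) if i not in used_a)
        b_only.extend((chrom, int(x)) for j, x in enumerate(pb) if j not in used_b)
    return BoundaryMatch(
        pd.DataFrame(cons, columns=["chrom", "bin_a", "bin_b"]),
        pd.DataFrame(a_only, columns=["chrom", "bin"]),
        pd.DataFrame(b_only, columns=["chrom", "bin"]),
    )


def differential_boundaries(
    normalT: InsulationTrack,
    tumourT: InsulationTrack,
    positions: list[tuple[str, int]],
    delta_threshold: float = DELTA_THRESHOLD,
) -> pd.DataFrame:
    """Classify candidate boundary positions between samples.

    Excluded when the log2 insulation score is greater than 0 in both
    samples (not a high-confidence boundary) or when either score is NaN;
    otherwise enhanced when tumour - normal < -delta_threshold (tumour more
    insulating), weakened when > +delta_threshold, else unchanged.
    """
    rows = []
    for chrom, b in positions:
        sn = normalT.log2[chrom][b] if chrom in normalT.log2 else np.nan
        st = tumourT.log2[chrom][b] if chrom in tumourT.log2 else np.nan
        delta = st - sn
        if not (np.isfinite(sn) and np.isfinite(st)):
            cls, reason = "excluded", "nan_score"
        elif sn > 0 and st > 0:
            cls, reason = "excluded", "both_positive"
        elif delta < -delta_threshold:
            cls, reason = "enhanced", ""
        elif delta > delta_threshold:
            cls, reason = "weakened", ""
        else:
            cls, reason = "unchanged", ""
        rows.append((chrom, b, sn, st, delta, cls, reason))
    return pd.DataFrame(
        rows,
        columns=["chrom", "bin", "normal_log2_is", "tumour_log2_is", "delta", "class", "reason"],
    )


def candidate_positions(
    A: BoundarySet, B: BoundarySet, tol_bins: int = 1
) -> list[tuple[str, int]]:
    """Union of called boundaries from both samples, deduplicated within
    ``tol_bins`` (conserved pairs contribute the first sample's position)."""
    m = match_boundaries(A, B, tol_bins)
    pos = [(r.chrom, r.bin_a) for r in m.conserved.itertuples()]
    pos += [(r.chrom, r.bin) for r in m.a_specific.itertuples()]
    pos += [(r.chrom, r.bin) for r in m.b_specific.itertuples()]
    return sorted(set(pos))


def boundary_pileup(
    T_normal: InsulationTrack,
    T_tumour: InsulationTrack,
    positions: list[tuple[str, int]],
    flank_bins: int = 20,
) -> pd.DataFrame:
    """NaN-aware mean log2IS profile around positions, per sample; columns
    ``offset`` (bins), ``normal``, ``tumour``."""
    if not positions:
        raise ValueError("empty position set")
    width = 2 * flank_bins + 1
    stacks = {"normal": [], "tumour": []}
    for name, T in (("normal", T_normal), ("tumour", T_tumour)):
        for chrom, b in positions:
            y = T.log2[chrom]
            if b - flank_bins < 0 or b + flank_bins >= y.size:
                continue
            stacks[name].append(y[b - flank_bins : b + flank_bins + 1])
    if not stacks["normal"] or not stacks["tumour"]:
        raise ValueError("no position admits a full flank window")
    out = {"offset": np.arange(-flank_bins, flank_bins + 1)}
    for name, st in stacks.items():
        out[name] = np.nanmean(np.vstack(st), axis=0)
    return pd.DataFrame(out)
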