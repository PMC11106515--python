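"""Seeded generator of paired tumour-like / normal-like Hi-C maps with
planted ground truth, plus coupled gene-expression tables.

The contact intensity of a cis pixel (i, j) is a power-law distance decay
``s^alpha`` modulated by a two-compartment plaid term ``1 + c * v_i v_j``,
a within-TAD enrichment ``t``, a multiplicative attenuation for every
planted boundary crossed (scaled by boundary strength), Gaussian focal
bumps at planted loop anchors, and multiplicative per-bin biases; counts
are Poisson-sampled at a configurable cis depth per chromosome.  The
structural modulation is normalised per separation so that the marginal
distance decay is exactly ``s^alpha`` in expectation — plaid, TAD and loop
effects are what they are downstream: enrichments at fixed separation.
This keeps the planted decay exponent identifiable by the IDE fit while
leaving every other planted feature detectable by its dedicated caller.

The tumour-like sample differs from the normal-like one by a planted set
of compartment sign flips, boundary strength deltas (enhanced/weakened)
and extra tumour-only boundaries, gained and lost loops, and a lower trans
fraction (higher cis fraction).  Gene expression is coupled to structure:
genes land 3:1 in A vs B bins, A genes express higher, and genes in
switched bins / at differential boundaries / at differential loop anchors
receive condition-specific log2 shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .contact_core import ContactMatrix, GenomeSpec


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.  Defaults give three
    5 Mb chromosomes of 500 bins at 10 kb with 2e6 cis contacts each."""

    n_chroms: int = 3
    bins_per_chrom: int = 500
    resolution: int = 10_000

    alpha: float = -1.0  # distance-decay exponent
    plaid_c: float = 0.3  # compartment plaid amplitude
    tad_t: float = 2.0  # within-TAD enrichment
    compartment_flip_prob: float = 0.4  # chance the A/B state flips at a boundary

    n_boundaries_per_chrom: int = 10
    boundary_strength_range: tuple[float, float] = (0.3, 0.7)
    boundary_attenuation: float = 0.7  # crossing factor = 1 - att * strength
    attenuation_decay_bins: float = 25.0  # insulation fades with separation
    tad_taper_bins: int = 5  # TAD enrichment ramps up over this many bins
    boundary_margin_bins: int = 40  # keep boundaries away from chrom edges
    min_boundary_gap_bins: int = 25

    n_loops_per_chrom: int = 8
    loop_amplitude: float = 3.0
    loop_sigma: float = 1.0  # bins
    loop_sep_range_bins: tuple[int, int] = (10, 100)
    loop_margin_bins: int = 25

    bias_sigma: float = 0.2  # lognormal(0, sigma) per-bin bias
    cis_depth_per_chrom: float = 2_000_000.0
    trans_fraction_normal: float = 0.15
    trans_fraction_tumour: float = 0.10

    # tumour differences
    switch_fraction: float = 0.2
    switch_ab_share: float = 0.6  # fraction of switched bins that go A-to-B
    n_extra_tumour_boundaries_per_chrom: int = 3
    n_enhanced_per_chrom: int = 4
    n_weakened_per_chrom: int = 1
    boundary_delta: float = 0.4  # strength shift for enhanced/weakened
    n_gained_per_chrom: int = 5
    n_lost_per_chrom: int = 1

    # expression
    n_genes: int = 600
    gene_density_ratio: float = 3.0  # A : B placement odds
    base_log2_a: float = 7.0
    base_log2_b: float = 5.0
    switch_effect: float = 1.8  # log2 shift for B-to-A (+) / A-to-B (-)
    boundary_effect: float = 1.5  # log2 shift for enhanced-boundary genes
    loop_effect: float = 1.5  # + at gained anchors, - at lost anchors
    replicate_sigma: float = 0.25  # log2-scale biological noise
    gene_window: int = 250_000  # boundary-gene association window (bp)


@dataclass
class SyntheticTruth:
    config: SimConfig
    seed: int
    spec: GenomeSpec
    v_normal: np.ndarray  # global per-bin compartment sign, +1 (A) / -1 (B)
    v_tumour: np.ndarray
    switched: np.ndarray  # boolean, global bins
    boundaries: pd.DataFrame  # chrom, bin, strength_normal, strength_tumour,
    #                           in_normal, in_tumour, class
    loops: pd.DataFrame  # chrom, bin1, bin2, amplitude, status
    bias: np.ndarray  # global per-bin multiplicative bias
    genes: pd.DataFrame  # gene, chrom, start, end, strand, compartment,
    #                      switch_category, effect_log2, base_log2

    def chrom_v(self, chrom: str, sample: str) -> np.ndarray:
        v = self.v_normal if sample == "normal" else self.v_tumour
        return v[self.spec.chrom_slice(chrom)]

    def boundary_bins(self, chrom: str, sample: str) -> pd.DataFrame:
        col = "in_normal" if sample == "normal" else "in_tumour"
        sub = self.boundaries[(self.boundaries["chrom"] == chrom) & self.boundaries[col]]
        return sub

    def loop_list(self, sample: str) -> pd.DataFrame:
        if sample == "normal":
            keep = self.loops["status"].isin(["shared", "lost"])
        else:
            keep = self.loops["status"].isin(["shared", "gained"])
        return self.loops[keep]


def _pick_positions(rng, lo: int, hi: int, k: int, min_gap: int) -> np.ndarray:
    """k sorted positions in [lo, hi) with pairwise gaps >= min_gap."""
    span = hi - lo - (k - 1) * min_gap
    if k > 0 and span < k:
        raise ValueError("infeasible: too many positions for the chromosome")
    base = np.sort(rng.choice(span, size=k, replace=False))
    return lo + base + np.arange(k) * min_gap


def make_truth(config: SimConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Draw a planted ground truth; deterministic for fixed (config, seed),
    with requested counts honoured exactly."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    chroms = tuple(f"chr{i + 1}" for i in range(cfg.n_chroms))
    lengths = tuple(cfg.bins_per_chrom * cfg.resolution for _ in chroms)
    spec = GenomeSpec(chroms, lengths, cfg.resolution)
    total = spec.total_bins

    # -- boundaries -------------------------------------------------------
    rows = []
    for chrom in chroms:
        k = cfg.n_boundaries_per_chrom + cfg.n_extra_tumour_boundaries_per_chrom
        pos = _pick_positions(
            rng, cfg.boundary_margin_bins, cfg.bins_per_chrom - cfg.boundary_margin_bins,
            k, cfg.min_boundary_gap_bins,
        )
        which_extra = set(
            rng.choice(k, size=cfg.n_extra_tumour_boundaries_per_chrom, replace=False)
        )
        shared_idx = [i for i in range(k) if i not in which_extra]
        strengths = {i: float(rng.uniform(*cfg.boundary_strength_range)) for i in range(k)}
        # enhanced boundaries strengthen in tumour, so they start weak;
        # weakened ones start strong — both shifts then clear the
        # differential-score rule without leaving (0, 1]
        order = sorted(shared_idx, key=lambda i: strengths[i])
        enhanced = set(order[: cfg.n_enhanced_per_chrom])
        weakened = set(order[len(order) - cfg.n_weakened_per_chrom :])
        for i, b in enumerate(pos):
            s = strengths[i]
            if i in which_extra:
                rows.append((chrom, int(b), 0.0, s, False, True, "tumour_only"))
            elif i in enhanced:
                st = min(0.9, s + cfg.boundary_delta)
                rows.append((chrom, int(b), s, st, True, True, "enhanced"))
            elif i in weakened:
                st = max(0.05, s - cfg.boundary_delta)
                rows.append((chrom, int(b), s, st, True, True, "weakened"))
            else:
                rows.append((chrom, int(b), s, s, True, True, "stable"))
    boundaries = pd.DataFrame(
        rows,
        columns=["chrom", "bin", "strength_normal", "strength_tumour",
                 "in_normal", "in_tumour", "class"],
    ).sort_values(["chrom", "bin"]).reset_index(drop=True)

    # -- compartments: A/B state flips only at boundaries shared by both
    # samples, as compartment transitions in real genomes coincide with TAD
    # boundaries; switched segments are whole inter-boundary segments, with
    # at most one partial segment to honour the requested fraction exactly.
    v_normal = np.empty(total)
    segments = []  # (global start, global end) inter-boundary segments
    for ci, chrom in enumerate(chroms):
        cuts = boundaries.loc[
            (boundaries["chrom"] == chrom) & boundaries["in_normal"], "bin"
        ].to_numpy()
        edges = np.concatenate([[0], cuts, [cfg.bins_per_chrom]])
        o = int(spec.offsets[ci])
        # draw segment signs until the chromosome has a realistic A fraction
        # (human chromosomes are roughly half A, half B)
        for _ in range(100):
            sign = rng.choice([-1.0, 1.0])
            seg_signs = []
            for _s in range(len(edges) - 1):
                seg_signs.append(sign)
                if rng.random() < cfg.compartment_flip_prob:
                    sign = -sign
            lens = np.diff(edges)
            frac_a = float(np.sum(lens[np.array(seg_signs) > 0]) / lens.sum())
            if 0.3 <= frac_a <= 0.7:
                break
        for s, e, sg in zip(edges[:-1], edges[1:], seg_signs):
            v_normal[o + s : o + e] = sg
            segments.append((o + int(s), o + int(e)))
    # A-to-B switches outnumber B-to-A, as reported for the tumour state,
    # and the quota is spread over chromosomes: concentrated switching
    # would leave a chromosome whose tumour compartments no longer track
    # gene density at all, which real tumours do not show
    n_switch = int(round(cfg.switch_fraction * total))
    switched = np.zeros(total, dtype=bool)
    off = spec.offsets
    per_chrom = [
        int(round(cfg.switch_fraction * spec.bins_per_chrom[ci]))
        for ci in range(len(chroms))
    ]
    per_chrom[-1] += n_switch - sum(per_chrom)
    for ci in range(len(chroms)):
        lo, hi = int(off[ci]), int(off[ci + 1])
        segs_c = [(s, e) for s, e in segments if lo <= s < hi]
        quota_c = per_chrom[ci]
        quotas = {
            1.0: int(round(cfg.switch_ab_share * quota_c)),  # A -> A-to-B
            -1.0: quota_c - int(round(cfg.switch_ab_share * quota_c)),
        }
        for s, e in rng.permutation(segs_c).tolist():
            sign = v_normal[s]
            if quotas[sign] <= 0:
                continue
            run = min(e - s, quotas[sign])
            switched[s : s + run] = True
            quotas[sign] -= run
        deficit = quota_c - int(switched[lo:hi].sum())
        if deficit > 0:  # one sign ran out of eligible bins; top up anywhere
            for s, e in rng.permutation(segs_c).tolist():
                free = np.flatnonzero(~switched[s:e])
                take = free[:deficit]
                switched[s + take] = True
                deficit -= take.size
                if deficit <= 0:
                    break
    v_tumour = np.where(switched, -v_normal, v_normal)

    # -- loops: intra-TAD, as cohesin loops do not span boundaries --------
    lrows = []
    for chrom in chroms:
        k = cfg.n_loops_per_chrom + cfg.n_gained_per_chrom + cfg.n_lost_per_chrom
        status = (["shared"] * cfg.n_loops_per_chrom
                  + ["gained"] * cfg.n_gained_per_chrom
                  + ["lost"] * cfg.n_lost_per_chrom)
        cuts_all = boundaries.loc[boundaries["chrom"] == chrom, "bin"].to_numpy()
        edges = np.concatenate(
            [[cfg.loop_margin_bins], np.sort(cuts_all), [cfg.bins_per_chrom - cfg.loop_margin_bins]]
        )
        segs = [
            (int(s), int(e)) for s, e in zip(edges[:-1], edges[1:])
            if e - s >= cfg.loop_sep_range_bins[0] + 4
        ]
        if not segs:
            raise ValueError("infeasible: no TAD segment can host a loop")
        seg_w = np.array([e - s for s, e in segs], dtype=float)
        placed = 0
        taken: list[tuple[int, int]] = []
        attempts = 0
        while placed < k:
            attempts += 1
            if attempts > 10000:
                raise ValueError("infeasible loop configuration")
            si = int(rng.choice(len(segs), p=seg_w / seg_w.sum()))
            s, e = segs[si]
            max_sep = min(cfg.loop_sep_range_bins[1], e - s - 4)
            if max_sep < cfg.loop_sep_range_bins[0]:
                continue
            sep = int(rng.integers(cfg.loop_sep_range_bins[0], max_sep + 1))
            b1 = int(rng.integers(s + 2, e - sep - 1))
            b2 = b1 + sep
            if any(abs(b1 - x) < 8 or abs(b2 - y) < 8 for x, y in taken):
                continue
            taken.append((b1, b2))
            amp = cfg.loop_amplitude * float(rng.uniform(0.85, 1.15))
            lrows.append((chrom, b1, b2, amp, status[placed]))
            placed += 1
    loops = pd.DataFrame(lrows, columns=["chrom", "bin1", "bin2", "amplitude", "status"])

    bias = rng.lognormal(0.0, cfg.bias_sigma, size=total)

    genes = _place_genes(rng, cfg, spec, v_normal, switched, boundaries, loops)

    return SyntheticTruth(
        cfg, seed, spec, v_normal, v_tumour, switched, boundaries, loops, bias, genes
    )


def _place_genes(rng, cfg, spec, v_normal, switched, boundaries, loops) -> pd.DataFrame:
    total = spec.total_bins
    res = spec.resolution
    weights = np.where(v_normal > 0, cfg.gene_density_ratio, 1.0)
    weights = weights / weights.sum()
    gbins = rng.choice(total, size=cfg.n_genes, p=weights)
    off = spec.offsets
    # per-sample shifts for genes near differential boundaries / loops
    enh = boundaries[boundaries["class"] == "enhanced"]
    gained = loops[loops["status"] == "gained"]
    lost = loops[loops["status"] == "lost"]
    wbins = cfg.gene_window // res // 2
    rows = []
    for g, gb in enumerate(gbins):
        ci = int(np.searchsorted(off, gb, side="right") - 1)
        chrom = spec.chroms[ci]
        b = int(gb - off[ci])
        start = b * res + int(rng.integers(0, max(1, res - 2000)))
        end = min(start + int(rng.integers(1000, 3 * res)), spec.lengths[ci] - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        comp = "A" if v_normal[gb] > 0 else "B"
        if switched[gb]:
            sw = "B-to-A" if v_normal[gb] < 0 else "A-to-B"
        else:
            sw = f"{comp}-to-{comp}"
        effect = 0.0
        if sw == "B-to-A":
            effect += cfg.switch_effect
        elif sw == "A-to-B":
            effect -= cfg.switch_effect
        ec = enh[enh["chrom"] == chrom]
        if len(ec) and np.min(np.abs(ec["bin"].to_numpy() - b)) <= wbins:
            effect += cfg.boundary_effect
        gc = gained[gained["chrom"] == chrom]
        if len(gc) and np.min(
            np.minimum(np.abs(gc["bin1"].to_numpy() - b), np.abs(gc["bin2"].to_numpy() - b))
        ) <= 2:
            effect += cfg.loop_effect
        lc = lost[lost["chrom"] == chrom]
        if len(lc) and np.min(
            np.minimum(np.abs(lc["bin1"].to_numpy() - b), np.abs(lc["bin2"].to_numpy() - b))
        ) <= 2:
            effect -= cfg.loop_effect
        base = cfg.base_log2_a if comp == "A" else cfg.base_log2_b
        rows.append((f"gene{g:04d}", chrom, start, end, strand, comp, sw, effect, base))
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "start", "end", "strand", "compartment",
                 "switch_category", "effect_log2", "base_log2"],
    )


# ---------------------------------------------------------------------------
# Contact-map simulation
# ---------------------------------------------------------------------------

def _cis_intensity(truth: SyntheticTruth, chrom: str, sample: str) -> np.ndarray:
    """Expected (unbiased-depth) cis intensity field for one chromosome,
    scaled so the upper triangle sums to the configured cis depth."""
    cfg = truth.config
    n = truth.spec.n_bins(chrom)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    s_eff = np.maximum(sep, 0.5).astype(float)
    decay = s_eff ** cfg.alpha

    v = truth.chrom_v(chrom, sample)
    mod = np.clip(1.0 + cfg.plaid_c * np.outer(v, v), 0.05, None)

    bnd = truth.boundary_bins(chrom, sample)
    col = "strength_normal" if sample == "normal" else "strength_tumour"
    cuts = bnd["bin"].to_numpy()
    strengths = bnd[col].to_numpy()
    # TAD membership from boundary partition; enrichment ramps up over a few
    # bins from the domain edge so corners are not step discontinuities
    tad_id = np.searchsorted(cuts, idx, side="right")
    same_tad = tad_id[:, None] == tad_id[None, :]
    if cuts.size:
        edge_dist = np.min(np.abs(idx[:, None] - cuts[None, :]), axis=1)
    else:
        edge_dist = np.full(n, cfg.tad_taper_bins)
    g = np.clip(edge_dist / max(cfg.tad_taper_bins, 1), 0.0, 1.0)
    ramp = np.minimum(g[:, None], g[None, :])
    mod = mod * np.where(same_tad, 1.0 + (cfg.tad_t - 1.0) * ramp, 1.0)
    # attenuation across each crossed boundary, fading smoothly with
    # separation: insulation is strong near the diagonal and negligible at
    # long range, so compartment-scale structure is untouched
    logf = np.zeros(n + 1)
    for b, s in zip(cuts, strengths):
        logf[b:] += np.log1p(-cfg.boundary_attenuation * s)
    cum = logf[idx]
    # real insulation transitions are not one-bin sharp: soften each step
    # over a few bins with a short triangular kernel
    ker = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    ker /= ker.sum()
    cum = np.convolve(np.pad(cum, 2, mode="edge"), ker, mode="valid")
    u = np.exp(-sep / cfg.attenuation_decay_bins)
    mod = mod * np.exp(-u * np.abs(cum[:, None] - cum[None, :]))

    for r in truth.loop_list(sample).itertuples():
        if r.chrom != chrom:
            continue
        di = idx - r.bin1
        dj = idx - r.bin2
        bump = np.exp(-(di[:, None] ** 2 + dj[None, :] ** 2) / (2 * cfg.loop_sigma**2))
        bump = bump + bump.T  # place the peak at (b1, b2) and its mirror
        mod = mod * (1.0 + r.amplitude * bump)
    # Alternate a Sinkhorn-style row flattening with per-separation
    # normalisation: the structural field then neither carries marginal
    # (bias-like) effects — those are planted separately as biases — nor
    # distorts the s^alpha decay.  Without the flattening, locally depleted
    # bins (e.g. boundary bins) would acquire compensating balancing
    # weights that turn into long-range stripe artifacts after ICE.
    counts = np.bincount(sep.ravel(), minlength=n)
    for _ in range(3):
        row = mod.mean(axis=1)
        mod = mod / np.sqrt(np.outer(row, row))
        strata_mean = np.zeros(n)
        np.add.at(strata_mean, sep.ravel(), mod.ravel())
        mod = mod / (strata_mean / counts)[sep]

    mu = decay * mod
    iu = np.triu_indices(n, k=0)
    scale = cfg.cis_depth_per_chrom / mu[iu].sum()
    return mu * scale


def simulate_contact_map(
    truth: SyntheticTruth, sample: str = "normal", seed: int = 0
) -> ContactMatrix:
    """Poisson-sample one contact map (cis and trans) from the truth."""
    cfg = truth.config
    if cfg.cis_depth_per_chrom <= 0:
        raise ValueError("zero depth")
    if sample not in ("normal", "tumour"):
        raise ValueError(f"unknown sample {sample!r}")
    rng = np.random.default_rng(seed)
    spec = truth.spec
    off = spec.offsets
    rows_all, cols_all, vals_all = [], [], []
    total_cis = 0.0
    for ci, chrom in enumerate(spec.chroms):
        mu = _cis_intensity(truth, chrom, sample)
        b = truth.bias[spec.chrom_slice(chrom)]
        mu = mu * np.outer(b, b)
        n = mu.shape[0]
        iu = np.triu_indices(n)
        # biases inflate total intensity; rescale so the configured cis
        # depth is the exact expectation
        mu *= cfg.cis_depth_per_chrom / mu[iu].sum()
        counts = rng.poisson(mu[iu])
        nz = counts > 0
        rows_all.append(iu[0][nz] + off[ci])
        cols_all.append(iu[1][nz] + off[ci])
        vals_all.append(counts[nz].astype(float))
        total_cis += mu[iu].sum()

    tf = cfg.trans_fraction_normal if sample == "normal" else cfg.trans_fraction_tumour
    if tf > 0 and spec.n_chroms > 1:
        t_total = total_cis * tf / (1.0 - tf)
        nb = spec.bins_per_chrom
        prod = np.outer(nb, nb).astype(float)
        np.fill_diagonal(prod, 0.0)
        pair_share = np.triu(prod, 1) / np.triu(prod, 1).sum()
        for ci in range(spec.n_chroms):
            for cj in range(ci + 1, spec.n_chroms):
                bi = truth.bias[spec.chrom_slice(spec.chroms[ci])]
                bj = truth.bias[spec.chrom_slice(spec.chroms[cj])]
                base = np.outer(bi, bj)
                mu_t = base / base.sum() * t_total * pair_share[ci, cj]
                counts = rng.poisson(mu_t)
                r, c = np.nonzero(counts)
                rows_all.append(r + off[ci])
                cols_all.append(c + off[cj])
                vals_all.append(counts[r, c].astype(float))

    return ContactMatrix.from_pixels(
        spec,
        np.concatenate(rows_all),
        np.concatenate(cols_all),
        np.concatenate(vals_all),
    )


def simulate_pair(
    truth: SyntheticTruth, seed_normal: int = 1, seed_tumour: int = 2
) -> tuple[ContactMatrix, ContactMatrix]:
    """Paired normal-like and tumour-like maps sharing all unchanged
    structure; for a replicate pair, call ``simulate_contact_map`` twice
    with the same sample and different seeds."""
    return (
        simulate_contact_map(truth, "normal", seed_normal),
        simulate_contact_map(truth, "tumour", seed_tumour),
    )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: SyntheticTruth, n_replicates: int = 3, seed: int = 0, coupling: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Per-gene log-normal counts for both conditions and a surrogate DE
    table (Welch t-test on log2 counts, BH-corrected).

    Returns (gene BED-like table, expression table, raw count array of
    shape (genes, 2 * n_replicates) with normal replicates first).
    ``coupling=False`` zeroes every planted condition effect (global null).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    g = truth.genes
    base = g["base_log2"].to_numpy()
    effect = g["effect_log2"].to_numpy() if coupling else np.zeros(len(g))
    ng = len(g)
    log_n = base[:, None] + rng.normal(0, cfg.replicate_sigma, (ng, n_replicates))
    log_t = (base + effect)[:, None] + rng.normal(0, cfg.replicate_sigma, (ng, n_replicates))
    counts = np.rint(2.0 ** np.concatenate([log_n, log_t], axis=1)).astype(int)
    t_res = ttest_ind(log_t, log_n, axis=1, equal_var=False)
    log2fc = log_t.mean(axis=1) - log_n.mean(axis=1)
    padj = multipletests(t_res.pvalue, method="fdr_bh")[1]
    expr = pd.DataFrame(
        {
            "gene": g["gene"],
            "log2FC": log2fc,
            "padj": padj,
            "pvalue": t_res.pvalue,
            "baseMean": counts.mean(axis=1),
        }
    )
    gene_bed = g[["chrom", "start", "end", "gene", "strand"]].copy()
    gene_bed.insert(4, "score", 0)
    return gene_bed, expr, counts


def gene_density(genes: pd.DataFrame, spec: GenomeSpec) -> dict[str, np.ndarray]:
    """TSS count per bin, per chromosome — the orientation covariate for
    compartment calling."""
    out = {c: np.zeros(spec.n_bins(c)) for c in spec.chroms}
    starts = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    for chrom, t in zip(genes["chrom"], starts):
        out[chrom][int(t) // spec.resolution] += 1
    return out
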