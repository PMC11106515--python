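"""Coupling structural layers (compartment switches, boundary classes,
loop classes) to gene annotations and a differential-expression table.

A DEG is a gene with |log2FC| > 1 (strict) and adjusted p < .05.  Group
comparisons of log2 fold changes use the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .contact_core import GenomeSpec

LOG2FC_THRESHOLD = 1.0
PADJ_THRESHOLD = 0.05


def read_gene_bed(path) -> pd.DataFrame:
    """6-column BED: chrom, start, end, name, score, strand."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene with start >= end")
    return df


def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns gene, log2FC, padj, baseMean."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2FC", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    bad = df["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("padj outside [0, 1]")
    return df


def tss(genes: pd.DataFrame) -> pd.Series:
    """Transcription start: start on +, end-1 on -."""
    return np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])


def deg_filter(expr: pd.DataFrame) -> pd.DataFrame:
    """Flag DEGs (|log2FC| > 1 strictly AND p_adj < .05) with direction."""
    out = expr.copy()
    padj = out["padj"].fillna(1.0)
    out["is_deg"] = (out["log2FC"].abs() > LOG2FC_THRESHOLD) & (padj < PADJ_THRESHOLD)
    out["direction"] = np.where(
        ~out["is_deg"], "none", np.where(out["log2FC"] > 0, "up", "down")
    )
    return out


def assign_genes_compartment(
    genes: pd.DataFrame, switch_per_bin: pd.DataFrame, spec: GenomeSpec
) -> pd.DataFrame:
    """Gene -> switch category of its TSS bin (unique per gene)."""
    cat = {
        (r.chrom, r.bin): r.category for r in switch_per_bin.itertuples()
    }
    rows = []
    starts = tss(genes)
    for (_, g), t in zip(genes.iterrows(), starts):
        if g.chrom not in spec.chroms:
            raise ValueError(f"gene {g.gene} on unknown chromosome {g.chrom}")
        length = spec.lengths[spec.chrom_index(g.chrom)]
        if g.start < 0 or g.end > length:
            raise ValueError(f"gene {g.gene} beyond {g.chrom} bounds")
        b = int(t) // spec.resolution
        rows.append((g.gene, g.chrom, b, cat.get((g.chrom, b), "unassigned")))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss_bin", "category"])


def assign_genes_boundary(
    genes: pd.DataFrame,
    boundary_table: pd.DataFrame,
    spec: GenomeSpec,
    window: int = 500_000,
) -> pd.DataFrame:
    """Gene associated with a boundary class when its body overlaps
    [boundary - window/2, boundary + window/2]."""
    res = spec.resolution
    brecs = boundary_table.to_dict("records")
    rows = []
    for _, g in genes.iterrows():
        hit = None
        for r in brecs:
            if r["chrom"] != g.chrom:
                continue
            centre = r["bin"] * res + res // 2
            lo, hi = centre - window // 2, centre + window // 2
            if g.start < hi and g.end > lo:
                hit = r
                break
        if hit is None:
            rows.append((g.gene, g.chrom, -1, "none"))
        else:
            rows.append((g.gene, g.chrom, hit["bin"], hit.get("class", "boundary")))
    return pd.DataFrame(rows, columns=["gene", "chrom", "boundary_bin", "category"])


def assign_genes_loops(
    genes: pd.DataFrame,
    loop_table: pd.DataFrame,
    spec: GenomeSpec,
    radius_bins: int = 2,
) -> pd.DataFrame:
    """Gene associated with a loop class when its TSS bin falls within
    ``radius_bins`` of either anchor bin."""
    starts = tss(genes)
    lrecs = loop_table.to_dict("records")
    rows = []
    for (_, g), t in zip(genes.iterrows(), starts):
        b = int(t) // spec.resolution
        cat = "none"
        anchor = -1
        for r in lrecs:
            if r["chrom"] != g.chrom:
                continue
            if abs(r["bin1"] - b) <= radius_bins or abs(r["bin2"] - b) <= radius_bins:
                cat = r.get("class", "loop")
                anchor = r["bin1"] if abs(r["bin1"] - b) <= abs(r["bin2"] - b) else r["bin2"]
                break
        rows.append((g.gene, g.chrom, b, anchor, cat))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss_bin", "anchor_bin", "category"])


@dataclass
class GroupComparison:
    summary: pd.DataFrame  # group, n, median_log2fc
    pairwise: pd.DataFrame  # group_a, group_b, p, p_adj


def compare_expression_by_category(
    expr: pd.DataFrame, annotation: pd.DataFrame, groups: list[str]
) -> GroupComparison:
    """Per-group log2FC distributions and pairwise two-sided Wilcoxon
    rank-sum p-values (BH-adjusted within the comparison family)."""
    merged = expr.merge(annotation[["gene", "category"]], on="gene")
    rows = []
    vals = {}
    for grp in groups:
        v = merged.loc[merged["category"] == grp, "log2FC"].dropna().to_numpy()
        if v.size == 0:
            raise ValueError(f"group {grp!r} is empty")
        vals[grp] = v
        rows.append((grp, v.size, float(np.median(v))))
    pw = []
    for a, b in combinations(groups, 2):
        if np.array_equal(vals[a], vals[b]):
            p = 1.0
        else:
            p = float(mannwhitneyu(vals[a], vals[b], alternative="two-sided").pvalue)
        pw.append((a, b, p))
    pw_df = pd.DataFrame(pw, columns=["group_a", "group_b", "p"])
    if len(pw_df):
        pw_df["p_adj"] = multipletests(pw_df["p"], method="fdr_bh")[1]
    return GroupComparison(
        pd.DataFrame(rows, columns=["group", "n", "median_log2fc"]), pw_df
    )


def switch_deg_fraction(
    expr: pd.DataFrame, switch_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per chromosome and switch direction: DEGs among switching genes over
    all switching genes; NaN where no gene switches."""
    flagged = deg_filter(expr)
    merged = flagged.merge(
        switch_annotation[["gene", "chrom", "category"]], on="gene"
    )
    sw = merged[merged["category"].isin(["A-to-B", "B-to-A"])]
    rows = []
    for (chrom, cat), grp in sw.groupby(["chrom", "category"]):
        n = len(grp)
        rows.append((chrom, cat, n, int(grp["is_deg"].sum()),
                     grp["is_deg"].sum() / n if n else np.nan))
    return pd.DataFrame(
        rows, columns=["chrom", "category", "n_genes", "n_degs", "deg_fraction"]
    )
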