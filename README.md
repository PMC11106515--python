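# hicdelta

Differential analysis of 3D genome architecture between two conditions —
built for tumour-vs-normal Hi-C comparisons such as GH-secreting pituitary
(somatotroph) tumours against normal pituitary tissue, where chromatin
reorganisation at every scale (compartments, TADs, loops) couples to gene
expression changes.

Given a pair of binned Hi-C contact maps, a gene annotation and a
differential-expression table, `hicdelta` computes:

- **Balanced contact matrices** — iterative correction (ICE) removes
  multiplicative per-bin biases by equalising row sums: find weights
  *w<sub>i</sub>* such that Σ<sub>j</sub> w<sub>i</sub> w<sub>j</sub>
  M<sub>ij</sub> is constant over valid bins.
- **Distance decay** — expected contact frequency per genomic separation
  *s* and its interaction decay exponent (IDE), the log–log slope of
  *E(s) ∝ s<sup>α</sup>*; plus cis/trans fractions, log2 tumour/normal ratio
  maps and inter-chromosomal observed/expected blocks.
- **Reproducibility** — the stratum-adjusted correlation coefficient,
  SCC = Σ<sub>k</sub> w<sub>k</sub> r<sub>k</sub> / Σ<sub>k</sub> w<sub>k</sub>
  with r<sub>k</sub> the Pearson correlation of the smoothed maps in
  separation stratum *k* and w<sub>k</sub> = N<sub>k</sub>√(var<sub>A,k</sub>·var<sub>B,k</sub>).
- **A/B compartments** at the chosen resolution — the leading eigenvector
  (PC1) of the mean-centred correlation matrix of the observed/expected
  cis map, oriented so that the gene-dense state is A (PC1 > 0), and a
  per-bin switch classification (A-to-A, B-to-B, A-to-B, B-to-A).
- **Insulation and TAD boundaries** — diamond insulation score
  log2(raw / chromosome mean); boundaries are prominent local minima; the
  differential rule excludes positions with log2IS > 0 in both samples and
  classifies the rest by |Δlog2IS| > 0.4 (tumour − normal < −0.4 enhanced,
  > +0.4 weakened).
- **Chromatin loops** — donut-filter calling at pixel level: each candidate
  is tested against four local expecteds (donut, horizontal and vertical
  stripes, lower-left block) with a dispersion-calibrated count model and
  λ-chunked FDR control, then clustered; gained/lost loops between samples
  by the observed/donut-expected ratio (threshold 2), and aggregate peak
  analysis (APA score = centre O/E over the lower-left corner block).
- **Expression coupling** — DEG flagging (|log2FC| > 1 and adjusted
  p < .05), Wilcoxon rank-sum comparisons of log2FC between structural
  categories, and per-chromosome DEG fractions among switching genes.

Because matched patient Hi-C data are generally not public, the package
ships a first-class synthetic generator (`hicdelta.synthetic_data`) that
plants all of this structure — power-law decay, compartment plaid, TADs
with boundaries of variable strength, focal loops, bin biases, Poisson
counts, and expression coupled to the planted differences — and exposes the
ground truth, so every caller in the package is benchmarked against known
answers.

## Worked example

Run the whole pipeline on a simulated tumour/normal pair (three 5 Mb
chromosomes at 10 kb, 2×10⁶ cis contacts each):

```bash
hicdelta all --seed 5 --outdir run_out
```

The stage summaries (`run_out/summary_*.json`) from this command read, in
part:

```
balance:      normal IDE per chromosome -0.976, -0.979, -0.954; cis fraction 0.850
              tumour cis fraction 0.900
scc:          pooled SCC tumour vs normal 0.875
compartments: A-to-A 36.1%  B-to-B 43.9%  A-to-B 11.8%  B-to-A 8.1%
insulation:   normal 31 boundaries / 28 TADs (mean spacing 416 kb)
              tumour 41 boundaries / 38 TADs (mean spacing 324 kb)
              differential: 17 enhanced, 5 weakened, 19 unchanged, 1 excluded
loops:        normal 28 loops (APA 5.00), tumour 41 loops (APA 5.08)
              differential: 25 shared, 17 gained, 4 lost
integrate:    600 genes, 134 up / 61 down DEGs
              median log2FC by switch class: B-to-A +1.78, A-to-B -1.59
```

Read them as follows: the planted decay exponent (−1) is recovered to a few
percent; the tumour-like map has a higher cis fraction, more and smaller
TADs, more loops, more enhanced than weakened boundaries, and far more
gained than lost loops; about 20 % of bins switch compartment with A-to-B
ahead of B-to-A; genes in regions switching B-to-A go up, A-to-B genes go
down — each the direction planted by the generator for the tumour state.
The two samples correlate well (SCC 0.87) but below replicate level
(~0.99), as expected for distinct conditions.

The same steps are available as library calls (`make_truth`,
`simulate_pair`, `ice_balance`, `scc`, `call_compartments`,
`insulation_track`/`call_boundaries`, `call_loops`, `differential_loops`,
`apa`, `deg_filter`, ...) — see the module docstrings.

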