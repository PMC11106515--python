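# Methods

This note documents the models, parameter choices and numerical decisions
behind `hicdelta`, and what the synthetic benchmark does and does not show
about real data.

## Contact-matrix model and balancing

Contacts are stored as a sparse upper triangle over a genome-wide bin grid
(0-based, half-open bins; genomic positions are floor-divided by the
resolution). Queries are symmetric by construction. The external format is
tab-separated triplet text (`chromA binA chromB binB count`) plus a
`chrom.sizes` file; both are trivially diffable and round-trip exactly.

ICE balancing finds multiplicative weights equalising the row sums of the
full (cis + trans) matrix. Before iterating, bins with zero coverage and
the bottom 2 % of nonzero-coverage bins (`mask_quantile=0.02`) are masked —
low-coverage bins otherwise receive extreme weights. Iteration updates
weights by the current balanced row sums until their coefficient of
variation over valid bins falls below `tol=1e-5` (cap `max_iter=200`;
non-convergence is a warning, not an error, matching common practice).
Weights are normalised to mean 1 on valid bins, so balanced values keep
roughly the raw-count scale. Balancing a matrix that is already balanced
changes the weights only within tolerance.

Known property: ICE attributes *all* row-sum variation to bias, including
genuine structural variation (chromosome-edge bins see fewer partners and
get up-weighted). On the benchmark this shifts the fitted decay exponent by
about +0.02 to +0.05; it is inherent to the method, not a defect of the
implementation.

## Distance decay and the IDE

The expected value at separation *s* is the mean balanced value over all
valid (unmasked) pixel pairs at that separation, zeros included, masked
bins excluded from numerator and denominator. The interaction decay
exponent is the ordinary least-squares slope of log10 expected vs log10
separation. The default fit range is 50 kb – 10 Mb; on the 5 Mb benchmark
chromosomes the tests fit 50 kb – 4 Mb, inside the available range. At
least 3 positive strata are required.

## SCC

HiCRep-style: mean-filter both cis maps with a (2h+1)² window truncated at
the matrix edge (h = 1 bin by default), then per separation stratum up to
`s_max` (5 Mb) compute the Pearson correlation of the paired pixel vectors
and combine with weights N<sub>k</sub>·√(var<sub>A,k</sub>·var<sub>B,k</sub>).
Zero-variance strata carry no correlation information and are skipped. The
genome-wide value weights chromosomes by their total stratum weight.
Computed on raw counts by default (the HiCRep convention); a flag switches
to balanced values. The train/test selection of the smoothing parameter in
the original method is out of scope.

## A/B compartments

Per chromosome: balanced cis map → observed/expected (each pixel divided by
its separation's expected) → Pearson correlation between bin rows (bins
with zero variance are masked) → leading eigenvector of the column-mean-
centred correlation matrix, computed by shifted power iteration (the shift
makes the algebraically largest eigenvalue dominant; the test suite checks
the result against a dense eigendecomposition to 1e-8). The eigenvector
sign is arbitrary, so it is oriented to correlate positively with gene
density (the gene BED is already an input of the pipeline; GC content would
serve equally). A bins have PC1 > 0, B bins PC1 < 0; exact zeros and masked
bins are unassigned. Orientation fails loudly (an error) if the correlation
with gene density is exactly zero.

Switch classification compares per-bin labels between samples; bins
unassigned in either sample are excluded, and category percentages are
reported over assigned bins (summing to 100).

## Insulation, boundaries, TADs

The diamond insulation score at bin *i* is the mean balanced value of the
w×w block spanning bins (i−w..i−1)×(i+1..i+w), with w = window/resolution.
Scores are NaN within the window of a chromosome edge, at masked bins, and
where fewer than half the diamond's cells are valid. The reported track is
log2(raw / chromosome mean of raw), which makes it exactly invariant to
global scaling. The module default window is 500 kb; the synthetic
benchmark uses 100 kb, matched to the generator's insulation decay length
(below) — with a 500 kb window half of each 5 Mb benchmark chromosome would
sit in the edge NaN zone, a property of the small test genome rather than
of the method.

Boundary calling takes local minima of the log2 track with prominence at
least `min_strength`, with two guards: interior NaN runs of up to 2 bins
are linearly interpolated first (strongly insulating boundaries often lose
their centre bin to the coverage mask, which would otherwise split the
scan segment exactly at the minimum), and minima with log2IS ≥ 0 are
rejected — a "boundary" less insulating than the chromosome average is a
ripple, not a boundary (the same logic as the high-confidence exclusion
rule below). The module default `min_strength` is 0.1 log2 units; the
benchmark calls with 0.3 because planted boundaries produce prominences
of 0.87 and above while background ripples stay near 0.2, so 0.3 sits in
the gap. Boundary count is monotone non-increasing in the threshold.

TADs are the intervals between consecutive boundaries on a chromosome
(half-open, in bp); intervals shorter than 3 bins are dropped. The size
statistic is the mean distance between adjacent boundaries.

Cross-sample boundary matching is greedy nearest-neighbour within a
tolerance (default 1 bin), each boundary matched at most once, yielding a
disjoint, exhaustive partition into conserved / sample-specific sets.

Differential classification evaluates candidate positions (the union of
boundaries called in either sample, deduplicated at 1 bin): positions with
log2IS > 0 in both samples are excluded (not high-confidence); otherwise
Δ = tumour − normal classifies the boundary as enhanced (Δ < −0.4, tumour
more insulating), weakened (Δ > +0.4) or unchanged. The sign convention —
enhanced means *more negative* tumour score — is stated explicitly because
insulation "strength" is often described loosely; here lower log2IS is
always stronger insulation. Positions with a NaN score are reported as
excluded with a reason rather than dropped silently.

## Loop calling

Candidates are cis pixels with nonzero raw count, both bins valid, in the
separation band 50 kb – 2 Mb. For each candidate, four local expected
rates are computed from the balanced matrix: the donut annulus
(p < Chebyshev ≤ w, minus the centre row and column), horizontal and
vertical stripes ((2p+1)-wide bands flanking the peak region), and the
lower-left (w−p)² block toward the diagonal, which guards against domain
corners. Defaults p=2, w=5 bins at 10 kb. Each neighborhood's
balanced-to-expected ratio is rescaled to raw-count space through the
pixel's distance expectation and its bias weights. Neighborhoods losing
more than half their area to the matrix bounds disqualify the pixel.

Two statistical choices depart from a naive Poisson/pooled-BH scheme, both
adopted because that scheme is anti-conservative on structured maps:

1. **Dispersion-calibrated test.** The Poisson null understates the
   variance wherever the local expected misses residual structure (domain
   edges, compartment transitions). A negative-binomial dispersion is
   moment-estimated within log-spaced chunks of the expected value,
   trimming the top 1 % of observed/expected ratios so genuine peaks do
   not inflate it, and the test uses that dispersion; where the estimate
   vanishes (e.g. on homogeneous maps) it reduces exactly to Poisson, so
   null calibration is preserved.
2. **λ-chunked FDR.** BH correction runs within log-spaced chunks of the
   expected value (chunk factor 2^(1/3)), not pooled genome-wide: pooled
   BH lets the astronomically small p-values at true peaks relax the
   rejection threshold for unrelated background pixels.

Survivors must have q ≤ 0.1 against all four neighborhoods and clear fold
floors of 1.75× (donut, lower-left) and 1.5× (stripes). They are clustered
by single linkage within 20 kb; each cluster is reported at its brightest
pixel.

Differential classification recomputes each union loop's observed/donut-
expected in both depth-normalised samples: gained = called in tumour only
with tumour O/E ≥ 2× normal O/E; lost is the mirror; everything else is
shared; pixels masked in one sample are flagged unevaluable. APA stacks
distance-normalised (O/E) windows (half-width 10 bins) over loop pixels
whose window fits; the score is the centre value over the mean of the
lower-left corner block of side half//2+1 = 6.

## Expression integration

A DEG has |log2FC| > 1 (strictly) and adjusted p < .05. Genes map to
compartment categories by their TSS bin (unique per gene), to boundary
classes by body overlap with a ±window/2 interval around the boundary, and
to loop classes by TSS within a small radius of either anchor. Group
comparisons of log2FC use the two-sided Wilcoxon rank-sum test, BH-adjusted
within each comparison family; per-chromosome DEG fractions among
switching genes are reported with NaN where no gene switches.

## The synthetic generator

The cis intensity of pixel (i, j) is

    mu_ij ∝ s^alpha · [plaid · TAD · boundary · loop]_ij · b_i b_j

with s the bin separation (the diagonal uses s = 0.5), alpha = −1 by
default, plaid = 1 + c·v_i·v_j (c = 0.3) for the ±1 compartment vector v,
a within-TAD enrichment t = 2 that ramps up over 5 bins from the domain
edge, a multiplicative attenuation (1 − 0.7·strength) for every planted
boundary crossed whose effect decays with separation as exp(−s/250 kb) and
whose step is smoothed over ±2 bins, Gaussian loop bumps (amplitude 3 ± 15 %,
σ = 1 bin) at planted anchors, and log-normal per-bin biases (σ = 0.2).
Counts are Poisson at 2×10⁶ cis contacts per chromosome; trans mass is
uniform up to biases at 15 % of the total (10 % for the tumour-like sample,
planting the higher tumour cis fraction).

Three structural conventions keep every planted parameter identifiable:

- **Per-separation normalisation with marginal flattening.** The bracketed
  structural field is normalised so its mean at every separation is 1
  (making the marginal decay exactly s^alpha, so the IDE is identifiable)
  and, alternating with that, Sinkhorn-style row flattening removes its
  marginal (bias-like) component — planted biases are then the *only*
  marginal effect, and locally depleted bins (boundary bins) do not
  acquire compensating ICE weights that would turn into long-range stripe
  artifacts. Plaid, TAD and loop effects remain what the downstream
  callers measure: enrichments at fixed separation.
- **Compartment transitions at boundaries.** A/B segments are bounded by
  planted boundaries (as compartment transitions in real genomes coincide
  with TAD boundaries), each chromosome's A fraction is kept in [0.3, 0.7]
  (real chromosomes are roughly balanced), and switched segments are whole
  inter-boundary segments with the quota spread over chromosomes and split
  60:40 toward A-to-B, mirroring the direction reported for the tumour
  state. The requested switch fraction is honoured exactly (one partial
  segment at most).
- **Intra-TAD loops.** Loop anchors lie within one TAD segment (cohesin
  loops do not span boundaries), which also bounds loop sizes by TAD size
  (host-segment-limited, 100 kb – 1 Mb). Anchors of distinct loops are kept
  ≥ 8 bins apart in both coordinates so clusters stay separable.

Tumour differences: switched segments, extra tumour-only boundaries
(3/chromosome), boundary strength shifts of ±0.4 (enhanced boundaries are
drawn from the weakest shared boundaries and weakened from the strongest,
so both shifts stay inside (0, 1] and clear the |Δlog2IS| > 0.4 rule),
5 gained and 1 lost loop per chromosome, and the lower trans fraction.

Expression: genes land 3:1 in A vs B bins; A genes have baseline log2
expression 7 vs 5; condition shifts of ±1.8 log2 apply to genes in
switched bins (B-to-A up, A-to-B down), +1.5 near enhanced boundaries and
±1.5 at gained/lost loop anchors. Replicates (3 per condition) add normal
noise (σ = 0.25 log2); the surrogate differential-expression table comes
from Welch t-tests on log2 counts with BH correction — deliberately not a
negative-binomial count model; the pipeline consumes the table format
either way.

## What the benchmark does and does not show

Passing the recovery suite shows the callers correctly invert the
generator's model at realistic depth and noise: boundary recall/precision
≥ 0.9 (±1 bin), compartment label accuracy ≥ 0.95, switch fraction within
0.05, loop recall ≥ 0.8 with false-call rate ≤ 0.1, gained/lost
classification ≥ 0.8, IDE within 0.1, and calibrated nulls (≈0 loop calls
on homogeneous Poisson maps; uniform rank-sum p-values and <1 % DEGs with
coupling off). It does not show robustness to features the generator
omits: restriction-fragment structure, copy-number aberrations,
translocations, unmappable regions, distance-dependent noise beyond
Poisson, or sub-compartment structure.

Known limitation: on paired maps, compartment switching changes the plaid
factor inside insulation diamonds, adding up to ±0.9 log2 units to the
tumour−normal insulation difference at individual boundaries. The
boundary-level differential classes are therefore noisy on the benchmark
(the aggregate directions — more enhanced than weakened, pileup centre
lower in tumour at enhanced boundaries — are stable). The same confound
exists in real tumour/normal comparisons; the 0.4 threshold implicitly
treats compartment-driven insulation change as real change.

## Benchmark problem sizes

The default benchmark genome is 3 chromosomes × 500 bins at 10 kb (5 Mb
each) with 2×10⁶ cis contacts per chromosome — large enough that every
statistic operates in its intended regime, small enough that the full test
suite and the acceptance script each run in about a minute. Null
calibration uses 20 homogeneous 300-bin maps and 20 (DEG) / 200 (rank-sum
uniformity) expression replicates.
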