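# Methods

## The distance model

A feature is a stranded 1-based genomic position (a putative TSS). Peaks are
0-based half-open BED intervals; the user coordinate is converted
(`q = pos − 1`) inside the distance function and nowhere else. The signed
distance between a TSS and a peak is

- `0` iff `start ≤ q < end` (half-open: a TSS exactly at `end` is outside,
  one at `start` is inside);
- otherwise the gap to the nearest peak edge — `start − q` when the peak
  lies at greater coordinates, `q − end + 1` when at smaller ones — with a
  positive sign when that edge is downstream of the feature (greater
  coordinates for `+`, smaller for `−`).

This rule is symmetric (adjacent bases on either side are both at distance
1), makes `distance = 0` exactly equivalent to overlap, and flips sign under
strand reversal. Nearest-peak ties (equal gaps up- and downstream) go to the
downstream peak; among equally distant peaks on one side, the one with the
smaller start. The tie rules are arbitrary but fixed and tested, so output
is reproducible.

CAGE peaks are stranded and only same-strand peaks are eligible for a CAGE
query; ChIP and DNase peaks are unstranded and always eligible.

## The index

Peaks are bucketed per (sample, chromosome) — per strand as well for CAGE —
and sorted by start. Because peak widths vary, the peak with the greatest
start to the left of a query is not necessarily the closest: the bucket
therefore also carries the running maximum of interval ends and its argmax.
One binary search over starts locates the insertion point; a second over the
(monotone) running-max array detects overlap and identifies the overlapping
peak with the smallest start. Both the left candidate (peak with the
greatest end among starts ≤ q) and the right candidate (first start > q) are
then compared. A brute-force linear scan serves as the oracle in the test
suite; the two must agree exactly on every instance.

## Statistics

For hits `d₁ … dₙ` (some possibly missing when a chromosome holds no
eligible peak):

- **ZH** = #{dᵢ = 0} / n. Missing hits count in the denominator.
- **AUZ_global** = Σ|dᵢ| over non-missing hits, i.e. each feature
  contributes a unit-height rectangle spanning TSS to nearest peak edge.
  AUZ_left / AUZ_right split the sum by sign. Missing hits are excluded and
  reported as `n_missing`. The area could alternatively be defined on the
  ranked zipper curve (trapezoids between consecutive ranks); the
  per-feature rectangle realization is isolated in `stats.auz` so an
  alternative could be swapped in. It reproduces the two properties that
  pin the statistic down: AUZ = 0 iff every feature overlaps its peak, and
  ZH and AUZ move in opposite directions as peaks shift away from TSSs.
- **AUZ_window** (and sided variants) clips each |dᵢ| at the window
  half-width `w` (default 5 000 nt). A missing hit behaves as an infinitely
  far peak and contributes `w`, split evenly between the sides.

### Permutation null

`AUZ_pval` is one-sided: the fraction of `reps` (default 100) random zipper
plots whose AUZ is ≤ the observed one. Random TSS sets preserve the
template's per-chromosome counts and per-chromosome strand multiset (strand
matters for CAGE nulls), and positions are drawn uniformly over the
complement of the exclusion set by cumulative allowed-length inversion, so a
position inside an excluded interval is impossible by construction rather
than by rejection. The plain quotient can be exactly 0; a `(k+1)/(R+1)`
pseudocount convention is available behind a flag. Sided p-values reuse the
same random draws. Random queries run in the same mode (one-sample or
all-samples) as the observed run.

Under the null (features drawn from the same generator) the p-value is
rank-based and uniform on {0, 1/R, …, 1} up to ties; the acceptance suite
verifies P(p ≤ q) ≈ q at q = 0.1, 0.2, 0.5 over 200 trials within binomial
error.

### Per-TSS tissue p-value

In one-sample mode, for each TSS: the fraction of samples whose best
|distance| is ≤ the chosen sample's. The chosen sample counts itself
("as close or closer" includes equality), so the minimum is 1/#samples;
samples without an eligible peak count as infinitely far.

## Peak database construction

narrowPeak / broadPeak / gappedPeak are parsed per the ENCODE column
definitions. The q-value column holds −log10(q), so the FDR filter
"q ≤ α" (default α = 0.05) is `column ≥ −log10 α`; the −1 sentinel
(unavailable) is dropped by default since an unscored peak cannot pass an
FDR filter (`keep_unscored` retains them). gappedPeak block structure is
discarded — distances use the outer interval's edges only. Extra trailing
columns are tolerated with a warning; missing required columns are errors.
CAGE tables are BED6 plus one tpm column per sample; the tpm filter is
strict (`tpm > threshold`) and off by default. Replicate collapsing is a
catalog-level concern: one file per sample_id, no automatic detection.

## Zipper plot and report

Hits are ranked by |distance| (stable; ties by signed distance descending so
overlaps and downstream peaks come first, then input order; missing hits
last). Each peak is drawn from its near edge extending by its width away
from the TSS, truncated at ±w; rows entirely outside the window keep their
rank but draw nothing, which is what makes two plots with equal windows
visually comparable. Rank 1 is at the top; enrichment (tpm or signalValue)
maps to colour on a log1p scale with a fixed colormap. SVG output is
byte-deterministic (fixed hash salt, no timestamp metadata). The HTML
report inlines the plot, the statistics block (4 significant digits;
distances as integers) and a client-side-sortable summary table; a JSON
sidecar carries the same numbers.

## The stitching audit

Gap is measured in transcription direction from the gene's 3′ end (1-based)
to the lncRNA TSS (1-based); `gap = tss − end3` on `+`, mirrored on `−`.
Bounds are inclusive: a CAGE peak at exactly 500 nt counts as support, a
gene at exactly 5 827 nt still stitches, gap 0 is allowed, negative gaps
(gene overlapping or downstream) never stitch. Every qualifying gene yields
its own candidate; for the binned summary each lncRNA counts once with its
maximum-support candidate.

Junction records are BED12 in the spliced-aligner dialect (two blocks whose
sizes are the flank lengths, score = read count). On `+` the genomic-left
flank must overlap a candidate-gene exon and the right flank an lncRNA exon
by ≥ 2 nt each (flanks swap on `−`). A flank that overlaps exons of both an
lncRNA and a protein-coding gene anywhere in the supplied universes (not
just the candidate pair) makes the junction ambiguous and discards it; the
ambiguity test uses the same ≥ min_overlap threshold as the support test,
since a sub-threshold brush against a foreign exon could not have been
called support either. The default 5 827 nt gap bound is the 80th
percentile (nearest-rank) of intron lengths in a reference protein-coding
set; `intron_length_percentile` recomputes it from any gene models.

## Synthetic data

The generator emulates the shapes of the real inputs, not their content:
features are placed on a spaced grid (spacing exceeds twice the maximum
offset plus peak width, so the planted peak is provably the nearest), peaks
are planted at exact signed distances per the distance model, exclusion
intervals occupy a leading fraction of each chromosome, and stitch cases
each occupy their own chromosome with controlled gap, flank-overlap,
ambiguity and CAGE-support geometry. All randomness flows from one integer
seed; identical seeds give byte-identical files. What passing tests show is
that the implementation computes its definitions exactly and that the
permutation machinery is calibrated; they do not show anything about real
peak densities, peak-width distributions or the biological frequency of
mis-annotated lncRNA 5′ ends, since the generator draws none of these from
empirical data.

## Problem sizes and defaults

Defaults: window half-width 5 000 nt, permutation reps 100, FDR α 0.05, tpm
threshold off, feature cap 20 000 (configurable; it guards interactive use,
not an algorithmic limit), CAGE support radius 500 nt, stitch gap bound
5 827 nt, junction overlap 2 nt. The acceptance checks run at desk scale as
the package's own test design: 100-feature closed-zipper scenarios, ~1 100
random oracle-equivalence instances, and 200 calibration trials of 100
replicates over 30-feature templates on two ~2 Mb chromosomes.

## Known limitations

- Peak databases must share one genome build with the input; no coordinate
  lift-over is provided.
- Chromosome names are matched literally.
- The per-feature rectangle AUZ is one realization of "area under the
  zipper"; see above.
- Junctions come from BED12 files; BAM parsing is out of scope (convert
  with a spliced aligner's junction export).
- Missing-hit handling in AUZ_window (contributing exactly `w`) is a
  modelling choice; with very sparse databases it dominates the statistic.
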