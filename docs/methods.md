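# Methods

## Scope and model

cistrokit treats a transcription-factor cistrome as a set of 0-based
half-open peak intervals over a genome, a condition comparison as interval
overlap between two such sets, and motif content as IUPAC-consensus matching
with a Hamming mismatch budget. These are deliberately simple, fully
deterministic primitives: every downstream quantity (dependency fractions,
enrichment p-values, super-enhancer counts, guide ranks) is an exact
function of the inputs and the configured parameters, so planted-truth
recovery can be asserted exactly rather than approximately.

## Consensus scanning

A motif is an IUPAC string with a mismatch budget `k` (default 2). A window
matches when the number of informative positions (consensus ≠ `N`) whose
base is outside the position's IUPAC set is ≤ `k`. Scanning covers both
strands; a minus-strand hit is reported on the plus-strand coordinates of
its footprint. Two rules make the scanner total and unambiguous:

- consensus `N` never mismatches (this is what makes composite-motif spacers
  free), and a sequence `N` (masked/unknown base) mismatches every
  informative position;
- for a palindromic consensus the plus- and minus-strand hits at one
  footprint are the same physical site, and the plus-strand record is kept
  (a determinism tie-break).

This is a direct-matching re-expression of consensus-to-profile scoring:
for a profile derived from a consensus string, a log-odds threshold chosen
to admit two mismatches accepts exactly the Hamming-ball the scanner
enumerates. Expressing it directly removes the dependence on any particular
profile tool's internal probability constants. Position-weight-matrix
scoring and de novo discovery are out of scope.

The scanner is vectorised (a boolean allowed-matrix indexed by a sliding
window view) and is verified in the tests against an independent pure-Python
per-window oracle on random sequence/motif pairs.

## Composite motifs

A composite is `element_a + spacer·N + element_b` with the element order
optionally flipped and element b optionally reverse-complemented; the sweep
enumerates spacers 0–8 × orders × orientations and drops configurations
whose derived consensus string is identical to an earlier one (for identical
elements in the same orientation, AB and BA collapse; the 15 bp palindromic
ARE arises as `AGAACA + NNN + revcomp(AGAACA)`). The mismatch budget applies
to the composite as a whole, not per element: a chimeric site degenerate in
one element but perfect in the other still scores as one unit, which is the
behaviour wanted for half-site biology.

Peak scanning restricts matching to a `window` (default 200 bp) centred on
the peak summit, falling back to the interval midpoint when no summit is
recorded. Neighbourhood co-occurrence counts a partner motif within
`neighbor_dist` (default 25 bp) centre-to-centre of an anchor match, and
compares against a positional null in which partner centres are re-drawn
uniformly within their containing peaks (seeded; 100 shuffles by default).

## Peak-set algebra

- `merge_within` joins peaks whose gap ≤ `merge_gap` (default 500 bp;
  negative gap = overlap) into their union span; idempotent.
- `partition_overlap` marks a peak shared iff it shares ≥ 1 bp with the
  other set (half-open coordinates, so abutting peaks are disjoint). Shared
  peaks are tallied per side, so a Venn summary is available even when
  overlap clusters are many-to-many.
- `classify_dependency` maps condition A/B to lost (A-only), retained
  (shared, reported in A coordinates), gained (B-only);
  `fraction_lost = |lost| / |A|`.
- `annotate_location` assigns promoter > exon > intron > distal_intergenic
  by the peak centre, with promoter = within ± `promoter_dist` (default
  1 kb) of a TSS. The fixed precedence keeps the assignment deterministic;
  it mirrors the convention of the standard annotators.

## Motif enrichment

Per-peak presence (any in-budget hit in the scan window) is the unit of
counting. For foreground F vs background B the p-value is the
hypergeometric upper tail of drawing ≥ x_F motif-positive peaks in |F|
draws from the pooled population of |F| + |B| peaks containing x_F + x_B
positives; q-values are Benjamini–Hochberg across the motif list, and the
log2 fold change uses a 0.5 pseudocount on hit counts so empty cells stay
finite. Exchanging the labels flips the tail exactly (`P(X_B ≥ x_B)` equals
`P(X_F ≤ x_F)` on fixed margins); the tests assert this identity and the
exactness of the tail against direct combinatorial summation. Because
presence is a 0/1 per peak and peaks are disjoint windows, the test is
calibrated under a null where both sets draw from the same sequence
background — verified by simulation (the p-value distribution is
indistinguishable from the enumerated null of the same statistic and is
conservative, never anti-conservative; discreteness at small margins makes
it sub-uniform rather than exactly uniform).

`gc_matched_background` provides a matched control set when no biological
background exists: for each foreground interval it rejection-samples an
interval of identical length whose GC content falls in the same bin
(width 0.05), excluding foreground overlap, and reports per-bin deficits if
the genome cannot supply one.

## Signal matrices

`signal_matrix` averages a bedGraph step function in fixed bins (default
25 bp) across a reference-point window centred on each summit, ± 2.5 kb
being the convention for histone signals and ± 1.5 kb for transcription
factors. Uncovered positions contribute zeros so rows stay rectangular;
skipping zero rows is a plotting concern, not a matrix concern.

## Super-enhancer calling

Peaks are stitched by transitive closure of "gap ≤ `stitch_dist`"
(default 12,500 bp, the conventional stitching distance; configurable) and
scored by track signal summed over constituent bp (not the stitched span,
so sparse constituents are not credited for empty interior). Regions are
ranked ascending, scaled to the unit square (`x` = rank, `y` = score), and
the cutoff placed at the tangent point of the line of slope `min_slope`
(default 1): the rank minimising `y − min_slope·x`. Calls are the strict
suffix past the tangent point. Two properties motivated this discrete rule:

- the backward-difference slope at the first call is ≥ `min_slope` by
  construction, so the "slope ≥ 1" contract holds at the cutoff exactly;
- it is robust to local rank-to-rank noise. A rule chaining per-rank slope
  thresholds breaks whenever two high-scoring regions happen to be close in
  score (order-statistic gaps shrink like 1/N), and a central-difference
  slope smears the typical-to-super jump one rank downward, systematically
  over-calling by one.

If the minimum is attained on a consecutive plateau the curve is locally
parallel to the threshold line (slope exactly `min_slope`), and the plateau
is included — hence an exactly linear curve calls every region, the boundary
reading of "slope ≥ 1". All-equal scores are rejected as a degenerate curve.
Calls are invariant under positive rescaling of scores and are always a
suffix of the ranking.

## Screen ranking

Counts are normalised per population to counts-per-million; guides are
ranked by `log2((cpm_low + pc)/(cpm_high + pc))` with pseudocount 1
(exposed), descending, ties broken by guide id. Normalisation is plain CPM —
the simplest defensible reading of "normalized counts" for a two-bin sorted
readout. Input-bin counts are read and carried through but do not enter the
ranking. Gene scores are unweighted means of guide ratios. Robust rank
aggregation (MAGeCK-style) is a non-goal.

## Synthetic data

The generators are pure functions of seed + parameters (byte-identical
reruns) and emit a truth manifest sufficient to recompute every expected
recovery value without re-running the generator.

- **Background DNA** is i.i.d. with configurable GC (default 0.41, the
  human genome-wide value). No dinucleotide/Markov structure, repeats, or
  mappability — adequate for consensus-with-budget scanning, not for
  benchmarking discovery tools against real genomes.
- **Planted sites** realise the consensus exactly, then apply the drawn
  number of mismatches at informative (non-spacer) positions only. Planted
  sites never overlap each other or peak boundaries. After planting, every
  scanned window is *scrubbed*: background positions producing chance
  in-budget matches are redrawn (planted footprints protected) until the
  planted instance is the only match. A 13–15 bp consensus at budget 2 has
  a ≈1% chance hit per 200 bp window, which would otherwise blur exact
  recovery of planted presence fractions; scrubbing makes the manifest
  exact truth. The cost is a background slightly depleted of near-motif
  sequence relative to real genomes — acceptable here because the recovery
  suite is about the analysis stages, not about genomic base composition.
- **Two-condition cistromes** place peaks 600 bp apart (beyond the 500 bp
  merge distance) on one synthetic chromosome, randomise class positions,
  and plant the chimeric composite in dependent peaks and the full-site ARE
  in independent peaks at configurable purity (plus an optional cross
  fraction of chimeric sites among independent peaks). Defaults: 1000
  wild-type peaks, dependent fraction 0.65. The forkhead element default
  (`TGTTTAC`) is a synthetic stand-in — real analyses should supply their
  own curated element consensi via the motif file.
- **Hockey-stick signal**: 990 regions with scores uniform in [1, 10] and
  10 in [100, 200], each realised as a constant-signal rectangle whose
  integral equals its score, spaced beyond the stitch distance. Overlapping
  score ranges are recorded as a manifest warning.
- **Screen counts**: the two sorted bins partition one infected cell pool,
  so each guide's abundance fluctuation (infection multiplicity, clonal
  growth) is shared between bins: a per-guide Gamma factor with variance
  `dispersion` (default 0.1) multiplies both bin means and bin-level
  sampling is Poisson. Marginal counts are exactly negative binomial with
  Var = μ + dispersion·μ², while the LOW/HIGH ratio carries only sampling
  noise — the property that makes a sorted screen far better powered than
  two independent biological samples at the same depth. Across-guide
  abundance is log-normal (σ = 0.5) around a mean depth of 500 reads/guide.
  PCR jackpotting, guide dropout, and sorting impurity are not modelled.

Passing the recovery suite therefore shows the analysis stages are exact
and calibrated under these idealised conditions; it does not certify
performance on real ChIP-seq peak calls, real genomic background, or real
screen count tables.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `window` | 200 | bp | scan window centred at peak summit |
| `max_mismatch` | 2 | positions | consensus mismatch budget (per composite) |
| `spacer_max` | 8 | bp | largest composite spacer in sweeps |
| `neighbor_dist` | 25 | bp | half-site co-occurrence distance (centre-to-centre) |
| `merge_gap` | 500 | bp | peak reduction distance |
| `promoter_dist` | 1000 | bp | ± distance from TSS for promoter assignment |
| `stitch_dist` | 12500 | bp | super-enhancer stitching distance |
| `slope` | 1.0 | — | tangent-slope threshold on the unit-scaled curve |
| `pseudocount` | 1.0 | CPM | screen ratio pseudocount (0.5 on counts for enrichment fold-changes) |

All are exposed in `RunConfig` / CLI flags; flags override config-file
values, and the effective configuration is echoed into the output directory.

## Known limitations

- bedGraph only (no bigWig); SAM/BAM, peak calling, and read simulation are
  out of scope.
- The overlap partition counts connected many-to-many overlap clusters once
  per side; other collapsing conventions (e.g. counting a cluster once
  globally) would shift Venn counts on heavily nested inputs.
- The co-occurrence null repositions partners within their containing peaks
  only; partners outside any peak keep their observed position.
- Enrichment treats peaks as exchangeable units; peak width or signal
  strength is not modelled as a covariate.
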