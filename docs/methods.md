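# Methods

## The flexibility model

The profiler uses the dinucleotide-step description of DNA torsional
flexibility: each of the 16 base-pair steps carries the magnitude of its
thermal twist-angle fluctuation, in degrees.  Because the two strands of a
duplex read the same physical step, the table must satisfy
σ(XY) = σ(revcomp(XY)) — 10 unique values generate all 16, and the loader
enforces the symmetry to 1e-9.  The flexibility of a window is the
unweighted arithmetic mean of its step values; no intra-window weighting is
applied.

**The packaged table is a synthetic stand-in.**  The published
parameter set of the Sarai et al. model is not bundled; the shipped file
(`data/twist_fluctuation_synthetic.tsv`) is constructed to satisfy the
symmetry and positivity invariants, to bracket the 7–16° range that window
averages of this model family span, and to preserve the qualitative
ordering (TA the most flexible step, pyrimidine–purine above
purine–purine).  Every qualitative behaviour of the pipeline — and every
test in this repository — holds for any table with these properties, but
absolute numbers on real genomes are only meaningful after substituting
transcribed literature values.  The table is a run-time input everywhere
(`--step-table`, `load_step_table`), never hard-coded.

## Windows and coordinates

* Window length L = 100 bp, shift s = 1 bp by default.  A window of L bp
  has L−1 steps; the mean is anchored at the midpoint step, index
  ⌊(L−1)/2⌋ within the window (position `start+49` for L = 100).  The
  "midpoint" of an even-length window is ambiguous by half a step; flooring
  is the deterministic choice and is used consistently, so all downstream
  coordinates are self-consistent.
* Only fully contained windows are evaluated:
  n = ⌊(len − L)/s⌋ + 1 placements.
* Any window containing an N is missing (NaN) and excluded from pooled
  statistics and from run extraction — the step model defines no N
  parameters, and silent imputation would bias the genome mean/sd.
* All internal coordinates are 0-based half-open; GFF3, wiggle and
  RepeatMasker conventions are converted at the I/O boundary only.
* Window means are computed in double precision with numpy's pairwise
  summation; they agree with a per-window `math.fsum` oracle to 1e-9.

## Peak calling

Preselection pools every defined window value across all chromosomes and
derives one genome-wide threshold 𝒮 = μ + kσ (k = 2, population σ).
Per-chromosome statistics are available for diagnostics but do not drive
thresholds.  Runs of consecutive windows with value ≥ 𝒮 (inclusive; a
missing window breaks a run, runs are never gap-merged) become flexible
regions whose footprint is the union of member-window footprints — hence a
minimum region length of L, which is why called peaks are always
substantially longer than the core tract that caused them.  A region is a
peak iff its maximum reaches θ = 13.8°, the threshold established in the
fragile-site flexibility literature; peaks are named `peak<ROMAN>-<k>` in
coordinate order per chromosome, with a configurable chromosome-to-numeral
map.

The value-distribution diagnostic compares the normalized window-value
histogram with a Gaussian of the same mean and sd and reports the excess
mass above a tail threshold (12° by default).  Note that the comparison
uses the *contaminated* mean/sd, so heavy mass planted far above the mean
inflates the fitted sd and can drive the excess negative; the diagnostic is
informative for the realistic regime where the non-Gaussian mass sits just
above the threshold.

## Annotation and co-localization

* Intergenic (interORF) regions are gaps between consecutive
  non-overlapping ORFs on a chromosome; terminal stretches and gaps
  involving overlapping ORFs are excluded.  Orientation classes follow the
  flanking strands: (+,−) convergent, (−,+) divergent, equal strands
  unidirectional.
* Placement priority is telomere > rRNA > inside_ORF > interORF.
  "Inside" requires ≥ 50% of the peak length overlapping one ORF (the
  cutoff is configurable; the notion is otherwise underdetermined), and
  interORF peaks take the class of the region containing the peak
  midpoint, so a wide peak straddling a border gets exactly one class.
* UTR intervals extend the measured 5′/3′ lengths upstream/downstream of
  each ORF on its strand; ORFs missing from the table fall back to the
  table's mean lengths (configurable).  A hit is ≥ 1 bp overlap between a
  peak footprint and a UTR interval, so one peak can legitimately hit the
  3′UTRs of both convergent neighbours.
* The built-in AT tandem-repeat detector finds maximal high-purity
  segments of a phase-match profile ((TA)n period 2; (TTA)n period 3,
  both strands one family; AT-rich as the generic fallback) by a
  maximal-scoring-segment walk with +1 per match and −p/(1−p) per
  mismatch, p = 0.8 by default, minimum length 20 bp.  Positive score
  implies purity > p, boundaries land on matching positions, and the
  penalty prevents a pure tract from creeping into merely AT-biased
  flanking sequence.  More specific families suppress overlapping calls of
  less specific ones.  A substitution within ~1/(1−p) bp of a tract
  terminus genuinely relocates the detected boundary; interior
  substitutions do not.  When a RepeatMasker `.out` file is supplied it
  takes precedence over the built-in detector.
* Poly(A) analysis keeps sites with score ≥ 945 (the intensity cutoff of
  the source cleavage-site dataset), measures the unsigned distance to the
  nearest in-peak repeat midpoint on the same chromosome, discards
  distances > 500 nt, and reports the fractions within 25 and 100 nt.
  Distances are unstranded.

## Statistics

Fisher's exact test is two-sided by the standard "sum all tables with
point probability ≤ observed" rule (hypergeometric with fixed margins,
1e-12 relative tie slack; exactly 1.0 when the observed table is the
mode).  Welch's unequal-variance t with Welch–Satterthwaite degrees of
freedom is used for group comparisons — half-life variances across gene
groups are not plausibly equal, and the pooled-variance alternative is
strictly less defensible here.  Reported p-values are uncorrected;
Benjamini–Hochberg q-values are available as a helper.  The 2×2 tables
behind each enrichment test are emitted verbatim so every margin can be
audited against the input counts; the background constructions
(interORF vs ORF base pairs; interORF region counts per orientation class;
regions overlapping a 3′UTR) are this package's documented choices.

## The synthetic study

The generator emulates the statistical structure the pipeline targets, not
yeast biology in detail:

* i.i.d. background sequence at GC 0.38 (no higher-order composition,
  no isochores) — sufficient to exercise window arithmetic, thresholds and
  repeat detection against a realistic AT-rich baseline.
* Three 100 kb chromosomes with ~1.9 kb gene pitch (genes 0.8–2 kb, gaps
  300–700 bp), strands cycling convergent/unidirectional/divergent/
  unidirectional for an exact-ground-truth 1:2:1 class mix.  UTRs are
  40–160 nt (5′) and 80–220 nt (3′).
* Six gaps per chromosome receive a (TA)60 tract (120 bp > L, so a fully
  contained window exists; its exact mean is computed analytically from
  the table and must exceed θ) with 1% substitutions, placed to overlap
  the 3′UTR of the flanking gene whose 3′ end abuts the gap.  One tract
  goes into a telomere and one into an rRNA locus to exercise placement
  priority.  Each tract is framed by single G/C guard bases so its
  boundaries are exact ground truth.
* Poly(A) sites per in-gap tract: offsets drawn from a 75%/25% mixture of
  uniform [5, 25] and [26, 500] nt around the tract midpoint (signed at
  random), scores 60% "intense" (≥ 945); plus 25 background sites per
  chromosome.
* Half-lives are lognormal: overall 22 min background vs 13 min for ORFs
  whose true 3′UTR overlaps a planted tract ± 100 bp (the called peak's
  typical halo), poly(A) 17 vs 10 min, σ_log 0.45, 2% missing.  In a
  convergent gap this flags both neighbours, mirroring shared terminator
  territory.  The medians are not drawn from a published table (the source
  half-life dataset prints none); they are a realistic yeast-scale
  turnover with a planted effect large enough to be unambiguous.

Everything is deterministic given (spec, seed) and recorded in an exact
manifest.  What passing tests on this fixture do **not** show: behaviour on
real chromatin composition (isochores, homopolymer runs, real repeat
families), on annotation edge cases of real GFFs, or absolute agreement of
thresholds/peak counts with any real genome — the latter depends entirely
on the parameter table (above).

## Problem sizes and numerical choices

The default test and reproduction runs profile ~3 × 10⁵ windows (three
100 kb chromosomes), a size chosen so the whole suite re-runs in seconds
while every stage still operates far from small-sample artifacts; the
implementation itself is linear in genome length and handles
tens-of-megabase genomes in minutes.  Histogram bins: 0.05° for value
distributions, 5 kb for inter-peak distances, 25 nt for poly(A) distances.
Ties: preselection and θ are inclusive (≥); the Fisher tie slack is 1e-12
relative; the repeat walk uses a 1e-9 score tolerance because p/(1−p) is
not exactly representable in binary.

## Known limitations

* The shipped step table is synthetic (see above); real-genome numbers
  require the literature parameters.
* The repeat detector is a stand-in for RepeatMasker with only three
  family labels; family proportions on real genomes are not comparable.
* Fisher backgrounds are documented constructions, not the only defensible
  ones; the emitted tables exist precisely so users can re-test their own.
* EE/PE consensus motif scanning (TAYRTA / AAWAAA), motif discovery,
  GO enrichment and cross-species conservation are out of scope.
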