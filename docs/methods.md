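# Methods

This note documents the models and procedures implemented in `flagmet`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.  It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Promoter and RBS scanning

Upstream regions are extracted on the coding strand, ending at the base
immediately before the annotated start codon (reverse-strand genes take the
reverse complement of the 3′ flank).  All spacings count nucleotides
*strictly between* elements: the −35/−10 spacer is the gap between the end
of the −35 box and the start of the −10 box, and "distance to start codon"
is the gap between the −10 end (or RBS end) and the first base of the start
codon, so a distance of 0 means the element abuts the start codon.

Consensus motifs are case-encoded strings: uppercase positions are strongly
conserved, lowercase weakly conserved; IUPAC degenerate letters are allowed
at either kind of position (M = A/C etc.).  The shipped defaults are the
*Butyrivibrio fibrisolvens* pairs — σ²⁸: −35 `TAAA`, −10 `MCGATAa`, native
spacer 16–17 bp; σ⁴³: −35 `TTtACA`, −10 `cATAAT`, native spacer 19 bp —
plus the general bacterial pairs (σ²⁸ `TAAA`/`CCGATAT` N15, σ⁴³
`TTGACA`/`TATAAT` N15) for comparison runs.  *B. fibrisolvens* is used as
the reference because it is the closest characterized relative of the
*Roseburia* group with mapped flagellin promoters.

A `ScanPolicy` fixes (i) the mismatch budget per element at strong
positions, (ii) the budget at weak/degenerate positions, (iii) the spacer
window searched, and (iv) the upstream search length.  Defaults: strong 0,
weak 1, spacer 8–30 bp, 400 bp upstream.  The spacer window is much wider
than the consensus-native windows because the predicted promoters of these
genomes include clearly unconventional spacings (observed 9–27 bp); calls
whose spacer falls inside the motif's native window carry a
`canonical=True` flag instead.  The 400 bp search length covers the largest
observed promoter-to-start distance (375 bp).  A second stock policy,
`LENIENT_POLICY` (strong budget 1), is needed to reproduce the published
calls: several reference elements (e.g. −10 `tcgatat` against `MCGATAa`,
or `tataaa` against `cATAAT`) deviate from the consensus at one strongly
conserved position, so a strict-strong policy cannot return them.  The
strict policy remains the default because it keeps chance matches in random
sequence rare; which policy was used is always an explicit argument.

Every placement of a −35/−10 pair that satisfies the policy is reported
(genes may legitimately carry both a σ²⁸ and a σ⁴³ promoter); calls are
ordered by distance to the start codon and the nearest call is treated as
primary.  The scanner is exhaustive over placements, and the test suite
checks it against an independently written brute-force enumeration.

RBS detection looks for the best hexamer against `AGGAGG` whose end lies
within 20 bp of the start codon: fewest mismatches first, then closest to
the start.  The per-operation default budget is 1 mismatch; the pipeline
default is 2, because observed sites include two-mismatch hexamers
(e.g. `AGGAAA`).

## TLR5 assessment

The D1-domain region of flagellin recognized by TLR5 is represented by an
11-residue consensus covering flagellin-numbering positions 87–97 (default
window `LQRVRELAVQS`; the string is configuration, not an assertion — all
tests plant their own windows).  The best-identity ungapped window of the
query is located exhaustively (ties break to the smallest offset) and
conservation is checked at the five critical positions L87, Q88, R89, L93,
Q96.  The verdict `predicted_pro_inflammatory` requires positions 87, 89,
93 and 96; position 88 may vary, because naturally occurring Q88D
flagellins are still regarded as pro-inflammatory.  The required set is
configurable.  The numbering convention — window start = position 87 — is
explicit and configurable, since query-internal and reference numbering
need not agree.

N-terminal comparisons use exact positional identity over the first ten
residues (the quantity produced by Edman sequencing of protein bands), and
clustering partitions proteins by their exact N-terminal 10-mer.

## Protein masses

Masses are the sum of average (isotope-abundance-weighted) residue masses
plus one water, reported in kDa to two decimals.  Published tables do not
state how their kDa values were derived (average vs monoisotopic masses,
signal-peptide handling), so the package documents its own convention and
does not assert equality with published values; the implementation is
cross-checked against Biopython's average protein weight.

## Synthetic data

The generator emulates the study system at its stated conditions:

* **Genomes** — random background sequence at 45 % GC (typical for these
  Lachnospiraceae; composition is configurable, as no value is prescribed),
  with a 34-gene motility locus placed contiguously on the + strand.  The
  default locus spec totals 30 732 bp (within the observed 30.5–31.5 kb
  span) with gene lengths 267–2085 bp and median ~900 bp.  Flagellin genes
  are dispersed with ≥450 bp of clear upstream room so promoters can be
  planted.
* **Promoter planting** writes the requested elements at the requested
  spacings and rejection-samples every other upstream position until a scan
  of the region returns exactly the planted calls (and RBS).  This makes
  planted-promoter tests exact rather than probabilistic.
* **Communities** — species → percent maps summing to 100; the default
  seven-species profile spans 0.01–31.59 %, the observed dynamic range.
* **Reads** — 91 bp single-end, allocated to species multinomially (or by
  rounded expectation in `expected` mode) and placed uniformly on the
  genome treated as circular.  Single-end suffices because per-CDS
  detectability depends only on start-position density; the circular
  convention avoids edge effects and matches the closed-form count model.
  Substitution errors are optional (default 0); indels, chimeras and
  realistic quality profiles are out of scope.
* **Coverage unevenness** is emulated by *blackout intervals* from which no
  read may start.  Real metagenomes show unevenness whose generating
  process is uncharacterized; blackout is one plausible emulation, chosen
  because it reproduces the qualitative observation that a whole locus can
  be missing from an otherwise abundant genome.  To make a locus entirely
  invisible the blackout must start one read length upstream of it,
  otherwise reads beginning just before the interval still overlap its
  first gene.
* **Cytokine experiments** — log-normal concentrations with a per-day
  (per-experiment) scale factor (σ = 0.5) shared across treatments and
  per-measurement noise (σ = 0.3), times the treatment's mean fold-change.
  The day scale cancels exactly under the proportion transform, which is
  the transform's purpose.  At these noise levels a 3-fold effect over six
  experiments is detected at α = 0.01 by the exact one-tailed test in the
  large majority of seeds, mirroring the design it emulates.

What passing tests on these synthetics do **not** show: performance on real
reads (sequencing error structure, strain-level variation, conserved
flagellin domains shared across species, assembly artefacts) or the
behaviour of the real aligner the study used.

## Read mapping and detectability

Mapping is substitution-only, end-to-end: a read maps wherever its full
length aligns with at most `max_mismatch` (default 2) substitutions.  The
mapper seeds with `max_mismatch + 1` disjoint 16-mers, so by pigeonhole at
least one seed is exact for any admissible placement — the mapper is
*complete* for this alignment model, not heuristic.  Ties are broken
deterministically (first genome, then smallest coordinate); a read
overlapping two CDSs by ≥1 bp increments both (configurable convention; no
external prescription exists).  The published analysis used an external
aligner whose exact behaviour is not reproducible; this contract replaces
it.

Expected counts follow from uniform circular placement: a read of length ℓ
overlaps a CDS of length L iff its start falls in a window of L + ℓ − 1
positions, giving E = n(L + ℓ − 1)/G.  Normalization multiplies raw counts
by mean depth / sample depth (mean 4.79 × 10⁹ bases); presence thresholds
are exactly 10 and 10^1.5 ≈ 31.62 on the normalized scale, compared with ≥.
Besides per-gene calls, a locus-majority summary (fraction of locus genes
at least "present") is provided, since presence can be judged per gene or
per locus.

The coverage formula multiplies metagenome size (Mb) by relative abundance
and divides by average genome size (Mb).  As printed it mixes percent and
fraction; it is implemented with abundance/100 so that 1 % of a 4 000 Mb
metagenome over a 4 Mb genome gives 10×, consistent with the worked
magnitudes it is used for (~28× at ~2 %).  Dimensional consistency decides
this.

The marker-based abundance estimator maps reads to the reference, computes
per-species reads per marker kilobase and renormalizes to 100 %.  It
requires markers unique to their species; with zero marker hits it returns
a uniform profile with a warning rather than failing, so pipelines proceed
on empty samples.  Contig species assignment follows the published rule:
assign iff at least half the contig's CDSs have best hits at ≥90 % identity
and those qualifying hits name exactly one species.  Percent identity is
matches over alignment columns under global alignment (match 1, mismatch 0,
linear gap −1 — the gap score shapes the traceback only), delegated to
Biopython's pairwise aligner and cross-checked against a hand-written
dynamic-programming oracle.

## Statistics

* Proportion transform: each concentration divided by the within-experiment
  sum; scale-invariant per experiment by construction.
* One-tailed Mann-Whitney U: exact (full enumeration, via scipy's exact
  method) when the pooled sample is ≤12 without ties, otherwise the normal
  approximation with tie correction; the mode used is recorded.  Completely
  tied data carries no evidence and returns p = 1 with a `degenerate-ties`
  flag.
* Kruskal-Wallis: scipy's tie-corrected H with df = k − 1; the all-identical
  case (where the rank statistic is undefined) is defined as H = 0, p = 1.
* Spearman association: rho and t-approximation p per species, adjusted
  across species by Bonferroni (default) or Benjamini-Hochberg.  Bonferroni
  is the default because the analysis it reproduces reports an adjusted p
  consistent with multiplying the smallest raw p by the number of species
  tested.  Constant vectors are flagged, not tested, and excluded from the
  correction count.  The "Tukey test on Kruskal-Wallis output" sometimes
  mentioned alongside such analyses is statistically irregular (a
  Nemenyi-type procedure is presumably meant) and is deliberately not
  implemented.

## Problem sizes and numerical choices

The acceptance script simulates at the study's own per-species scale:
a 3.5 Mb genome and the target species' share of a 4.79 Gb metagenome
(52 637 reads at 0.1 %, 210 549 at 0.4 %), with 10 simulation seeds per
quantity; it completes in about a minute on one CPU.  The test suite uses
smaller geometries (50–350 kb genomes, 10³–10⁵ reads) chosen so that
expected counts sit well away from decision boundaries; stochastic
assertions use 3-standard-deviation bands under fixed seeds, and the
Monte-Carlo check of the expected-count formula uses 4 × 10⁶ placements on
a geometry where the binomial sampling error is comfortably below the 1 %
comparison band.  The single ~1 kb acceptance CDS is 999 bp, the nearest
codon multiple.  All generators derive from `numpy.random.default_rng`
seeds; every stage of the CLI fans a global seed out by fixed offsets so
stages are independently reproducible.

## Known limitations

* No indel tolerance in mapping; real reads with indels near a CDS boundary
  would be dropped, slightly deflating counts.
* Synthetic backgrounds are i.i.d. sequence: no repeats, no homology between
  species, so cross-mapping — a real confounder for conserved flagellin
  domains — is absent by construction.
* The promoter scanner is consensus/mismatch based, not a position-weight
  or energy model, and scans the coding strand only.
* FASTA/TSV IO is deliberately minimal (no GenBank/GFF3, no ambiguity-aware
  translation, no frameshift correction).
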