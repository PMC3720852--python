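# flagmet

Flagellar motility genes of commensal gut *Eubacterium* and *Roseburia*
species sit in a ~31 kb locus of ≥34 contiguous genes (*flgB–fliA*), with
flagellin (*fliC*) genes mostly dispersed elsewhere in the genome.  These
flagellins matter twice over: they are transcribed from dedicated σ²⁸
(FliA) or housekeeping σ⁴³ promoters, and the proteins carry the conserved
D1-domain region through which human TLR5 recognizes flagellin and triggers
IL-8 secretion.  Whether such genes can even be *seen* in a shotgun
metagenome depends on sequencing depth, gene length and the species'
relative abundance.

`flagmet` is a Python library (plus a thin `flagmet` CLI) that implements
this whole in-silico workflow on synthetic communities, for microbiome
researchers who want the analysis reproducible end to end:

* **`flagmet.seqio`** — FASTA and gene-feature-table IO, protein masses.
* **`flagmet.synth`** — synthetic genomes with a planted 34-gene motility
  locus (30.5–31.5 kb), flagellin genes with planted promoters/RBS,
  community abundance profiles (0.01–31.59 %), 91-bp shotgun reads with
  hidden origin labels, and synthetic cytokine experiments.
* **`flagmet.promoter`** — σ²⁸/σ⁴³ −35/−10 consensus scanning
  (case-encoded consensus strings, per-element mismatch budgets, spacer
  windows) and Shine–Dalgarno (AGGAGG) detection within 20 bp of the start
  codon.
* **`flagmet.tlr5`** — classification of flagellins as predicted
  pro-inflammatory by conservation of the critical residues (L87, Q88, R89,
  L93, Q96) in the TLR5-recognized 11-residue consensus window, and
  N-terminal 10-mer comparisons.
* **`flagmet.detect`** — substitution-only end-to-end read mapping to
  target CDSs, depth normalization, presence thresholds, heat matrices,
  marker-based abundance estimation, coverage arithmetic and the contig
  species-assignment rule.
* **`flagmet.stats`** — the per-experiment proportion transform, exact
  one-tailed Mann-Whitney U, Kruskal-Wallis, and Spearman association with
  multiple-testing adjustment.

## The model in brief

Reads are placed uniformly on a circular genome.  A read of length ℓ
overlaps a CDS of length *L* by ≥1 bp iff its start falls in a window of
*L* + ℓ − 1 positions, so with *n* = depth × abundance/100 ÷ ℓ reads from
the target species the expected mapped count per CDS is

    E = n · (L + ℓ − 1) / G

for a genome of size *G*.  Counts from metagenomes of unequal depth are
rescaled by

    normalized = raw × (mean depth / sample depth),   mean depth = 4.79 Gb,

and a CDS is called **present** at ≥10 normalized reads and **strong** at
≥10^1.5 ≈ 32.  Genome coverage uses the companion formula
metagenome size (Mb) × abundance (%) / genome size (Mb), with the percent
taken as a fraction (1 % of 4 000 Mb over a 4 Mb genome = 10×).

## Worked example

`examples/detectability.py` simulates a target species' share of a deep
metagenome at a geometry scaled to one tenth of study size (350 kb genome,
479 Mb depth — per-CDS expectations unchanged) and prints:

```
abundance 0.1%: median normalized count 12.5, 68% of 34 locus genes present
  fliQ (267 bp): observed 5, expected 5.4, call absent
  flhA (2085 bp): observed 28, expected 32.7, call present
abundance 0.01%: median normalized count 2.0, 0% of 34 locus genes present
  fliQ (267 bp): observed 1, expected 0.5, call absent
  flhA (2085 bp): observed 5, expected 3.3, call absent
```

At 0.1 % relative abundance a typical (~900 bp) motility CDS clears the
presence threshold while the shortest genes do not — detectability is a
function of CDS length and abundance; at 0.01 % the locus is effectively
invisible.  The other examples are equally short:
`examples/promoter_scan.py` plants a σ²⁸ promoter (−35 `taaa`, 17 bp
spacer, −10 `tcgatat`, 69 bp to the start codon, RBS `AGGAAA` at 9 bp) and
recovers exactly those values; `examples/tlr5_assessment.py` shows that a
Q88D flagellin is still predicted pro-inflammatory while R89A is not, and
that four of the five *E. rectale* A1-86 flagellins share an identical
N-terminal 10-mer (the fifth conserves 4/10); `examples/cytokine_stats.py`
reproduces the proportion transform and gets an exact one-tailed
Mann-Whitney p = 0.0011 for a 3-fold IL-8 effect over six experiments.

A full pipeline run (`synth → promoters → tlr5 → detect → stats`) is one
command:

```
flagmet all --config run.yaml --seed 7 --outdir out/
```

## Reference tables

Two small published tables ship with the package
(`flagmet.load_reference_flagellins()` / `load_reference_promoters()`):
per-flagellin sizes, N-terminal 10-mers and clades, and the predicted
promoter/RBS calls with their spacings.  Summarizing the promoter table
with `summarize_promoter_spacings` gives the per-sigma −10-to-start
distances: mean 139 bp over 17 σ²⁸ calls (max 375) and mean 108 bp over 10
σ⁴³ calls (min 0).

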