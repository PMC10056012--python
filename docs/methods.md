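# Methods

`dysfrna` implements the downstream analytics of a blood-based targeted
RNA-Seq diagnostic workflow for dysferlinopathy, an autosomal-recessive
muscular dystrophy caused by biallelic pathogenic variants in *DYSF*.  The
package covers the post-alignment stages only: it consumes count tables
(allele counts at heterozygous sites, splice-junction counts, gene/panel
read totals, per-exon relative coverage), not reads.  Alignment and RNA
variant calling are out of scope.

## Coordinate model

All positions are HGVS c.-style 1-based transcript coordinates.  Intronic
offsets are carried symbolically (`2810+1`, `2811-20`) and never flattened
to genomic positions; no genome build is used anywhere.  The bundled default
gene model (`synthetic_dysf_model.json`) is **synthetic**: a 55-exon
DYSF-like transcript of 6243 coding nucleotides whose boundaries honour the
coordinate anchors implied by published DYSF variant nomenclature (exon 4 =
c.237–342, exon 9 = c.856–906 and in frame, exon 17 starting at c.1481,
exon 26 donor at c.2810, exon 43 = c.4639–4794 and in frame, exon 52 =
c.5768–5926); the remaining boundaries are invented at plausible lengths.
Exon 17 carries a blood inclusion fraction of 0.2 — it is mostly spliced out
of blood *DYSF* transcripts, which is why events and allele counts confined
to it are flagged as unreliable proxies for muscle.

The NMD rule follows the conventional 50-nt convention: a protein-truncating
variant (PTV) escapes nonsense-mediated decay when it lies in the last exon
or within 50 nt upstream of the final exon–exon junction (window
configurable).  The escape rule is monotone in transcript position.

## Decay transcript-mixture model

Each haplotype contributes weight 1/2 to the transcript pool.  An isoform
carrying a decay-triggering premature termination codon survives with
probability `1 - e`, where `e` is the decay efficiency (default **2/3**).
The closed forms used throughout follow from this mixture:

* lesser-allele fraction at a het SNV in cis with the sole triggering PTV:
  `(1-e)/(2-e)` — 0.25 at the default `e`, matching the ~75:25
  greater:lesser ratio seen in one-PTV samples;
* relative gene abundance for 0/1/2 triggering haplotypes: `1`, `(2-e)/2`,
  `1-e` (1, 2/3, 1/3 at the default).

`e = 2/3` is therefore not a free dial but the value at which the mixture
reproduces the observed one-PTV regime; it is still configurable for
sensitivity analyses.  Decay is modelled per transcript with no positional
attenuation beyond the escape rule.

## Synthetic-data generator

The generator (`simulate`) emits counts, not reads: allele counts are
binomial draws at Poisson site depths (default 500 expected reads/site,
8 informative het SNVs per sample), junction reads are Poisson around the
surviving isoform mixture per boundary (default 200/junction), gene and
panel totals are Poisson (20 000 / 1 000 000).  Sites in the variable exon
are attenuated by the inclusion fraction.  Samples are built from named
genotype archetypes (one-PTV, biallelic PTV, last-exon PTV, exon-17-only
markers, an off-model deviator whose decay efficiency is drawn far below the
model value, leaky splice, heterozygous and homozygous splice events,
intragenic deletion and duplication, same-exon trans pair, same-transcript
cis pair) that mirror the case types such a cohort presents.  Truth records
(haplotype assignments, event fractions, decay efficiency, phase) are
first-class outputs so that recovery tests never reverse-engineer the
sampler.  Fixed seeds give byte-identical output files.

Two deliberate departures from strict haplotype bookkeeping:

* **Leaky splice variants** are parameterized by *observed* transcript
  shares (default 0.28 aberrant / 0.16 normally spliced variant-bearing,
  the regime reported for the exon-43 leaky donor variant).  The site depth
  covers normally spliced transcripts only (the event removes the site's
  exon), so the site alt fraction is `f_mis/(1-f_ab)` and the estimator
  rescales it back to all transcripts.
* **Same-region read pairs** are simulated error-free: in the regime being
  emulated no phase-discordant pairs were observed at these loci.  The
  caller still tolerates 5% noise for real data.

What the generator does *not* emulate: read-level errors and mapping
artefacts, expression variation across blood cell types, RNA degradation,
and library-specific coverage unevenness.  Passing recovery tests therefore
demonstrates the estimators are correct under the stated statistical model,
not that real libraries are free of these additional error modes.

## AEI estimation and phasing

Informative sites are heterozygous substitution SNVs in constitutively
included exons with depth ≥ 20 (indels, splice-region variants and
variable-exon sites are flagged and excluded; they follow the pattern with
less accuracy).  Allele A is, by labelling convention, the haplotype
carrying the first-listed candidate variant.  Orientation maps each site's
alt fraction onto its haplotype so `mean_fraction_A + mean_fraction_B = 1`
identically.  Relative abundance normalizes the gene's read total by the
sample's panel total (targeted-panel context) before dividing by the control
mean.

A trans call by AEI requires: exactly one decay-triggering PTV, ≥ 3
informative SNVs, mean lesser fraction in [0.15, 0.35], SD ≤ 0.10, and no
last-exon or inconsistency flag.  The published pattern reports no numeric
cutoffs; these defaults separate the closed-form regimes (0.25 vs 0.5) at
the default depth and are all configurable.  Biallelic-PTV and zero-PTV
samples are structurally indeterminate (their expected fraction is 0.5), so
the false-trans rate under the model is zero by construction.  Same-region
phasing accepts trans when both single-alt read-pair haplotypes hold ≥ 20%
of pairs and double-ref + double-alt stay within 5% noise; cis mirrors this.

The cohort study behind this design reports a significance level for the
one-PTV fraction shift without naming the test; the package reports
descriptive statistics and does not attempt that p-value.

## Splice-event quantification

Junctions are classified against the reference exon chain: donor of exon
k−1 to acceptor of exon k+1 is an exon skip; an intronic-offset acceptor or
donor is an exon extension; a boundary strictly inside an exon is a cryptic
site; an acceptor upstream of its donor is the back-junction signature of a
tandem duplication.  Intron retention has no junction signature and is not
called from junction tables.  Events need ≥ 5 supporting reads.

The percentage of transcripts carrying an event is
`100 · J_ab / (J_ab + J_can)`.  The published percentages never define the
denominator; here `J_can` is the **mean** canonical read count over the
boundaries the aberrant junction bridges (summing both flanks would bias a
50% event down to 33%), with absent canonical junctions counting zero — so
a homozygous event with no surviving canonical reads is exactly 100%.  An
empty denominator is reported as ND, reproducing the cases where no
reference sequence exists at the locus.  Reported fractions are raw
observed shares; decay skews frameshift-event percentages away from the
naive 50% and no correction is applied.

A candidate causal DNA variant is attached when one lies within ±20 nt of a
disrupted splice boundary.  Unexplained skips whose exons show relative
coverage depressed to ≤ 0.7 (toward the 0.5 heterozygous-deletion
expectation) are deletion candidates; back-junctions over exons elevated to
≥ 1.35 (toward 1.5×) are duplication candidates.  Exon coverage ratios are
median-normalized within sample, which keeps a 26-exon duplication from
dragging its own baseline up.

## ACMG/AMP engine

Evidence codes arrive as inputs with optional per-code strength overrides
(e.g. PM3 upgraded to strong as unrelated trans observations accumulate);
the study-specific criteria refinements are expressed through these
overrides and configuration rather than hard-coded.  The combining table is
the standard one; pathogenic tiers are checked before likely tiers, `>=`
count semantics are used throughout (the literal one-vs-at-least
distinctions are immaterial under that ordering, verified exhaustively
against an independently transcribed oracle), and a simultaneously fired
pathogenic and benign tier — or nothing firing — yields VUS.  Prior-call
normalization treats P+LP (and B+LB) mixtures as consistent single
categories and any VUS-containing or direction-crossing mixture as
conflicting; this reproduces every published reclassification count.

## Diagnosis rule and yield

A case is definitively diagnosed when it carries ≥ 2 P/LP variants in trans
or homozygous; a permissive flag accepts unphased pairs.  Cis pairs never
qualify.  Protein-level annotations are carried in rationale text only and
never enter the rule.  Yield percentages mirror the conventional mixed
precision (pre-study to one decimal, post-study to the nearest integer) and
raw fractions are always emitted beside them.  The packaged
`synthetic_cohort_cases.tsv` is a synthetic 77-case table reproducing the
published stratum counts (24 pre-diagnosed / 34 one-P/LP / 19
VUS-or-conflicting, one other-gene diagnosis); the published partition
leaves no zero-variant stratum, so those cases sit inside the
VUS/conflicting bucket.

## Problem sizes and numerical choices

Recovery tests use 200 simulated samples at depth 500 (allele fractions),
junction depth 10⁴ (splice fractions, tolerance 2 points), and depth 10⁵
for the convergence check (tolerance 0.01) — sizes chosen so Monte-Carlo
error is well inside the assertion tolerances.  Ties and degenerate inputs:
zero-depth sites are never emitted; zero-denominator fractions are ND;
empty cohorts yield zero summaries; per-variant classification errors are
reported in-table without aborting the batch.  All randomness flows from a
single integer seed through per-sample child generators.

## Known limitations

The gene model is synthetic; results on it validate the machinery, not real
DYSF annotation.  Event detection assumes the junction table is indexed to
the same transcript model.  Back-junctions violate donor < acceptor by
construction — that inversion *is* the duplication signature.  The ACMG
engine classifies from supplied evidence; it does not assign codes from
population databases or in-silico predictors.  Breakpoint-level CNV
resolution, splice-prediction scoring and clinical report language are out
of scope.
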