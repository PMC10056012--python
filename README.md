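# dysfrna

Downstream RNA-Seq diagnostics for **dysferlinopathy**, an autosomal
recessive limb–girdle muscular dystrophy caused by biallelic pathogenic
variants in *DYSF*.  Blood-based targeted RNA-Seq can resolve the variants
that DNA sequencing leaves ambiguous — by phasing candidate variants through
allele expression imbalance, demonstrating aberrant splicing, and exposing
intragenic copy-number events in exon usage — and those observations feed
ACMG/AMP variant classification and, ultimately, a case's diagnostic status.
`dysfrna` implements that post-alignment analytic stack as a tested,
reusable pipeline, together with a synthetic cohort generator that emulates
the statistical structure the analysis assumes, so every stage is testable
without any sequencing data.

For: genomic diagnosticians and method developers working on RNA-based
Mendelian diagnostics who need the count-level analytics (not aligners or
variant callers) as composable, inspectable functions.

## The model in brief

**AEI phasing under NMD.** A protein-truncating variant (PTV) triggers
nonsense-mediated decay of its transcript with efficiency *e*.  With one
triggering PTV, a heterozygous SNV in cis is depleted to a lesser-allele
fraction

    f_lesser = (1 - e) / (2 - e)        # = 0.25 at e = 2/3  (~75:25)

while total gene abundance falls to (2−e)/2, and with biallelic PTVs the
ratio returns to ~0.5 at abundance 1−e.  A consistent ~25% lesser fraction
across SNVs therefore places the partner variant in **trans** without
parental sequencing.  PTVs in the last exon or within 50 nt of the final
junction escape decay and disqualify the call.

**Splice quantification.** Aberrant junctions (exon skips, extensions,
cryptic sites, duplication back-junctions) are called against the reference
exon chain, and each event's transcript share is

    % transcripts = 100 · J_ab / (J_ab + J_can)

with `J_can` the mean canonical read count over the bridged boundaries —
exactly 100% for homozygous events with no surviving canonical reads, ND
when no denominator exists.  Leaky exonic splice variants are split into
their aberrant and normally spliced variant-bearing shares.  Unexplained
skips over exons at ~0.5× coverage flag deletions; back-junctions over
exons at ~1.5× flag duplications.

**Classification and yield.** An ACMG/AMP rule engine combines evidence
codes (with strength modifiers) into the five-tier scale and diffs the
result against prior calls; a diagnosis rule (≥ 2 P/LP variants in trans or
homozygous) aggregates to cohort diagnostic-yield summaries.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from dysfrna import load_default_model
from dysfrna.simulate import SimConfig, simulate_cohort
from dysfrna.aei import aei_table

model = load_default_model()                 # synthetic DYSF-like 55-exon model
cohort = simulate_cohort([{"archetype": "one_ptv", "n": 3}],
                         SimConfig(seed=42), model)
aei_df, phase_df, _ = aei_table(cohort.allele_counts, cohort.variants, model)
print(aei_df[["sample_id", "n_informative_snvs", "mean_lesser", "ptv_count"]]
      .round(3).to_string(index=False))
print(phase_df[["sample_id", "variant_1", "variant_2", "call"]]
      .to_string(index=False))
```

prints

```
  sample_id  n_informative_snvs  mean_lesser  ptv_count
one_ptv_000                  10        0.260          1
one_ptv_001                  10        0.244          1
one_ptv_002                  10        0.241          1

  sample_id variant_1 variant_2  call
one_ptv_000  c.757C>T c.1004G>C trans
one_ptv_001  c.757C>T c.1004G>C trans
one_ptv_002  c.757C>T c.1004G>C trans
```

Each sample carries one nonsense variant (c.757C>T) and a candidate
missense partner: the lesser-allele fraction sits at the decay closed form
(1−e)/(2−e) = 0.25 across all informative SNVs, so the two variants are
phased trans — the configuration a recessive diagnosis requires.

The same stages are available from the shell:

```sh
dysfrna simulate --seed 3 --outdir sim/
dysfrna aei --allele-counts sim/allele_counts.tsv --variants sim/variants.tsv \
        --gene-abundance sim/gene_abundance.tsv --outdir aei/
dysfrna splice --junctions sim/junctions.tsv --variants sim/variants.tsv \
        --exon-abundance sim/exon_abundance.tsv --outdir splice/
dysfrna classify --evidence evidence.tsv --outdir acmg/
dysfrna yield                # cohort diagnostic-yield summary
dysfrna run --seed 5 --outdir out/   # full pipeline + Markdown report
```

Junction tables use a STAR SJ-style TSV dialect
(`sample_id, donor, acceptor, reads, canonical`) in transcript coordinates
with symbolic intronic offsets (`2811-20`); allele counts are
`sample_id, variant_id, ref_count, alt_count`.

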