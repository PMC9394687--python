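# clonescreen

Forward-genetics resistance-screen analysis: from per-clone variant
calls of hypermutated, compound-resistant cancer clones to ranked
candidate target genes, together with the dose-response quantification
used to validate candidates.

## The problem

A forward-genetics screen selects spontaneously resistant clones of a
mismatch-repair-deficient (hypermutator) cell line under a cytotoxic
compound. Mutations that confer resistance often hit the compound's
direct protein target, so the analysis task is to find the gene(s)
under positive selection among thousands of passenger mutations:

1. **Somatic filtering.** Each clone's variant calls are hard-filtered
   on calling annotations (remove when QD < 2, FS > 60, MQ < 40,
   DP < 3 or GQ < 7; boundary values pass) and reduced to *acquired
   somatic* mutations: variant allele frequency (VAF) > 0.2 in the
   clone, < 0.01 in the parental line, and < 0.05 in every
   counter-screen clone (clones resistant to an unrelated compound,
   which subtract selection-independent background). VAF is computed
   from allele depths, alt/(ref+alt). Non-coding mutations are
   excluded.
2. **Clone relatedness.** Clones sharing many somatic mutations
   descend from a common pre-selection ancestor and are not
   independent evidence; pairs sharing ≥ 20 mutations are grouped and
   each group votes once in the collapsed recurrence count.
3. **Recurrence ranking.** Genes are ranked by the number of
   (unrelated) clones carrying a coding mutation, then by *codon
   recurrence* — the same codon hit in independent clones, possibly
   with different substitutions (e.g. G142A and G142S), the strongest
   signature of positive selection.
4. **Dose-response validation.** Viability curves are normalized to
   vehicle and fitted with the normalized log-logistic model
   `response(x) = 100 / (1 + 10^((x − log10 IC50)·h))` (x = log10
   concentration, h the Hill slope); resistance is quantified as the
   fold-change in IC50 versus the parental line.

Because real screen data require a full alignment/calling pipeline,
the package ships a **simulator** that generates panel VCFs with
planted ground truth — Poisson per-clone mutation burdens,
zygosity-structured true VAFs (1, 1/2, 1/3), binomial allele-depth
sampling, a shared lineage branch between two clones, homopolymer
indels, parental artifact sites, and driver mutations planted at
chosen codons — so every stage is testable end to end.

## Worked example

Simulate the headline scenario — 6 resistant clones, a driver gene hit
in 4 of them at codons 47 and 142, and two clones sharing a
91-mutation lineage branch — then run the full analysis:

```sh
clonescreen simulate --out-dir demo/sim --seed 7 --scenario paper
clonescreen run \
    --vcf demo/sim/panel.vcf --reference demo/sim/reference.fa \
    --gene-models demo/sim/gene_models.tsv --out-dir demo/out \
    --parental A673-M1 \
    --clone TK216-A --clone TK216-B --clone TK216-C \
    --clone TK216-D --clone TK216-E --clone TK216-F \
    --counter MLN-1 --counter MLN-2 --min-clones 3
```

prints

```
ranked candidate genes (collapsed count >= 3):
  TUBA1B	raw=4	collapsed=4	recurrent_codons=47,142
  GENE012	raw=3	collapsed=3	recurrent_codons=-
  GENE072	raw=4	collapsed=3	recurrent_codons=-
  GENE127	raw=4	collapsed=3	recurrent_codons=-
```

The planted driver (`TUBA1B`) ranks first: it is mutated in four
clones spanning four unrelated groups (`raw=4`, `collapsed=4`) and is
the only gene with recurrently hit codons (47 and 142). The passenger
genes below it reach at most three unrelated clones and no recurrent
codon. The relatedness matrix (`demo/out/relatedness.tsv`) shows the
constructed pair sharing 90 recovered somatic mutations (91 planted,
one lost to read sampling) while all other pairs share none:

```
clone	TK216-A	TK216-B	TK216-C	TK216-D	TK216-E	TK216-F
TK216-A	108	0	90	0	0	0
```

`demo/out/` also contains per-clone somatic TSVs, a codon-level
recurrence table, a JSON report with full provenance, and a run log
recording every threshold used.

For dose-response data, `clonescreen dose --viability plate.csv
--parental-sample A673-M1 --out-dir out` fits each (compound, sample)
curve and reports IC50, Hill slope, standard errors and
fold-resistance versus the parental sample.

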