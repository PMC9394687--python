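# Methods

## Data model and coordinate conventions

Variants are keyed by (chromosome, 1-based position, ref, alt) after
multi-allelic decomposition and indel normalization (shared-base
trimming, left-alignment through repeats when the reference is
available), so set operations across samples compare like with like.
Everything else internal — transcript CDS intervals, genomic offsets —
is 0-based half-open; conversions live only in the readers/writers.
Missing INFO/FORMAT values are an explicit `None`, distinguishable
from 0.

VAF is computed from allele depths, alt/(ref+alt), not from DP: DP may
include reads uninformative for either allele, and the AD-based
definition keeps VAF in [0, 1] by construction. A zero denominator is
*indeterminate*, a value distinct from 0 that downstream logic must
handle explicitly.

## Hard filters and the acquired-somatic definition

The site/genotype hard filters follow standard short-variant
hard-filtering semantics: a call is **removed** when QD < 2, FS > 60,
MQ < 40, DP < 3 or GQ < 7, all strict, so boundary values pass.
DP/GQ are evaluated on the clone's own genotype; the parental and
counter-screen samples enter only through VAF. By default a missing
annotation fails the filter (conservative); `missing_annotation_fails
= False` inverts this.

A variant is an acquired somatic mutation of a clone when clone
VAF > 0.2, parental VAF < 0.01, every counter-screen sample's
VAF < 0.05 (per-sample, not pooled — the conservative reading), and
the consequence is coding. Two callability choices were genuinely
open:

- **Parental coverage guard.** Accepting "parental VAF < 0.01" from a
  site with 2 parental reads would be meaningless, so a site must have
  parental depth ≥ `parental_min_depth` (default 10) to count; an
  indeterminate parental VAF at sufficient depth counts as 0, and an
  undercovered site excludes the variant ("uncallable").
- **Counter-screen samples** get no such guard and an indeterminate
  VAF counts as 0: counter clones are a background subtraction, and
  excluding a variant because a counter sample happened to lack
  coverage would silently discard real signal.

Synonymous and splice-region variants (±2 intronic bases of each CDS
edge, the canonical donor/acceptor footprint) count as coding by
default; both are toggles. The VAF-threshold ordering
parental ≤ counter ≤ clone is advisory (a warning, not an error) so
that thresholds can be disabled by setting them to their extremes.

## Consequence annotation

One canonical transcript per gene is required, making codon numbering
unambiguous. SNVs are mapped to a 1-based codon index (CDS offset in
transcription direction, // 3 + 1) and the ref/alt codons are
translated with the standard genetic code, reverse-complementing on
the minus strand. Indels are frameshift when the length change is not
a multiple of 3, inframe otherwise, attributed to the first affected
codon; an indel spanning a CDS/intron boundary is classified
frameshift with a warning. The test suite checks codon calls against
an independent brute-force oracle that splices the entire CDS, applies
the mutation, and translates both sequences end to end.

## Relatedness and recurrence

Pairwise shared somatic-mutation counts (exact key intersection) form
a symmetric matrix with set sizes on the diagonal. Pairs sharing at
least `share_threshold` mutations are related; related groups are
connected components of that graph. The default threshold 20 sits
between the two observed regimes — a genuinely related pair shares on
the order of a hundred pre-selection mutations, while unrelated
hypermutator clones share close to none — and is reported in every
output.

Gene recurrence reports both the **raw** clone count and the
**collapsed** count in which each related group votes once; both are
always emitted because either may be the quantity of interest. A codon
is recurrent when ≥ 2 *unrelated* clones hit the same (gene, codon),
regardless of the substitution. Ranking is by collapsed count, then
number of recurrent codons, then gene name — fully deterministic. No
significance model is attached: with a handful of clones the ranking,
not a p-value, is the screen's output.

## Dose-response model

Curves are normalized to the mean vehicle reading (vehicle ↦ 100%)
and fitted with the normalized variable-slope log-logistic,
`response = 100/(1 + 10^((x − log10 IC50)·h))`, on x = log10 molar
concentration; a 4-parameter variant (free top/bottom) sits behind a
flag. Initialization is log IC50 at the concentration whose mean
response is nearest 50% and h = 1; standard errors come from the
curvature approximation at the optimum. A fit is flagged
non-converged — never an exception — when the optimizer fails, the
response span is under 10 percentage points (non-responsive), the Hill
slope is non-positive (viability rising with concentration), or the
IC50 lands more than 100× outside the tested range. Fold-resistance is
the IC50 ratio of two converged fits and is invariant to the common
concentration unit.

Reporting helpers follow the field's printing style: concentrations
half-even-rounded to 2 decimals (µM) or 1 decimal (nM), folds to 2
significant figures.

## Simulator

The generator produces the statistical structure the analysis
consumes, not reads:

- **Genomes.** Two builtins, both with one canonical transcript per
  gene, minus-strand and two-exon genes included, and gene 0 an
  alpha-tubulin-like gene (451 codons in the screen genome) whose
  codons 47 and 142 are fixed to Asp (GAC) and Gly (GGC) so the
  D47G/H and G142A/S substitutions are each reachable by a single SNV.
  `toy` (10 genes, ~92 kb) keeps unit tests fast. `screen` (150 genes,
  ~4.5 Mb, coding fraction 0.04) is the scaled-down exome used for
  end-to-end recovery: what matters for recurrence realism is the
  per-gene, per-clone hit probability (~300 × 0.04 / 150 ≈ 0.08),
  which keeps chance gene recurrence across ≥ 4 unrelated clones rare,
  as in a real exome where any one gene is a tiny mutational target.
- **Mutations.** Each clone draws Poisson(λ = 300) private mutations,
  uniform over the genome (so the coding fraction sets the
  coding/non-coding split): 90% SNVs with a 2:1 transition:transversion
  bias, 10% single-base insertions/deletions placed at homopolymer
  runs ≥ 4 — the replication-slippage signature of mismatch-repair
  deficiency. Zygosities are drawn from {1, 1/2, 1/3} with
  probabilities 0.15/0.70/0.15, mirroring the observed homozygous /
  heterozygous / one-of-three-alleles classes. λ = 300 is a nominal
  hypermutator burden; the true per-clone burden of any given screen
  depends on its mutator and selection time.
- **Lineage branch.** The related pair shares `branch_size` identical
  mutations drawn from *coding* positions, because the shared-mutation
  count the analysis measures is over acquired somatic (coding) sets;
  uniform placement at 4% coding would leave a coding overlap of ~4
  and no relatedness signal at any sensible threshold.
- **Drivers** are reverse-engineered from the codon table (first
  single-base change reaching the requested amino acid, deterministic
  order) and never receive planted filter failures.
- **Evidence.** Per site and sample, depth ~ Poisson(80) and alt
  reads ~ Binomial(depth, true VAF). The parental line carries 300
  heterozygous background variants (inherited by every sample) and
  Poisson(rate × genome length) artifact sites with true VAF in
  (0.002, 0.009). QD/FS/MQ/GQ are drawn from pass-region distributions
  (QD ~ U(15,35), FS ~ min(Exp(3), 59), MQ ~ U(55,60), GQ ~ U(30,99));
  a 2% fraction of non-driver variants gets one criterion pushed into
  its failure region, exercising each hard filter. Annotation
  generation is phenomenological — the pipeline only thresholds these
  fields — and no read-level artifacts (strand bias that correlates
  with VAF, mapping errors, contamination) are modeled. Passing tests
  therefore demonstrate the pipeline's logic, not robustness to every
  failure mode of real exome data.
- Output is a plain-text VCF + FASTA + gene-model TSV plus a JSON
  truth set, byte-reproducible for a fixed seed.

Viability plates are simulated as model(conc) × (1 + N(0, cv)),
truncated at 0, with vehicle wells at the 100 level.

## Problem sizes and numerical choices

The end-to-end recovery battery runs 20 simulated screens of the
headline scenario (6 clones, driver in 4, 91-mutation branch, ~2,800
variants each); dose-response recovery uses 50 replicate simulations
per curve at the duplicate 15-point design with 2% noise — enough that
the Monte-Carlo error of a mean recovered IC50 (~0.3%) is far inside
the tolerances being checked. Ties in ranking are broken
deterministically; all randomness flows through a single seeded
generator per simulation.

## Known limitations

- One canonical transcript per gene; overlapping genes and
  multi-transcript codon numbering are out of scope.
- Equal-length multi-base substitutions (MNVs) are rejected at the
  key level; upstream decomposition is assumed.
- The simulator does not model mutation-rate heterogeneity beyond the
  homopolymer indel rule, nor sequencing error in clone reads at
  non-variant sites.
- The left-alignment routine handles the simple-indel case the
  pipeline emits and consumes; pathological nested repeats may not
  reach the fully canonical spelling an upstream normalizer would
  produce.
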