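# Methods

This note documents the models and procedures implemented in `paleokit`,
their assumptions and tunable parameters, what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Damage model and profile estimation

Post-mortem cytosine deamination is modelled geometrically: at 5′ offset
*i* (0-based from the fragment end) a reference C is read as T with
probability `d5 · decay^i`, and symmetrically a reference G as A at 3′
offset *j* with probability `d3 · decay^j`. The geometric form is a
parametric choice — the empirical phenomenon is only that terminal
substitutions become more frequent toward fragment ends — selected because
it is the standard single-exponential description and yields closed-form
expectations for tests. Both rules apply at every position of a fragment
(the probability is negligible away from the relevant end); a base can
trigger only one rule since it is either C or G. Sequencing error (uniform
base substitution at rate `seq_error`, default 0) is applied after damage
and is deliberately not recorded in the damage truth counters, so exact
truth-vs-profile equality tests use `seq_error = 0`.

Fragment lengths are log-normal, parameterised by the median (`frag_median`,
default 60 bp — a typical ancient-DNA fragment scale) and the log-scale
standard deviation (`frag_sd`, default 0.3), truncated below at 20 bp. The
distribution of any particular sequencing library is not being imitated;
the defaults are a realistic shape, not a calibration.

The profile estimator counts, at each offset from each end over a 25-position
window (the conventional window; configurable), the number of reference-C
(resp. -G) sites and the number read as T (resp. A). Frequencies are
defined only where the denominator is positive. Reads shorter than the
window contribute only to offsets they cover, and the two end windows of a
short read may overlap. Only ungapped substitution-only alignments are
profiled; reads with indel CIGAR operations ingested from SAM/BAM are
skipped and counted. A mapping-quality cutoff (default MQ ≥ 30 in the
pipeline) can be applied during counting.

## Mappability

Reference mappability is the fraction of reference positions covered by at
least one uniquely placeable read when reads of fixed length (default 50 bp)
are drawn uniformly to a fixed fold depth (default 30×). A read is uniquely
placeable iff its sequence, counting both strands, occurs exactly once in
the reference — an exact-occurrence criterion standing in for an aligner's
ambiguity flagging, chosen because it is reproducible and
dependency-free. At saturating depth the statistic converges to the exact
unique-coverage fraction, which the package also exposes directly
(`unique_coverage_fraction`) and which the test suite recomputes with an
independent substring-counting oracle. The window-occurrence table is
computed by hashing all windows, so the cost is linear in reference length;
the intended scale is the 10-kb-range desk validation, not mammalian
genomes.

## Community reports and the E-score

The community generator allocates a library's reads multinomially over
species with probability proportional to source-category weight times
within-category relative abundance, then fabricates the report columns with
the geometry that gives the k-mer dispersion statistic its meaning. For a
genuine taxon, reads scatter along the genome: the distinctly covered bases
follow a saturation curve `C(1 − exp(−nL/C))` (C: distinct-k-mer capacity
from genome size, n: reads, L: read length), distinct k-mers track covered
bases, and the report's coverage column is the local fold coverage of the
covered region (≈1 until saturation). For a spurious taxon, reads stack on
one short locus: at most ~2 new k-mers per read, a covered region of a few
read lengths, and correspondingly deep local coverage. Mild log-normal
jitter (σ = 0.05) keeps the integer fields from being exactly deterministic.

Under the literal reading of the score — E = (k-mers per read) / coverage —
genuine taxa then score in the tens-to-hundreds and spurious taxa well
below 1, straddling the acceptance threshold of 7 by a wide margin. The
prose definition the threshold comes from is ambiguous, and the companion
methods defining the exact functional form were not reproduced here; the
formula is therefore implemented behind a named strategy
(`ESCORE_STRATEGIES`) so alternatives can be swapped without touching the
filter, and the generator's separation margin is deliberately large enough
that any monotone variant of the dispersion idea classifies the synthetic
taxa identically. This is the main caveat when applying the default
formula to real classifier reports: the reported `cov` column must have
the local-coverage semantics described above for the default threshold to
be meaningful.

Filtering keeps records with E ≥ `min_escore` (default 7) and reads ≥
`min_reads` (default 10). Records with undefined E (zero reads or zero
coverage) are excluded and logged, never silently kept.

## Source-panel curation, rarefaction, CLR, PCA

Curation for source attribution merges one target sample (sink) with a
reference source panel: species are kept iff total reference reads ≥ 200
and target reads ≥ 50, and species below 0.02% relative abundance in the
merged dataset are then discarded — the read-count cuts first, the
abundance cut second, following the order in which the rules are stated.
The abundance cut is computed on raw read counts (not post-rarefaction
proportions), the natural reading when rarefaction happens afterwards.
Species are reconciled by taxid; names are display-only.

Rarefaction draws without replacement to exactly the requested depth
(default 100) via a multivariate hypergeometric draw; samples whose total
is below the depth are excluded and logged.

The centred log-ratio transform adds a pseudocount (default 1) to raw
counts, closes each sample to proportions, takes logs and subtracts the
sample's log-mean; each output row sums to zero to within 1e-9, and with
pseudocount 0 the transform is invariant to per-sample scaling. The simple
pseudocount was chosen over multiplicative replacement for monotonicity and
transparency.

PCA is a column-centred SVD. Component signs are fixed by requiring the
largest-magnitude loading of each component to be positive, making outputs
deterministic; explained-variance fractions are non-increasing and the
full-rank reconstruction error is at the 1e-9 level (floating-point exact).

## SNP-panel construction

Per-sample VCFs are union-merged (the `bcftools merge --merge all` shape):
sites are keyed by (contig, position), REF conflicts are a hard error
naming the site, merged ALT sets are sorted lexicographically for
determinism, and each sample's GT/AD indices are remapped onto the merged
allele list. A sample with no record at a site is treated identically to an
explicit missing genotype.

Each call collapses to one base or N:

1. N if the genotype is missing, GQ < 30 (`-q`), or depth < 3 (`-d`);
2. otherwise let f = max(AD)/sum(AD): the majority allele's base if
   f ≥ 0.9 (`-r`), else N; an exact tie in allele depths is always N
   (no majority exists).

The threshold is inclusive (f ≥ r): a flag value of 0.9 is read as the
boundary of acceptance, and 9-of-10 reads is the canonical passing case. A
`strict_het_ratio` switch provides the exclusive reading (f > r) since the
prose ("above 90%") admits it. AD all zero while depth passes is an error,
not a silent N. GQ or AD absent entirely masks to N — conservative, since
the rule cannot be evaluated.

Site selection then drops indel sites; requires exactly two distinct non-N
bases across samples (variant and biallelic *after* masking — a site
monomorphic once masked is dropped even if the merged VCF listed an ALT);
requires a non-N fraction ≥ 0.75 (`-m`, counting masked samples as absent);
and finally enforces ≥3 bp (`-p`) between retained positions by a greedy
left-to-right scan per contig. Masking is applied before the biallelic
test, spacing after all other filters (maximising retained sites) — the
rule order is not fully determined by the rules' statement, and these
choices are deterministic and documented. The retained columns are emitted
as a multi-FASTA over {A,C,G,T,N} in coordinate order.

p-distances count mismatches over columns where neither sequence is N; a
pair with no comparable columns is NaN, which the tree builder rejects.
Neighbor joining is the standard agglomeration with ties in the Q-matrix
broken by the lowest index pair and branch lengths left unclamped, so
additive matrices are recovered exactly; it is a desk-scale check on the
alignment, not a substitute for maximum-likelihood inference, which the
alignment export (FASTA/PHYLIP) feeds externally.

## Proteomic filtering and statistics

Peptides pass if their search score is ≤ 0.01 (inclusive; lower is better —
the contract assumes only an ascending-is-worse score). Contaminant removal
drops records whose sequence occurs in the extraction blank or whose
accession is in the contaminant list, except records that are human
collagen (taxon human and protein name containing a configurable collagen
token). Both predicates are record-local, so score filtering and
contaminant removal commute — a property the tests assert. Protein groups
require ≥2 distinct peptide sequences; raw PSM totals are tallied
separately, since "unique spectral matches" conflates the two readings.
Deamidation is quantified per residue occurrence: deamidated N/Q over all
N/Q residues, pooled per sample; the PTM proportion is all modification
annotations over all amino acids. Origin classification maps the top-hit
taxon to one of eight categories, with unmapped taxa kept in an explicit
"unclassified" bucket and bacterial peptides additionally split oral vs
non-oral against a supplied species list. Venn regions are computed for 2–4
sets and always partition the union.

The peptide generator plants contaminants two ways — blank-shared sequences
and contaminant-database accessions — and plants human collagen records on
both sides of the exception, so the removal logic is exercised in all four
cells of its truth table.

## Seeding and determinism

All randomness flows from one integer seed through named substreams
(`SeedSequence([seed, crc32(name)])`), so every generator is independently
reproducible and enabling or disabling one pipeline stage never perturbs
another stage's draws. Pipeline runs write a manifest of output files with
SHA-256 checksums; identical config and seed give identical manifests.

## Validation scales and what passing shows

The validation suite runs at desk scale: 500 random call tables up to 50
sites × 10 samples for oracle equivalence, 20 replicates of 8 strains ×
50 kb genomes at 30× noise-free coverage for phylogenetic recovery, 10,000
reads per damage setting, 10 kb references for mappability, 100 random
tables for the screening oracles, and ~15,000 peptides for proteomic
recovery. These sizes give the binomial/multinomial 3σ bounds the tests
assert while keeping the whole suite in seconds.

The generators emulate the statistical structure of real data — fragment
length and damage gradients, genuine-vs-spurious k-mer dispersion,
mixed-source communities, multi-strain SNP variation, deamidated peptide
populations — but not alignment artefacts, reference bias, within-species
pangenome variation, classifier database errors, or search-engine score
miscalibration. Passing therefore demonstrates that the implementations
compute their definitions correctly and recover known parameters under the
stated models, not that the thresholds themselves are optimal for any
particular archaeological dataset.

## Known limitations

- The E-score's exact published functional form is not derivable from its
  prose definition; the default is a literal reading behind a pluggable
  strategy (see above).
- The damage model is single-strand-break geometric only; no
  double-stranded overhang model or per-library calibration.
- Mappability's exact-occurrence criterion ignores near-duplicate
  sequences that a real aligner would down-weight via mapping quality.
- NJ/p-distance is a consistency check; bootstrap support and
  maximum-likelihood inference are intentionally out of scope.
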