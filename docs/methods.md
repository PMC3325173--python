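# Methods

## Scope and data model

The package implements a homozygosity-mapping workflow for multiplex
nuclear families: genome-wide SNP genotypes (PED/MAP or minimal VCF) feed
ROH detection and relatedness estimation; per-proband exome variant tables
(TSV/VCF) feed a filtration cascade, per-family segregation tests,
ROH-overlay prioritization and a case/control burden test. All coordinates
are 1-based inclusive for variants (VCF convention); ROH intervals are
exported 0-based half-open in BED and 1-based in reports. PED phenotype
coding is the PLINK text dialect (2 = affected, 1 = unaffected, 0/−9 =
unknown). Per-marker allele dictionaries are built from the observed
alleles with codes assigned in sorted symbol order (deterministic
round-trips; markers with more than two observed alleles are dropped with a
warning, since only biallelic SNPs are analyzed). PED carries no reference
allele, so ref/alt orientation of a monomorphic marker is not recoverable
from a written file.

## ROH detection

A run of homozygosity is a **containment-maximal** marker interval that
begins and ends on a homozygous call, never contains more than
`max_consecutive_het` (default 2) heterozygous calls in a row, and contains
at most `max_het_per_window` (default 3) heterozygous calls in every window
of `window_size` (default 10) consecutive markers lying fully inside the
interval; intervals shorter than `window_size` markers face only the
consecutive-het rule. Missing calls are neutral: they do not interrupt a
run and are not counted as heterozygous by either rule, but they occupy
window positions; a run cannot begin or end on a missing call. Reported
segments must exceed `min_length_cM` (default 5, strict) between their
first and last markers — no extension to the midpoints of flanking
intervals — and contain at least `min_markers` (default 25) markers, a
floor that prevents two-marker "5 cM" artifacts on sparse maps. The X
chromosome is excluded for male samples (hemizygous by construction).

The implementation is linear-time. Every way the tolerance rules can fail
is witnessed by a local *violation span*: either `max_consecutive_het + 1`
heterozygous calls with no intervening homozygote, or a full window with
too many heterozygotes. An interval is valid exactly when it contains no
span, so the maximal right endpoint reachable from each start is a suffix
minimum over span ends, and maximal intervals are read off with two
pointers. A brute-force oracle that tests every (i, j) interval against
the definitions verifies exact equivalence on hundreds of random
chromosomes.

Two consequences of maximality are worth noting. First, maximal valid
intervals can, in rare heterozygote configurations, overlap by a few
markers (validity is not preserved under union); total ROH coverage should
therefore be measured as the length of the union when parameters are
compared, and the monotonicity guarantees (looser het tolerance or a lower
length threshold never shrink coverage) hold for the union. Second, runs
are extended greedily through homozygous-by-state flanks, so detected
segments slightly exceed the underlying autozygous tracts.

### The chance-run floor and marker density

The tolerance rules are calibrated for dense SNP arrays. At array density
(~550,000 markers over a 3,500 cM map, ≈0.0064 cM/marker) a 5 cM run spans
~780 markers and the probability that identity-by-state alone sustains the
3-in-10 rule over such a stretch is negligible: simulated outbred offspring
show 0% of the genome in detected ROH, and the mean detected percentage in
first-cousin offspring matches the pedigree expectation of 6.25% within
Monte-Carlo error. At sparser densities the floor rises quickly — at 0.1
cM/marker a 5 cM run is only ~50 markers and chance runs just above
threshold cover ~1.8% of an outbred genome under a Uniform(0.05, 0.5)
founder MAF spectrum, inflating first-cousin estimates to ~8.3%. The
autozygosity-recovery experiments in the acceptance suite therefore run at
array density; the simulator's default spacing (0.1 cM) is retained for
fast pipeline-level tests where absolute ROH coverage is not the quantity
under test.

### Shared intervals

Intervals supporting a recessive locus must be covered by an ROH of every
affected sibling, be homozygous for the same allele at every non-missing
marker across the affected (the "same haplotype" condition), satisfy the
same length and marker-count thresholds, and not be fully covered by any
unaffected sibling's ROH. With a single affected individual the
same-haplotype condition is vacuous and the individual's own ROHs are
returned unchanged (tolerated heterozygous calls inside a run do not split
it); with several affected, markers where any affected is heterozygous
break the shared interval, which slightly sharpens interval ends relative
to the per-sample runs.

## Relatedness

IBS0/IBS1/IBS2 are counted over jointly non-missing autosomal markers;
IBS2\* is the both-heterozygous subset of IBS2. IBS2\*\_ratio =
IBS2\*/(IBS2\*+IBS0) has expectation 2/3 for unrelated individuals
independent of the MAF spectrum (per marker P(het,het) = 4p²q² vs
P(opposite homozygotes) = 2p²q²) and 1 for parent–offspring (IBS0
impossible); the ratio is returned as an undefined sentinel (None), not 0,
when its denominator is empty. Percent informative is
(IBS0+IBS2\*)/(IBS0+IBS1+IBS2). Genome-wide Z0/Z1/Z2 come from the
classical method of moments: observed IBS counts are equated to their
expectations given per-marker allele frequencies, solved sequentially,
truncated at zero and renormalized to the simplex; PI_HAT = Z1/2 + Z2. No
finite-sample allele-count bias correction is applied — with a few
thousand polymorphic markers the estimates are within ±0.05 of their
pedigree expectations, which is the accuracy the workflow needs. Allele
frequencies default to estimates from pedigree founders only (descendants
would inflate them); markers with MAF < 0.01 are excluded from the moment
equations (unstable denominators). No relatedness classification is
attempted: the statistics are reported, thresholds are the analyst's.

## Filtration and segregation

Quality thresholds are strict inequalities: SNPs survive with mapping
quality > 25, indels > 10; variants without a mapping quality are dropped
with a warning. "Rare" at the filtration stage means absent from the
supplied common-variant catalog (exact chrom/pos/ref/alt match; the
operation is idempotent and commutes with quality filtering);
control-cohort frequency enters later, during prioritization. Predicted
consequence uses a single-transcript gene model carrying its reference
sequence: the canonical ±2 bp intronic window is splice_site (variants
beyond it are deliberately noncoding — noncanonical splice candidates are
not admitted); CDS indels are frameshift when the net length change is not
a multiple of 3, otherwise in-frame protein-altering; CDS SNVs are
classified by translating the affected codon on the coding strand with the
standard nuclear code. A test oracle translates the entire CDS before and
after each edit and agrees on thousands of random toy transcripts.

Three disjoint candidate streams are extracted per proband: autosomal
rare deleterious homozygous-alt variants; genes with ≥2 distinct rare
deleterious heterozygous variants (genes owning a homozygous candidate are
excluded here); and X-linked rare deleterious hemizygous-alt variants for
male probands. Deleterious classes default to {nonsynonymous, frameshift,
splice_site}.

Segregation verdicts are `segregates`, `fails`, `unphaseable` (compound
het only), `mendel_error`, or `segregates_incomplete` when a required
member's genotype is missing — reported separately rather than silently
passed or failed, since real families are often incompletely genotyped.
Monozygotic-twin groups contribute one informative genotype. Compound-het
phasing enumerates all pairs when a gene holds more than two variants and
the gene segregates if any pair is in trans in all affected siblings with
no unaffected sibling carrying both. An apparent homozygous-alt child of a
homozygous-reference parent, or a hemizygous-alt son of a
homozygous-reference mother, is a Mendelian inconsistency and is flagged
(possible genotyping error, de novo event or cell-line artifact), never
counted as segregating. Orthogonal validation genotypes, when supplied,
replace exome calls; a proband whose homozygous call is contradicted — or
whose assay could not be designed or run — leaves the candidate stream,
while discordant calls in other members are logged only (the handling of
parental discordances is otherwise undefined in the source protocol).

## Prioritization

Candidates grouped by gene are annotated with shared-ROH membership (every
variant inside a shared interval; the covering interval's cM size is
recorded) and control prevalence (allele frequency as a percent of control
chromosomes plus a homozygote count, from supplied counts or control
genotypes). Exclusion reasons are evaluated in a fixed order — outside
shared ROH, prevalent in controls, not brain-expressed, known
other-disorder gene, noncanonical splice — with the first failure recorded
as *the* exclusion and all failures retained in the JSON export; unknown
annotations never exclude. Control prevalence excludes when any control
homozygote exists or the allele frequency exceeds a configurable ceiling
(default 0.5% — the operative published rule was "zero homozygotes", and
every retained variant there sat at ≤0.07%, so the ceiling mainly guards
against pathological inputs). Neuronal-activity annotations, if present,
are carried for ranking and never used to exclude. The cascade report
traces per-family counts (exome homozygous candidates → assays designed →
run → validated → segregating → in shared ROH); its stage-to-stage rates
are reported as whole percents rounded half-toward-zero, which is the
rounding that reproduces the published per-family table.

## Burden testing

An individual carries a qualifying recessive genotype for a gene set when,
in any gene of the set, they are homozygous (or hemizygous) alternate for
a qualifying variant or heterozygous for two distinct qualifying variants
— unphased compound heterozygosity, appropriate to a case/control screen
without parental genotypes. Qualifying variants are the deleterious
classes with allele frequency at or below `maf_ceiling` (default 5%)
computed within the combined case+control cohort (the screen is
self-contained; external counts can be substituted). Individuals are
counted once per gene set (deduplicated across genes). Enrichment in cases
is a one-tailed Fisher's exact test — the hypergeometric upper tail,
accumulated in log space with log-gamma binomial coefficients for
numerical stability — fixed to the direction "more carriers in cases".
The implementation agrees with exact integer enumeration to 10⁻¹² on every
2×2 table with N ≤ 50 and with an independent library implementation on
spot checks.

## The simulator

The generator emulates the study substrate: a nuclear family with 2
affected and 1 unaffected sibling by default, whose parents are connected
by a first-cousin loop (alternatives: second-cousin, outbred), genotyped
on an evenly spaced sex-averaged map of 22 equal autosomes totalling
3,500 cM (default 0.1 cM spacing; 1 cM is mapped to 1 Mb of physical
coordinate; an X chromosome of 180 cM is added for X-linked scenarios).
Founder haplotypes draw alleles i.i.d. per marker from a Uniform(0.05,
0.5) alt-frequency spectrum and carry unique labels; meiosis follows the
Haldane model (Poisson(length/100) crossovers, positions uniform in cM, no
interference), fathers transmit their X unrecombined to daughters and
nothing to sons. Truth autozygosity — both haplotype labels descending
from one founder haplotype — is recorded before genotyping error (random
state flip) and missingness (both default 0) corrupt the emitted matrix.

The exome table holds 700 background variants by default (the scale of
per-exome potentially pathogenic calls): 70% common — catalogued, with
population frequencies 5–50% assigned to founder haplotypes by Bernoulli
draws — and 30% rare, each borne on a single founder haplotype, with a
consequence mix of 60% nonsynonymous / 30% synonymous / 5% splice / 5%
frameshift, mapping qualities Uniform(20, 60), control counts drawn
binomially from ~1,400 control chromosomes, and gene-level brain-expression
(P = 0.5) and known-disorder (P = 0.1) annotations. Member genotypes at
every variant derive from the traced haplotype labels, so background
variation is automatically Mendelian-consistent and can, realistically,
fall inside autozygous segments. The implanted causal variant is placed on
a founder haplotype such that all affected children match the chosen model
(homozygous by descent inside a shared autozygous run of at least 6 cM for
the recessive model, so the variant sits strictly inside a detectable
shared ROH; a trans pair for compound het; a maternal X haplotype for
X-linked) while no unaffected child does and carrier parents are
heterozygous; descent is resimulated (up to 100 attempts) when no
compatible site exists. A single master seed drives everything; replicate
families in a batch get child seeds drawn from the master stream, so each
is independently reproducible.

What the simulator does **not** model — linkage disequilibrium between
markers, allele-frequency ascertainment of array SNPs, sex-specific maps,
crossover interference, population structure, sequencing depth — bounds
what passing tests show: recovery results demonstrate the pipeline's logic
(filtration, segregation, overlay, exclusion ordering) under idealized
Mendelian data, not calling performance on real exomes.

## Numerical and design choices

* Fisher p-values: log-space accumulation; deterministic; p ∈ (0, 1].
* IBD moments: simplex truncation then renormalization; degenerate
  (monomorphic-only) marker sets raise rather than return noise.
* ROH ">5 cM" is strict; percent of genome in ROH uses the map length
  (sum over chromosomes of last-minus-first cM) as denominator.
* Exclusion order and the 0.5% control-frequency ceiling are contracts,
  configurable at call sites; all failing reasons are retained.
* Problem sizes in the test-suite experiments (50 array-density replicates
  for autozygosity recovery, 20 families for end-to-end recovery, 500
  random chromosomes for the ROH oracle, 1,000 toy transcripts for the
  translation oracle, all 2×2 tables to N = 50 for the Fisher oracle)
  were chosen as the smallest sizes at which Monte-Carlo error is
  comfortably below the tolerances being asserted.

## Known limitations

* Per-exome variant counts of real data (tens of thousands of calls per
  exome) are not emulated; the background-variant scale starts at the
  post-annotation stage.
* The compound-het stream requires parental genotypes; population-based
  statistical phasing is out of scope.
* Only biallelic SNVs/indels are handled; no CNVs, no multi-allelic
  decomposition, no liftover.
* ROH calling is rule-based, not model-based (no LOD scores, no
  genotype-error-aware HMM); at marker densities far below array scale the
  chance-run floor documented above applies.
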