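# Methods

## Data model and coordinates

A cohort is a set of patients, each with exactly one matched-normal sample
and an ordered list of staged tumor samples (DCIS, primary, ALN metastasis,
distant metastasis). A mutation is identified by (patient, chrom, pos, ref,
alt); coordinates are 1-based, fully closed, VCF-style, and indels are
consumed as given (no re-normalization, no multi-allelic decomposition).
B-allele frequency is alt_reads/depth with no mapping-quality weighting and
is undefined at zero depth; filter code treats a zero-depth sample as
providing no evidence (BAF 0 for signal purposes) while the depth threshold
itself rejects such sites whenever a positive minimum depth is configured.
Gene symbols are taken as given and only uppercase-normalized for set
operations; no symbol remapping is attempted. BED blacklists are 0-based
half-open on disk and converted to 1-based closed intervals internally.

## Validation filter

Boundary semantics follow the criteria's phrasing literally: the normal-BAF
bound is exclusive (< 0.02), the depth minimum (≥ 50×, applied to **all**
samples including the normal) and the tumor-BAF minimum (≥ 0.05, maximum
over tumor samples) are inclusive, the rescue depth is strictly greater
(> 200×), and the population-AF rule excludes only AF strictly above 1%.
Rejection reasons are accumulated in a fixed order (normal contamination,
low depth, no tumor signal, region, population SNP, blacklist, cluster), so
a decision lists every violated rule, not just the first. Decisions are
per-mutation independent given curation flags; this makes the filter
order-invariant and monotone in its thresholds (property-tested).

Visual curation of alignments cannot be re-implemented; it is modeled as an
input blacklist (BED) plus per-mutation curation flags. "Many adjacent
variants" is quantified as ≥ 3 variants within a 10 bp window (both
configurable); sex chromosomes are treated like autosomes.

## Progression categories

Categorization uses the post-rescue presence vector — the same evidence a
deep-sequencing read-out supports — restricted to protein-altering classes
(everything but synonymous/unknown; splice sites included). "Metastasis"
pools ALN and distant metastases. Category 1 is "present in any of
DCIS/primary and no metastasis sample"; DCIS presence is not required even
when DCIS was sampled. The three categories partition the retained
class-included mutations; concordance counts are the Venn partition of
per-sample presence and marginalize to per-sample totals (tested).
Recurrence multiplicity counts distinct genomic variants, never reads or
samples.

## Selection statistics

The NS count covers missense, stopgain and stoploss single-nucleotide
substitutions; S covers synonymous SNVs. Splice-site mutations and indels
are excluded from both by default because the ratio's 2:1 neutral
expectation is a statement about amino-acid-changing versus silent
substitutions; both inclusions are config options (`include_splice_in_ns`,
`include_indels_in_ns`) so their effect can be measured. The test is the
exact one-tailed binomial upper tail P(X ≥ NS) with X ~ Binomial(NS+S, p₀),
p₀ = r/(r+1) for the neutral ratio r (2 by default, so p₀ = 2/3), computed
by log-space summation (log-gamma coefficients, `logsumexp`); it agrees
with a repeated-multiplication brute-force pmf summation to 1e-12 over all
0 ≤ k ≤ n ≤ 200 and with `scipy.stats.binom.sf` (both kept as independent
cross-checks, never the implementation). The driver estimate is
max(NS − round(r·S), 0); the clamp matters only for sampled data, where the
excess can go negative. Displayed ratios are truncated, not rounded, to two
decimals (177/47 = 3.7659 → 3.76), matching the convention of the
validation tables; full precision is kept internally.

Because the test is discrete, its size at nominal α = 0.05 is conservative:
for group sizes in the low hundreds the achievable rejection rate under the
null averages ≈ 0.042. The calibration experiment (2,000 neutral cohorts of
~180 primary mutations) therefore checks the empirical rate against a 3-SE
band around 0.05, which the conservative exact test satisfies.

## Over-representation

The hypergeometric upper tail is computed by the same log-space pattern and
checked against exact integer-combinatorics enumeration (N ≤ 500) and
`scipy.stats.hypergeom.sf`. Two parameters are deliberately config-exposed
defaults rather than constants derived from data: the gene universe
N = 45,956 and the tested-family size m = 186 for a KEGG-scale collection.
Benjamini–Hochberg is implemented directly (step-up with family size m ≥
list length) because the reported q-values require adjusting displayed
top-k p-values against the full tested family, a case standard
multiple-testing helpers do not cover; it matches
`statsmodels.stats.multitest.multipletests` whenever m equals the list
length. Sets with zero overlap are dropped from output but counted in m.
Queries are gene-level: a gene mutated several times counts once.

## Driver triage

The qualifying rule is: frameshift (insertion or deletion), stopgain or
splice-site consequence — truncating classes qualify unconditionally — or a
per-mutation driver flag from a pluggable scorer. The original analysis
used an external SVM-based web classifier for the missense flag; that tool
is abstracted behind the scorer interface (`mutation -> (score, flag)`),
with a deterministic table-backed scorer for exact tests and a conservative
truncating-only fallback. Gene-list membership (e.g. COSMIC CGC, KEGG
cancer pathway) is annotation only. Triage is monotone in the scorer:
flagging more mutations can only add calls (tested).

## Synthetic cohort generator

The generator emulates the study design, not read-level sequencing: per
patient one normal plus one sample per configured stage; truncal mutations
reach every tumor sample, private mutations exactly one stage, and an
optional branch is shared by the two metastases (distant disease descends
from the primary lineage, so most mutations are shared — the truncal
default dominates). Depths are negative-binomial with mean 465× (targeted
panel; 100× exome preset) and size parameter 10; alt reads are binomial at
0.5 × purity (diploid heterozygous assumption; copy number out of scope)
for reached samples and at error rate 0.001 otherwise, the normal always at
error rate. Neutral consequences are non-synonymous with probability 2/3,
split 9:1 missense:stopgain (an arbitrary fixed convention; no class
breakdown is implied by the 2:1 expectation); injected drivers are all
non-synonymous. Default per-patient totals (60 truncal + 15/120/25/45
stage-private) sit in the middle of the observed per-patient range of
validated coding mutation counts. Population-SNP and blacklist artifacts
are planted at rates 0.02 and 0.01 with ground-truth labels.

What passing recovery tests shows is therefore limited: the generator has
no copy-number variation, no subclonal structure below the stage-private
level, no FFPE or strand artifacts, and mutation classes independent of
position. It validates the pipeline's logic and statistical calibration,
not performance on real tumor sequencing.

Determinism: one `numpy` Generator seeded from the config drives every
draw; identical configs yield byte-identical output tables. Experiment
sizes (2,000 neutral replicates for calibration, 200 for driver recovery)
were chosen to put Monte-Carlo standard errors well below the effect sizes
being checked while keeping the default suite quick.

## Known limitations

- The filter cannot reproduce judgment calls of manual curation; the
  blacklist/flag mechanism only represents their output.
- The NS:S framework uses the flat 2:1 expectation; trinucleotide-context
  dN/dS correction is explicitly out of scope.
- Multi-allelic VCF records must be decomposed upstream.
- The BH family size and gene universe are assumptions of the
  over-representation model and should be set to match whatever collection
  a user actually tests.
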