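# Methods

This note documents the models and algorithms implemented in `salhi`, the
choices made where the published description of the approach leaves the
design open, and what the built-in simulator does and does not emulate.

## Problem setting

Genomic selection assumes every individual is genotyped at high density,
which is rarely true in livestock populations: genotyping all selection
candidates (and historically, all dams) is expensive. The package
implements segregation-analysis + long-haplotype-library imputation
(SALHI): high-density genotypes are inferred for non-genotyped or
low-density genotyped pedigree members by matching per-locus genotype
probabilities against a library of chromosome-length haplotypes phased
from the densely genotyped part of the population. The imputed genotypes
then feed a BayesA marker model to compute genomic breeding values
(GEBVs), and the accuracy cost of reduced genotyping is quantified
against full genotyping and against marker-free pedigree BLUP.

## Genotype probabilities (geneprobs)

Single-locus iterative peeling over the pedigree: each individual's
posterior genotype distribution is the normalized product of a penetrance
term (point mass if observed), an *anterior* term propagating information
down from its parents' families, and one *posterior* term per mating
propagating information up from each family of offspring. Founders carry
Hardy–Weinberg priors at the locus's allele frequency, estimated from
observed genotypes (clamped to [0.001, 0.999]; 0.5 when nothing is
observed). Anterior and posterior terms are iterated — one top-down and
one bottom-up family sweep per iteration — until the largest posterior
change is below `tol` (default 1e-6, `max_iter` 50). On loop-free
pedigrees the fixed point is the exact posterior (verified against full
enumeration to 1e-9–1e-16 in the tests); with pedigree loops it is the
usual iterative-peeling approximation. Individuals with exactly one known
parent get an internal dummy unobserved mate so the family equations
apply unchanged. Mendelian-inconsistent child observations are treated
as missing with a warning rather than aborting.

Each geneprob triple gets a genotype probability index,

    GPI = 100 * (1 - H(posterior) / H(prior)),

with `H` the Shannon entropy and the prior the HWE triple at that locus;
the value is clamped to [0, 100], degenerate priors and observed
genotypes score 100. The published description cites an information
index without giving a formula; the entropy ratio satisfies every
property used downstream (0 at the prior, 100 at certainty, monotone in
information content), and every GPI threshold in the package is
configurable so a different index could be dropped in.

## Long-range phasing and the haplotype library

Each chromosome is cut into cores at the first SNP at/after each
multiple of `core_length_mb`; a tail shorter than half a core merges into
the previous core. Within a core an individual's homozygous loci phase
trivially, a homozygous parent forces its side at heterozygous loci, and
remaining heterozygous loci are resolved by *surrogate* voting. Surrogate
candidates on, say, the paternal side are the sire, the sire's parents,
and paternal half-sibs; full sibs are excluded because a match through
them cannot be attributed to one side. A candidate survives if it shows
at most `max_opposing` (default 0) opposing homozygotes with the
individual inside the core. A surviving surrogate votes with the allele
it carries on the (putatively shared) gamete whenever that allele is
determinable: the surrogate is homozygous, or its other parent is
homozygous. A side is assigned when a fraction ≥ `agreement_threshold`
(default 0.9, at least one informative vote) agrees; the other side is
the complement of the dosage.

Voting is iterated (`n_passes`, default 3). From the second pass,
surrogates are re-filtered by haplotype-level consistency — a half-sib
whose previously resolved shared-side haplotype conflicts with the
individual's resolved haplotype inside the core is dropped — and vote
with their resolved shared-side haplotypes, which greatly increases both
coverage and precision at loci where both parents are heterozygous. The
first pass requires unanimity to avoid anchoring later passes on weak
majorities.

Core haplotypes of a gamete are concatenated into one chromosome-length
haplotype. A gamete enters the library when its unphased fraction is
below `1 - completeness_min` (default 0.99), residual gaps can be filled
from the complement (other gamete + dosage), every resolved allele is
confidence-flagged (homozygous, parent-forced, or a unanimous vote of at
least `min_confident_votes` surrogates), and the gamete passes a mosaic
screen: it must be writable as a mosaic of its parent's two phased
haplotypes with at most `library_max_switches` (default 3) template
switches — isolated allele errors cost two switches each and are
rejected, genuine recombinants are not. Library haplotypes are
deduplicated with occurrence counts.

Known limitation: families can settle on a *consistent but wrong*
consensus at a handful of loci (two sire gametes merged into one),
which no within-family screen can detect. Phased-allele accuracy is
≥ 99.8% on the simulated designs in the tests, but a minority of
chromosome-length library haplotypes (~10–15%) carry one or a few such
alleles. Removing them would require the full iterative long-range
phasing machinery (surrogates of surrogates), which is outside this
package's scope.

## Imputation

For every individual with missing genotypes, per chromosome:

1. **Pre-selection.** The most probable genotype per locus is the argmax
   of the geneprob triple, defaulting to the heterozygote on ties; loci
   with GPI below `gpi_min_step1` (default 90) are excluded.
2. **Step 1 — single haplotypes.** Each library haplotype is compared at
   the putative homozygous loci; it is excluded when the count of loci
   whose homozygote it cannot produce exceeds the step-1 error
   threshold. Heterozygous loci never contribute.
3. **Step 2 — pairs.** Survivors are paired in all combinations
   (self-pairs included). At a GPI minimum starting at
   `gpi_min_step2_start` (99) the pair's implied genotype (allele sum)
   is compared with the most probable genotype at every locus above the
   minimum; pairs with more mismatches than the step-2 threshold are
   excluded. While more than one pair survives, the minimum is lowered
   by `gpi_step2_decrement` (5) down to `gpi_min_step2_floor` (60),
   adding loci; a re-filter that would eliminate every pair is undone.
4. **Step 3 — scoring.** If several pairs remain, each pair is scored by
   the *sum* over loci of the geneprob mass assigned to its implied
   genotype (a product score is available via `step3_score="product"`),
   and the best pair wins; ties break to the smallest id pair.

Error thresholds default to max(1, 1% of the compared loci). Because a
library essentially never contains the exact recombinant gametes of
fresh selection candidates, a fixed tight threshold can reject every
pair precisely when the most information is available (dense panels) —
inverting the expected gain from low-density genotyping. The thresholds
are therefore treated as data-fit parameters: when no pair survives,
both thresholds are relaxed geometrically (`adaptive_relax`, default
×2, capped at `max_relax` = 32×) until a pair is found. A GPI of 100
leaves no ambiguity, so certain loci are always called from the
geneprob, never from the pair. When no pair exists at all (empty
library), loci where a fraction ≥ `fallback_freq_threshold` (0.9) of
surviving pairs agree are called from that majority, GPI-100 loci from
the geneprob, and everything else is filled with the geneprob argmax so
the output matrix is complete for genomic prediction. Every call carries
a provenance code (observed / pair / fallback_freq / fallback_gpi /
geneprob_fill), and imputation accuracy is reported overall and per
provenance class.

Low-density panel genotypes are treated as observed data: they enter the
peeling as observations (equivalently, `overlay_low_density` replaces
the geneprob with a point mass and GPI 100 at panel loci).

## Genomic and pedigree prediction

**BayesA.** y = μ + Σ xⱼaⱼ + e with aⱼ | σⱼ² ~ N(0, σⱼ²) and σⱼ² ~
scaled-inv-χ²(ν, S); Gibbs sampling with locus-wise updates on centered
dosages. Defaults: ν = 4.012; S solved from an assumed proportion
`var_prop` = 0.5 of phenotypic variance explained by markers, divided by
the realized Σ var(xⱼ); residual scaled-inv-χ²(4, scale from
(1 − var_prop)·var(y)). Chains default to 10,000 iterations, 2,000
burn-in, thinning 10 (the experiment pipeline uses 1,500/300/5, sized to
its smaller data); posterior means over the retained samples are
reported and fixed seeds give bit-identical chains. GEBV = Σ dosageⱼ ×
effectⱼ. Imputed genotypes enter as hard 0/1/2 calls by default;
`dosage_mode="expected"` uses pAB + 2·pBB instead.

**Pedigree BLUP.** Animal model with the overall mean as the only fixed
effect, solved from the mixed-model equations with the inverse of the
numerator relationship matrix (tabular method) and variance ratio
(1 − h²)/h²; matches a dense GLS solve to 1e-8 and gives unphenotyped
terminal offspring exactly the parent average.

**Accuracy.** Correlation of (G)EBV with true breeding value, computed
within each sex and averaged. Pooling the sexes would bias the estimate
whenever their breeding-value levels differ — which the paternally
imprinted QTL induce — so the sex-split mean is the headline metric; a
missing or degenerate sex is flagged and the other carries the average.

## The simulator

`simulate_pedigree` builds a discrete-generation nucleus: generation 0
holds the founder breeders (`n_sires` + `n_dams`), each later generation
is bred from sires and dams sampled from the previous one, each dam
producing exactly `offspring_per_dam` offspring (default 30, the
prolific-dam structure typical of the pig and poultry nucleus herds this
method targets) by one randomly assigned sire; sex is Bernoulli(½) at
birth. Founder
haplotypes are block-copied from a small pool of ancestral haplotypes
(pool 8, blocks of 8 loci, target allele frequencies uniform in
[0.1, 0.5]) giving strong within-block LD; gene drop transmits
recombinant gametes with Poisson crossovers at 1 cM/Mb (Haldane, no
interference). The quantitative trait has `n_qtl` = 20 QTL drawn from
the mapped SNPs with standard-normal effects, 2 of them paternally
imprinted (only the paternal allele contributes, doubled to preserve
the expected variance contribution); phenotype = TBV + N(0, σe²) with
σe² solved from h² = 0.5 on the realized TBV variance; only training
generations are phenotyped. Masking scenarios: BASE (all observed), S1
(training females fully ungenotyped; library from training males only),
S2 (training fully observed; library from all training individuals);
prediction individuals are ungenotyped or keep one SNP nearest each
multiple of the panel spacing (2/5/10 Mb, ties to the lower position).

What the simulator does *not* emulate: any particular real genome,
mutation, genotyping error, selection (parents are sampled at random, so
there is no selection-induced LD or inbreeding trend), overlapping
generations, and epistasis. Passing grid tests therefore show that the pipeline
reproduces the *orderings* (denser panels help; a fully genotyped
training set beats males-only; full genotyping ≥ imputed ≥ pedigree
BLUP), not the dataset's absolute percentages.

## Default experiment sizes

The built-in experiment grid runs a 1,578-individual population (5
generations; 5 sires and 13 dams per generation; 30 offspring per dam),
5 chromosomes × 150 SNPs over 100 Mb each, 25 Mb phasing cores, and
BayesA chains of 1,500. These sizes were chosen so a full scenario ×
density grid replicate completes in under two minutes on one CPU while
every stage (peeling, phasing, library matching, MCMC) still operates in
its intended regime; all of them are plain config fields
(`ExperimentConfig`) and scale up freely.

## Numerical notes

- Peeling normalizes every anterior/posterior/penetrance product to sum
  one; a zero-sum product (impossible configuration) falls back to the
  prior for anteriors and to uniform for family messages, which only
  occurs on Mendelian-inconsistent input that the pre-cleaning missed.
- Ties in the most-probable-genotype argmax are declared at 1e-9 and
  default to the heterozygote; step-3 ties at 1e-9 break to the
  lexicographically smallest haplotype id pair and are logged.
- Step-2 mismatch counting is done with three integer matrix products
  per GPI level (match-count decomposition by target genotype class), so
  the cost is survivors² × new loci rather than pairs × loci.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`; numba's internal generator for the Gibbs
  sampler, seeded per fit); phasing and imputation are deterministic
  given their inputs.
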