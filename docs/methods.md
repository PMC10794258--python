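# Methods

This note records the models, conventions and design choices behind
`nestkin`, in the order the pipeline runs them.

## Data model

Genotypes are alternate-allele counts in {0, 1, 2} with −1 for missing,
stored sample × locus alongside a same-shaped non-negative integer read-depth
matrix. Only biallelic records are accepted; multi-allelic VCF records are
dropped with a logged count. A missing genotype may still carry a depth
(the reads existed but no call was made). Positions are 1-based as in VCF
and locus ids are `chrom:pos`; phased and unphased genotype separators are
treated identically because no downstream statistic uses phase. Metadata
dates are ISO-8601.

## Clutch simulator

The simulator emulates a post-genotyping SNP matrix for hatchlings sampled
from sea-turtle nests, with these components:

* **Two source populations** (Atlantic, Mediterranean) under the
  Balding–Nichols model: ancestral frequency p ~ Uniform(0.05, 0.95) per
  locus, population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so
  E = p and Var = F·p(1−p). Default F = 0.10 — nuclear divergence between
  Atlantic and Mediterranean rookeries is substantial but not printed for
  these markers, so F is an explicit scenario parameter, never inferred.
* **Pedigree**: mothers and fathers are Hardy–Weinberg draws from their
  population; each hatchling receives one allele per parent per locus;
  loci are independent (no linkage map, no mutation). Nests sharing a
  `mother_id` are laid by the same female; nests sharing a `father_group`
  draw sires from the same pool, so a planted same-mother pair with a
  common father group contains cross-nest full siblings.
* **Multiple paternity**: with n declared sires, each sires at least one
  sampled hatchling and the remainder are assigned uniformly at random.
  The guarantee exists because a declared two-sire nest must genuinely
  contain two sires for truth-scoring to be meaningful; with purely
  uniform assignment a small clutch can collapse to single paternity.
* **mtDNA**: each hatchling carries its mother's haplotype label, drawn
  from per-population haplotype frequencies unless fixed in the scenario.
* **Noise**: depths are negative-binomial with mean 25 and dispersion 5
  (Poisson in the dispersion → ∞ limit), matching the ~25× mean coverage
  typical of 2bRAD panels at this scale; genotypes are set missing with
  probability 0.02 and perturbed one step (0↔1↔2, heterozygote errors
  split evenly between the homozygotes) with probability 0.005.

The **baseline scenario** mirrors the 2016–2019 Spanish sporadic-nest
study design: eight genotyped nests of 2, 2, 8, 4, 7, 7, 7, 8 hatchlings
(45 samples) across 2016–2019, 2,300 loci, the published haplotype labels
and dates, one planted same-season same-mother pair with a shared sire and
a shared rare Mediterranean haplotype (SN05/SN08, the SP07/SP11 analogue),
and one two-sire nest of two hatchlings (SN01, the SP01 analogue). A
remigrant variant moves the second planted nest to a later year.

What the simulator does **not** emulate: allele dropout correlated with
restriction-site polymorphism, batch/library effects, linkage between tag
SNPs, population admixture, or reference-bias in mapping. Passing recovery
tests therefore demonstrates the statistical machinery under idealised
Mendelian sampling with realistic depth/missingness, not robustness to
every artefact of real reduced-representation data.

## Filtering

Order is fixed and matters: (1) genotypes with depth < 5 are set missing;
(2) loci with mean depth strictly above the cutoff are dropped; (3) loci
called in less than 95% of samples — counted after the depth masking — are
dropped. The depth cutoff is either a fixed value (default 50) or the
Tukey upper whisker Q3 + 1.5·IQR of per-locus mean depths; quartiles use
linear interpolation between order statistics (the ubiquitous "type 7"
convention), and the convention plus the threshold actually used are
recorded in the filter report. Per-locus mean depth is taken over all
samples with a recorded depth (in practice all samples). Boundary
semantics are strict: depth 5 survives, mean depth exactly 50 survives,
19/20 = 0.95 called survives.

## Diversity

A locus is polymorphic within a nest when at least two distinct alleles
are observed among the nest's non-missing genotypes — a single
heterozygote suffices (the allele-based convention of standard
population-genetics software). Loci entirely missing within the nest stay
in the denominator by default; a flag excludes them. Observed
heterozygosity is heterozygous calls / non-missing calls per sample, with
nest values the mean over samples. All aggregate SDs are sample SDs
(n − 1); this convention reproduces the published across-nest SDs (4.75
for percent polymorphic, 0.062 for relatedness) exactly.

## Kinship and ordination

The Manichaikul within-pair (KING-robust) estimator is computed from
category counts over pairwise-complete loci:

    φ̂_ij = (N_AaAa − 2·N_AAaa) / (N_Aa(i) + N_Aa(j))

It requires no allele frequencies and is exactly 0.5 for self-comparison
whenever the sample has a heterozygous locus. Pairs with a zero
denominator are reported absent. Per-nest mean relatedness averages the
unordered within-nest pairs, excluding the diagonal — including self-pairs
would inflate small nests toward 0.5, which is inconsistent with how
published per-nest values behave (e.g. a two-sample nest at 0.082).

IBS distance is `mean(|g_i − g_j|)/2` over pairwise-complete loci (no
imputation). Classical (Torgerson) MDS double-centres −½D², takes the
eigendecomposition, and scales the top-k (default 3) positive-eigenvalue
eigenvectors by √λ; negative eigenvalues are discarded with their variance
share logged, and each axis's sign is fixed so its largest-magnitude
loading is positive, making coordinates bit-reproducible. The one-per-nest
MDS draws one hatchling per nest with a seeded RNG to remove family-size
clustering artefacts. The dendrogram clusters max(φ)−φ with average
linkage (UPGMA; no linkage is canonical for this display, so the choice is
recorded in the output) and exports Newick plus the leaf order.

## Nest-pair classification

Rule cascade, every fired rule appended to the evidence trail:

1. Different mtDNA haplotypes → different females, unconditionally
   (maternal inheritance makes this an absolute exclusion).
2. Matching haplotypes (unknown haplotypes proceed with a warning): the
   pair is a same-mother candidate when the median cross-nest φ reaches
   τ_sib = 0.1875, the midpoint of the half-sib (0.125) and full-sib
   (0.25) expectations. An optional rank-test mode additionally requires
   that a permutation rank-sum test (10,000 permutations, seeded) fail to
   separate cross-nest from pooled within-nest φ at α = 0.05 — with as few
   as a handful of pairs per nest, a permutation null is the only
   defensible one. A median in [0.0625, τ_sib) earns a
   `possible_same_mother_halfsib` note (same mother, different sires
   across clutches), a case the threshold rule cannot confirm.
3. Candidate + same calendar year → re-nester. The feasible
   laying-to-laying interval is computed exactly when both laying dates
   exist, otherwise back-computed from the second nest's emergence date
   and an incubation-duration range (supplied, or derived from the
   dataset's nests that have both dates), and checked for consistency with
   k ≥ 1 internesting cycles of 12–16 days.
4. Candidate + different years → remigrant.
5. Otherwise → different females; no defined cross-nest φ → inconclusive.

Distinct females are counted by union–find over same-female verdicts;
inconsistent triangles are merged with a loud warning in the report.

Multiple paternity is flagged when a nest's mean within-nest φ falls below
τ_mp = 0.1875. Two consequences worth knowing: (a) applied to the
published per-nest values, the rule flags not only the clearly depressed
nest (0.082) but also marginally the 0.180 nest — the threshold is a
bright line, not a test; (b) for large clutches the full/half-sib mixture
mean under near-even sire shares (~0.18 for 8 hatchlings and 2 sires) lies
within estimator noise of the threshold, so detection power at 2,300 loci
is modest (~70% of replicates) and declines further under skewed paternity.
Small two-sire nests, whose sampled pairs are outright half sibs, are
detected essentially always. Both thresholds are exposed in the
configuration.

## Phenology

Sex-ratio curves are logistic in incubation duration,
f(d) = 1/(1 + exp(s·(d − p))), strictly decreasing (long/cool incubations
produce males). The curve parameters of published models are not
distributed with this package — users supply (p, s) per model, and per-nest
results are the min/max envelope over the supplied set.
`example_sex_ratio_models()` ships four illustrative synthetic curves with
pivots at 58.5–61.5 days for tests and demonstrations only.

Spearman ρ is the Pearson correlation of average (tie-corrected) ranks,
computed directly; the two-sided p-value is by seeded permutation
(default 100,000 draws) since annual event counts are small, discrete and
tied, with the large-sample t approximation as an option. The SST
threshold flag marks event years with mean June–July SST above 21 °C, the
suggested nesting-onset temperature in the Western Mediterranean. The
synthetic SST/event generator encodes that threshold structurally (zero
expected events below 21 °C) and couples counts to SST log-linearly, so the
simulated series reproduce the qualitative pattern (positive rank
correlation; all events in above-threshold years).

## Reproducibility and problem sizes

Every stochastic component takes a seed; one pipeline seed fans out to
stages by fixed offsets, and identical configuration + seed reproduces
every output file byte-for-byte (the VCF writer emits no timestamps).
Calibration and recovery checks run at the study's own scales: 5,000 loci
and 50 pairs per relationship for estimator calibration (±0.02 tolerance),
2,300 loci and 45 samples per replicate with 100 replicates for end-to-end
recovery. The recorded internesting window for the planted pair
(laying day 0, emergence day 85, incubation range 47–64 d → 21–38 d,
consistent with two 12–16-day cycles) follows from the packaged dates; the
incubation range is an explicit parameter because different choices move
the window.

## Known limitations

* The classifier assumes nests are mutually comparable on a shared locus
  panel; heavy differential missingness shrinks pairwise-complete counts
  and widens φ noise.
* Half-sib same-mother pairs across nests (different sires, e.g. sperm
  from different mating events across seasons) fall below τ_sib by design
  and are only surfaced as a note, not a verdict.
* KING-robust φ between individuals from *different* populations is
  negative in expectation; that is harmless here (it only reinforces
  "different females") but the φ values themselves should not be read as
  coancestry across populations.
* Percent-polymorphic and H_o depend on the retained locus panel, so
  values are comparable within a run, not across filtering regimes.
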