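# Methods

This note documents the generative models, the analysis engine, the
calibration of the simulator's nuisance parameters, and the numerical
design choices, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trait models

A two-locus trait model assigns a penetrance to the pair of genotypes at
the disease loci A and B. Alleles are biallelic; allele 1 is the disease
allele. A locus "carries the disease genotype" when it has ≥ 1 disease
allele (dominant mode) or 2 (recessive mode).

- **Epistasis** (models DD, DR, RD, RR — mode at A then at B):
  P(affected) = f·I_A·I_B with joint penetrance f = 1 by default
  ("fully penetrant" interaction: both disease genotypes are necessary
  and jointly sufficient).
- **Heterogeneity** (D+D, D+R, R+D, R+R): either locus suffices, each
  with per-locus penetrance f = 0.5. The default generative rule resolves
  causation per individual ("union"): P(affected) =
  1 − (1 − f·I_A)(1 − f·I_B). An alternative "admixture" rule assigns one
  causal locus per family with probability ½ each; it is selectable
  (`het_rule="admixture"`) because either reading of "independently
  caused by two loci" is defensible. The union rule is the default since
  it requires no extra family-level latent variable.
- Disease allele frequencies: 0.1 at a dominant locus, 0.2 at a recessive
  locus. Phenocopy rates are zero in all generating models.

Population prevalences follow from Hardy–Weinberg proportions and random
mating; `trait_models.prevalence` computes them analytically and the test
suite checks them against Monte-Carlo draws.

## Map and linkage disequilibrium

The default "chromosome" has 18 loci: disease locus A at position 5,
disease locus B at position 13, the rest biallelic SNP markers with
allele frequencies 0.5 — except the marker at position 4, which can be
associated with the disease allele at A. Adjacent recombination fractions
are θ = 0.001, with two exceptions: θ = 0 between marker 4 and A (the
associated marker rides with the disease locus) and θ = 0.5 between
positions 9 and 10, so the compound recombination fraction between A and
B is exactly 0.5 — the two disease loci are unlinked and any shared
linkage signal must come through the trait model.

Founder haplotypes for the (A, marker 4) pair are drawn from a 2×2
haplotype table built from the marginal allele frequencies and D′:
D = D′·D_max with D_max = min(p_A(1−p_1), (1−p_A)p_1), and
freq(disease, allele 1) = p_A·p_1 + D. Allele 1 of marker 4 is always the
associated allele (positive-D orientation). By default the marker allele
frequency is matched to the disease allele frequency, so D′ = 1 implies
r² = 1 (the associated allele *is* an error-free tag of the disease
allele). All other founder loci are sampled independently.

## Simulator

Families are two-generation pedigrees: founder haplotypes as above, each
offspring receiving one recombinant gamete per parent with independent
crossovers per interval (Haldane model, no interference), affection
assigned by the trait-model penetrance with an independent uniform draw.
Genotypes are stored phase-known internally; phase is erased on
LINKAGE-format export, and the two disease-locus columns are written only
to a separate truth sidecar — analysis software sees markers and
affection only. Sex alternates and is non-informative (autosomal models).

Ascertainment is by rejection sampling: a family enters a dataset iff it
has ≥ 1 affected offspring and ≥ 4 members. Sampling is vectorised in
batches grouped by sibship size; batches are truncated in original draw
order so that no sibship size is favoured (this is asserted by a test).
A dataset is 50 ascertained families; an experiment is 100+ datasets,
each with a child seed derived deterministically from the master seed.

### Sibship-size distribution (calibrated nuisance parameter)

Sibship sizes (2–10, so families have 4–12 members) follow a truncated
geometric distribution, P(s) ∝ r^(s−2). The published family-size source
for this design is not reproduced here, and the simulation study we
mirror reports only aggregate sample-size tallies, so the ratio r is
treated as a nuisance parameter and calibrated once, by least squares,
against the eight full-scale sample-size retention values (families and
subjects remaining after pruning, for the four epistatic models). The
sweep has a flat optimum at r ≈ 0.56–0.58; the package fixes **r = 0.57**
(ascertained DD-model sibships then average ≈ 3.6 offspring). Only
sample-size tallies enter this calibration — no lod or INT quantity is
fit — yet the resulting lod-score levels independently land on the
reported means, which is a useful cross-check of the whole generative
setup. The distribution is an explicit probability table in
`SimulationConfig`, so any published distribution can be substituted.

### Bookkeeping conventions

After pruning, a family with fewer than two remaining offspring is an
uninformative trio: it leaves the *analysis* and the family count, but
its parents and retained carrier offspring stay in the *subject* count
(subject loss is exactly the removed non-carrier offspring). These
conventions reproduce the reference tallies, which are not mutually
consistent under a drop-whole-family subject count.

## Multipoint lod engine

The engine computes, per family,

lod(x) = log10 [ P(markers, phenotypes | disease locus at x) /
                 (P(markers) · P(phenotypes)) ],

summing over families (the likelihood factorises). It is a hidden Markov
model over inheritance vectors: 2 bits per offspring meiosis, transitions
between adjacent loci flip each bit independently with probability θ,
marker emissions marginalise the 16 ordered founder-couple allele
configurations per locus against the observed phase-unknown genotypes,
and the phenotype factor marginalises founder disease genotypes under
Hardy–Weinberg at the analysis frequency. Conditioning on the inheritance
vector at the test position renders phenotypes and markers independent,
so the lod numerator is an inner product of the forward/backward marker
distributions with the phenotype factor.

Analysis model: penetrance 0.5 for disease-genotype carriers, phenocopy
rate 0, mode of inheritance and allele frequency matched to the
generating values at B — penetrance vector (0, .5, .5) dominant,
(0, 0, .5) recessive. Marker allele frequencies are taken from the map,
not re-estimated from the (possibly pruned) sample, which isolates the
stratification effect. The associated marker is always among the analysis
markers; being unlinked to B it cannot inflate the lod there.

Exact state-space reductions (both verified against the oracle):

- **Exchangeable siblings.** Siblings with identical observed data (same
  unordered genotype at every informative marker and same affection) are
  exchangeable, so a group of k such sibs is tracked by its count
  multiset over the 4 inheritance values — C(k+3, 3) states instead of
  4^k. Group transition matrices are built recursively by adding one
  sibling at a time; state multiplicities (multinomial coefficients)
  re-weight inner products. With a dense map, large sibships share long
  non-recombinant haplotypes and collapse heavily; this is what keeps
  10-offspring families tractable without approximation.
- **Free-recombination gaps.** Markers separated from every evaluated
  position by a θ = 0.5 interval carry no information about the
  inheritance vector there, and their likelihood factor cancels in the
  lod ratio; the sweep is restricted to the linked marker segment.

Numerics: forward/backward vectors are renormalised per locus (the scale
cancels in the ratio); θ = 0 intervals use the identity transition; a
zero marker likelihood raises a structured Mendelian-inconsistency error
naming the family; all-missing data yield lod ≡ 0. Families with more
than 10 offspring are refused rather than approximated.

Evaluation grid: the "linkage interval containing B" runs from the
flanking marker at position 12 to the flanking marker at position 14;
the default grid is both flanks, B itself, and 4 equally spaced interior
points per sub-interval (11 positions). On this map the interval is
~0.2 cM wide and the curve is flat to well under 0.01 lod, so the grid
density does not affect the reported maxima.

### Independent oracle

`elston_stewart_loglik` computes the same likelihood by brute force —
explicit summation over all founder multilocus ordered genotypes and all
offspring transmission patterns — sharing no code with the HMM. It is
exponential in loci and offspring (limits: 6 loci, 4 offspring) and
exists purely as a correctness oracle; the acceptance suite checks
|HMM − enumeration| ≤ 1e-6 on 200 randomized small families, including
families with deliberately identical siblings and maps containing
θ = 0.5 gaps.

## Stratification

The carrier predicate defaults to: dominant mode at A → keep offspring
with ≥ 1 disease allele; recessive mode at A → keep offspring with the
homozygous disease genotype ("disease allele or genotype"); both rules
are selectable, as is pruning on ≥ 1 (default) or 2 copies of the
associated marker allele when only an association is known. Parents are
always retained. Pruning is idempotent and partitions offspring exactly
(asserted in tests). If a pruned dataset retains no informative family,
its stratified lod is defined as 0 (no evidence).

## INT summaries

INT = stratified − unstratified maximum lod in the B interval, per
dataset. Strictly positive INT counts as evidence of interaction
(INT = 0 is non-positive). Summary tables condition on the unstratified
lod with inclusive thresholds (≥ 0, ≥ 1.5, 1.5 ≤ lod < 3, < 0); the
power-versus-D′ table conditions on a strictly positive unstratified lod,
matching the two conditioning conventions in use. Standard deviations are
sample (n−1) deviations — the convention is recorded here because the
source does not state one.

## Scale of the shipped experiments

The reference study used 500 datasets × 50 families per scenario. The
acceptance script runs 110–220 datasets per scenario (≥ 100 everywhere)
so the full evaluation completes in roughly ten to fifteen minutes on one
CPU; binomial standard errors on percentage outcomes are then ≈ 3–5
points, and the test suite applies ±3 SE / ≈ ±10-point tolerances
accordingly. The pytest tier-2 checks use 25–30 datasets per model with
correspondingly wider Monte-Carlo bands; the 100-dataset sample-size
checks need no lod computation and run at full width.

## What the generator does and does not emulate

The synthetic data reproduce: ascertainment-induced selection on family
size and parental genotypes, phase-unknown marker data, the LD structure
between the known locus and its tag, and both interaction and
heterogeneity architectures. They do not include: genotyping error or
missingness (all members fully typed), phenocopies, parental-affection
ascertainment, multi-generation or looped pedigrees, allelic
heterogeneity at A, population stratification, or maps with
interference. Passing tests therefore demonstrate the statistic's
behaviour under the idealised design, not robustness to real-data
artefacts.

## Known limitations

- The INT statistic ships without a formal null distribution or p-value;
  the heterogeneity scenarios provide an empirical false-positive rate
  only.
- The exact engine is limited to nuclear families of ≤ 10 offspring.
- The sibship distribution is a calibrated stand-in (see above); the
  sample-size tallies it is fit to are reproduced to within ~4 percentage
  points RMSE but not exactly, and residual discrepancies of that order
  should be expected in sample-size-related outputs.
- Heterogeneity-model analyses use the single-locus lod, not
  heterogeneity-admixture (HLOD) maximisation.
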