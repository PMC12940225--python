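# Methods

## Scope and model

`gutwbm` implements a desk-scale version of the personalised
host–microbiome whole-body modelling workflow: species-level abundance
processing, pan-species and community model assembly, FBA-based maximal
blood-flux prediction, flux post-processing, metabolomics QC, and the
association battery against aging risk factors. The package deliberately
replaces the two large external ingredients of such studies — strain-level
reconstruction resources and organ-resolved whole-body reconstructions —
with small toy models, because the scientific content exercised here is the
*pipeline*: the constraints, thresholds, and statistics, all of which are
implemented at full fidelity.

### FBA formulation

Steady-state mass balance `S·v = 0` with flux bounds, solved as an LP with
the HiGHS dual simplex (scipy). Feasibility/optimality tolerances of 1e-9
are requested from the solver; optimal solutions are asserted to satisfy
mass balance, bounds and coupling within 1e-6, and a violation raises
rather than returning a silently degraded optimum. Solver failure is
propagated as a status (`infeasible`/`unbounded`), never as a fabricated
zero. Only objective values are persisted: LP degeneracy can change the
flux vector, never the optimum, so storing objectives makes results
reproducible across solvers and orderings.

Coupling constraints `|v_j| ≤ C·v_bio,k` are kept as explicit inequality
rows beside S (two rows per coupled reaction), not folded into bounds —
this matches the flux-capacity-coupling semantics of the COBRA ecosystem
and keeps S itself purely stoichiometric. `C = 400` (dimensionless) by
default.

### Community and host assembly

Pan-species models take the union of strain reactions by id; duplicate ids
must agree in stoichiometry (conflict is a hard error naming both strains)
and merge to the widest observed bound interval. The community connects
namespaced species models through a shared lumen (`[luM]`); the
`communityBiomass` reaction consumes species-biomass metabolites with the
relative abundances `a_k` as coefficients. Because the community-biomass
excretion is pinned to 1 mmol/day/person, each species' biomass flux is
forced to exactly `a_k`, and the coupling cap on its reactions becomes
`400·a_k` — the mechanism behind the linear abundance–flux law for
sole-producer metabolites. Abundances must arrive normalized; community
assembly refuses to renormalize silently (that is the mapping stage's job).
A member with positive abundance but no biomass reaction is a hard error,
since community biomass would be undefined.

The host join adds reversible 1:1 lumen↔large-intestine transport for every
shared-lumen metabolite, routes community biomass to feces, and pins both
`Excretion_EX_microbiota_LI_biomass[fe]` and `Whole_body_objective_rxn` to
lb = ub = 1. Diet is applied on `EX_*[d]` exchanges with the
uptake-negative convention (diet flux f ⇒ bounds (−f, 0)); non-diet
exchanges are closed from below; internal reactions default to ±1,000,000
mmol/day/person.

## Thresholds (defaults, all surfaced in `PipelineConfig`)

| parameter | default | role |
|---|---|---|
| abundance floor | 1e-6 | zero + renormalize; also excluded from richness/coverage counts |
| coupling factor C | 400 | microbial flux capacity per unit growth |
| flux rounding | 6 decimals | storage precision of all flux layers |
| zero/identity fractions | 0.9 | metabolite refinement cuts |
| identity tolerance | 1e-6 | "identical flux" binning (single-linkage chaining on sorted values; the tolerance is stated, the clustering rule is this package's reading) |
| grouping R² | 0.999 | linear-dependence edge threshold, complete-case samples |
| metabolite missingness | 0.70 | QC metabolite cut |
| aliquot CV | 0.30 | QC reproducibility cut (SD/mean within replicate groups, averaged) |
| sample missingness | mean + 5·SD | QC sample cut; the source rule is ambiguous between mean+5·SD and 5·SD alone — mean+5·SD is the declared reading and is not changed silently |
| KNN neighbours | 10 | imputation over samples on the standardized log2 matrix (k is this package's choice) |

Renormalization is two-pass (normalize → floor → normalize), a declared
ordering; it is idempotent, which the suite checks property-based.

Whether bound-limited masking should remove only the max-attaining samples
or the whole metabolite is ambiguous in the workflow this follows;
sample-level masking is the declared reading (the refinement stage then
drops metabolites that lose >90% of samples anyway).

## Statistics

Regressions are OLS with the focal predictor (and continuous outcome)
z-scored, two-sided Wald p on the focal coefficient, BH-FDR applied per
analysis family (the metabolite battery of one analysis). Education enters
as ordinal 1–4; sex as a binary indicator. Kruskal–Wallis uses the
tie-corrected H; an exact permutation mode enumerates all distinct
assignments for small instances (≤ 50,000), since no installed library
provides an exact KW p. Dunn post-hoc z statistics come from pooled ranks
with tie correction and are reported unadjusted. Wilcoxon rank-sum defers
to scipy (exact for small tie-free samples). The 2×C Fisher test sums
multivariate-hypergeometric probabilities over all tables with the observed
margins (vectorised enumeration over the C−1 free cells, a 1e-7 relative
tie slack, and a seeded Monte-Carlo fallback beyond the enumeration cap).
The two-sample t test is Welch by default (the equal-variance variant of
the source is unstated) and accepts (mean, SD, n) summaries. The PC1-based
global cognition score is sign-oriented to correlate positively with the
mean standardized subtest, so "higher = better" is reproducible.

Driver attribution regresses log2-standardized abundances (zeros treated as
missing) against the flux for candidate species — those whose model can
produce the metabolite, exchange it with the lumen, or produce a declared
precursor (the union of both readings) — and ranks by R². Note the R² of a
true sole producer is slightly below 1 because the flux is linear in the
abundance while the regressor is logarithmic.

## Synthetic cohort: what it emulates, and what it does not

The generator's defaults define the study conditions. Demographic anchors
(age 61.7 ± 5.5 years truncated to 51–92, 57% female, BMI 27.4 ± 4.5,
education and APOE genotype frequencies) mirror a healthy aging cohort.
Cognitive subtests follow a one-factor model `x_j = λ·f + e`, `e ~ N(0,1)`,
with λ = 0.714 chosen so the population first-PC variance fraction is 0.47,
the level typically reported for global cognition scores; the factor
carries a mild age decline (−0.2 SD per age SD) and a female advantage
(0.4 SD). 28 SNP dosages are binomial with uniform MAFs; PRS weights are
fixed by the master seed.

Abundances follow the declared log-normal design: per-species base weights,
covariate effects added on the log scale with coefficient
`slope/√(1−slope²)·σ` so the *standardized* log-abundance slope equals the
configured value (σ = 0.6 log units, a realistic inter-individual spread),
then closure to the simplex within the mapped block. Closure makes
compositions sum to one but also leaks a small anti-correlation from an
effect-carrying species onto all others; the generator therefore gives
effect-carrying species a smaller base share (~5%), keeping the leaked
correlation on null species below |0.03| — small enough that planted nulls
are genuinely null at n = 500. The mapped-block share of species reads
(0.64 ± 0.116) and the species share of all reads (0.495 ± 0.097) are drawn
per sample around the coverage levels typical of 16S-to-reconstruction
mapping, so the mapping report reproduces those statistics.

The toy universe has seven mapped species: sole producers for an
L-arginine-like and a deoxycholate-like metabolite, a two-step bile
acid-like chain producer (`ba_a → 0.8 ba_b`; the deliberately lossy yield
makes the chain members' maxima distinct so the smaller-max representative
rule is exercised without ties — a unit-yield chain is available in
configuration and forces equal maxima), two null producers, one
non-producing species with an uptake/degradation route for the
arginine-like metabolite (a non-driver attribution candidate), and one
fully inert species. Species biomass draws on a *separate* uptake reaction
from the production substrate, so growth never competes with production on
one coupled uptake and the coupling cap `400·a_k` is the unique active
bound for sole producers — making the coupling law exact rather than
`399·a_k`. The host is a minimal multi-compartment model (diet → LI lumen →
blood → pinned objective) with a capped host-only synthesis route whose
flux is identical with and without a microbiome (scaled flux exactly 0).

Metabolomics: 60 metabolites with log-normal intensities, two batches with
scale factors (1.0, 2.5), 5% missingness, six duplicate-aliquot replicate
groups, a planted log2 shift of 1.0 on `dca_serum` in the APOE E4 group,
and three QC plants — a 10× missingness-outlier sample, an 85%-missing
metabolite, and a metabolite whose aliquots differ by 1:1.65 (CV exactly
0.347, just above the 0.30 cut).

What the generator does **not** emulate: 16S read-level error, chimeras or
compositional sequencing artifacts; realistic metabolic network content or
organ physiology; genotype–phenotype linkage beyond the planted effects;
serum–flux coupling beyond the planted APOE group shift. Passing tests
therefore demonstrate that the pipeline's rules and statistics behave
correctly and recover planted effects under controlled conditions — not
that the toy models predict real biology.

## Problem sizes and numerical choices

Routine analyses use 200–500 samples; effect-recovery properties are
assessed over repeated seeds at n = 500 with 50 seeds in the acceptance
suite (20 in the standalone acceptance script). Each personalised model has
~80 reactions, solved in milliseconds; all oracle checks (vertex
enumeration of basic feasible solutions) run on toy LPs of ≤ 12 reactions
where full enumeration is tractable. Ties in the grouping representative
are broken lexicographically; rows that sum to zero during abundance
processing are flagged and excluded, never imputed. Degenerate statistical
inputs (constant subtests, single-sex data, groups smaller than two) raise
or drop with a logged warning as documented per function.

## Known limitations

- The toy host has no organ resolution; sex specificity is a tag plus
  sample matching, not differing physiology, so germ-free layers are
  identical across sexes in the default universe.
- The LP path is dense; it is sized for toy models, not genome-scale ones.
- Exact KW enumeration is capped at 50,000 assignments; beyond that the
  chi-square approximation is used.
- Serum metabolomics and fluxes are linked only through the planted APOE
  group shift, so cross-modality "validation" analyses have power only for
  that contrast.
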