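# Methods

`demohist` reconstructs the demographic history of a two-group population
system — a montane group (NL) and an eastern group (ES) — from reduced-
representation SNP genotypes.  The pipeline has five stages: SNP
filtering, diversity and AMOVA statistics, construction of the folded
two-population joint site frequency spectrum (SFS), simulation-based
composite-likelihood fitting of ten competing demographic scenarios with
AIC ranking, and conversion of the estimates to natural units.  A
coalescent synthetic-data generator makes every stage testable without
any external download.

## Genotype filtering

A locus is retained iff

1. its whole-sample minor allele frequency (computed on non-missing
   alleles) is at least `min_maf` (default 0.05);
2. at least `min_populations` (default 5) populations each genotype at
   least `min_genotyping_rate` (default 80%) of their individuals at the
   locus — a single rule that makes the "genotyping rate within
   populations" and "minimum number of populations" criteria jointly well
   defined;
3. its whole-sample observed heterozygosity is at most `max_obs_het`
   (default 50%), screening paralog collapse.

For reporting, a locus failing several criteria is attributed to the
first matching criterion in the order MAF, genotyping rate (among loci
with data in enough populations), heterozygosity, too-few-populations;
the retained set is independent of that order.

## Diversity and AMOVA

Expected heterozygosity uses Nei's unbiased estimator
`2n/(2n-1) * (1 - p^2 - q^2)` with per-locus sample sizes; the correction
is material at the 5–14 diploids per population typical of the system.
Per-site nucleotide diversity is the average of `2j(k-j)/(k(k-1))` over
loci.  Pairwise differentiation is the Weir–Cockerham theta with the
multilocus ratio-of-sums rule; slightly negative estimates are reported
unclamped.

The AMOVA decomposes squared Euclidean distances between individual
dosage vectors (missing loci pairwise-deleted and rescaled to the full
locus count) into among-group, among-population-within-group, and
within-population components via the standard nested moments equations
with unbalanced-design coefficients; degrees of freedom are (G−1, P−G,
N−P), matching an individual-level analysis.  Fixation indices are
Fct = σ²a/σ²T, Fsc = σ²b/(σ²b+σ²c), Fst = (σ²a+σ²b)/σ²T, and the identity
Fst = Fct + (1−Fct)·Fsc holds algebraically.  Significance is assessed by
seeded permutation (default 999): individuals among populations for Fst,
individuals among populations within groups for Fsc, and whole
populations among groups for Fct; p-values are `(1 + #extreme)/(n_perm + 1)`.

## Folded joint SFS

Folding is on the whole-(two-deme)-sample minor allele (the
easySFS/fastsimcoal convention), not per deme.  A site whose overall
frequency is exactly 1/2 contributes half a count to each member of the
conjugate entry pair.  Missing genotypes are handled by projecting each
locus's non-missing alleles down to fixed sample sizes `(n1, n2)` by
hypergeometric expectation; loci with fewer available alleles than the
projection contribute nothing.  The monomorphic corner (0,0), its
fully-folded complement, and the structural-zero region beyond the fold
line are masked and excluded from totals and likelihoods.

## Scenario registry

Ten two-deme scenarios are registered, reconstructed from the named model
families: NIS (no isolation: one panmictic deme), IS (clean split), MIG
(split + continuous bidirectional migration), MIG1W (one-way migration
out of the focal deme), AMIG (migration only in the older half of the
divergence, epoch boundary fixed at T_DIV/2 so the family stays
distinguishable from SEC), RMIG (recent half only, same fixed boundary),
BOT (epoch-limited bottleneck in the focal deme), SEC (migration resumes
at a free secondary-contact time T_SEC), EXP (exponential expansion of
the focal deme from N_PRE at a free onset), and SECEXP (migration and
expansion both starting at T_SEC; k = 8 free parameters).  Either deme
can play the focal ("split source") role via a mirrored spec.

Search bounds are wide, FSC2-style ranges chosen once: deme sizes
log-uniform in 1e2–1e7 diploids, pre-expansion/bottleneck sizes 1e1–1e6,
T_DIV log-uniform in 1e3–1e7 generations, event-time ratios (T_SEC/T_DIV
etc.) log-uniform in 1e-3–0.95 so event ordering holds by construction,
and migration intensities uniform in 0–20 migrants/generation (uniform
because one-way and no-migration models need exact zeros).  Migration is
parameterized internally as a backward per-generation proportion `m` and
reported as `M = 2*N*m` individual migrants per generation (N the
receiving deme).

## Coalescent engine

Genealogy simulation delegates to msprime on the diploid time scale
(pairwise coalescence rate 1/(2N)); haploid allele copies are sampled via
per-sample-set ploidy.  Loci are unlinked with no within-locus
recombination — the same exchangeability assumption the SFS composite
likelihood makes.  Mutations follow the infinite-sites model on
continuous coordinates.  A deliberately simple event-driven
structured-coalescent simulator (`demohist._reference`) written
independently of msprime serves as a cross-check oracle in the tests for
panmictic, isolation, and migration histories.

The synthetic-data generator emulates the study layout: 11 populations
in two groups (7 NL, 4 ES), 5–14 diploid individuals per population (112
total), uniform genotype missingness (default 10%, matching an 80–90%
genotyping rate), and a per-generation mutation rate of 1.16e-7 per site.
The default locus length is 3 bp at 5,000–50,000 loci, chosen so the
SNP yield is in the tens of thousands and SNPs are effectively
unlinked — the regime of the real GBS data after extraction filters.
Long, SNP-dense loci would violate the likelihood's independence
assumption badly enough to move composite-likelihood optima; this is a
property of composite likelihood itself, not of the generator.  The
generator does not model sequencing error, allele dropout, paralog
collapse, or non-uniform missingness, so passing tests demonstrate
correctness of the inference machinery under the model, not robustness
to those artifacts.

## Composite-likelihood fitting

The expected folded joint SFS under a candidate demography is the
Monte-Carlo mean of the branch-mode frequency spectrum over `n_sims`
independent genealogies, normalized over unmasked entries — a
Rao-Blackwellized estimate (branch lengths rather than sampled mutations)
of the per-site configuration probabilities conditional on polymorphism.
The observed counts are scored with the multinomial composite
log-likelihood Σ m_ij ln p̂_ij, with p̂ floored at
`1/(10 * n_sims * n_entries)`.  AIC = 2k − 2 lnL̂ with natural
logarithms; conventions that report log10 likelihoods differ by the
constant factor ln 10 in every model, leaving ΔAIC ordering unchanged.

Three numerical devices make this objective optimizable at desk-scale
simulation counts:

1. **Analytic scale profiling.**  The coalescent SFS shape is invariant
   under rescaling all sizes and times by `c` (with `m -> m/c`, keeping
   2Nm), so when the observation carries a total site count and mutation
   rate the monomorphic-class term is maximized in closed form (Poisson
   random field over sites: `c*` equates expected and observed SNP
   density).  One size parameter therefore carries no shape information
   and is held fixed during the search; the profile scale is restored on
   the reported estimates.  Without the anchor, fits are shape-only and
   the results are flagged theta-confounded.
2. **Working resolution.**  Replicate refinement uses the observation
   down-projected to at most 14 allele copies per deme (hypergeometric
   projection, the easySFS operation).  Both sides of the comparison are
   coarsened by the same linear operator, so the estimator stays
   consistent while the per-cell Monte-Carlo noise of the expected
   spectrum drops; endpoint selection and the final refinement run at the
   full observed resolution, where the curvature that separates
   near-equivalent histories is strongest.
3. **Noise-bias correction.**  E[ln p̂] ≈ ln p − Var(p̂)/2p², so an
   uncorrected Monte-Carlo objective systematically favours demographies
   with low genealogy-to-genealogy variance — enough to relocate the
   global optimum at small `n_sims`.  The likelihood is therefore
   debiased with the first-order correction computed from the per-tree
   variance of the folded branch spectrum (relative variances capped at 1
   where the expansion is unreliable).

The search itself is multi-start, FSC2-style, with one addition: a
deterministic grid of method-of-moments starting candidates.  Within-
deme and pooled per-site diversity and the between-deme divergence d_xy
(all invariant to folding) give closed-form anchors (`Ne ~ pi/4mu`,
`T_DIV ~ (d_xy - pi_tot)/2mu`); a fixed grid of multiplicative variants
covers the anchors' known biases (gene flow inflates within-deme
diversity, incomplete lineage sorting shrinks apparent divergence,
expansion hides the pre-expansion size), with deflated-size variants
paired to the migration that explains the diversity they shed.  The
candidate pool (moment grid plus `n_scan` log-uniform prior draws) is
ranked once per fit at reduced Monte-Carlo resolution, and optimizer
replicates rotate over the top entries so distinct starting basins get
refined rather than one greedy scan winner.  Each replicate refines its
start by bracketed per-parameter line searches in the transformed (log)
space plus a short bounded Nelder-Mead, holding one simulation seed
fixed across evaluations (common random numbers), so the fit is
deterministic given its seed.  Replicate endpoints are compared at
`selection_factor x n_sims` simulations (default 8x) on a common seed at
full observed resolution, and the winner is further refined directly on
that high-precision selection surface by per-parameter line searches
that accept only improving moves (monotone in the reported likelihood by
construction).

Random prior starts alone essentially never reach the generating basin
of an 8-parameter scenario at desk-scale evaluation budgets — the moment
candidates are what makes the multi-start effective — and even so,
parameters lying on shallow likelihood ridges (notably the size of a
deme whose diversity is dominated by immigration) are recovered only up
to a factor of a few at 2,000-simulation resolution; see Known
limitations.

## Unit scaling

The per-generation mutation rate is the product of a yearly clock rate
and the generation time (defaults 2.32e-8 substitutions/site/year and
5 years, hence 1.16e-7 per generation).  Times in generations convert to
years by multiplying with the generation time, and to Ma by dividing by
1e6.  Sizes are in diploid individuals whenever the observation was
mutation-rate anchored.

## Validation design

- Closed forms: Watterson's E[S] = θ Σ 1/i for the simulator; neutral
  folded SFS shape 1/i + 1/(2n−i); hand-computed hypergeometric weights.
- Independent oracles: the pure-Python structured coalescent vs msprime;
  a centroid-identity balanced AMOVA vs the distance-matrix route;
  explicit Weir–Cockerham sums vs the vectorized implementation;
  exhaustive allele-subsample enumeration vs the hypergeometric SFS
  builder.
- Experiments: SECEXP parameter recovery on 50,000 synthetic loci at
  (20, 20) allele copies with 10 optimizer replicates x 2,000
  simulations, and model-selection power (SECEXP vs IS vs MIG) on 20
  seeded replicates of 3,000-locus datasets at (10, 10).

## Known limitations

- Composite likelihood ignores residual linkage; uncertainty intervals
  are not provided (and would be anti-conservative if read off the
  likelihood surface).
- The AMIG/RMIG epoch boundary at T_DIV/2 is a registry convention, not
  an estimate.
- At desk-scale simulation counts (thousands of genealogies per
  likelihood evaluation) some parameter combinations are resolvable only
  partially.  In the SECEXP recovery experiment the divergence time and
  the dominant migration rate come back within +-25% / factor 2, but the
  deme-size pair sits on a curved likelihood ridge — a deme whose
  diversity is dominated by immigration trades its size against
  migration, divergence time and the ancestral size at a cost of only a
  few hundred log-likelihood units — so sizes are recovered only within
  a factor of a few.  The generating parameters are verifiably the
  global optimum at high Monte-Carlo resolution; closing the last gap is
  a search-budget question (roughly an order of magnitude more
  simulation effort), not a bias of the estimator.
- The reference simulator supports piecewise-constant two-deme histories
  only; growth and bottleneck scenarios are validated against closed
  forms and internal consistency instead.
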