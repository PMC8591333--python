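# demohist

Demographic-history inference for a two-group population system from
SNP genotypes: SNP filtering, diversity and AMOVA statistics, the folded
two-population joint site frequency spectrum (SFS), coalescent
simulation, and simulation-based composite-likelihood selection among
ten demographic scenarios with AIC.

The package targets the classic montane phylogeography setting: a
western montane group of populations (**NL**) and an eastern group
(**ES**) that split from an ancestral population and may subsequently
have experienced isolation, migration, secondary contact, bottlenecks,
or expansion.  The scenario of central interest, **SECEXP**, combines
isolation at `T_DIV`, secondary contact at `T_SEC` with asymmetric
migration (`M_NL-ES`, `M_ES-NL` individual migrants per generation), and
demographic expansion of NL from a small pre-expansion size
`N_e-pre-exp` to its present size.

## The statistic and the model

For two demes with `n1` and `n2` sampled allele copies, the folded joint
SFS counts sites by minor-allele copy number `(i, j)`.  For a candidate
demography θ the expected spectrum `p(θ)` is estimated by Monte-Carlo
coalescent simulation (mean branch-length spectrum over genealogies, the
fastsimcoal approach), and scenarios are scored by the composite
log-likelihood

    lnL(θ) = Σ_ij  m_ij · ln p̂_ij(θ)         (+ a monomorphic-class term
                                              when the total site count and
                                              mutation rate are known)

maximized by a multi-start derivative-free search; models are ranked by
`AIC = 2k − 2 lnL̂`.  Estimates convert to natural units through a
per-generation mutation rate `μ = clock rate × generation time`
(defaults `2.32e-8 /site/year × 5 years = 1.16e-7 /site/generation`) and
times scale to years as `generations × generation time`.

See `docs/methods.md` for the estimators (Nei-unbiased He,
Weir–Cockerham θ, three-level AMOVA with permutation tests), the
scenario registry, and the numerical devices behind the fit (analytic
profiling of the absolute scale, working-resolution projection, and
Monte-Carlo noise-bias correction).

## Worked example

Everything below runs from scratch in a few minutes on a laptop;
no data download is needed — the example simulates a GBS-style dataset
(11 populations in 2 groups, 112 individuals, 10% missingness) under the
SECEXP demography and pushes it through the full pipeline.

```sh
demohist demo --out-dir demo_run --seed 1
```

prints the AMOVA summary and the scenario ranking (output of this exact
command):

```
                                  df  sum_of_squares  variance_component  percent_of_variation
source
among groups                       1     45512.65741           875.14321              61.44275
among populations within groups    9      4577.49734            -4.49195              -0.31537
within populations               101     55920.84850           553.67177              38.87263
total                            111    106011.00325          1424.32302             100.00000
Fct = 0.6144 (p = 0.005)   Fsc = -0.0082 (p = 0.955)   Fst = 0.6113 (p = 0.005)
note: negative variance component(s) reported unclamped
          k           lnL           AIC         dAIC     est_NE_ANC     est_NE_NL  ...
scenario
SECEXP    8 -17982.916778  35981.833557     0.000000  370057.111672  58958.724584  ...
MIG       6 -18323.434172  36658.868344   677.034787  334021.728185   5043.477336  ...
IS        4 -19466.462245  38940.924490  2959.090933  148088.166301  23593.897092  ...
```

The generating scenario (SECEXP) wins the AIC ranking by a wide margin,
and the estimates sit close to the generating values where the data are
informative: the present NL size comes back as 58,959 diploids against a
generating value of 57,495, the secondary-contact time as ~16,600
generations against 20,000, and the weak ES-to-NL migration as 0.31
against 0.33 migrants/generation.  The among-group variance fraction
(61%) is far below the real system's 96% because the demo simulates only
two panmictic demes — the 11 sampled populations within a group are
samples of the same deme, so almost no among-population-within-group
variance exists (the slightly negative component is the unclamped
moments estimate of zero).

The library surface mirrors statsmodels: a model object built from data,
a results object from `fit()`:

```python
import demohist as dh

dem = dh.build_demography("SECEXP", dh.DEMO_SECEXP_PARAMS)
req = dh.SimulationRequest(demography=dem, n1=20, n2=20, num_loci=20_000,
                           mutation_rate=1.16e-7, locus_length=3, seed=7)
obs = dh.simulate_joint_sfs(req)

model = dh.DemographicModel(obs, "SECEXP")
res = model.fit(n_replicates=5, n_sims=2000, seed=1)
print(res.summary())
scaled = res.scale(dh.ScalingSpec(clock_rate=2.32e-8, generation_time=5.0))
print(scaled.table())
```

`res.params` holds the estimates in natural units (diploid sizes,
generations, migrants/generation); `scaled.table()` adds years and Ma.

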