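# spatfda

Spatial summary functions of single-cell imaging data as functional
covariates in additive functional Cox survival models.

Multiplex tissue imaging (mIHC, MIBI, IMC, CODEX, ...) yields, for each
subject, the coordinates and phenotypes of thousands of cells in a tissue
section — a *marked point pattern*. How tumor, stromal and immune cells
arrange themselves around one another carries prognostic information, but
that arrangement is a *function of inter-cell distance*, not a single
number. `spatfda` is for biostatisticians and imaging groups who want to
take the whole distance profile into a survival model instead of collapsing
it to a scalar.

The pipeline has three stages:

1. **Distance-indexed spatial summaries.** For each image the package
   estimates Ripley's K and the pair correlation function g(r) (with
   cross-type variants and translation edge correction), the **mark
   connection function** between two cell types i and j,

       mcf_ij(r) = λ_i λ_j g_ij(r) / (λ• g(r)),

   reported by default in the normalised form g_ij(r)/g(r) whose
   random-labeling baseline is exactly 1 (values below 1 = same-type
   clustering, above 1 = cross-type mixing), and a **distance-band Moran's
   I profile** for a continuous marker m observed on two cell types,

       I_m^ij(r) = Σ_{s∈i} Σ_{t∈j, |d(s,t)−r|≤h} (m_s − m̄_i)(m_t − m̄_j)
                   / [ Σ_s (m_s − m̄_pool)² + Σ_t (m_t − m̄_pool)² ].

2. **Additive functional Cox regression (AFCM).** Per-subject summary
   curves X_i(s) enter the log hazard together with scalar covariates Z_i:

       log λ_i(t) = log λ_0(t) + Z_i'β + ∫ F(s, X_i(s)) ds,

   with F(s,x) = Σ_jk θ_jk B_j(s) B_k(x) a tensor product of cubic
   regression splines, estimated by penalized partial likelihood
   (Newton–Raphson with step halving, Breslow ties) with one curvature
   penalty per margin; smoothing parameters maximize the log Laplace
   approximate marginal likelihood (LAML). The Breslow step estimator of
   the cumulative baseline hazard, surface evaluation and linear-predictor
   prediction on new subjects are provided. The estimator
   (`AdditiveFunctionalCoxModel`) follows scikit-learn conventions
   (`fit(X, y)` / `predict` / `get_params`).

3. **FPCA-based survival simulation.** A Karhunen–Loève generator
   (`FunctionalPCA` fitted to real curves, or a declared stand-in) draws
   curves X*_i(s), a survival time is drawn by inverting
   S_i(t) = exp{−e^{η_i} Λ_0(t)} with η_i = βZ*_i + (functional term of
   X*³(s)s), censoring is applied, and three models — scalar+functional,
   functional-only, scalar-only — are compared by test-set mean squared
   error of the linear predictor over replicated 75/25 splits.

Synthetic pattern generators (Poisson, random labeling, displaced two-type
Thomas cluster processes with smooth latent marks) make the whole pipeline
testable without any imaging data.

## Worked example

Mark connection functions separate "mixed" from "compartmentalized"
two-type architectures:

```python
from spatfda import PatternSimConfig, RGrid, mark_connection, simulate_pattern

mixed = PatternSimConfig(process="random_labeling", intensity=1300.0)
compartmentalized = PatternSimConfig(process="two_type_thomas", kappa=30.0,
                                     sigma=0.02, mu_offspring=25.0,
                                     displacement=0.5)
grid = RGrid.uniform(0.25, 26)
for name, cfg in [("mixed", mixed), ("compartmentalized", compartmentalized)]:
    pat = simulate_pattern(cfg, seed=1)
    mcf = mark_connection(pat, "a", "b", grid)
    print(f"{name:>18}: n={pat.n}, mcf(0.02)={mcf.values[2]:.2f}, "
          f"mcf(0.10)={mcf.values[10]:.2f}, mcf(0.20)={mcf.values[20]:.2f}")
```

```
             mixed: n=1301, mcf(0.02)=1.00, mcf(0.10)=0.99, mcf(0.20)=0.99
 compartmentalized: n=1337, mcf(0.02)=0.26, mcf(0.10)=0.93, mcf(0.20)=1.10
```

Under random labeling the normalised mcf sits at its baseline 1 at every
distance; in the compartmentalized pattern cross-type contact is strongly
depleted at short range (0.26 at r = 0.02) and recovers toward 1 beyond the
compartment scale.

The replicated three-model experiment shows what the functional covariate
buys in prediction:

```python
from spatfda import run_mse_experiment, standin_simulation_config

config = standin_simulation_config(n=200, replicates=10)
table = run_mse_experiment(config, seed=1)
print(table.summary().round(2))
print(f"mean scalar coefficient: {table.beta_hats.mean():.2f} (truth: 1)")
```

```
            mean    sd  n_replicates
model
both        0.08  0.04            10
functional  1.29  0.35            10
scalar      4.27  0.88            10
mean scalar coefficient: 0.99 (truth: 1)
```

The joint model predicts the held-out linear predictor far better than
either single-covariate model; the functional-only model misses the
scalar term's variance (≈1), the scalar-only model misses the functional
term's (larger here by construction), and the true unit log hazard ratio
is recovered.

A `spatfda` command-line interface wraps the same stages for shell use:
`spatfda ingest`, `spatfda summarize --stat mcf --types tumor,stroma`,
`spatfda fit`, `spatfda simulate`, and `spatfda synth pattern|cohort`.

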