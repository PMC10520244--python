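# pcube

Subgroup-stratified survival prediction for heterogeneous cohorts, built
around kidney-transplant allograft survival.

## The problem

Risk models for graft survival are usually fit once on a whole registry
cohort. The fit is then dominated by the majority of patients, and minority
strata — paediatric recipients, elderly recipients with comorbidity — get
systematically worse predictions even when the overall concordance looks
excellent. `pcube` implements a *precision prediction pathway*: split the
cohort into homogeneous subgroups first, fit a survival model per subgroup,
and route each new donor–recipient pair to the subgroup model that actually
describes patients like them.

The pipeline has four stages:

1. **Consensus clustering.** An ensemble of base clusterings (K-means
   restarts and agglomerative runs with ward/average/complete linkage, over
   a range of k) is summarized in the co-association matrix
   `M[i,j] = fraction of runs placing i and j together`. An average-linkage
   tree on `1 − M` is cut into K clusters, with K chosen by a consensus-fit
   stability score (how well `M` matches the block structure of the
   candidate partition; ties prefer smaller K).
2. **Per-subgroup MTLR.** Multi-task logistic regression is a discrete-time
   survival model with one logistic score `g_j(x) = θ_j·x + b_j` per time
   grid point `t_1 < … < t_m`. Legal event sequences `s_k` (event in
   `(t_{k−1}, t_k]`; `s_{m+1}` = survived past `t_m`) get scores
   `f_k(x) = Σ_{j≥k} g_j(x)` and probabilities
   `P(s_k|x) = exp(f_k)/Σ_{k'} exp(f_{k'})`; survival is the tail sum
   `S(t_j|x) = Σ_{k>j} P(s_k|x)`, monotone by construction. Censored
   patients contribute the marginal likelihood of every sequence consistent
   with their censoring time. Fitting is L-BFGS on the penalized negative
   log-likelihood with a ridge term on `θ` and a temporal-smoothness term on
   `θ_{j+1} − θ_j`.
3. **Risk-factor selection.** Each feature's importance is its net weight
   `w_f = |Σ_j θ_{j,f}|`; ranked importances are cut at the first
   consecutive difference below a threshold (default 0.007), giving each
   subgroup its own risk-factor profile (never empty).
4. **Routing and evaluation.** A shallow CART "model decision tree" learns
   the subgroup labels and routes new patients, producing a human-readable
   pathway trace; predictions are compared against a pooled ridge-penalized
   Cox model using Harrell's C-index (bootstrap CIs), the IPCW Brier score
   at fixed horizons, and a perturbation-stability analysis (refit on a
   random 80% subsample, Pearson correlation of predicted survival
   probabilities).

Real transplant registries are access-controlled, so the package ships a
synthetic-registry generator (`pcube.simulate`) with three planted
recipient subgroups (paediatric / middle-aged healthy / elderly comorbid),
subgroup-specific Weibull hazards, and covariate effects that are global
(donor age, ABO compatibility), paediatric-only (PRA, donor–recipient age
difference), or elderly-only (HLA-DR mismatch, diabetes, cardiovascular
disease). Every pipeline stage is testable against this planted truth.

## Worked example

```bash
pcube demo --out runs/demo --n 1500 --seed 7
```

prints

```
subgroups: 4
validation C-index: P-cube 0.759 vs baseline 0.750
  paediatric recipient, 16 y, sensitized -> subgroup 3
  middle-aged recipient, 45 y, no comorbidity -> subgroup 4
  elderly recipient, 62 y, diabetes + cardiovascular disease -> subgroup 2
```

The consensus step found four subgroups in this draw (the planted
middle-aged stratum split in two). The three hypothetical patients route to
three distinct pathways; their predicted survival at 1/3/5/10 years (from
`runs/demo/pathways.json`) is

| patient | S(1y) | S(3y) | S(5y) | S(10y) |
|---|---|---|---|---|
| paediatric, 16 y, sensitized | 0.961 | 0.829 | 0.665 | 0.449 |
| middle-aged, 45 y, healthy | 0.936 | 0.843 | 0.704 | 0.459 |
| elderly, 62 y, diabetic + CVD | 0.567 | 0.116 | 0.035 | 0.014 |

The elderly comorbid patient's curve drops steeply, driven by the planted
HLA-DR-mismatch and comorbidity effects that only their subgroup model
carries. The demo directory also contains the fitted model bundle
(`model.json`), the evaluation report with bootstrap CIs and Brier scores
(`report.json`; here Brier at 5 years was 0.162 for the pathway model vs
0.170 for the pooled Cox baseline), and the cross-subgroup feature ranking
(`feature_ranking.csv`).

Other subcommands: `pcube simulate`, `pcube fit`, `pcube predict`,
`pcube evaluate`, `pcube stability` (see `--help` for each).

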