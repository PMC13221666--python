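# rhlvggm

Robust heterogeneity-adjusted latent-variable Gaussian graphical models.

## The problem

Gaussian graphical models read conditional dependencies between variables
off the zeros of the precision matrix Θ = Σ⁻¹.  Applied to molecular data
(e.g. gene-expression panels from tumour cohorts) the naive estimate is
distorted by three things at once:

* **latent variables** — unobserved regulators induce indirect
  correlations, so the marginal precision matrix is dense even when the
  direct network is sparse;
* **heterogeneity** — unknown subpopulations (tumour subtypes, cell
  clusters) shift the means, so a pooled covariance mixes within-group
  dependence with between-group separation;
* **outliers** — technical artifacts and rare phenotypes bias every
  moment estimate.

`rhlvggm` addresses all three simultaneously.  The observed profiles are
modelled as a K-component Gaussian mixture with subgroup-specific means
μ_k, a *shared* precision matrix decomposed as Θ = S − L (S sparse: the
direct network; L ⪰ 0 low-rank: the latent-variable footprint, via the
Schur complement), plus an improper uniform noise component of constant
density δ with weight π₀ that absorbs outliers.  Estimation maximises

    (1/n) Σᵢ log( π₀ δ + Σₖ πₖ N(xᵢ; μₖ, (S−L)⁻¹) )
        − Σ_{i≠j} p(|S_ij|; λ₁) − Σⱼ p(σⱼ(L); λ₂),   S − L ≻ 0, L ⪰ 0,

with minimax concave penalties p(·; λ) on the off-diagonal of S and on
the eigenvalues of L, fitted by an EM algorithm whose M-step solves the
matrix subproblem with ADMM (eigenvalue thresholding updates), and tuned
by an AIC line search.  One fit yields the direct network, the subgroup
assignments and the outlier flags at once.  See `docs/methods.md` for the
full account of the model, algorithm and design choices.

For whom: anyone estimating conditional-dependence networks from
heterogeneous, contaminated multivariate data — expression panels,
proteomics, functional connectivity — who would otherwise run a
graphical lasso per hand-curated subgroup.

## Worked example

Simulate a contaminated three-subgroup dataset with a known sparse +
low-rank truth, tune by the AIC line search, and score the fit:

```python
import numpy as np
from rhlvggm import (SimulationConfig, simulate, ObservedData, FitConfig,
                     TuningGrid, line_search, evaluate)

truth = simulate(SimulationConfig(p=20, r=3, n=900, pi0=0.04,
                                  mu_scale=3.0, seed=2))
data = ObservedData(truth.X)
res = line_search(data, TuningGrid(), FitConfig(K=3, variant="proposed"))
fit = res.best_fit
print(f"selected lambda1={res.best_lambda1:.3f}, lambda2={res.best_lambda2:.3f}")
print(f"converged={fit.converged}, outer iterations={fit.n_outer}")
print(f"mixture weights: {np.round(fit.params.pi, 3)}")
rep = evaluate(fit, truth, FitConfig(K=3, variant="proposed"))
for k, v in rep.to_dict().items():
    print(f"{k:>9s}: {v:.3f}")
```

Output:

```
selected lambda1=0.046, lambda2=0.151
converged=True, outer iterations=3
mixture weights: [0.065 0.324 0.306 0.305]
    err_S: 0.153
    err_L: 0.381
err_Theta: 0.148
 rank_hat: 3.000
      tpr: 0.950
      fpr: 0.006
    ari_c: 0.951
    ari_o: 0.570
    ari_p: 0.941
```

Reading it: the noise component claims 6.5% of the sample (4% true
outliers plus low-density Gaussian points — the model is deliberately
conservative there), the three subgroups are recovered almost exactly
(ARI 0.95 on true inliers), the estimated precision matrix is within 15%
relative Frobenius error of the truth, the latent rank r = 3 is found
exactly, and 95% of true direct edges are recovered at a 0.6% false
positive rate.

The same pipeline is available from the shell:

```
rhlvggm simulate --config sim.yaml --out data/ --seed 7
rhlvggm fit --input data/X.csv --config cfg.yaml --out results/ --variant proposed --K 3
rhlvggm replicate --config experiment.yaml --out tables/ --replicates 10
```

`fit` writes `S_hat.csv`, `L_hat.csv`, `Theta_hat.csv`, means,
proportions, per-sample labels with responsibilities, an edge list, the
AIC selection table and a JSON manifest that makes the run reproducible.
Pass `--select-k` to choose K by AIC over the configured candidates.

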