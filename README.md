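# dmmix — Dirichlet multinomial mixtures for microbial community data

`dmmix` models taxa-by-sample count matrices from microbial surveys (16S
amplicon genus/OTU tables, shotgun taxon profiles) with a mixture of
Dirichlet "metacommunities". It is aimed at microbial ecologists who want
model-based alternatives to distance-based clustering and to discriminative
classifiers: the model respects the discreteness, sparsity and unequal
library sizes of count data instead of normalising them away.

## The model

Each sample `i` carries counts `x_i` over `S` taxa with library size
`J_i = Σ_j x_ij`. The generative chain is

1. a component `k ~ Categorical(π)` — the sample's *metacommunity*;
2. a latent community composition `p ~ Dirichlet(α_k)`;
3. observed counts `x_i ~ Multinomial(J_i, p)`.

Writing `α_k = θ_k m_k` with `m_k` on the simplex, `m_k` is the
metacommunity's mean composition and the precision `θ_k = Σ_j α_kj` controls
how tightly communities cluster around it: large `θ` means homogeneous
samples, small `θ` a variable, dispersed metacommunity. Because the
Dirichlet is conjugate to the multinomial, `p` integrates out exactly:

    p(x | α) = [J! / Π_j x_j!] · B(α + x) / B(α),
    B(α) = Π_j Γ(α_j) / Γ(Σ_j α_j),

so every sample has a closed-form marginal evidence and the mixture evidence
is `Σ_k π_k p(x | α_k)`. Fitting maximises the posterior of the
hyperparameters under i.i.d. `Gamma(η, ν)` priors on each `α_kj` (the
"evidence framework"): an EM algorithm alternates Bayes-rule
responsibilities, a closed-form weight update, and per-component BFGS
maximisation over `λ = log α` with analytic digamma gradients. The number of
components `K` is chosen by the Laplace approximation to the log model
evidence,

    log p(X | K) ≈ log posterior(Θ*) + (P/2) log 2π − ½ log det H,

reported as its negative so a smaller value is a better fit; the inverse
Hessian also yields approximate 95% credible intervals on the component
compositions. Samples are clustered (into enterotypes/envirotypes) by their
maximum posterior responsibility, and a generative classifier fits one
mixture per class, with `P(c | x) ∝ P(c) Σ_k π_k^{(c)} p(x | α_k^{(c)})`.

## Worked example

Simulate 150 samples from three well-separated metacommunities (θ = 100
each), select `K` by evidence, and summarise the recovered structure:

```python
import numpy as np
from dmmix import FitConfig, fit_dmm, select_k, difference_to_reference, recovery_report
from dmmix.simulate import k3_benchmark_spec, sample_dataset

X, truth = sample_dataset(k3_benchmark_spec(seed=42))
sel = select_k(X, 1, 4, FitConfig(seed=0))
print(sel.k_values, [round(v, 1) for v in sel.neg_evidences], sel.best_k)
# [1, 2, 3, 4] [9552.8, 9100.6, 8161.3, 8198.8] 3

best = sel.fits[sel.k_values.index(sel.best_k)]
print(np.round(best.model.weights, 3), [round(c.theta, 1) for c in best.model.components])
# [0.307 0.333 0.36 ] [100.6, 98.9, 106.4]

print(recovery_report(truth, best)["assignment_accuracy"])
# 1.0

ref = fit_dmm(X, 1, FitConfig(seed=0)).model.components[0]
tab = difference_to_reference(best.model.components, ref, X.taxon_names)
print([round(d, 1) for d in tab.attrs["component_totals_pct"]])
# [97.2, 93.7, 92.2]
```

The negative log evidence dips at `K = 3` (8161.3 against 9100.6 for two and
8198.8 for four components — the extra component is penalised), the fitted
weights and precisions match the generating values, every sample is assigned
to its true metacommunity, and each component's mean composition differs
from the pooled single-component reference by ~90–100% on the 0–200% summed
absolute-difference scale, with the per-taxon breakdown ranked in `tab`.

The same steps are available from the shell:

```sh
dmmix simulate --spec spec.json --out-prefix sim
dmmix select-k --counts sim.counts.tsv --kmin 1 --kmax 4 --out sweep.tsv
dmmix cluster --counts sim.counts.tsv --model best.json --out-prefix clusters
dmmix classify loo --counts sim.counts.tsv --labels labels.tsv --out-prefix loo
```

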