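# iggaucs

Survival-associated **pathway** selection from gene-expression data by
group-L<sub>p</sub> penalized maximization of the global AUC summary
(GAUCS), with a group-lasso Cox comparator, univariate permutation
screening, cross-validated tuning, and a block-correlated Weibull
survival simulator.

## The problem and the model

Complex diseases perturb biological pathways, not single genes, and genes
on a pathway are correlated. Given right-censored survival data
{(t_i, δ_i, x_i)} and a partition of the m expression features into r
pathways, the goal is to find a sparse-at-the-pathway-level linear risk
score M(x) = wᵀx that ranks patients' survival well.

Ranking quality is the global AUC summary

> GAUCS = P(M_j > M_k | t_j < t_k),

the probability that of two subjects with known survival ordering, the
earlier death has the higher score (1 = perfect ranking, 0.5 = random).
Under right censoring the ordering is known exactly for *comparable
pairs* — (j, k) with δ_j = 1 and t_j < t_k — and GAUCS is estimated by
concordant-pair counting over the N such pairs. Smoothing the pair
indicator with a sigmoid and lower-bounding by the pairwise
log-likelihood gives the fitted objective

> E_p(w) = (1/N) Σ_pairs log σ(wᵀ(x_j − x_k)) − λ Σ_l d_l ‖w_l‖₂^p ,

a group-L<sub>p</sub> (0 < p ≤ 1) penalized concordance surrogate:
whole pathways are driven to zero, and p < 1 (typically 0.1) selects
groups far less biasedly than the group lasso. E_p is maximized by an
EM-style algorithm that alternates conjugate-gradient ascent on a
quadratic variational bound of the penalty with the closed-form bound
update θ_l ← w_l; each cycle provably cannot decrease E_p. Tuning of
(p, λ) is by 10-fold cross-validated test GAUCS on training data only.
See `docs/methods.md` for the algorithmic details and numerical
safeguards.

## Worked example

Simulate a pathway-structured study (100 samples, 300 features in 100
triple-groups, within-group correlation 0.5, only the first three groups
associated with survival, ~30% censoring) and fit the penalized GAUCS
model at p = 0.1, λ = 0.3:

```bash
iggaucs simulate --gamma 0.5 --n 100 --seed 7 --out-prefix demo
iggaucs fit --expr demo.expr.tsv --surv demo.surv.tsv \
            --groups demo.groups.gmt --p 0.1 --lam 0.3 \
            --seed 1 --out-prefix demofit
# -> selected 2 groups; outputs at demofit.*
head -4 demofit.groups.tsv
# group   score                 rank
# g1      1.7995274316370387    1
# g2      1.132654566050517     2
# g10     0.0                   3
```

The run log (`demofit.run.json`) records convergence (`converged: true`
after 407 iterations), the selected pathways (`g1`, `g2` — two of the
three truly associated groups; the third is weak and needs a smaller λ),
and the training concordance `train_gaucs: 0.9028`, i.e. ~90% of
comparable patient pairs are ranked correctly. The per-pathway `score`
column is the mean absolute coefficient Σ_j |w_j| / L used to rank
pathways. `iggaucs cv` tunes (p, λ) and reports relevance counts (how
many of the k × repeats cross-validation fits kept each pathway);
`iggaucs screen` runs the univariate R(t, x) = |2·GAUCS − 1| permutation
screen; `iggaucs replicate` runs the full simulation replication study.

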