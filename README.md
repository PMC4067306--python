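# arhohmm — autoregressive higher-order HMMs for tumor expression profiles

`arhohmm` identifies differentially expressed genes from chromosome-ordered
tumor expression profiles (per-gene log2 tumor/reference ratios, ordered from
the p-arm to the q-arm). Because deletions and duplications span many
adjacent genes, neighboring log-ratios are strongly correlated; the package
exploits that structure with a three-state hidden Markov model — `=`
(unchanged), `-` (underexpressed), `+` (overexpressed) — that carries two
kinds of memory:

* **higher-order state transitions** (order *L*): the distribution of the
  next hidden state depends on the previous *L* states, with lower-order
  "ramp-up" matrices `A^(1) .. A^(L-1)` covering sequence starts;
* **autoregressive Gaussian emissions** (order *P*): in state *s* the mean
  of observation *o<sub>t</sub>* is

  ```
  mean_s(t) = mu_s + sum_{j=1..P} h(t, j) * c_{s,j} * o_{t-j}
  ```

  where `h(t, j)` truncates terms reaching before the first gene.

The family `AR(P)-HMM(L)` nests the standard toolkit as special cases purely
through the orders: `AR(0)-HMM(0)` is a Gaussian mixture, `AR(0)-HMM(1)` a
first-order HMM, `AR(P)-HMM(0)` an autoregressive mixture, `AR(0)-HMM(L)` a
higher-order HMM — all on one code path.

Training is **Bayesian Baum-Welch** (MAP-EM): Dirichlet priors on the initial
distribution and every transition row, a Gaussian-Inverted-Gamma prior per
state on the basic mean and variance (flat priors on the AR coefficients);
each M-step solves a posterior-weighted system of normal equations for
`(mu_s, c_s)`. Genes are then ranked by their state posteriors
`gamma_t(s) = P(q_t = s | O, theta)` from an exact scaled forward-backward
over state contexts, and rankings are evaluated against copy-number-defined
candidate genes via ROC / TPR at a fixed small FPR. A simulator generates
segmental, autocorrelated profiles with optional coupled copy-number tracks,
so the whole pipeline is testable without external data.

Audience: bioinformaticians analysing per-sample chromosome-ordered
expression (or similar linearly ordered log-ratio) profiles, and method
developers who need a reference implementation of higher-order /
autoregressive HMM inference and MAP-EM training.

## Worked example

Simulate 20 copy-number-coupled profiles, train an AR(2)-HMM(2), decode, and
evaluate the `+`-posterior ranking against 3-fold copy-number candidates:

```sh
arhohmm simulate --seed 7 --n-sequences 20 --length 200 \
    --out-profiles profiles.tsv --out-cn cn.tsv
arhohmm train --profiles profiles.tsv --L 2 --P 2 --out model.yaml
arhohmm decode --profiles profiles.tsv --model model.yaml \
    --out posteriors.tsv --bed segments.bed
arhohmm autocorr --profiles profiles.tsv --max-lag 10 --permutations 100 \
    --seed 7 --out acf.tsv
arhohmm evaluate --posteriors posteriors.tsv --copy-numbers cn.tsv \
    --cutoff 3 --fpr 0.05 --out roc.tsv
```

which prints:

```
simulated 20 profiles of length 200 -> profiles.tsv
trained in 40 iterations; final log-posterior -6053.8864
decoded 20 profiles -> posteriors.tsv
lag-1 mean autocorrelation 0.2166 (permutation baseline -0.0033 +/- 0.0158)
AUC 0.9944; TPR at FPR<=0.05: 0.9769
```

Reading the output: simulated profiles carry real chromosomal
autocorrelation (lag-1 mean 0.22, versus a permutation baseline
indistinguishable from zero — permuting gene order destroys the signal);
after training, ranking genes by their `+` posterior recovers 97.7% of the
genes in amplified (3.5-fold) segments at a false positive rate of 5%. The
posterior table has one row per gene with `P(=) P(-) P(+)` and the decoded
state; the BED file contains the contiguous same-state runs. The same
functionality is available as a library (`arhohmm.fit`,
`arhohmm.forward_backward`, `arhohmm.rank_genes`, ...).

For pathway-level analysis, per-gene `+`/`-` posteriors are summed within
tumor groups (`arhohmm pathways`), the top-k genes per group are intersected
with GMT gene sets, and overlaps are compared with the chance expectation
`k * m / G`. A curated table of overexpressed genes in the discriminative
glioma pathways ships with the package for membership summaries
(`arhohmm.pathways.load_glioma_calls`).

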