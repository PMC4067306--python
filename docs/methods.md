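# Methods

## Model

A profile is the sequence `O = o_1 .. o_T` of log2 tumor/reference expression
ratios of the genes on one chromosome of one sample, ordered from p-arm to
q-arm by base-pair position (positions are used only for ordering; ties break
lexicographically by gene id). Hidden states `S = {'=', '-', '+'}` represent
unchanged, underexpressed and overexpressed genes; the architecture is fully
connected and the code is N-agnostic (N >= 2), with index 0 the unchanged
state by convention.

**State transitions (order L).** The hidden chain is a homogeneous Markov
chain of order L: an initial distribution `pi` for `q_1`, ramp-up matrices
`A^(d)` (d = 1 .. L-1) for the transitions into positions 2 .. L where only a
partial context exists, and the full-order matrix `A^(L)` thereafter. A
length-d context `(q_{t-d}, .., q_{t-1})` is encoded base-N with the most
recent state in the lowest digit; `A^(d)` has `N^d` rows. With L = 0 there
are no transition matrices and `pi` is reused at every position (mixture
model).

**Emissions (order P).** In state s, `o_t` is Gaussian with standard
deviation `sigma_s` and mean

    mean_s(t) = mu_s + sum_{j=1..P} h(t, j) * c_{s,j} * o_{t-j},

with `h(t, j) = 0` when `t - j < 1` and 1 otherwise. The conditioning is on
*observed* values, so the emission term never needs the hidden history;
truncation at the sequence start is the only boundary effect. Positions are
1-based in formulas and 0-based in storage; the boundary is the module
interface of `arhohmm.model`.

**Inference.** State posteriors `gamma_t(s)` and the log-likelihood come
from a scaled forward-backward over contexts: the forward vector lives on
`N^min(t, L)` contexts, growing during ramp-up and shifting one digit
afterwards; per-position normalisation constants are accumulated so
`loglik = sum_t log(scale_t)`. Posterior decoding assigns each gene its
argmax state (exact ties resolve toward `=`, then the lower state index).
The recursion is vectorised over batches of equal-length sequences.
Equivalently, the order-L chain can be expanded to a first-order chain over
`N^L` tuples (`expand_to_first_order`); the package uses the direct context
recursion and keeps the expansion as a consistency oracle. Viterbi is
deliberately absent: analyses use posterior decoding and posterior-based
rankings only.

## Priors and MAP-EM

The prior factorises over parameter groups:

* `pi` and every row of every `A^(d)`: Dirichlet with pseudocounts
  `eta >= 1`. MAP row update: `p_j ∝ xi_j + eta_j - 1` (rows with zero
  denominator fall back to the uniform row). Each ramp-up matrix is trained
  from its own (sparse — one transition per sequence) counts with its own
  prior rather than tied to `A^(L)`; the prior stabilises those rows.
* per state: `N(mu_s | m_s, sigma_s^2 / kappa_s) * InvGamma(sigma_s^2 | a_s,
  b_s)`; flat priors on the AR coefficients. The M-step solves the
  (P+1)-dimensional gamma-weighted normal equations with `kappa_s` added to
  the Gram diagonal entry of `mu_s` and `kappa_s * m_s` to its right-hand
  side; singular systems take the least-norm solution (logged). The variance
  update is

      sigma_s^2 = (resid + 2 b_s + kappa_s (mu_s - m_s)^2)
                  / (W_s + 2 (a_s + 1) + [kappa_s > 0]),

  where `W_s` is the state's posterior mass and the indicator term is the
  log-sigma contribution of the Gaussian mean prior. The flat limit
  (`kappa = 0, a = -1, b = 0`, `PriorSpec.flat`) reduces every update to
  maximum likelihood, so flat-prior training at P = L = 0 is exactly
  Gaussian-mixture EM (tested against an independent implementation), and
  the flat prior contributes 0 to the log-posterior so MAP and ML traces are
  comparable.

`default_prior` centres the prior on the initial model with moderate
strengths (`kappa_pi = kappa_A = 10` effective counts, `kappa_s = 1`,
`a_s = 2`) and sets `b_s = sigma_init^2 * (a_s + 1.5)`, which makes the
joint prior mode of `sigma^2` equal to `sigma_init^2`. Consequently the MAP
update with empty expected counts returns the initialization exactly — a
tested fixed point.

**Stopping.** Training stops when the log-posterior increase is below
`stop_epsilon` (default 1e-4; the two-successive-iterations rule is fixed,
only the threshold is a default) for `patience = 2` consecutive iterations,
or after `max_iterations = 500`. A decrease beyond 1e-8 raises immediately,
since exact EM guarantees ascent — any decrease signals an implementation
bug, not a modelling problem.

## Initialization

`init_model` uses `pi_init = (0.9, 0.05, 0.05)` (differential expression is
rare), `mu_init = (0, -2, +2)` on the log2 scale (typical trained means of
differential states), `sigma_init = (0.5, 1, 1)`, and `c = 0` (the initial
model is emission-equivalent to a non-autoregressive HMM). The first-order
matrix has off-diagonals `rho * pi_j` and diagonals `1 - rho * (1 - pi_i)`,
which leaves `pi` stationary (`pi M = pi`); `rho = 0.1` sets expected
segment lengths of roughly 10-100 genes. Every higher-order context row
copies the row of its most recent state.

## Numerical choices

* Per-position rescaling of the forward/backward vectors plus a per-position
  max-shift of the emission densities; stable for T up to at least 10^4.
* `sigma_floor = 1e-3` (log2-ratio scale) bounds all standard deviations
  away from collapse on constant segments; configurable.
* Degenerate inputs: T = 1 sequences contribute no transition counts;
  sequences with T <= L simply never reach `A^(L)`; states with zero
  posterior mass and no prior are skipped with a warning, keeping their
  previous parameters.
* Model YAML serialization round-trips floats at full precision
  (shortest-repr; files are re-read with round-trip float parsing).
* Ranking tie-breaks: descending posterior, then (sample, chromosome,
  position); top-k boundary ties in pathway scoring break lexicographically
  by gene id. Both are determinism choices.

## Evaluation conventions

* **Autocorrelation.** Per profile, lag-k autocorrelation with the lagged
  product averaged over the `T - k` available pairs and normalised by the
  full-profile variance (`statsmodels.tsa.stattools.acf(adjusted=True)`);
  this makes a strictly alternating series score exactly -1 at lag 1.
  Profiles are averaged unweighted; a profile enters lag k only if `T > k`
  and its variance is nonzero. The permutation baseline permutes gene order
  within every profile independently per repeat (default 100 repeats) and
  reports per-lag mean and sd. Lag pairs are non-cyclic.
* **ROC.** Candidates of overexpression are genes whose matched copy-number
  fold change meets the cutoff (2/3/4-fold). ROC uses a descending score
  sweep with ties collapsed to one operating point
  (`sklearn.metrics.roc_curve`); `tpr_at_fpr(f)` is the step-function value
  at the largest achievable FPR <= f, with no interpolation — conservative
  and deterministic. AUC equals the Mann-Whitney rank statistic (tested).
* **Pathway overlap.** Random expectation of the top-k overlap with an
  m-gene pathway in a G-gene universe is the hypergeometric mean `k * m / G`
  (a simulation cross-check is in the tests); the universe defaults to the
  scored genes and is overridable.

## Synthetic data

`simulate_profiles` draws hidden states through the ramp-up/full-order
transition process and observations from the autoregressive Gaussian around
the realised history; hidden states are returned for recovery scoring. A
single integer seed drives `numpy.random.default_rng`; identical seeds give
byte-identical output.

`simulate_cn_coupled` emulates the coupling between copy number and
expression used to anchor ROC evaluation: each state carries a fold level
(defaults `= -> 1.0`, `- -> 0.5`, `+ -> 3.5`, emitted as a linear-scale
copy-number track), and expression is `mu_state + beta * log2(fold) +
N(0, noise_sd)` with defaults `mu = (0, -1, +1)`, `beta = 0.5`,
`noise_sd = 1.0` and ~10-gene expected segments. Total shifts of about
+1.9 / -1.5 against noise sd 1.0 give a moderately overlapping ranking
problem — hard enough that neighborhood information matters, which is the
regime the model class targets. Truth labels are the genes in `+` segments,
so a 3-fold cutoff on the emitted track recovers them exactly.

**Simulation-study designs.** The parameter-recovery study uses 200
sequences of length 500 from an AR(1)-HMM(1) with `pi = (0.8, 0.1, 0.1)` and
AR coefficients 0.3: giving each differential state ~10% occupancy means
every state-specific parameter is informed by roughly 10^4 observations, so
the recovery tolerances (transitions ±0.03, means ±0.05, coefficients ±0.05)
sit near two standard errors of the estimator — a deliberately
well-conditioned design, as is standard for recovery studies. The end-to-end
ranking benchmark uses 50 coupled profiles of length 300.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: microarray artefacts (dye bias, saturation,
probe effects), heavy-tailed or skewed log-ratio noise, realistic human
copy-number landscapes (recurrent breakpoints, focal amplicons, whole-arm
events), gene-density variation along chromosomes, trans-acting expression
changes uncoupled from copy number, and inter-sample correlation. Results on
real profiles depend on those factors; the tests establish correctness of
the algorithms and the qualitative behaviour of the model class, not field
performance.

## Known limitations

* Gaussian emissions only; no distance-dependent transitions (gene spacing
  is ignored beyond ordering), no left-to-right architectures.
* No missing-data mechanism: genes with missing log-ratios are dropped from
  that sample's profile on read.
* Model-order selection is out of scope; the log-posterior trace is
  reported, but no AIC/BIC machinery is provided. Orders around P, L = 2
  are a practical default; parameter count grows as `N^L` rows.
* MAP-EM finds local optima; results depend on the (documented)
  initialization. No restarts are built in.
* Pathway scoring reports overlaps against the chance expectation; it does
  not compute enrichment p-values or multiple-testing corrections.
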