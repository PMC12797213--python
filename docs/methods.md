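# Methods

This note documents the models, the numerical choices, and what the
simulation-based validation does and does not establish.

## Pipeline and freezing

The three stages run strictly sequentially. Stage 1 (VAE) learns the latent
space; its encoder/decoder are then frozen — the deconvolution stage hashes
the decoder parameters before and after fitting and asserts equality. Stage
2 learns the fraction network and per-gene NB parameters against the frozen
decoder outputs evaluated at the posterior means; stage 3 learns only the
β-network against the frozen fractions. The pipeline runner stores a SHA-256
per checkpoint and refuses to reuse a modified one.

Cells are split 85/10/5 (train/validation/test) for the VAE: the validation
ELBO drives early stopping, the test cells give a held-out reconstruction
log-likelihood. The cell split plays no role in stages 2–3, whose
likelihoods sum over bulk samples and involve every reference cell through
the mixture mean; the deconvolution stage instead stops when its objective
plateaus (relative improvement < `tol` over `patience` checks), and the
hazard stage uses its own 60/20/20 split of the bulk samples with early
stopping on the validation partial likelihood. Latent inputs to stages 2–3
are the posterior means (deterministic, reproducible); a flag switches to a
posterior sample.

## Stage 1: count VAE

- Poisson observation model on raw counts with rate l_c·f(z_c, p_c), where
  l_c is the per-cell mean count over genes. The decoder output is therefore
  a library-normalised expression profile; it is not constrained to a
  simplex — l_c carries all scale.
- Encoder input is log1p(counts) concatenated with the batch one-hot; the
  decoder input is [z, one-hot]. Both are 2×128 tanh MLPs; the posterior SD
  uses a softplus head (+1e-6), the decoder a softplus head with a 1e-8 rate
  floor guarding log(0).
- Latent dimension M = 10 by default; Adam lr 1e-3, minibatch 128, patience
  20 epochs, at most 400 epochs. All configurable.
- Validation/early-stopping ELBO is evaluated at the posterior mean (ε = 0)
  so the stopping signal carries no sampling noise.
- The closed-form Gaussian KL is verified against numerical integration, and
  the ELBO against a quadrature marginal on a 1-D conjugate toy.

## Stage 2: negative-binomial deconvolution

- NB parameterisation: mean μ and inverse-dispersion α with
  Var = μ + μ²/α. `nb_loglik` is tested against `scipy.stats.nbinom` and the
  Poisson limit (α → ∞).
- The fraction network is an MLP from z to one logit per sample, softmaxed
  across cells; this is the only construction that satisfies Σ_c m_cb = 1 by
  design, after every optimiser step rather than at convergence only.
- r, o, α are softplus-parameterised. Initialisation is scale-aware: r is
  set so that uniform fractions reproduce the observed bulk gene means,
  which puts the optimiser in the right regime regardless of sequencing
  depth; o starts at 0.1 and α at 2.
- Full-batch Adam (default lr 5e-3, ≤3000 iterations). Non-integer bulk
  matrices are rounded with a warning; gene vocabularies are intersected
  case-sensitively and the dropped count logged.
- Spatial spots use the same class with spots in place of samples and
  optional coordinates attached.

## Stage 3: per-cell Cox model

- Breslow and Efron partial log-likelihoods are implemented with
  log-sum-exp stabilisation over precomputed risk-set/tie-group indicator
  matrices; gradients flow through autograd. Both match `survival::coxph`
  (evaluated at a fixed linear predictor) to ~1e-13, and each other when no
  ties exist. Default tie handling: Efron when tied event times are present,
  Breslow otherwise.
- The β-network is a 2×64 MLP with a linear (signed) output. Since the
  fractions sum to one per sample, adding a constant to β shifts every η_b
  equally and leaves the partial likelihood unchanged — β is identified up
  to location (and the usual Cox scale caveats), so analyses use contrasts,
  orderings and correlations, never absolute values.
- c-index: Harrell's convention. Comparable pairs are (i, j) with
  T_i < T_j and i an event, plus time-tied event/censored pairs with the
  event first; η ties score 0.5; event pairs tied in time are excluded.
  Matches `lifelines.utils.concordance_index` exactly.
- IBS: Graf's IPCW construction with a Breslow baseline cumulative hazard
  from the training split, Kaplan–Meier censoring weights (events precede
  censorings at tied times, weights evaluated right-continuously), and a
  trapezoid integral over 100 evenly spaced points from the first event time
  to the 80th percentile of observed time. Matches
  `sksurv.metrics.integrated_brier_score` to machine precision; a zero
  censoring-survival estimate inside the grid raises with an explanation.
- Split-resampled confidence intervals refit the hazard stage under
  independent 60/20/20 splits and report percentile bounds of the test
  c-index.

## Synthetic data generator

The generator mirrors the observation models so recovery is well-posed:

- Per-gene base log-mean ~ N(log 0.5, 1) (a shallowly sequenced panel,
  ~0.5 counts/gene/cell); cluster offsets ~ N(0, 1) give well-separated
  populations; batch offsets ~ N(0, 0.3) are mild technical shifts (first
  batch is the reference level). Counts are NB with inverse-dispersion 10.
- Pseudo-bulk: per-sample cluster proportions ~ Dirichlet(1) (uniform on the
  simplex); 1000 cells are drawn per sample with replacement, multinomially
  split across clusters, and their raw counts summed. The true proportions
  are recorded for scoring.
- Survival: constant baseline hazard, so T = −log U / (rate·exp(η)) with
  η = proportions·coefficients. Censoring is an independent exponential
  whose rate is calibrated by bisection so the expected censored fraction
  matches the request (default 20%, a typical cohort attrition).
- Repeated-coefficient experiments draw i.i.d. N(0, 2²) cluster coefficient
  vectors: with Dirichlet(1) proportions this yields η contrasts large
  enough that prognosis is learnable but far from deterministic (test
  c-indices ~0.6–0.75).
- Label-mismatch scenarios: `merge_cluster_labels` coarsens the truth;
  `split_cluster_labels` halves each cluster at the median of a random
  expression projection.

The study scale used by the test suite and the acceptance script — 1000
cells (500 after the reference/pseudo-bulk split), 200 genes, 5 clusters,
300 bulk samples, 10 coefficient settings, 20 resampled splits — keeps the
whole validation under a few minutes on one CPU while leaving all recovery
margins wide (proportion correlation ≈ 0.99 against a 0.8 requirement;
coefficient recovery ≈ 0.95 against 0.7).

What the simulations do not show: robustness to reference/cohort mismatch
(cell states absent from the reference receive no mass by construction),
real platform effects beyond a per-gene affine map, informative censoring,
or ambient-RNA/doublet artefacts. Conclusions about real cohorts need the
usual external checks.

## Permutation importance

Contributions are shuffled among the cells of one cluster at a time, η and
the c-index recomputed (full cohort by default; an index argument restricts
the evaluation split), and the mean decrement over `n_perm` shuffles
reported with two dispersion columns: `se` (standard error of the mean
decrement) and `perm_sd` (SD of the permutation null). For a cluster whose
contributions carry no signal, the unpermuted baseline is itself a draw from
the permutation null, so the decrement scatters with dispersion `perm_sd` —
that, not `se`, is the scale against which a null decrement should be
judged. Single-cell clusters get decrement 0 with a warning.

## Other conventions

- Spatial hazard display values are winsorised at the 2.5%/97.5% quantiles
  (linear interpolation). Raw scores are always retained; re-clipping with
  the recorded bounds is idempotent, whereas re-estimating quantiles on
  clipped data would move the cut-offs inward.
- Gene–contribution correlations use the reconstructed (denoised) expression
  f(z_c, p_c) by default; zero-variance genes get r = 0 with a flag. A
  caller-supplied mask restricts to a cell subset (e.g. one cell type).
- Cross-dataset similarity is the Pearson correlation of per-gene r vectors
  over the shared vocabulary (≥10 genes required).
- All on-disk tables use explicit string identifiers (cell_id, sample_id,
  spot_id, gene); orientation of dense matrices is auto-detected from header
  overlap with the reference vocabulary and logged.
- Determinism: every stochastic component takes a seed; two runs with equal
  configs produce identical metric manifests in single-threaded mode.
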