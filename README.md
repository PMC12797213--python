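# cellhazard

Single-cell resolution deconvolution of bulk transcriptomes with per-cell
Cox proportional-hazards contributions.

Bulk RNA-seq cohorts with survival follow-up are abundant; single-cell
cohorts with outcomes are not. `cellhazard` bridges the two: given a
single-cell RNA-seq reference and a bulk cohort with right-censored survival
times, it estimates the proportion of **every individual reference cell** in
every bulk sample, and a per-cell regression coefficient quantifying that
cell's contribution to the hazard of death. Because both quantities are
smooth functions of a learned latent cell state, cells in similar states get
similar proportions and contributions — no cluster annotation is needed, so
the results do not depend on how (or whether) the reference was clustered.
The same machinery maps hazard scores onto spatial transcriptomics spots.

It is aimed at computational biologists analysing tumor or immune
heterogeneity against clinical endpoints (e.g. TCGA-style cohorts with a
public single-cell atlas as reference).

## Model

Three stages, fitted sequentially; each stage's parameters are frozen before
the next begins.

**1. Latent cell states (conditional VAE).** For cell *c* with raw counts
x_c ∈ ℕ^G, batch one-hot p_c and library mean l_c (mean count over genes):

    z_c ~ N(0, I_M),        x_cg ~ Poisson( l_c · f_θ(z_c, p_c)_g )

with decoder MLP f_θ and Gaussian posterior q(z_c | x_c, p_c) =
N(μ_Φ, diag σ_Φ²). Training maximises the ELBO with the reparameterisation
trick; batch conditioning absorbs patient effects.

**2. Deconvolution (negative binomial).** Bulk sample *b* with expression
e_b is modelled as

    e_bg ~ NB(μ_bg, α_g),   μ_bg = r_g · Σ_c f_θ(z_c, p_c)_g · m(z_c)_b + o_g

where the fraction network m maps latent states to per-sample logits,
softmaxed **across cells** so Σ_c m(z_c)_b = 1: each bulk sample is a
probability distribution over reference cells. r_g > 0 (capture rate) and
o_g > 0 (shift) reconcile platform scale; α_g is a per-gene
inverse-dispersion (variance μ + μ²/α). Spatial spots use the identical
model with spots in place of samples.

**3. Per-cell hazard (extended Cox).** Each sample's hazard is
h_b(t) = h₀(t)·exp(η_b) with

    η_b = Σ_c β(z_c) · m(z_c)_b

where β is an MLP over the frozen latent states. β is fitted by maximising
the Cox partial log-likelihood (Breslow, or Efron under tied event times)
with early stopping on a validation split; generalisation is reported as
Harrell's c-index and an IPCW integrated Brier score on held-out samples.
Positive β(z_c) marks cells whose abundance is associated with worse
outcome.

Downstream analyses: within-cluster permutation importance (c-index
decrement), per-gene correlation between reconstructed expression and
contributions, spatial hazard maps with quantile-clipped display values, and
cross-dataset similarity of gene-correlation profiles.

## Worked example

Everything below is simulated, so ground truth is known:

```python
import numpy as np
from cellhazard import synthetic
from cellhazard.vae import CountVAE
from cellhazard.deconv import BulkDeconvolver, aggregate_fractions
from cellhazard.hazard import CellHazardCox

full, _ = synthetic.generate_reference(
    n_cells=600, n_genes=150, n_clusters=4, n_batches=2, seed=0)
reference, bulk_source = synthetic.split_reference(full, 0.5, seed=1)
bulk, proportions = synthetic.generate_pseudobulk(bulk_source, n_bulk=200, seed=2)
coefficients = np.array([2.0, -2.0, 0.0, 0.0])
survival = synthetic.simulate_survival(
    proportions, coefficients, censor_fraction=0.2, seed=3)

vae = CountVAE(random_state=0).fit(reference)
deconv = BulkDeconvolver(random_state=0).fit(bulk, vae)
cox = CellHazardCox(random_state=0).fit(
    vae.latent_mean_, deconv.fractions_, survival)

estimated, _ = aggregate_fractions(deconv.fractions_, reference.cluster_labels)
r = np.corrcoef(estimated.ravel(), proportions.ravel())[0, 1]
cluster_beta = np.array(
    [cox.beta_[reference.cluster_labels == k].mean() for k in range(4)])
print(f"proportion recovery r = {r:.3f}")
print(f"cluster-mean contributions = {np.round(cluster_beta, 2)}")
print(f"test c-index = {cox.cindex_test_:.3f}, test IBS = {cox.ibs_test_:.3f}")
```

Output:

```
proportion recovery r = 0.996
cluster-mean contributions = [ 1.05 -1.   -0.37  0.14]
test c-index = 0.655, test IBS = 0.186
```

The per-cell fractions, aggregated back to the true clusters, track the
simulated mixing proportions almost perfectly (r = 0.996). The cluster-mean
contributions recover the sign and ordering of the true coefficients
(+2, −2, 0, 0) — the Cox partial likelihood only identifies η up to scale
and location, so the ordering and contrasts are the meaningful quantities.
A test c-index of 0.66 says held-out samples are ranked well above chance
(0.5); the IBS of 0.19 beats the 0.25 of an uninformative constant
prediction.

The same workflow is available from the shell:

```bash
cellhazard simulate --outdir data --n-cells 600 --n-bulk 200
cellhazard run-all --outdir results --set synthetic.n_bulk=200
```

`run-all` executes data → VAE → deconvolution → hazard → downstream, writes
per-stage checkpoints, CSV tables (latent states, contributions, gene
correlations, permutation importance) and a JSON metrics manifest, and skips
already-completed stages on rerun (tampered checkpoints are detected by
hash).

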