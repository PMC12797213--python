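"""Stage 2: negative-binomial deconvolution of bulk samples (or spatial spots)
into per-cell fractions over the frozen single-cell reference.

Observation model for bulk sample b and gene g:

    e_bg ~ NB(mu_bg, alpha_g),   mu_bg = r_g * sum_c f(z_c, p_c)_g m(z_c)_b + o_g

where f is the frozen stage-1 decoder evaluated at the posterior means, m is a
fraction network (MLP over latent states -> per-sample logits, softmax across
cells so fractions sum to 1 over cells for every sample), r_g a positive
per-gene capture rate shared across samples, o_g a positive per-gene shift and
alpha_g a positive per-gene inverse-dispersion (variance mu + mu^2/alpha).
All of r, o, alpha are parameterised through softplus of unconstrained reals.
"""

from __future__ import annotations

import warnings

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import grad
from autograd.scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._nn import Adam, init_mlp, mlp_forward, params_hash, softplus


def nb_loglik(observed, mean, dispersion):
    """Negative-binomial log-pmf, mean/inverse-dispersion parameterisation
    (variance = mean + mean^2/dispersion), summed over all entries."""
    k = observed
    mu = mean
    a = dispersion
    if isinstance(k, np.ndarray) and isinstance(mu, np.ndarray):
        if np.any(~np.isfinite(k)) or np.any(~np.isfinite(mu)):
            raise ValueError("nb_loglik requires finite inputs")
    return anp.sum(
        gammaln(k + a)
        - gammaln(a)
        - gammaln(k + 1.0)
        + a * anp.log(a / (a + mu))
        + k * anp.log(mu / (a + mu))
    )


def cell_fractions(latent_states, fraction_params):
    """Fraction matrix m (cells x samples): MLP logits softmaxed across cells,
    so every sample's column sums to 1."""
    logits = mlp_forward(fraction_params, latent_states)
    mx = anp.max(logits, axis=0, keepdims=True)
    ex = anp.exp(logits - mx)
    return ex / anp.sum(ex, axis=0, keepdims=True)


def bulk_mean(fractions, decoder_outputs, r, o):
    """mu_bg = r_g * sum_c f_cg m_cb + o_g; returns (samples x genes)."""
    F = decoder_outputs
    if fractions.shape[0] != F.shape[0]:
        raise ValueError("fractions and decoder outputs must align on cells")
    mix = anp.dot(fractions.T, F)  # (B, G)
    return r[None, :] * mix + o[None, :]


def aggregate_fractions(fractions, cluster_labels):
    """Cluster-level proportions (samples x clusters): entry (b, k) sums the
    per-cell fractions of cluster k in sample b. Rows sum to 1."""
    fractions = np.asarray(fractions)
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != fractions.shape[0]:
        raise ValueError("cluster labels must cover all cells")
    clusters = np.unique(labels)
    out = np.stack(
        [fractions[labels == k].sum(axis=0) for k in clusters], axis=1
    )
    return out, clusters


def _inv_softplus(y):
    y = np.maximum(y, 1e-10)
    return y + np.log1p(-np.exp(-y))


class BulkDeconvolver(BaseEstimator):
    """Fits the NB mixture model by full-batch gradient ascent with Adam.

    fit(E, vae) consumes the bulk count matrix (samples x genes, genes aligned
    with the reference) and a fitted CountVAE whose decoder and posterior means
    are frozen. Early stopping monitors the objective plateau: optimisation
    halts when the relative improvement over ``patience`` consecutive checks
    (every ``check_every`` steps) falls below ``tol``.

    Fitted attributes: fractions_ (cells x samples), capture_rate_, shift_,
    dispersion_ (per gene), mean_ (samples x genes), history_.
    """

    def __init__(
        self,
        hidden=(128,),
        lr: float = 5e-3,
        max_iter: int = 3000,
        check_every: int = 25,
        patience: int = 8,
        tol: float = 1e-5,
        use_posterior_sample: bool = False,
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.lr = lr
        self.max_iter = max_iter
        self.check_every = check_every
        self.patience = patience
        self.tol = tol
        self.use_posterior_sample = use_posterior_sample
        self.random_state = random_state

    def fit(self, E, vae):
        E = np.asarray(E, dtype=float)
        if E.ndim != 2:
            raise ValueError("bulk expression must be (samples x genes)")
        if E.shape[1] != vae.n_genes_:
            raise ValueError(
                "empty or mismatched gene intersection between bulk and reference"
            )
        if np.any(E != np.round(E)):
            warnings.warn(
                "non-integer bulk expression supplied; rounding for the NB likelihood"
            )
            E = np.round(E)

        Z = vae.latent_sample_ if self.use_posterior_sample else vae.latent_mean_
        F = vae.decoder_matrix()  # (C, G), frozen
        self._decoder_hash_before_ = params_hash(vae.decoder_params_)
        C, G = F.shape
        B = E.shape[0]
        self.latent_ = np.asarray(Z)

        rng = np.random.default_rng(self.random_state)
        net = init_mlp([Z.shape[1], *self.hidden, B], rng)
        # scale-aware init: uniform fractions reproduce the bulk gene means
        f_mean = F.mean(axis=0)
        r0 = np.maximum(E.mean(axis=0), 1e-3) / np.maximum(f_mean, 1e-8)
        rho_r = _inv_softplus(r0)
        rho_o = _inv_softplus(np.full(G, 0.1))
        rho_a = _inv_softplus(np.full(G, 2.0))
        params = [net, rho_r, rho_o, rho_a]

        def unpack(params):
            net, rho_r, rho_o, rho_a = params
            m = cell_fractions(Z, net)
            r = softplus(rho_r) + 1e-6
            o = softplus(rho_o) + 1e-6
            a = softplus(rho_a) + 1e-6
            return m, r, o, a

        def neg_ll(params):
            m, r, o, a = unpack(params)
            mu = bulk_mean(m, F, r, o)
            return -nb_loglik(E, mu, a[None, :]) / (B * G)

        loss_grad = grad(neg_ll)
        opt = Adam(params, lr=self.lr)
        history = []
        best = np.inf
        stale = 0
        for it in range(self.max_iter):
            g = loss_grad(params)
            params = opt.step(params, g)
            if (it + 1) % self.check_every == 0:
                cur = float(neg_ll(params))
                history.append({"iter": it + 1, "neg_loglik_per_entry": cur})
                if best - cur > self.tol * abs(best):
                    best = cur
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break

        m, r, o, a = unpack(params)
        self.fraction_params_ = params[0]
        self.fractions_ = np.asarray(m)
        self.capture_rate_ = np.asarray(r)
        self.shift_ = np.asarray(o)
        self.dispersion_ = np.asarray(a)
        self.mean_ = np.asarray(bulk_mean(m, F, r, o))
        self.loglik_ = float(nb_loglik(E, self.mean_, self.dispersion_[None, :]))
        self.history_ = pd.DataFrame(history)
        self._decoder_hash_after_ = params_hash(vae.decoder_params_)
        assert self._decoder_hash_before_ == self._decoder_hash_after_
        return self

    def aggregate(self, cluster_labels):
        """Cluster-level proportion matrix (samples x clusters)."""
        props, _ = aggregate_fractions(self.fractions_, cluster_labels)
        return props


class SpotDeconvolver(BulkDeconvolver):
    """Spatial-spot variant: identical model with spots in place of bulk
    samples; stores spot coordinates for hazard mapping."""

    def fit(self, E, vae, coordinates=None):
        super().fit(E, vae)
        if coordinates is not None:
            coordinates = np.asarray(coordinates, dtype=float)
            if coordinates.shape[0] != np.asarray(E).shape[0]:
                raise ValueError("coordinates must have one row per spot")
        self.coordinates_ = coordinates
        return self


def fit_deconvolution(bulk, vae, config: dict | None = None) -> BulkDeconvolver:
    """Functional wrapper over BulkDeconvolver."""
    return BulkDeconvolver(**(config or {})).fit(bulk, vae)


def fit_spot_deconvolution(
    spots, vae, coordinates=None, config: dict | None = None
) -> SpotDeconvolver:
    """Functional wrapper over SpotDeconvolver."""
    return SpotDeconvolver(**(config or {})).fit(spots, vae, coordinates)
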