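"""Stage 1: batch-conditional variational autoencoder for raw single-cell counts.

Generative model per cell c:

    z_c ~ N(0, I_M)                         (latent cell state, M-dimensional)
    x_cg ~ Poisson(l_c * f(z_c, p_c)_g)     (raw count of gene g)

where p_c is the one-hot batch (patient) label, l_c the per-cell mean count
over genes, and f a decoder MLP with a softplus output head. The variational
posterior q(z_c | x_c, p_c) = N(mu(x_c, p_c), diag(sd(x_c, p_c)^2)) is an
encoder MLP over log1p counts concatenated with the batch one-hot. Training
maximises the ELBO (Poisson reconstruction log-likelihood minus the KL of the
posterior from the standard-normal prior) with the reparameterisation trick.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import grad
from autograd.scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, init_mlp, mlp_forward, softplus
from .data import CellReference


def kl_gaussian(mu, sd):
    """Closed-form KL( N(mu, diag(sd^2)) || N(0, I) ), summed over dimensions.

    Accepts (n, M) or (M,) arrays; returns per-row KL (or a scalar)."""
    return 0.5 * anp.sum(mu**2 + sd**2 - 1.0 - 2.0 * anp.log(sd), axis=-1)


def poisson_loglik(counts, rate):
    """Poisson log-pmf summed over genes; per-row totals."""
    return anp.sum(counts * anp.log(rate) - rate - gammaln(counts + 1.0), axis=-1)


def elbo_terms(counts, rate, mu, sd):
    """ELBO decomposition at explicit posterior/rate values.

    Returns (reconstruction, kl) where the ELBO is reconstruction - kl; both
    summed over the supplied cells."""
    recon = anp.sum(poisson_loglik(counts, rate))
    kl = anp.sum(kl_gaussian(mu, sd))
    return recon, kl


class CountVAE(TransformerMixin, BaseEstimator):
    """Conditional VAE over raw counts with a Poisson decoder.

    Parameters
    ----------
    n_latent : latent dimension M.
    hidden : hidden layer widths for both encoder and decoder MLPs.
    lr, batch_size, max_epochs, patience : Adam optimisation settings; early
        stopping monitors the validation ELBO (evaluated at the posterior
        mean) with the given patience in epochs.
    split : cell fractions for train / validation / test.
    rate_floor : additive floor on the Poisson rate, guards log(0).
    random_state : seed for the split, initialisation and reparameterisation.

    Fitted attributes
    -----------------
    encoder_params_, decoder_params_ : frozen MLP parameters.
    latent_mean_, latent_sd_ : (C, M) posterior parameters for the fitted cells.
    latent_sample_ : one reparameterised draw per fitted cell.
    history_ : per-epoch train/validation ELBO (per cell).
    test_loglik_ : held-out reconstruction log-likelihood per test cell.
    """

    def __init__(
        self,
        n_latent: int = 10,
        hidden=(128, 128),
        lr: float = 1e-3,
        batch_size: int = 128,
        max_epochs: int = 400,
        patience: int = 20,
        split=(0.85, 0.10, 0.05),
        rate_floor: float = 1e-8,
        random_state: int = 0,
    ):
        self.n_latent = n_latent
        self.hidden = hidden
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.split = split
        self.rate_floor = rate_floor
        self.random_state = random_state

    # ---- network pieces ------------------------------------------------

    def _encode_params(self, params, x_log, onehot):
        out = mlp_forward(params, anp.concatenate([x_log, onehot], axis=-1))
        mu = out[..., : self.n_latent]
        sd = softplus(out[..., self.n_latent :]) + 1e-6
        return mu, sd

    def _decode_params(self, params, z, onehot):
        out = mlp_forward(params, anp.concatenate([z, onehot], axis=-1))
        return softplus(out) + self.rate_floor

    def encode(self, counts, batch_onehot, rng=None):
        """Posterior (mu, sd, z) for given cells; z via the reparameterisation
        z = mu + sd * eps with eps ~ N(0, I) from ``rng`` (mu if rng is None)."""
        self._check_fitted()
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        if np.any(~np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")
        onehot = np.atleast_2d(batch_onehot)
        mu, sd = self._encode_params(self.encoder_params_, np.log1p(counts), onehot)
        if rng is None:
            z = mu
        else:
            z = mu + sd * rng.standard_normal(mu.shape)
        return np.asarray(mu), np.asarray(sd), np.asarray(z)

    def decode(self, z, batch_onehot, library_mean=1.0):
        """Normalised expression f(z, p) and reconstruction l_c * f(z, p)."""
        self._check_fitted()
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[-1] != self.n_latent:
            raise ValueError(f"z must have {self.n_latent} dimensions")
        onehot = np.atleast_2d(batch_onehot)
        f = np.asarray(self._decode_params(self.decoder_params_, z, onehot))
        xhat = np.asarray(library_mean)[..., None] * f
        return f, xhat

    # ---- objective -----------------------------------------------------

    def _neg_elbo(self, params, x, x_log, onehot, lib, eps):
        enc, dec = params
        mu, sd = self._encode_params(enc, x_log, onehot)
        z = mu + sd * eps
        rate = lib[:, None] * self._decode_params(dec, z, onehot)
        recon = poisson_loglik(x, rate)
        kl = kl_gaussian(mu, sd)
        return -anp.mean(recon - kl)

    def elbo(self, counts, batch_onehot, library_mean=None, eps=None):
        """ELBO (summed over the given cells) under the fitted model.

        ``eps`` supplies the reparameterisation noise (zeros = posterior mean).
        """
        self._check_fitted()
        x = np.atleast_2d(np.asarray(counts, dtype=float))
        if x.size == 0:
            raise ValueError("elbo requires a non-empty batch of cells")
        onehot = np.atleast_2d(batch_onehot)
        lib = x.mean(axis=1) if library_mean is None else np.asarray(library_mean)
        eps = np.zeros((x.shape[0], self.n_latent)) if eps is None else eps
        val = -self._neg_elbo(
            (self.encoder_params_, self.decoder_params_), x, np.log1p(x), onehot, lib, eps
        )
        return float(val * x.shape[0])

    # ---- training ------------------------------------------------------

    def fit(self, X, y=None, batch=None):
        """Fit on a CellReference or a (cells x genes) count matrix.

        ``batch`` (integer labels per cell) is required for multi-batch data;
        defaults to a single batch.
        """
        if isinstance(X, CellReference):
            ref = X
        else:
            X = np.asarray(X)
            b = np.zeros(X.shape[0], dtype=int) if batch is None else np.asarray(batch)
            ref = CellReference(counts=X, batch=b)

        C, G = ref.counts.shape
        fr_train, fr_val, fr_test = self.split
        if abs(fr_train + fr_val + fr_test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        n_train = int(round(fr_train * C))
        n_val = int(round(fr_val * C))
        if n_train < 1 or n_val < 1 or C - n_train - n_val < 1:
            raise ValueError(
                f"{C} cells are too few for a {self.split} train/val/test split"
            )

        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(C)
        idx_train = perm[:n_train]
        idx_val = perm[n_train : n_train + n_val]
        idx_test = perm[n_train + n_val :]
        self.split_indices_ = {"train": idx_train, "val": idx_val, "test": idx_test}

        P = ref.n_batches
        enc = init_mlp([G + P, *self.hidden, 2 * self.n_latent], rng)
        dec = init_mlp([self.n_latent + P, *self.hidden, G], rng)
        params = [enc, dec]

        x = ref.counts.astype(float)
        x_log = np.log1p(x)
        onehot = ref.batch_onehot
        lib = ref.library_mean

        loss_grad = grad(self._neg_elbo)
        opt = Adam(params, lr=self.lr)

        def eval_elbo(idx):
            eps0 = np.zeros((len(idx), self.n_latent))
            return -self._neg_elbo(
                params, x[idx], x_log[idx], onehot[idx], lib[idx], eps0
            )

        best_val = -np.inf
        best_params = params
        best_epoch = 0
        history = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(idx_train)
            for start in range(0, len(order), self.batch_size):
                mb = order[start : start + self.batch_size]
                eps = rng.standard_normal((len(mb), self.n_latent))
                g = loss_grad(params, x[mb], x_log[mb], onehot[mb], lib[mb], eps)
                params = opt.step(params, g)
            train_elbo = float(eval_elbo(idx_train))
            val_elbo = float(eval_elbo(idx_val))
            history.append(
                {"epoch": epoch, "train_elbo": train_elbo, "val_elbo": val_elbo}
            )
            if val_elbo > best_val:
                best_val = val_elbo
                best_params = [[(W.copy(), b.copy()) for W, b in net] for net in params]
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break

        self.encoder_params_, self.decoder_params_ = best_params
        self.history_ = pd.DataFrame(history)
        self.best_val_elbo_ = best_val
        self.n_genes_ = G
        self.n_batches_ = P

        mu, sd = self._encode_params(self.encoder_params_, x_log, onehot)
        self.latent_mean_ = np.asarray(mu)
        self.latent_sd_ = np.asarray(sd)
        eps = np.random.default_rng(self.random_state + 1).standard_normal(mu.shape)
        self.latent_sample_ = self.latent_mean_ + self.latent_sd_ * eps
        self.batch_onehot_ = onehot
        self.library_mean_ = lib

        rate = lib[idx_test, None] * np.asarray(
            self._decode_params(self.decoder_params_, mu[idx_test], onehot[idx_test])
        )
        self.test_loglik_ = float(
            np.mean(poisson_loglik(x[idx_test], rate))
        )
        return self

    def transform(self, X, batch=None):
        """Posterior latent means for the given cells."""
        if isinstance(X, CellReference):
            counts, onehot = X.counts, X.batch_onehot
        else:
            counts = np.asarray(X)
            b = np.zeros(counts.shape[0], dtype=int) if batch is None else np.asarray(batch)
            onehot = np.zeros((counts.shape[0], self.n_batches_))
            onehot[np.arange(counts.shape[0]), b] = 1.0
        mu, _, _ = self.encode(counts, onehot)
        return mu

    def decoder_matrix(self) -> np.ndarray:
        """f(mu_c, p_c) for every fitted cell: the (C, G) normalised-expression
        matrix consumed by the deconvolution stage."""
        self._check_fitted()
        f, _ = self.decode(self.latent_mean_, self.batch_onehot_, self.library_mean_)
        return f

    def _check_fitted(self):
        if not hasattr(self, "encoder_params_"):
            raise AttributeError("CountVAE instance is not fitted yet")


def train_vae(reference: CellReference, config: dict | None = None) -> CountVAE:
    """Functional wrapper: fit a CountVAE on a reference with config overrides."""
    model = CountVAE(**(config or {}))
    return model.fit(reference)
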