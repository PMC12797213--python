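"""Stage 3: per-cell Cox hazard contributions.

The hazard of bulk sample b is h_b(t) = h0(t) * exp(eta_b) with

    eta_b = sum_c beta(z_c) * m(z_c)_b

where beta is an MLP over the frozen latent cell states and m the frozen
cell-fraction map from the deconvolution stage. beta is fitted by maximising
the Cox partial log-likelihood (Breslow, or Efron under tied event times)
over a 60/20/20 train/validation/test split of the bulk samples, with early
stopping on the validation partial likelihood. Evaluation uses Harrell's
concordance index and an IPCW integrated Brier score with a Breslow baseline.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import grad
from sklearn.base import BaseEstimator

from ._nn import Adam, init_mlp, mlp_forward
from .data import SurvivalTable


# ---------------------------------------------------------------------------
# partial log-likelihoods
# ---------------------------------------------------------------------------


def _tie_structure(survival: SurvivalTable):
    """Constant matrices used by both partial likelihoods.

    Returns (ev, R, Q, frac): event positions; risk-set indicator rows per
    event; tied-event indicator rows per event; Efron fractions (r-1)/d.
    """
    time = survival.time
    event = survival.event
    ev = np.flatnonzero(event == 1)
    if len(ev) == 0:
        raise ValueError("partial likelihood undefined: no events in the data")
    R = (time[None, :] >= time[ev, None]).astype(float)
    Q = ((time[None, :] == time[ev, None]) & (event[None, :] == 1)).astype(float)
    d, r = survival.tie_groups()
    frac = (r[ev] - 1) / d[ev]
    return ev, R, Q, frac


def breslow_loglik(eta, survival: SurvivalTable) -> float:
    """Breslow partial log-likelihood:
    sum over events b of eta_b - log sum_{i: T_i >= T_b} exp(eta_i)."""
    eta = np.asarray(eta, dtype=float)
    if np.any(~np.isfinite(eta)):
        raise ValueError("eta must be finite")
    ev, R, _, _ = _tie_structure(survival)
    return float(_partial_loglik_core(eta, ev, R, None, None))


def efron_loglik(eta, survival: SurvivalTable) -> float:
    """Efron partial log-likelihood: the tied-event sum is progressively
    down-weighted by (r_b - 1)/d_b within each tie group; identical to
    Breslow when every d_b = 1."""
    eta = np.asarray(eta, dtype=float)
    if np.any(~np.isfinite(eta)):
        raise ValueError("eta must be finite")
    ev, R, Q, frac = _tie_structure(survival)
    return float(_partial_loglik_core(eta, ev, R, Q, frac))


def _partial_loglik_core(eta, ev, R, Q, frac):
    """Autograd-differentiable core; log-sum-exp stabilised by max(eta)."""
    mx = anp.max(eta)
    ex = anp.exp(eta - mx)
    denom = anp.dot(R, ex)
    if Q is not None:
        denom = denom - frac * anp.dot(Q, ex)
    return anp.sum(eta[ev] - (anp.log(denom) + mx))


def partial_loglik(eta, survival: SurvivalTable, ties: str = "auto") -> float:
    """Dispatch: 'breslow', 'efron', or 'auto' (Efron iff ties are present)."""
    if ties == "auto":
        ev_times = survival.time[survival.event == 1]
        ties = "efron" if len(ev_times) != len(np.unique(ev_times)) else "breslow"
    if ties == "breslow":
        return breslow_loglik(eta, survival)
    if ties == "efron":
        return efron_loglik(eta, survival)
    raise ValueError(f"unknown tie method {ties!r}")


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def concordance_index(eta, survival: SurvivalTable) -> float:
    """Harrell's c-index.

    A pair (i, j) is comparable when T_i < T_j and sample i had the event, or
    when T_i == T_j with i an event and j censored. The pair is concordant
    when eta_i > eta_j; ties in eta score 0.5; pairs of events tied in time
    are excluded.
    """
    eta = np.asarray(eta, dtype=float)
    t = survival.time
    e = survival.event
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    tied_time = (
        (t[:, None] == t[None, :]) & (e[:, None] == 1) & (e[None, :] == 0)
    )
    comparable = earlier | tied_time
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs for the concordance index")
    concordant = (eta[:, None] > eta[None, :]) & comparable
    tied_eta = (eta[:, None] == eta[None, :]) & comparable
    return float((concordant.sum() + 0.5 * tied_eta.sum()) / n_pairs)


def breslow_baseline(eta, survival: SurvivalTable):
    """Breslow estimator of the baseline cumulative hazard.

    Returns (times, H0): unique event times and the cumulative hazard
    H0(t) = sum_{T_b <= t, event} d_b / sum_{i: T_i >= T_b} exp(eta_i),
    as a right-continuous step function."""
    eta = np.asarray(eta, dtype=float)
    t, e = survival.time, survival.event
    times = np.unique(t[e == 1])
    increments = []
    for tk in times:
        d = np.sum((t == tk) & (e == 1))
        denom = np.sum(np.exp(eta[t >= tk]))
        increments.append(d / denom)
    return times, np.cumsum(increments)


def predict_survival(eta, baseline, time_grid):
    """S(t | b) = exp(-H0(t) * exp(eta_b)) on the grid; shape (B, len(grid))."""
    times, H0 = baseline
    idx = np.searchsorted(times, time_grid, side="right") - 1
    H = np.where(idx >= 0, H0[np.clip(idx, 0, len(H0) - 1)], 0.0)
    return np.exp(-np.outer(np.exp(np.asarray(eta)), H))


def _censoring_km(survival: SurvivalTable):
    """Kaplan-Meier of the censoring distribution G(t) (delta = 0 as events).

    At tied times, true events are taken to precede censorings: the censoring
    risk set at t excludes events occurring at t. Returns a callable
    evaluating G right-continuously."""
    t, e = survival.time, survival.event
    uniq = np.unique(t)
    surv = []
    g = 1.0
    for tk in uniq:
        at_risk = np.sum(t >= tk) - np.sum((t == tk) & (e == 1))
        n_cens = np.sum((t == tk) & (e == 0))
        if n_cens > 0:
            g *= 1.0 - n_cens / at_risk
        surv.append(g)
    surv = np.asarray(surv)

    def G(x):
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(uniq, x, side="right") - 1
        return np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)

    return G


def brier_scores(eta, survival: SurvivalTable, baseline, time_grid):
    """IPCW Brier score at each grid time (Graf et al. construction).

    BS(t) = mean_b [ S(t|b)^2 1{T_b <= t, event} / G(T_b)
                   + (1 - S(t|b))^2 1{T_b > t} / G(t) ]
    with G the Kaplan-Meier censoring survival estimated on ``survival``
    (events precede censorings at tied times).
    """
    time_grid = np.asarray(time_grid, dtype=float)
    t, e = survival.time, survival.event
    G = _censoring_km(survival)
    g_at_T = G(t)
    S = predict_survival(eta, baseline, time_grid)
    out = np.empty(len(time_grid))
    for j, tau in enumerate(time_grid):
        had_event = (t <= tau) & (e == 1)
        still_alive = t > tau
        if np.any(had_event & (g_at_T <= 0)) or (np.any(still_alive) and G(tau) <= 0):
            raise ValueError(
                f"censoring survival estimate is zero at time {tau}; "
                "shrink the evaluation grid"
            )
        term_event = np.where(had_event, S[:, j] ** 2 / np.where(g_at_T > 0, g_at_T, 1.0), 0.0)
        term_alive = np.where(still_alive, (1.0 - S[:, j]) ** 2 / G(tau), 0.0)
        out[j] = np.mean(term_event + term_alive)
    return out


def integrated_brier_score(eta, survival: SurvivalTable, baseline, time_grid=None):
    """Trapezoid integral of the IPCW Brier score over the grid, normalised by
    the grid span. Default grid: 100 evenly spaced points from the earliest
    event time to the 80th percentile of observed time."""
    if time_grid is None:
        t_lo = survival.time[survival.event == 1].min()
        t_hi = np.quantile(survival.time, 0.8)
        if t_hi <= t_lo:
            raise ValueError("degenerate time grid; supply time_grid explicitly")
        time_grid = np.linspace(t_lo, t_hi, 100)
    time_grid = np.asarray(time_grid, dtype=float)
    bs = brier_scores(eta, survival, baseline, time_grid)
    return float(np.trapezoid(bs, time_grid) / (time_grid[-1] - time_grid[0]))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class CellHazardCox(BaseEstimator):
    """Per-cell Cox hazard contributions via a beta-network over latent states.

    fit(Z, fractions, survival) maximises the partial log-likelihood of
    eta = fractions.T @ beta(Z) on the training bulk split, early-stopping on
    the validation split.

    Fitted attributes: beta_ (per cell), eta_ (per sample), cindex_test_,
    ibs_test_, split_indices_, history_.
    """

    def __init__(
        self,
        hidden=(64, 64),
        lr: float = 1e-3,
        max_epochs: int = 1000,
        patience: int = 20,
        ties: str = "auto",
        split=(0.6, 0.2, 0.2),
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.ties = ties
        self.split = split
        self.random_state = random_state

    def _beta(self, params, Z):
        return mlp_forward(params, Z)[:, 0]

    def fit(self, Z, fractions, survival: SurvivalTable):
        Z = np.asarray(Z, dtype=float)
        M = np.asarray(fractions, dtype=float)
        if M.shape[0] != Z.shape[0]:
            raise ValueError("fractions must be (cells x samples), aligned with Z")
        if M.shape[1] != len(survival):
            raise ValueError("survival table must align with the bulk samples")

        rng = np.random.default_rng(self.random_state)
        B = M.shape[1]
        fr = self.split
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        perm = rng.permutation(B)
        n_tr = int(round(fr[0] * B))
        n_va = int(round(fr[1] * B))
        idx = {
            "train": perm[:n_tr],
            "val": perm[n_tr : n_tr + n_va],
            "test": perm[n_tr + n_va :],
        }
        surv = {k: survival.subset(v) for k, v in idx.items()}
        if surv["train"].n_events == 0:
            raise ValueError("training split contains no events")
        self.split_indices_ = idx

        ties = self.ties
        if ties == "auto":
            ev_times = survival.time[survival.event == 1]
            ties = "efron" if len(ev_times) != len(np.unique(ev_times)) else "breslow"
        self.ties_ = ties

        structures = {k: _tie_structure(surv[k]) for k in ("train", "val")}
        M_sub = {k: M[:, idx[k]] for k in ("train", "val")}

        def neg_pl(params, key):
            eta = anp.dot(M_sub[key].T, self._beta(params, Z))
            ev, R, Q, frac = structures[key]
            if ties == "breslow":
                Q_, frac_ = None, None
            else:
                Q_, frac_ = Q, frac
            return -_partial_loglik_core(eta, ev, R, Q_, frac_) / len(ev)

        params = init_mlp([Z.shape[1], *self.hidden, 1], rng)
        opt = Adam(params, lr=self.lr)
        loss_grad = grad(lambda p: neg_pl(p, "train"))

        best_val = -np.inf
        best_params = params
        best_epoch = 0
        history = []
        for epoch in range(self.max_epochs):
            g = loss_grad(params)
            params = opt.step(params, g)
            val_pl = (
                float(-neg_pl(params, "val")) if surv["val"].n_events > 0 else np.nan
            )
            train_pl = float(-neg_pl(params, "train"))
            history.append({"epoch": epoch, "train_pl": train_pl, "val_pl": val_pl})
            monitor = val_pl if np.isfinite(val_pl) else train_pl
            if monitor > best_val:
                best_val = monitor
                best_params = [(W.copy(), b.copy()) for W, b in params]
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break

        self.params_ = best_params
        self.history_ = pd.DataFrame(history)
        self.beta_ = np.asarray(self._beta(best_params, Z))
        self.eta_ = M.T @ self.beta_

        te = idx["test"]
        self.cindex_train_ = concordance_index(self.eta_[idx["train"]], surv["train"])
        try:
            self.cindex_test_ = concordance_index(self.eta_[te], surv["test"])
        except ValueError:
            self.cindex_test_ = np.nan
        baseline = breslow_baseline(self.eta_[idx["train"]], surv["train"])
        self.baseline_ = baseline
        try:
            self.ibs_test_ = integrated_brier_score(self.eta_[te], surv["test"], baseline)
        except ValueError:
            self.ibs_test_ = np.nan
        return self

    def predict(self, Z_or_fractions=None, fractions=None):
        """Per-sample linear predictor eta for a fraction matrix (cells aligned
        with the fitted Z); with no argument returns the fitted eta_."""
        if Z_or_fractions is None and fractions is None:
            return self.eta_
        M = np.asarray(fractions if fractions is not None else Z_or_fractions)
        return M.T @ self.beta_


def fit_hazard(vae, deconv, survival: SurvivalTable, config: dict | None = None):
    """Functional wrapper over CellHazardCox using frozen stage-1/2 results."""
    model = CellHazardCox(**(config or {}))
    return model.fit(vae.latent_mean_, deconv.fractions_, survival)


def resample_cindex_ci(
    Z,
    fractions,
    survival: SurvivalTable,
    n_iter: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
    **cox_kwargs,
):
    """Percentile CI of the test c-index over independently resampled
    train/validation/test splits of the bulk samples.

    Returns (lower, upper, cindices)."""
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    rng = np.random.default_rng(seed)
    cindices = []
    for _ in range(n_iter):
        model = CellHazardCox(random_state=int(rng.integers(2**31)), **cox_kwargs)
        model.fit(Z, fractions, survival)
        cindices.append(model.cindex_test_)
    cindices = np.asarray(cindices)
    lower = float(np.quantile(cindices, alpha / 2))
    upper = float(np.quantile(cindices, 1 - alpha / 2))
    return lower, upper, cindices
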