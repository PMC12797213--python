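"""Simulators for clustered single-cell references, pseudo-bulk mixtures and
Cox-generated survival times.

The generative story mirrors the observation models fitted downstream so every
stage of the pipeline can be validated offline against known ground truth:

* each cluster k has a log-mean expression profile ``base_g + delta_kg`` with
  an additive per-batch log-offset; counts are negative-binomial around the
  exponentiated profile (fixed dispersion);
* pseudo-bulk samples mix cluster proportions drawn from a Dirichlet prior,
  sampling cells per cluster and summing their raw counts;
* survival times come from a Cox model with constant baseline hazard, so the
  event time is exponential with rate ``baseline_rate * exp(eta)`` and
  ``eta = proportions @ coefficients``; censoring is independent exponential,
  calibrated by bisection to the requested expected censoring fraction.
"""

from __future__ import annotations

import numpy as np

from .data import CellReference, SurvivalTable, SyntheticTruth

# Defaults chosen to resemble a shallowly sequenced scRNA-seq panel: gene base
# means around 0.5 counts/cell, well-separated clusters, mild batch shifts.
BASE_LOG_MEAN = np.log(0.5)
GENE_SD = 1.0
CLUSTER_SD = 1.0
BATCH_SD = 0.3
NB_DISPERSION = 10.0


def _nb_sample(rng, mean, dispersion):
    """NB draw with variance mean + mean^2/dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_reference(
    n_cells: int,
    n_genes: int,
    n_clusters: int,
    n_batches: int = 1,
    seed: int = 0,
    cluster_sd: float = CLUSTER_SD,
    batch_sd: float = BATCH_SD,
    dispersion: float = NB_DISPERSION,
):
    """Simulate a clustered, multi-batch single-cell count reference.

    Returns (CellReference, SyntheticTruth). Cluster and batch assignments are
    balanced so every cluster and batch is non-empty.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if n_cells < n_clusters:
        raise ValueError("n_cells must be at least n_clusters")
    if n_batches < 1:
        raise ValueError("n_batches must be at least 1")
    if n_genes < 1:
        raise ValueError("n_genes must be positive")

    rng = np.random.default_rng(seed)
    base = rng.normal(BASE_LOG_MEAN, GENE_SD, size=n_genes)
    delta = rng.normal(0.0, cluster_sd, size=(n_clusters, n_genes))
    batch_offset = rng.normal(0.0, batch_sd, size=(n_batches, n_genes))
    batch_offset[0] = 0.0  # first batch is the reference level

    # round-robin assignment then shuffle: every cluster/batch non-empty
    clusters = np.resize(np.arange(n_clusters), n_cells)
    rng.shuffle(clusters)
    batches = np.resize(np.arange(n_batches), n_cells)
    rng.shuffle(batches)

    log_mu = base[None, :] + delta[clusters] + batch_offset[batches]
    counts = _nb_sample(rng, np.exp(log_mu), dispersion)

    ref = CellReference(counts=counts, batch=batches, cluster_labels=clusters)
    truth = SyntheticTruth(
        cluster_labels=clusters, seed=seed, cluster_log_means=base[None, :] + delta
    )
    return ref, truth


def split_reference(reference: CellReference, fraction: float = 0.5, seed: int = 0):
    """Stratified split of the cells into a reference half and a bulk-source half.

    The two halves are disjoint and exhaustive; stratification by cluster
    guarantees every cluster appears on both sides.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if reference.cluster_labels is None:
        raise ValueError("split_reference requires cluster labels")

    rng = np.random.default_rng(seed)
    labels = reference.cluster_labels
    first, second = [], []
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        if len(members) < 2:
            raise ValueError(f"cluster {k} has fewer than 2 cells and cannot be split")
        perm = rng.permutation(members)
        n_first = int(round(fraction * len(members)))
        n_first = min(max(n_first, 1), len(members) - 1)
        first.append(perm[:n_first])
        second.append(perm[n_first:])
    first = np.sort(np.concatenate(first))
    second = np.sort(np.concatenate(second))
    return reference.subset(first), reference.subset(second)


def generate_pseudobulk(
    bulk_source: CellReference,
    n_bulk: int = 300,
    concentration: float = 1.0,
    seed: int = 0,
    cells_per_sample: int = 1000,
    proportions: np.ndarray | None = None,
):
    """Mix cluster proportions into pseudo-bulk count profiles.

    For each sample, cluster proportions are drawn from Dirichlet(concentration)
    (or taken from ``proportions`` if supplied), ``cells_per_sample`` cells are
    sampled with replacement cluster-by-cluster according to a multinomial
    split, and their raw counts are summed.

    Returns (bulk_counts (n_bulk, G), true_proportions (n_bulk, K)).
    """
    if n_bulk < 1:
        raise ValueError("n_bulk must be at least 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if bulk_source.cluster_labels is None:
        raise ValueError("bulk source must carry cluster labels")

    rng = np.random.default_rng(seed)
    labels = bulk_source.cluster_labels
    cluster_ids = np.unique(labels)
    pools = []
    for k in cluster_ids:
        members = np.flatnonzero(labels == k)
        if len(members) == 0:
            raise ValueError(f"cluster {k} is empty in the bulk source half")
        pools.append(members)
    K = len(cluster_ids)

    if proportions is None:
        proportions = rng.dirichlet(np.full(K, concentration), size=n_bulk)
    else:
        proportions = np.asarray(proportions, dtype=float)
        if proportions.shape != (n_bulk, K):
            raise ValueError("proportions must have shape (n_bulk, n_clusters)")

    G = bulk_source.n_genes
    bulk = np.zeros((n_bulk, G), dtype=np.int64)
    for b in range(n_bulk):
        n_per_cluster = rng.multinomial(cells_per_sample, proportions[b])
        for k in range(K):
            if n_per_cluster[k] == 0:
                continue
            chosen = rng.choice(pools[k], size=n_per_cluster[k], replace=True)
            bulk[b] += bulk_source.counts[chosen].sum(axis=0)
    return bulk, proportions


def _calibrate_censoring_rate(event_rates: np.ndarray, censor_fraction: float) -> float:
    """Bisection for the exponential censoring rate lam_c such that the
    expected censored fraction mean_b lam_c/(lam_b + lam_c) hits the target."""

    def expected_censored(lam_c):
        return float(np.mean(lam_c / (event_rates + lam_c)))

    lo, hi = 1e-12, float(event_rates.max())
    while expected_censored(hi) < censor_fraction:
        hi *= 2.0
        if hi > 1e18:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_censored(mid) < censor_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(
    true_proportions: np.ndarray,
    true_coefficients: np.ndarray,
    baseline_rate: float = 1.0,
    censor_fraction: float = 0.2,
    seed: int = 0,
):
    """Draw Cox survival times from cluster proportions and coefficients.

    The baseline hazard is constant, so T = -log(U) / (baseline_rate * exp(eta))
    with eta = proportions @ coefficients. Independent exponential censoring is
    calibrated so the expected censored fraction equals ``censor_fraction``.
    """
    P = np.asarray(true_proportions, dtype=float)
    beta = np.asarray(true_coefficients, dtype=float)
    if P.shape[1] != beta.shape[0]:
        raise ValueError("coefficients length must equal the number of clusters")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0.0 <= censor_fraction < 1.0:
        raise ValueError("censor_fraction must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    eta = P @ beta
    rates = baseline_rate * np.exp(eta)
    T = rng.exponential(1.0 / rates)

    if censor_fraction == 0.0:
        return SurvivalTable(time=T, event=np.ones(len(T), dtype=int))

    lam_c = _calibrate_censoring_rate(rates, censor_fraction)
    Cens = rng.exponential(1.0 / lam_c, size=len(T))
    observed = np.minimum(T, Cens)
    event = (T <= Cens).astype(int)
    return SurvivalTable(time=observed, event=event)


def make_coefficient_settings(
    n_settings: int, n_clusters: int = 5, seed: int = 0, sd: float = 2.0
):
    """Draw i.i.d. Gaussian cluster-coefficient vectors for repeated survival
    simulations (one hazard refit per setting on shared pseudo-bulk data)."""
    if n_settings < 1:
        raise ValueError("n_settings must be at least 1")
    rng = np.random.default_rng(seed)
    return [rng.normal(0.0, sd, size=n_clusters) for _ in range(n_settings)]


def merge_cluster_labels(cluster_labels: np.ndarray, groups):
    """Relabel clusters by merging groups (label-mismatch scenario).

    ``groups`` is a list of iterables of original cluster ids; every original
    cluster must appear in exactly one group. Returns new integer labels where
    cells in group i get label i.
    """
    labels = np.asarray(cluster_labels)
    mapping = {}
    for new, group in enumerate(groups):
        for k in group:
            if k in mapping:
                raise ValueError(f"cluster {k} assigned to more than one group")
            mapping[k] = new
    missing = set(np.unique(labels)) - set(mapping)
    if missing:
        raise ValueError(f"clusters {sorted(missing)} not assigned to any group")
    return np.array([mapping[k] for k in labels])


def split_cluster_labels(reference: CellReference, seed: int = 0):
    """Split each cluster in two by a random expression hyperplane
    (label-mismatch scenario with finer labels than the truth).

    Cells are projected on a random gene-space direction of their log1p counts
    and each cluster is cut at its median projection. Returns new labels with
    2K values: original cluster k maps to 2k (below median) or 2k+1 (above).
    """
    if reference.cluster_labels is None:
        raise ValueError("reference must carry cluster labels")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=reference.n_genes)
    proj = np.log1p(reference.counts) @ direction
    labels = np.asarray(reference.cluster_labels)
    out = np.zeros(len(labels), dtype=int)
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        cut = np.median(proj[members])
        out[members] = 2 * int(k) + (proj[members] > cut).astype(int)
    return out
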