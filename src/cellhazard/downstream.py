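"""Post-fit analyses: cluster permutation importance, gene-contribution
correlations, spatial hazard maps and cross-dataset similarity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalTable
from .hazard import concordance_index


@dataclass
class PermutationReport:
    """Per-cluster c-index decrement under within-cluster shuffling of the
    per-cell contributions (larger decrement = cluster's internal contribution
    heterogeneity matters more for ranking patients)."""

    table: pd.DataFrame  # columns: cluster, decrement, se, perm_sd, n_cells
    baseline_cindex: float
    n_permutations: int
    seed: int


def permutation_importance(
    contributions,
    fractions,
    cluster_labels,
    survival: SurvivalTable,
    n_perm: int = 10,
    seed: int = 0,
    eval_idx=None,
) -> PermutationReport:
    """Shuffle contributions within one cluster at a time (all other cells
    fixed), recompute eta = fractions.T @ beta and the c-index, and report the
    mean decrement from baseline over ``n_perm`` permutations per cluster.

    ``eval_idx`` restricts evaluation to a subset of the bulk samples
    (default: full cohort)."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    beta = np.asarray(contributions, dtype=float)
    M = np.asarray(fractions, dtype=float)
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != beta.shape[0] or M.shape[0] != beta.shape[0]:
        raise ValueError("contributions, fractions and labels must align on cells")

    if eval_idx is None:
        eval_idx = np.arange(M.shape[1])
    M_eval = M[:, eval_idx]
    surv_eval = survival.subset(np.asarray(eval_idx))

    baseline = concordance_index(M_eval.T @ beta, surv_eval)
    rng = np.random.default_rng(seed)
    rows = []
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        if len(members) < 2:
            warnings.warn(f"cluster {k} has a single cell; decrement set to 0")
            rows.append(
                {"cluster": k, "decrement": 0.0, "se": 0.0, "perm_sd": 0.0,
                 "n_cells": len(members)}
            )
            continue
        cvals = np.empty(n_perm)
        for p in range(n_perm):
            perm_beta = beta.copy()
            perm_beta[members] = beta[members][rng.permutation(len(members))]
            cvals[p] = concordance_index(M_eval.T @ perm_beta, surv_eval)
        decrements = baseline - cvals
        sd = decrements.std(ddof=1) if n_perm > 1 else 0.0
        rows.append(
            {
                "cluster": k,
                "decrement": float(decrements.mean()),
                "se": float(sd / np.sqrt(n_perm)),
                "perm_sd": float(sd),
                "n_cells": len(members),
            }
        )
    return PermutationReport(
        table=pd.DataFrame(rows),
        baseline_cindex=float(baseline),
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class GeneCorrelationTable:
    """Per-gene Pearson correlation between (reconstructed) expression and the
    per-cell hazard contribution, with top/bottom rankings."""

    table: pd.DataFrame  # columns: gene, r, rank, zero_variance
    top: pd.DataFrame
    bottom: pd.DataFrame


def gene_contribution_correlation(
    decoder_outputs,
    contributions,
    top_k: int = 30,
    gene_names=None,
    cell_mask=None,
) -> GeneCorrelationTable:
    """Correlate each gene's expression across cells with the contributions.

    ``decoder_outputs`` is typically the reconstructed (denoised) expression
    f(z_c, p_c); pass raw counts to correlate on observed expression instead.
    ``cell_mask`` restricts to a cell subset (e.g. one cell type).
    Zero-variance genes get r = 0 and are flagged.
    """
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    F = np.asarray(decoder_outputs, dtype=float)
    beta = np.asarray(contributions, dtype=float)
    if cell_mask is not None:
        mask = np.asarray(cell_mask)
        F = F[mask]
        beta = beta[mask]
    if gene_names is None:
        gene_names = np.array([f"gene_{j}" for j in range(F.shape[1])])

    Fc = F - F.mean(axis=0)
    bc = beta - beta.mean()
    sd_f = Fc.std(axis=0)
    sd_b = bc.std()
    zero_var = (sd_f == 0) | (sd_b == 0)
    denom = np.where(zero_var, 1.0, sd_f * sd_b)
    r = np.where(zero_var, 0.0, (Fc * bc[:, None]).mean(axis=0) / denom)

    table = pd.DataFrame(
        {"gene": np.asarray(gene_names), "r": r, "zero_variance": zero_var}
    )
    table = table.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return GeneCorrelationTable(
        table=table, top=table.head(top_k).copy(), bottom=table.tail(top_k).copy()
    )


@dataclass
class SpatialHazardMap:
    """Per-spot hazard scores; ``clipped`` is a display copy winsorised at the
    2.5% / 97.5% quantiles of the raw scores."""

    raw: np.ndarray
    clipped: np.ndarray
    quantiles: tuple
    coordinates: np.ndarray | None = None


def clip_quantiles(values, lo: float = 0.025, hi: float = 0.975, bounds=None):
    """Winsorise at the given quantiles (linear-interpolation convention).

    ``bounds`` reuses previously computed (lo, hi) cut-offs; clipping is
    idempotent when the recorded bounds are reapplied (re-estimating quantiles
    on already-clipped data would move the cut-offs inward)."""
    values = np.asarray(values, dtype=float)
    if bounds is None:
        qlo, qhi = np.quantile(values, [lo, hi])
    else:
        qlo, qhi = bounds
    return np.clip(values, qlo, qhi), (float(qlo), float(qhi))


def spatial_hazard(spot_fractions, contributions, coordinates=None) -> SpatialHazardMap:
    """score_s = sum_c beta(z_c) m_spot(z_c)_s per spot; raw scores retained,
    clipped copy for display."""
    M = np.asarray(spot_fractions, dtype=float)
    beta = np.asarray(contributions, dtype=float)
    if M.shape[0] != beta.shape[0]:
        raise ValueError("spot fractions and contributions must align on cells")
    raw = M.T @ beta
    clipped, q = clip_quantiles(raw)
    return SpatialHazardMap(raw=raw, clipped=clipped, quantiles=q, coordinates=coordinates)


def spot_group_mean_hazard(spatial_map: SpatialHazardMap, spot_groups) -> pd.DataFrame:
    """Mean raw hazard per spot group, ranked from highest to lowest."""
    groups = np.asarray(spot_groups)
    if groups.shape[0] != spatial_map.raw.shape[0]:
        raise ValueError("spot groups must cover all spots")
    rows = []
    for gname in np.unique(groups):
        members = spatial_map.raw[groups == gname]
        if len(members) == 0:
            raise ValueError(f"spot group {gname} is empty")
        rows.append({"group": gname, "mean_hazard": float(members.mean()), "n_spots": len(members)})
    out = pd.DataFrame(rows).sort_values("mean_hazard", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def cross_dataset_similarity(tables: list) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-gene correlation vectors across
    datasets, restricted to the shared gene vocabulary."""
    if len(tables) < 2:
        raise ValueError("need at least two gene-correlation tables")
    frames = []
    for i, t in enumerate(tables):
        df = t.table if isinstance(t, GeneCorrelationTable) else t
        frames.append(df.set_index("gene")["r"].rename(i))
    merged = pd.concat(frames, axis=1, join="inner")
    if len(merged) < 10:
        raise ValueError(
            f"only {len(merged)} shared genes; need at least 10 for similarity"
        )
    return merged.corr(method="pearson")
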