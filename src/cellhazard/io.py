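"""Readers and writers for the on-disk formats.

Reference counts: H5AD, an MTX directory (matrix.mtx + barcodes.tsv +
features.tsv, with batch/cluster columns in barcodes.tsv), or a dense CSV with
an obs sidecar. Bulk/spot matrices: CSV/TSV with orientation auto-detected by
header overlap with the reference gene vocabulary. Survival: CSV with
sample_id, time, event. All tables use explicit string identifiers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CellReference, SurvivalTable

log = logging.getLogger("cellhazard")


def load_reference(path, obs_path=None) -> CellReference:
    """Load a single-cell reference; a ``batch`` annotation is required.

    path may be an .h5ad file, an MTX directory, or a dense cells x genes CSV
    (with obs_path a CSV carrying cell_id, batch and optional cluster)."""
    path = Path(path)
    if path.is_dir():
        return _load_mtx_dir(path)
    if path.suffix == ".h5ad":
        return _load_h5ad(path)
    if path.suffix in (".csv", ".tsv"):
        return _load_dense_csv(path, obs_path)
    raise ValueError(f"unrecognised reference format: {path}")


def _load_h5ad(path) -> CellReference:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if "batch" not in adata.obs:
        raise ValueError("reference is missing the required per-cell 'batch' column")
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    cluster = None
    if "cluster" in adata.obs:
        cluster = pd.Categorical(adata.obs["cluster"]).codes
    return CellReference(
        counts=np.asarray(X),
        batch=pd.Categorical(adata.obs["batch"]).codes,
        cluster_labels=cluster,
        cell_ids=adata.obs_names.to_numpy(),
        gene_names=adata.var_names.to_numpy(),
    )


def _load_mtx_dir(path: Path) -> CellReference:
    from scipy.io import mmread

    mtx = path / "matrix.mtx"
    barcodes = path / "barcodes.tsv"
    features = path / "features.tsv"
    for p in (mtx, barcodes, features):
        if not p.exists():
            raise FileNotFoundError(f"MTX directory is missing {p.name}")
    counts = np.asarray(mmread(mtx).todense())  # genes x cells, CellRanger layout
    obs = pd.read_csv(barcodes, sep="\t")
    if "batch" not in obs.columns:
        raise ValueError("barcodes.tsv is missing the required 'batch' column")
    genes = pd.read_csv(features, sep="\t", header=None)[0].to_numpy()
    cluster = (
        pd.Categorical(obs["cluster"]).codes if "cluster" in obs.columns else None
    )
    return CellReference(
        counts=counts.T,
        batch=pd.Categorical(obs["batch"]).codes,
        cluster_labels=cluster,
        cell_ids=obs.iloc[:, 0].to_numpy(),
        gene_names=genes,
    )


def _load_dense_csv(path, obs_path) -> CellReference:
    df = pd.read_csv(path, index_col=0)
    if obs_path is None:
        raise ValueError(
            "dense CSV references require an obs sidecar providing the "
            "required per-cell 'batch' column"
        )
    obs = pd.read_csv(obs_path)
    if "batch" not in obs.columns:
        raise ValueError("obs sidecar is missing the required 'batch' column")
    cells = obs.iloc[:, 0].astype(str).to_numpy()
    # orientation: cells may be rows or columns; match against the obs cell ids
    row_overlap = np.isin(df.index.astype(str), cells).mean()
    col_overlap = np.isin(df.columns.astype(str), cells).mean()
    if col_overlap > row_overlap:
        log.info("dense CSV detected as genes-as-rows; transposing")
        df = df.T
    df = df.loc[cells]
    cluster = (
        pd.Categorical(obs["cluster"]).codes if "cluster" in obs.columns else None
    )
    return CellReference(
        counts=df.to_numpy(),
        batch=pd.Categorical(obs["batch"]).codes,
        cluster_labels=cluster,
        cell_ids=cells,
        gene_names=df.columns.to_numpy(),
    )


def write_reference(ref: CellReference, path):
    """Write as .h5ad, or as an MTX directory for any other path."""
    path = Path(path)
    if path.suffix == ".h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=ref.counts.astype(np.float32),
            obs=pd.DataFrame(
                {
                    "batch": ref.batch.astype(str),
                    **(
                        {"cluster": ref.cluster_labels.astype(str)}
                        if ref.cluster_labels is not None
                        else {}
                    ),
                },
                index=ref.cell_ids.astype(str),
            ),
            var=pd.DataFrame(index=ref.gene_names.astype(str)),
        )
        adata.write_h5ad(path)
        return
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "matrix.mtx", csr_matrix(ref.counts.T))  # genes x cells
    obs = pd.DataFrame({"cell_id": ref.cell_ids, "batch": ref.batch})
    if ref.cluster_labels is not None:
        obs["cluster"] = ref.cluster_labels
    obs.to_csv(path / "barcodes.tsv", sep="\t", index=False)
    pd.Series(ref.gene_names).to_csv(
        path / "features.tsv", sep="\t", index=False, header=False
    )


def load_matrix(path, reference_genes) -> pd.DataFrame:
    """Bulk or spot expression CSV/TSV as (samples x genes), orientation
    auto-detected by which axis overlaps the reference gene vocabulary."""
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, index_col=0, sep=sep)
    genes = set(map(str, reference_genes))
    col_overlap = np.mean([str(c) in genes for c in df.columns])
    row_overlap = np.mean([str(r) in genes for r in df.index])
    if row_overlap > col_overlap:
        log.info("matrix %s detected as genes-as-rows; transposing", path.name)
        df = df.T
    return df


def align_genes(bulk_df: pd.DataFrame, reference_genes):
    """Intersect the bulk gene columns with the reference vocabulary
    (case-sensitive). Returns (array samples x genes_kept, kept gene order,
    reference column indices)."""
    ref_genes = list(map(str, reference_genes))
    keep = [g for g in ref_genes if g in set(map(str, bulk_df.columns))]
    dropped = len(ref_genes) - len(keep)
    if not keep:
        raise ValueError("empty gene intersection between bulk data and reference")
    if dropped:
        log.info("dropped %d reference genes absent from the bulk matrix", dropped)
    idx = [ref_genes.index(g) for g in keep]
    return bulk_df[keep].to_numpy(dtype=float), np.array(keep), np.array(idx)


def load_survival(path) -> SurvivalTable:
    df = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival CSV must have columns {sorted(required)}")
    return SurvivalTable(
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        sample_ids=df["sample_id"].astype(str).to_numpy(),
    )


def write_survival(surv: SurvivalTable, path):
    surv.to_frame().to_csv(path, index=False)


def load_spot_coordinates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"spot coordinate CSV must have columns {sorted(required)}")
    return df
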