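"""Sequential pipeline orchestration with frozen-stage checkpoints.

Stages run in order (simulate/load -> vae -> deconv -> hazard -> downstream);
each stage writes a checkpoint and its parameters are frozen for all later
stages. Re-running with an existing output directory skips completed stages
after verifying the stored config hash and checkpoint file hashes; a modified
checkpoint raises an integrity error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .data import CellReference, SurvivalTable
from .deconv import BulkDeconvolver, SpotDeconvolver
from .downstream import (
    gene_contribution_correlation,
    permutation_importance,
    spatial_hazard,
)
from .hazard import CellHazardCox
from .io import align_genes, load_matrix, load_reference, load_survival, write_survival
from .vae import CountVAE

log = logging.getLogger("cellhazard")

DEFAULT_SYNTHETIC = {
    "n_cells": 1000,
    "n_genes": 200,
    "n_clusters": 5,
    "n_batches": 2,
    "n_bulk": 300,
    "concentration": 1.0,
    "cells_per_sample": 1000,
    "coefficient_sd": 2.0,
    "baseline_rate": 1.0,
    "censor_fraction": 0.2,
}


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _save_net(store: dict, prefix: str, params):
    for i, (W, b) in enumerate(params):
        store[f"{prefix}_{i}_W"] = W
        store[f"{prefix}_{i}_b"] = b


def _load_net(npz, prefix: str):
    params = []
    i = 0
    while f"{prefix}_{i}_W" in npz:
        params.append((npz[f"{prefix}_{i}_W"], npz[f"{prefix}_{i}_b"]))
        i += 1
    return params


class Pipeline:
    """Runs the sequential stages and manages checkpoints under ``outdir``."""

    def __init__(self, config: dict, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        chash = _config_hash(config)
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
            if self.manifest.get("config_hash") != chash:
                log.info("config changed; starting a fresh manifest")
                self.manifest = {"config_hash": chash, "stages": {}}
        else:
            self.manifest = {"config_hash": chash, "stages": {}}

    # -- manifest helpers -------------------------------------------------

    def _stage_done(self, name: str) -> bool:
        entry = self.manifest["stages"].get(name)
        if not entry:
            return False
        path = self.outdir / entry["file"]
        if not path.exists():
            return False
        if _file_sha256(path) != entry["sha256"]:
            raise RuntimeError(
                f"checkpoint for stage '{name}' was modified after it was frozen "
                f"(hash mismatch on {path.name})"
            )
        return True

    def _record(self, name: str, path: Path, metrics: dict):
        self.manifest["stages"][name] = {
            "file": path.name,
            "sha256": _file_sha256(path),
            "metrics": metrics,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))

    # -- stages -----------------------------------------------------------

    def stage_data(self):
        cfg = self.config
        seed = cfg.get("seed", 0)
        ckpt = self.outdir / "data.npz"
        if self._stage_done("data"):
            npz = np.load(ckpt, allow_pickle=False)
            self.reference = CellReference(
                counts=npz["counts"],
                batch=npz["batch"],
                cluster_labels=npz["clusters"] if "clusters" in npz else None,
            )
            self.bulk = npz["bulk"]
            self.survival = SurvivalTable(npz["time"], npz["event"])
            self.truth = {
                k: npz[k]
                for k in ("true_proportions", "true_coefficients")
                if k in npz
            }
            return
        if cfg.get("synthetic") is not None:
            s = {**DEFAULT_SYNTHETIC, **cfg["synthetic"]}
            full, _ = synthetic.generate_reference(
                s["n_cells"], s["n_genes"], s["n_clusters"], s["n_batches"], seed=seed
            )
            ref_half, bulk_half = synthetic.split_reference(full, 0.5, seed=seed + 1)
            bulk, props = synthetic.generate_pseudobulk(
                bulk_half,
                s["n_bulk"],
                s["concentration"],
                seed=seed + 2,
                cells_per_sample=s["cells_per_sample"],
            )
            coef = np.asarray(
                s.get("coefficients")
                if s.get("coefficients") is not None
                else synthetic.make_coefficient_settings(
                    1, s["n_clusters"], seed=seed + 3, sd=s["coefficient_sd"]
                )[0]
            )
            surv = synthetic.simulate_survival(
                props, coef, s["baseline_rate"], s["censor_fraction"], seed=seed + 4
            )
            self.reference, self.bulk, self.survival = ref_half, bulk, surv
            self.truth = {"true_proportions": props, "true_coefficients": coef}
            store = {
                "counts": ref_half.counts,
                "batch": ref_half.batch,
                "bulk": bulk,
                "time": surv.time,
                "event": surv.event,
                **self.truth,
            }
            if ref_half.cluster_labels is not None:
                store["clusters"] = ref_half.cluster_labels
            write_survival(surv, self.outdir / "survival.csv")
            pd.DataFrame(props).to_csv(self.outdir / "true_proportions.csv", index=False)
        else:
            ref = load_reference(cfg["reference"])
            bulk_df = load_matrix(cfg["bulk"], ref.gene_names)
            bulk, kept, idx = align_genes(bulk_df, ref.gene_names)
            ref = CellReference(
                counts=ref.counts[:, idx],
                batch=ref.batch,
                cluster_labels=ref.cluster_labels,
                cell_ids=ref.cell_ids,
                gene_names=kept,
            )
            surv = load_survival(cfg["survival"])
            self.reference, self.bulk, self.survival = ref, bulk, surv
            self.truth = {}
            store = {
                "counts": ref.counts,
                "batch": ref.batch,
                "bulk": bulk,
                "time": surv.time,
                "event": surv.event,
            }
            if ref.cluster_labels is not None:
                store["clusters"] = ref.cluster_labels
        np.savez_compressed(ckpt, **store)
        self._record("data", ckpt, {"n_cells": int(self.reference.n_cells)})

    def stage_vae(self):
        ckpt = self.outdir / "vae.npz"
        cfg = {**self.config.get("vae", {})}
        cfg.setdefault("random_state", self.config.get("seed", 0))
        model = CountVAE(**cfg)
        if self._stage_done("vae"):
            npz = np.load(ckpt)
            model.encoder_params_ = _load_net(npz, "enc")
            model.decoder_params_ = _load_net(npz, "dec")
            model.latent_mean_ = npz["latent_mean"]
            model.latent_sd_ = npz["latent_sd"]
            model.latent_sample_ = npz["latent_sample"]
            model.batch_onehot_ = npz["batch_onehot"]
            model.library_mean_ = npz["library_mean"]
            model.n_genes_ = int(npz["n_genes"])
            model.n_batches_ = int(npz["n_batches"])
            model.test_loglik_ = float(npz["test_loglik"])
            self.vae = model
            return
        model.fit(self.reference)
        store = {
            "latent_mean": model.latent_mean_,
            "latent_sd": model.latent_sd_,
            "latent_sample": model.latent_sample_,
            "batch_onehot": model.batch_onehot_,
            "library_mean": model.library_mean_,
            "n_genes": model.n_genes_,
            "n_batches": model.n_batches_,
            "test_loglik": model.test_loglik_,
        }
        _save_net(store, "enc", model.encoder_params_)
        _save_net(store, "dec", model.decoder_params_)
        np.savez_compressed(ckpt, **store)
        model.history_.to_csv(self.outdir / "vae_history.csv", index=False)
        pd.DataFrame(
            model.latent_mean_,
            index=self.reference.cell_ids,
            columns=[f"latent_{i}" for i in range(model.latent_mean_.shape[1])],
        ).to_csv(self.outdir / "latent.csv", index_label="cell_id")
        self._record(
            "vae",
            ckpt,
            {
                "best_val_elbo": model.best_val_elbo_,
                "test_loglik": model.test_loglik_,
            },
        )
        self.vae = model

    def stage_deconv(self):
        ckpt = self.outdir / "deconv.npz"
        cfg = {**self.config.get("deconv", {})}
        cfg.setdefault("random_state", self.config.get("seed", 0))
        model = BulkDeconvolver(**cfg)
        if self._stage_done("deconv"):
            npz = np.load(ckpt)
            model.fractions_ = npz["fractions"]
            model.capture_rate_ = npz["capture_rate"]
            model.shift_ = npz["shift"]
            model.dispersion_ = npz["dispersion"]
            model.loglik_ = float(npz["loglik"])
            self.deconv = model
            return
        model.fit(self.bulk, self.vae)
        np.savez_compressed(
            ckpt,
            fractions=model.fractions_,
            capture_rate=model.capture_rate_,
            shift=model.shift_,
            dispersion=model.dispersion_,
            loglik=model.loglik_,
        )
        pd.DataFrame(
            {
                "gene": self.reference.gene_names,
                "capture_rate": model.capture_rate_,
                "shift": model.shift_,
                "dispersion": model.dispersion_,
            }
        ).to_csv(self.outdir / "gene_parameters.csv", index=False)
        self._record("deconv", ckpt, {"loglik": model.loglik_})
        self.deconv = model

    def stage_hazard(self):
        ckpt = self.outdir / "hazard.npz"
        cfg = {**self.config.get("hazard", {})}
        cfg.setdefault("random_state", self.config.get("seed", 0))
        model = CellHazardCox(**cfg)
        if self._stage_done("hazard"):
            npz = np.load(ckpt)
            model.beta_ = npz["beta"]
            model.eta_ = npz["eta"]
            model.cindex_test_ = float(npz["cindex_test"])
            model.ibs_test_ = float(npz["ibs_test"])
            self.cox = model
            return
        model.fit(self.vae.latent_mean_, self.deconv.fractions_, self.survival)
        np.savez_compressed(
            ckpt,
            beta=model.beta_,
            eta=model.eta_,
            cindex_test=model.cindex_test_,
            ibs_test=model.ibs_test_,
        )
        pd.DataFrame(
            {"cell_id": self.reference.cell_ids, "beta": model.beta_}
        ).to_csv(self.outdir / "contributions.csv", index=False)
        pd.DataFrame(
            {"sample_id": self.survival.sample_ids, "eta": model.eta_}
        ).to_csv(self.outdir / "eta.csv", index=False)
        metrics = {
            "cindex_train": model.cindex_train_,
            "cindex_test": model.cindex_test_,
            "ibs_test": model.ibs_test_,
            "ties": model.ties_,
        }
        (self.outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        self._record("hazard", ckpt, metrics)
        self.cox = model

    def stage_downstream(self):
        cfg = self.config.get("downstream", {})
        if self.reference.cluster_labels is not None:
            report = permutation_importance(
                self.cox.beta_,
                self.deconv.fractions_,
                self.reference.cluster_labels,
                self.survival,
                n_perm=cfg.get("n_perm", 10),
                seed=self.config.get("seed", 0),
            )
            report.table.to_csv(self.outdir / "permutation_importance.csv", index=False)
        genes = gene_contribution_correlation(
            self.vae.decoder_matrix(),
            self.cox.beta_,
            top_k=cfg.get("top_k", 30),
            gene_names=self.reference.gene_names,
        )
        genes.table.to_csv(self.outdir / "gene_correlations.csv", index=False)
        if self.config.get("spots") is not None:
            spots_df = load_matrix(self.config["spots"], self.reference.gene_names)
            E, _, idx = align_genes(spots_df, self.reference.gene_names)
            spot_model = SpotDeconvolver(
                **{**self.config.get("deconv", {}),
                   "random_state": self.config.get("seed", 0)}
            )
            spot_model.fit(E, self.vae)
            smap = spatial_hazard(spot_model.fractions_, self.cox.beta_)
            pd.DataFrame(
                {
                    "spot_id": spots_df.index,
                    "raw": smap.raw,
                    "clipped": smap.clipped,
                }
            ).to_csv(self.outdir / "spatial_hazard.csv", index=False)

    def run(self, until: str = "downstream"):
        order = ["data", "vae", "deconv", "hazard", "downstream"]
        for stage in order[: order.index(until) + 1]:
            log.info("running stage %s", stage)
            getattr(self, f"stage_{stage}")()
        return self.manifest


def run_pipeline(config: dict, outdir, until: str = "downstream"):
    """Execute the sequential pipeline; returns the metrics manifest."""
    return Pipeline(config, outdir).run(until=until)
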