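"""Shared fixtures.

The session-scoped "study" fixtures fit the full three-stage pipeline once on
a simulated dataset (5 clusters, 300 pseudo-bulk samples, strong two-cluster
hazard signal) and are reused by every test that needs a fitted model.
"""

import numpy as np
import pytest

from cellhazard import synthetic
from cellhazard.deconv import BulkDeconvolver
from cellhazard.hazard import CellHazardCox
from cellhazard.vae import CountVAE

# Simulation design for the recovery experiments: 5 clusters, two batches,
# 300 pseudo-bulk samples of 1000 cells each, Dirichlet(1) proportions, 20%
# censoring. The hazard signal lives in clusters 0 (+2.5) and 1 (-2.5).
STUDY = {
    "n_cells": 1000,
    "n_genes": 200,
    "n_clusters": 5,
    "n_batches": 2,
    "n_bulk": 300,
    "cells_per_sample": 1000,
    "concentration": 1.0,
    "coefficients": np.array([2.5, -2.5, 0.0, 0.0, 0.0]),
    "baseline_rate": 1.0,
    "censor_fraction": 0.2,
    "seed": 0,
}


@pytest.fixture(scope="session")
def study_data():
    s = STUDY
    full, truth = synthetic.generate_reference(
        s["n_cells"], s["n_genes"], s["n_clusters"], s["n_batches"], seed=s["seed"]
    )
    reference, bulk_source = synthetic.split_reference(full, 0.5, seed=s["seed"] + 1)
    bulk, proportions = synthetic.generate_pseudobulk(
        bulk_source,
        s["n_bulk"],
        s["concentration"],
        seed=s["seed"] + 2,
        cells_per_sample=s["cells_per_sample"],
    )
    survival = synthetic.simulate_survival(
        proportions,
        s["coefficients"],
        s["baseline_rate"],
        s["censor_fraction"],
        seed=s["seed"] + 3,
    )
    return {
        "reference": reference,
        "bulk_source": bulk_source,
        "bulk": bulk,
        "proportions": proportions,
        "survival": survival,
        "coefficients": s["coefficients"],
    }


@pytest.fixture(scope="session")
def fitted_vae(study_data):
    return CountVAE(random_state=STUDY["seed"]).fit(study_data["reference"])


@pytest.fixture(scope="session")
def fitted_deconv(study_data, fitted_vae):
    return BulkDeconvolver(random_state=STUDY["seed"]).fit(
        study_data["bulk"], fitted_vae
    )


@pytest.fixture(scope="session")
def fitted_cox(study_data, fitted_vae, fitted_deconv):
    return CellHazardCox(random_state=STUDY["seed"]).fit(
        fitted_vae.latent_mean_, fitted_deconv.fractions_, study_data["survival"]
    )


@pytest.fixture(scope="session")
def small_reference():
    """Small clustered reference for fast unit fits."""
    full, _ = synthetic.generate_reference(300, 80, 3, 2, seed=7)
    return full


@pytest.fixture(scope="session")
def small_vae(small_reference):
    return CountVAE(max_epochs=120, random_state=7).fit(small_reference)
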