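"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CellReference:
    """Raw single-cell counts plus per-cell batch (and optional cluster) labels.

    counts        : (C, G) non-negative integer matrix
    batch         : (C,) integer batch codes in [0, n_batches)
    cluster_labels: optional (C,) integer cluster codes
    cell_ids      : (C,) string identifiers
    gene_names    : (G,) string identifiers
    """

    counts: np.ndarray
    batch: np.ndarray
    cluster_labels: np.ndarray | None = None
    cell_ids: np.ndarray | None = None
    gene_names: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (cells x genes) matrix")
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"counts contain a negative entry at cell {bad[0]}, gene {bad[1]}"
            )
        if np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts must be integers")
        self.batch = np.asarray(self.batch, dtype=int)
        if self.batch.shape[0] != self.counts.shape[0]:
            raise ValueError("batch labels must have one entry per cell")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)
        C, G = self.counts.shape
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(C)])
        if self.gene_names is None:
            self.gene_names = np.array([f"gene_{j}" for j in range(G)])

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_batches(self) -> int:
        return int(self.batch.max()) + 1

    @property
    def batch_onehot(self) -> np.ndarray:
        """(C, P) one-hot encoding of the batch labels."""
        oh = np.zeros((self.n_cells, self.n_batches))
        oh[np.arange(self.n_cells), self.batch] = 1.0
        return oh

    @property
    def library_mean(self) -> np.ndarray:
        """l_c: per-cell mean count over genes (carries the library scale)."""
        return self.counts.mean(axis=1)

    def subset(self, idx: np.ndarray) -> "CellReference":
        return CellReference(
            counts=self.counts[idx],
            batch=self.batch[idx],
            cluster_labels=None if self.cluster_labels is None else self.cluster_labels[idx],
            cell_ids=self.cell_ids[idx],
            gene_names=self.gene_names,
        )


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes for the bulk samples.

    time : (B,) strictly positive observed times
    event: (B,) 1 = event observed (death), 0 = censored
    """

    time: np.ndarray
    event: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicator must be 0 or 1")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"sample_{i}" for i in range(len(self.time))])

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalTable":
        return SurvivalTable(self.time[idx], self.event[idx], self.sample_ids[idx])

    def tie_groups(self):
        """Tie structure of the event times.

        Returns (d, r): for every sample b with event[b] == 1, d[b] is the
        number of events sharing time T_b and r[b] its 1-based position within
        that tie group (r[b] = 1 when d[b] = 1). Censored entries get d = r = 0.
        """
        d = np.zeros(len(self), dtype=int)
        r = np.zeros(len(self), dtype=int)
        ev = np.flatnonzero(self.event == 1)
        for t in np.unique(self.time[ev]):
            members = ev[self.time[ev] == t]
            d[members] = len(members)
            r[members] = np.arange(1, len(members) + 1)
        return d, r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the simulators, for scoring recovered estimates."""

    cluster_labels: np.ndarray | None = None
    true_proportions: np.ndarray | None = None
    true_coefficients: np.ndarray | None = None
    baseline_rate: float | None = None
    censor_fraction: float | None = None
    seed: int | None = None
    cluster_log_means: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.true_proportions is not None:
            rows = self.true_proportions.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                raise ValueError("true_proportions rows must sum to 1")
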