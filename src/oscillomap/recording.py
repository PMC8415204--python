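"""Core in-memory containers for the envelope-connectivity pipeline.

The pipeline's data flow is

    EpochedRecording --(band-pass, orthogonalize, Hilbert, downsample)-->
    EnvelopeSet --(correlate)--> ConnectivityMatrix
    EnvelopeSet --(coefficient of variation)--> ActivityMap

Each container carries its (subject, drug, session) labels so that tidy
long-format exports and the study-level statistics can be assembled
without external bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .bands import BandDefinition

#: Valid processing stages for a connectivity matrix.
CONNECTIVITY_STAGES = ("r", "fisher_z", "z_surrogate", "z_session")

#: Valid processing stages for an activity map.
ACTIVITY_STAGES = ("cov", "z_session")


@dataclass(frozen=True)
class RecordingMeta:
    """Design labels of one recording: who, which arm, which session."""

    subject: str
    drug: str
    session: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.subject, self.drug, self.session)


@dataclass
class EpochedRecording:
    """Node x time array with fixed sampling rate and epoch structure.

    ``data`` has shape (n_nodes, n_samples); ``n_samples`` must be an
    integer multiple of ``fs * epoch_length_s``.
    """

    data: np.ndarray
    fs: float
    epoch_length_s: float = 2.0
    node_labels: Optional[list[str]] = None
    meta: Optional[RecordingMeta] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (nodes x time), got {self.data.ndim}-D")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 nodes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        samples_per_epoch = self.fs * self.epoch_length_s
        if abs(samples_per_epoch - round(samples_per_epoch)) > 1e-9:
            raise ValueError(
                f"fs * epoch_length_s = {samples_per_epoch} is not an integer"
            )
        if self.data.shape[1] % round(samples_per_epoch):
            raise ValueError(
                f"recording length {self.data.shape[1]} is not divisible by the "
                f"epoch length ({round(samples_per_epoch)} samples)"
            )
        if self.node_labels is None:
            self.node_labels = [f"node{i:03d}" for i in range(self.data.shape[0])]
        if len(self.node_labels) != self.data.shape[0]:
            raise ValueError("node_labels length does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return round(self.fs * self.epoch_length_s)

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.samples_per_epoch

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def epoch_view(self) -> np.ndarray:
        """Return a (n_nodes, n_epochs, samples_per_epoch) view of the data."""
        return self.data.reshape(self.n_nodes, self.n_epochs, self.samples_per_epoch)

    def with_data(self, data: np.ndarray) -> "EpochedRecording":
        return replace(self, data=data)


@dataclass
class EnvelopeSet:
    """Per-node amplitude envelopes at 1-s resolution for one band.

    ``env`` has shape (n_nodes, T) with T = floor(recording duration in
    seconds); values are nonnegative by construction.
    """

    env: np.ndarray
    band: BandDefinition
    resolution_s: float = 1.0
    node_labels: Optional[list[str]] = None
    meta: Optional[RecordingMeta] = None

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        if self.env.ndim != 2:
            raise ValueError("env must be 2-D (nodes x time)")
        if not np.all(np.isfinite(self.env)):
            raise ValueError("envelope contains non-finite values")
        if np.any(self.env < 0):
            raise ValueError("envelope values must be nonnegative")
        if self.node_labels is None:
            self.node_labels = [f"node{i:03d}" for i in range(self.env.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.env.shape[0]

    @property
    def n_samples(self) -> int:
        return self.env.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node edge-strength matrix with a processing stage tag.

    The diagonal is stored as NaN: self-connectivity is undefined.
    ``stage`` tracks how far along the normalization chain the values are:
    raw Pearson r -> Fisher z -> surrogate-normalised z -> session-standardised z.
    """

    values: np.ndarray
    stage: str
    band: BandDefinition
    node_labels: Optional[list[str]] = None
    meta: Optional[RecordingMeta] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in CONNECTIVITY_STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {CONNECTIVITY_STAGES}"
            )
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.all(np.isfinite(v[off])):
            raise ValueError("off-diagonal connectivity values must be finite")
        if not np.allclose(v[off], v.T[off], equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if self.node_labels is None:
            self.node_labels = [f"node{i:03d}" for i in range(v.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def upper_values(self) -> np.ndarray:
        """The n(n-1)/2 unique edge values in row-major (i<j) order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]

    def with_values(self, values: np.ndarray, stage: str) -> "ConnectivityMatrix":
        return replace(self, values=values, stage=stage)


@dataclass
class ActivityMap:
    """Per-node envelope coefficient-of-variation values for one band/recording."""

    values: np.ndarray
    band: BandDefinition
    stage: str = "cov"
    node_labels: Optional[list[str]] = None
    meta: Optional[RecordingMeta] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in ACTIVITY_STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {ACTIVITY_STAGES}"
            )
        if self.values.ndim != 1:
            raise ValueError("activity values must be a 1-D per-node vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        if self.stage == "cov" and np.any(self.values < 0):
            raise ValueError("coefficient-of-variation values must be nonnegative")
        if self.node_labels is None:
            self.node_labels = [f"node{i:03d}" for i in range(len(self.values))]

    @property
    def n_nodes(self) -> int:
        return len(self.values)


def upper_triangle_indices(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the unique (i<j) edges of an n-node matrix."""
    return np.triu_indices(n_nodes, k=1)
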