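"""Domain containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd


@dataclass
class EmgTrial:
    """A raw multi-channel surface-EMG recording of one STS repetition.

    ``samples`` is time x channels in mV; ``onset_sample`` / ``offset_sample``
    delimit the seat-off-to-stand epoch that downstream stages analyse.
    """

    subject: str
    condition: str
    trial: int
    fs: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    onset_sample: int
    offset_sample: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        n = self.samples.shape[0]
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_labels):
            raise ValueError("samples must be time x channels")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (0 <= self.onset_sample < self.offset_sample <= n):
            raise ValueError(
                f"event markers [{self.onset_sample}, {self.offset_sample}] "
                f"outside signal of length {n}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject, self.condition, self.trial)


@dataclass
class SynthGroundTruth:
    """Planted quantities behind one synthetic trial.

    ``W_true`` (muscles x k) and ``C_true`` (k x time) are the spatial and
    temporal synergy factors the generator modulated the carriers with;
    ``ecg_template`` maps trunk channel label -> injected artifact waveform;
    ``precision_true`` is populated only for Gaussian weight observations.
    """

    W_true: np.ndarray
    C_true: np.ndarray
    ecg_template: dict[str, np.ndarray] = field(default_factory=dict)
    precision_true: Optional[np.ndarray] = None
    onset_sample: int = 0
    offset_sample: int = 0

    def envelope(self) -> np.ndarray:
        """Planted per-channel envelope, time x channels."""
        return (self.W_true @ self.C_true).T


@dataclass
class ProcessedTrial:
    """Normalized activation envelope on the 0-100 % STS time base."""

    subject: str
    condition: str
    trial: int
    channel_labels: tuple[str, ...]
    envelope: np.ndarray  # n_points x channels, values in [0, 1]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.channel_labels = tuple(self.channel_labels)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject, self.condition, self.trial)


@dataclass
class SynergyDecomposition:
    """NMF factors of one envelope matrix M ~ W C.

    W is muscles x k (relative activation levels), C is k x time with each
    row scaled to unit maximum, so W carries the amplitude and is comparable
    across trials.
    """

    W: np.ndarray
    C: np.ndarray
    k: int
    vaf: float
    seed: int
    n_restarts: int
    converged: bool
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class WeightObservations:
    """Per-trial spatial weight vectors for one synergy and condition.

    Rows are subject-trial observations, columns are muscles; this is the
    input to Gaussian graphical model estimation.
    """

    condition: str
    synergy_index: int
    matrix: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.channel_labels):
            raise ValueError("matrix must be observations x muscles")

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.channel_labels))


@dataclass
class PcorNetwork:
    """Sparse partial-correlation network over muscles.

    ``weights`` holds the signed partial correlations -theta_ij /
    sqrt(theta_ii theta_jj) of the selected precision matrix; a zero entry
    means conditional independence given the remaining muscles.
    """

    channel_labels: tuple[str, ...]
    weights: np.ndarray
    precision: np.ndarray
    rho_selected: float
    ebic: float
    gamma: float
    n_obs: int

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.weights = np.asarray(self.weights, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.channel_labels)

    @property
    def possible_edges(self) -> int:
        p = self.n_nodes
        return p * (p - 1) // 2

    @property
    def nonzero_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.channel_labels)
        return pd.DataFrame(self.weights, index=labels, columns=labels)


@dataclass
class SimilarityResult:
    """DeltaCon comparison of two networks on a shared node set."""

    pair: tuple[str, str]
    distance: float
    similarity: float
    epsilon: float


@dataclass
class BootstrapSummary:
    """Edge confidence intervals and pairwise difference flags."""

    n_boot: int
    alpha: float
    seed: int
    edge_table: pd.DataFrame
    edge_diff: pd.DataFrame
    centrality_diff: dict[str, pd.DataFrame]
    n_failed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)
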