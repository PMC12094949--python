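"""Configuration objects and shared domain types.

The defaults mirror the recording and analysis settings of the sit-to-stand
(STS) study this package models: 8 muscles sampled at 1,000 Hz, an 80-200 Hz
zero-phase Butterworth band, a 0.2 s moving average, synergy counts searched
over k = 1..7, EBIC hyperparameter gamma = 0.5, and 200 bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

#: SENIAM-placed muscles, distal to proximal: soleus, tibialis anterior,
#: gastrocnemius lateralis, rectus femoris, vastus lateralis, biceps femoris
#: (long head), rectus abdominis, erector spinae longissimus.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "SOL", "TA", "GASL", "RF", "VASL", "BFL", "RA", "ESL",
)

#: Trunk channels that pick up the cardiac (ECG) artifact.
TRUNK_CHANNELS: tuple[str, ...] = ("RA", "ESL")

CONDITIONS: tuple[str, ...] = ("self", "robot")


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class SynthEmgConfig:
    """Parameters of the synthetic sit-to-stand EMG generator.

    Attributes
    ----------
    n_subjects : number of simulated subjects.
    trials_per_condition : repetitions of the STS movement per condition.
    channel_labels : muscle names, one recording channel each.
    k_true : number of planted muscle synergies.
    fs : sampling rate in Hz.
    duration_s : trial length in seconds; the STS epoch occupies the
        central 80 % of the trial.
    snr_db : envelope signal-to-noise ratio of the additive measurement
        noise, in dB (``inf`` disables the noise).
    drift_sd : half-normal scale of the per-trial slow gain drift that
        makes some executions sloppier than others (0 disables it).
    snr_jitter_db : SD of the per-trial normal jitter applied to snr_db,
        modelling trials recorded cleaner or noisier than average.
    ecg_amplitude : RMS of the cardiac artifact on the trunk channels,
        relative to the clean channel RMS (0 disables it).
    heart_rate_bpm : cardiac rate of the simulated ECG.
    dominant_share : fraction of planted-envelope energy carried by the
        first synergy.
    seed : base RNG seed; every draw derives from it deterministically.
    """

    n_subjects: int = 6
    trials_per_condition: int = 5
    n_muscles: int = 8
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    k_true: int = 2
    fs: float = 1000.0
    duration_s: float = 3.0
    snr_db: float = 20.0
    ecg_amplitude: float = 0.5
    heart_rate_bpm: float = 75.0
    dominant_share: float = 0.8
    drift_sd: float = 0.13
    snr_jitter_db: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.n_muscles = len(self.channel_labels)
        if self.k_true < 1:
            raise ConfigError(f"k_true must be >= 1, got {self.k_true}")
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 2 * 400.0:
            # the 80-200 Hz analysis band must sit inside an 20-450 Hz
            # carrier band, which needs fs > 800 Hz
            raise ConfigError(f"fs must exceed 800 Hz, got {self.fs}")
        if not (0.0 < self.dominant_share <= 1.0):
            raise ConfigError(
                f"dominant_share must lie in (0, 1], got {self.dominant_share}"
            )
        if not (30.0 <= self.heart_rate_bpm <= 200.0):
            raise ConfigError(
                f"heart_rate_bpm must lie in [30, 200], got {self.heart_rate_bpm}"
            )
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ConfigError("n_subjects and trials_per_condition must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def trunk_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, lab in enumerate(self.channel_labels) if lab in TRUNK_CHANNELS
        )


@dataclass
class PreprocessParams:
    """Settings of the envelope-extraction chain."""

    band_low: float = 80.0
    band_high: float = 200.0
    filter_order: int = 4
    ma_window_s: float = 0.2
    ssa_window_s: float = 0.25
    cardiac_band: tuple[float, float] = (0.7, 2.5)
    ssa_components: int = 20
    n_points: int = 101
    ssa_channels: tuple[str, ...] = TRUNK_CHANNELS

    def __post_init__(self) -> None:
        if not (0.0 < self.band_low < self.band_high):
            raise ConfigError("need 0 < band_low < band_high")
        if self.ma_window_s <= 0 or self.ssa_window_s <= 0:
            raise ConfigError("window lengths must be positive")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (simulate through similarity)."""

    synth: SynthEmgConfig = field(default_factory=SynthEmgConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    nmf_restarts: int = 20
    vaf_restarts: int = 3
    nmf_max_iter: int = 2000
    nmf_tol: float = 1.0e-6
    alpha: float = 0.05
    gamma: float = 0.5
    path_points: int = 100
    path_ratio: float = 0.01
    n_boot: int = 200
    seed: int = 0
    k_true_by_condition: dict[str, int] = field(
        default_factory=lambda: {"self": 2, "robot": 3}
    )

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ConfigError("n_boot must be >= 2")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SynthEmgConfig(**raw.pop("synth", {}))
        pre = PreprocessParams(**raw.pop("preprocess", {}))
        kwargs = dict(raw)
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(kwargs["k_range"])
        return cls(synth=synth, preprocess=pre, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["channel_labels"] = list(self.synth.channel_labels)
        return d


def derive_seed(base: int, *tokens: int | str) -> int:
    """Fan a base seed out into independent per-stage seeds.

    Strings are hashed stably (sum of code points), so the same
    ``(base, tokens)`` always yields the same child seed.
    """
    keys = [int(base) & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            keys.append(sum((i + 1) * ord(c) for i, c in enumerate(t)) & 0x7FFFFFFF)
        else:
            keys.append(int(t) & 0x7FFFFFFF)
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def rng_from(base: int, *tokens: int | str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base, *tokens))
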