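"""Synthetic sit-to-stand EMG and Gaussian weight observations.

The generator emulates the measurement chain of the study design this
package targets: eight SENIAM-placed muscles sampled at 1,000 Hz while a
subject stands up five times per condition (unassisted "self" vs.
robot-assisted "robot").  Each channel is a broadband carrier (surface-EMG
interference pattern) amplitude-modulated by a planted synergy envelope
``W_true @ C_true``, contaminated by a quasi-periodic ECG artifact on the
trunk channels (RA, ESL) and by white measurement noise.  A separate
generator draws multivariate-Gaussian spatial-weight observations from a
known sparse precision matrix for network-recovery experiments.

Every function is a pure function of its arguments: the same configuration
and identifiers reproduce the same samples bit for bit.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .config import ConfigError, SynthEmgConfig, TRUNK_CHANNELS, rng_from
from .types import EmgTrial, SynthGroundTruth, WeightObservations

__all__ = [
    "generate_ecg",
    "generate_emg_trial",
    "generate_dataset",
    "generate_weight_observations",
    "chain_precision",
]

#: Fraction of the trial occupied by the STS movement epoch.
_EPOCH_START_FRAC = 0.1
_EPOCH_STOP_FRAC = 0.9

#: Carrier band of the surface-EMG interference pattern, Hz.
_CARRIER_BAND = (20.0, 450.0)


def _qrs_template(fs: float) -> np.ndarray:
    """Stylised QRS complex: small Q dip, sharp R peak, S undershoot."""
    t = np.arange(-0.06, 0.06 + 0.5 / fs, 1.0 / fs)
    g = lambda mu, sd: np.exp(-0.5 * ((t - mu) / sd) ** 2)  # noqa: E731
    return -0.2 * g(-0.025, 0.008) + 1.0 * g(0.0, 0.01) - 0.3 * g(0.03, 0.009)


def generate_ecg(
    fs: float,
    heart_rate_bpm: float,
    duration_s: float,
    amplitude: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Quasi-periodic ECG-like spike train.

    A QRS-shaped template is placed at beat times with small beat-to-beat
    jitter (SD 3 % of the beat period), so the repetition rate matches
    ``heart_rate_bpm`` up to jitter.  ``amplitude`` scales the R-peak height;
    0 returns silence.
    """
    if not (30.0 <= heart_rate_bpm <= 200.0):
        raise ConfigError(f"heart_rate_bpm must lie in [30, 200], got {heart_rate_bpm}")
    n = int(round(duration_s * fs))
    out = np.zeros(n)
    if amplitude == 0.0 or n == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    period = 60.0 / heart_rate_bpm
    template = _qrs_template(fs)
    half = len(template) // 2
    # first beat lands at a random phase inside one period
    t_beat = rng.uniform(0.0, period)
    while t_beat < duration_s + period:
        center = int(round(t_beat * fs))
        lo, hi = center - half, center - half + len(template)
        s_lo, s_hi = max(lo, 0), min(hi, n)
        if s_lo < s_hi:
            out[s_lo:s_hi] += template[s_lo - lo : s_hi - lo]
        t_beat += period * (1.0 + 0.03 * rng.standard_normal())
    return amplitude * out


def _activation_profiles(
    k: int,
    n_samples: int,
    onset: int,
    offset: int,
    centers_frac: np.ndarray,
    widths_frac: np.ndarray,
    tonic: float,
) -> np.ndarray:
    """Temporal patterns C_true: staggered Gaussian bursts inside the epoch.

    Each synergy fires once during the movement; the first synergy also
    carries a tonic plateau over the whole epoch (``tonic`` relative to its
    burst peak), modelling the sustained whole-body extension drive on top
    of which the phasic bursts ride.  Rows have unit maximum.
    """
    t = np.arange(n_samples, dtype=float)
    span = offset - onset
    C = np.zeros((k, n_samples))
    for j in range(k):
        center = onset + span * centers_frac[j]
        C[j] = np.exp(-0.5 * ((t - center) / (widths_frac[j] * span)) ** 2)
    if tonic > 0.0:
        # smooth box over the movement epoch
        edge = 0.05 * span
        plateau = 1.0 / (1.0 + np.exp(-(t - onset) / edge))
        plateau *= 1.0 / (1.0 + np.exp((t - offset) / edge))
        C[0] += tonic * plateau
    C /= C.max(axis=1, keepdims=True)
    return C


def _spatial_weights(k: int, n_muscles: int, rng: np.random.Generator) -> np.ndarray:
    """Spatial patterns W_true.

    The first synergy recruits every muscle (whole-body extension drive);
    later synergies each dominate a disjoint round-robin subset of muscles
    over a small common baseline — the classic picture of phase-specific
    recruitment modules.
    """
    W = 0.05 + 0.1 * rng.uniform(size=(n_muscles, k))
    W[:, 0] += 0.5 * (1.0 + rng.uniform(size=n_muscles))
    for i in range(n_muscles):
        W[i, i % k] += 0.7 + 0.4 * rng.uniform()
    return W


def _scale_dominant(W: np.ndarray, C: np.ndarray, share: float) -> np.ndarray:
    """Scale synergy 1 so it carries ``share`` of the planted envelope energy.

    Solves ||a P||^2 / ||a P + R||^2 = share for the scale a, where
    P = W_1 C_1 and R is the remaining synergies' envelope, including the
    cross term (the tonic plateau overlaps the other bursts, so the
    separable approximation would be off).
    """
    k = W.shape[1]
    if k == 1 or share >= 1.0:
        return W
    P = np.outer(W[:, 0], C[0])
    R = W[:, 1:] @ C[1:]
    p = float(np.sum(P**2))
    c = float(np.sum(P * R))
    r = float(np.sum(R**2))
    s = share
    a1 = (s * c + np.sqrt(s**2 * c**2 + p * (1.0 - s) * s * r)) / (p * (1.0 - s))
    W = W.copy()
    W[:, 0] *= a1
    return W


def _carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise carrier (20-450 Hz)."""
    low, high = _CARRIER_BAND
    high = min(high, 0.45 * fs)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


#: Tonic plateau level of synergy 1, relative to its burst peak.
_TONIC_LEVEL = 0.6

#: Trial-to-trial motor variability: log-normal SD of the spatial weights
#: and timing jitter of the burst centers/widths (fractions of the epoch).
_WEIGHT_JITTER_SD = 0.06
_CENTER_JITTER_SD = 0.012
_WIDTH_JITTER_SD = 0.04

#: Trial-to-trial model violation: each muscle's envelope drifts by a slow
#: multiplicative gain curve (electrode/physiology nonstationarity).  The
#: drift SD is itself drawn per trial (half-normal, truncated), so some
#: executions are clean and some sloppy — this is what spreads the VAF of
#: real trials.  The per-trial scale is drawn from config.drift_sd.
_DRIFT_CAP = 0.15
_DRIFT_CUTOFF_HZ = 2.0


def _base_centers_widths(k: int) -> tuple[np.ndarray, np.ndarray]:
    centers = np.empty(k)
    centers[0] = 0.40
    if k > 1:
        centers[1:] = np.linspace(0.22, 0.85, k - 1) if k > 2 else [0.70]
    widths = np.full(k, 0.07)
    widths[0] = 0.18
    return centers, widths


def ground_truth_for(
    config: SynthEmgConfig,
    condition: str,
    subject: str | None = None,
    trial: int | None = None,
) -> SynthGroundTruth:
    """Planted synergy factors for one condition.

    Without ``subject``/``trial`` the condition-level factors are returned;
    with them, trial-specific motor variability is applied: multiplicative
    log-normal jitter on the spatial weights and small timing jitter on the
    activation bursts, so repeated movements differ the way repeated human
    executions do.
    """
    n = config.n_samples
    onset = int(round(_EPOCH_START_FRAC * n))
    offset = int(round(_EPOCH_STOP_FRAC * n))
    k = config.k_true
    rng = rng_from(config.seed, "ground-truth", condition)
    W = _spatial_weights(k, config.n_muscles, rng)
    centers, widths = _base_centers_widths(k)
    if subject is not None and trial is not None:
        jit = rng_from(config.seed, "motor-var", subject, condition, trial)
        W = W * np.exp(_WEIGHT_JITTER_SD * jit.standard_normal(W.shape))
        centers = centers + _CENTER_JITTER_SD * jit.standard_normal(k)
        widths = widths * np.exp(_WIDTH_JITTER_SD * jit.standard_normal(k))
    C = _activation_profiles(k, n, onset, offset, centers, widths, _TONIC_LEVEL)
    W = _scale_dominant(W, C, config.dominant_share)
    return SynthGroundTruth(
        W_true=W, C_true=C, onset_sample=onset, offset_sample=offset
    )


def generate_emg_trial(
    config: SynthEmgConfig, subject: str, condition: str, trial: int
) -> tuple[EmgTrial, SynthGroundTruth]:
    """Simulate one raw EMG trial plus its ground truth.

    The per-channel signal is ``gain * envelope(t) * carrier(t)`` with the
    envelope taken from the planted synergy model, plus the ECG artifact on
    trunk channels and white noise at ``config.snr_db``.
    """
    config.__post_init__()  # re-validate in case fields were mutated
    gt = ground_truth_for(config, condition, subject=subject, trial=trial)
    n = config.n_samples
    env = gt.envelope()  # time x channels
    # per-subject amplitude factor (height/weight/skin impedance effects)
    gain = float(np.exp(0.3 * rng_from(config.seed, "gain", subject).standard_normal()))

    rng = rng_from(config.seed, "trial", subject, condition, trial)
    # per-trial global effort scale: faster/stronger executions raise every
    # muscle's amplitude together.  VAF is scale-invariant, so this only
    # shows up as the strong positive co-variation of spatial weights
    # across trials that the network stage feeds on.
    effort = float(np.exp(0.25 * rng.standard_normal()))
    # slow multiplicative gain drift per muscle (model violation)
    drift_sd = min(abs(config.drift_sd * rng.standard_normal()), _DRIFT_CAP)
    sos_lp = signal.butter(2, _DRIFT_CUTOFF_HZ, btype="low", fs=config.fs, output="sos")
    samples = np.empty((n, config.n_muscles))
    for ch in range(config.n_muscles):
        b = signal.sosfiltfilt(sos_lp, rng.standard_normal(n))
        b /= max(b.std(), 1e-12)
        drift = np.exp(drift_sd * b)
        samples[:, ch] = (
            effort * gain * env[:, ch] * drift * _carrier(n, config.fs, rng)
        )

    # additive white measurement noise at the requested SNR; per-trial
    # jitter models recording-quality variation across repetitions
    if np.isfinite(config.snr_db):
        snr = config.snr_db + config.snr_jitter_db * rng.standard_normal()
        snr = max(snr, 5.0)
        sig_rms = np.sqrt(np.mean(samples**2, axis=0))
        noise_rms = sig_rms * 10.0 ** (-snr / 20.0)
        samples += noise_rms * rng.standard_normal((n, config.n_muscles))

    # cardiac artifact on trunk channels: one heart, channel-specific gain
    ecg_templates: dict[str, np.ndarray] = {}
    if config.ecg_amplitude > 0.0:
        base_ecg = generate_ecg(
            config.fs, config.heart_rate_bpm, config.duration_s, 1.0, rng
        )
        ecg_rms = np.sqrt(np.mean(base_ecg**2))
        for ch in config.trunk_indices:
            label = config.channel_labels[ch]
            ch_gain = 1.0 if label == TRUNK_CHANNELS[0] else 0.8
            clean_rms = np.sqrt(np.mean(samples[:, ch] ** 2))
            wave = base_ecg * (
                config.ecg_amplitude * ch_gain * clean_rms / max(ecg_rms, 1e-12)
            )
            samples[:, ch] += wave
            ecg_templates[label] = wave
    gt.ecg_template = ecg_templates

    emg = EmgTrial(
        subject=subject,
        condition=condition,
        trial=trial,
        fs=config.fs,
        channel_labels=config.channel_labels,
        samples=samples,
        onset_sample=gt.onset_sample,
        offset_sample=gt.offset_sample,
    )
    return emg, gt


def generate_dataset(
    config: SynthEmgConfig, conditions: tuple[str, ...] = ("self", "robot")
) -> tuple[list[EmgTrial], dict[str, SynthGroundTruth]]:
    """All trials of the study design: subjects x conditions x repetitions."""
    trials: list[EmgTrial] = []
    truths: dict[str, SynthGroundTruth] = {}
    for cond in conditions:
        truths[cond] = ground_truth_for(config, cond)
        for s in range(config.n_subjects):
            subject = f"S{s + 1:02d}"
            for t in range(config.trials_per_condition):
                trial, _ = generate_emg_trial(config, subject, cond, t)
                trials.append(trial)
    return trials, truths


def generate_weight_observations(
    precision_true: np.ndarray,
    n_obs: int,
    seed: int = 0,
    channel_labels: tuple[str, ...] | None = None,
    condition: str = "synthetic",
    synergy_index: int = 1,
    mean: float = 0.0,
) -> WeightObservations:
    """Draw rows from N(mean, inverse(precision_true)).

    ``mean`` shifts every coordinate by a constant, which leaves partial
    correlations untouched but lets the draws stand in for non-negative
    synergy weights when fed to synergy-level code.
    """
    Theta = np.asarray(precision_true, dtype=float)
    if Theta.ndim != 2 or Theta.shape[0] != Theta.shape[1]:
        raise ValueError("precision_true must be square")
    if not np.allclose(Theta, Theta.T, atol=1e-10):
        raise ValueError("precision_true must be symmetric")
    if n_obs < 1:
        raise ValueError(f"n_obs must be >= 1, got {n_obs}")
    try:
        np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError as err:
        raise ValueError("precision_true must be positive definite") from err
    cov = np.linalg.inv(Theta)
    cov = 0.5 * (cov + cov.T)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(
        np.full(Theta.shape[0], mean), cov, size=n_obs, method="cholesky"
    )
    if channel_labels is None:
        channel_labels = tuple(f"V{i + 1}" for i in range(Theta.shape[0]))
    return WeightObservations(
        condition=condition,
        synergy_index=synergy_index,
        matrix=X,
        channel_labels=channel_labels,
    )


def chain_precision(p: int, partial_corr: float = 0.4) -> np.ndarray:
    """Sparse chain-graph precision matrix: node i linked only to i±1.

    Off-diagonal entries are ``-partial_corr`` on the first sub/super
    diagonal of a unit-diagonal matrix, giving partial correlations equal to
    ``partial_corr`` on the chain edges and exact zeros elsewhere.
    """
    if not (0 <= abs(partial_corr) < 0.5):
        raise ValueError("need |partial_corr| < 0.5 for positive definiteness")
    Theta = np.eye(p)
    idx = np.arange(p - 1)
    Theta[idx, idx + 1] = -partial_corr
    Theta[idx + 1, idx] = -partial_corr
    return Theta
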