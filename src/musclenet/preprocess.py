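"""Raw EMG to normalized activation envelopes.

Chain: zero-phase 80-200 Hz Butterworth bandpass -> singular-spectrum
analysis (SSA) removal of the cardiac artifact on the trunk channels ->
full-wave rectification -> 0.2 s centered moving average -> per-subject,
per-muscle amplitude normalization over all of that subject's trials ->
linear time normalization of the movement epoch onto a 0-100 % grid
(101 points).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .config import PreprocessParams
from .types import EmgTrial, ProcessedTrial

__all__ = [
    "bandpass_filter",
    "remove_ecg_ssa",
    "rectify",
    "moving_average",
    "normalize_amplitude",
    "time_normalize",
    "preprocess_trials",
]


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 80.0,
    high: float = 200.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward application).

    The effective amplitude response is the squared one-pass response, so
    the nominal passband edges sit at -6 dB rather than -3 dB.
    """
    x = np.asarray(x, dtype=float)
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"band [{low}, {high}] Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs a minimum signal length for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(f"signal of length {x.shape[-1]} too short to filter")
    return signal.sosfiltfilt(sos, x)


def _truncated_svd(
    X: np.ndarray, k: int, n_iter: int = 1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomized truncated SVD (Halko-Martinsson-Tropp range finder).

    Accurate enough for SSA grouping: the leading subspace only needs to
    capture the artifact components, not resolve them to machine precision.
    """
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((X.shape[1], k + 8))
    Q = np.linalg.qr(X @ G)[0]
    for _ in range(n_iter):
        Q = np.linalg.qr(X.T @ Q)[0]
        Q = np.linalg.qr(X @ Q)[0]
    U, s, Vt = np.linalg.svd(Q.T @ X, full_matrices=False)
    return (Q @ U)[:, :k], s[:k], Vt[:k]


def _series_is_cardiac(
    series: np.ndarray, fs: float, cardiac_band: tuple[float, float]
) -> bool:
    """Does this SSA component's envelope beat inside the cardiac band?

    The rectified-and-smoothed component is Fourier analysed; the component
    is flagged cardiac when the dominant non-drift envelope frequency falls
    inside ``cardiac_band``.
    """
    env = moving_average(np.abs(series), fs, window_s=0.1)
    env = env - env.mean()
    if np.allclose(env, 0.0):
        return False
    spec = np.abs(np.fft.rfft(env * np.hanning(len(env))))
    freqs = np.fft.rfftfreq(len(env), d=1.0 / fs)
    # ignore drift below 0.3 Hz and anything far above plausible heart rates
    mask = (freqs >= 0.3) & (freqs <= 8.0)
    if not mask.any() or spec[mask].max() <= 0:
        return False
    f_peak = freqs[mask][np.argmax(spec[mask])]
    return cardiac_band[0] <= f_peak <= cardiac_band[1]


def remove_ecg_ssa(
    x: np.ndarray,
    fs: float,
    window_s: float = 0.25,
    cardiac_band: tuple[float, float] = (0.7, 2.5),
    n_components: int = 20,
) -> np.ndarray:
    """Subtract cardiac-band SSA components from a trunk-channel signal.

    The signal is embedded into an L x K trajectory (Hankel) matrix with
    window L = round(window_s * fs), decomposed by truncated SVD, and each
    leading rank-1 component is reconstructed by diagonal averaging.
    Components whose envelope periodicity is dominated by the cardiac band
    are summed and subtracted; everything outside the leading subspace is
    untouched, so EMG content is preserved.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    L = int(round(window_s * fs))
    if L < 2 or L > n // 2:
        raise ValueError(
            f"SSA window of {L} samples invalid for signal of length {n} "
            "(need 2 <= window <= n/2)"
        )
    K = n - L + 1
    X = np.lib.stride_tricks.sliding_window_view(x, L).T  # L x K, no copy
    k = min(n_components, L, K)
    U, s, Vt = _truncated_svd(X, k)
    # diagonal-averaging weights: how many antidiagonal cells map to each t
    counts = signal.fftconvolve(np.ones(L), np.ones(K))
    removed = np.zeros(n)
    for j in range(k):
        series = s[j] * signal.fftconvolve(U[:, j], Vt[j]) / counts
        if _series_is_cardiac(series, fs, cardiac_band):
            removed += series
    return x - removed


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def moving_average(x: np.ndarray, fs: float, window_s: float = 0.2) -> np.ndarray:
    """Centered moving mean; edges average over the available samples."""
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError(f"window of {window_s} s at {fs} Hz is below one sample")
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def normalize_amplitude(
    envelopes: list[np.ndarray], channel_labels: tuple[str, ...]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Scale each muscle by its maximum over all of a subject's trials.

    After scaling, the global per-muscle maximum across the trials equals
    exactly 1, which removes subject-specific amplitude factors (electrode
    impedance, anthropometry).  Returns the scaled envelopes and the
    per-channel maxima used.
    """
    if not envelopes:
        raise ValueError("no trials to normalize")
    stack_max = np.max([env.max(axis=0) for env in envelopes], axis=0)
    zero = np.nonzero(stack_max <= 0.0)[0]
    if zero.size:
        names = ", ".join(channel_labels[i] for i in zero)
        raise ValueError(f"zero maximum amplitude on channel(s): {names}")
    return [env / stack_max for env in envelopes], stack_max


def time_normalize(
    envelope: np.ndarray, onset: int, offset: int, n_points: int = 101
) -> np.ndarray:
    """Resample the [onset, offset] epoch onto a 0-100 % grid.

    Linear interpolation at ``n_points`` equally spaced sample positions,
    inclusive of both markers.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    if envelope.shape[0] == 1:
        envelope = envelope.T
    n = envelope.shape[0]
    if not (0 <= onset < offset <= n - 1):
        raise ValueError(
            f"markers [{onset}, {offset}] outside envelope of length {n}"
        )
    grid = np.linspace(onset, offset, n_points)
    base = np.arange(n, dtype=float)
    out = np.empty((n_points, envelope.shape[1]))
    for ch in range(envelope.shape[1]):
        out[:, ch] = np.interp(grid, base, envelope[:, ch])
    return out


def _trial_envelope(trial: EmgTrial, params: PreprocessParams) -> tuple[np.ndarray, list[dict]]:
    """Per-trial stages before subject-level normalization."""
    prov: list[dict] = []
    env = np.empty_like(trial.samples)
    ssa_idx = [
        i for i, lab in enumerate(trial.channel_labels) if lab in params.ssa_channels
    ]
    for ch in range(trial.samples.shape[1]):
        x = bandpass_filter(
            trial.samples[:, ch],
            trial.fs,
            params.band_low,
            params.band_high,
            params.filter_order,
        )
        if ch in ssa_idx:
            x = remove_ecg_ssa(
                x,
                trial.fs,
                params.ssa_window_s,
                params.cardiac_band,
                params.ssa_components,
            )
        env[:, ch] = moving_average(rectify(x), trial.fs, params.ma_window_s)
    prov.append(
        {
            "step": "bandpass",
            "low_hz": params.band_low,
            "high_hz": params.band_high,
            "order": params.filter_order,
        }
    )
    prov.append(
        {
            "step": "ssa_ecg_removal",
            "channels": [trial.channel_labels[i] for i in ssa_idx],
            "window_s": params.ssa_window_s,
            "cardiac_band_hz": list(params.cardiac_band),
        }
    )
    prov.append({"step": "rectify"})
    prov.append({"step": "moving_average", "window_s": params.ma_window_s})
    return env, prov


def preprocess_trials(
    trials: list[EmgTrial], params: PreprocessParams | None = None
) -> list[ProcessedTrial]:
    """Run the full chain on a set of trials.

    Amplitude normalization pools all trials of each subject (both
    conditions), so pass a subject's complete trial set in one call.
    """
    if params is None:
        params = PreprocessParams()
    raw: dict[tuple[str, str, int], tuple[np.ndarray, list[dict], EmgTrial]] = {}
    subjects: dict[str, list[tuple[str, str, int]]] = {}
    for tr in trials:
        env, prov = _trial_envelope(tr, params)
        raw[tr.key] = (env, prov, tr)
        subjects.setdefault(tr.subject, []).append(tr.key)

    out: list[ProcessedTrial] = []
    for subject, keys in subjects.items():
        envs = [raw[k][0] for k in keys]
        labels = raw[keys[0]][2].channel_labels
        scaled, maxima = normalize_amplitude(envs, labels)
        for key, env in zip(keys, scaled):
            _, prov, tr = raw[key]
            prov = prov + [
                {
                    "step": "normalize_amplitude",
                    "scope": "subject",
                    "n_trials": len(keys),
                    "channel_max": [float(m) for m in maxima],
                },
                {"step": "time_normalize", "n_points": params.n_points},
            ]
            warped = time_normalize(
                env, tr.onset_sample, min(tr.offset_sample, env.shape[0] - 1),
                params.n_points,
            )
            out.append(
                ProcessedTrial(
                    subject=tr.subject,
                    condition=tr.condition,
                    trial=tr.trial,
                    channel_labels=labels,
                    envelope=warped,
                    provenance=prov,
                )
            )
    return out
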