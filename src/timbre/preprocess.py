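"""Multichannel LFP preprocessing: analytic signal, carrier, demodulation, whitening.

The decoding pipeline represents the theta-band LFP at each electrode as a
complex analytic signal whose modulus and argument give instantaneous
amplitude and phase.  A single dominant rhythm ("theta", the first principal
component of the complex multichannel signal) serves as the carrier for
carrier-based decoding: subtracting its phase from every channel converts
absolute phases into phases relative to theta (demodulation).  Carrier-free
decoding instead consumes a whitened version of the complex signal in which
low-variance dimensions are shrunk, ridge-style.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawLFP",
    "AnalyticLFP",
    "Carrier",
    "WhitenedLFP",
    "SWREvents",
    "preprocess_lfp",
    "edge_mask",
    "extract_carrier",
    "demodulate",
    "split_complex",
    "combine_complex",
    "whiten",
    "relative_theta_power",
    "equal_count_bins",
    "detect_swr",
]


@dataclasses.dataclass
class RawLFP:
    """Raw multichannel LFP: real samples [T x N] at sampling rate ``fs``."""

    samples: np.ndarray
    fs: float
    channel_ids: list | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ValueError("raw LFP must be a [T x N] matrix with T >= 2")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("raw LFP contains non-finite values")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.samples.shape[1]))


@dataclasses.dataclass
class AnalyticLFP:
    """Complex analytic signal [T x N] at sampling rate ``fs`` (nominally 25 Hz)."""

    z: np.ndarray
    fs: float

    def __post_init__(self):
        self.z = np.atleast_2d(np.asarray(self.z, dtype=complex))
        if not np.all(np.isfinite(self.z)):
            raise ValueError("analytic LFP contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.z.shape[0]

    @property
    def n_channels(self) -> int:
        return self.z.shape[1]


@dataclasses.dataclass
class Carrier:
    """Dominant complex component (theta) of a multichannel analytic LFP."""

    theta: np.ndarray
    explained_variance_fraction: float
    channel_weights: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.explained_variance_fraction <= 1.0 + 1e-12:
            raise ValueError("explained variance fraction must lie in [0, 1]")


@dataclasses.dataclass
class WhitenedLFP:
    """Ridge-whitened complex score matrix [T x N] (columns ~ unit variance)."""

    v: np.ndarray
    epsilon: float = 1e-5


@dataclasses.dataclass
class SWREvents:
    """Sharp-wave-ripple detections from z-scored 150-250 Hz band power."""

    event_indices: np.ndarray      # sample index of each event (window centers)
    rate: float                    # events per second
    z_power: np.ndarray            # z-scored band power per window
    window_centers: np.ndarray     # sample index of each window center
    mask: np.ndarray               # z_power > threshold per window


def _zero_phase_highpass(x: np.ndarray, fs: float, cutoff: float = 2.0,
                         order: int = 2) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def _decimation_stages(q: int) -> list[int]:
    # Chebyshev IIR decimation is applied in stages of <= 10 for stability.
    stages = []
    while q > 10:
        for f in (10, 8, 7, 6, 5, 4, 3, 2):
            if q % f == 0:
                stages.append(f)
                q //= f
                break
        else:
            raise ValueError(f"cannot factor decimation ratio {q} into stages <= 10")
    if q > 1:
        stages.append(q)
    return stages


def preprocess_lfp(raw: RawLFP, fs_out: float = 25.0) -> AnalyticLFP:
    """Decimate, high-pass (2 Hz), and Hilbert-transform a raw multichannel LFP.

    Anti-aliased decimation uses an order-8 Chebyshev-I low-pass at
    0.4 * fs_out (the classic ``decimate`` filter), applied zero-phase.  The
    2 Hz second-order Butterworth high-pass removes DC and drift, and the
    Hilbert transform yields the analytic signal per channel.
    """
    if raw.samples.shape[0] < 2 * raw.fs:
        raise ValueError("need at least 2 s of data for filter warm-up")
    ratio = raw.fs / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sampling rate {raw.fs} is not an integer multiple of fs_out={fs_out}")
    q = int(round(ratio))
    x = raw.samples
    if q > 1:
        for stage in _decimation_stages(q):
            x = sps.decimate(x, stage, n=8, ftype="iir", axis=0, zero_phase=True)
    x = _zero_phase_highpass(x, fs_out)
    z = sps.hilbert(x, axis=0)
    return AnalyticLFP(z=z, fs=fs_out)


def edge_mask(n_samples: int, fs: float, edge_seconds: float = 1.0) -> np.ndarray:
    """Boolean mask flagging samples within ``edge_seconds`` of either end.

    The Hilbert transform is computed on the full session, so the first/last
    second carries filter edge effects and is excluded from training by
    default.
    """
    k = int(round(edge_seconds * fs))
    mask = np.zeros(n_samples, dtype=bool)
    mask[:k] = True
    if k > 0:
        mask[n_samples - k:] = True
    return mask


def extract_carrier(lfp: AnalyticLFP) -> Carrier:
    """First principal component of the complex LFP, scaled by its singular value.

    The SVD phase gauge is fixed deterministically by rotating so that the
    largest-magnitude channel weight is real and positive; the carrier's
    counterclockwise rotation (positive mean phase advance) is intrinsic to
    analytic signals and unaffected by this constant rotation.
    """
    z = lfp.z
    if z.shape[1] < 2:
        raise ValueError("carrier extraction needs at least 2 channels")
    u, s, vh = np.linalg.svd(z, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("cannot extract carrier from an all-zero LFP")
    w = vh[0]                      # conjugate channel weights
    jmax = int(np.argmax(np.abs(w)))
    gauge = w[jmax] / abs(w[jmax])
    theta = u[:, 0] * s[0] * gauge
    weights = np.conj(w / gauge)
    return Carrier(theta=theta,
                   explained_variance_fraction=float(s[0] ** 2 / total),
                   channel_weights=weights)


def demodulate(lfp: AnalyticLFP | np.ndarray, carrier: Carrier | np.ndarray) -> np.ndarray:
    """Subtract the carrier's phase from every channel, preserving magnitudes.

    out[t, n] = |z[t, n]| * exp(i * (angle(z[t, n]) - angle(theta[t]))).
    Zero-magnitude carrier samples take phase 0 by convention (channels pass
    through unchanged there).
    """
    z = lfp.z if isinstance(lfp, AnalyticLFP) else np.asarray(lfp)
    theta = carrier.theta if isinstance(carrier, Carrier) else np.asarray(carrier)
    if z.shape[0] != theta.shape[0]:
        raise ValueError("LFP and carrier must have the same number of samples")
    mag = np.abs(theta)
    unit = np.where(mag > 0, theta / np.where(mag > 0, mag, 1.0), 1.0)
    return z * np.conj(unit)[:, None]


def split_complex(m: np.ndarray) -> np.ndarray:
    """[T x N] complex -> [T x 2N] real: real parts first, imaginary after."""
    m = np.asarray(m)
    return np.concatenate([m.real, m.imag], axis=1)


def combine_complex(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`split_complex`."""
    m = np.asarray(m, dtype=float)
    n = m.shape[1] // 2
    return m[:, :n] + 1j * m[:, n:]


def _column_var(v: np.ndarray) -> np.ndarray:
    centered = v - v.mean(axis=0, keepdims=True)
    return np.mean(np.abs(centered) ** 2, axis=0)


def whiten(lfp: AnalyticLFP | np.ndarray, epsilon: float = 1e-5) -> WhitenedLFP:
    """Ridge-whitening of the complex LFP via its SVD score matrix.

    Columns of the score matrix U*S (ordered by descending singular value)
    are rescaled as V_i / sqrt(var(V_i) + epsilon * sum_j var(V_j)): exact
    whitening for dominant components, with the smallest (noisiest)
    dimensions shrunk toward zero instead of amplified.
    """
    z = lfp.z if isinstance(lfp, AnalyticLFP) else np.asarray(lfp, dtype=complex)
    if not np.any(z):
        raise ValueError("cannot whiten an all-zero signal")
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    var = _column_var(scores)
    denom = np.sqrt(var + epsilon * var.sum())
    denom = np.where(denom > 0, denom, 1.0)
    return WhitenedLFP(v=scores / denom, epsilon=epsilon)


def equal_count_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Assign samples to 1..n_bins equal-count bins; ties share the lowest bin.

    Generic (all-distinct) inputs produce occupancies differing by at most
    one; samples with identical values are all assigned the lowest bin any of
    them would occupy, for determinism.
    """
    values = np.asarray(values)
    t = values.shape[0]
    order = np.argsort(values, kind="stable")
    provisional = np.empty(t, dtype=int)
    provisional[order] = np.arange(t) * n_bins // t + 1
    # collapse ties onto the lowest eligible bin
    sorted_vals = values[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
    group_min = np.minimum.reduceat(provisional[order], boundaries)
    group_ids = np.cumsum(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]]) - 1
    labels = np.empty(t, dtype=int)
    labels[order] = group_min[group_ids]
    return labels


def relative_theta_power(lfp: AnalyticLFP, carrier: Carrier,
                         n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample fraction of multichannel power in the carrier, plus decile labels.

    Ratio |theta(t)|^2 / sum_n |z[t, n]|^2 (0 where the total power is 0),
    then equal-count decile assignment (1..n_bins).  Relative rather than
    absolute power is used so broadband transients do not masquerade as
    strong theta.
    """
    if lfp.z.shape[0] != carrier.theta.shape[0]:
        raise ValueError("LFP and carrier must have the same number of samples")
    total = np.sum(np.abs(lfp.z) ** 2, axis=1)
    ratio = np.zeros_like(total)
    nz = total > 0
    ratio[nz] = np.abs(carrier.theta[nz]) ** 2 / total[nz]
    return ratio, equal_count_bins(ratio, n_bins)


def detect_swr(raw: RawLFP, threshold: float = 2.0,
               band: tuple[float, float] = (150.0, 250.0),
               window_s: float = 0.05) -> SWREvents:
    """Detect sharp-wave ripples from z-scored ripple-band power.

    Band power (150-250 Hz) is estimated in 50 ms windows with 50 % overlap,
    averaged across channels and z-scored over the session.  Events are
    local maxima of the z-scored power exceeding ``threshold``.
    """
    if raw.fs < 2.4 * band[1]:
        raise ValueError(
            f"sampling rate {raw.fs} Hz too low for a {band[1]} Hz ripple band")
    sos = sps.butter(4, band, btype="bandpass", fs=raw.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.samples, axis=0)
    power = np.mean(filtered ** 2, axis=1)
    win = max(int(round(window_s * raw.fs)), 2)
    hop = max(win // 2, 1)
    n_windows = 1 + (len(power) - win) // hop
    if n_windows < 3:
        raise ValueError("signal too short for windowed ripple power")
    idx = np.arange(n_windows)[:, None] * hop + np.arange(win)[None, :]
    win_power = power[idx].mean(axis=1)
    centers = (np.arange(n_windows) * hop + win // 2).astype(int)
    sd = win_power.std()
    z = (win_power - win_power.mean()) / (sd if sd > 0 else 1.0)
    mask = z > threshold
    interior = np.flatnonzero(
        (z[1:-1] > z[:-2]) & (z[1:-1] >= z[2:]) & (z[1:-1] > threshold)) + 1
    duration = raw.samples.shape[0] / raw.fs
    return SWREvents(event_indices=centers[interior],
                     rate=len(interior) / duration,
                     z_power=z, window_centers=centers, mask=mask)
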