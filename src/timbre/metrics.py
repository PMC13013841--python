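"""Quantitative comparison layer: information, selectivity, variance, t-tests.

These statistics compare the dominant theta rhythm with the learned
position-tuned components (p-thetas) and compare decoders across
cross-validation folds whose training sets overlap (the correlated t-test).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal as sps
from scipy import stats

from .preprocess import _zero_phase_highpass

__all__ = [
    "InfoResult", "SelectivityResult", "CorrectedTTest",
    "spatial_information", "spike_analytic_signal",
    "theta_ptheta_selectivity", "variance_partition", "corrected_ttest",
    "circular_linear_slope",
]


@dataclasses.dataclass
class InfoResult:
    raw_bits: float
    shift_corrected_bits: float
    n_shifts: int


@dataclasses.dataclass
class SelectivityResult:
    """Per-neuron theta vs p-theta selectivity: s = (|w_t| - |w_p|)/(|w_t| + |w_p|).

    s = 1 when the neuron's analytic signal is explained entirely by theta,
    s = -1 when entirely by the p-theta regressor.
    """

    s: float
    w_theta: complex
    w_ptheta: complex


@dataclasses.dataclass
class CorrectedTTest:
    """Cross-validated correlated t-test over per-fold differences.

    The variance term is inflated by 1/(n-1) on top of 1/n to account for the
    dependency among overlapping training folds, which widens the test
    relative to the naive paired t.
    """

    t: float
    p1: float
    p2: float
    n: int
    mean_difference: float
    variance: float
    degenerate: bool = False


def _info_bits(response: np.ndarray, occupancy: np.ndarray,
               arms: np.ndarray) -> float:
    overall = response.mean()
    info = 0.0
    for a in arms:
        rows = occupancy == a
        p = rows.mean()
        r = response[rows].mean()
        if r > 0 and p > 0:
            ratio = r / overall
            info += p * ratio * np.log2(ratio)
    return float(info)


def spatial_information(response: np.ndarray, arm_occupancy: np.ndarray,
                        n_shifts: int = 100, seed: int = 0) -> InfoResult:
    """Arm information of a nonnegative response, with a circular-shift null.

    Info = sum_i P_i (R_i / R) log2(R_i / R) over arms i, where P_i is
    occupancy probability, R_i the mean response in arm i, R the overall
    mean.  Terms with R_i = 0 contribute 0 by continuity.  The sparse-signal
    bias is corrected by subtracting the mean information over ``n_shifts``
    circular shifts of the occupancy series (shift offsets uniform on
    [0.1 T, 0.9 T] to avoid near-identity shifts).
    """
    response = np.asarray(response, dtype=float)
    arm_occupancy = np.asarray(arm_occupancy)
    if np.any(response < 0):
        raise ValueError("response must be nonnegative")
    if response.mean() <= 0:
        raise ValueError("information undefined for a zero-mean response")
    arms = np.unique(arm_occupancy)
    if len(arms) < 2:
        raise ValueError("need at least 2 visited arms")
    raw = _info_bits(response, arm_occupancy, arms)
    rng = np.random.default_rng(seed)
    T = len(response)
    lo, hi = int(0.1 * T), int(0.9 * T)
    shifts = rng.integers(lo, max(hi, lo + 1), n_shifts)
    null = np.mean([_info_bits(response, np.roll(arm_occupancy, int(s)), arms)
                    for s in shifts])
    return InfoResult(raw_bits=raw, shift_corrected_bits=raw - float(null),
                      n_shifts=n_shifts)


def spike_analytic_signal(spike_times: np.ndarray, duration_s: float,
                          fs: float = 25.0) -> np.ndarray:
    """Complex analytic signal of a band-limited spike rate.

    Spikes are binned at ``fs``, low-pass filtered (10 Hz, 8th-order
    Butterworth, zero-phase), high-pass filtered (2 Hz, 2nd-order
    Butterworth, zero-phase), and Hilbert transformed — the same chain used
    for the LFP, so neuron and LFP signals live in a common representation.
    """
    n_bins = int(round(duration_s * fs))
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) == 0:
        warnings.warn("empty spike train: returning a zero signal")
        return np.zeros(n_bins, dtype=complex)
    counts, _ = np.histogram(spike_times, bins=np.arange(n_bins + 1) / fs)
    sos = sps.butter(8, 10.0, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, counts.astype(float))
    x = _zero_phase_highpass(x[:, None], fs)[:, 0]
    return sps.hilbert(x)


def _complex_lstsq(design: np.ndarray, target: np.ndarray,
                   ridge: float = 1e-8) -> np.ndarray:
    G = design.conj().T @ design
    scale = np.trace(G).real / G.shape[0]
    w = np.linalg.solve(G + ridge * scale * np.eye(G.shape[0]),
                        design.conj().T @ target)
    return w


def theta_ptheta_selectivity(neuron_signal: np.ndarray, theta: np.ndarray,
                             ptheta: np.ndarray) -> SelectivityResult:
    """Complex regression of a neuron's analytic signal on theta and p-theta.

    Collinear regressors (|corr| > 0.999) trigger a warning and a heavier
    ridge penalty rather than failure.
    """
    theta = np.asarray(theta)
    ptheta = np.asarray(ptheta)
    if not (np.any(theta) and np.any(ptheta)):
        raise ValueError("both regressors must be nonzero")
    design = np.column_stack([theta, ptheta])
    corr = abs(np.vdot(theta, ptheta)) / (np.linalg.norm(theta)
                                          * np.linalg.norm(ptheta))
    ridge = 1e-8
    if corr > 0.999:
        warnings.warn("theta and p-theta are nearly collinear; using ridge")
        ridge = 1e-3
    w = _complex_lstsq(design, np.asarray(neuron_signal), ridge)
    wt, wp = np.abs(w[0]), np.abs(w[1])
    s = 0.0 if wt + wp == 0 else (wt - wp) / (wt + wp)
    return SelectivityResult(s=float(s), w_theta=complex(w[0]),
                             w_ptheta=complex(w[1]))


def variance_partition(lfp_z: np.ndarray, theta: np.ndarray,
                       pthetas: np.ndarray,
                       train_mask: np.ndarray | None = None,
                       test_mask: np.ndarray | None = None) -> dict:
    """Fractions of multichannel LFP variance explained by theta vs p-thetas.

    A joint complex regression predicts every channel from [theta,
    p-theta_1..K] (joint, so theta explains away shared variance).  On the
    evaluation samples, each regressor's reconstruction variance is summed
    over channels and normalized by the total LFP variance; the K p-theta
    fractions are summed into one number.  Zero-variance regressors are
    dropped with a warning.
    """
    pthetas = np.atleast_2d(np.asarray(pthetas))
    if pthetas.shape[0] == len(theta) and pthetas.ndim == 2:
        pass
    else:
        pthetas = pthetas.T
    T = len(theta)
    train = np.ones(T, bool) if train_mask is None else train_mask
    test = np.ones(T, bool) if test_mask is None else test_mask
    regs = [np.asarray(theta)] + [pthetas[:, k] for k in range(pthetas.shape[1])]
    keep = []
    for i, r in enumerate(regs):
        if np.var(np.abs(r[train])) + np.mean(np.abs(r[train])) ** 2 > 0:
            keep.append(i)
        else:
            warnings.warn(f"dropping zero-variance regressor {i}")
    design = np.column_stack([regs[i] for i in keep])
    B = _complex_lstsq(design[train], lfp_z[train])
    total = np.sum(np.mean(np.abs(lfp_z[test]) ** 2, axis=0))
    fractions = {}
    for j, i in enumerate(keep):
        recon = np.outer(design[test][:, j], B[j])
        fractions[i] = float(np.sum(np.mean(np.abs(recon) ** 2, axis=0)) / total)
    theta_frac = fractions.get(0, 0.0)
    ptheta_frac = sum(v for i, v in fractions.items() if i > 0)
    return {"theta": theta_frac, "ptheta": ptheta_frac,
            "per_regressor": fractions}


def corrected_ttest(x: np.ndarray, sided: int = 1) -> CorrectedTTest:
    """Correlated t-test on per-fold differences x.

    t = mean(x) / sqrt(var(x) (1/n + 1/(n-1))), with n-1 degrees of freedom.
    p1 is the upper-tail probability; p2 the two-sided probability.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 folds")
    mean = x.mean()
    var = x.var(ddof=1)
    if var == 0:
        t = np.inf * np.sign(mean) if mean != 0 else 0.0
        p1 = 0.0 if mean > 0 else 1.0
        p2 = 0.0 if mean != 0 else 1.0
        return CorrectedTTest(t=float(t), p1=p1, p2=p2, n=n,
                              mean_difference=float(mean), variance=0.0,
                              degenerate=True)
    t = mean / np.sqrt(var * (1.0 / n + 1.0 / (n - 1)))
    p1 = float(stats.t.sf(t, n - 1))
    p2 = float(2 * stats.t.sf(abs(t), n - 1))
    return CorrectedTTest(t=float(t), p1=p1, p2=p2, n=n,
                          mean_difference=float(mean), variance=float(var))


def circular_linear_slope(phases: np.ndarray, x: np.ndarray,
                          slope_grid: np.ndarray | None = None) -> float:
    """Circular-linear regression slope (rad per unit of x).

    Maximizes the mean resultant length of (phase - m x) over a slope grid,
    then refines with a golden-section style local search.  Used to recover
    the phase-precession slope from simulated spike phases.
    """
    phases = np.asarray(phases)
    x = np.asarray(x)
    span = np.ptp(x)
    if span == 0:
        raise ValueError("x has no extent")
    if slope_grid is None:
        mmax = 4 * np.pi / span
        slope_grid = np.linspace(-mmax, mmax, 2001)

    def resultant(m):
        return np.abs(np.mean(np.exp(1j * (phases - m * x))))

    vals = [resultant(m) for m in slope_grid]
    i = int(np.argmax(vals))
    lo = slope_grid[max(i - 1, 0)]
    hi = slope_grid[min(i + 1, len(slope_grid) - 1)]
    for _ in range(60):
        m1 = lo + (hi - lo) * 0.382
        m2 = lo + (hi - lo) * 0.618
        if resultant(m1) < resultant(m2):
            lo = m1
        else:
            hi = m2
    return float((lo + hi) / 2)
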