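"""Position + orientation decoding in a 2-D arena via a pose RBF grid.

The animal's pose (x, y, heading) is encoded as graded activations of a
10 x 10 x 10 grid of radial basis functions — Gaussian in normalized position,
wrapped-Gaussian in orientation — normalized to sum to 1.  Decoders (softmax
linear models minimizing the KL divergence to the RBF target) predict this
field; the pose estimate is the center of the maximally activated basis after
smoothing the predicted field in orientation and time, with the smoothing
chosen on training folds.  Chance baselines and the position-conditioned
orientation control quantify how much orientation information exceeds what
position alone implies.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .network import ComplexSoftmaxNet, SoftmaxRegressor, TrainConfig, train
from .preprocess import equal_count_bins

__all__ = [
    "PoseRBF", "PoseEstimate", "rbf_encode_pose", "train_pose_decoder",
    "decode_pose", "select_smoothing", "chance_baselines",
    "position_conditioned_orientation", "velocity_stratified_error",
    "wrapped_angle_error", "smooth_velocity",
]

ARENA_CM = 152.4


@dataclasses.dataclass
class PoseRBF:
    """10 x 10 x 10 pose basis: sigma_xy = 1/9 (linear), sigma_phi = 1/10 (wrapped)."""

    n_xy: int = 10
    n_phi: int = 10
    sigma_xy: float = 1.0 / 9.0
    sigma_phi: float = 1.0 / 10.0

    @property
    def xy_centers(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_xy)

    @property
    def phi_centers(self) -> np.ndarray:
        return np.linspace(0.0, 2 * np.pi, self.n_phi, endpoint=False)

    @property
    def n_bases(self) -> int:
        return self.n_xy * self.n_xy * self.n_phi

    def centers(self) -> np.ndarray:
        """All basis centers as rows (x_i, y_j, phi_k), x fastest in j, ... ."""
        xi, yj, pk = np.meshgrid(self.xy_centers, self.xy_centers,
                                 self.phi_centers, indexing="ij")
        return np.c_[xi.ravel(), yj.ravel(), pk.ravel()]


@dataclasses.dataclass
class PoseEstimate:
    """Decoded pose series and errors (normalized units / wrapped radians)."""

    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    position_error: np.ndarray | None = None
    orientation_error: np.ndarray | None = None
    arena_cm: float = ARENA_CM

    def position_error_cm(self) -> np.ndarray:
        return self.position_error * self.arena_cm


def wrapped_angle_error(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute angular difference wrapped to [0, pi]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def rbf_encode_pose(x: np.ndarray, y: np.ndarray, phi: np.ndarray,
                    basis: PoseRBF | None = None) -> np.ndarray:
    """[T x 1000] pose encoding, rows normalized to sum to 1.

    Gaussian in (x, y) on [0, 1]^2, wrapped Gaussian in orientation
    (distance min(|dphi|, 2 pi - |dphi|)).
    """
    basis = basis or PoseRBF()
    x = np.asarray(x, float)[:, None]
    y = np.asarray(y, float)[:, None]
    phi = np.asarray(phi, float)[:, None]
    dx2 = (x - basis.xy_centers[None, :]) ** 2          # [T x nx]
    dy2 = (y - basis.xy_centers[None, :]) ** 2
    dphi = np.abs(phi - basis.phi_centers[None, :]) % (2 * np.pi)
    dphi = np.minimum(dphi, 2 * np.pi - dphi)
    ex = np.exp(-dx2 / (2 * basis.sigma_xy ** 2))
    ey = np.exp(-dy2 / (2 * basis.sigma_xy ** 2))
    ep = np.exp(-dphi ** 2 / (2 * basis.sigma_phi ** 2))
    out = (ex[:, :, None, None] * ey[:, None, :, None] *
           ep[:, None, None, :]).reshape(len(x), -1)
    return out / out.sum(axis=1, keepdims=True)


def train_pose_decoder(inputs: np.ndarray, targets: np.ndarray, mode: str,
                       val_fraction: float = 0.2,
                       cfg: TrainConfig | None = None, seed: int = 0):
    """Fit a softmax model of the pose RBF field under the KL objective.

    ``carrier_free``: complex inputs projected through a complex layer whose
    amplitudes are softmaxed (shared-phase invariant).  ``carrier_based`` /
    ``spikes``: real inputs through a linear-softmax model.  The KL
    divergence to the (clipped) RBF targets equals cross-entropy up to the
    target entropy, so training reuses the network machinery.  The last
    ``val_fraction`` of samples monitors early stopping.
    """
    targets = np.clip(np.asarray(targets, float), 1e-12, None)
    targets = targets / targets.sum(axis=1, keepdims=True)
    if targets.max(axis=0).min() > 0.99:
        import warnings
        warnings.warn("degenerate pose targets: all mass on one basis")
    n_out = targets.shape[1]
    n_train = int(round(len(targets) * (1 - val_fraction)))
    if mode == "carrier_free":
        model = ComplexSoftmaxNet(inputs.shape[1], n_out, n_classes=None,
                                  unit_norm=False, seed=seed)
    elif mode in ("carrier_based", "spikes"):
        model = SoftmaxRegressor(inputs.shape[1], n_out, seed=seed)
    else:
        raise ValueError(f"unknown decoder mode {mode!r}")
    model, history = train(model, inputs[:n_train], targets[:n_train],
                           inputs[n_train:], targets[n_train:],
                           cfg or TrainConfig(seed=seed))
    return model, history


def _smooth_orientation(field: np.ndarray, basis: PoseRBF,
                        sigma_phi: float) -> np.ndarray:
    if sigma_phi <= 0:
        return field
    spacing = 2 * np.pi / basis.n_phi
    offsets = np.arange(basis.n_phi) * spacing
    d = np.minimum(offsets, 2 * np.pi - offsets)
    kernel = np.exp(-d ** 2 / (2 * sigma_phi ** 2))
    kernel = kernel / kernel.sum()
    # circular convolution along the orientation axis
    fk = np.fft.rfft(kernel)
    return np.fft.irfft(np.fft.rfft(field, axis=-1) * fk, n=basis.n_phi, axis=-1)


def _smooth_time(field: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    if tau_s <= 0:
        return field
    from scipy.signal import fftconvolve
    sigma = tau_s * fs
    half = int(np.ceil(3 * sigma))
    k = np.exp(-np.arange(-half, half + 1) ** 2 / (2 * sigma ** 2))
    shape = field.shape
    flat = field.reshape(shape[0], -1)
    padded = np.pad(flat, ((half, half), (0, 0)), mode="edge")
    out = fftconvolve(padded, k[:, None], mode="valid") / k.sum()
    return out.reshape(shape)


def decode_pose(predicted: np.ndarray, basis: PoseRBF,
                sigma_phi_smooth: float = 0.0, tau_s: float = 0.0,
                fs: float = 25.0,
                true_pose: tuple | None = None) -> PoseEstimate:
    """Pose estimate series from a predicted RBF field.

    The field is smoothed circularly in orientation (wrapped Gaussian,
    ``sigma_phi_smooth`` rad) and in time (Gaussian FIR, std ``tau_s``
    seconds), then the estimate is the center of the maximal basis.  Errors
    against ``true_pose = (x, y, phi)`` are Euclidean (normalized units) and
    wrapped angular (radians).
    """
    T = predicted.shape[0]
    field = predicted.reshape(T, basis.n_xy, basis.n_xy, basis.n_phi)
    field = _smooth_orientation(field, basis, sigma_phi_smooth)
    field = _smooth_time(field, tau_s, fs)
    flat = field.reshape(T, -1)
    centers = basis.centers()
    best = np.argmax(flat, axis=1)
    est = PoseEstimate(x=centers[best, 0], y=centers[best, 1],
                       phi=centers[best, 2])
    if true_pose is not None:
        tx, ty, tphi = true_pose
        est.position_error = np.hypot(est.x - tx, est.y - ty)
        est.orientation_error = wrapped_angle_error(est.phi, tphi)
    return est


def select_smoothing(predicted_train: np.ndarray, true_pose_train: tuple,
                     basis: PoseRBF, fs: float = 25.0,
                     sigma_grid: tuple = (0.0, 0.2, 0.4, 0.8),
                     tau_grid: tuple = (0.0, 0.4, 1.6, 6.4, 25.6)):
    """Exhaustive grid search for the smoothing minimizing training position error."""
    best = None
    for sigma in sigma_grid:
        for tau in tau_grid:
            est = decode_pose(predicted_train, basis, sigma, tau, fs,
                              true_pose=true_pose_train)
            err = float(est.position_error.mean())
            if best is None or err < best[0]:
                best = (err, sigma, tau)
    return {"sigma_phi": best[1], "tau_s": best[2], "train_error": best[0]}


def chance_baselines(true_xy: np.ndarray, n_draws: int = 1_000_000,
                     seed: int = 0) -> float:
    """Chance position error: mean distance from true positions to uniform noise."""
    rng = np.random.default_rng(seed)
    true_xy = np.atleast_2d(np.asarray(true_xy, float))
    draws = rng.uniform(0, 1, (n_draws, 2))
    idx = rng.integers(0, len(true_xy), n_draws)
    return float(np.mean(np.hypot(draws[:, 0] - true_xy[idx, 0],
                                  draws[:, 1] - true_xy[idx, 1])))


def position_conditioned_orientation(train_pose: tuple, est_xy: tuple,
                                     basis: PoseRBF | None = None) -> np.ndarray:
    """Most likely orientation given estimated position, from training occupancy.

    The joint position x orientation distribution is the inner product of a
    position-only (10 x 10 x 1) and an orientation-only (1 x 1 x 10) RBF
    encoding of the training poses; orientation is predicted as the argmax
    of that joint distribution at the estimated position.
    """
    basis = basis or PoseRBF()
    tx, ty, tphi = train_pose
    pos_rbf = _position_rbf(tx, ty, basis)
    ori_rbf = _orientation_rbf(tphi, basis)
    joint = pos_rbf.T @ ori_rbf                    # [100 x 10]
    ex, ey = est_xy
    est_pos_rbf = _position_rbf(ex, ey, basis)
    scores = est_pos_rbf @ joint                   # [T x 10]
    return basis.phi_centers[np.argmax(scores, axis=1)]


def _position_rbf(x, y, basis: PoseRBF) -> np.ndarray:
    x = np.asarray(x, float)[:, None]
    y = np.asarray(y, float)[:, None]
    ex = np.exp(-(x - basis.xy_centers) ** 2 / (2 * basis.sigma_xy ** 2))
    ey = np.exp(-(y - basis.xy_centers) ** 2 / (2 * basis.sigma_xy ** 2))
    out = (ex[:, :, None] * ey[:, None, :]).reshape(len(x), -1)
    return out / out.sum(axis=1, keepdims=True)


def _orientation_rbf(phi, basis: PoseRBF) -> np.ndarray:
    phi = np.asarray(phi, float)[:, None]
    d = np.abs(phi - basis.phi_centers) % (2 * np.pi)
    d = np.minimum(d, 2 * np.pi - d)
    out = np.exp(-d ** 2 / (2 * basis.sigma_phi ** 2))
    return out / out.sum(axis=1, keepdims=True)


def smooth_velocity(x: np.ndarray, y: np.ndarray, fs: float,
                    cutoff_hz: float = 3.2) -> np.ndarray:
    """Speed from low-pass-filtered position (removes tracking jitter)."""
    from scipy import signal as sps
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    xs = sps.sosfiltfilt(sos, np.asarray(x, float))
    ys = sps.sosfiltfilt(sos, np.asarray(y, float))
    v = np.hypot(np.gradient(xs), np.gradient(ys)) * fs
    return v


def velocity_stratified_error(errors: np.ndarray, velocity: np.ndarray,
                              n_bins: int = 10) -> dict:
    """Mean decoding error per velocity decile, plus the slow/fast log-ratio.

    log_ratio = log(mean error below median velocity / mean error above), so
    positive values mean decoding is worse when the animal moves slowly.
    """
    errors = np.asarray(errors, float)
    velocity = np.asarray(velocity, float)
    deciles = equal_count_bins(velocity, n_bins)
    # heavily tied velocities can leave upper deciles empty (ties go low)
    per_decile = np.array([errors[deciles == d].mean()
                           if np.any(deciles == d) else np.nan
                           for d in range(1, n_bins + 1)])
    median = np.median(velocity)
    slow = errors[velocity <= median].mean()
    fast = errors[velocity > median].mean()
    return {"decile_error": per_decile,
            "log_ratio_slow_fast": float(np.log(slow / fast)),
            "decile_labels": deciles}
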