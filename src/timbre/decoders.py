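"""Baseline decoders and cross-validation plumbing.

Covers the comparison decoders used alongside the carrier-free network:
L1-regularized logistic classification of the demodulated LFP (carrier-based)
or of smoothed spike rates, a Poisson Bayesian position decoder, a ridge
decoder onto radial-basis position targets, multiclass complex CSP, plus
trial-to-fold assignment with arm balancing and unit-subsampling curves.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.multiclass import OneVsRestClassifier

__all__ = [
    "FoldPlan", "RBF1D", "assign_folds", "balanced_training_mask",
    "logistic_arm_decoder", "carrier_based_decoder", "spike_rate_features",
    "rbf_encode_1d", "fit_tuning_curves", "bayesian_decode",
    "linear_rbf_decode", "csp_multiclass", "subsample_units",
]


@dataclasses.dataclass
class FoldPlan:
    """Trial-to-fold assignment with the equal-arm training quota.

    ``quota`` is the per-(fold, arm) training sample count retained after
    balancing (the minimum over folds and arms of available training
    samples), so every fold trains on exactly ``n_arms * quota`` samples.
    """

    fold_of_trial: dict
    n_folds: int
    quota: int
    seed: int


@dataclasses.dataclass
class RBF1D:
    """Per-arm 1-D radial basis grid: 10 evenly spaced Gaussians, width 1/9."""

    n_centers: int = 10
    sigma: float = 1.0 / 9.0

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_centers)


def _objective(assignment: np.ndarray, trial_arms: np.ndarray,
               trial_sizes: np.ndarray, n_folds: int) -> int:
    """Per-(fold, arm) training quota for a candidate assignment."""
    arms = np.unique(trial_arms)
    quota = None
    for f in range(n_folds):
        train = assignment != f
        for a in arms:
            count = trial_sizes[train & (trial_arms == a)].sum()
            quota = count if quota is None else min(quota, count)
    return int(quota)


def assign_folds(trial_arms: np.ndarray, trial_sizes: np.ndarray | None = None,
                 n_folds: int = 5, n_candidates: int = 100,
                 seed: int = 0) -> FoldPlan:
    """Pick, from random candidates, the fold assignment retaining the most data.

    Training data is subsampled so each arm is equally represented and all
    folds train on equal amounts; of ``n_candidates`` random assignments the
    one with the largest retained quota wins (first candidate wins ties).

    ``trial_sizes`` gives the number of samples each trial contributes (all
    ones by default, i.e. the quota counts trials).  Pass per-trial sample
    counts when the plan will be used to draw sample-level training masks:
    :func:`balanced_training_mask` interprets the quota in those units.
    """
    trial_arms = np.asarray(trial_arms)
    n_trials = len(trial_arms)
    if trial_sizes is None:
        trial_sizes = np.ones(n_trials, dtype=int)
    trial_sizes = np.asarray(trial_sizes)
    for a in np.unique(trial_arms):
        if np.sum(trial_arms == a) < n_folds:
            raise ValueError(f"arm {a} has fewer than {n_folds} trials")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_candidates):
        assignment = rng.integers(0, n_folds, n_trials)
        if len(np.unique(assignment)) < n_folds:
            continue
        quota = _objective(assignment, trial_arms, trial_sizes, n_folds)
        if best is None or quota > best[0]:
            best = (quota, assignment)
    if best is None:
        raise ValueError("no candidate assignment used all folds")
    return FoldPlan(fold_of_trial=dict(enumerate(best[1].tolist())),
                    n_folds=n_folds, quota=best[0], seed=seed)


def balanced_training_mask(fold: int, plan: FoldPlan, sample_trials: np.ndarray,
                           sample_arms: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Training mask for one fold: other folds' samples, subsampled to the quota."""
    sample_folds = np.array([plan.fold_of_trial[t] for t in sample_trials])
    mask = np.zeros(len(sample_trials), dtype=bool)
    for a in np.unique(sample_arms):
        cand = np.flatnonzero((sample_folds != fold) & (sample_arms == a))
        keep = rng.choice(cand, size=min(plan.quota, len(cand)), replace=False)
        mask[keep] = True
    return mask


def logistic_arm_decoder(features: np.ndarray, class_labels: np.ndarray,
                         arm_of_class: np.ndarray, sample_trials: np.ndarray,
                         plan: FoldPlan, C: float = 1.0,
                         seed: int = 0) -> pd.DataFrame:
    """Per-fold arm accuracy of one-vs-rest L1 logistic regression.

    ``class_labels`` may be finer than arms (e.g. 12 track sections); scoring
    maps the predicted class to its arm and counts a sample correct when that
    arm is the one occupied.
    """
    features = np.asarray(features, dtype=float)
    class_labels = np.asarray(class_labels)
    arm_of_class = np.asarray(arm_of_class)
    sample_arms = arm_of_class[class_labels]
    rng = np.random.default_rng(seed)
    sample_folds = np.array([plan.fold_of_trial[t] for t in sample_trials])
    rows = []
    for fold in range(plan.n_folds):
        train = balanced_training_mask(fold, plan, sample_trials, sample_arms, rng)
        test = sample_folds == fold
        if len(np.unique(class_labels[train])) < 2:
            raise ValueError("training fold contains a single class")
        # lasso-penalized logistic (l1_ratio=1), one-vs-rest, liblinear
        clf = OneVsRestClassifier(LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", tol=1e-4, max_iter=1000))
        clf.fit(features[train], class_labels[train])
        pred_arms = arm_of_class[clf.predict(features[test])]
        rows.append({"fold": fold,
                     "accuracy": float(np.mean(pred_arms == sample_arms[test])),
                     "n_test": int(test.sum())})
    return pd.DataFrame(rows)


# the carrier-based decoder is the logistic arm decoder applied to the
# split real/imaginary parts of the demodulated LFP
carrier_based_decoder = logistic_arm_decoder


def spike_rate_features(spike_trains: list, duration_s: float, fs: float = 25.0,
                        lowpass_hz: float = 3.0,
                        condition_mask: np.ndarray | None = None):
    """Binned (fs) spike counts, zero-phase 3 Hz low-pass, per-neuron std scaling.

    Standard deviations are computed within ``condition_mask`` (e.g. run or
    stay samples only).  Silent neurons are excluded with a warning; returns
    (features [T x n_kept], kept_indices).
    """
    n_bins = int(round(duration_s * fs))
    edges = np.arange(n_bins + 1) / fs
    counts = np.column_stack([np.histogram(st, bins=edges)[0]
                              for st in spike_trains]).astype(float)
    sos = sps.butter(8, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    smooth = sps.sosfiltfilt(sos, counts, axis=0)
    mask = np.ones(n_bins, bool) if condition_mask is None else condition_mask
    sd = smooth[mask].std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < counts.shape[1]:
        warnings.warn(f"excluding {counts.shape[1] - len(kept)} silent neuron(s)")
    return smooth[:, kept] / sd[kept], kept


def rbf_encode_1d(x_track: np.ndarray, arm: np.ndarray,
                  basis: RBF1D | None = None, n_arms: int = 3) -> np.ndarray:
    """Per-arm Gaussian RBF encoding of within-arm position, rows summing to 1.

    ``x_track`` is position rescaled to [0, 1] within the occupied arm; the
    10 bases of that arm respond, all other arms' bases are 0.
    """
    basis = basis or RBF1D()
    x_track = np.asarray(x_track, dtype=float)
    arm = np.asarray(arm, dtype=int)
    responses = np.exp(-(x_track[:, None] - basis.centers[None, :]) ** 2
                       / (2 * basis.sigma ** 2))
    responses = responses / responses.sum(axis=1, keepdims=True)
    out = np.zeros((len(x_track), basis.n_centers * n_arms))
    for a in range(n_arms):
        rows = arm == a
        out[rows, a * basis.n_centers:(a + 1) * basis.n_centers] = responses[rows]
    return out


def fit_tuning_curves(counts: np.ndarray, position_bins: np.ndarray,
                      n_pos: int, floor: float = 1e-3) -> np.ndarray:
    """Occupancy-normalized mean spike counts per bin, floored to keep logs finite."""
    curves = np.full((n_pos, counts.shape[1]), floor)
    for b in range(n_pos):
        rows = position_bins == b
        if rows.any():
            curves[b] = np.maximum(counts[rows].mean(axis=0), floor)
    return curves


def bayesian_decode(counts: np.ndarray, curves: np.ndarray) -> np.ndarray:
    """MAP position bins under independent Poisson likelihoods, uniform prior.

    log P(n | x) = sum_i n_i log f_i(x) - sum_i f_i(x) (+ const); ties break
    to the lowest bin.
    """
    log_curves = np.log(curves)
    loglik = counts @ log_curves.T - curves.sum(axis=1)[None, :]
    return np.argmax(loglik, axis=1)


def linear_rbf_decode(features_train: np.ndarray, targets_train: np.ndarray,
                      features_test: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Ridge regression onto RBF position targets; decoded bin = argmax prediction.

    Features should be standardized; the ridge penalty is 1.0.
    """
    model = Ridge(alpha=alpha)
    model.fit(features_train, targets_train)
    return np.argmax(model.predict(features_test), axis=1)


def csp_multiclass(z: np.ndarray, labels: np.ndarray, n_per_class: int = 2,
                   shrinkage: float = 1e-9):
    """Multiclass common spatial patterns on complex signals.

    For each class i, solves the generalized Hermitian eigenproblem
    C_i v = lambda C v (class covariance against pooled covariance) and keeps
    the ``n_per_class`` top eigenvectors.  Returns (filters [N x K],
    amplitude features |z @ conj(filters)| [T x K], eigenvalues [K]).
    """
    z = np.asarray(z)
    labels = np.asarray(labels)
    n = z.shape[1]
    pooled = z.conj().T @ z / len(z)
    tr = np.trace(pooled).real / n
    pooled = pooled + shrinkage * tr * np.eye(n)
    cond = np.linalg.cond(pooled)
    if cond > 1e12:
        warnings.warn("pooled covariance is ill-conditioned; shrinking harder")
        pooled = pooled + 1e-6 * tr * np.eye(n)
    filters, eigvals = [], []
    for c in np.unique(labels):
        zc = z[labels == c]
        Ci = zc.conj().T @ zc / len(zc)
        w, v = sla.eigh(Ci, pooled)
        order = np.argsort(w)[::-1][:n_per_class]
        filters.append(v[:, order])
        eigvals.append(w[order])
    filters = np.concatenate(filters, axis=1)
    features = np.abs(z @ np.conj(filters))
    return filters, features, np.concatenate(eigvals)


def subsample_units(decode_accuracy, n_units: int,
                    n_grid: tuple[int, ...], n_reps: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """Accuracy vs number of units, averaged over random unit subsets.

    ``decode_accuracy(unit_indices) -> float`` runs the decoder on a subset.
    Returns mean and s.e.m. per grid point.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        if n > n_units:
            raise ValueError(f"cannot sample {n} of {n_units} units")
        accs = []
        for _ in range(n_reps):
            idx = np.sort(rng.choice(n_units, size=n, replace=False))
            accs.append(float(decode_accuracy(idx)))
        accs = np.asarray(accs)
        sem = accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
        rows.append({"n_units": n, "mean_accuracy": accs.mean(),
                     "sem_accuracy": sem})
    return pd.DataFrame(rows)
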