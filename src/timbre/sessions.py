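"""Synthetic recording sessions: trajectories, spikes, LFPs, and file I/O.

Two session kinds are generated:

* ``maze`` — a 3-arm maze emulating a delayed-sequence task.  Each trial is a
  run epoch (the agent advances along one arm toward its reward port) followed
  by a stay epoch at the port.  Arms are laid out as thirds of the simulator's
  unit circular track, so the same phase-precessing place-cell population
  drives both the LFP and the spike trains.
* ``open_field`` — a smoothed random walk with heading in a square arena.
  Cells have 2-D Gaussian place fields and precess along the direction of
  motion, which makes the LFP phase pattern orientation-dependent.

Spikes are drawn as an inhomogeneous Poisson process with rate proportional
to each cell's response magnitude.  Sessions are written to HDF5 (complex
arrays stored as paired real arrays, timestamps disabled) so that identical
seeds produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd

from .simulate import (NoiseSpec, SimPopulation, filtered_phase_noise,
                       make_mixing, mix_lfp, population_response)

__all__ = ["MazeConfig", "OpenFieldConfig", "Session", "generate_session",
           "save_session", "load_session", "read_dat", "write_dat"]

RUN, STAY = 0, 1


@dataclasses.dataclass
class MazeConfig:
    """3-arm maze session parameters.

    Trials follow the left, center, right, center visiting order of the
    delayed-sequence task.  ``run_duration_s`` is the time to traverse an
    arm; ``stay_duration_s`` the time spent at the reward port.
    """

    n_trials: int = 36
    run_duration_s: float = 2.0
    stay_duration_s: float = 3.0
    fs: float = 25.0
    n_electrodes: int = 64
    n_cells: int = 300
    field_sigma: float = 0.04        # place-field width, track units (~26 cm)
    theta_freq: float = 8.0
    rate_scale: float = 5.0          # peak expected firing rate, Hz
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    smooth_mixing: bool = True
    port_progress: float = 0.9       # fractional arm position of the port

    def validate(self):
        if self.n_trials < 3 or self.run_duration_s <= 0 or self.stay_duration_s < 0:
            raise ValueError("invalid maze config")


@dataclasses.dataclass
class OpenFieldConfig:
    """Open-field foraging session parameters (normalized [0, 1]^2 arena)."""

    duration_s: float = 480.0
    fs: float = 25.0
    n_electrodes: int = 64
    n_cells: int = 300
    field_sigma: float = 0.08        # 2-D place-field width, arena units
    theta_freq: float = 8.0
    rate_scale: float = 5.0
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    smooth_mixing: bool = True
    speed_tau_s: float = 1.0         # velocity autocorrelation time
    mean_speed: float = 0.15         # arena units / s
    arena_cm: float = 152.4

    def validate(self):
        if self.duration_s <= 0 or self.field_sigma <= 0:
            raise ValueError("invalid open-field config")


@dataclasses.dataclass
class Session:
    """In-memory synthetic session: complex LFP + behavior table + spikes."""

    z: np.ndarray                 # complex analytic LFP [T x N]
    fs: float
    behavior: pd.DataFrame        # t, x, y, orientation, arm, epoch, trial, track_pos
    spikes: list                  # per-cell arrays of spike times (s)
    kind: str
    seed: int
    config: dict
    mixing: np.ndarray | None = None
    cell_centers: np.ndarray | None = None


def _arm_sequence(n_trials: int) -> np.ndarray:
    base = [0, 1, 2, 1]           # left, center, right, center
    reps = int(np.ceil(n_trials / len(base)))
    return np.array((base * reps)[:n_trials])


def _poisson_spikes(rate_hz: np.ndarray, fs: float,
                    rng: np.random.Generator) -> list:
    """Inhomogeneous Poisson spike times from per-sample rates [T x n_cells]."""
    dt = 1.0 / fs
    counts = rng.poisson(rate_hz * dt)
    spikes = []
    for c in range(rate_hz.shape[1]):
        t_idx = np.repeat(np.flatnonzero(counts[:, c]),
                          counts[counts[:, c] > 0, c])
        times = (t_idx + rng.uniform(0, 1, len(t_idx))) * dt
        spikes.append(np.sort(times))
    return spikes


def _generate_maze(config: MazeConfig, rng: np.random.Generator) -> Session:
    config.validate()
    fs = config.fs
    n_run = int(round(config.run_duration_s * fs))
    n_stay = int(round(config.stay_duration_s * fs))
    arms = _arm_sequence(config.n_trials)
    prog_run = np.linspace(0.05, config.port_progress, n_run, endpoint=False)
    progress, arm_lab, epoch, trial = [], [], [], []
    for i, a in enumerate(arms):
        progress.append(prog_run)
        progress.append(np.full(n_stay, config.port_progress))
        arm_lab.append(np.full(n_run + n_stay, a))
        epoch.append(np.r_[np.full(n_run, RUN), np.full(n_stay, STAY)])
        trial.append(np.full(n_run + n_stay, i))
    progress = np.concatenate(progress)
    arm_lab = np.concatenate(arm_lab).astype(int)
    epoch = np.concatenate(epoch).astype(int)
    trial = np.concatenate(trial).astype(int)
    track_pos = (arm_lab + progress) / 3.0
    T = len(track_pos)
    t = np.arange(T) / fs
    angles = np.deg2rad(90 + 120 * arm_lab)
    x = progress * np.cos(angles)
    y = progress * np.sin(angles)

    pop = SimPopulation(n_cells=config.n_cells, sigma=config.field_sigma,
                        theta_freq=config.theta_freq)
    theta_phase = 2 * np.pi * config.theta_freq * t
    eps = filtered_phase_noise(config.noise, T, config.n_cells, fs, rng)
    resp = population_response(track_pos, theta_phase, pop, eps)
    mixing = make_mixing(config.n_electrodes, config.n_cells,
                         smooth=config.smooth_mixing, rng=rng)
    z = mix_lfp(resp, mixing)
    spikes = _poisson_spikes(config.rate_scale * np.abs(resp), fs, rng)
    behavior = pd.DataFrame({
        "t": t, "x": x, "y": y, "orientation": angles % (2 * np.pi),
        "arm": arm_lab, "epoch": epoch, "trial": trial,
        "track_pos": track_pos,
    })
    return Session(z=z, fs=fs, behavior=behavior, spikes=spikes, kind="maze",
                   seed=0, config=dataclasses.asdict(config),
                   mixing=mixing.A, cell_centers=pop.centers)


def _smooth_walk(T: int, fs: float, tau_s: float, mean_speed: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Reflected Ornstein-Uhlenbeck walk in [0, 1]^2; returns positions, headings."""
    dt = 1.0 / fs
    decay = np.exp(-dt / tau_s)
    # stationary per-axis velocity std for target mean speed (Rayleigh mean)
    sv = mean_speed / np.sqrt(np.pi / 2)
    v = np.zeros(2)
    p = np.array([0.5, 0.5])
    pos = np.empty((T, 2))
    vel = np.empty((T, 2))
    kicks = rng.normal(0, sv * np.sqrt(1 - decay ** 2), (T, 2))
    for i in range(T):
        v = v * decay + kicks[i]
        p = p + v * dt
        for ax in range(2):
            if p[ax] < 0:
                p[ax] = -p[ax]
                v[ax] = -v[ax]
            elif p[ax] > 1:
                p[ax] = 2 - p[ax]
                v[ax] = -v[ax]
        pos[i] = p
        vel[i] = v
    heading = np.arctan2(vel[:, 1], vel[:, 0]) % (2 * np.pi)
    return pos, heading


def _generate_open_field(config: OpenFieldConfig,
                         rng: np.random.Generator) -> Session:
    config.validate()
    fs = config.fs
    T = int(round(config.duration_s * fs))
    pos, heading = _smooth_walk(T, fs, config.speed_tau_s, config.mean_speed, rng)
    t = np.arange(T) / fs
    # cells on a jittered grid covering the arena
    side = int(np.ceil(np.sqrt(config.n_cells)))
    gx, gy = np.meshgrid((np.arange(side) + 0.5) / side,
                         (np.arange(side) + 0.5) / side)
    centers = np.c_[gx.ravel(), gy.ravel()][:config.n_cells]
    centers = np.clip(centers + rng.normal(0, 0.2 / side, centers.shape), 0, 1)
    delta = pos[:, None, :] - centers[None, :, :]          # [T x C x 2]
    dist2 = np.sum(delta ** 2, axis=2)
    tuning = np.exp(-dist2 / (2 * config.field_sigma ** 2))
    # precession along the instantaneous direction of motion
    along = (delta[:, :, 0] * np.cos(heading)[:, None] +
             delta[:, :, 1] * np.sin(heading)[:, None])
    slope = -np.pi / (np.sqrt(2) * config.field_sigma)
    theta_phase = 2 * np.pi * config.theta_freq * t
    eps = filtered_phase_noise(config.noise, T, config.n_cells, fs, rng)
    phase = theta_phase[:, None] + slope * along + np.asarray(eps)
    resp = tuning * np.exp(1j * phase)
    mixing = make_mixing(config.n_electrodes, config.n_cells,
                         smooth=config.smooth_mixing, rng=rng)
    z = mix_lfp(resp, mixing)
    spikes = _poisson_spikes(config.rate_scale * np.abs(resp), fs, rng)
    behavior = pd.DataFrame({
        "t": t, "x": pos[:, 0], "y": pos[:, 1], "orientation": heading,
        "arm": np.full(T, -1), "epoch": np.full(T, RUN),
        "trial": np.zeros(T, dtype=int), "track_pos": np.full(T, np.nan),
    })
    return Session(z=z, fs=fs, behavior=behavior, spikes=spikes,
                   kind="open_field", seed=0,
                   config=dataclasses.asdict(config),
                   mixing=mixing.A, cell_centers=centers)


def generate_session(kind: str, config=None, seed: int = 0) -> Session:
    """Generate a synthetic maze or open-field session (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    if kind == "maze":
        session = _generate_maze(config or MazeConfig(), rng)
    elif kind == "open_field":
        session = _generate_open_field(config or OpenFieldConfig(), rng)
    else:
        raise ValueError(f"unknown session kind {kind!r}")
    session.seed = seed
    return session


def _config_to_json(config: dict) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))
    return json.dumps(config, default=default, sort_keys=True)


def save_session(session: Session, path: str) -> None:
    """Write a session container to HDF5 (deterministic: no timestamps)."""
    kw = dict(track_times=False)
    with h5py.File(path, "w", track_order=False) as f:
        lfp = f.create_group("lfp")
        lfp.create_dataset("re", data=session.z.real, **kw)
        lfp.create_dataset("im", data=session.z.imag, **kw)
        lfp.create_dataset("fs", data=float(session.fs), **kw)
        beh = f.create_group("behavior")
        for col in session.behavior.columns:
            beh.create_dataset(col, data=session.behavior[col].to_numpy(), **kw)
        spk = f.create_group("spikes")
        for i, times in enumerate(session.spikes):
            spk.create_dataset(f"cell_{i:04d}", data=np.asarray(times, float), **kw)
        meta = f.create_group("meta")
        meta.create_dataset("kind", data=session.kind.encode(), **kw)
        meta.create_dataset("seed", data=int(session.seed), **kw)
        meta.create_dataset("config", data=_config_to_json(session.config).encode(), **kw)
        if session.mixing is not None:
            meta.create_dataset("mixing_re", data=session.mixing.real, **kw)
            meta.create_dataset("mixing_im", data=session.mixing.imag, **kw)
        if session.cell_centers is not None:
            meta.create_dataset("cell_centers", data=session.cell_centers, **kw)


def load_session(path: str) -> Session:
    with h5py.File(path, "r") as f:
        z = f["lfp/re"][()] + 1j * f["lfp/im"][()]
        fs = float(f["lfp/fs"][()])
        behavior = pd.DataFrame({k: f["behavior"][k][()]
                                 for k in sorted(f["behavior"])})
        spikes = [f["spikes"][k][()] for k in sorted(f["spikes"])]
        kind = f["meta/kind"][()].decode()
        seed = int(f["meta/seed"][()])
        config = json.loads(f["meta/config"][()].decode())
        mixing = None
        if "mixing_re" in f["meta"]:
            mixing = f["meta/mixing_re"][()] + 1j * f["meta/mixing_im"][()]
        centers = f["meta/cell_centers"][()] if "cell_centers" in f["meta"] else None
    return Session(z=z, fs=fs, behavior=behavior, spikes=spikes, kind=kind,
                   seed=seed, config=config, mixing=mixing, cell_centers=centers)


def read_dat(path: str, meta_path: str) -> tuple[np.ndarray, float]:
    """Read flat interleaved int16 LFP with a JSON sidecar.

    The sidecar gives ``n_channels``, ``fs`` and optionally ``gain`` (volts
    per count).  Returns (samples [T x N] as float, fs).
    """
    with open(meta_path) as fh:
        meta = json.load(fh)
    n_channels = int(meta["n_channels"])
    fs = float(meta["fs"])
    gain = float(meta.get("gain", 1.0))
    raw = np.fromfile(path, dtype="<i2")
    if len(raw) % n_channels:
        raise ValueError("file length is not a multiple of the channel count")
    return raw.reshape(-1, n_channels).astype(float) * gain, fs


def write_dat(path: str, meta_path: str, samples: np.ndarray, fs: float,
              gain: float = 1.0) -> None:
    """Write samples as flat interleaved int16 with a JSON sidecar."""
    scaled = np.clip(np.round(samples / gain), -32768, 32767).astype("<i2")
    scaled.tofile(path)
    with open(meta_path, "w") as fh:
        json.dump({"n_channels": int(samples.shape[1]), "fs": float(fs),
                   "gain": float(gain)}, fh, sort_keys=True)
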