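"""Synthetic generators for the three macrophage motility modes.

Time-lapse cultures of polarized macrophages show three recognisable
migratory signatures: naive (M0, circular) cells spin in place and stay
near their starting position; M1 (protruded) cells make large jumps but
wander around their origin; M2 (elongated) cells move persistently in
one direction, far from where they started.  The three stochastic
processes here are the minimal models exhibiting those signatures:

* spinner  — noisy circular orbit of fixed radius and angular rate;
* jumper   — jump–diffusion with mean reversion toward the start point;
* mover    — persistent random walk (slowly diffusing heading).

Default parameters are frozen so that, on ensembles of >= 100 cells per
class, the class means reproduce the qualitative orderings seen in real
cultures: hull area and perimeter M2 > M1 > M0, and maximum pairwise
distance M1 well above M0 while M1 and M2 remain similar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .track_io import ClassLabel, TrackPoint, Trajectory, TrackSet

__all__ = [
    "SpinnerParams",
    "JumperParams",
    "MoverParams",
    "SimConfig",
    "ParameterError",
    "simulate_spinner",
    "simulate_jumper",
    "simulate_mover",
    "generate_labeled_dataset",
]


class ParameterError(ValueError):
    """A simulator parameter is outside its valid range."""


@dataclass(frozen=True)
class SpinnerParams:
    """Noisy circular orbit (M0 / circular cells).

    The cell circles a fixed center at ``radius`` (length units),
    advancing ``angular_step`` radians per frame, with isotropic
    Gaussian positional noise of sd ``positional_noise_sd`` added to
    every sample. The starting phase is drawn uniformly.
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 4.0
    angular_step: float = 2.0 * math.pi / 12.0
    positional_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"radius must be > 0, got {self.radius}")
        if self.positional_noise_sd < 0:
            raise ParameterError("positional_noise_sd must be >= 0")


@dataclass(frozen=True)
class JumperParams:
    """Jump–diffusion wanderer (M1 / protruded cells).

    Each frame, with probability ``jump_prob`` the cell takes a jump of
    length Uniform(jump_len_min, jump_len_max) in a uniform random
    direction; otherwise an isotropic Gaussian step of sd
    ``small_step_sd``. After each step the position relaxes toward the
    start point by fraction ``confinement`` (kappa in [0, 1]), which
    keeps the excursions centred on the origin of the track.
    """

    small_step_sd: float = 1.0
    jump_prob: float = 0.25
    jump_len_min: float = 7.0
    jump_len_max: float = 14.0
    confinement: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.jump_prob <= 1.0:
            raise ParameterError(f"jump_prob must be in [0,1], got {self.jump_prob}")
        if not 0.0 < self.jump_len_min <= self.jump_len_max:
            raise ParameterError(
                f"need 0 < jump_len_min <= jump_len_max, got "
                f"({self.jump_len_min}, {self.jump_len_max})"
            )
        if self.small_step_sd < 0:
            raise ParameterError("small_step_sd must be >= 0")
        if not 0.0 <= self.confinement <= 1.0:
            raise ParameterError("confinement must be in [0,1]")


@dataclass(frozen=True)
class MoverParams:
    """Persistent random walk (M2 / elongated cells).

    The heading diffuses by Gaussian increments of sd ``heading_sd``
    per frame; step length is ``step_length`` plus Gaussian noise of sd
    ``step_noise_sd``, truncated at zero. ``initial_heading`` may be a
    fixed angle in radians or ``"random"`` (uniform on the circle).
    """

    step_length: float = 1.6
    heading_sd: float = 0.5
    step_noise_sd: float = 0.35
    initial_heading: float | str = "random"

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ParameterError(f"step_length must be > 0, got {self.step_length}")
        if self.heading_sd < 0 or self.step_noise_sd < 0:
            raise ParameterError("heading_sd and step_noise_sd must be >= 0")


@dataclass
class SimConfig:
    """Study-scale configuration of the synthetic culture.

    Defaults mirror a culture recording: 37 frames at 5 minutes per
    frame. One shared random source, seeded from ``seed``, is consumed
    class by class (M0, M1, M2) and cell by cell, so adding classes or
    cells at the end never perturbs earlier draws.
    """

    n_frames: int = 37
    frame_interval: float = 5.0
    n_per_class: int = 70
    seed: int = 0
    spinner: SpinnerParams = field(default_factory=SpinnerParams)
    jumper: JumperParams = field(default_factory=JumperParams)
    mover: MoverParams = field(default_factory=MoverParams)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")


def _to_trajectory(
    xy: np.ndarray, cell_id: str, label: ClassLabel | None, frame_interval: float
) -> Trajectory:
    pts = [
        TrackPoint(k, k * frame_interval, float(x), float(y))
        for k, (x, y) in enumerate(xy)
    ]
    return Trajectory(cell_id, pts, label)


def simulate_spinner(
    params: SpinnerParams,
    n_frames: int,
    rng: np.random.Generator,
    cell_id: str = "spinner",
    frame_interval: float = 5.0,
) -> Trajectory:
    """Simulate one spinning, confined trajectory."""
    if n_frames < 2:
        raise ParameterError(f"n_frames must be >= 2, got {n_frames}")
    phi0 = rng.uniform(0.0, 2.0 * math.pi)
    ang = phi0 + np.arange(n_frames) * params.angular_step
    xy = np.stack(
        [
            params.center[0] + params.radius * np.cos(ang),
            params.center[1] + params.radius * np.sin(ang),
        ],
        axis=1,
    )
    xy = xy + rng.normal(0.0, params.positional_noise_sd, size=xy.shape)
    return _to_trajectory(xy, cell_id, ClassLabel.M0, frame_interval)


def simulate_jumper(
    params: JumperParams,
    n_frames: int,
    rng: np.random.Generator,
    cell_id: str = "jumper",
    frame_interval: float = 5.0,
) -> Trajectory:
    """Simulate one jump-and-wander trajectory around the start point."""
    if n_frames < 2:
        raise ParameterError(f"n_frames must be >= 2, got {n_frames}")
    xy = np.zeros((n_frames, 2))
    p0 = np.zeros(2)
    pos = p0.copy()
    for k in range(1, n_frames):
        if rng.uniform() < params.jump_prob:
            length = rng.uniform(params.jump_len_min, params.jump_len_max)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            step = length * np.array([math.cos(theta), math.sin(theta)])
        else:
            step = rng.normal(0.0, params.small_step_sd, size=2)
        pos = pos + step
        pos = pos + params.confinement * (p0 - pos)
        xy[k] = pos
    return _to_trajectory(xy, cell_id, ClassLabel.M1, frame_interval)


def simulate_mover(
    params: MoverParams,
    n_frames: int,
    rng: np.random.Generator,
    cell_id: str = "mover",
    frame_interval: float = 5.0,
) -> Trajectory:
    """Simulate one persistent, directional trajectory."""
    if n_frames < 2:
        raise ParameterError(f"n_frames must be >= 2, got {n_frames}")
    if params.initial_heading == "random":
        theta = rng.uniform(0.0, 2.0 * math.pi)
    else:
        theta = float(params.initial_heading)
    xy = np.zeros((n_frames, 2))
    pos = np.zeros(2)
    for k in range(1, n_frames):
        theta = theta + rng.normal(0.0, params.heading_sd)
        length = max(0.0, params.step_length + rng.normal(0.0, params.step_noise_sd))
        pos = pos + length * np.array([math.cos(theta), math.sin(theta)])
        xy[k] = pos
    return _to_trajectory(xy, cell_id, ClassLabel.M2, frame_interval)


def generate_labeled_dataset(config: SimConfig) -> TrackSet:
    """Generate a labeled synthetic culture, ``n_per_class`` cells per class.

    Cells are named ``<class>_<i>`` (``m0_000`` ...). Deterministic for
    a fixed seed: the single generator is consumed class by class in the
    order M0, M1, M2, and cell by cell within each class.
    """
    rng = np.random.default_rng(config.seed)
    sims = [
        ("m0", lambda r, cid: simulate_spinner(
            config.spinner, config.n_frames, r, cid, config.frame_interval)),
        ("m1", lambda r, cid: simulate_jumper(
            config.jumper, config.n_frames, r, cid, config.frame_interval)),
        ("m2", lambda r, cid: simulate_mover(
            config.mover, config.n_frames, r, cid, config.frame_interval)),
    ]
    trajectories = []
    for prefix, sim in sims:
        for i in range(config.n_per_class):
            trajectories.append(sim(rng, f"{prefix}_{i:03d}"))
    return TrackSet(
        trajectories,
        frame_interval=config.frame_interval,
        n_frames=config.n_frames,
        units="px",
    )
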