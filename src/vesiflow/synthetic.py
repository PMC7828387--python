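"""Ground-truthed synthetic vesicle movies.

The generator emulates the imaging regime the pipeline is designed for:
bright, sub-resolution quantum-dot-labeled vesicles rendered as isotropic
Gaussian spots on a dim uniform cell body (a disk) over dark background,
acquired as a uniform-interval time-lapse.  Vesicles move radially inward
(endocytic transport toward the cell center), radially outward, or purely
diffusively, each with per-axis Gaussian jitter, and the camera adds
Gaussian read noise with optional Poisson shot noise.

Every movie is fully determined by its :class:`SceneConfig` (including the
seed), and the generator returns the exact per-frame vesicle positions as
:class:`GroundTruth`, so downstream stages can be scored against known
motion without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .image_io import ImageStack

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_movie",
    "ground_truth_direction",
    "vesicle_proximity_masks",
    "radial_scene",
    "peripheral_scene",
    "MOTION_MODES",
]

MOTION_MODES = ("inward", "outward", "diffusive")

#: Minimum distance (px) from the cell center at which an inward vesicle
#: is considered arrived and stops.
ARRIVAL_RADIUS = 1.0


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe a mid-plane confocal cross-section of a single cell:
    a 128x128 field with a 45 px cell radius, 50 vesicles split evenly
    between inward and outward transport at 1.5 px/frame with 0.2 px/frame
    diffusive jitter, diffraction-limited spots (sigma 1.5 px) and additive
    Gaussian noise at 5 % of the spot amplitude.
    """

    image_size: tuple[int, int] = (128, 128)
    n_frames: int = 20
    cell_center: tuple[float, float] = (63.5, 63.5)  # (row, col)
    cell_radius: float = 45.0
    n_vesicles: int = 50
    #: one mode for all vesicles, a per-vesicle sequence, or a mapping
    #: mode -> fraction (fractions are turned into deterministic counts).
    motion_modes: str | Sequence[str] | Mapping[str, float] = field(
        default_factory=lambda: {"inward": 0.5, "outward": 0.5}
    )
    radial_speed: float = 1.5
    diffusion_sigma: float = 0.2
    psf_sigma: float = 1.5
    spot_amplitude: float = 150.0
    cell_body_level: float = 30.0
    background_level: float = 10.0
    #: Gaussian read-noise sigma; None -> 0.05 * spot_amplitude, 0 disables.
    noise_sigma: float | None = None
    poisson_noise: bool = False
    #: initial vesicle radii as fractions of cell_radius (uniform in radius)
    initial_radius_range: tuple[float, float] = (0.3, 0.9)
    seed: int = 0

    def resolved_noise_sigma(self) -> float:
        if self.noise_sigma is None:
            return 0.05 * self.spot_amplitude
        return float(self.noise_sigma)

    def validate(self) -> None:
        problems = []
        m, n = self.image_size
        if m < 8 or n < 8:
            problems.append(f"image_size {self.image_size} too small (min 8x8)")
        if self.n_frames < 2:
            problems.append(f"n_frames must be >= 2, got {self.n_frames}")
        if self.cell_radius < 3 * self.psf_sigma:
            problems.append(
                f"cell_radius ({self.cell_radius}) must be >= 3*psf_sigma "
                f"({3 * self.psf_sigma})"
            )
        cr, cc = self.cell_center
        if not (0 <= cr < m and 0 <= cc < n):
            problems.append(f"cell_center {self.cell_center} outside image {self.image_size}")
        if self.n_vesicles < 0:
            problems.append("n_vesicles must be non-negative")
        lo, hi = self.initial_radius_range
        if not (0 <= lo <= hi <= 1):
            problems.append(
                f"initial_radius_range {self.initial_radius_range} must satisfy "
                "0 <= lo <= hi <= 1 (fractions of cell_radius)"
            )
        if self.radial_speed < 0 or self.diffusion_sigma < 0 or self.psf_sigma <= 0:
            problems.append("radial_speed, diffusion_sigma >= 0 and psf_sigma > 0 required")
        for level in ("spot_amplitude", "cell_body_level", "background_level"):
            if getattr(self, level) < 0:
                problems.append(f"{level} must be non-negative")
        if isinstance(self.motion_modes, str):
            if self.motion_modes not in MOTION_MODES:
                problems.append(f"unknown motion mode {self.motion_modes!r}")
        elif isinstance(self.motion_modes, Mapping):
            if any(k not in MOTION_MODES for k in self.motion_modes):
                problems.append(f"unknown motion modes in {dict(self.motion_modes)}")
            if self.motion_modes and not np.isclose(sum(self.motion_modes.values()), 1.0):
                problems.append("motion_modes fractions must sum to 1")
        else:
            modes = list(self.motion_modes)
            if len(modes) != self.n_vesicles:
                problems.append(
                    f"motion_modes sequence length {len(modes)} != n_vesicles {self.n_vesicles}"
                )
            if any(mode not in MOTION_MODES for mode in modes):
                problems.append(f"unknown motion modes in {modes}")
        if problems:
            raise ValidationError("invalid SceneConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["motion_modes"], tuple):
            d["motion_modes"] = list(d["motion_modes"])
        d["image_size"] = list(self.image_size)
        d["cell_center"] = list(self.cell_center)
        d["initial_radius_range"] = list(self.initial_radius_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneConfig":
        d = dict(d)
        for key in ("image_size", "cell_center", "initial_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact vesicle trajectories underlying a synthetic movie.

    ``positions`` has shape ``(n_frames, n_vesicles, 2)`` in (row, col);
    ``modes`` is the per-vesicle motion mode; ``cell_center`` is the true
    center the motion was simulated around.
    """

    positions: np.ndarray
    modes: tuple[str, ...]
    cell_center: tuple[float, float]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_vesicles(self) -> int:
        return self.positions.shape[1]

    def distances_to_center(self, frame: int) -> np.ndarray:
        d = self.positions[frame] - np.asarray(self.cell_center)
        return np.hypot(d[:, 0], d[:, 1])

    def to_dataframe(self) -> pd.DataFrame:
        n_f, n_v, _ = self.positions.shape
        frames = np.repeat(np.arange(n_f), n_v)
        ves = np.tile(np.arange(n_v), n_f)
        flat = self.positions.reshape(-1, 2)
        return pd.DataFrame(
            {
                "frame": frames,
                "vesicle_id": ves,
                "row": flat[:, 0],
                "col": flat[:, 1],
                "mode": [self.modes[v] for v in ves],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)


def _assign_modes(config: SceneConfig) -> tuple[str, ...]:
    requested = config.motion_modes
    v = config.n_vesicles
    if isinstance(requested, str):
        return (requested,) * v
    if isinstance(requested, Mapping):
        # largest-remainder apportionment, deterministic in MOTION_MODES order
        fractions = [(mode, requested.get(mode, 0.0)) for mode in MOTION_MODES]
        counts = {mode: int(np.floor(frac * v)) for mode, frac in fractions}
        remainder = v - sum(counts.values())
        by_frac = sorted(fractions, key=lambda kv: -(kv[1] * v - np.floor(kv[1] * v)))
        for mode, _ in by_frac[:remainder]:
            counts[mode] += 1
        modes: list[str] = []
        for mode in MOTION_MODES:
            modes.extend([mode] * counts[mode])
        return tuple(modes)
    return tuple(requested)


def _render_spot(frame: np.ndarray, row: float, col: float, amp: float, sigma: float) -> None:
    """Add an isotropic Gaussian spot in-place, truncated at 4 sigma."""
    m, n = frame.shape
    half = int(np.ceil(4 * sigma))
    r0 = max(int(np.floor(row)) - half, 0)
    r1 = min(int(np.floor(row)) + half + 1, m)
    c0 = max(int(np.floor(col)) - half, 0)
    c1 = min(int(np.floor(col)) + half + 1, n)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    frame[r0:r1, c0:c1] += amp * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def generate_movie(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate one movie and return it with its exact ground truth.

    Per frame, each vesicle takes a radial step of ``radial_speed`` toward
    (inward) or away from (outward) the true center, plus independent
    N(0, diffusion_sigma^2) jitter on each axis; diffusive vesicles jitter
    only.  Inward vesicles freeze once within 1 px of the center; outward
    vesicles freeze at the cell boundary (clamped onto it).  Rendering and
    noise are applied after all trajectories are simulated; identical
    configs (same seed) give bit-identical stacks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m, n = config.image_size
    center = np.asarray(config.cell_center, dtype=float)
    v = config.n_vesicles
    modes = _assign_modes(config)
    mode_arr = np.asarray(modes)

    lo, hi = config.initial_radius_range
    radii = rng.uniform(lo, hi, size=v) * config.cell_radius
    angles = rng.uniform(0.0, 2 * np.pi, size=v)
    pos = center + np.column_stack([radii * np.sin(angles), radii * np.cos(angles)])

    positions = np.empty((config.n_frames, v, 2), dtype=float)
    stopped = np.zeros(v, dtype=bool)
    inward = mode_arr == "inward"
    outward = mode_arr == "outward"
    for k in range(config.n_frames):
        positions[k] = pos
        if k == config.n_frames - 1:
            break
        jitter = rng.normal(0.0, config.diffusion_sigma, size=(v, 2))
        to_center = center[None, :] - pos
        dist = np.hypot(to_center[:, 0], to_center[:, 1])
        unit = np.zeros_like(to_center)
        moving = dist > 1e-12
        unit[moving] = to_center[moving] / dist[moving, None]
        step = np.zeros_like(pos)
        # inward steps never overshoot past the center
        inward_len = np.minimum(config.radial_speed, dist[inward])
        step[inward] = inward_len[:, None] * unit[inward]
        step[outward] = -config.radial_speed * unit[outward]
        new = pos + step + jitter
        new[stopped] = pos[stopped]
        d_new = np.hypot(*(center[None, :] - new).T)
        arrived = inward & ~stopped & (d_new < ARRIVAL_RADIUS)
        escaped = outward & ~stopped & (d_new > config.cell_radius)
        if np.any(escaped):
            away = new[escaped] - center[None, :]
            norm = np.hypot(away[:, 0], away[:, 1])
            new[escaped] = center[None, :] + away / norm[:, None] * config.cell_radius
        stopped |= arrived | escaped
        pos = new

    rows = np.arange(m)[:, None]
    cols = np.arange(n)[None, :]
    disk = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= config.cell_radius**2
    base = config.background_level + config.cell_body_level * disk

    frames = np.empty((config.n_frames, m, n), dtype=float)
    for k in range(config.n_frames):
        frame = base.astype(float).copy()
        for i in range(v):
            _render_spot(
                frame,
                positions[k, i, 0],
                positions[k, i, 1],
                config.spot_amplitude,
                config.psf_sigma,
            )
        frames[k] = frame

    sigma = config.resolved_noise_sigma()
    if sigma > 0:
        frames = frames + rng.normal(0.0, sigma, size=frames.shape)
    if config.poisson_noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    np.clip(frames, 0, None, out=frames)

    truth = GroundTruth(positions=positions, modes=modes, cell_center=tuple(center))
    return ImageStack(frames), truth


def radial_scene(seed: int = 0, **overrides) -> SceneConfig:
    """Study scene for direction classification: mixed radial transport.

    50 vesicles split evenly between inward and outward motion at
    1.5 px/frame with 0.2 px/frame jitter and default noise — the
    conditions the direction-recovery tests are defined on.
    """
    return SceneConfig(seed=seed, **overrides)


def peripheral_scene(seed: int = 0, **overrides) -> SceneConfig:
    """Study scene for center estimation: quiet interior, busy periphery.

    350 diffusive vesicles tethered (small 0.5 px/frame jitter) in the
    outer annulus (0.55-1.0 of the cell radius) over 60 frames.  The
    jitter is kept small so spots stay peripheral: a larger random walk
    would migrate them into the interior and erase the quiet core the
    STD-map estimator relies on.  The density and duration are chosen so
    the annulus STD is uniformly high — sparse or short movies leave
    quiet pockets between spots that bias the centroid.
    """
    params = dict(
        motion_modes="diffusive",
        n_vesicles=350,
        diffusion_sigma=0.5,
        n_frames=60,
        initial_radius_range=(0.55, 1.0),
    )
    params.update(overrides)
    return SceneConfig(seed=seed, **params)


def ground_truth_direction(
    truth: GroundTruth, frame_pair: int, tolerance: float = 0.25
) -> np.ndarray:
    """Per-vesicle motion label over the frame pair ``(k, k+1)``.

    A vesicle is ``"inward"`` if its distance to the true center decreased
    by more than ``tolerance`` pixels between the two frames, ``"outward"``
    if it increased by more, else ``"static"``.
    """
    if not 0 <= frame_pair < truth.n_frames - 1:
        raise ValidationError(
            f"frame_pair {frame_pair} out of range [0, {truth.n_frames - 2}]"
        )
    d0 = truth.distances_to_center(frame_pair)
    d1 = truth.distances_to_center(frame_pair + 1)
    change = d1 - d0
    labels = np.full(truth.n_vesicles, "static", dtype=object)
    labels[change < -tolerance] = "inward"
    labels[change > tolerance] = "outward"
    return labels


def vesicle_proximity_masks(
    truth: GroundTruth,
    frame_pair: int,
    radius: float,
    shape: tuple[int, int],
    tolerance: float = 0.25,
) -> dict[str, np.ndarray]:
    """Boolean masks of pixels within ``radius`` px of a vesicle per label.

    Labels come from :func:`ground_truth_direction` for the given frame
    pair; distances are measured from vesicle positions at the first frame
    of the pair.  Used to score direction maps against ground truth.
    """
    labels = ground_truth_direction(truth, frame_pair, tolerance)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    masks = {lab: np.zeros(shape, dtype=bool) for lab in ("inward", "outward", "static")}
    for i in range(truth.n_vesicles):
        r, c = truth.positions[frame_pair, i]
        near = (rows - r) ** 2 + (cols - c) ** 2 <= radius**2
        masks[str(labels[i])] |= near
    return masks
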