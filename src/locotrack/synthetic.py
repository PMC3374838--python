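"""Synthetic multi-animal locomotion data.

Generates ground-truth crawling trajectories (and optionally rendered
dark-field-style frames) with the statistical structure the downstream
analysis assumes: ~1 Hz sampling, 2-minute assays, instantaneous speeds in
the 0-0.3 mm/s range, per-frame detection dropout producing realistic track
fragmentation, and per-genotype differences in mean speed and in the size of
speed fluctuations.

The speed of each animal follows a mean-reverting (Ornstein-Uhlenbeck)
diffusion reflected at zero,

    dv = theta * (mu - v) dt + sigma dW,    v <- |v|,

whose unreflected stationary distribution is N(mu, sigma^2 / (2 theta)).
The two phenotype axes of interest -- average speed and fluctuation
magnitude -- are therefore controlled independently by ``mu_speed`` and by
``sigma`` (at fixed ``theta``).  Heading follows an independent random walk,
so trajectories are smooth persistent paths confined to the arena by
reflective walls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeParams",
    "SimConfig",
    "GroundTruth",
    "PRESETS",
    "stationary_speed_sd",
    "sample_animal_params",
    "simulate_track_population",
    "simulate_speed_trace",
    "simulate_trajectory",
    "generate_dataset",
    "render_frame",
    "render_stack",
]


@dataclass(frozen=True)
class GenotypeParams:
    """Generative parameters for one simulated strain/condition.

    Parameters
    ----------
    label : str
        Strain/condition name carried through to ground truth and stats.
    mu_speed : float
        Long-run mean crawling speed, mm/s.
    theta : float
        Mean-reversion rate of the speed process, 1/s.  Larger theta means
        faster decorrelation of speed fluctuations.
    sigma : float
        Diffusion coefficient of the speed process, mm s^-3/2.  The
        stationary SD of the unreflected process is sigma / sqrt(2 theta).
    turn_sd : float
        Heading random-walk scale, radians per observation step.
    mu_sd : float
        Between-animal SD of the personal mean speed, mm/s.  Individual
        animals of one strain differ in their characteristic speed, which
        is what spreads tracks across average-speed bins; each simulated
        animal draws its own mean from |N(mu_speed, mu_sd^2)|.  Zero means
        every animal shares ``mu_speed`` exactly.
    """

    label: str
    mu_speed: float
    theta: float
    sigma: float
    turn_sd: float = 0.5
    mu_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_speed < 0:
            raise ValueError("mu_speed must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.turn_sd < 0:
            raise ValueError("turn_sd must be >= 0")
        if self.mu_sd < 0:
            raise ValueError("mu_sd must be >= 0")


def stationary_speed_sd(params: GenotypeParams) -> float:
    """Stationary SD of the unreflected speed process, sigma/sqrt(2 theta)."""
    return params.sigma / math.sqrt(2.0 * params.theta)


def _preset(label, mu, sd, mu_sd, theta=0.5, turn_sd=0.5):
    # sigma chosen so the stationary SD of the speed process equals `sd`
    return GenotypeParams(
        label=label,
        mu_speed=mu,
        theta=theta,
        sigma=sd * math.sqrt(2.0 * theta),
        turn_sd=turn_sd,
        mu_sd=mu_sd,
    )


#: Phenomenological strain presets.  Within-track stationary speed SDs
#: follow the wild-type-like (0.037 mm/s) vs dopamine-deficient-like
#: (0.054 mm/s) fluctuation contrast, and between-animal mean-speed SDs
#: (0.031 vs 0.047 mm/s) the corresponding spread of individual average
#: speeds; means are matched so fluctuation size is the only difference
#: between the first pair.  ``slowed_mutant`` lowers mean speed without
#: touching the fluctuation parameters (serotonin-pathway-like suppression
#: of hyperactivity), and ``da_pretreated`` restores the wild-type set.
PRESETS: dict[str, GenotypeParams] = {
    "wild_type": _preset("wild_type", mu=0.15, sd=0.037, mu_sd=0.031),
    "cat2_like": _preset("cat2_like", mu=0.15, sd=0.054, mu_sd=0.047),
    "slowed_mutant": _preset("slowed_mutant", mu=0.08, sd=0.054, mu_sd=0.047),
    "da_pretreated": _preset("da_pretreated", mu=0.15, sd=0.037, mu_sd=0.031),
}


def sample_animal_params(
    params: GenotypeParams, rng: np.random.Generator
) -> GenotypeParams:
    """Draw one animal's personal parameter set: its mean speed comes from
    |N(mu_speed, mu_sd^2)|; everything else is shared."""
    if params.mu_sd == 0:
        return params
    mu = abs(rng.normal(params.mu_speed, params.mu_sd))
    return replace(params, mu_speed=mu, mu_sd=0.0)


def simulate_track_population(
    params: GenotypeParams,
    n_tracks: int,
    n_steps: int,
    dt: float,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """Simulate ``n_tracks`` independent animals' true speed traces, each
    with its own personal mean speed.  Convenient for population-level
    analyses that do not need positions or imaging."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [
        simulate_speed_trace(sample_animal_params(params, rng), n_steps, dt, rng)
        for _ in range(n_tracks)
    ]


@dataclass(frozen=True)
class SimConfig:
    """Assay-level simulation parameters.

    Defaults mirror the automated assay: 2-minute recordings sampled at
    1 Hz.  ``dropout_prob`` is the per-frame per-animal probability that a
    centroid goes undetected; the default reproduces the empirical track
    fragmentation scale (mean recovered track length around 53 s) under the
    default tracker settings.
    """

    n_animals: int = 20
    duration_s: float = 120.0
    dt: float = 1.0
    arena_size: tuple[float, float] = (12.0, 12.0)  # mm
    dropout_prob: float = 0.135
    mm_per_px: float = 0.01
    min_separation: float | None = None  # confine animals to cells, mm gap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = self.duration_s / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s must be a whole number of frames")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.dt)) + 1


@dataclass
class GroundTruth:
    """Full per-animal trajectories and identities, before any dropout.

    ``positions`` has shape (n_animals, n_frames, 2) in mm; ``speeds`` has
    shape (n_animals, n_frames) in mm/s, where ``speeds[a, t]`` is the true
    process speed governing the step from frame t to t+1 (the final entry
    repeats the last interval's speed).
    """

    times: np.ndarray
    positions: np.ndarray
    speeds: np.ndarray
    genotypes: list[str]

    @property
    def n_animals(self) -> int:
        return self.positions.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        n_a, n_f, _ = self.positions.shape
        return pd.DataFrame(
            {
                "frame": np.tile(np.arange(n_f), n_a),
                "time_s": np.tile(self.times, n_a),
                "animal_id": np.repeat(np.arange(n_a), n_f),
                "genotype": np.repeat(np.asarray(self.genotypes, dtype=object), n_f),
                "x_mm": self.positions[:, :, 0].ravel(),
                "y_mm": self.positions[:, :, 1].ravel(),
                "true_speed_mm_s": self.speeds.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


def simulate_speed_trace(
    params: GenotypeParams,
    n_steps: int,
    dt: float,
    seed: int | np.random.Generator,
    v0: float | None = None,
    substeps: int = 1,
) -> np.ndarray:
    """Simulate a reflected mean-reverting speed trace.

    Euler-Maruyama integration at step ``dt / substeps``, reflection at zero
    applied as an absolute value after each substep, observations returned
    every ``dt``.  Returns ``n_steps`` nonnegative values; the first is the
    initial condition (a draw from the stationary normal, folded at zero,
    unless ``v0`` is given).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    sd_stat = stationary_speed_sd(params)
    if v0 is None:
        v = abs(params.mu_speed + sd_stat * rng.standard_normal()) if sd_stat > 0 else params.mu_speed
    else:
        v = float(v0)

    h = dt / substeps
    sqh = math.sqrt(h)
    out = np.empty(n_steps)
    out[0] = abs(v)
    if params.sigma > 0:
        noise = rng.standard_normal((n_steps - 1, substeps))
    else:
        noise = np.zeros((n_steps - 1, substeps))
    v = out[0]
    for i in range(1, n_steps):
        for k in range(substeps):
            v = v + params.theta * (params.mu_speed - v) * h + params.sigma * sqh * noise[i - 1, k]
            v = abs(v)
        out[i] = v
    return out


def simulate_trajectory(
    speeds: np.ndarray,
    turn_sd: float,
    start: tuple[float, float],
    arena_size: tuple[float, float],
    seed: int | np.random.Generator,
    dt: float = 1.0,
    heading0: float | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Integrate positions from a speed trace and a heading random walk.

    Returns ``len(speeds) + 1`` positions (mm).  Each step moves
    ``speeds[i] * dt`` along the current heading; paths are kept inside the
    arena (or the explicit ``bounds`` rectangle ``(x0, y0, x1, y1)``) by
    reflecting off the walls, flipping the corresponding heading component.
    """
    speeds = np.asarray(speeds, dtype=float)
    if np.any(speeds < 0):
        raise ValueError("speed series must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if bounds is None:
        bounds = (0.0, 0.0, float(arena_size[0]), float(arena_size[1]))
    x0, y0, x1, y1 = bounds
    x, y = float(start[0]), float(start[1])
    if not (x0 <= x <= x1 and y0 <= y <= y1):
        raise ValueError(f"start position {start} outside arena bounds {bounds}")

    heading = rng.uniform(0, 2 * math.pi) if heading0 is None else float(heading0)
    n = len(speeds)
    pos = np.empty((n + 1, 2))
    pos[0] = (x, y)
    turns = rng.normal(0.0, turn_sd, size=n) if turn_sd > 0 else np.zeros(n)
    for i in range(n):
        step = speeds[i] * dt
        x += step * math.cos(heading)
        y += step * math.sin(heading)
        # reflective walls; step sizes are tiny relative to the arena so a
        # couple of folds always suffice
        while not (x0 <= x <= x1 and y0 <= y <= y1):
            if x < x0:
                x = 2 * x0 - x
                heading = math.pi - heading
            elif x > x1:
                x = 2 * x1 - x
                heading = math.pi - heading
            if y < y0:
                y = 2 * y0 - y
                heading = -heading
            elif y > y1:
                y = 2 * y1 - y
                heading = -heading
        pos[i + 1] = (x, y)
        heading += turns[i]
    return pos


def _initial_layout(config: SimConfig):
    """Grid layout of starting positions; raises if the arena is too small.

    With ``min_separation`` set, each animal is confined to its own grid
    cell shrunk by half the separation on every side, so any two animals
    are always at least ``min_separation`` apart.
    """
    n = config.n_animals
    w, hgt = config.arena_size
    ncol = int(math.ceil(math.sqrt(n * w / hgt))) or 1
    nrow = int(math.ceil(n / ncol))
    cw, ch = w / ncol, hgt / nrow
    gap = config.min_separation or 0.0
    if cw - gap < 0.05 or ch - gap < 0.05:
        raise ValueError(
            f"arena {config.arena_size} mm too small for {n} animals "
            f"with separation {gap} mm"
        )
    starts, cells = [], []
    for a in range(n):
        r, c = divmod(a, ncol)
        bx0, by0 = c * cw + gap / 2, r * ch + gap / 2
        bx1, by1 = (c + 1) * cw - gap / 2, (r + 1) * ch - gap / 2
        starts.append(((bx0 + bx1) / 2, (by0 + by1) / 2))
        cells.append((bx0, by0, bx1, by1))
    if config.min_separation is None:
        cells = [(0.0, 0.0, w, hgt)] * n
    return starts, cells


def generate_dataset(
    config: SimConfig,
    genotypes: list[GenotypeParams],
) -> tuple[list[np.ndarray], GroundTruth]:
    """Simulate a multi-animal assay.

    Animals are assigned to ``genotypes`` round-robin.  Returns per-frame
    centroid arrays (each of shape (k, 2), mm, with dropouts removed) and
    the full :class:`GroundTruth`.  With ``dropout_prob == 0`` the emitted
    centroids equal the true positions exactly.
    """
    if not genotypes:
        raise ValueError("need at least one GenotypeParams")
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    starts, cells = _initial_layout(config)

    positions = np.empty((config.n_animals, n_frames, 2))
    speeds = np.empty((config.n_animals, n_frames))
    labels = []
    for a in range(config.n_animals):
        params = sample_animal_params(genotypes[a % len(genotypes)], rng)
        labels.append(params.label)
        v = simulate_speed_trace(params, n_frames - 1, config.dt, rng) if n_frames > 2 else np.full(
            max(n_frames - 1, 1), params.mu_speed
        )
        positions[a] = simulate_trajectory(
            v, params.turn_sd, starts[a], config.arena_size, rng,
            dt=config.dt, bounds=cells[a],
        )
        speeds[a, :-1] = v
        speeds[a, -1] = v[-1]

    detected = rng.random((n_frames, config.n_animals)) >= config.dropout_prob
    frames = [positions[detected[t], t, :].copy() for t in range(n_frames)]
    times = np.arange(n_frames) * config.dt
    return frames, GroundTruth(times=times, positions=positions, speeds=speeds, genotypes=labels)


def render_frame(
    positions_mm: np.ndarray,
    image_shape: tuple[int, int],
    blob_sigma: float = 3.0,
    intensity: float = 255.0,
    mm_per_px: float = 0.01,
    background: float = 0.0,
) -> np.ndarray:
    """Render a dark-field-style frame: bright isotropic Gaussian blobs on a
    dark background.  ``positions_mm`` is (k, 2) as (x, y); rows are image
    y, columns image x.  Overlapping blobs simply add."""
    img = np.full(image_shape, background, dtype=float)
    positions_mm = np.atleast_2d(np.asarray(positions_mm, dtype=float)) if len(positions_mm) else np.empty((0, 2))
    half = int(math.ceil(5 * blob_sigma))
    h, w = image_shape
    for x_mm, y_mm in positions_mm:
        cx, cy = x_mm / mm_per_px, y_mm / mm_per_px
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"position ({x_mm}, {y_mm}) mm falls outside the image")
        r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += intensity * np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * blob_sigma**2)
        )
    return img


def render_stack(
    frames: list[np.ndarray],
    image_shape: tuple[int, int] | None = None,
    arena_size: tuple[float, float] = (12.0, 12.0),
    blob_sigma: float = 3.0,
    intensity: float = 255.0,
    mm_per_px: float = 0.01,
) -> np.ndarray:
    """Render per-frame centroid lists into a (T, H, W) image stack."""
    if image_shape is None:
        image_shape = (
            int(math.ceil(arena_size[1] / mm_per_px)) + 1,
            int(math.ceil(arena_size[0] / mm_per_px)) + 1,
        )
    return np.stack(
        [
            render_frame(f, image_shape, blob_sigma, intensity, mm_per_px)
            for f in frames
        ]
    )
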