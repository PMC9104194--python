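"""Overdamped particle-migration simulator and synthetic frame renderer.

Particles are in the low-Reynolds regime, so inertia is neglected and
each particle moves at its instantaneous terminal velocity,

    dz/dt = F_net(z) / (6 pi eta r),

with absorbing boundaries at the cuvette bottom (z = 0, precipitated)
and the top of the gap (z = d, floated).  Motion is deterministic; an
optional Brownian term can be switched on for realism studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSeries, Roi
from .physics import (
    CONSTANTS,
    MagnetConfig,
    ParamagneticMedium,
    PhysicalConstants,
    axial_field,
)

__all__ = [
    "ParticlePopulation",
    "Trajectory",
    "OpticsConfig",
    "TerminalState",
    "simulate_trajectories",
    "classify_fractions",
    "render_frames",
]


class TerminalState:
    LEVITATING = "levitating"
    PRECIPITATED = "precipitated"
    FLOATED = "floated"


@dataclass
class ParticlePopulation:
    """Ensemble of corona-coated particles entering the cuvette."""

    densities: np.ndarray        # kg/m^3
    radii: np.ndarray            # m
    susceptibilities: np.ndarray # dimensionless SI
    initial_positions: np.ndarray  # m, within [0, d]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.densities = np.atleast_1d(np.asarray(self.densities, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.susceptibilities = np.atleast_1d(
            np.asarray(self.susceptibilities, dtype=float)
        )
        self.initial_positions = np.atleast_1d(
            np.asarray(self.initial_positions, dtype=float)
        )
        n = len(self.densities)
        for name in ("radii", "susceptibilities", "initial_positions"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.densities <= 0) or np.any(self.radii <= 0):
            raise ValueError("densities and radii must be > 0")

    @property
    def n_particles(self) -> int:
        return len(self.densities)

    @property
    def volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * self.radii**3

    @classmethod
    def from_mixture(
        cls,
        n_particles: int,
        density_mixture: list[tuple[float, float, float]],
        config: MagnetConfig,
        radius_mean: float = 1.0e-5,
        radius_cv: float = 0.15,
        susceptibility: float = -9.0e-6,
        injection_band: tuple[float, float] = (0.1, 0.9),
        seed: int | None = None,
    ) -> "ParticlePopulation":
        """Draw a population from a Gaussian density mixture.

        ``density_mixture`` is a list of ``(mean, sd, weight)`` in
        kg/m^3; weights must sum to 1.  Particles are released in a
        band near the cuvette bottom (fractions of d), mimicking
        bottom injection.
        """
        weights = np.array([w for _, _, w in density_mixture], dtype=float)
        if not math.isclose(weights.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        rng = np.random.default_rng(seed)
        comps = rng.choice(len(density_mixture), size=n_particles, p=weights)
        means = np.array([m for m, _, _ in density_mixture])
        sds = np.array([s for _, s, _ in density_mixture])
        densities = rng.normal(means[comps], sds[comps])
        densities = np.clip(densities, 1.0, None)
        radii = rng.normal(radius_mean, radius_cv * radius_mean, size=n_particles)
        radii = np.clip(radii, 0.1 * radius_mean, None)
        lo, hi = injection_band
        z0 = rng.uniform(lo * config.separation_d, hi * config.separation_d, n_particles)
        return cls(
            densities=densities,
            radii=radii,
            susceptibilities=np.full(n_particles, susceptibility),
            initial_positions=z0,
            seed=seed,
        )


@dataclass
class Trajectory:
    times: np.ndarray            # (T,) s
    positions: np.ndarray        # (T, N) m
    terminal_states: np.ndarray  # (N,) str
    population: ParticlePopulation
    config: MagnetConfig
    medium: ParamagneticMedium

    def terminal_positions(self) -> np.ndarray:
        return self.positions[-1]


def _net_force_vec(
    z: np.ndarray,
    volumes: np.ndarray,
    densities: np.ndarray,
    chis: np.ndarray,
    medium: ParamagneticMedium,
    config: MagnetConfig,
    constants: PhysicalConstants,
) -> np.ndarray:
    bz, dbz = axial_field(z, config)
    dchi = chis - medium.susceptibility_chi_m
    f_mag = dchi / constants.mu0 * volumes * bz * dbz
    f_grav = -(densities - medium.density_rho_m) * volumes * constants.g
    return f_mag + f_grav


def simulate_trajectories(
    population: ParticlePopulation,
    medium: ParamagneticMedium,
    config: MagnetConfig,
    duration: float = 1200.0,
    dt: float = 1.0,
    constants: PhysicalConstants = CONSTANTS,
    brownian: bool = False,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Integrate overdamped motion for every particle.

    Forward-Euler with automatic sub-stepping: a step is subdivided
    until the fastest particle moves less than d/100 per sub-step, so
    the displacement per force evaluation stays small relative to the
    field-gradient length scale.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    d = config.separation_d
    n = population.n_particles
    volumes = population.volumes
    drag = 6.0 * np.pi * medium.viscosity_eta * population.radii
    kbt = 1.380649e-23 * medium.temperature
    if brownian and rng is None:
        rng = np.random.default_rng(population.seed)

    n_steps = int(round(duration / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    positions = np.empty((n_steps + 1, n))
    z = np.clip(population.initial_positions.astype(float).copy(), 0.0, d)
    positions[0] = z
    # absorbed particles stop being integrated
    state = np.full(n, TerminalState.LEVITATING, dtype=object)
    active = (z > 0.0) & (z < d)
    state[z <= 0.0] = TerminalState.PRECIPITATED
    state[z >= d] = TerminalState.FLOATED

    max_step = d / 100.0
    for k in range(1, n_steps + 1):
        if active.any():
            idx = np.nonzero(active)[0]
            zi = z[idx]
            f = _net_force_vec(
                zi, volumes[idx], population.densities[idx],
                population.susceptibilities[idx], medium, config, constants,
            )
            if not np.all(np.isfinite(f)):
                raise FloatingPointError(
                    "non-finite net force encountered; check medium/analyte parameters"
                )
            v = f / drag[idx]
            vmax = np.max(np.abs(v)) if len(v) else 0.0
            n_sub = max(1, int(np.ceil(vmax * dt / max_step)))
            h = dt / n_sub
            for _ in range(n_sub):
                f = _net_force_vec(
                    zi, volumes[idx], population.densities[idx],
                    population.susceptibilities[idx], medium, config, constants,
                )
                zi = zi + f / drag[idx] * h
                if brownian:
                    diff = kbt / drag[idx]
                    zi = zi + rng.normal(0.0, np.sqrt(2.0 * diff * h))
                zi = np.clip(zi, 0.0, d)
            z[idx] = zi
            hit_bottom = idx[zi <= 0.0]
            hit_top = idx[zi >= d]
            state[hit_bottom] = TerminalState.PRECIPITATED
            state[hit_top] = TerminalState.FLOATED
            active[hit_bottom] = False
            active[hit_top] = False
        positions[k] = z
    return Trajectory(
        times=times,
        positions=positions,
        terminal_states=np.asarray(state, dtype=object),
        population=population,
        config=config,
        medium=medium,
    )


def classify_fractions(trajectory: Trajectory) -> dict[str, float]:
    """Proportions of particles by terminal state; sums to 1."""
    states = trajectory.terminal_states
    n = len(states)
    if n == 0:
        raise ValueError("empty trajectory")
    return {
        "levitating_fraction": float(np.sum(states == TerminalState.LEVITATING)) / n,
        "precipitated_fraction": float(np.sum(states == TerminalState.PRECIPITATED)) / n,
        "floated_fraction": float(np.sum(states == TerminalState.FLOATED)) / n,
    }


@dataclass(frozen=True)
class OpticsConfig:
    """Camera model for synthetic frames.

    The image covers the full magnet gap vertically: pixel row maps
    linearly to z, with the bottom of the gap at the last image row.
    Per-particle integrated intensity is proportional to particle
    volume; the point-spread function is an isotropic Gaussian.
    """

    image_height_px: int = 240
    image_width_px: int = 64
    psf_sigma_px: float = 2.0
    background_level: float = 100.0
    noise_sigma: float = 2.0
    frame_interval: float = 20.0
    intensity_per_volume: float = 2.5e20  # counts per m^3 of particle
    col_margin_px: int = 8

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")


def render_frames(
    trajectory: Trajectory,
    optics: OpticsConfig = OpticsConfig(),
    seed: int | None = None,
    start_time: float = 0.0,
) -> FrameSeries:
    """Render a trajectory into a synthetic time-lapse series.

    Frames are sampled at multiples of ``optics.frame_interval`` (which
    must land on integration time points) beginning at ``start_time``
    (camera start after cuvette insertion; recorded frame times are
    re-zeroed to it).  A 20-min run at 20 s spacing yields 61 frames
    including t = 0.
    """
    d = trajectory.config.separation_d
    h_px, w_px = optics.image_height_px, optics.image_width_px
    times = trajectory.times
    t_end = times[-1]
    if not 0.0 <= start_time <= t_end:
        raise ValueError("start_time outside the simulated span")
    n_frames = int(np.floor((t_end - start_time) / optics.frame_interval + 1e-9)) + 1
    frame_times = start_time + np.arange(n_frames) * optics.frame_interval
    # map frame times onto integration samples
    idx = []
    for t in frame_times:
        j = int(np.argmin(np.abs(times - t)))
        if abs(times[j] - t) > 1e-6 * max(1.0, optics.frame_interval):
            raise ValueError("frame_interval does not divide sampled times")
        idx.append(j)

    rng = np.random.default_rng(
        seed if seed is not None else trajectory.population.seed
    )
    n = trajectory.population.n_particles
    cols = (
        rng.uniform(optics.col_margin_px, w_px - optics.col_margin_px, size=n)
        if n
        else np.empty(0)
    )
    amps = optics.intensity_per_volume * trajectory.population.volumes

    sigma = optics.psf_sigma_px
    half = int(np.ceil(4 * sigma))

    frames = np.empty((n_frames, h_px, w_px))
    rows_axis = np.arange(h_px)
    for f_i, j in enumerate(idx):
        img = np.zeros((h_px, w_px))
        zs = trajectory.positions[j]
        # z -> image row (row 0 at top)
        rows = (1.0 - zs / d) * (h_px - 1)
        for p in range(n):
            r0, c0 = rows[p], cols[p]
            rr = np.exp(-((rows_axis - r0) ** 2) / (2 * sigma**2))
            c_lo = max(0, int(np.floor(c0)) - half)
            c_hi = min(w_px, int(np.ceil(c0)) + half + 1)
            cc = np.exp(-((np.arange(c_lo, c_hi) - c0) ** 2) / (2 * sigma**2))
            kernel = np.outer(rr, cc)
            kernel *= amps[p] / (2 * np.pi * sigma**2)
            img[:, c_lo:c_hi] += kernel
        img += optics.background_level
        if optics.noise_sigma > 0:
            img += rng.normal(0.0, optics.noise_sigma, size=img.shape)
        frames[f_i] = img

    frame_times = frame_times - start_time
    pixel_to_mm = d * 1000.0 / h_px
    roi = Roi(0, h_px, optics.col_margin_px, w_px - optics.col_margin_px)
    meta = {
        "start_time_s": start_time,
        "seed": seed if seed is not None else trajectory.population.seed,
        "gap_m": d,
        "optics": {
            "psf_sigma_px": sigma,
            "background_level": optics.background_level,
            "noise_sigma": optics.noise_sigma,
            "frame_interval": optics.frame_interval,
        },
    }
    return FrameSeries(
        frames=frames,
        times=frame_times,
        pixel_to_mm=pixel_to_mm,
        roi=roi,
        metadata=meta,
    )
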