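"""Synthetic donor cohorts at two fidelity levels.

Fingerprint-level generation draws donor fingerprints directly from
class-conditional bivariate normals with a donor-effect / replicate-
noise hierarchy (matching the triplicate acquisition design).
Image-level generation instead draws a particle population per donor
from a class density mixture, simulates the levitation run and renders
frames, so the full extraction pipeline can be exercised end to end.

All default effect sizes are synthetic: the study publishes no
fingerprint coordinates, only the qualitative class structure (the
pancreatic class shifted most in starting position relative to the
healthy reference, the breast class in the opposite direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import FrameSeries
from .physics import MagnetConfig, ParamagneticMedium
from .simulate import (
    OpticsConfig,
    ParticlePopulation,
    classify_fractions,
    render_frames,
    simulate_trajectories,
)
from .stats import Cohort

__all__ = [
    "ClassSpec",
    "default_class_specs",
    "generate_fingerprint_cohort",
    "cohort_from_replicates",
    "generate_image_cohort",
    "generate_saxs_curve",
]


@dataclass(frozen=True)
class ClassSpec:
    """Generator parameters for one donor class."""

    class_name: str
    fingerprint_mean: tuple[float, float]        # (mm, area)
    fingerprint_cov: tuple = ((0.25, 0.0), (0.0, 0.04))
    n_donors: int = 5
    n_replicates: int = 3
    replicate_cov_scale: float = 0.25            # replicate noise vs donor effect
    density_mixture: tuple = (
        (1350.0, 30.0, 0.7),                     # precipitating fraction
        (1062.0, 4.0, 0.3),                      # levitating fraction
    )
    n_particles: int = 150
    seed: int | None = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.fingerprint_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("fingerprint_cov must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("fingerprint_cov must be positive semidefinite")
        w = sum(wi for _, _, wi in self.density_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("density_mixture weights must sum to 1")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")

    @property
    def cov(self) -> np.ndarray:
        return np.asarray(self.fingerprint_cov, dtype=float)


def default_class_specs(
    n_nop: int = 15,
    n_per_cancer: int = 5,
    n_pdac: int = 15,
) -> list[ClassSpec]:
    """Five-class cohort shaped like the study design (15/5/5/5/15 donors).

    Means and covariances are synthetic; the pancreatic class is the
    most shifted in starting position, the breast class is shifted the
    opposite way, and the prostate/colorectal classes overlap the
    healthy reference.
    """
    base_cov = ((0.50, 0.02), (0.02, 0.06))
    return [
        ClassSpec("NOP", (12.0, 2.0), base_cov, n_donors=n_nop),
        ClassSpec("breast", (10.8, 2.1), base_cov, n_donors=n_per_cancer),
        ClassSpec("prostate", (12.3, 2.05), base_cov, n_donors=n_per_cancer),
        ClassSpec("colorectal", (12.4, 1.95), base_cov, n_donors=n_per_cancer),
        ClassSpec(
            "PDAC",
            (14.6, 1.6),
            base_cov,
            n_donors=n_pdac,
            density_mixture=((1350.0, 30.0, 0.75), (1058.5, 4.0, 0.25)),
        ),
    ]


def generate_fingerprint_cohort(
    specs: list[ClassSpec],
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate-level fingerprint table for a multi-class cohort.

    Per donor, a donor-level mean is drawn from the class distribution
    and ``n_replicates`` replicates are drawn around it with covariance
    ``replicate_cov_scale * fingerprint_cov``.  Columns: donor_id,
    replicate_id, class, starting_position_mm, levitating_area.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        spec_rng = rng if spec.seed is None else np.random.default_rng(spec.seed)
        rep_cov = spec.replicate_cov_scale * spec.cov
        for i in range(spec.n_donors):
            donor_id = f"{spec.class_name}-{i + 1:03d}"
            donor_mean = spec_rng.multivariate_normal(spec.fingerprint_mean, spec.cov)
            for j in range(spec.n_replicates):
                point = spec_rng.multivariate_normal(donor_mean, rep_cov)
                rows.append(
                    {
                        "donor_id": donor_id,
                        "replicate_id": f"r{j + 1}",
                        "class": spec.class_name,
                        "starting_position_mm": point[0],
                        "levitating_area": max(point[1], 0.0),
                    }
                )
    return pd.DataFrame(rows)


def cohort_from_replicates(table: pd.DataFrame) -> Cohort:
    """Average replicates per donor and build a donor-level cohort."""
    agg = (
        table.groupby(["donor_id", "class"], as_index=False)[
            ["starting_position_mm", "levitating_area"]
        ]
        .mean()
        .sort_values("donor_id", kind="stable")
        .reset_index(drop=True)
    )
    return Cohort.from_frame(agg)


def generate_image_cohort(
    specs: list[ClassSpec],
    config: MagnetConfig | None = None,
    medium: ParamagneticMedium | None = None,
    optics: OpticsConfig | None = None,
    seed: int | None = None,
    duration: float = 1200.0,
    dt: float = 2.0,
    settle_time: float = 600.0,
) -> tuple[dict[str, FrameSeries], pd.DataFrame]:
    """Per-donor synthetic frame series plus a ground-truth table.

    Each donor gets one rendered levitation run whose particle
    population is drawn from the class density mixture.  The camera
    starts ``settle_time`` seconds after insertion, so the first
    recorded frame already carries the early class-dependent migration
    (this is what makes the starting position informative).  The
    returned table records the drawn population summary and simulated
    terminal fractions per donor for oracle checks.
    """
    config = config or MagnetConfig()
    medium = medium or ParamagneticMedium()
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    series: dict[str, FrameSeries] = {}
    rows = []
    for spec in specs:
        for i in range(spec.n_donors):
            donor_id = f"{spec.class_name}-{i + 1:03d}"
            pop_seed = int(rng.integers(0, 2**31 - 1))
            pop = ParticlePopulation.from_mixture(
                n_particles=spec.n_particles,
                density_mixture=list(spec.density_mixture),
                config=config,
                seed=pop_seed,
            )
            traj = simulate_trajectories(
                pop, medium, config, duration=settle_time + duration, dt=dt
            )
            fs = render_frames(traj, optics, seed=pop_seed, start_time=settle_time)
            fs.metadata["donor_id"] = donor_id
            fs.metadata["class"] = spec.class_name
            series[donor_id] = fs
            frac = classify_fractions(traj)
            lev = traj.terminal_states == "levitating"
            rows.append(
                {
                    "donor_id": donor_id,
                    "class": spec.class_name,
                    "seed": pop_seed,
                    "mean_density": float(pop.densities.mean()),
                    "levitating_fraction": frac["levitating_fraction"],
                    "precipitated_fraction": frac["precipitated_fraction"],
                    "floated_fraction": frac["floated_fraction"],
                    "mean_levitating_height_m": (
                        float(traj.terminal_positions()[lev].mean())
                        if lev.any()
                        else np.nan
                    ),
                }
            )
    return series, pd.DataFrame(rows)


def generate_saxs_curve(
    exponent: float,
    q_range: tuple[float, float] = (0.1, 1.0),
    n_points: int = 100,
    noise_cv: float = 0.02,
    amplitude: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic power-law scattering curve I = A q^-D on log-spaced q.

    Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (unit mean).
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    lo, hi = q_range
    if lo <= 0 or hi <= lo:
        raise ValueError("q_range must be positive and increasing")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    q = np.logspace(np.log10(lo), np.log10(hi), n_points)
    intensity = amplitude * q**-exponent
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_points)
        intensity = intensity * noise
    return q, intensity
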