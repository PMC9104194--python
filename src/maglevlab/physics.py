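"""Magneto-Archimedes levitation physics.

A diamagnetic object immersed in a paramagnetic solution between two
like-facing permanent magnets settles where the magnetic body force and
the buoyancy-corrected weight cancel.  This module provides the force
balance, the closed-form levitation height for the linear axial field,
a numerical equilibrium solver that also handles the analytic
cuboid-magnet field, and a first-principles estimate of the medium's
volume susceptibility from the Dy(III) salt concentration.

All quantities are SI internally (m, kg, s, T).  Helper formatters for
mm/cm are provided for display; see :func:`format_length`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const
from scipy.optimize import brentq

__all__ = [
    "MagnetConfig",
    "PhysicalConstants",
    "CONSTANTS",
    "ParamagneticMedium",
    "Analyte",
    "FieldModel",
    "LevitationOutcome",
    "EquilibriumResult",
    "SingularParametersError",
    "curie_molar_susceptibility",
    "medium_susceptibility",
    "axial_field",
    "net_force",
    "levitation_height_closed_form",
    "solve_equilibrium",
    "format_length",
    "parse_length",
]

# Dy(NO3)3 anhydrous molar mass, g/mol
DY_NITRATE_MOLAR_MASS = 348.52
# effective moment of Dy3+ in Bohr magnetons (free-ion value)
DY_EFFECTIVE_MOMENT_BOHR = 10.6
# volume susceptibility of water at room temperature, SI (dimensionless)
WATER_SUSCEPTIBILITY = -9.0e-6


class SingularParametersError(ValueError):
    """Raised when sample and medium susceptibilities coincide."""


class FieldModel(str, enum.Enum):
    LINEAR_AXIAL = "linear_axial"
    CUBOID_ANALYTIC = "cuboid_analytic"


class LevitationOutcome(str, enum.Enum):
    LEVITATING = "levitating"
    PRECIPITATES = "precipitates"
    FLOATS = "floats"


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants used by the force balance."""

    mu0: float = _const.mu_0          # T m / A
    g: float = _const.g               # m / s^2


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class MagnetConfig:
    """Geometry and surface field of the two-magnet device.

    ``separation_d`` is the gap between the opposing magnet faces; the
    axial coordinate z runs from 0 at the lower face to ``separation_d``
    at the upper face, positive up.
    """

    separation_d: float = 0.028
    surface_field_b0: float = 0.5
    magnet_width: float = 0.025
    magnet_length: float = 0.025
    magnet_height: float = 0.05
    field_model: FieldModel = FieldModel.LINEAR_AXIAL

    def __post_init__(self) -> None:
        if self.separation_d <= 0:
            raise ValueError("separation_d must be > 0")
        if self.surface_field_b0 <= 0:
            raise ValueError("surface_field_b0 must be > 0")
        for name in ("magnet_width", "magnet_length", "magnet_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        object.__setattr__(self, "field_model", FieldModel(self.field_model))


@dataclass(frozen=True)
class ParamagneticMedium:
    """Aqueous paramagnetic solution (Dy(III) nitrate by default)."""

    density_rho_m: float = 1060.0
    susceptibility_chi_m: float = field(default=None)  # type: ignore[assignment]
    dy_concentration: float = 80.0    # mg/mL
    viscosity_eta: float = 0.9e-3     # Pa s at 25 degC
    temperature: float = 298.15       # K

    def __post_init__(self) -> None:
        if self.susceptibility_chi_m is None:
            chi = medium_susceptibility(
                self.dy_concentration,
                temperature=self.temperature,
            )
            object.__setattr__(self, "susceptibility_chi_m", chi)
        if self.density_rho_m <= 0:
            raise ValueError("density_rho_m must be > 0")
        if self.viscosity_eta <= 0:
            raise ValueError("viscosity_eta must be > 0")
        if self.susceptibility_chi_m <= 0:
            raise ValueError("medium must be paramagnetic (chi_m > 0)")


@dataclass(frozen=True)
class Analyte:
    """A diamagnetic object (corona-coated particle ensemble member)."""

    density_rho_s: float
    susceptibility_chi_s: float = WATER_SUSCEPTIBILITY
    volume_v: float = 4.19e-15        # ~10 um radius sphere
    radius: float = 1.0e-5            # hydrodynamic radius for Stokes drag

    def __post_init__(self) -> None:
        if self.density_rho_s <= 0:
            raise ValueError("density_rho_s must be > 0")
        if self.volume_v <= 0:
            raise ValueError("volume_v must be > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of a levitation-height computation.

    ``height`` is in metres and is ``None`` unless the outcome is
    ``LEVITATING``.
    """

    outcome: LevitationOutcome
    height: float | None = None

    @property
    def in_range(self) -> bool:
        return self.outcome is LevitationOutcome.LEVITATING


def curie_molar_susceptibility(
    mu_eff_bohr: float = DY_EFFECTIVE_MOMENT_BOHR,
    temperature: float = 298.15,
) -> float:
    """Curie-law molar susceptibility (SI, m^3/mol) for a paramagnetic ion.

    chi_mol = mu0 * N_A * mu_eff^2 * mu_B^2 / (3 kB T).
    """
    mu = mu_eff_bohr * _const.value("Bohr magneton")
    return _const.mu_0 * _const.N_A * mu**2 / (3.0 * _const.k * temperature)


def medium_susceptibility(
    dy_concentration: float,
    molar_mass: float = DY_NITRATE_MOLAR_MASS,
    molar_susceptibility: float | None = None,
    solvent_susceptibility: float = WATER_SUSCEPTIBILITY,
    temperature: float = 298.15,
) -> float:
    """Volume susceptibility of the paramagnetic medium.

    Parameters
    ----------
    dy_concentration : mg/mL of the dissolved paramagnetic salt.
    molar_mass : g/mol of the salt.
    molar_susceptibility : SI molar susceptibility (m^3/mol) of the ion;
        defaults to the Curie-law value for Dy3+ at ``temperature``.
    solvent_susceptibility : dimensionless volume susceptibility of the
        solvent (water).
    """
    if dy_concentration < 0:
        raise ValueError("dy_concentration must be >= 0")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    if molar_susceptibility is None:
        molar_susceptibility = curie_molar_susceptibility(temperature=temperature)
    # mg/mL == g/L; mol/m^3 = (g/L / g/mol) * 1000
    molar_conc = dy_concentration / molar_mass * 1000.0
    return molar_susceptibility * molar_conc + solvent_susceptibility


# --- axial magnetic field models -------------------------------------------

def _cuboid_face_term(x, a, b):
    """atan2 form of the on-axis field term of one rectangular pole face."""
    x = np.asarray(x, dtype=float)
    s = np.sqrt(4.0 * x * x + a * a + b * b)
    return np.arctan2(a * b, 2.0 * x * s)


def _cuboid_face_term_deriv(x, a, b):
    x = np.asarray(x, dtype=float)
    s = np.sqrt(4.0 * x * x + a * a + b * b)
    f = 2.0 * x * s
    fp = (16.0 * x * x + 2.0 * a * a + 2.0 * b * b) / s
    return -a * b * fp / (f * f + a * a * b * b)


def _cuboid_block_field(x, a, b, length):
    """Unscaled on-axis field of a single block magnet at distance x from its face."""
    return _cuboid_face_term(x, a, b) - _cuboid_face_term(x + length, a, b)


def _cuboid_block_field_deriv(x, a, b, length):
    return _cuboid_face_term_deriv(x, a, b) - _cuboid_face_term_deriv(
        x + length, a, b
    )


def axial_field(z, config: MagnetConfig):
    """Signed axial field component Bz and its gradient at height(s) z.

    z is measured from the lower magnet face, positive up, and must lie
    in [0, separation_d].  Returns ``(Bz, dBz_dz)`` in T and T/m; both
    are scalars for scalar z and arrays for array z.

    ``linear_axial``: Bz(z) = B0 (1 - 2 z / d), the field whose
    equilibrium is the closed-form height.  ``cuboid_analytic``:
    superposition of two analytic block-magnet axial fields with
    opposing polarity, scaled so |Bz(0)| = B0.
    """
    z_arr = np.asarray(z, dtype=float)
    d = config.separation_d
    b0 = config.surface_field_b0
    if np.any(z_arr < 0) or np.any(z_arr > d):
        raise ValueError(f"z must lie within [0, {d}] m")

    if config.field_model is FieldModel.LINEAR_AXIAL:
        bz = b0 * (1.0 - 2.0 * z_arr / d)
        dbz = np.full_like(z_arr, -2.0 * b0 / d)
    else:
        a, b, length = config.magnet_width, config.magnet_length, config.magnet_height
        raw0 = _cuboid_block_field(0.0, a, b, length) - _cuboid_block_field(
            d, a, b, length
        )
        scale = b0 / raw0
        bz = scale * (
            _cuboid_block_field(z_arr, a, b, length)
            - _cuboid_block_field(d - z_arr, a, b, length)
        )
        dbz = scale * (
            _cuboid_block_field_deriv(z_arr, a, b, length)
            + _cuboid_block_field_deriv(d - z_arr, a, b, length)
        )
    if np.isscalar(z) or np.ndim(z) == 0:
        return float(bz), float(dbz)
    return bz, dbz


def net_force(
    z,
    analyte: Analyte,
    medium: ParamagneticMedium,
    config: MagnetConfig,
    constants: PhysicalConstants = CONSTANTS,
):
    """Signed vertical force (N, positive up) on the analyte at height z.

    Sum of the magnetic body force ((chi_s - chi_m)/mu0) V Bz dBz/dz and
    the buoyancy-corrected weight -(rho_s - rho_m) V g.
    """
    bz, dbz = axial_field(z, config)
    dchi = analyte.susceptibility_chi_s - medium.susceptibility_chi_m
    f_mag = dchi / constants.mu0 * analyte.volume_v * bz * dbz
    f_grav = -(analyte.density_rho_s - medium.density_rho_m) * analyte.volume_v * constants.g
    return f_mag + f_grav


def levitation_height_closed_form(
    analyte: Analyte,
    medium: ParamagneticMedium,
    config: MagnetConfig,
    constants: PhysicalConstants = CONSTANTS,
) -> EquilibriumResult:
    """Closed-form equilibrium height for the linear axial field.

    h = d/2 + (rho_s - rho_m) g mu0 d^2 / (4 (chi_s - chi_m) B0^2).

    Out-of-range equilibria are reported categorically: ``PRECIPITATES``
    if h < 0, ``FLOATS`` if h > d.
    """
    dchi = analyte.susceptibility_chi_s - medium.susceptibility_chi_m
    if dchi == 0:
        raise SingularParametersError(
            "chi_s == chi_m: levitation height undefined"
        )
    d = config.separation_d
    b0 = config.surface_field_b0
    drho = analyte.density_rho_s - medium.density_rho_m
    h = d / 2.0 + drho * constants.g * constants.mu0 * d**2 / (4.0 * dchi * b0**2)
    if h < 0:
        return EquilibriumResult(LevitationOutcome.PRECIPITATES)
    if h > d:
        return EquilibriumResult(LevitationOutcome.FLOATS)
    return EquilibriumResult(LevitationOutcome.LEVITATING, h)


def solve_equilibrium(
    analyte: Analyte,
    medium: ParamagneticMedium,
    config: MagnetConfig,
    constants: PhysicalConstants = CONSTANTS,
    z_tol: float = 1.0e-9,
    n_scan: int = 256,
) -> EquilibriumResult:
    """Numerical equilibrium: root of the net force over [0, d].

    Scans for sign changes, brackets each root with Brent's method, and
    returns the stable one (negative force gradient).  If the force has
    no zero in [0, d] the particle ends up at a wall: ``PRECIPITATES``
    when the force is downward, ``FLOATS`` when upward.
    """
    d = config.separation_d

    def f(z):
        return net_force(z, analyte, medium, config, constants)

    zs = np.linspace(0.0, d, n_scan)
    fs = np.asarray(f(zs))
    roots: list[float] = []
    for i in range(n_scan - 1):
        lo, hi = fs[i], fs[i + 1]
        if lo == 0.0:
            roots.append(float(zs[i]))
        elif lo * hi < 0:
            roots.append(float(brentq(f, zs[i], zs[i + 1], xtol=z_tol)))
    if fs[-1] == 0.0:
        roots.append(float(zs[-1]))

    # dedupe near-identical roots from the scan grid
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 10 * z_tol:
            uniq.append(r)

    if not uniq:
        direction = LevitationOutcome.PRECIPITATES if fs.mean() < 0 else LevitationOutcome.FLOATS
        return EquilibriumResult(direction)

    stable = [r for r in uniq if _force_gradient(f, r, d) < 0]
    if len(uniq) > 1:
        warnings.warn(
            f"multiple force-balance roots found ({len(uniq)}); "
            "returning the stable one",
            stacklevel=2,
        )
    chosen = stable[0] if stable else uniq[0]
    return EquilibriumResult(LevitationOutcome.LEVITATING, chosen)


def _force_gradient(f, z: float, d: float, rel_h: float = 1.0e-6) -> float:
    h = d * rel_h
    lo, hi = max(0.0, z - h), min(d, z + h)
    return (f(hi) - f(lo)) / (hi - lo)


# --- display units ---------------------------------------------------------

# decimal exponent of each display unit relative to the metre
_LENGTH_UNITS = {"m": 0, "cm": 2, "mm": 3, "um": 6}


def format_length(value_m: float, unit: str = "mm") -> str:
    """Format a length (m) in a display unit, bit-exactly recoverable.

    Scaling is done in decimal arithmetic (exact for powers of ten), so
    ``parse_length(format_length(x, u)) == x`` for every finite float x.
    """
    from decimal import Decimal

    if unit not in _LENGTH_UNITS:
        raise ValueError(f"unknown unit {unit!r}")
    scaled = Decimal(value_m).scaleb(_LENGTH_UNITS[unit])
    return f"{scaled} {unit}"


def parse_length(text: str) -> float:
    """Parse the output of :func:`format_length` back to metres."""
    from decimal import Decimal

    num, unit = text.rsplit(" ", 1)
    if unit not in _LENGTH_UNITS:
        raise ValueError(f"unknown unit {unit!r}")
    return float(Decimal(num).scaleb(-_LENGTH_UNITS[unit]))
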