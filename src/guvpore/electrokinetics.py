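"""Electric membrane tension, the pore-nucleation rate law and prepore
free-energy landscapes.

Under a DC field E a vesicle of radius R develops the membrane potential
V_m = 1.5 R E (membrane charging assumed instantaneous).  The Maxwell
stress of the accumulated interfacial charge puts a lateral tension on the
bilayer,

    sigma_c = eps_m eps_0 (h / (2 h_e^2)) V_m^2,

which with the default dielectric constants simplifies to
sigma_c = 22.86 (R E)^2 mN/m for R in m and E in V/m.

Pore nucleation is modelled as escape over the prepore free-energy barrier
(mean-first-passage-time / Kramers form):

    k_p(sigma_t) = A_F (sigma_t + B) exp[-pi Gamma^2 / (k T (sigma_t + B))]

with line tension Gamma, electrostatic term B (an input constant for
charged membranes) and pre-exponential factor A_F.  The prepore free
energy is U(r) = 2 pi Gamma r - pi r^2 (sigma_t + B) with critical radius
r_c = Gamma / (sigma_t + B) and barrier U_b = pi Gamma^2 / (sigma_t + B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import CONSTANTS, PhysicalConstants
from .membrane import MembraneSpec

__all__ = [
    "FieldProtocol",
    "KineticParams",
    "PreporeProfile",
    "CHOL_KINETICS",
    "DOPG_DOPC_KINETICS",
    "KINETIC_PRESETS",
    "membrane_potential",
    "electric_tension",
    "electric_tension_coefficient",
    "field_for_tension",
    "rate_constant",
    "invert_rate",
    "prepore_energy",
    "critical_radius",
    "barrier",
    "profile",
    "total_tension",
    "temperature_sensitivity",
]


@dataclass(frozen=True)
class FieldProtocol:
    """Field protocol applied to one GUV.

    The field ramps from ``baseline_field`` to ``target_field`` over
    ``ramp_duration`` seconds, then holds for ``hold_duration`` seconds.
    Default baseline 3.2e4 V/m (320 V/cm), ramp ~7 s, hold 60 s.
    """

    target_field: float
    guv_radius: float
    baseline_field: float = 3.2e4
    ramp_duration: float = 7.0
    hold_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.target_field < 0 or self.baseline_field < 0:
            raise ValueError("fields must be non-negative")
        if self.ramp_duration < 0 or self.hold_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.guv_radius <= 0:
            raise ValueError("guv_radius must be positive")


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the pore-nucleation rate law.

    line_tension (Gamma) in N; electrostatic_term (B) in N/m;
    prefactor (A_F) in m^2 s^-1 J^-1; temperature in K.
    """

    line_tension: float
    electrostatic_term: float
    prefactor: float
    temperature: float = CONSTANTS.default_temperature

    def __post_init__(self) -> None:
        if self.line_tension <= 0:
            raise ValueError("line_tension must be positive")
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        if self.electrostatic_term < 0:
            raise ValueError("electrostatic_term must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


#: Fitted parameters for DOPG/DOPC/chol(46/39/15) membranes.
CHOL_KINETICS = KineticParams(
    line_tension=12.9e-12, electrostatic_term=2.14e-3, prefactor=8.4e5
)
#: Fitted parameters for DOPG/DOPC(40/60) membranes.
DOPG_DOPC_KINETICS = KineticParams(
    line_tension=12.1e-12, electrostatic_term=1.76e-3, prefactor=8.8e6
)

KINETIC_PRESETS: dict[str, KineticParams] = {
    "DOPG/DOPC/chol(46/39/15)": CHOL_KINETICS,
    "DOPG/DOPC(40/60)": DOPG_DOPC_KINETICS,
}


@dataclass(frozen=True)
class PreporeProfile:
    """Free-energy profile U(r) of a prepore at fixed total tension."""

    radii: np.ndarray
    energies: np.ndarray
    critical_radius: float
    barrier: float
    tension: float

    def as_kT(self, constants: PhysicalConstants = CONSTANTS, temperature: float | None = None) -> np.ndarray:
        """Energies in units of k_B T."""
        T = constants.default_temperature if temperature is None else temperature
        return self.energies / (constants.boltzmann_k * T)


def membrane_potential(R: float, E: float) -> float:
    """Membrane potential V_m = 1.5 R E, in V (instantaneous charging)."""
    if R < 0 or E < 0:
        raise ValueError("R and E must be non-negative")
    return 1.5 * R * E


def electric_tension_coefficient(
    spec: MembraneSpec, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Coefficient c such that sigma_c = c (R E)^2, in N/m per V^2.

    c = 1.5^2 eps_m eps_0 h / (2 h_e^2); equals 22.86e-3 to the printed
    precision with the default dielectric constants.
    """
    if spec.dielectric_thickness <= 0:
        raise ValueError("dielectric thickness must be positive")
    return (
        2.25
        * spec.membrane_permittivity
        * constants.vacuum_permittivity
        * spec.thickness
        / (2.0 * spec.dielectric_thickness**2)
    )


def electric_tension(
    spec: MembraneSpec, R: float, E: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Maxwell-stress electric tension sigma_c, N/m, for radius R (m) and
    field E (V/m)."""
    Vm = membrane_potential(R, E)
    return (
        spec.membrane_permittivity
        * constants.vacuum_permittivity
        * spec.thickness
        / (2.0 * spec.dielectric_thickness**2)
        * Vm**2
    )


def field_for_tension(
    spec: MembraneSpec,
    R: float,
    sigma_c: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Field E (V/m) that produces electric tension ``sigma_c`` on a GUV of
    radius R: the exact inverse of :func:`electric_tension`."""
    if sigma_c < 0:
        raise ValueError("sigma_c must be non-negative")
    if R <= 0:
        raise ValueError("R must be positive")
    coef = electric_tension_coefficient(spec, constants)
    return math.sqrt(sigma_c / coef) / R


def rate_constant(
    sigma_t: float | np.ndarray,
    params: KineticParams,
    constants: PhysicalConstants = CONSTANTS,
) -> float | np.ndarray:
    """Pore-nucleation rate k_p(sigma_t), s^-1.

    k_p = A_F (sigma_t + B) exp[-pi Gamma^2 / (k T (sigma_t + B))].
    Strictly increasing in sigma_t; vanishes as sigma_t + B -> 0+.
    """
    x = np.asarray(sigma_t, dtype=float) + params.electrostatic_term
    if np.any(x <= 0):
        raise ValueError("sigma_t + B must be positive")
    kT = constants.boltzmann_k * params.temperature
    out = params.prefactor * x * np.exp(
        -math.pi * params.line_tension**2 / (kT * x)
    )
    return float(out) if np.isscalar(sigma_t) else out


def invert_rate(
    k_p: float,
    params: KineticParams,
    constants: PhysicalConstants = CONSTANTS,
    bracket: tuple[float, float] = (1e-6, 1.0),
) -> float:
    """Tension sigma_t (N/m) at which the rate law yields ``k_p``.

    The rate law is strictly increasing in sigma_t, so the root is unique;
    solved by bracketed root finding in log-rate space with automatic
    bracket expansion.  Relative tolerance 1e-10.
    """
    if k_p <= 0:
        raise ValueError("k_p must be positive")
    log_target = math.log(k_p)
    kT = constants.boltzmann_k * params.temperature
    c = math.pi * params.line_tension**2 / kT
    log_A = math.log(params.prefactor)
    B = params.electrostatic_term

    # analytic log-rate avoids exp underflow at tiny tension
    def f(sigma: float) -> float:
        x = sigma + B
        return log_A + math.log(x) - c / x - log_target

    lo, hi = bracket
    for _ in range(80):
        if f(hi) >= 0:
            break
        hi *= 2.0
    else:
        raise ValueError(
            f"k_p = {k_p:g} s^-1 exceeds any representable rate "
            f"(bracket expansion up to sigma_t = {hi:g} N/m failed)"
        )
    for _ in range(400):
        if f(lo) <= 0:
            break
        lo /= 2.0
    else:
        raise ValueError(f"could not bracket root for k_p = {k_p:g} s^-1")
    return brentq(f, lo, hi, rtol=1e-12, xtol=1e-18)


def prepore_energy(
    r: float | np.ndarray, sigma_t: float, params: KineticParams
) -> float | np.ndarray:
    """Prepore free energy U(r) = 2 pi Gamma r - pi r^2 (sigma_t + B), J."""
    rr = np.asarray(r, dtype=float)
    if np.any(rr < 0):
        raise ValueError("r must be non-negative")
    x = sigma_t + params.electrostatic_term
    out = 2.0 * math.pi * params.line_tension * rr - math.pi * rr**2 * x
    return float(out) if np.isscalar(r) else out


def critical_radius(sigma_t: float, params: KineticParams) -> float:
    """Critical prepore radius r_c = Gamma / (sigma_t + B), m."""
    x = sigma_t + params.electrostatic_term
    if x <= 0:
        raise ValueError("sigma_t + B must be positive")
    return params.line_tension / x


def barrier(sigma_t: float, params: KineticParams) -> float:
    """Free-energy barrier U_b = pi Gamma^2 / (sigma_t + B), J."""
    x = sigma_t + params.electrostatic_term
    if x <= 0:
        raise ValueError("sigma_t + B must be positive")
    return math.pi * params.line_tension**2 / x


def profile(
    sigma_t: float,
    params: KineticParams,
    r_max: float | None = None,
    n_points: int = 501,
) -> PreporeProfile:
    """Tabulated prepore free-energy profile on [0, r_max].

    ``r_max`` defaults to 3 r_c so the barrier sits well inside the grid.
    """
    rc = critical_radius(sigma_t, params)
    if r_max is None:
        r_max = 3.0 * rc
    if r_max <= 0 or n_points < 2:
        raise ValueError("r_max must be positive and n_points >= 2")
    radii = np.linspace(0.0, r_max, n_points)
    energies = prepore_energy(radii, sigma_t, params)
    return PreporeProfile(
        radii=radii,
        energies=energies,
        critical_radius=rc,
        barrier=barrier(sigma_t, params),
        tension=sigma_t,
    )


def total_tension(sigma_c: float, sigma_os: float) -> float:
    """Total membrane tension sigma_t = sigma_c + sigma_os, N/m."""
    if not (math.isfinite(sigma_c) and math.isfinite(sigma_os)):
        raise ValueError("tensions must be finite")
    return sigma_c + sigma_os


def temperature_sensitivity(
    sigma_t: float,
    params: KineticParams,
    delta_T: float = 1.0,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[float, float, float]:
    """Rate at T - dT, T and T + dT, for gauging the +/-1 K thermostat
    uncertainty of the experiment."""
    rates = []
    for T in (params.temperature - delta_T, params.temperature, params.temperature + delta_T):
        p = KineticParams(
            line_tension=params.line_tension,
            electrostatic_term=params.electrostatic_term,
            prefactor=params.prefactor,
            temperature=T,
        )
        rates.append(rate_constant(sigma_t, p, constants))
    return tuple(rates)  # type: ignore[return-value]
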