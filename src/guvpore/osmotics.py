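"""Solution bookkeeping and the osmotic membrane tension at swelling
equilibrium.

The experimental chain this module reproduces: GUVs grow in buffer with
sucrose inside; the suspension is diluted slightly at pre-hydration, then a
small volume of it is mixed into a chamber filled with a lower-osmolarity
glucose buffer.  The resulting inside-minus-outside osmolarity difference
``delta_C0`` drives water influx; at swelling equilibrium the membrane
carries a lateral tension set by ``delta_C0``, the external osmolarity and
the area compressibility modulus K_A.

Osmolarities come from linear osmometer calibrations (mOsm/L versus mM);
1 mOsm/L is numerically 1 mol/m^3, so SI conversions are trivial.
Internally everything is kept at full precision; integer mOsm/L and
one-decimal mN/m appear only in the reporting helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .constants import CONSTANTS, PhysicalConstants
from .membrane import MembraneSpec

__all__ = [
    "SoluteCalibration",
    "OsmoticCondition",
    "SUCROSE_CALIBRATION",
    "GLUCOSE_CALIBRATION",
    "osmolarity",
    "dilute_osmolarity",
    "chamber_mixing",
    "build_condition",
    "osmotic_pressure",
    "osmotic_tension",
    "propagate_tension_error",
    "equilibrium_radius_increase",
]


@dataclass(frozen=True)
class SoluteCalibration:
    """Linear osmometer calibration: osmolarity = slope * C + intercept.

    ``slope`` in (mOsm/L)/mM, ``intercept`` in mOsm/L (the buffer's own
    osmolarity at zero added solute).
    """

    solute: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.intercept <= 0:
            raise ValueError("calibration slope and intercept must be positive")


#: Osmometer calibrations for sucrose and glucose in the working buffer.
SUCROSE_CALIBRATION = SoluteCalibration("sucrose", 1.029, 292.9)
GLUCOSE_CALIBRATION = SoluteCalibration("glucose", 1.010, 294.2)

#: Single-measurement osmometer uncertainty, mOsm/L.
DEFAULT_OSMOMETER_ERROR = 2.8


@dataclass(frozen=True)
class OsmoticCondition:
    """One osmotic condition of a rupture experiment.

    ``delta_C0 = C_in0 - C_out`` is enforced exactly.  ``delta_C0_error``
    defaults to the quadrature sum of the two osmometer readings that enter
    the difference.  All osmolarities in mOsm/L (= mol/m^3).
    """

    C_in0: float
    C_out: float
    delta_C0: float = field(default=None)  # type: ignore[assignment]
    osmometer_error: float = DEFAULT_OSMOMETER_ERROR
    delta_C0_error: float = field(default=None)  # type: ignore[assignment]
    initial_radius: float = 10e-6
    temperature: float = CONSTANTS.default_temperature
    equilibrium_radius_increase: float | None = None

    def __post_init__(self) -> None:
        if self.C_out <= 0:
            raise ValueError("C_out must be positive")
        if self.initial_radius <= 0:
            raise ValueError("initial_radius must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        expected = self.C_in0 - self.C_out
        if self.delta_C0 is None:
            object.__setattr__(self, "delta_C0", expected)
        elif abs(self.delta_C0 - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("delta_C0 must equal C_in0 - C_out exactly")
        if self.delta_C0_error is None:
            object.__setattr__(
                self, "delta_C0_error", math.hypot(self.osmometer_error, self.osmometer_error)
            )
        if self.delta_C0 < 0:
            warnings.warn(
                "hypertonic condition: delta_C0 < 0 (outside osmolarity exceeds inside)",
                stacklevel=3,
            )

    @property
    def is_hypertonic(self) -> bool:
        return self.delta_C0 < 0

    def rounded(self) -> dict[str, int]:
        """Integer-mOsm/L view for reporting (exact values kept internally)."""
        return {
            "C_in0_mOsm": round(self.C_in0),
            "C_out_mOsm": round(self.C_out),
            "delta_C0_mOsm": round(self.C_in0) - round(self.C_out),
        }

    def with_overrides(self, **kwargs) -> "OsmoticCondition":
        if ("C_in0" in kwargs or "C_out" in kwargs) and "delta_C0" not in kwargs:
            kwargs["delta_C0"] = None
        return replace(self, **kwargs)


def osmolarity(calibration: SoluteCalibration, concentration_mM: float) -> float:
    """Osmolarity (mOsm/L) of a solution from its solute concentration (mM)."""
    if concentration_mM < 0:
        raise ValueError("concentration must be non-negative")
    return calibration.slope * concentration_mM + calibration.intercept


def dilute_osmolarity(
    osm: float, solution_volume: float, added_water_volume: float
) -> float:
    """Osmolarity after adding pure water: osm * V / (V + V_added).

    Volumes may be in any common unit.
    """
    if solution_volume <= 0:
        raise ValueError("solution volume must be positive")
    if added_water_volume < 0:
        raise ValueError("added water volume must be non-negative")
    return osm * solution_volume / (solution_volume + added_water_volume)


def chamber_mixing(
    C_chamber: float,
    V_chamber: float,
    C_suspension: float,
    V_suspension: float,
) -> float:
    """Total external solute concentration (mM) after mixing the GUV
    suspension into the chamber: volume-weighted average of the chamber
    glucose and the carried-over suspension sucrose."""
    if V_chamber <= 0 or V_suspension <= 0:
        raise ValueError("volumes must be positive")
    if C_chamber < 0 or C_suspension < 0:
        raise ValueError("concentrations must be non-negative")
    return (C_chamber * V_chamber + C_suspension * V_suspension) / (
        V_chamber + V_suspension
    )


def build_condition(
    inside_sucrose_mM: float = 100.0,
    *,
    chamber_glucose_mM: float | None = None,
    outside_mM: float | None = None,
    chamber_volume_uL: float = 280.0,
    suspension_volume_uL: float = 20.0,
    suspension_sucrose_mM: float = 98.0,
    hydration_volume_uL: float = 1000.0,
    prehydration_water_uL: float = 20.0,
    sucrose_calibration: SoluteCalibration = SUCROSE_CALIBRATION,
    glucose_calibration: SoluteCalibration = GLUCOSE_CALIBRATION,
    osmometer_error: float = DEFAULT_OSMOMETER_ERROR,
    initial_radius: float = 10e-6,
    temperature: float = CONSTANTS.default_temperature,
) -> OsmoticCondition:
    """Assemble an :class:`OsmoticCondition` from the full solution chain.

    Inside osmolarity: sucrose calibration at ``inside_sucrose_mM``, then
    the pre-hydration dilution (20 uL water into 1 mL by default).  Outside
    osmolarity: the glucose calibration applied to the total mixed external
    solute concentration -- either computed from the chamber glucose plus
    the carried-over suspension sucrose (``chamber_glucose_mM``), or given
    directly (``outside_mM``).  Applying the glucose line to the total
    mixed concentration, sucrose carry-over included, is deliberate: it is
    what reproduces the experimental bookkeeping (78 mM -> 373 mOsm/L).
    """
    if (chamber_glucose_mM is None) == (outside_mM is None):
        raise ValueError("provide exactly one of chamber_glucose_mM or outside_mM")
    C_in0 = dilute_osmolarity(
        osmolarity(sucrose_calibration, inside_sucrose_mM),
        hydration_volume_uL,
        prehydration_water_uL,
    )
    if outside_mM is None:
        outside_mM = chamber_mixing(
            chamber_glucose_mM,
            chamber_volume_uL,
            suspension_sucrose_mM,
            suspension_volume_uL,
        )
    C_out = osmolarity(glucose_calibration, outside_mM)
    return OsmoticCondition(
        C_in0=C_in0,
        C_out=C_out,
        osmometer_error=osmometer_error,
        initial_radius=initial_radius,
        temperature=temperature,
    )


def osmotic_pressure(
    condition: OsmoticCondition, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Van 't Hoff osmotic pressure Pi = R T delta_C0, in Pa.

    1 mOsm/L is numerically 1 mol/m^3, so delta_C0 converts directly.
    """
    return constants.gas_constant * condition.temperature * condition.delta_C0


def osmotic_tension(
    spec: MembraneSpec,
    condition: OsmoticCondition,
    mode: str = "approx",
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Membrane tension at swelling equilibrium, N/m.

    approx mode (the form used for the reported theory values):

        sigma = 2 K_A delta_C0 / (3 C_out)

    full mode keeps the elastic 2 K_A / r0 term in the force balance:

        sigma = K_A R T delta_C0 / (2 K_A / r0 + (R T / 2)(3 C_out - delta_C0))

    which reduces to the approx form as r0 -> inf and delta_C0 / C_out -> 0.
    """
    KA = spec.area_compressibility
    dC = condition.delta_C0  # mol/m^3
    Cout = condition.C_out
    if mode == "approx":
        return 2.0 * KA * dC / (3.0 * Cout)
    if mode == "full":
        RT = constants.gas_constant * condition.temperature
        denom = 2.0 * KA / condition.initial_radius + 0.5 * RT * (3.0 * Cout - dC)
        return KA * RT * dC / denom
    raise ValueError(f"unknown mode {mode!r}; expected 'approx' or 'full'")


def propagate_tension_error(
    spec: MembraneSpec, condition: OsmoticCondition
) -> float:
    """First-order uncertainty of the approx-form osmotic tension, N/m.

    Relative error in quadrature over the three inputs of the approx form:
    delta_C0 (its error taken as the linear sum of the two osmometer
    readings that form the difference -- the dominant term), C_out (one
    osmometer reading) and K_A.  For delta_C0 = 0 the relative form is
    undefined; the limit expression (error slope times the delta_C0 error)
    is returned instead.
    """
    delta_dC = 2.0 * condition.osmometer_error  # linear sum of two readings
    rel_Cout = condition.osmometer_error / condition.C_out
    rel_KA = spec.K_A_relative_error
    if condition.delta_C0 == 0:
        # d sigma / d(delta_C0) * delta(delta_C0), approx form
        return 2.0 * spec.area_compressibility * delta_dC / (3.0 * condition.C_out)
    rel_dC = delta_dC / abs(condition.delta_C0)
    sigma = abs(osmotic_tension(spec, condition, mode="approx"))
    return sigma * math.sqrt(rel_dC**2 + rel_Cout**2 + rel_KA**2)


def equilibrium_radius_increase(
    sigma_os: float, r0: float, K_A: float
) -> float:
    """Linear-elastic radius increase at swelling equilibrium, m.

    delta_r_eq = sigma * r0 / (2 K_A); valid while delta_r_eq << r0.
    """
    if r0 <= 0 or K_A <= 0:
        raise ValueError("r0 and K_A must be positive")
    return sigma_os * r0 / (2.0 * K_A)
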