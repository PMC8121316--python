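"""Synthetic rupture experiments with known ground truth.

The generator emulates the laboratory protocol: per condition, a handful
of replicate experiments each watch ~18 single GUVs (radii around 10 um)
under a constant electric tension for a 60 s window.  Each GUV's rupture
waiting time is exponential with the rate given by the nucleation rate law
evaluated at the total tension sigma_t = sigma_c + sigma_os; vesicles
still intact at the end of the window are right-censored.

By default the ~7 s field ramp preceding the hold is excluded from the
hazard (the experimental time origin is the instant the target field is
reached).  ``include_ramp=True`` adds the ramp exposure, with the electric
tension rising linearly from the baseline-field value, via a thinning
(inhomogeneous Poisson) scheme; it exists to quantify the bias of the
t = 0 convention.

Seeding is counter-based: each (tension, replicate) group derives its
stream from the master seed and a stable hash of its group label, so
adding an arm to a study never perturbs the draws of existing arms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .electrokinetics import KineticParams, rate_constant
from .membrane import MembraneSpec
from .osmotics import OsmoticCondition, osmotic_tension
from .rupture import DEFAULT_WINDOW, RuptureRecord

__all__ = [
    "ExperimentDesign",
    "sample_radii",
    "simulate_experiment",
    "simulate_study",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one synthetic rupture experiment (one osmotic arm).

    ``tensions`` are the applied electric tensions sigma_c in N/m;
    ``condition`` is None for the zero-osmotic-pressure baseline arm.
    Radii default to lognormal with median 10 um and log-sd 0.2 (the
    protocol reports ~10 um exemplars; the dispersion is a modelling
    choice).  ``sigma_os_override`` injects a known ground-truth osmotic
    tension directly, bypassing the theory value.
    """

    label: str
    membrane: MembraneSpec
    kinetics: KineticParams
    tensions: tuple[float, ...]
    condition: OsmoticCondition | None = None
    sigma_os_override: float | None = None
    guvs_per_tension: int = 18
    replicates: int = 3
    window: float = DEFAULT_WINDOW
    radius_median: float = 10e-6
    radius_log_sd: float = 0.2
    include_ramp: bool = False
    ramp_duration: float = 7.0
    baseline_tension: float = 0.5e-3  # sigma_c at the ~320 V/cm holding field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.guvs_per_tension < 1 or self.replicates < 1:
            raise ValueError("counts must be >= 1")
        if not self.tensions or any(s <= 0 for s in self.tensions):
            raise ValueError("tensions must be positive and non-empty")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.radius_median <= 0 or self.radius_log_sd < 0:
            raise ValueError("invalid radius distribution parameters")

    @property
    def sigma_os(self) -> float:
        """Ground-truth osmotic tension for this arm, N/m."""
        if self.sigma_os_override is not None:
            return self.sigma_os_override
        if self.condition is None:
            return 0.0
        return osmotic_tension(self.membrane, self.condition, mode="approx")


def _group_rng(master_seed: int, label: str) -> np.random.Generator:
    """Independent stream for one group, stable under study re-composition."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


def sample_radii(
    n: int,
    median: float = 10e-6,
    log_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample n GUV radii (m) from a lognormal with the given median.

    ``log_sd = 0`` degenerates to all radii equal to the median.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if median <= 0 or log_sd < 0:
        raise ValueError("invalid distribution parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return median * np.exp(rng.normal(0.0, log_sd, size=n)) if log_sd > 0 else np.full(
        n, median
    )


def _draw_waiting_time(
    rng: np.random.Generator,
    sigma_c: float,
    sigma_os: float,
    design: ExperimentDesign,
    constants: PhysicalConstants,
) -> float | None:
    """One rupture waiting time, measured from the design's time origin.

    Returns None when the GUV survives the whole observation.  With the
    ramp included, times are measured from ramp start and the effective
    window is ramp_duration + window; the tension rises linearly from
    ``baseline_tension`` to sigma_c during the ramp (thinning algorithm).
    """
    k_hold = rate_constant(sigma_c + sigma_os, design.kinetics, constants)
    if not design.include_ramp:
        t = rng.exponential(1.0 / k_hold) if k_hold > 0 else np.inf
        return float(t) if t <= design.window else None

    # thinning over the ramp; hazard is increasing, so k_hold bounds it
    t = 0.0
    while True:
        t += rng.exponential(1.0 / k_hold)
        if t >= design.ramp_duration:
            break
        sig = design.baseline_tension + (sigma_c - design.baseline_tension) * (
            t / design.ramp_duration
        )
        k_t = rate_constant(sig + sigma_os, design.kinetics, constants)
        if rng.uniform() < k_t / k_hold:
            return float(t)
    t_hold = rng.exponential(1.0 / k_hold)
    total = design.ramp_duration + t_hold
    return float(total) if t_hold <= design.window else None


def simulate_experiment(
    design: ExperimentDesign,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[list[RuptureRecord], dict]:
    """Simulate one arm of a study.

    Returns the rupture records and a ground-truth manifest holding the
    injected osmotic tension, the true rate per tension, the seeds and a
    design echo.
    """
    sigma_os = design.sigma_os
    window = design.window + (design.ramp_duration if design.include_ramp else 0.0)
    records: list[RuptureRecord] = []
    true_rates = {}
    for sigma_c in design.tensions:
        true_rates[sigma_c] = rate_constant(
            sigma_c + sigma_os, design.kinetics, constants
        )
        for rep in range(1, design.replicates + 1):
            group = f"{design.label}|sc{sigma_c * 1e3:.2f}mN|rep{rep}"
            rng = _group_rng(design.seed, group)
            radii = sample_radii(
                design.guvs_per_tension,
                design.radius_median,
                design.radius_log_sd,
                seed=rng,
            )
            for i, _radius in enumerate(radii, start=1):
                t = _draw_waiting_time(rng, sigma_c, sigma_os, design, constants)
                records.append(
                    RuptureRecord(
                        guv_id=f"{group}|g{i:03d}",
                        group=group,
                        sigma_c=sigma_c,
                        time=t,
                        censored=t is None,
                        window=window,
                    )
                )
    manifest = {
        "label": design.label,
        "membrane": design.membrane.name,
        "true_sigma_os_N_per_m": sigma_os,
        "true_k_p_per_tension": {f"{s:.6g}": k for s, k in true_rates.items()},
        "kinetics": {
            "line_tension_N": design.kinetics.line_tension,
            "electrostatic_term_N_per_m": design.kinetics.electrostatic_term,
            "prefactor": design.kinetics.prefactor,
            "temperature_K": design.kinetics.temperature,
        },
        "tensions_N_per_m": list(design.tensions),
        "guvs_per_tension": design.guvs_per_tension,
        "replicates": design.replicates,
        "window_s": window,
        "include_ramp": design.include_ramp,
        "radius_median_m": design.radius_median,
        "radius_log_sd": design.radius_log_sd,
        "seed": design.seed,
    }
    return records, manifest


def simulate_study(
    designs: list[ExperimentDesign],
    master_seed: int | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> dict:
    """Simulate a multi-arm study (baseline plus osmotic arms).

    Per-arm seeds derive from ``master_seed`` (when given) and the arm
    label, so arms are independent and stable under re-composition.
    Returns ``{"records": [...], "manifests": {label: manifest}}``.
    """
    if not designs:
        raise ValueError("at least one design is required")
    labels = [d.label for d in designs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate arm labels: {labels}")
    records: list[RuptureRecord] = []
    manifests: dict[str, dict] = {}
    for design in designs:
        if master_seed is not None:
            arm_seed = zlib.crc32(
                f"{master_seed}|{design.label}".encode("utf-8")
            ) % (2**31)
            design = replace(design, seed=arm_seed)
        recs, manifest = simulate_experiment(design, constants)
        records.extend(recs)
        manifests[design.label] = manifest
    return {"records": records, "manifests": manifests}
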