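"""Survival analysis of rupture times, rate-model fitting and the
curve-shift estimation of the osmotic membrane tension.

A rupture experiment watches a set of single GUVs under a constant
electric tension for a fixed 60 s window and records, per vesicle, the
time rupture starts or the fact that it stayed intact (right-censored).
The fraction of intact vesicles decays as a single exponential,
P_intact(t) = exp(-k_p t), whose rate k_p feeds the nucleation rate law.

The headline procedure is the curve shift: the k_p-versus-tension curve
measured under osmotic pressure is displaced horizontally relative to the
zero-pressure curve, and the displacement is the osmotic membrane tension
sigma_os.  Per measured (sigma_c, k_p) point the equivalent zero-pressure
tension is found by inverting the rate law, and the shift is its excess
over the applied electric tension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import CONSTANTS, PhysicalConstants
from .electrokinetics import KineticParams, invert_rate, rate_constant
from .membrane import MembraneSpec
from .osmotics import OsmoticCondition, osmotic_tension, propagate_tension_error

__all__ = [
    "RuptureRecord",
    "SurvivalCurve",
    "RateEstimate",
    "TensionShiftEstimate",
    "empirical_survival",
    "fit_rate_constant",
    "average_rates",
    "fit_kinetic_model",
    "estimate_shift_tension",
    "leakage_prediction",
]

DEFAULT_WINDOW = 60.0


@dataclass(frozen=True)
class RuptureRecord:
    """One GUV's outcome: rupture-onset time within the window, or censored."""

    guv_id: str
    group: str
    sigma_c: float  # N/m
    time: float | None = None  # s; None when censored
    censored: bool = False
    window: float = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.censored:
            if self.time is not None:
                raise ValueError("censored record must not carry a rupture time")
        else:
            if self.time is None:
                raise ValueError("uncensored record requires a rupture time")
            if not (0.0 < self.time <= self.window):
                raise ValueError("rupture time must lie in (0, window]")


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical step function of the intact fraction P_intact(t)."""

    times: np.ndarray  # sorted rupture times
    p_intact: np.ndarray  # value just after each drop
    n_total: int
    window: float

    @property
    def p_pore_end(self) -> float:
        """Rupture probability by the end of the window, 1 - P_intact(window)."""
        return 1.0 - (self.p_intact[-1] if len(self.p_intact) else 1.0)

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """P_intact at arbitrary times (right-continuous step function)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        values = np.concatenate(([1.0], self.p_intact))
        return values[idx]


@dataclass(frozen=True)
class RateEstimate:
    """Estimated rupture rate constant for one experiment."""

    k_p: float  # s^-1
    stderr: float
    method: str
    n_ruptured: int
    n_total: int
    status: str = "ok"


@dataclass(frozen=True)
class TensionShiftEstimate:
    """Curve-shift estimate of the osmotic membrane tension.

    ``per_point`` rows are (sigma_c, k_p, equivalent_sigma, shift) in SI;
    shift = equivalent_sigma - sigma_c.  ``theory`` and ``theory_error``
    hold the independent theoretical value when inputs were provided.
    """

    per_point: list[tuple[float, float, float, float]]
    mean_shift: float
    sd_shift: float | None
    theory: float | None = None
    theory_error: float | None = None


def empirical_survival(records: list[RuptureRecord]) -> SurvivalCurve:
    """Empirical intact-fraction curve from a set of rupture records.

    Drops by (tied count)/n_total at each rupture time; censored vesicles
    stay in the denominator for the whole window.
    """
    if not records:
        raise ValueError("at least one record is required")
    windows = {r.window for r in records}
    if len(windows) > 1:
        raise ValueError(f"inconsistent observation windows: {sorted(windows)}")
    window = windows.pop()
    n_total = len(records)
    rupture_times = np.sort(
        np.array([r.time for r in records if not r.censored], dtype=float)
    )
    unique_times, counts = np.unique(rupture_times, return_counts=True)
    p = 1.0 - np.cumsum(counts) / n_total
    return SurvivalCurve(times=unique_times, p_intact=p, n_total=n_total, window=window)


def fit_rate_constant(
    records: list[RuptureRecord], method: str = "survival-lsq"
) -> RateEstimate:
    """Fit the single-exponential decay rate k_p to one experiment.

    survival-lsq (default): unweighted nonlinear least squares of
    exp(-k t) against the empirical survival step curve, evaluated just
    after each rupture time and at the window end.  censored-mle: the
    exact maximum-likelihood estimator for exponentially distributed,
    right-censored waiting times, n_ruptured / total exposure time, with
    stderr k_p / sqrt(n_ruptured).

    Zero ruptures yield k_p = 0 with status ``"lower-bound"`` (the data
    only bound the rate from above).
    """
    curve = empirical_survival(records)
    n_ruptured = sum(1 for r in records if not r.censored)
    n_total = curve.n_total
    if n_ruptured == 0:
        return RateEstimate(0.0, math.nan, method, 0, n_total, status="lower-bound")

    exposure = sum(r.time if not r.censored else r.window for r in records)
    k_mle = n_ruptured / exposure

    if method == "censored-mle":
        return RateEstimate(
            k_mle, k_mle / math.sqrt(n_ruptured), method, n_ruptured, n_total
        )
    if method != "survival-lsq":
        raise ValueError(f"unknown method {method!r}")

    t_fit = np.concatenate((curve.times, [curve.window]))
    p_fit = np.concatenate((curve.p_intact, [curve.p_intact[-1]]))
    popt, pcov = curve_fit(
        lambda t, k: np.exp(-k * t),
        t_fit,
        p_fit,
        p0=[k_mle],
        bounds=(0.0, np.inf),
        maxfev=10000,
    )
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
    return RateEstimate(float(popt[0]), stderr, "survival-lsq", n_ruptured, n_total)


def average_rates(estimates: list[RateEstimate]) -> tuple[float, float | None]:
    """Unweighted mean and sample sd (n-1) of replicate rate estimates.

    A single estimate has no sd (returned as None).
    """
    if not estimates:
        raise ValueError("at least one estimate is required")
    ks = np.array([e.k_p for e in estimates], dtype=float)
    mean = float(ks.mean())
    sd = float(ks.std(ddof=1)) if len(ks) >= 2 else None
    return mean, sd


def fit_kinetic_model(
    points: list[tuple[float, float]],
    fixed_B: float | None = None,
    temperature: float = CONSTANTS.default_temperature,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[KineticParams, dict]:
    """Fit the nucleation rate law to measured (sigma_t, k_p) points.

    Least squares in log(k_p) space.  With ``fixed_B`` set (the default
    workflow: B is quoted from electrostatics, not fitted) the free
    parameters are Gamma and A_F, needing >= 2 points; with B free all
    three are fitted and >= 3 points are required.

    Returns the fitted :class:`KineticParams` and a diagnostics dict with
    residuals (log space) and the parameter covariance.
    """
    n_free = 2 if fixed_B is not None else 3
    if len(points) < n_free:
        raise ValueError(
            f"{len(points)} point(s) cannot determine {n_free} free parameters"
        )
    sigmas = np.array([p[0] for p in points], dtype=float)
    ks = np.array([p[1] for p in points], dtype=float)
    if np.any(ks <= 0):
        raise ValueError("all rate constants must be positive")
    kT = constants.boltzmann_k * temperature
    log_k = np.log(ks)

    def model(sigma, gamma_pN, log10_A, B_mN):
        gamma = gamma_pN * 1e-12
        x = sigma + B_mN * 1e-3
        return math.log(10.0) * log10_A + np.log(x) - math.pi * gamma**2 / (kT * x)

    guess_gamma = 12.0
    guess_logA = math.log10(max(ks.max() / (sigmas.max() + 1e-3), 1e-3)) + 5.0

    if fixed_B is not None:
        B_mN = fixed_B * 1e3

        def model2(sigma, gamma_pN, log10_A):
            return model(sigma, gamma_pN, log10_A, B_mN)

        popt, pcov = curve_fit(
            model2, sigmas, log_k, p0=[guess_gamma, guess_logA], maxfev=20000
        )
        gamma_pN, log10_A = popt
        B_fit = fixed_B
    else:
        popt, pcov = curve_fit(
            model, sigmas, log_k, p0=[guess_gamma, guess_logA, 2.0], maxfev=20000
        )
        gamma_pN, log10_A, B_mN = popt
        B_fit = B_mN * 1e-3

    params = KineticParams(
        line_tension=float(gamma_pN) * 1e-12,
        electrostatic_term=float(B_fit),
        prefactor=10.0 ** float(log10_A),
        temperature=temperature,
    )
    residuals = log_k - np.log(rate_constant(sigmas, params, constants))
    diagnostics = {
        "log_residuals": residuals,
        "rms_log_residual": float(np.sqrt(np.mean(residuals**2))),
        "covariance": pcov,
        "fixed_B": fixed_B,
    }
    return params, diagnostics


def estimate_shift_tension(
    osm_points: list[tuple[float, float]],
    baseline: KineticParams,
    membrane: MembraneSpec | None = None,
    condition: OsmoticCondition | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> TensionShiftEstimate:
    """Curve-shift estimate of the osmotic membrane tension.

    For each measured (sigma_c, k_p) under osmotic pressure, invert the
    zero-pressure rate law at k_p to get the equivalent tension; the shift
    is equivalent - sigma_c.  Mean and sample sd are taken over points.
    When ``membrane`` and ``condition`` are given, the theoretical tension
    at swelling equilibrium and its propagated error are attached.
    """
    if not osm_points:
        raise ValueError("at least one (sigma_c, k_p) point is required")
    per_point = []
    for sigma_c, k_p in osm_points:
        if k_p <= 0:
            raise ValueError("all k_p values must be positive")
        equivalent = invert_rate(k_p, baseline, constants)
        per_point.append((sigma_c, k_p, equivalent, equivalent - sigma_c))
    shifts = np.array([p[3] for p in per_point])
    mean_shift = float(shifts.mean())
    sd_shift = float(shifts.std(ddof=1)) if len(shifts) >= 2 else None
    theory = theory_err = None
    if membrane is not None and condition is not None:
        theory = osmotic_tension(membrane, condition, mode="approx")
        theory_err = propagate_tension_error(membrane, condition)
    return TensionShiftEstimate(
        per_point=per_point,
        mean_shift=mean_shift,
        sd_shift=sd_shift,
        theory=theory,
        theory_error=theory_err,
    )


def leakage_prediction(sigma_os: float, sigma_critical: float = 7e-3) -> bool:
    """Predict osmotically driven content leakage.

    True when the osmotic tension alone reaches the critical rupture
    tension (default 7 mN/m, the zero-pressure tension scale at which
    electric rupture sets in for these membranes).
    """
    if sigma_os < 0 or sigma_critical < 0:
        raise ValueError("tensions must be non-negative")
    return sigma_os >= sigma_critical
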