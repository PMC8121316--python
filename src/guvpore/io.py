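"""Rupture-record file format, pipeline configuration and the end-to-end
analysis pipeline.

Rupture records travel as comma-separated UTF-8 text with the header

    guv_id,group,sigma_c_mN_per_m,time_s,censored,window_s

(units embedded in column names; empty ``time_s`` for censored rows).
The canonical serialisation is deterministic, so write(read(x)) == x.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from . import electrokinetics as ek
from . import membrane as mb
from . import osmotics as osm
from . import rupture as rs
from . import simulate as sim

__all__ = [
    "read_rupture_records",
    "write_rupture_records",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("guvpore")

HEADER = "guv_id,group,sigma_c_mN_per_m,time_s,censored,window_s"


class RecordFormatError(ValueError):
    """Malformed rupture-record file (carries the offending line number)."""


def read_rupture_records(path: str | Path) -> list[rs.RuptureRecord]:
    """Parse a rupture-record CSV; errors name the offending line."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != HEADER:
        raise RecordFormatError(f"{path}:1: expected header {HEADER!r}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 6:
            raise RecordFormatError(
                f"{path}:{lineno}: expected 6 comma-separated fields, got {len(parts)}"
            )
        guv_id, group, sigma_mN, time_s, censored_s, window_s = (
            p.strip() for p in parts
        )
        try:
            censored = {"0": False, "1": True}[censored_s]
        except KeyError:
            raise RecordFormatError(
                f"{path}:{lineno}: censored flag must be 0 or 1, got {censored_s!r}"
            ) from None
        if censored and time_s:
            raise RecordFormatError(
                f"{path}:{lineno}: censored row must have an empty time_s field"
            )
        try:
            record = rs.RuptureRecord(
                guv_id=guv_id,
                group=group,
                sigma_c=float(sigma_mN) * 1e-3,
                time=float(time_s) if time_s else None,
                censored=censored,
                window=float(window_s),
            )
        except ValueError as exc:
            raise RecordFormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(record)
    return records


def write_rupture_records(
    records: list[rs.RuptureRecord], path: str | Path
) -> None:
    """Write records in the canonical format (lossless round trip)."""
    path = Path(path)
    out = [HEADER]
    for r in records:
        time_s = "" if r.censored else f"{r.time:.6f}"
        out.append(
            f"{r.guv_id},{r.group},{r.sigma_c * 1e3:.6f},{time_s},"
            f"{int(r.censored)},{r.window:.1f}"
        )
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# pipeline configuration


class ArmConfig(BaseModel):
    """One study arm: a set of applied tensions under one osmotic condition."""

    model_config = ConfigDict(extra="forbid")

    label: str
    tensions_mN_per_m: list[float]
    chamber_glucose_mM: Optional[float] = None
    outside_mM: Optional[float] = None
    sigma_os_mN_per_m: Optional[float] = None  # direct ground-truth override

    @model_validator(mode="after")
    def _one_condition_source(self) -> "ArmConfig":
        sources = [
            self.chamber_glucose_mM is not None,
            self.outside_mM is not None,
            self.sigma_os_mN_per_m is not None,
        ]
        if sum(sources) > 1:
            raise ValueError(
                f"arm {self.label!r}: give at most one of chamber_glucose_mM, "
                "outside_mM, sigma_os_mN_per_m (none means baseline)"
            )
        return self

    @property
    def is_baseline(self) -> bool:
        return (
            self.chamber_glucose_mM is None
            and self.outside_mM is None
            and (self.sigma_os_mN_per_m is None or self.sigma_os_mN_per_m == 0)
        )


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    guvs_per_tension: int = 18
    replicates: int = 3
    window_s: float = 60.0
    radius_median_um: float = 10.0
    radius_log_sd: float = 0.2
    include_ramp: bool = False


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: str = "survival-lsq"
    fixed_B: bool = True


class PipelineConfig(BaseModel):
    """Schema-validated configuration of the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    membrane: str = "DOPG/DOPC/chol(46/39/15)"
    inside_sucrose_mM: float = 100.0
    arms: list[ArmConfig]
    simulation: SimulationConfig = SimulationConfig()
    fit: FitConfig = FitConfig()
    seed: int = 0
    records_path: Optional[str] = None  # analyse existing data instead of simulating


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# pipeline


def _condition_for_arm(
    cfg: PipelineConfig, arm: ArmConfig
) -> osm.OsmoticCondition | None:
    if arm.chamber_glucose_mM is not None:
        return osm.build_condition(
            cfg.inside_sucrose_mM, chamber_glucose_mM=arm.chamber_glucose_mM
        )
    if arm.outside_mM is not None:
        return osm.build_condition(cfg.inside_sucrose_mM, outside_mM=arm.outside_mM)
    return None


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full analysis: simulate (or load) records, fit per-group
    rates, average over replicates, fit/choose the baseline rate law, and
    estimate the osmotic tension of every non-baseline arm by the
    curve-shift procedure, alongside the theoretical value.

    Returns the results bundle as a JSON-serialisable dict; when
    ``output_dir`` is given, writes ``records.csv``, ``results.json`` and
    ``manifest.json`` there.
    """
    spec = mb.get_membrane(config.membrane)
    kinetics = ek.KINETIC_PRESETS[config.membrane]
    simcfg = config.simulation
    logger.info(
        "pipeline: membrane=%s method=%s fixed_B=%s seed=%d",
        config.membrane,
        config.fit.method,
        config.fit.fixed_B,
        config.seed,
    )

    conditions = {arm.label: _condition_for_arm(config, arm) for arm in config.arms}

    if config.records_path is not None:
        records = read_rupture_records(config.records_path)
        manifests = {}
    else:
        designs = []
        for arm in config.arms:
            sigma_override = (
                arm.sigma_os_mN_per_m * 1e-3
                if arm.sigma_os_mN_per_m is not None
                else None
            )
            designs.append(
                sim.ExperimentDesign(
                    label=arm.label,
                    membrane=spec,
                    kinetics=kinetics,
                    tensions=tuple(s * 1e-3 for s in arm.tensions_mN_per_m),
                    condition=conditions[arm.label],
                    sigma_os_override=sigma_override,
                    guvs_per_tension=simcfg.guvs_per_tension,
                    replicates=simcfg.replicates,
                    window=simcfg.window_s,
                    radius_median=simcfg.radius_median_um * 1e-6,
                    radius_log_sd=simcfg.radius_log_sd,
                    include_ramp=simcfg.include_ramp,
                )
            )
        bundle = sim.simulate_study(designs, master_seed=config.seed)
        records = bundle["records"]
        manifests = bundle["manifests"]

    # group records by (arm label, tension, replicate) -> fit k_p
    results: dict = {"membrane": config.membrane, "seed": config.seed, "arms": {}}
    arm_rate_tables: dict[str, list[tuple[float, float, float | None]]] = {}
    for arm in config.arms:
        by_tension: dict[float, dict[str, list[rs.RuptureRecord]]] = {}
        for r in records:
            if not r.group.startswith(arm.label + "|"):
                continue
            by_tension.setdefault(r.sigma_c, {}).setdefault(r.group, []).append(r)
        table = []
        for sigma_c in sorted(by_tension):
            estimates = [
                rs.fit_rate_constant(recs, method=config.fit.method)
                for recs in by_tension[sigma_c].values()
            ]
            mean_k, sd_k = rs.average_rates(estimates)
            table.append((sigma_c, mean_k, sd_k))
        arm_rate_tables[arm.label] = table

    baseline_arms = [a for a in config.arms if a.is_baseline]
    baseline_params = kinetics
    baseline_fit_info = None
    if baseline_arms:
        points = [
            (s, k) for s, k, _ in arm_rate_tables[baseline_arms[0].label] if k > 0
        ]
        if len(points) >= 2:
            fixed = kinetics.electrostatic_term if config.fit.fixed_B else None
            baseline_params, diag = rs.fit_kinetic_model(points, fixed_B=fixed)
            baseline_fit_info = {
                "line_tension_pN": baseline_params.line_tension * 1e12,
                "electrostatic_term_mN_per_m": baseline_params.electrostatic_term * 1e3,
                "prefactor": baseline_params.prefactor,
                "rms_log_residual": diag["rms_log_residual"],
            }
            logger.info(
                "baseline fit: Gamma=%.2f pN, A_F=%.3g (B %s at %.2f mN/m)",
                baseline_params.line_tension * 1e12,
                baseline_params.prefactor,
                "fixed" if config.fit.fixed_B else "free",
                baseline_params.electrostatic_term * 1e3,
            )

    for arm in config.arms:
        table = arm_rate_tables[arm.label]
        arm_out = {
            "rate_table": [
                {
                    "sigma_c_mN_per_m": round(s * 1e3, 1),
                    "k_p_per_s": k,
                    "k_p_sd_per_s": sd,
                }
                for s, k, sd in table
            ]
        }
        if not arm.is_baseline:
            points = [(s, k) for s, k, _ in table if k > 0]
            if points:
                shift = rs.estimate_shift_tension(
                    points,
                    baseline_params,
                    membrane=spec,
                    condition=conditions[arm.label],
                )
                arm_out["shift_estimate"] = {
                    "per_point": [
                        {
                            "sigma_c_mN_per_m": round(sc * 1e3, 1),
                            "k_p_per_s": kp,
                            "equivalent_sigma_mN_per_m": round(eq * 1e3, 1),
                            "sigma_os_mN_per_m": round(sh * 1e3, 1),
                        }
                        for sc, kp, eq, sh in shift.per_point
                    ],
                    "mean_sigma_os_mN_per_m": round(shift.mean_shift * 1e3, 1),
                    "sd_sigma_os_mN_per_m": (
                        round(shift.sd_shift * 1e3, 1)
                        if shift.sd_shift is not None
                        else None
                    ),
                    "theory_sigma_os_mN_per_m": (
                        round(shift.theory * 1e3, 1) if shift.theory is not None else None
                    ),
                    "theory_error_mN_per_m": (
                        round(shift.theory_error * 1e3, 1)
                        if shift.theory_error is not None
                        else None
                    ),
                }
        cond = conditions[arm.label]
        if cond is not None:
            arm_out["condition"] = cond.rounded()
        results["arms"][arm.label] = arm_out

    if baseline_fit_info is not None:
        results["baseline_fit"] = baseline_fit_info

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        write_rupture_records(records, output_dir / "records.csv")
        (output_dir / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (output_dir / "manifest.json").write_text(
            json.dumps(manifests, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return results
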