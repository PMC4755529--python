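"""Run configuration and end-to-end pipeline (generate -> simulate -> report).

A run is fully described by a :class:`RunConfig` (loadable from YAML); given
the same config and seed the JSON artifacts are byte-identical, and the
manifest written next to the outputs is itself a valid config, so any run
can be re-executed from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .burden_model import (
    DEFAULT_AF_THRESHOLD_MINUTES,
    DEFAULT_BLANKING_DAYS,
    PatientRecord,
    read_cohort,
    write_cohort,
)
from .cohort_analysis import (
    burden_strata,
    chads2_strata,
    detection_table,
    median_burden_split,
    table_to_dataframe,
    whole_cohort_stratum,
)
from .snapshot_simulator import (
    DEFAULT_N_REPS,
    MonitoringWindow,
    STANDARD_WINDOW_LENGTHS,
    simulate_cohort,
)
from .synthetic_cohort import LogNormalSpec, SyntheticCohortParams, calibration_report, generate_cohort

logger = logging.getLogger("afsnapshot")

VALID_STRATA_KINDS = ("all", "chads2", "median_burden")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    seed: int
    windows: tuple[int, ...] = STANDARD_WINDOW_LENGTHS
    n_reps: int = DEFAULT_N_REPS
    blanking_days: int = DEFAULT_BLANKING_DAYS
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES
    policy: str = "zero"
    ci_method: str = "clopper_pearson"
    strata: tuple[str, ...] = ("all",)
    burden_csv: str | None = None
    covariates_csv: str | None = None
    generator: dict[str, Any] | None = None
    output_dir: str = "out"

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed: required (no silent nondeterminism)")
        if not self.windows or any(w < 1 for w in self.windows):
            raise ConfigError(f"windows: all must be >= 1, got {list(self.windows)}")
        if self.n_reps < 1:
            raise ConfigError(f"n_reps: must be >= 1, got {self.n_reps}")
        if self.blanking_days < 0:
            raise ConfigError(f"blanking_days: must be >= 0, got {self.blanking_days}")
        if self.policy not in ("zero", "raw"):
            raise ConfigError(f"policy: must be 'zero' or 'raw', got {self.policy!r}")
        if self.ci_method not in ("clopper_pearson", "wilson"):
            raise ConfigError(f"ci_method: unknown method {self.ci_method!r}")
        for s in self.strata:
            if s not in VALID_STRATA_KINDS and not s.startswith("fixed_burden:"):
                raise ConfigError(
                    f"strata: unknown stratification {s!r} "
                    f"(expected one of {VALID_STRATA_KINDS} or fixed_burden:<hours>)"
                )
        if self.generator is None and self.burden_csv is None:
            raise ConfigError("burden_csv: either input paths or a generator block is required")
        for key in ("burden_csv", "covariates_csv"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{key}: path {path!r} does not exist")

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("seed: required")
        raw = dict(raw)
        if "windows" in raw:
            raw["windows"] = tuple(int(w) for w in raw["windows"])
        if "strata" in raw:
            raw["strata"] = tuple(str(s) for s in raw["strata"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path}: expected a mapping at top level")
        return cls.from_mapping(raw)

    def to_mapping(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        d["strata"] = list(self.strata)
        return d


def _generator_params(cfg: RunConfig) -> SyntheticCohortParams:
    raw = dict(cfg.generator or {})
    for key in ("af_day_rate_dist", "burden_dist"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = LogNormalSpec(**raw[key])
    raw.setdefault("seed", cfg.seed)
    raw.setdefault("blanking_days", cfg.blanking_days)
    raw.setdefault("af_threshold_minutes", cfg.af_threshold_minutes)
    try:
        return SyntheticCohortParams(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"generator: {exc}") from exc


def _build_strata(cfg: RunConfig, cohort: Sequence[PatientRecord]):
    out = {}
    for kind in cfg.strata:
        if kind == "all":
            out["all"] = whole_cohort_stratum()
        elif kind == "chads2":
            out["chads2"] = chads2_strata()
        elif kind == "median_burden":
            cutoff, strata = median_burden_split(
                cohort, cfg.blanking_days, cfg.af_threshold_minutes
            )
            logger.info("median burden split cutoff: %.4f h/day", cutoff)
            out["median_burden"] = strata
        elif kind.startswith("fixed_burden:"):
            cutoff = float(kind.split(":", 1)[1])
            out[kind] = burden_strata(cutoff, cfg.blanking_days, cfg.af_threshold_minutes)
    return out


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_or_generate_cohort(cfg: RunConfig, outdir: Path) -> list[PatientRecord]:
    if cfg.generator is not None:
        params = _generator_params(cfg)
        logger.info("generating synthetic cohort: n=%d seed=%d", params.n_patients, params.seed)
        cohort = generate_cohort(params)
        write_cohort(cohort, outdir / "cohort.csv", outdir / "covariates.csv")
        _write_json(
            outdir / "calibration.json",
            calibration_report(cohort, cfg.blanking_days, cfg.af_threshold_minutes),
        )
        return cohort
    logger.info("reading cohort from %s", cfg.burden_csv)
    return read_cohort(cfg.burden_csv, cfg.covariates_csv)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute generate/load -> simulate -> report; returns the output dir.

    Artifacts: cohort.csv + covariates.csv + calibration.json (generated
    cohorts only), report.csv, report.json, simulation.json, manifest.json.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_or_generate_cohort(cfg, outdir)
    windows = [MonitoringWindow(length_days=w, start_day=cfg.blanking_days + 1)
               for w in cfg.windows]

    # per-patient simulation output for the whole cohort
    sim_records = []
    for window in windows:
        logger.info(
            "simulating window=%dd reps=%d seed=%d policy=%s",
            window.length_days, cfg.n_reps, cfg.seed, cfg.policy,
        )
        sim = simulate_cohort(
            cohort, window, cfg.n_reps, cfg.af_threshold_minutes, cfg.policy, cfg.seed
        )
        for o in sim.outcomes:
            sim_records.append(
                {
                    "patient_id": o.patient_id,
                    "window_days": window.length_days,
                    "analytic_prob": o.analytic_prob,
                    "mc_detect_fraction": o.mc_detect_fraction,
                    "n_reps": o.n_reps,
                }
            )
    _write_json(outdir / "simulation.json", sim_records)

    report_rows = []
    csv_path = outdir / "report.csv"
    csv_path.unlink(missing_ok=True)
    for kind, strata in _build_strata(cfg, cohort).items():
        logger.info("reporting stratification=%s reps=%d seed=%d", kind, cfg.n_reps, cfg.seed)
        rows = detection_table(
            cohort,
            windows,
            strata,
            n_reps=cfg.n_reps,
            seed=cfg.seed,
            ci_method=cfg.ci_method,
            af_threshold_minutes=cfg.af_threshold_minutes,
            policy=cfg.policy,
        )
        for row in rows:
            rec = dataclasses.asdict(row)
            rec["stratification"] = kind
            report_rows.append(rec)
        df = table_to_dataframe(rows)
        df.insert(0, "stratification", kind)
        df.to_csv(csv_path, mode="a" if csv_path.exists() else "w",
                  header=not csv_path.exists(), index=False)
    _write_json(outdir / "report.json", report_rows)

    manifest = {"config": cfg.to_mapping(), "package_version": __version__}
    _write_json(outdir / "manifest.json", manifest)
    return outdir
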