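"""Full two-trial emulation from a single config, with a manifest of outputs.

For each exposure (antimicrobial, gastrointestinal nutraceutical) the
pipeline runs: eligibility filtering (when raw presentation records are
supplied) → propensity fitting and stabilised weights → pre/post balance
table → unadjusted risk difference → IP-weighted risk difference →
unadjusted Kaplan–Meier with log-rank → IP-weighted standardised survival
curves with the 5-day-interval probability table.  Every reported number is
written to a stage output file; the manifest records the config hash, the
root seed and a checksum per artifact, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import balance, effects, schema, survival
from .propensity import PropensityModelSpec, default_spec, fit_propensity
from .simulate import SimulationConfig, default_study_config, generate_cohort

logger = logging.getLogger(__name__)

#: the per-exposure report tables, in pipeline order
EXPOSURE_TABLES = (
    "weights.csv",
    "balance.csv",
    "rd_unadjusted.json",
    "rd_iptw.json",
    "unadjusted_tte.json",
    "tte_curves.csv",
    "tte_timepoints.csv",
)


class StageError(RuntimeError):
    """A pipeline stage failed; completed stages are already on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class EmulationConfig:
    """Inputs and settings for one full emulation run."""

    output_dir: str
    seed: int
    input_path: str | None = None          # cohort or raw-presentation CSV
    simulation: SimulationConfig | None = None
    exposures: tuple[str, ...] = schema.EXPOSURES
    propensity_specs: dict[str, PropensityModelSpec] = field(default_factory=dict)
    time_model: str = "linear+quadratic"
    n_boot: int = 500
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be set")
        for exp in self.exposures:
            if exp not in schema.EXPOSURES:
                raise ValueError(f"unknown exposure {exp!r}")
            self.propensity_specs.setdefault(exp, default_spec(exp))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EmulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if "simulation" in raw:
            overrides = raw.pop("simulation") or {}
            base = default_study_config(
                n=overrides.pop("n", 894), seed=overrides.pop("seed", raw.get("seed", 0)))
            sim = dataclasses.replace(base, **overrides)
        return cls(simulation=sim, **raw)


def _config_digest(config: EmulationConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_emulation(config: EmulationConfig) -> dict:
    """Run both emulated trials end to end; returns the manifest dict.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    from completed stages remain on disk alongside a partial manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("vettrial")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "config_hash": _config_digest(config),
        "seed": config.seed,
        "tables": {},
        "aux_files": [],
        "completed_stages": [],
    }
    stage = "input"
    try:
        if config.simulation is not None:
            cohort, truth = generate_cohort(config.simulation)
            schema.write_cohort(cohort, out / "cohort.csv")
            truth.to_csv(out / "truth.csv", index=False)
            manifest["aux_files"] += ["cohort.csv", "truth.csv"]
            tally = {rule: 0 for rule in schema.ELIGIBILITY_RULES}
            tally["retained"] = len(cohort)
        else:
            df = pd.read_csv(config.input_path, dtype={"dog_id": str},
                             float_precision="round_trip")
            if set(schema.RAW_COLUMNS) <= set(df.columns):
                raw = schema.validate_cohort(df, raw=True)
                cohort, tally = schema.apply_eligibility(raw)
            else:
                cohort = schema.validate_cohort(df)
                tally = {rule: 0 for rule in schema.ELIGIBILITY_RULES}
                tally["retained"] = len(cohort)
            schema.write_cohort(cohort, out / "cohort.csv")
            manifest["aux_files"].append("cohort.csv")
        schema.write_exclusion_report(tally, out / "eligibility_tally.json")
        manifest["aux_files"].append("eligibility_tally.json")
        manifest["completed_stages"].append(stage)

        for exposure in config.exposures:
            exp_dir = out / exposure
            exp_dir.mkdir(exist_ok=True)
            tables: dict[str, str] = {}

            stage = f"{exposure}:weights"
            ws = fit_propensity(cohort, config.propensity_specs[exposure])
            wtab = pd.DataFrame({
                "dog_id": cohort["dog_id"], "e": ws.propensity,
                "p_A": ws.p_treat, "w": ws.w, "sw": ws.sw,
            })
            wtab.to_csv(exp_dir / "weights.csv", index=False)
            ws.coefficients.to_csv(exp_dir / "coefficients.csv", index=False)
            manifest["aux_files"].append(f"{exposure}/coefficients.csv")
            tables["weights.csv"] = _sha256(exp_dir / "weights.csv")
            manifest["completed_stages"].append(stage)

            stage = f"{exposure}:balance"
            tab = balance.balance_table(cohort, exposure, ws)
            tab.to_csv(exp_dir / "balance.csv", index=False)
            balance.love_plot_frame(tab).to_csv(exp_dir / "love_plot.csv", index=False)
            manifest["aux_files"].append(f"{exposure}/love_plot.csv")
            tables["balance.csv"] = _sha256(exp_dir / "balance.csv")
            manifest["completed_stages"].append(stage)

            stage = f"{exposure}:effect"
            a = cohort[exposure].to_numpy()
            y = cohort["resolved_30d"].to_numpy()
            crude = effects.unadjusted_rd(
                int((a == 1).sum()), int(y[a == 1].sum()),
                int((a == 0).sum()), int(y[a == 0].sum()))
            _write_json(crude.to_dict(), exp_dir / "rd_unadjusted.json")
            adj = effects.iptw_rd(cohort, exposure, ws)
            _write_json(adj.to_dict(), exp_dir / "rd_iptw.json")
            tables["rd_unadjusted.json"] = _sha256(exp_dir / "rd_unadjusted.json")
            tables["rd_iptw.json"] = _sha256(exp_dir / "rd_iptw.json")
            manifest["completed_stages"].append(stage)

            stage = f"{exposure}:tte"
            times = cohort["escalation_day"].to_numpy()
            events = cohort["escalated"].to_numpy()
            km = survival.km_curve(times, events, a)
            chi2, p = survival.logrank(times, events, a)
            _write_json({
                "logrank_chi2": chi2, "logrank_p": p,
                "km": km.to_frame().to_dict(orient="list"),
            }, exp_dir / "unadjusted_tte.json")
            boot_seed = (config.seed * 1000003 + 7919 * (1 + list(config.exposures).index(exposure))) % (2 ** 31)
            curve, timepoints = survival.ipw_survival(
                cohort, exposure, ws, time_model=config.time_model,
                n_boot=config.n_boot, seed=boot_seed)
            curve.to_frame().to_csv(exp_dir / "tte_curves.csv", index=False)
            timepoints.to_csv(exp_dir / "tte_timepoints.csv", index=False)
            tables["unadjusted_tte.json"] = _sha256(exp_dir / "unadjusted_tte.json")
            tables["tte_curves.csv"] = _sha256(exp_dir / "tte_curves.csv")
            tables["tte_timepoints.csv"] = _sha256(exp_dir / "tte_timepoints.csv")
            manifest["completed_stages"].append(stage)

            manifest["tables"][exposure] = tables
    except Exception as exc:
        _write_json(manifest, out / "manifest.json")
        root.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc) from exc

    _write_json(manifest, out / "manifest.json")
    root.removeHandler(handler)
    handler.close()
    return manifest
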