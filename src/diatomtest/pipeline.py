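"""End-to-end pipeline: simulation experiment, accuracy-curve fitting,
image-budget thresholds and L/D case reports, driven by one config.

Every stochastic stage derives its seed from the config seed; reruns
with the same config produce byte-identical outputs (no timestamps or
entropy enter the files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import control_cases, study_cases
from .diagnostics import analyze_case, CaseRecord
from .estimation import run_strategy_experiment
from .geometry import MembraneSpec, make_scatter_plan, make_transect_plan
from .io import CaseInput, read_cases_csv, write_cases_csv
from .regression import fit_log_curve, images_needed
from .synthetic import simulate_membrane

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "generate_fixtures"]

log = logging.getLogger("diatomtest")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``cases_csv`` points at a long-format case table (see
    :func:`diatomtest.io.read_cases_csv`); when None the L/D stage is
    skipped.  ``experiment`` toggles the Monte-Carlo strategy comparison
    whose aggregated accuracies feed the log-curve fit.
    """

    seed: int = 0
    diameter_mm: float = 10.0
    fields_per_diameter: int = 40
    experiment: bool = True
    process: str = "clustered"
    intensity: float = 20.0
    cluster_rate: float = 0.5
    cluster_size_mean: float = 40.0
    cluster_sd_mm: float = 0.3
    n_replicates: int = 100
    target_accuracy_pct: float = 95.0
    cases_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    @property
    def spec(self) -> MembraneSpec:
        return MembraneSpec(self.diameter_mm, self.fields_per_diameter)

    def sha256(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _case_record(case: CaseInput) -> CaseRecord:
    if case.lung is None:
        raise PipelineError(
            f"ld_diagnostics stage: case {case.case_id!r} has no lung sample"
        )
    if case.medium is None:
        raise PipelineError(
            f"ld_diagnostics stage: case {case.case_id!r} has no drowning-medium sample"
        )
    return analyze_case(
        case.case_id, case.lung, case.medium, case.peripheral_counts, case.flags
    )


def _records_frame(records: list[CaseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "diatoms_per_g_lung": [r.lung_per_gram for r in records],
            "diatoms_per_ml_medium": [r.medium_per_ml for r in records],
            "ld_ratio": [r.ld_reported for r in records],
            "diagnostic_class": [r.diagnostic_class.value for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )


def _text_report(records: list[CaseRecord]) -> str:
    lines = [
        "Case  Diatoms per g lung tissue  Diatoms per ml drowning medium  "
        "L/D ratio  Class"
    ]
    for r in records:
        lines.append(
            f"{r.case_id:<5} {r.lung_per_gram:>25.1f} {r.medium_per_ml:>31.1f} "
            f"{r.ld_reported:>10.1f}  {r.diagnostic_class.value}"
        )
        for flag in r.flags:
            lines.append(f"      note: {flag}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the configured stages and write their outputs under ``out_dir``.

    Returns a summary dict with the experiment table, fitted curves,
    image thresholds and case records (also written to disk).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_sha256": config.sha256(), "version": __version__,
                     "seed": config.seed}
    spec = config.spec

    if config.experiment:
        log.info("stage experiment: %d replicates, %s process",
                 config.n_replicates, config.process)
        try:
            table = run_strategy_experiment(
                spec,
                process=config.process,
                n_replicates=config.n_replicates,
                seed=config.seed,
                intensity=config.intensity,
                cluster_rate=config.cluster_rate,
                cluster_size_mean=config.cluster_size_mean,
                cluster_sd_mm=config.cluster_sd_mm,
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"experiment stage: {exc}") from exc
        table.to_csv(out / "experiment.csv", index=False)
        summary["experiment"] = table

        log.info("stage accuracy_model: fitting log curves")
        curves = {}
        for strategy, group in table.groupby("strategy"):
            pts = list(zip(group["n_images"], group["mean_accuracy_pct"]))
            curve = fit_log_curve(pts, strategy=strategy)
            try:
                needed = images_needed(curve, config.target_accuracy_pct)
            except ValueError:
                needed = None
            curves[strategy] = {
                "a": curve.a,
                "b": curve.b,
                "images_needed": needed,
                "target_pct": config.target_accuracy_pct,
            }
        with open(out / "curves.json", "w", encoding="utf-8") as fh:
            json.dump(curves, fh, indent=2, sort_keys=True)
        summary["curves"] = curves

    if config.cases_csv is not None:
        log.info("stage ld_diagnostics: %s", config.cases_csv)
        records = [_case_record(c) for c in read_cases_csv(config.cases_csv)]
        frame = _records_frame(records)
        frame.to_csv(out / "cases.csv", index=False)
        (out / "report.txt").write_text(_text_report(records), encoding="utf-8")
        summary["cases"] = records

    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": config.seed,
                "config_sha256": config.sha256(),
                "config": dataclasses.asdict(config),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return summary


def generate_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write small deterministic fixture files: a simulated point
    pattern, transect/scatter plans, per-field counts, the published
    per-case concentrations as a case CSV, the control tissue triples,
    and the empirical accuracy ladders."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = MembraneSpec()
    paths: dict[str, Path] = {}

    pattern = simulate_membrane(spec, "clustered", cluster_rate=0.3,
                                cluster_size_mean=25.0, cluster_sd_mm=0.3, seed=seed)
    paths["pattern"] = out / "pattern.csv"
    pattern.to_csv(paths["pattern"])

    plan = make_scatter_plan(spec, "full")
    paths["plan"] = out / "plan_scatter_full.csv"
    plan.to_csv(paths["plan"])
    tplan = make_transect_plan(spec, "full")
    paths["plan_transect"] = out / "plan_transect_full.csv"
    tplan.to_csv(paths["plan_transect"])

    from .estimation import count_fields  # local import avoids cycle at module load

    counts = count_fields(pattern, plan)
    paths["counts"] = out / "counts_scatter_full.csv"
    counts.to_csv(paths["counts"])

    rows = []
    for rec in study_cases().itertuples(index=False):
        # concentrations are stored per unit size (1 g lung, 1 ml medium)
        rows.append(
            {
                "case_id": rec.case_id,
                "sample_kind": "lung",
                "size_g_or_ml": 1.0,
                "diatom_count": rec.lung_per_gram,
                "flags": rec.flags,
            }
        )
        rows.append(
            {
                "case_id": rec.case_id,
                "sample_kind": "medium",
                "size_g_or_ml": 1.0,
                "diatom_count": rec.medium_per_ml,
                "flags": "",
            }
        )
    paths["cases"] = out / "study_cases.csv"
    write_cases_csv(paths["cases"], rows)

    ctrl_rows = []
    for case_id, (masses, cnts) in control_cases().items():
        for m, c in zip(masses, cnts):
            ctrl_rows.append(
                {"case_id": case_id, "sample_kind": "lung", "size_g_or_ml": m,
                 "diatom_count": c, "flags": ""}
            )
    paths["controls"] = out / "control_tissue.csv"
    write_cases_csv(paths["controls"], ctrl_rows)

    from .datasets import scatter_accuracy_ladder, transect_accuracy_ladder

    ladder = pd.DataFrame(
        [("transect", n, a) for n, a in transect_accuracy_ladder()]
        + [("scatter", n, a) for n, a in scatter_accuracy_ladder()],
        columns=["strategy", "n_images", "accuracy_pct"],
    )
    paths["ladder"] = out / "accuracy_ladder.csv"
    ladder.to_csv(paths["ladder"], index=False)
    return paths
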