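"""End-to-end orchestration: load -> derive -> screen -> fit -> CV -> rank -> report.

One invocation analyses one response (the urinary and fecal databases are
separate); ``run_both`` is a convenience wrapper.  Every artifact is stamped
with a hash of the configuration and the seed, and two runs with identical
config produce byte-identical CSV/JSON reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import evaluation, mixed_model, screening, synthetic_data
from .database import (
    StudyDatabase,
    ValidationReport,
    derive_k_intake,
    load_database,
    summarize,
    write_database,
)
from .evaluation import EvaluationError
from .mixed_model import ModelFitError, ModelSpec

__all__ = ["PipelineConfig", "PipelineResult", "DEFAULT_PREDICTORS", "run", "run_both"]

log = logging.getLogger("kexmeta")

#: candidate predictors per response, in reporting order
DEFAULT_PREDICTORS = {
    "k_ur": ("dmi", "k_intake", "dietary_k", "water_intake", "urine_volume", "milk_yield"),
    "k_fa": ("dmi", "k_intake", "dietary_k", "milk_yield"),
}
#: variables screened for extreme values (those with data are used)
DEFAULT_SCREEN_VARIABLES = {
    "k_ur": ("k_ur", "dmi", "k_intake", "urine_volume"),
    "k_fa": ("k_fa", "dmi", "k_intake"),
}

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    response_name: str = "k_ur"
    input_csv: str | None = None
    synthetic: synthetic_data.SyntheticConfig | None = None
    candidate_predictors: tuple[str, ...] | None = None
    screening_variables: tuple[str, ...] | None = None
    screening_factor: float = 1.5
    blocklist_studies: tuple[str, ...] = ()
    blocklist_records: tuple[str, ...] = ()
    out_dir: str = "kexmeta_out"
    seed: int = 0
    skip_failing: bool = False
    dry_run: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where the report is
        written does not change what was computed)."""
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("dry_run")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineResult:
    config: PipelineConfig
    database: StudyDatabase
    validation: ValidationReport | None
    screening_report: screening.ScreeningReport
    models: dict[str, mixed_model.FittedModel]
    cv_sets: dict[str, evaluation.CVPredictionSet]
    metrics: dict[str, evaluation.EvaluationMetrics]
    ranking: list[str]
    failures: dict[str, str] = field(default_factory=dict)


def _acquire(config: PipelineConfig) -> tuple[StudyDatabase, ValidationReport | None]:
    if (config.input_csv is None) == (config.synthetic is None):
        raise ValueError("exactly one of input_csv / synthetic must be given")
    if config.input_csv is not None:
        db, report = load_database(config.input_csv, config.response_name)
        log.info("load: %d records, %d studies, %d rows rejected", len(db), len(db.study_ids()), report.n_rejected)
        return db, report
    syn = dataclasses.replace(config.synthetic, seed=config.seed, response_name=config.response_name)
    db = synthetic_data.generate(syn)
    log.info("simulate: %d records, %d studies (seed %d)", len(db), len(db.study_ids()), config.seed)
    return db, None


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to ``out_dir``.

    Emits the screening report, descriptive summary, fitted equations,
    cross-validated metrics, the ranked model list and per-model plot data.
    With ``dry_run`` the config and input are validated and nothing is
    written.  A model that fails to fit aborts the run unless
    ``skip_failing`` is set, in which case it is recorded and skipped.
    """
    db, validation = _acquire(config)
    if config.dry_run:
        log.info("dry-run: config and input valid; stopping before analysis")
        return PipelineResult(config, db, validation, screening.ScreeningReport((), (), 0), {}, {}, {}, [])

    if config.blocklist_studies or config.blocklist_records:
        keep = tuple(
            r
            for r in db.records
            if r.study_id not in config.blocklist_studies and r.record_id not in config.blocklist_records
        )
        log.info("blocklist: removed %d records", len(db.records) - len(keep))
        db = dataclasses.replace(db, records=keep)

    db = db.map_records(derive_k_intake)

    screen_vars = config.screening_variables or DEFAULT_SCREEN_VARIABLES[config.response_name]
    db, screen_report = screening.apply_screen(db, screen_vars, config.screening_factor, skip_sparse=True)
    for line in screen_report.log_lines():
        log.info("screening: %s", line)

    summary = summarize(db)

    predictors = config.candidate_predictors or DEFAULT_PREDICTORS[config.response_name]
    models: dict[str, mixed_model.FittedModel] = {}
    cv_sets: dict[str, evaluation.CVPredictionSet] = {}
    metrics: dict[str, evaluation.EvaluationMetrics] = {}
    failures: dict[str, str] = {}
    for pred in predictors:
        spec = ModelSpec(response_name=config.response_name, predictor_name=pred)
        try:
            models[pred] = mixed_model.fit(db, spec)
            cv_sets[pred] = evaluation.loso_cv(db, spec)
            metrics[pred] = evaluation.decompose_mspe(cv_sets[pred])
            log.info("model %s: %s | RSR=%.3f CCC=%.3f", spec.name, models[pred].equation(), metrics[pred].rsr, metrics[pred].ccc)
        except (ModelFitError, EvaluationError) as exc:
            if not config.skip_failing:
                raise
            failures[pred] = str(exc)
            log.warning("model %s failed (skipped): %s", spec.name, exc)
    ranked = evaluation.rank_models([(models[p].spec, metrics[p]) for p in metrics])
    ranking = [s.predictor_name for s, _ in ranked]

    _write_bundle(config, db, validation, screen_report, summary, models, cv_sets, metrics, ranking, failures)
    return PipelineResult(config, db, validation, screen_report, models, cv_sets, metrics, ranking, failures)


def _jdump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_bundle(config, db, validation, screen_report, summary, models, cv_sets, metrics, ranking, failures) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    _jdump({"config": config.to_dict(), **stamp}, out / "manifest.json")
    if validation is not None:
        _jdump(
            {
                "rejections": [
                    {"row_index": r.row_index, "record_id": r.record_id, "reasons": list(r.reasons)}
                    for r in validation.rejections
                ],
                **stamp,
            },
            out / "rejected_rows.json",
        )
    (out / "screening.json").write_text(screen_report.to_json() + "\n", encoding="utf-8")

    # Table-1-style summary, CSV + JSON
    rows = [
        {
            "variable": r.variable,
            "n": r.n,
            "mean": r.mean,
            "sd": r.sd,
            "min": r.min,
            "max": r.max,
            "cv_pct": r.cv_pct,
        }
        for r in summary.rows
    ]
    _jdump({"rows": rows, "excretion_share_pct": summary.excretion_share_pct, **stamp}, out / "summary.json")
    _write_csv(out / "summary.csv", ["variable", "n", "mean", "sd", "min", "max", "cv_pct"], rows)

    _jdump({p: m.to_dict() for p, m in models.items()} | {"_stamp": stamp}, out / "models.json")
    (out / "equations.txt").write_text(
        "".join(f"{models[p].equation()}\n" for p in models), encoding="utf-8"
    )

    mrows = [
        {"predictor": p, "n": metrics[p].n, "r2_marginal": models[p].r2_marginal}
        | {k: getattr(metrics[p], k) for k in ("rmspe_pct", "mb_pct", "sb_pct", "ed_pct", "rsr", "ccc", "p_mean_bias", "p_slope_bias")}
        for p in metrics
    ]
    _jdump({"metrics": mrows, **stamp}, out / "metrics.json")
    _write_csv(
        out / "metrics.csv",
        ["predictor", "n", "r2_marginal", "rmspe_pct", "mb_pct", "sb_pct", "ed_pct", "rsr", "ccc", "p_mean_bias", "p_slope_bias"],
        mrows,
    )
    _write_csv(out / "ranking.csv", ["rank", "predictor"], [{"rank": i + 1, "predictor": p} for i, p in enumerate(ranking)])
    if failures:
        _jdump({"failures": failures, **stamp}, out / "failures.json")

    plots = out / "plot_data"
    plots.mkdir(exist_ok=True)
    for p, cvset in cv_sets.items():
        pd_ = evaluation.plot_data(cvset)
        _jdump(pd_ | {"_stamp": stamp}, plots / f"{p}.json")
        _write_csv(
            plots / f"{p}.csv",
            ["record_id", "study_id", "predicted", "observed", "residual"],
            pd_["rows"],
        )
    write_database(db, out / "analysis_database.csv")


def _write_csv(path: Path, columns: list[str], rows: list[dict]) -> None:
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    lines = [",".join(columns)]
    lines += [",".join(fmt(row[c]) for c in columns) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_both(config: PipelineConfig) -> dict[str, PipelineResult]:
    """Run the urinary and fecal analyses with shared settings."""
    results = {}
    for resp in ("k_ur", "k_fa"):
        sub = dataclasses.replace(
            config,
            response_name=resp,
            candidate_predictors=None,
            screening_variables=None,
            out_dir=str(Path(config.out_dir) / resp),
        )
        results[resp] = run(sub)
    return results
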