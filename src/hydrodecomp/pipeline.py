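"""One-shot orchestration: check, fit, predict, score, with artifacts.

``run_full`` ties the stages together on a component table: consistency
audit of printed totals, origin-constrained LRT fit (when interaction-
energy pairs are supplied), ASA-linear non-electrostatic refit (when the
records carry ASA values), ΔA_hyd prediction under a chosen non-ES model,
and MAE/RMSE scoring against experimental references when present.  Every
artifact lands in the run directory stamped with a hash of the
configuration and the seed; inputs are never mutated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import decomposition, lrt, pb_models
from .decomposition import SoluteRecord, check_consistency, load_component_table
from .lrt import EnergyPair
from .pb_models import MODIFIED_PB, ORIGINAL_PB, NonESModel

__all__ = ["RunConfig", "RunReport", "run_full"]

logger = logging.getLogger(__name__)

_MODELS = {"original": ORIGINAL_PB, "modified": MODIFIED_PB}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for a full pipeline run.

    ``table_path`` None means the packaged aromatic component table.
    ``model`` is ``original``, ``modified`` or ``refit`` (refit requires
    ASA values on the records).  ``alpha_from``/``alpha_to`` optionally
    rescale the electrostatic component between LRT coefficients.
    """

    output_dir: str
    table_path: str | None = None
    lrt_pairs_path: str | None = None
    model: str = "modified"
    consistency_tol: float = decomposition.CONSISTENCY_TOL
    alpha_from: float | None = None
    alpha_to: float | None = None
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the scientific configuration; where artifacts land does
        not change a run's identity, so output_dir is excluded."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class RunReport:
    config_hash: str
    seed: int
    n_records: int
    n_consistency_flags: int
    lrt_fit: lrt.LinearFit | None
    non_es_model: NonESModel | None
    error_report: pb_models.ErrorReport | None
    artifacts: tuple[str, ...]


def _load_pairs(path: str) -> list[EnergyPair]:
    import csv

    pairs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"dA", "u_mean"} <= set(reader.fieldnames):
            raise StageError("fit-lrt: pairs CSV needs columns 'dA' and 'u_mean'")
        for row in reader:
            pairs.append(
                EnergyPair(
                    dA=float(row["dA"].replace("−", "-")),
                    u_mean=float(row["u_mean"].replace("−", "-")),
                    label=row.get("label", ""),
                )
            )
    return pairs


def run_full(config: RunConfig) -> RunReport:
    """Execute the full analysis; returns the report and writes artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    def emit(name: str, payload) -> None:
        p = out / name
        p.write_text(json.dumps({**stamp, **payload}, indent=2, sort_keys=True) + "\n",
                     encoding="utf-8")
        artifacts.append(str(p))

    # stage: load
    try:
        if config.table_path is None:
            records = decomposition.aromatics_records()
        else:
            records = load_component_table(config.table_path)
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc
    logger.info("load: %d records in", len(records))

    # stage: consistency
    try:
        report = check_consistency(records, tol=config.consistency_tol)
    except Exception as exc:
        raise StageError(f"consistency: {exc}") from exc
    flags = [e for e in report if e.flagged]
    emit(
        "consistency.json",
        {
            "tol": config.consistency_tol,
            "entries": [dataclasses.asdict(e) for e in report],
            "n_flagged": len(flags),
        },
    )
    logger.info("consistency: %d checked, %d flagged", len(report), len(flags))

    # stage: LRT fit (optional input)
    lrt_fit = None
    if config.lrt_pairs_path is not None:
        pairs = _load_pairs(config.lrt_pairs_path)
        try:
            lrt_fit = lrt.fit_through_origin(pairs)
        except Exception as exc:
            raise StageError(f"fit-lrt: {exc}") from exc
        emit("lrt_fit.json", {"fit": dataclasses.asdict(lrt_fit)})
        logger.info("fit-lrt: %d pairs in, slope %.4f", lrt_fit.n, lrt_fit.slope)
    else:
        logger.info("fit-lrt: no pairs supplied, stage skipped")

    # stage: non-ES model
    have_asa = all(r.asa is not None for r in records) and records
    non_es_model: NonESModel | None
    if config.model == "refit":
        if not have_asa:
            raise StageError("non-es: refit requested but records lack ASA values")
        try:
            non_es_model = pb_models.refit_non_es(records)
        except Exception as exc:
            raise StageError(f"non-es: {exc}") from exc
    elif config.model in _MODELS:
        non_es_model = _MODELS[config.model]
    else:
        raise StageError(f"non-es: unknown model {config.model!r}")
    emit("non_es_model.json", {"model": dataclasses.asdict(non_es_model)})
    logger.info("non-es: model %s (slope %.4f, intercept %.2f)",
                non_es_model.label, non_es_model.slope, non_es_model.intercept)

    # stage: predict (only possible with ASA)
    error_report = None
    if have_asa:
        try:
            preds = pb_models.predict_all(
                records, non_es_model, config.alpha_from, config.alpha_to
            )
        except Exception as exc:
            raise StageError(f"predict: {exc}") from exc
        pred_csv = out / "predictions.csv"
        with open(pred_csv, "w", encoding="utf-8") as fh:
            fh.write("name,e_reorg,dA_es_used,dA_non_es_used,dA_hyd_pred\n")
            for p in preds:
                fh.write(
                    f"{p.name},{p.e_reorg!r},{p.dA_es_used!r},"
                    f"{p.dA_non_es_used!r},{p.dA_hyd_pred!r}\n"
                )
        artifacts.append(str(pred_csv))
        logger.info("predict: %d records in, %d predictions out", len(records), len(preds))

        refs = [(p, r.exp_dA_hyd) for p, r in zip(preds, records) if r.exp_dA_hyd is not None]
        if refs:
            error_report = pb_models.score(
                [p.dA_hyd_pred for p, _ in refs], [e for _, e in refs]
            )
            emit("scores.json", {"scores": dataclasses.asdict(error_report)})
            logger.info("score: %d references, MAE %.3f RMSE %.3f",
                        error_report.n, error_report.mae, error_report.rmse)
        else:
            logger.info("score: no experimental references, stage skipped")
    else:
        logger.info("predict: records lack ASA values, stage skipped")

    run_report = RunReport(
        config_hash=stamp["config_hash"],
        seed=config.seed,
        n_records=len(records),
        n_consistency_flags=len(flags),
        lrt_fit=lrt_fit,
        non_es_model=non_es_model,
        error_report=error_report,
        artifacts=tuple(artifacts),
    )
    emit(
        "run_report.json",
        {
            "n_records": run_report.n_records,
            "n_consistency_flags": run_report.n_consistency_flags,
            "lrt_fit": None if lrt_fit is None else dataclasses.asdict(lrt_fit),
            "non_es_model": dataclasses.asdict(non_es_model),
            "scores": None if error_report is None else dataclasses.asdict(error_report),
            "artifacts": sorted(a.rsplit("/", 1)[-1] for a in artifacts),
        },
    )
    return run_report
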