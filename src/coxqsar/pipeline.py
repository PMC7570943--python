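"""End-to-end orchestration of the QSAR + screening analysis.

``run_qsar`` is the modelling arm: correlation report, sign-blind
descriptor selection, exhaustive subset enumeration and fitting, model
ranking, residual validation on the training and internal sets with
outlier flagging, and external validation of the chosen model.
``run_screen`` is the triage arm: Lipinski filtering and optional
Tanimoto filtering of candidates, then activity prediction with the
chosen model. Reports are deterministic given config + inputs;
timestamps are confined to the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compound_table import (
    CompoundTable,
    load_external_validation,
    load_internal_validation,
    load_training_table,
    read_compound_table,
)
from .errors import ConfigurationError, CoxQsarError, DataError, OrderingError
from .qsar_regression import (
    ModelLeaderboard,
    PredictionRecord,
    RegressionModel,
    ValidationSummary,
    build_correlation_report,
    build_leaderboard,
    external_validation,
    flag_outliers,
    predict,
    residual_table,
    select_descriptors,
)
from .screening_filters import (
    Fingerprint,
    PropertyProfile,
    filter_by_tanimoto,
    lipinski_violations,
    load_property_profiles,
    read_fingerprints,
    tanimoto,
)

logger = logging.getLogger("coxqsar")

__all__ = ["PipelineConfig", "QsarResult", "ScreenResult", "run_qsar", "run_screen"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study defaults."""

    training_path: str | None = None
    internal_path: str | None = None
    external_path: str | None = None
    candidates_path: str | None = None
    fingerprints_path: str | None = None
    reference_fingerprint_id: str | None = None
    correlation_cutoff: float = 0.4
    max_p: int = 4
    outlier_threshold: float = 0.4
    tanimoto_cutoff: float = 0.35
    lipinski_max_violations: int = 1
    dg_sign_mode: str = "as-printed"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation_cutoff <= 1.0:
            raise ConfigurationError(
                f"correlation_cutoff must be in [0, 1], got {self.correlation_cutoff}"
            )
        if not 0.0 <= self.tanimoto_cutoff <= 1.0:
            raise ConfigurationError(
                f"tanimoto_cutoff must be in [0, 1], got {self.tanimoto_cutoff}"
            )
        if self.max_p < 1:
            raise ConfigurationError(f"max_p must be >= 1, got {self.max_p}")
        if self.outlier_threshold < 0:
            raise ConfigurationError(
                f"outlier_threshold must be >= 0, got {self.outlier_threshold}"
            )
        if self.dg_sign_mode not in ("as-printed", "thermodynamic"):
            raise ConfigurationError(f"unknown dg_sign_mode {self.dg_sign_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _records_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "model_id": r.model_id,
                "observed_pic50": r.observed_pic50,
                "predicted_pic50": r.predicted_pic50,
                "residual": r.residual,
            }
            for r in records
        ]
    )


@dataclass
class QsarResult:
    """Everything the modelling stage produced."""

    leaderboard: ModelLeaderboard
    chosen_model: RegressionModel
    selected_descriptors: list[str]
    training_records: list[PredictionRecord]
    internal_records: list[PredictionRecord]
    internal_flagged: list[PredictionRecord]
    external_summary: ValidationSummary | None

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.leaderboard.to_frame().to_csv(
            out / "leaderboard.csv", index=False, float_format="%.6f"
        )
        model = self.chosen_model
        document = {
            "subset": model.descriptor_subset,
            "intercept": model.intercept,
            "coefficients": model.coefficients,
            "n_train": model.n_train,
            "stats": model.stats,
        }
        (out / "chosen_model.json").write_text(json.dumps(document, indent=2) + "\n")
        _records_frame(self.training_records).to_csv(
            out / "residuals_training.csv", index=False, float_format="%.6f"
        )
        if self.internal_records:
            _records_frame(self.internal_records).to_csv(
                out / "residuals_internal.csv", index=False, float_format="%.6f"
            )
        if self.external_summary is not None:
            _records_frame(self.external_summary.records).to_csv(
                out / "residuals_external.csv", index=False, float_format="%.6f"
            )


def run_qsar(config: PipelineConfig) -> QsarResult:
    """Execute the full modelling stage; see the module docstring."""
    try:
        training = (
            read_compound_table(config.training_path)
            if config.training_path
            else load_training_table()
        )
        internal = (
            read_compound_table(config.internal_path)
            if config.internal_path
            else load_internal_validation()
        )
        external = (
            read_compound_table(config.external_path)
            if config.external_path
            else load_external_validation()
        )
    except CoxQsarError as exc:
        raise type(exc)(f"qsar input: {exc}") from exc

    logger.info(
        "qsar: version=%s seed=%d cutoff=%.3g max_p=%d n_train=%d",
        __version__, config.seed, config.correlation_cutoff, config.max_p, len(training),
    )
    report = build_correlation_report(training, config.correlation_cutoff)
    selected = select_descriptors(report)
    logger.info("qsar: selected descriptors %s", "+".join(selected))
    leaderboard = build_leaderboard(training, selected, config.max_p)
    chosen = leaderboard.best
    logger.info(
        "qsar: chosen model %s (R2=%.4f SEE=%.4f)",
        chosen.model_id, chosen.stats["R2"], chosen.stats["SEE"],
    )

    training_records = residual_table(training, [chosen])
    internal_records = (
        residual_table(internal, [chosen]) if len(internal) else []
    )
    _, internal_flagged = (
        flag_outliers(internal_records, config.outlier_threshold)
        if internal_records
        else ([], [])
    )
    for record in internal_flagged:
        logger.info(
            "qsar: internal outlier %s |residual|=%.4f > %.3g",
            record.compound_id, abs(record.residual), config.outlier_threshold,
        )
    summary = external_validation(chosen, external) if len(external) else None

    result = QsarResult(
        leaderboard=leaderboard,
        chosen_model=chosen,
        selected_descriptors=selected,
        training_records=training_records,
        internal_records=internal_records,
        internal_flagged=internal_flagged,
        external_summary=summary,
    )
    if config.output_dir:
        result.write(config.output_dir)
    return result


@dataclass
class ScreenResult:
    """Candidate triage report."""

    report: pd.DataFrame
    exclusions: list[dict]

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "candidates_ranked.csv", index=False, float_format="%.4f")
        (out / "screen_exclusions.json").write_text(
            json.dumps(self.exclusions, indent=2) + "\n"
        )


def run_screen(
    config: PipelineConfig,
    model: RegressionModel | None = None,
    candidates: CompoundTable | None = None,
    profiles: list[PropertyProfile] | None = None,
) -> ScreenResult:
    """Triage candidates and predict their activity with the chosen model.

    Requires a chosen model (pass one or run :func:`run_qsar` first).
    Candidates failing the Lipinski budget or, when fingerprints are
    supplied, the Tanimoto cutoff are excluded with a logged reason.
    """
    if model is None:
        raise OrderingError("no chosen model; run the qsar stage first")
    if candidates is None:
        if not config.candidates_path:
            raise ConfigurationError("no candidate table provided")
        candidates = read_compound_table(config.candidates_path, require_activity=False)
    if profiles is None:
        profiles = load_property_profiles()
    profile_by_id = {p.id: p for p in profiles}

    similarity: dict[str, float] = {}
    if config.fingerprints_path:
        fingerprints = read_fingerprints(config.fingerprints_path)
        by_id = {fp.id: fp for fp in fingerprints}
        reference_id = config.reference_fingerprint_id
        if reference_id is None or reference_id not in by_id:
            raise ConfigurationError(
                f"reference fingerprint {reference_id!r} not found in "
                f"{config.fingerprints_path}"
            )
        reference = by_id[reference_id]
        similarity = {
            fp.id: tanimoto(fp, reference)
            for fp in fingerprints
            if fp.id != reference_id
        }

    rows, exclusions = [], []
    for compound in candidates:
        profile = profile_by_id.get(compound.id)
        violations = lipinski_violations(profile) if profile else None
        if violations is not None and violations > config.lipinski_max_violations:
            reason = {
                "compound_id": compound.id,
                "rule": "lipinski",
                "value": violations,
                "limit": config.lipinski_max_violations,
            }
            exclusions.append(reason)
            logger.info("screen: excluded %s (%s)", compound.id, reason)
            continue
        if similarity and compound.id in similarity:
            if not similarity[compound.id] > config.tanimoto_cutoff:
                reason = {
                    "compound_id": compound.id,
                    "rule": "tanimoto",
                    "value": similarity[compound.id],
                    "limit": config.tanimoto_cutoff,
                }
                exclusions.append(reason)
                logger.info("screen: excluded %s (%s)", compound.id, reason)
                continue
        rows.append(
            {
                "id": compound.id,
                "role": compound.role,
                **{d: compound.descriptors.get(d) for d in candidates.descriptor_names},
                "lipinski_violations": violations,
                "tanimoto": similarity.get(compound.id),
                "predicted_pic50": predict(model, compound.descriptors),
            }
        )
    report = pd.DataFrame(rows)
    if not report.empty:
        report = report.sort_values(
            "predicted_pic50", ascending=False, kind="stable"
        ).reset_index(drop=True)
    else:
        logger.warning("screen: no candidates passed the filters")
    result = ScreenResult(report=report, exclusions=exclusions)
    if config.output_dir:
        result.write(config.output_dir)
    return result
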