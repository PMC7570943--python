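"""Descriptor selection, exhaustive-subset MLR fitting, and validation.

The modelling strategy is the classical small-molecule QSAR recipe:

1. score every descriptor against pIC50 with the Pearson correlation and
   keep those with |rho| at or above a cutoff (0.4 by default; the sign is
   ignored, so strong negative correlates such as acceptor counts survive);
2. enumerate every subset of the retained descriptors up to size ``max_p``
   and fit an ordinary-least-squares model pIC50 ~ intercept + subset for
   each — C(n, p) models per size p, 2^n - 1 in total;
3. rank the models by R^2 and validate the front-runner by residuals on
   held-out compounds (internal and external sets), flagging residuals
   whose magnitude exceeds an outlier threshold (0.4 by default).

Quality statistics follow the standard OLS definitions: R^2 = 1 - SSE/SST,
R = +sqrt(R^2) (the multiple correlation is non-negative by convention),
adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1), SEE = sqrt(SSE/(n - p - 1)),
and F = (R^2/p) / ((1 - R^2)/(n - p - 1)).

Published reference equations carry coefficients rounded to 4 decimals;
:func:`load_reference_models` exposes them so predictions can be made
"as printed", while :func:`fit_mlr` refits at full precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .compound_table import CompoundTable, _data_path
from .errors import (
    CollinearityError,
    DataError,
    DegenerateInputError,
    DomainError,
    EmptySelectionError,
    MissingDescriptorError,
)

__all__ = [
    "CorrelationReport",
    "RegressionModel",
    "ModelLeaderboard",
    "PredictionRecord",
    "ValidationSummary",
    "pearson",
    "build_correlation_report",
    "select_descriptors",
    "enumerate_subsets",
    "fit_mlr",
    "predict",
    "residual_table",
    "flag_outliers",
    "external_validation",
    "build_leaderboard",
    "load_reference_models",
]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation between two equal-length vectors.

    Defined as sum((x_i - xbar)(y_i - ybar)) / ((n - 1) s_x s_y) with the
    sample (n - 1) standard deviations. Raises instead of returning NaN
    when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"expected equal-length 1-D vectors, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise DomainError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input to Pearson correlation")
    return float(scipy.stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationReport:
    """Pairwise descriptor correlations and each descriptor's correlation
    with pIC50, plus the selection cutoff to be applied to the latter."""

    descriptor_names: list[str]
    pairwise: np.ndarray
    vs_activity: np.ndarray
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.pairwise, index=self.descriptor_names, columns=self.descriptor_names
        )
        frame["pIC50"] = self.vs_activity
        return frame


def build_correlation_report(table: CompoundTable, cutoff: float = 0.4) -> CorrelationReport:
    """Correlation structure of a training table's descriptors vs activity."""
    if cutoff < 0:
        raise DomainError(f"cutoff must be non-negative, got {cutoff}")
    names = list(table.descriptor_names)
    X = table.descriptor_matrix(names)
    y = table.pic50_vector()
    if len(table) < 3:
        raise DomainError("need at least 3 compounds for a correlation report")

    for i, name in enumerate(names):
        if np.ptp(X[:, i]) == 0:
            raise DegenerateInputError(
                f"descriptor {name!r} is constant; correlation undefined"
            )
    n = len(names)
    pairwise = np.eye(n)
    vs_activity = np.empty(n)
    for i in range(n):
        vs_activity[i] = pearson(X[:, i], y)
        for j in range(i + 1, n):
            pairwise[i, j] = pairwise[j, i] = pearson(X[:, i], X[:, j])
    return CorrelationReport(names, pairwise, vs_activity, cutoff)


def select_descriptors(report: CorrelationReport) -> list[str]:
    """Descriptors whose |rho vs activity| meets the report's cutoff.

    Selection is sign-blind: a strongly negative correlate carries as much
    linear information as a positive one. Input order is preserved.
    """
    kept = [
        name
        for name, rho in zip(report.descriptor_names, report.vs_activity)
        if abs(rho) >= report.cutoff
    ]
    if not kept:
        raise EmptySelectionError(
            f"no descriptor reaches |rho| >= {report.cutoff}; modelling cannot proceed"
        )
    return kept


def enumerate_subsets(descriptors: Sequence[str], p: int) -> list[tuple[str, ...]]:
    """All C(n, p) descriptor subsets of size ``p``, in lexicographic
    order of member indices, without repetition."""
    n = len(descriptors)
    if not 1 <= p <= n:
        raise DomainError(f"subset size p={p} out of range 1..{n}")
    return list(itertools.combinations(descriptors, p))


@dataclass
class RegressionModel:
    """A fitted (or published) descriptor-subset MLR with quality statistics."""

    descriptor_subset: list[str]
    intercept: float
    coefficients: dict[str, float]
    n_train: int
    stats: dict[str, float] = field(default_factory=dict)
    label: str | None = None

    @property
    def p(self) -> int:
        return len(self.descriptor_subset)

    @property
    def model_id(self) -> str:
        """Subset signature such as ``"ATM+ACC+DONN+ARO"``."""
        return "+".join(self.descriptor_subset)

    def as_printed(self, ndigits: int = 4) -> "RegressionModel":
        """Copy with intercept and coefficients rounded for presentation.

        Published equations carry 4-decimal coefficients; evaluating this
        rounded form reproduces reference predictions digit for digit.
        """
        return RegressionModel(
            descriptor_subset=list(self.descriptor_subset),
            intercept=round(self.intercept, ndigits),
            coefficients={k: round(v, ndigits) for k, v in self.coefficients.items()},
            n_train=self.n_train,
            stats=dict(self.stats),
            label=self.label,
        )

    def predict(self, descriptors: Mapping[str, float]) -> float:
        return predict(self, descriptors)


def fit_mlr(table: CompoundTable, subset: Sequence[str]) -> RegressionModel:
    """Ordinary-least-squares fit of pIC50 on a descriptor subset.

    Requires more compounds than parameters and a full-rank design.
    """
    subset = list(subset)
    y = table.pic50_vector()
    X = table.descriptor_matrix(subset)
    n, p = X.shape
    if n <= p + 1:
        raise DataError(
            f"insufficient degrees of freedom: n={n} compounds cannot "
            f"support p={p} descriptors plus an intercept"
        )
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise CollinearityError(
            f"design matrix for subset {'+'.join(subset)} is rank-deficient "
            f"(rank {rank} < {p + 1}); some columns are linearly dependent"
        )
    fit = sm.OLS(y, design).fit()

    residuals = y - fit.fittedvalues
    sse = float(residuals @ residuals)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    see = math.sqrt(sse / (n - p - 1))
    # a perfect fit has zero residual variance; report F as +inf
    f_stat = (
        math.inf if r2 >= 1.0 else (r2 / p) / ((1.0 - r2) / (n - p - 1))
    )
    return RegressionModel(
        descriptor_subset=subset,
        intercept=float(fit.params[0]),
        coefficients={name: float(c) for name, c in zip(subset, fit.params[1:])},
        n_train=n,
        stats={"R": math.sqrt(r2), "R2": r2, "R2_adj": r2_adj, "SEE": see, "F": f_stat},
    )


def predict(model: RegressionModel, descriptors: Mapping[str, float]) -> float:
    """Affine evaluation: intercept + sum(coefficient * descriptor value)."""
    total = model.intercept
    for name in model.descriptor_subset:
        if name not in descriptors:
            raise MissingDescriptorError(name)
        total += model.coefficients[name] * descriptors[name]
    return total


@dataclass
class PredictionRecord:
    """Observed vs predicted pIC50 for one compound under one model."""

    compound_id: str
    model_id: str
    predicted_pic50: float
    observed_pic50: float | None = None

    @property
    def residual(self) -> float | None:
        """Observed minus predicted (the Delta of residual tables)."""
        if self.observed_pic50 is None:
            return None
        return self.observed_pic50 - self.predicted_pic50


def residual_table(
    table: CompoundTable, models: Iterable[RegressionModel]
) -> list[PredictionRecord]:
    """One prediction record per compound x model, residuals included."""
    records = []
    for model in models:
        for compound in table:
            records.append(
                PredictionRecord(
                    compound_id=compound.id,
                    model_id=model.label or model.model_id,
                    predicted_pic50=predict(model, compound.descriptors),
                    observed_pic50=compound.pic50,
                )
            )
    return records


def flag_outliers(
    records: Sequence[PredictionRecord], threshold: float = 0.4
) -> tuple[list[PredictionRecord], list[PredictionRecord]]:
    """Partition records into (retained, flagged) by |residual| > threshold."""
    retained, flagged = [], []
    for record in records:
        if record.residual is None:
            raise DataError(
                f"record {record.compound_id!r} has no observed pIC50; "
                "cannot screen for outliers"
            )
        (flagged if abs(record.residual) > threshold else retained).append(record)
    return retained, flagged


@dataclass
class ValidationSummary:
    """External-validation residual report for one model."""

    model_id: str
    records: list[PredictionRecord]
    max_abs_residual: float
    mean_abs_residual: float


def external_validation(model: RegressionModel, table: CompoundTable) -> ValidationSummary:
    """Residuals of ``model`` on a table's external-validation compounds."""
    external = table.subset_by_role("external_validation")
    if len(external) == 0:
        raise DataError("table contains no external_validation compounds")
    records = residual_table(external, [model])
    abs_res = [abs(r.residual) for r in records]
    return ValidationSummary(
        model_id=model.label or model.model_id,
        records=records,
        max_abs_residual=max(abs_res),
        mean_abs_residual=sum(abs_res) / len(abs_res),
    )


@dataclass
class ModelLeaderboard:
    """All fitted subset models, grouped by subset size and ranked."""

    models: list[RegressionModel]
    ranking_key: str = "R2"

    def by_size(self, p: int) -> list[RegressionModel]:
        return [m for m in self.models if m.p == p]

    @property
    def best(self) -> RegressionModel:
        return self.ranked()[0]

    def ranked(self) -> list[RegressionModel]:
        """All models, best first: ranking key descending, ties broken by
        smaller subset then lexicographic subset signature."""
        return sorted(
            self.models,
            key=lambda m: (-m.stats[self.ranking_key], m.p, m.model_id),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subset": m.model_id,
                "p": m.p,
                "R": m.stats["R"],
                "R2": m.stats["R2"],
                "R2_adj": m.stats["R2_adj"],
                "SEE": m.stats["SEE"],
                "F": m.stats["F"],
            }
            for m in self.ranked()
        ]
        return pd.DataFrame(rows, columns=["subset", "p", "R", "R2", "R2_adj", "SEE", "F"])


def build_leaderboard(
    table: CompoundTable,
    descriptors: Sequence[str],
    max_p: int | None = None,
    ranking_key: str = "R2",
) -> ModelLeaderboard:
    """Fit every descriptor subset of size 1..max_p and rank the results."""
    max_p = len(descriptors) if max_p is None else min(max_p, len(descriptors))
    models = []
    for p in range(1, max_p + 1):
        for subset in enumerate_subsets(descriptors, p):
            models.append(fit_mlr(table, subset))
    return ModelLeaderboard(models, ranking_key)


def load_reference_models() -> dict[str, RegressionModel]:
    """The four published prediction equations, keyed mono/bi/tri/tetra.

    Coefficients are the printed 4-decimal values; n_train is the
    20-compound reference set they were fitted on. Evaluate these to
    reproduce published predictions digit for digit; refit with
    :func:`fit_mlr` for full-precision statistics.
    """
    frame = pd.read_csv(_data_path("prediction_equations.csv"), comment="#")
    models = {}
    for _, row in frame.iterrows():
        coefficients = {
            name: float(row[name])
            for name in ("ATM", "ACC", "DONN", "ARO")
            if pd.notna(row.get(name))
        }
        models[row["model"]] = RegressionModel(
            descriptor_subset=list(coefficients),
            intercept=float(row["intercept"]),
            coefficients=coefficients,
            n_train=20,
            label=str(row["model"]),
        )
    return models
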