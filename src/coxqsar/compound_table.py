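"""Compound/descriptor/activity tables and the packaged reference datasets.

A :class:`CompoundTable` is the container every other stage consumes: an
ordered list of molecules, each carrying integer pharmacophore descriptor
counts (ATM, ARO, DONN, ACC, optionally SF, F, HYD), an IC50 in nanomolar
and/or a pIC50, and a role tag that assigns it to the pivot, training,
internal-validation, external-validation, candidate or control set.

Activity is stored in the units the field reports it in: IC50 in nM, with
conversion to the molar scale confined to :func:`pic50_from_ic50`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import DomainError, FormatError, ParseError

__all__ = [
    "ROLES",
    "CompoundRecord",
    "CompoundTable",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "read_compound_table",
    "write_compound_table",
    "load_training_table",
    "load_internal_validation",
    "load_external_validation",
    "load_activity_series",
    "load_candidate_table",
]

ROLES = frozenset(
    {
        "pivot",
        "training",
        "internal_validation",
        "external_validation",
        "candidate",
        "control",
    }
)

#: Roles that participate in model fitting (the pivot is part of the
#: 20-compound regression set).
TRAINING_ROLES = frozenset({"pivot", "training"})

_META_COLUMNS = ("id", "name", "role", "ic50_nM", "pic50", "note")


def pic50_from_ic50(ic50_nM: float) -> float:
    """Convert an IC50 in nanomolar to pIC50 = -log10(IC50 in molar).

    Parameters
    ----------
    ic50_nM : float
        Half-maximal inhibitory concentration in nM; must be positive.

    Returns
    -------
    float
        pIC50 at full precision (round only for presentation).
    """
    if not ic50_nM > 0:
        raise DomainError(f"IC50 must be positive, got {ic50_nM!r}")
    return -math.log10(ic50_nM * 1e-9)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50`: pIC50 back to IC50 in nM."""
    return 10.0 ** (9.0 - pic50)


@dataclass
class CompoundRecord:
    """One molecule: descriptors, activity, and its role in the study."""

    id: str
    descriptors: dict[str, int]
    name: str | None = None
    ic50_nM: float | None = None
    pic50: float | None = None
    role: str = "training"
    note: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(
                f"record {self.id!r}: unknown role {self.role!r}; "
                f"expected one of {sorted(ROLES)}"
            )
        if self.ic50_nM is not None and not self.ic50_nM > 0:
            raise DomainError(
                f"record {self.id!r}: IC50 must be positive, got {self.ic50_nM}"
            )
        for key, value in self.descriptors.items():
            if value != int(value) or value < 0:
                raise DomainError(
                    f"record {self.id!r}: descriptor {key} must be a "
                    f"non-negative integer count, got {value!r}"
                )
            self.descriptors[key] = int(value)

    def activity_consistent(self, tol: float = 1.5e-4) -> bool:
        """Whether stored pIC50 agrees with the stored IC50 within ``tol``.

        True when either activity field is absent. Printed reference rows
        flagged in their ``note`` are known to fail this at 4 decimals.
        """
        if self.ic50_nM is None or self.pic50 is None:
            return True
        return abs(self.pic50 - pic50_from_ic50(self.ic50_nM)) <= tol


@dataclass
class CompoundTable:
    """Ordered collection of compounds sharing one descriptor vocabulary."""

    records: list[CompoundRecord]
    descriptor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate compound ids: {dupes}")
        for record in self.records:
            missing = [d for d in self.descriptor_names if d not in record.descriptors]
            if missing:
                raise FormatError(
                    f"record {record.id!r} is missing descriptor(s) {missing}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        for record in self.records:
            if record.id == compound_id:
                return record
        raise KeyError(compound_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset_by_role(self, *roles: str) -> "CompoundTable":
        """New table restricted to records whose role is in ``roles``."""
        unknown = set(roles) - ROLES
        if unknown:
            raise FormatError(f"unknown role(s) {sorted(unknown)}")
        kept = [r for r in self.records if r.role in roles]
        return CompoundTable(kept, list(self.descriptor_names))

    def descriptor_matrix(self, names: Sequence[str] | None = None):
        """Descriptor counts as an (n_compounds, n_descriptors) float array."""
        import numpy as np

        names = list(names) if names is not None else list(self.descriptor_names)
        rows = []
        for record in self.records:
            try:
                rows.append([record.descriptors[n] for n in names])
            except KeyError as exc:
                raise FormatError(
                    f"record {record.id!r} lacks descriptor {exc.args[0]!r}"
                ) from exc
        return np.asarray(rows, dtype=float).reshape(len(self.records), len(names))

    def pic50_vector(self):
        """Observed pIC50 values; raises if any record lacks one."""
        import numpy as np

        missing = [r.id for r in self.records if r.pic50 is None]
        if missing:
            raise FormatError(f"records without pIC50: {missing}")
        return np.asarray([r.pic50 for r in self.records], dtype=float)

    def check_activity_consistency(self, tol: float = 1.5e-4) -> list[str]:
        """Ids of unflagged records whose pIC50/IC50 pair disagrees beyond ``tol``."""
        return [
            r.id
            for r in self.records
            if not r.note and not r.activity_consistent(tol)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame view (meta columns first, then descriptors)."""
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "name": r.name,
                "role": r.role,
                **{d: r.descriptors.get(d) for d in self.descriptor_names},
                "ic50_nM": r.ic50_nM,
                "pic50": r.pic50,
                "note": r.note,
            }
            rows.append(row)
        columns = ["id", "name", "role", *self.descriptor_names, "ic50_nM", "pic50", "note"]
        return pd.DataFrame(rows, columns=columns)


def _frame_to_table(
    frame: pd.DataFrame, source: str, require_activity: bool = True
) -> CompoundTable:
    if "id" not in frame.columns:
        raise FormatError(f"{source}: required column 'id' is missing")
    if require_activity and "ic50_nM" not in frame.columns and "pic50" not in frame.columns:
        raise FormatError(
            f"{source}: at least one of columns 'ic50_nM'/'pic50' is required"
        )
    descriptor_names = [c for c in frame.columns if c not in _META_COLUMNS]

    records = []
    for row_index, row in frame.iterrows():
        descriptors = {}
        for column in descriptor_names:
            raw = row[column]
            try:
                value = float(raw)
                if math.isnan(value):
                    raise ValueError
                descriptors[column] = int(value)
                if descriptors[column] != value:
                    raise ValueError
            except (TypeError, ValueError):
                raise ParseError(
                    f"{source}: row {row_index + 1}, column {column!r}: "
                    f"expected an integer count, got {raw!r}"
                ) from None

        def _optional_float(column: str) -> float | None:
            if column not in frame.columns:
                return None
            raw = row[column]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                return None
            try:
                return float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{source}: row {row_index + 1}, column {column!r}: "
                    f"expected a number, got {raw!r}"
                ) from None

        name = row.get("name") if "name" in frame.columns else None
        if isinstance(name, float) and math.isnan(name):
            name = None
        note = row.get("note", "") if "note" in frame.columns else ""
        if not isinstance(note, str):
            note = "" if (note is None or (isinstance(note, float) and math.isnan(note))) else str(note)
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                name=name,
                role=str(row.get("role", "training")) if "role" in frame.columns else "training",
                descriptors=descriptors,
                ic50_nM=_optional_float("ic50_nM"),
                pic50=_optional_float("pic50"),
                note=note,
            )
        )
    return CompoundTable(records, descriptor_names)


def read_compound_table(
    path: str | Path, delimiter: str = ",", require_activity: bool = True
) -> CompoundTable:
    """Read a compound table from a delimited text file.

    The header must name ``id`` plus ``ic50_nM`` and/or ``pic50`` (unless
    ``require_activity`` is False, as for candidate tables whose activity
    is yet to be predicted); every other non-meta column is treated as an
    integer descriptor. Lines starting with ``#`` are comments. Row order
    is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=delimiter, comment="#", dtype={"id": str})
    return _frame_to_table(frame, str(path), require_activity)


def write_compound_table(table: CompoundTable, path: str | Path, delimiter: str = ",") -> None:
    """Write ``table`` as delimited text, formatting reals to 6 decimals."""
    frame = table.to_frame()
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.6f")


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("coxqsar.data").joinpath(filename)))


def _load_fixture(filename: str) -> CompoundTable:
    return read_compound_table(_data_path(filename))


def load_training_table() -> CompoundTable:
    """The 20-compound reference training set (pivot + 19 inhibitors)."""
    return _load_fixture("training_set.csv")


def load_internal_validation() -> CompoundTable:
    """The 5-compound internal validation set (molecules 21-25)."""
    return _load_fixture("internal_validation.csv")


def load_external_validation() -> CompoundTable:
    """The external validation set (molecules 26-31 plus celecoxib)."""
    return _load_fixture("external_validation.csv")


def load_candidate_table() -> CompoundTable:
    """Z-series screening candidates and the two control drugs."""
    frame = pd.read_csv(_data_path("candidates.csv"), comment="#", dtype={"id": str})
    frame = frame[["id", "role", "ATM", "ARO", "DONN", "ACC"]]
    return _frame_to_table(frame, "candidates.csv", require_activity=False)


def load_activity_series() -> pd.DataFrame:
    """The full published IC50/pIC50 series (32 rows) as a DataFrame."""
    frame = pd.read_csv(_data_path("activity_series.csv"), comment="#", dtype={"id": str})
    return frame.fillna({"note": ""})


def load_predictions_reference() -> pd.DataFrame:
    """Published per-model predictions and residuals for every molecule."""
    frame = pd.read_csv(
        _data_path("predictions_reference.csv"), comment="#", dtype={"id": str}
    )
    return frame


def load_candidate_reference() -> pd.DataFrame:
    """Candidate table including the published per-model predictions."""
    return pd.read_csv(_data_path("candidates.csv"), comment="#", dtype={"id": str})
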