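"""Candidate triage: Tanimoto similarity, coordinate RMSD, Lipinski rules.

Three independent screens applied to virtual-screening hits before any
expensive modelling:

* Tanimoto similarity on binary fingerprints against a reference ligand
  (J = M11 / (M01 + M10 + M11)), with a configurable strict cutoff;
* root-mean-square deviation between index-paired 3-D coordinate sets,
  the standard redocking-validation measure (no superposition is
  performed — inputs must arrive pre-paired and pre-aligned);
* Lipinski rule-of-five violation counting on physicochemical profiles
  (MW <= 500 g/mol, logP <= 5, H-bond donors <= 5, H-bond acceptors <= 10).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compound_table import _data_path
from .errors import DimensionError, DomainError, FormatError

__all__ = [
    "Fingerprint",
    "CoordinateSet",
    "PropertyProfile",
    "tanimoto",
    "filter_by_tanimoto",
    "rmsd",
    "lipinski_violations",
    "read_fingerprints",
    "write_fingerprints",
    "read_xyz",
    "write_xyz",
    "load_property_profiles",
]


@dataclass
class Fingerprint:
    """A named fixed-length binary feature vector."""

    id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or self.bits.size == 0:
            raise DimensionError(f"fingerprint {self.id!r}: bits must be a non-empty vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise DomainError(f"fingerprint {self.id!r}: bits must be 0 or 1")

    @classmethod
    def from_bitstring(cls, id: str, bitstring: str) -> "Fingerprint":
        if not set(bitstring) <= {"0", "1"}:
            raise DomainError(f"fingerprint {id!r}: bitstring must contain only 0/1")
        return cls(id, np.frombuffer(bitstring.encode(), dtype=np.uint8) - ord("0"))

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity J = M11 / (M01 + M10 + M11).

    M11 counts positions where both fingerprints are 1, M10/M01 where
    exactly one is. A pair of all-zero fingerprints has an undefined
    ratio; by convention 0.0 is returned with a warning so that batch
    filtering stays total.
    """
    if a.bits.size != b.bits.size:
        raise DimensionError(
            f"fingerprint lengths differ: {a.id!r} has {a.bits.size}, "
            f"{b.id!r} has {b.bits.size}"
        )
    m11 = int(np.sum((a.bits == 1) & (b.bits == 1)))
    union = int(np.sum((a.bits == 1) | (b.bits == 1)))
    if union == 0:
        warnings.warn(
            f"tanimoto({a.id!r}, {b.id!r}): both fingerprints are all-zero; "
            "returning 0.0 by convention",
            stacklevel=2,
        )
        return 0.0
    return m11 / union


def filter_by_tanimoto(
    candidates: list[Fingerprint], reference: Fingerprint, cutoff: float = 0.35
) -> list[Fingerprint]:
    """Candidates strictly more similar than ``cutoff`` to the reference.

    The inequality is strict ("greater than"), so cutoff=1.0 retains
    nothing and cutoff=0.0 retains anything with at least one shared
    on-bit. Order is preserved.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise DomainError(f"cutoff must be in [0, 1], got {cutoff}")
    return [c for c in candidates if tanimoto(c, reference) > cutoff]


@dataclass
class CoordinateSet:
    """Named ordered list of atomic (x, y, z) coordinates in Angstroms."""

    id: str
    atoms: np.ndarray
    elements: list[str] | None = None

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)
        if self.atoms.shape[0] == 0:
            raise DimensionError(f"coordinate set {self.id!r} has no atoms")
        if not np.isfinite(self.atoms).all():
            raise DomainError(f"coordinate set {self.id!r} has non-finite coordinates")

    def __len__(self) -> int:
        return self.atoms.shape[0]


def rmsd(a: CoordinateSet, b: CoordinateSet) -> float:
    """RMSD between two index-paired coordinate sets, in Angstroms.

    sqrt((1/N) sum_i |a_i - b_i|^2). Atoms are paired by index; no
    superposition or atom matching is attempted, so the value measures
    the displacement between two poses of the same ordered atom list.
    """
    if len(a) != len(b):
        raise DimensionError(
            f"atom counts differ: {a.id!r} has {len(a)}, {b.id!r} has {len(b)}"
        )
    delta = a.atoms - b.atoms
    return float(math.sqrt(np.mean(np.sum(delta * delta, axis=1))))


@dataclass
class PropertyProfile:
    """Physicochemical profile used by the rule-of-five screen."""

    id: str
    mw: float
    logp: float
    n_hd: int
    n_ha: int
    tpsa: float | None = None
    n_rotb: int | None = None
    volume: float | None = None

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise DomainError(f"{self.id!r}: molecular weight must be positive")
        if self.n_hd < 0 or self.n_ha < 0:
            raise DomainError(f"{self.id!r}: donor/acceptor counts must be >= 0")


#: The four rule-of-five bounds, as (attribute, upper limit) pairs.
LIPINSKI_RULES = (("mw", 500.0), ("logp", 5.0), ("n_hd", 5), ("n_ha", 10))


def lipinski_violations(profile: PropertyProfile) -> int:
    """Number of rule-of-five bounds exceeded (0..4)."""
    return sum(
        1 for attribute, limit in LIPINSKI_RULES if getattr(profile, attribute) > limit
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read ``id<TAB>bitstring`` lines; '#' lines are comments."""
    fingerprints = []
    for line_number, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{path}: line {line_number}: expected 'id<TAB>bitstring'"
            )
        fingerprints.append(Fingerprint.from_bitstring(parts[0], parts[1]))
    return fingerprints


def write_fingerprints(fingerprints: list[Fingerprint], path: str | Path) -> None:
    lines = [f"{fp.id}\t{fp.to_bitstring()}" for fp in fingerprints]
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> CoordinateSet:
    """Read an XYZ-style file: count line, comment/id line, then atoms."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated XYZ file")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"{path}: first line must be the atom count") from None
    set_id = lines[1].strip() or Path(path).stem
    elements, coords = [], []
    for line in lines[2 : 2 + n_atoms]:
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom line {line!r}")
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    if len(coords) != n_atoms:
        raise FormatError(f"{path}: expected {n_atoms} atoms, found {len(coords)}")
    return CoordinateSet(set_id, np.array(coords), elements)


def write_xyz(coordinates: CoordinateSet, path: str | Path) -> None:
    elements = coordinates.elements or ["X"] * len(coordinates)
    lines = [str(len(coordinates)), coordinates.id]
    for element, (x, y, z) in zip(elements, coordinates.atoms):
        lines.append(f"{element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_property_profiles() -> list[PropertyProfile]:
    """Bundled physicochemical profiles of the candidates and controls."""
    frame = pd.read_csv(_data_path("property_profiles.csv"), comment="#")
    return [
        PropertyProfile(
            id=row["id"],
            mw=float(row["mw"]),
            logp=float(row["milogp"]),
            n_hd=int(row["n_hd"]),
            n_ha=int(row["n_ha"]),
            tpsa=float(row["tpsa"]),
            n_rotb=int(row["n_rotb"]),
            volume=float(row["volume"]),
        )
        for _, row in frame.iterrows()
    ]


def load_property_reference() -> pd.DataFrame:
    """Bundled property table including the published violation counts."""
    return pd.read_csv(_data_path("property_profiles.csv"), comment="#")
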