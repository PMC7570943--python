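"""Binding-energy bookkeeping: Ki-to-deltaG, MM-GBSA sums, selectivity.

None of this module runs a simulation. Energy terms arrive as numbers
(from docking or MM-GBSA post-processing) and the module performs the
arithmetic that relates them:

* deltaG from an inhibition constant, deltaG = -RT ln(Ki), with
  R = 1.987e-3 kcal/(mol K). Note the sign: with Ki < 1 M this published
  form yields a *positive* energy; the standard thermodynamic convention
  deltaG = +RT ln(Ki) yields the negative of it. Both are implemented
  behind a mode flag, defaulting to the published form.
* MM-GBSA aggregation: deltaG_bind = deltaE_internal + deltaE_ele +
  deltaE_vdW + deltaG_GB + deltaG_NP + (-T deltaS), where each delta term
  is complex - receptor - ligand.
* Per-residue decomposition totals and the COX-2/COX-1 selectivity ratio
  pair used to argue isoform selectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .compound_table import _data_path
from .errors import DataError, DomainError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EnergyTermSet",
    "ResidueContribution",
    "AffinityRecord",
    "delta_g_from_ki",
    "mmgbsa_bind",
    "decompose_per_residue",
    "selectivity_ratio",
    "load_docking_affinities",
    "load_mmgbsa_reference",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3

#: Reference inhibition constants (molar) and assay temperature used in the
#: published deltaG comparison for the two control drugs.
KI_REFERENCE = {"Rofecoxib": 310e-9, "Celecoxib": 340e-9}
KI_REFERENCE_TEMPERATURE = 310.0


def delta_g_from_ki(ki: float, temperature: float, mode: str = "as-printed") -> float:
    """Binding free energy from an inhibition constant, in kcal/mol.

    Parameters
    ----------
    ki : float
        Inhibition constant in molar; must be positive.
    temperature : float
        Absolute temperature in kelvin; must be positive.
    mode : {"as-printed", "thermodynamic"}
        "as-printed" evaluates -RT ln(Ki) (the published form, positive
        for sub-molar Ki); "thermodynamic" evaluates +RT ln(Ki) (the
        standard convention, negative for favourable binding). The two
        are exact negations.
    """
    if not ki > 0:
        raise DomainError(f"Ki must be positive, got {ki}")
    if not temperature > 0:
        raise DomainError(f"temperature must be positive, got {temperature}")
    if mode not in ("as-printed", "thermodynamic"):
        raise DomainError(f"unknown mode {mode!r}")
    value = -GAS_CONSTANT_KCAL * temperature * math.log(ki)
    return value if mode == "as-printed" else -value


@dataclass
class EnergyTermSet:
    """Named MM-GBSA energy components for one system, in kcal/mol.

    ``minus_t_ds`` is the -T*deltaS entropy term; it is frequently not
    computed, in which case it defaults to 0 and ``has_entropy`` is False
    so reports can flag its absence.
    """

    label: str
    e_internal: float = 0.0
    e_ele: float = 0.0
    e_vdw: float = 0.0
    g_gb: float = 0.0
    g_np: float = 0.0
    minus_t_ds: float | None = None

    @property
    def has_entropy(self) -> bool:
        return self.minus_t_ds is not None

    @property
    def terms(self) -> dict[str, float]:
        return {
            "e_internal": self.e_internal,
            "e_ele": self.e_ele,
            "e_vdw": self.e_vdw,
            "g_gb": self.g_gb,
            "g_np": self.g_np,
            "minus_t_ds": self.minus_t_ds or 0.0,
        }

    def total(self) -> float:
        return sum(self.terms.values())


def mmgbsa_bind(
    complex: EnergyTermSet, receptor: EnergyTermSet, ligand: EnergyTermSet
) -> tuple[float, EnergyTermSet]:
    """MM-GBSA binding free energy and the per-term differences.

    Forms delta = complex - receptor - ligand for every component, then
    sums: deltaG_bind = deltaE_internal + deltaE_ele + deltaE_vdW +
    deltaG_GB + deltaG_NP + (-T deltaS). Returns (deltaG_bind, delta
    term set). The entropy term is carried only if present on all three
    inputs; otherwise it is treated as 0 and left unflagged on the delta.
    """
    with_entropy = all(s.has_entropy for s in (complex, receptor, ligand))
    delta = EnergyTermSet(
        label=f"delta({complex.label})",
        e_internal=complex.e_internal - receptor.e_internal - ligand.e_internal,
        e_ele=complex.e_ele - receptor.e_ele - ligand.e_ele,
        e_vdw=complex.e_vdw - receptor.e_vdw - ligand.e_vdw,
        g_gb=complex.g_gb - receptor.g_gb - ligand.g_gb,
        g_np=complex.g_np - receptor.g_np - ligand.g_np,
        minus_t_ds=(
            complex.minus_t_ds - receptor.minus_t_ds - ligand.minus_t_ds
            if with_entropy
            else None
        ),
    )
    return delta.total(), delta


@dataclass
class ResidueContribution:
    """Per-residue MM-GBSA decomposition terms, in kcal/mol."""

    residue: str
    e_vdw: float
    e_elec: float
    e_pol: float
    e_np: float

    def total(self) -> float:
        return self.e_vdw + self.e_elec + self.e_pol + self.e_np


def decompose_per_residue(contribs: list[ResidueContribution]) -> pd.DataFrame:
    """Per-residue totals, most favourable (most negative) first.

    The grand total equals the sum of residue totals by construction.
    """
    residues = [c.residue for c in contribs]
    if len(residues) != len(set(residues)):
        dupes = sorted({r for r in residues if residues.count(r) > 1})
        raise DataError(f"duplicate residue(s) in decomposition: {dupes}")
    frame = pd.DataFrame(
        [
            {
                "residue": c.residue,
                "e_vdw": c.e_vdw,
                "e_elec": c.e_elec,
                "e_pol": c.e_pol,
                "e_np": c.e_np,
                "total": c.total(),
            }
            for c in contribs
        ]
    )
    return frame.sort_values("total", kind="stable").reset_index(drop=True)


@dataclass
class AffinityRecord:
    """A ligand's binding free energy against one COX isoform."""

    ligand: str
    target: str
    delta_g: float


def selectivity_ratio(cox2: AffinityRecord, cox1: AffinityRecord) -> tuple[float, float]:
    """The (COX-2/COX-1, COX-1/COX-2) energy-ratio pair for one ligand."""
    if cox2.ligand != cox1.ligand:
        raise DataError(
            f"selectivity ratio needs one ligand, got {cox2.ligand!r} and {cox1.ligand!r}"
        )
    if cox2.delta_g == 0 or cox1.delta_g == 0:
        raise DomainError("zero binding energy; ratio undefined")
    return cox2.delta_g / cox1.delta_g, cox1.delta_g / cox2.delta_g


def load_docking_affinities() -> list[AffinityRecord]:
    """Bundled docking binding energies of candidates against COX-1/COX-2."""
    frame = pd.read_csv(_data_path("docking_affinities.csv"), comment="#")
    return [
        AffinityRecord(row["ligand"], row["target"], float(row["delta_g"]))
        for _, row in frame.iterrows()
    ]


def load_mmgbsa_reference() -> pd.DataFrame:
    """Bundled trajectory-derived MM-GBSA binding energies (reporting only)."""
    return pd.read_csv(_data_path("mmgbsa_reference.csv"), comment="#")
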