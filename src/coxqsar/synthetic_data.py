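"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without external data:

* descriptor/activity tables drawn from a known linear model with
  additive Gaussian noise, so regression fitting has a ground truth to
  recover;
* i.i.d. Bernoulli fingerprints for the Tanimoto screen;
* coordinate pairs where the second pose is the first plus isotropic
  Gaussian displacement, so the expected RMSD is displacement_sd*sqrt(3)
  in the large-N limit;
* random MM-GBSA term sets for the energy bookkeeping.

Defaults mirror the reference training conditions: 20 compounds,
descriptor counts uniform on the empirical ranges of the reference set
(ATM 29-50, ARO 1-4, DONN 0-3, ACC 2-5), the published four-descriptor
coefficients, and noise_sd 0.22 pIC50 units (the residual scale of the
reference fit). All generators are pure functions of spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compound_table import CompoundRecord, CompoundTable, ic50_from_pic50
from .errors import ConfigurationError
from .screening_filters import CoordinateSet, Fingerprint
from .energetics import EnergyTermSet

__all__ = [
    "DEFAULT_DESCRIPTOR_RANGES",
    "DEFAULT_COEFFICIENTS",
    "LinearGeneratorSpec",
    "generate_training_table",
    "generate_fingerprints",
    "generate_coordinate_pair",
    "generate_energy_term_set",
]

DEFAULT_DESCRIPTOR_RANGES: dict[str, tuple[int, int]] = {
    "ATM": (29, 50),
    "ARO": (1, 4),
    "DONN": (0, 3),
    "ACC": (2, 5),
}

#: The published four-descriptor equation, used as the default ground truth.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "ATM": 0.0907,
    "ACC": -0.3721,
    "DONN": 0.3766,
    "ARO": -0.0674,
}
DEFAULT_INTERCEPT = 6.1250


@dataclass
class LinearGeneratorSpec:
    """Recipe for a synthetic descriptor/activity table.

    pIC50 = intercept + sum(coefficient * descriptor) + N(0, noise_sd),
    descriptors uniform integers on closed ranges, IC50 back-computed
    as 10^(9 - pIC50) nM.
    """

    n_compounds: int = 20
    descriptor_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_RANGES)
    )
    intercept: float = DEFAULT_INTERCEPT
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    noise_sd: float = 0.22
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if set(self.coefficients) - set(self.descriptor_ranges):
            raise ConfigurationError(
                "coefficients reference descriptors without ranges: "
                f"{sorted(set(self.coefficients) - set(self.descriptor_ranges))}"
            )
        for name, (lo, hi) in self.descriptor_ranges.items():
            if lo > hi:
                raise ConfigurationError(f"empty range for {name}: [{lo}, {hi}]")
        if self.n_compounds < len(self.coefficients) + 2:
            raise ConfigurationError(
                f"n_compounds={self.n_compounds} too small for "
                f"{len(self.coefficients)} coefficients"
            )


def generate_training_table(spec: LinearGeneratorSpec) -> CompoundTable:
    """Draw a reproducible synthetic descriptor/activity table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = list(spec.descriptor_ranges)
    counts = {
        name: rng.integers(lo, hi + 1, size=spec.n_compounds)
        for name, (lo, hi) in spec.descriptor_ranges.items()
    }
    noise = (
        rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)
        if spec.noise_sd > 0
        else np.zeros(spec.n_compounds)
    )
    records = []
    for i in range(spec.n_compounds):
        descriptors = {name: int(counts[name][i]) for name in names}
        pic50 = spec.intercept + sum(
            coef * descriptors[name] for name, coef in spec.coefficients.items()
        ) + noise[i]
        records.append(
            CompoundRecord(
                id=f"SYN-{i + 1:03d}",
                descriptors=descriptors,
                ic50_nM=ic50_from_pic50(pic50),
                pic50=float(pic50),
                role="training",
            )
        )
    return CompoundTable(records, names)


def generate_fingerprints(
    n: int, length: int, density: float, seed: int
) -> list[Fingerprint]:
    """n random fingerprints with i.i.d. Bernoulli(density) bits."""
    if n < 1 or length < 1:
        raise ConfigurationError(f"n and length must be >= 1, got n={n}, length={length}")
    if not 0.0 < density < 1.0:
        raise ConfigurationError(f"density must be in (0, 1), got {density}")
    rng = np.random.default_rng(seed)
    bits = (rng.random((n, length)) < density).astype(np.uint8)
    return [Fingerprint(f"FP-{i + 1:04d}", bits[i]) for i in range(n)]


def generate_coordinate_pair(
    n_atoms: int, displacement_sd: float, seed: int
) -> tuple[CoordinateSet, CoordinateSet]:
    """A random pose and a Gaussian-perturbed copy of it.

    Each coordinate of the second set is the first plus N(0,
    displacement_sd); the expected RMSD approaches
    displacement_sd*sqrt(3) as n_atoms grows.
    """
    if n_atoms < 1:
        raise ConfigurationError(f"n_atoms must be >= 1, got {n_atoms}")
    rng = np.random.default_rng(seed)
    reference = rng.uniform(-10.0, 10.0, size=(n_atoms, 3))
    displaced = reference + rng.normal(0.0, displacement_sd, size=(n_atoms, 3))
    return (
        CoordinateSet("pose-reference", reference),
        CoordinateSet("pose-displaced", displaced),
    )


def generate_energy_term_set(label: str, seed: int, scale: float = 20.0) -> EnergyTermSet:
    """A random MM-GBSA term set (uniform on [-scale, scale] kcal/mol)."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(-scale, scale, size=5)
    return EnergyTermSet(
        label=label,
        e_internal=float(values[0]),
        e_ele=float(values[1]),
        e_vdw=float(values[2]),
        g_gb=float(values[3]),
        g_np=float(values[4]),
    )
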