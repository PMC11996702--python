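"""Domain records shared across the pipeline stages.

These are deliberately thin dataclasses: validation that requires context
(donor ratios, specimen joins, design balance) lives in the stage that has
that context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class FunctionalGroup(str, Enum):
    """Functional role of a forelimb muscle in the wingbeat cycle."""

    UPSTROKE = "upstroke"
    DOWNSTROKE = "downstroke"
    ELBOW = "elbow"


class Preservation(str, Enum):
    FRESH = "fresh"
    FIXED_STAINED = "fixed_stained"


class FibreLengthSource(str, Enum):
    """Provenance of a muscle's mean fibre length."""

    MEASURED = "measured"
    RATIO_TRANSFER = "ratio_transfer"


class Specialization(str, Enum):
    """Qualitative architectural specialization of a muscle."""

    FORCE = "force"
    POWER = "power"
    DISPLACEMENT = "displacement"
    GENERALIST = "generalist"
    UNCLASSIFIED = "unclassified"


@dataclass
class MuscleRecord:
    """One muscle's raw measurements on one specimen.

    ``mean_fibre_length`` carries a pre-averaged fibre length (as printed in
    published architecture tables); ``fibre_lengths`` carries the individual
    acid-digested fibre samples. Either, both, or neither may be present —
    a muscle with neither gets its fibre length by ratio transfer from a
    donor specimen, or is excluded.
    """

    specimen_id: str
    muscle_code: str
    functional_group: Optional[FunctionalGroup] = None
    mass: Optional[float] = None  # g
    muscle_length: Optional[float] = None  # mm
    fibre_lengths: Sequence[float] = field(default_factory=tuple)  # mm
    mean_fibre_length: Optional[float] = None  # mm, pre-averaged input
    volume: Optional[float] = None  # mm^3
    preservation: Preservation = Preservation.FRESH

    def __post_init__(self) -> None:
        if self.mass is None and self.volume is None:
            raise ValueError(
                f"{self.specimen_id}/{self.muscle_code}: at least one of "
                "mass or volume must be present"
            )
        for name in ("mass", "muscle_length", "volume", "mean_fibre_length"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(
                    f"{self.specimen_id}/{self.muscle_code}: {name} must be "
                    f"positive, got {v}"
                )
        if any(f <= 0 for f in self.fibre_lengths):
            raise ValueError(
                f"{self.specimen_id}/{self.muscle_code}: fibre lengths must "
                "be positive"
            )
        # Fibres longer than the muscle belly are anatomically suspect but
        # can arise from digestion artefacts: warn, never clip or drop.
        if self.muscle_length is not None:
            for f in self.fibre_lengths:
                if f > self.muscle_length:
                    warnings.warn(
                        f"{self.specimen_id}/{self.muscle_code}: fibre length "
                        f"{f} mm exceeds muscle length {self.muscle_length} mm",
                        stacklevel=2,
                    )


@dataclass(frozen=True)
class ArchitectureResult:
    """Derived architecture of one muscle: mean Lf, PCSA, muscle:fibre ratio."""

    muscle_code: str
    mean_fibre_length: float  # mm
    fibre_length_source: FibreLengthSource
    pcsa: float  # mm^2
    muscle_fibre_ratio: Optional[float]  # Lf / muscle length, dimensionless
    mass_used: float  # g
    n_fibres: int = 0


@dataclass(frozen=True)
class GroupComposition:
    """Per-functional-group percentages of total muscle mass."""

    fractions: dict  # FunctionalGroup -> percent
    total_mass: float  # g
    excluded: tuple  # muscle codes with no usable mass


@dataclass(frozen=True)
class SpecimenInfo:
    """Specimen-level metadata needed for body-mass normalization."""

    specimen_id: str
    species: str
    body_mass: float  # g
    source: str = ""

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError(
                f"specimen {self.specimen_id}: body mass must be positive"
            )
        if not self.species:
            raise ValueError(f"specimen {self.specimen_id}: species is empty")


@dataclass
class MorphospacePoint:
    """One muscle's mass-normalized coordinate in (Lf, PCSA) morphospace."""

    species: str
    muscle_code: str
    norm_lf: float  # mm / g^lf_exponent
    norm_pcsa: float  # mm^2 / g^pcsa_exponent
    specialization: Specialization = Specialization.UNCLASSIFIED


class FibreCompartment(str, Enum):
    """Cranial-to-caudal compartments of the pectoralis pars posterior."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"


class FibreDepth(str, Enum):
    SUPERFICIAL = "superficial"
    DEEP = "deep"


@dataclass(frozen=True)
class FibreSample:
    """A single regional fibre-length measurement."""

    compartment: str
    depth: str
    length: float  # mm

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"fibre length must be positive, got {self.length}")
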