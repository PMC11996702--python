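"""Body-mass normalization and morphospace assembly.

Muscle fibre length and PCSA are normalized to body mass B under geometric
isometry — lengths scale as B^0.33 and areas as B^0.66 — so that muscles of
animals spanning orders of magnitude in size occupy a common
(Lf/B^0.33, PCSA/B^0.66) plane. A muscle's position in that plane is read
functionally: short-fibred/high-PCSA muscles are force specialists,
long-fibred/high-PCSA ones power specialists, long-fibred/low-PCSA ones
displacement specialists.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Sequence

from .constants import DEFAULT_CONSTANTS, Constants
from .records import (
    ArchitectureResult,
    MorphospacePoint,
    Specialization,
    SpecimenInfo,
)

__all__ = [
    "normalize_lf",
    "normalize_pcsa",
    "implied_body_mass",
    "assemble_morphospace",
    "classify_specialization",
]

logger = logging.getLogger(__name__)


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {v}")


def normalize_lf(
    fibre_length: float,
    body_mass: float,
    *,
    exponent: float = DEFAULT_CONSTANTS.lf_exponent,
) -> float:
    """Fibre length (mm) divided by body mass (g) to the length exponent."""
    _check_positive(fibre_length=fibre_length, body_mass=body_mass)
    return fibre_length / body_mass**exponent


def normalize_pcsa(
    pcsa: float,
    body_mass: float,
    *,
    exponent: float = DEFAULT_CONSTANTS.pcsa_exponent,
) -> float:
    """PCSA (mm^2) divided by body mass (g) to the area exponent."""
    _check_positive(pcsa=pcsa, body_mass=body_mass)
    return pcsa / body_mass**exponent


def implied_body_mass(
    raw: float, normalized: float, exponent: float
) -> float:
    """Body mass implied by one (raw, normalized) pair: (raw/norm)^(1/exp).

    Inverts the normalization; useful for recovering the body mass behind a
    published normalized value when the raw measurement is also printed.
    """
    _check_positive(raw=raw, normalized=normalized, exponent=exponent)
    return (raw / normalized) ** (1.0 / exponent)


def assemble_morphospace(
    architecture: Iterable[ArchitectureResult],
    specimens: Sequence[SpecimenInfo],
    *,
    species: str | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> List[MorphospacePoint]:
    """One morphospace point per muscle, normalized by its species' body mass.

    With a single specimen the join is implicit; with several, ``species``
    selects which specimen's body mass to use (an error if ambiguous).
    Muscles lacking a fibre length or PCSA never reach this stage — the
    architecture step already excluded them.
    """
    architecture = list(architecture)
    if not architecture:
        return []
    if not specimens:
        raise ValueError("assemble_morphospace: no specimen metadata supplied")
    if species is None:
        distinct = {s.species for s in specimens}
        if len(distinct) != 1:
            raise ValueError(
                "multiple species present; pass species= to disambiguate: "
                f"{sorted(distinct)}"
            )
        species = next(iter(distinct))
    matching = [s for s in specimens if s.species == species]
    if not matching:
        raise ValueError(f"no specimen with species {species!r}")
    # A species may contribute several specimens; architecture tables are
    # per-animal composites, so the species body mass is their mean.
    body_mass = sum(s.body_mass for s in matching) / len(matching)
    points = []
    for arch in architecture:
        points.append(
            MorphospacePoint(
                species=species,
                muscle_code=arch.muscle_code,
                norm_lf=normalize_lf(
                    arch.mean_fibre_length,
                    body_mass,
                    exponent=constants.lf_exponent,
                ),
                norm_pcsa=normalize_pcsa(
                    arch.pcsa, body_mass, exponent=constants.pcsa_exponent
                ),
            )
        )
    return points


def classify_specialization(
    points: Iterable[MorphospacePoint],
) -> List[MorphospacePoint]:
    """Label each muscle by quadrant relative to its species' medians.

    Within each species, fibre length and PCSA are split at the species
    median: (low Lf, high PCSA) -> force, (high, high) -> power,
    (high, low) -> displacement, (low, low) -> generalist. Values exactly
    at the median count as low. Species with fewer than four muscles stay
    unclassified — a median split over three points says nothing.

    This is an interpretation layer over a qualitative reading of the
    morphospace; the labels never feed any numeric output.
    """
    points = [
        MorphospacePoint(
            species=p.species,
            muscle_code=p.muscle_code,
            norm_lf=p.norm_lf,
            norm_pcsa=p.norm_pcsa,
        )
        for p in points
    ]
    by_species: Dict[str, List[MorphospacePoint]] = {}
    for p in points:
        by_species.setdefault(p.species, []).append(p)
    for species, group in by_species.items():
        if len(group) < 4:
            logger.info(
                "species %s has %d muscles (<4); left unclassified",
                species,
                len(group),
            )
            continue
        med_lf = _median(sorted(p.norm_lf for p in group))
        med_pcsa = _median(sorted(p.norm_pcsa for p in group))
        for p in group:
            high_lf = p.norm_lf > med_lf
            high_pcsa = p.norm_pcsa > med_pcsa
            if high_pcsa:
                p.specialization = (
                    Specialization.POWER if high_lf else Specialization.FORCE
                )
            else:
                p.specialization = (
                    Specialization.DISPLACEMENT
                    if high_lf
                    else Specialization.GENERALIST
                )
    return points


def _median(sorted_values: Sequence[float]) -> float:
    n = len(sorted_values)
    mid = n // 2
    if n % 2:
        return sorted_values[mid]
    return 0.5 * (sorted_values[mid - 1] + sorted_values[mid])
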