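"""Per-muscle derived architecture: PCSA, fibre-ratio transfer, volume-to-mass
conversion, shrinkage, and functional-group mass composition.

The central quantity is the physiological cross-sectional area

    PCSA [mm^2] = M [g] / (Lf [mm] * rho [g/mm^3]),   rho = 0.001056,

a proxy for a muscle's maximum isometric force, with mean fibre length Lf a
proxy for contractile excursion. Where a muscle's fibres were not digested
and measured directly, Lf is estimated by transferring the muscle:fibre
length ratio measured on a donor specimen to the target muscle's belly
length (the two specimens are assumed architecturally homologous).
"""

from __future__ import annotations

import math
import warnings
from statistics import fmean
from typing import Dict, Iterable, List, Mapping, Optional

from .constants import DEFAULT_CONSTANTS, Constants
from .records import (
    ArchitectureResult,
    FibreLengthSource,
    FunctionalGroup,
    GroupComposition,
    MuscleRecord,
)

__all__ = [
    "compute_pcsa",
    "muscle_fibre_ratio",
    "transfer_fibre_length",
    "volume_to_mass",
    "shrinkage_percent",
    "group_fractions",
    "donor_ratio",
    "derive_architecture",
    "excluded_muscles",
]


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {v}")


def compute_pcsa(
    mass: float, fibre_length: float, *, rho: float = DEFAULT_CONSTANTS.rho_muscle
) -> float:
    """Physiological cross-sectional area in mm^2.

    Parameters
    ----------
    mass : float
        Muscle mass in grams.
    fibre_length : float
        Mean fibre length in mm.
    rho : float
        Muscle density in g/mm^3.
    """
    _require_positive(mass=mass, fibre_length=fibre_length, rho=rho)
    return mass / (fibre_length * rho)


def muscle_fibre_ratio(fibre_length: float, muscle_length: float) -> float:
    """Fibre length divided by muscle belly length.

    Near 1 for strap-like parallel-fibred muscles, low for pennate ones.
    """
    _require_positive(fibre_length=fibre_length, muscle_length=muscle_length)
    return fibre_length / muscle_length

def transfer_fibre_length(
    muscle_length_target: float, ratio_reference: float
) -> float:
    """Estimate a fibre length from a donor specimen's muscle:fibre ratio.

    ``muscle_length_target * ratio_reference``; results produced this way
    are tagged :attr:`FibreLengthSource.RATIO_TRANSFER` downstream.
    """
    _require_positive(
        muscle_length_target=muscle_length_target, ratio_reference=ratio_reference
    )
    return muscle_length_target * ratio_reference


def volume_to_mass(
    volume: float,
    *,
    density: float = DEFAULT_CONSTANTS.density_volume_to_mass,
) -> float:
    """Convert a segmentation volume (mm^3) to mass (g) at skeletal density."""
    _require_positive(volume=volume, density=density)
    return volume * density


def shrinkage_percent(reference_mass: float, stained_mass: float) -> float:
    """Percent mass lost between a reference (fresh) and a stained muscle.

    ``100 * (reference - stained) / reference``; negative values indicate
    swelling and are returned as-is.
    """
    _require_positive(reference_mass=reference_mass, stained_mass=stained_mass)
    return 100.0 * (reference_mass - stained_mass) / reference_mass


def group_fractions(
    records: Iterable[MuscleRecord],
    grouping: Optional[Mapping[str, FunctionalGroup]] = None,
    *,
    constants: Constants = DEFAULT_CONSTANTS,
) -> GroupComposition:
    """Percent of total muscle mass contributed by each functional group.

    ``grouping`` maps muscle codes to groups and overrides any group carried
    on the records themselves (the assignment is data, not code — published
    sources disagree on individual muscles). Muscles with neither a mass nor
    a volume-derived mass, or with no group, are excluded and listed.
    """
    records = list(records)
    if not records:
        raise ValueError("group_fractions: no muscle records supplied")
    totals: Dict[FunctionalGroup, float] = {}
    excluded: List[str] = []
    known_codes = {r.muscle_code for r in records}
    if grouping:
        for code in grouping:
            if code not in known_codes:
                warnings.warn(
                    f"grouping lists unknown muscle code {code!r}", stacklevel=2
                )
    for rec in records:
        mass = rec.mass
        if mass is None and rec.volume is not None:
            mass = volume_to_mass(
                rec.volume, density=constants.density_volume_to_mass
            )
        group = None
        if grouping and rec.muscle_code in grouping:
            group = FunctionalGroup(grouping[rec.muscle_code])
        elif rec.functional_group is not None:
            group = FunctionalGroup(rec.functional_group)
        if mass is None or group is None:
            excluded.append(rec.muscle_code)
            continue
        totals[group] = totals.get(group, 0.0) + mass
    total = sum(totals.values())
    if total <= 0:
        raise ValueError("group_fractions: no muscle carries a usable mass")
    fractions = {g: 100.0 * m / total for g, m in totals.items()}
    return GroupComposition(
        fractions=fractions, total_mass=total, excluded=tuple(excluded)
    )


def donor_ratio(muscle_code: str, donor_ratios: Mapping[str, float]) -> float:
    """Look up a donor specimen's muscle:fibre ratio for one muscle.

    Raises a ``KeyError`` naming the missing code and listing the donor's
    available codes, so a typo'd muscle abbreviation fails loudly.
    """
    if muscle_code not in donor_ratios:
        raise KeyError(
            f"no donor ratio for muscle {muscle_code!r}; available codes: "
            f"{sorted(donor_ratios)}"
        )
    return donor_ratios[muscle_code]


def derive_architecture(
    records: Iterable[MuscleRecord],
    donor_ratios: Optional[Mapping[str, float]] = None,
    *,
    strict_donor: bool = False,
    constants: Constants = DEFAULT_CONSTANTS,
) -> List[ArchitectureResult]:
    """Derive mean Lf, PCSA and muscle:fibre ratio for every muscle.

    Fibre-length resolution order, per muscle:

    1. arithmetic mean of the individual fibre samples, if any;
    2. a pre-averaged ``mean_fibre_length`` on the record (tagged
       ``ratio_transfer`` when a donor map is supplied without that code
       being measurable — otherwise ``measured``);
    3. ratio transfer from ``donor_ratios`` applied to the muscle length.

    Muscles resolving no fibre length (or no mass) are skipped; callers that
    need the exclusion list use :func:`excluded_muscles`. With
    ``strict_donor=True`` a muscle that would need a transfer but has no
    donor ratio raises instead of being skipped.
    """
    results: List[ArchitectureResult] = []
    for rec in records:
        mass = rec.mass
        if mass is None and rec.volume is not None:
            mass = volume_to_mass(
                rec.volume, density=constants.density_volume_to_mass
            )
        if mass is None:
            continue
        lf: Optional[float] = None
        source = FibreLengthSource.MEASURED
        n_fibres = 0
        if rec.fibre_lengths:
            lf = fmean(rec.fibre_lengths)
            n_fibres = len(rec.fibre_lengths)
        elif rec.mean_fibre_length is not None:
            lf = rec.mean_fibre_length
        elif donor_ratios is not None and rec.muscle_length is not None:
            if rec.muscle_code not in donor_ratios:
                if strict_donor:
                    donor_ratio(rec.muscle_code, donor_ratios)
                continue
            lf = transfer_fibre_length(
                rec.muscle_length, donor_ratios[rec.muscle_code]
            )
            source = FibreLengthSource.RATIO_TRANSFER
        if lf is None:
            continue
        ratio = (
            muscle_fibre_ratio(lf, rec.muscle_length)
            if rec.muscle_length is not None
            else None
        )
        results.append(
            ArchitectureResult(
                muscle_code=rec.muscle_code,
                mean_fibre_length=lf,
                fibre_length_source=source,
                pcsa=compute_pcsa(mass, lf, rho=constants.rho_muscle),
                muscle_fibre_ratio=ratio,
                mass_used=mass,
                n_fibres=n_fibres,
            )
        )
    return results


def excluded_muscles(
    records: Iterable[MuscleRecord], results: Iterable[ArchitectureResult]
) -> List[str]:
    """Muscle codes present in the input but absent from the derived results."""
    derived = {r.muscle_code for r in results}
    return [r.muscle_code for r in records if r.muscle_code not in derived]
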