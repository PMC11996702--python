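"""Physical and statistical constants used throughout the pipeline.

All values are module-level defaults collected in an immutable
:class:`Constants` record so that a run configuration can carry (and
serialize) the exact constants it used.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Muscle density in g/mm^3, used in the PCSA formula PCSA = M / (Lf * rho).
RHO_MUSCLE: float = 0.001056

#: Average skeletal-tissue density for converting segmentation volumes to
#: mass: 1.06 kg/L == 0.00106 g/mm^3.
DENSITY_VOLUME_TO_MASS: float = 0.00106

#: Geometric-isometry exponents: lengths scale with body mass^0.33 and
#: areas with body mass^0.66 (the conventional two-decimal approximations
#: of 1/3 and 2/3).
LF_EXPONENT: float = 0.33
PCSA_EXPONENT: float = 0.66

#: Tukey boxplot fences: outliers beyond 1.5x IQR, far outliers beyond 3x.
TUKEY_FENCE: float = 1.5
FAR_FENCE: float = 3.0

#: Significance threshold for the fibre-heterogeneity tests.
ALPHA: float = 0.025


@dataclass(frozen=True)
class Constants:
    """Immutable bundle of the pipeline's numeric constants.

    Attributes
    ----------
    rho_muscle : float
        Muscle density in g/mm^3 for the PCSA formula.
    density_volume_to_mass : float
        Skeletal density in g/mm^3 for volume-to-mass conversion.
    lf_exponent, pcsa_exponent : float
        Body-mass scaling exponents for fibre length and PCSA.
    tukey_fence, far_fence : float
        IQR multipliers for outlier / far-outlier fences.
    alpha : float
        Significance threshold.
    """

    rho_muscle: float = RHO_MUSCLE
    density_volume_to_mass: float = DENSITY_VOLUME_TO_MASS
    lf_exponent: float = LF_EXPONENT
    pcsa_exponent: float = PCSA_EXPONENT
    tukey_fence: float = TUKEY_FENCE
    far_fence: float = FAR_FENCE
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        for name in (
            "rho_muscle",
            "density_volume_to_mass",
            "lf_exponent",
            "pcsa_exponent",
            "tukey_fence",
            "far_fence",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name!r} must be positive")


DEFAULT_CONSTANTS = Constants()
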