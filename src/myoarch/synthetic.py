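"""Synthetic dissection-style datasets with known ground truth.

The generator emulates the structure of a small-bodied flying mammal
dissection study: a handful of specimens per species, ~19 proximal forelimb
muscles in three functional groups (downstroke / upstroke / elbow), twenty
acid-digested fibre measurements per muscle, one fixed-and-stained specimen
whose muscles shrank by tens of percent, and a pectoralis sampled regionally
over a 4-compartment x 2-depth grid.

Muscles are drawn morphospace-first: each muscle's mass-normalized
(fibre length, PCSA) coordinate is sampled in log space around a species
archetype, then converted back to raw measurements (mass, belly length,
fibre samples) through the same isometric-scaling and PCSA relations the
analysis pipeline inverts. The drawn coordinates, per-species disparities
and regional cell means are recorded in a truth sidecar, so parameter
recovery can be asserted exactly.

Spread multipliers scale each species' log-space deviations from its
archetype centroid, planting an ordered disparity ranking; an outlier spec
inflates one muscle's deviation, planting a Tukey (far) outlier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS

__all__ = [
    "RegionalModel",
    "GeneratorConfig",
    "generate_species",
    "generate_isometric_twin",
    "generate_stained_twin",
    "generate_regional_fibres",
    "write_dataset",
]

_GROUPS = ("downstroke", "upstroke", "elbow")


@dataclass(frozen=True)
class RegionalModel:
    """Per-cell mean fibre lengths (mm) for the regional pectoralis grid.

    Defaults encode a cranial-to-caudal decline and a superficial > deep
    offset, the two effects the regional ANOVA is built to detect.
    """

    superficial_means: Tuple[float, ...] = (58.0, 52.0, 46.0, 40.0)
    deep_offset: float = -8.0
    noise_sd: float = 4.0
    n_per_cell: int = 20

    @property
    def cell_means(self) -> np.ndarray:
        sup = np.asarray(self.superficial_means, dtype=float)
        return np.stack([sup, sup + self.deep_offset], axis=1)  # (4, 2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dissection study.

    Defaults mirror the bat study design: one species, three ~105 g
    specimens, 19 muscles with a downstroke-dominated mass budget, 20
    fibres per muscle, ~39% mean staining shrinkage.
    """

    seed: int = 0
    n_species: int = 1
    n_specimens_per_species: int = 3
    n_muscles: int = 19
    body_mass_range: Tuple[float, float] = (90.0, 130.0)  # g, log-uniform
    muscle_budget_fraction: float = 0.13  # total muscle mass / body mass
    group_mix: Tuple[float, float, float] = (0.62, 0.197, 0.183)
    ratio_range: Tuple[float, float] = (0.25, 0.93)
    fibre_cv: float = 0.08
    n_fibres_per_muscle: int = 20
    shrinkage_mean: float = 39.33  # percent
    shrinkage_sd: float = 9.68
    isometry_exponents: Tuple[float, float] = (
        DEFAULT_CONSTANTS.lf_exponent,
        DEFAULT_CONSTANTS.pcsa_exponent,
    )
    # Log-space archetype of the normalized morphospace cloud.
    log_lf_mean: float = 1.28  # exp ~ 3.6 mm/g^0.33
    log_lf_sd: float = 0.45
    log_pcsa_mean: float = 0.1  # exp ~ 1.1 mm^2/g^0.66
    log_pcsa_sd: float = 0.75
    specimen_mass_cv: float = 0.05  # between-specimen muscle-mass jitter
    spread_multipliers: Optional[Tuple[float, ...]] = None  # per species
    # (species_index, muscle_index, inflation factor) or None
    planted_outlier: Optional[Tuple[int, int, float]] = None
    regional: RegionalModel = field(default_factory=RegionalModel)

    def validate(self) -> None:
        if self.n_species < 1 or self.n_specimens_per_species < 1:
            raise ValueError("need at least one species and one specimen")
        if self.n_muscles < 2:
            raise ValueError("need at least two muscles")
        lo, hi = self.body_mass_range
        if not (0 < lo <= hi):
            raise ValueError("body_mass_range must be positive and ordered")
        if abs(sum(self.group_mix) - 1.0) > 1e-9:
            raise ValueError("group_mix proportions must sum to 1")
        rlo, rhi = self.ratio_range
        if not (0 < rlo <= rhi <= 1.5):
            raise ValueError("ratio_range must lie in (0, 1.5] and be ordered")
        if self.fibre_cv < 0 or self.specimen_mass_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.spread_multipliers is not None and len(
            self.spread_multipliers
        ) != self.n_species:
            raise ValueError("spread_multipliers must have one entry per species")
        if self.regional.n_per_cell < 2:
            raise ValueError("regional n_per_cell must be >= 2")


def _streams(seed: int) -> Dict[str, np.random.Generator]:
    """Independent RNG streams, one per output, spawned from one master seed.

    Adding a new output gets a new named stream without perturbing the
    draws of existing ones.
    """
    names = ("specimens", "muscles", "fibres", "regional", "stained")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _lognormal_mean_cv(
    rng: np.random.Generator, mean: np.ndarray, cv: float, size=None
) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and CV."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return np.broadcast_to(mean, size if size is not None else mean.shape).copy()
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_species(
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate ``(muscles, fibres, specimens, truth)`` tables.

    ``muscles`` and ``specimens`` follow the pipeline's input CSV schemas;
    ``fibres`` holds per-fibre samples for each species' first specimen.
    ``truth`` records, per species, the body mass, the exact normalized
    coordinates each muscle was generated at, and the point-mean disparity
    of that coordinate cloud.
    """
    config.validate()
    rngs = _streams(config.seed)
    e_lf, e_pcsa = config.isometry_exponents
    rho = DEFAULT_CONSTANTS.rho_muscle

    specimen_rows: List[dict] = []
    muscle_rows: List[dict] = []
    fibre_rows: List[dict] = []
    truth: dict = {"config_seed": config.seed, "species": {}}

    rng_spec = rngs["specimens"]
    rng_mus = rngs["muscles"]
    rng_fib = rngs["fibres"]

    n_groups = len(_GROUPS)
    group_of = [
        _GROUPS[min(int(i * n_groups / config.n_muscles), n_groups - 1)]
        for i in range(config.n_muscles)
    ]

    for s in range(config.n_species):
        species = f"species_{s:02d}"
        lo, hi = config.body_mass_range
        body_mass = float(np.exp(rng_spec.uniform(np.log(lo), np.log(hi))))

        # --- morphospace truth -------------------------------------------
        log_lf = rng_mus.normal(config.log_lf_mean, config.log_lf_sd, config.n_muscles)
        log_pcsa = rng_mus.normal(
            config.log_pcsa_mean, config.log_pcsa_sd, config.n_muscles
        )
        mult = (
            config.spread_multipliers[s]
            if config.spread_multipliers is not None
            else 1.0
        )
        for arr in (log_lf, log_pcsa):
            centre = arr.mean()
            arr[:] = centre + mult * (arr - centre)
        if config.planted_outlier is not None:
            sp_i, mu_i, factor = config.planted_outlier
            if sp_i == s:
                # Push the muscle to at least `factor` cloud-SDs from the
                # geometric centroid along its own direction, so the plant
                # is extreme regardless of the muscle's original draw.
                for arr, sd in ((log_lf, config.log_lf_sd),
                                (log_pcsa, config.log_pcsa_sd)):
                    centre = arr.mean()
                    dev = arr[mu_i] - centre
                    sign = 1.0 if dev >= 0 else -1.0
                    arr[mu_i] = centre + factor * sign * max(abs(dev), sd)
        norm_lf = np.exp(log_lf)
        norm_pcsa = np.exp(log_pcsa)

        # Rescale PCSA so total muscle mass meets the body-mass budget.
        lf = norm_lf * body_mass**e_lf
        pcsa = norm_pcsa * body_mass**e_pcsa
        masses = pcsa * lf * rho
        budget = config.muscle_budget_fraction * body_mass
        scale = budget / masses.sum()
        pcsa *= scale
        norm_pcsa *= scale
        masses *= scale

        ratios = rng_mus.uniform(*config.ratio_range, config.n_muscles)
        lengths = lf / ratios

        coords = np.stack([norm_lf, norm_pcsa], axis=1)
        centroid = coords.mean(axis=0)
        disparity = float(
            np.hypot(*(coords - centroid).T).mean()
        )
        truth["species"][species] = {
            "body_mass_g": body_mass,
            "spread_multiplier": mult,
            "muscles": {
                f"MUS{i:02d}": {
                    "norm_lf": float(norm_lf[i]),
                    "norm_pcsa": float(norm_pcsa[i]),
                    "mass_g": float(masses[i]),
                    "fibre_length_mm": float(lf[i]),
                    "group": group_of[i],
                }
                for i in range(config.n_muscles)
            },
            "mean_disparity": disparity,
        }

        # --- specimen tables ---------------------------------------------
        for k in range(config.n_specimens_per_species):
            specimen = f"{species}_sp{k}"
            bm = (
                body_mass
                if k == 0
                else float(
                    _lognormal_mean_cv(
                        rng_spec, np.array(body_mass), config.specimen_mass_cv
                    )
                )
            )
            specimen_rows.append(
                {
                    "specimen_id": specimen,
                    "species": species,
                    "body_mass_g": bm,
                    "source": "synthetic",
                }
            )
            jitter = (
                np.ones(config.n_muscles)
                if k == 0
                else _lognormal_mean_cv(
                    rng_mus,
                    np.ones(config.n_muscles),
                    config.specimen_mass_cv,
                    size=config.n_muscles,
                )
            )
            for i in range(config.n_muscles):
                muscle_rows.append(
                    {
                        "specimen_id": specimen,
                        "muscle_code": f"MUS{i:02d}",
                        "functional_group": group_of[i],
                        "mass_g": masses[i] * jitter[i],
                        "muscle_length_mm": lengths[i],
                        "volume_mm3": "",
                        "preservation": "fresh",
                    }
                )
            if k == 0:
                for i in range(config.n_muscles):
                    samples = _lognormal_mean_cv(
                        rng_fib,
                        np.array(lf[i]),
                        config.fibre_cv,
                        size=config.n_fibres_per_muscle,
                    )
                    for j, length in enumerate(samples):
                        fibre_rows.append(
                            {
                                "specimen_id": specimen,
                                "muscle_code": f"MUS{i:02d}",
                                "fibre_id": j,
                                "length_mm": float(length),
                            }
                        )

    muscles = pd.DataFrame(muscle_rows)
    fibres = pd.DataFrame(fibre_rows)
    specimens = pd.DataFrame(specimen_rows)
    return muscles, fibres, specimens, truth


def generate_isometric_twin(
    muscles: pd.DataFrame,
    fibres: pd.DataFrame,
    specimens: pd.DataFrame,
    k: float,
    *,
    suffix: str = "_twin",
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Geometrically scaled copy: lengths x k, masses x k^3.

    Under exponents (1/3, 2/3) the twin occupies exactly the same
    normalized morphospace as the original.
    """
    if k <= 0:
        raise ValueError("scale factor k must be positive")
    m = muscles.copy()
    m["specimen_id"] = m["specimen_id"] + suffix
    m["mass_g"] = m["mass_g"].astype(float) * k**3
    m["muscle_length_mm"] = m["muscle_length_mm"].astype(float) * k
    f = fibres.copy()
    f["specimen_id"] = f["specimen_id"] + suffix
    f["length_mm"] = f["length_mm"].astype(float) * k
    s = specimens.copy()
    s["specimen_id"] = s["specimen_id"] + suffix
    s["species"] = s["species"] + suffix
    s["body_mass_g"] = s["body_mass_g"].astype(float) * k**3
    return m, f, s


def generate_stained_twin(
    muscles: pd.DataFrame,
    *,
    shrinkage_mean: float = 39.33,
    shrinkage_sd: float = 9.68,
    seed: int = 0,
    specimen_id: Optional[str] = None,
    suffix: str = "_stained",
) -> pd.DataFrame:
    """Fixed-and-stained copy of a fresh specimen's muscle table.

    Each muscle's mass is multiplied by ``1 - s/100`` with s drawn from a
    normal distribution truncated to (0, 100). Muscle lengths (and hence
    fibre lengths and ratios) are untouched: staining shrinks mass, not
    relative fibre geometry.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    sel = muscles
    if specimen_id is not None:
        sel = muscles[muscles["specimen_id"] == specimen_id]
        if sel.empty:
            raise ValueError(f"no rows for specimen {specimen_id!r}")
    out = sel.copy()
    n = len(out)
    s = rng.normal(shrinkage_mean, shrinkage_sd, size=n)
    # Redraw until inside (0, 100); shrinkage can be tiny but not negative.
    bad = (s <= 0) | (s >= 100)
    while bad.any():
        s[bad] = rng.normal(shrinkage_mean, shrinkage_sd, size=int(bad.sum()))
        bad = (s <= 0) | (s >= 100)
    out["mass_g"] = out["mass_g"].astype(float) * (1.0 - s / 100.0)
    out["specimen_id"] = out["specimen_id"] + suffix
    out["preservation"] = "fixed_stained"
    out.attrs["shrinkage_percent"] = s
    return out


def generate_regional_fibres(
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, dict]:
    """Regional pectoralis fibre table: 4 compartments x 2 depths x n fibres.

    Gaussian noise around the configured per-cell means. Returns the table
    and a truth dict with the exact cell means used.
    """
    config.validate()
    rng = _streams(config.seed)["regional"]
    model = config.regional
    means = model.cell_means  # (4, 2)
    rows = []
    compartments = ("M1", "M2", "M3", "M4")
    depths = ("superficial", "deep")
    for i, comp in enumerate(compartments):
        for j, depth in enumerate(depths):
            lengths = rng.normal(means[i, j], model.noise_sd, model.n_per_cell)
            lengths = np.abs(lengths)  # fibre lengths are physical lengths
            for length in lengths:
                rows.append(
                    {
                        "specimen_id": "synthetic_regional",
                        "muscle_code": "PPos",
                        "compartment": comp,
                        "depth": depth,
                        "length_mm": float(length),
                    }
                )
    truth = {
        "cell_means": {
            f"{c}/{d}": float(means[i, j])
            for i, c in enumerate(compartments)
            for j, d in enumerate(depths)
        },
        "noise_sd": model.noise_sd,
        "n_per_cell": model.n_per_cell,
    }
    return pd.DataFrame(rows), truth


def write_dataset(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write muscles/fibres/specimens/regional CSVs plus ``truth.json``."""
    config.validate()  # fail before creating anything on disk
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    muscles, fibres, specimens, truth = generate_species(config)
    regional, regional_truth = generate_regional_fibres(config)
    truth["regional"] = regional_truth
    muscles.to_csv(out / "muscles.csv", index=False)
    fibres.to_csv(out / "fibre_lengths.csv", index=False)
    specimens.to_csv(out / "specimens.csv", index=False)
    regional.to_csv(out / "fibres_regional.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return out
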