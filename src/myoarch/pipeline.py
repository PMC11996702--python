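"""End-to-end pipeline: architecture -> morphospace -> disparity -> ANOVA.

A :class:`RunConfig` collects the input paths and analysis options; the
pipeline validates it fully before touching the filesystem, writes each
stage's output CSV, and finishes with a JSON run summary (counts,
exclusions, key statistics) plus a copy of the resolved configuration for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import io as mio
from .architecture import derive_architecture, excluded_muscles, group_fractions
from .constants import DEFAULT_CONSTANTS, Constants
from .disparity import CENTROID_CONVENTIONS, compare_species, envelope
from .heterogeneity import (
    pairwise_depth_comparisons,
    simple_main_effects,
    two_way_anova,
)
from .morphospace import assemble_morphospace, classify_specialization

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    muscles_csv: str
    specimens_csv: str
    out_dir: str
    fibres_csv: Optional[str] = None
    regional_csv: Optional[str] = None
    grouping_csv: Optional[str] = None
    donor_specimen: Optional[str] = None  # specimen providing transfer ratios
    centroid: str = "point-mean"
    alpha: float = DEFAULT_CONSTANTS.alpha
    constants: Constants = field(default_factory=Constants)

    def validate(self) -> None:
        for name in ("muscles_csv", "specimens_csv"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name}: no such file: {p}")
        for name in ("fibres_csv", "regional_csv", "grouping_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{name}: no such file: {p}")
        if self.centroid not in CENTROID_CONVENTIONS:
            raise ValueError(
                f"centroid must be one of {CENTROID_CONVENTIONS}, "
                f"got {self.centroid!r}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _donor_ratio_map(results) -> Dict[str, float]:
    return {
        r.muscle_code: r.muscle_fibre_ratio
        for r in results
        if r.muscle_fibre_ratio is not None
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle to ``out_dir``.

    Returns the run summary dict (also written as ``run_summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = mio.read_muscles(config.muscles_csv)
    if config.fibres_csv:
        records = mio.attach_fibres(records, mio.read_fibres(config.fibres_csv))
    specimens = mio.read_specimens(config.specimens_csv)
    grouping = (
        mio.read_grouping(config.grouping_csv) if config.grouping_csv else None
    )
    spec_by_id = {s.specimen_id: s for s in specimens}
    species_of = {s.specimen_id: s.species for s in specimens}

    # Donor ratios: measured on the donor specimen, transferred to others.
    donor_ratios: Optional[Dict[str, float]] = None
    if config.donor_specimen:
        donor_records = [
            r for r in records if r.specimen_id == config.donor_specimen
        ]
        if not donor_records:
            raise ValueError(
                f"donor specimen {config.donor_specimen!r} has no muscle rows"
            )
        donor_ratios = _donor_ratio_map(
            derive_architecture(donor_records, constants=config.constants)
        )

    summary: dict = {"species": {}, "counts": {}, "exclusions": {}}
    all_points = []
    for specimen_id in sorted({r.specimen_id for r in records}):
        specimen_records = [r for r in records if r.specimen_id == specimen_id]
        results = derive_architecture(
            specimen_records, donor_ratios, constants=config.constants
        )
        excluded = excluded_muscles(specimen_records, results)
        mio.write_architecture(
            results, specimen_records, out / f"architecture_{specimen_id}.csv"
        )
        comp = group_fractions(
            specimen_records, grouping, constants=config.constants
        )
        summary["species"].setdefault(
            species_of.get(specimen_id, specimen_id), {}
        )[specimen_id] = {
            "n_muscles": len(specimen_records),
            "n_derived": len(results),
            "excluded": {code: "no fibre length or mass" for code in excluded},
            "group_fractions_percent": {
                g.value: f for g, f in comp.fractions.items()
            },
            "total_muscle_mass_g": comp.total_mass,
        }
        if specimen_id in spec_by_id:
            points = assemble_morphospace(
                results,
                [spec_by_id[specimen_id]],
                constants=config.constants,
            )
            all_points.extend(points)

    if not all_points:
        raise ValueError(
            "no muscle resolved both a fibre length and a PCSA; supply a "
            "fibre-samples file, a fibre_length_mm column, or a ratio donor"
        )
    all_points = classify_specialization(all_points)
    mio.write_morphospace(all_points, out / "morphospace.csv")

    by_species: Dict[str, list] = {}
    for p in all_points:
        by_species.setdefault(p.species, []).append(p)
    envelopes = []
    for species, pts in sorted(by_species.items()):
        # A species measured on several specimens contributes each muscle
        # once: keep the first specimen's point per muscle code.
        seen = {}
        for p in pts:
            seen.setdefault(p.muscle_code, p)
        pts = list(seen.values())
        if len(pts) < 2:
            raise ValueError(
                f"species {species!r} has fewer than two morphospace points"
            )
        envelopes.append(envelope(pts, centroid=config.centroid))

    rows = []
    for env in envelopes:
        from .disparity import tukey_summary

        tk = (
            tukey_summary(env.distances, constants=config.constants)
            if len(env.distances) >= 3
            else None
        )
        for code, dist in env.distances.items():
            rows.append(
                {
                    "species": env.species,
                    "muscle_code": code,
                    "distance": dist,
                    "is_outlier": bool(tk and code in tk.outliers),
                    "is_far_outlier": bool(tk and code in tk.far_outliers),
                }
            )
    pd.DataFrame(rows).to_csv(out / "disparity.csv", index=False)

    summary_rows = []
    if len(envelopes) >= 2:
        for row in compare_species(envelopes, constants=config.constants):
            tk = row.pop("tukey")
            row.update(
                {
                    "lower_hinge": tk.lower_hinge if tk else None,
                    "upper_hinge": tk.upper_hinge if tk else None,
                    "iqr": tk.iqr if tk else None,
                    "outliers": ";".join(row["outliers"]),
                    "far_outliers": ";".join(row["far_outliers"]),
                }
            )
            summary_rows.append(row)
    else:
        env = envelopes[0]
        summary_rows.append(
            {
                "species": env.species,
                "n_muscles": len(env.distances),
                "mean_disparity": env.mean_disparity,
                "rank": 1,
            }
        )
    pd.DataFrame(summary_rows).to_csv(out / "disparity_summary.csv", index=False)
    summary["counts"]["n_species"] = len(envelopes)
    summary["counts"]["n_morphospace_points"] = len(all_points)
    summary["disparity"] = {
        env.species: env.mean_disparity for env in envelopes
    }

    if config.regional_csv:
        samples = mio.read_regional_fibres(config.regional_csv)
        anova = two_way_anova(samples)
        lines = [anova.summary(), ""]
        sme_rows = []
        for factor, other_levels in (
            ("compartment", anova.levels_b),
            ("depth", anova.levels_a),
        ):
            for held in other_levels:
                f, df1, df2, p = simple_main_effects(samples, factor, held)
                sme_rows.append(
                    {
                        "factor": factor,
                        "held_level": held,
                        "F": f,
                        "df1": df1,
                        "df2": df2,
                        "p": p,
                        "significant": p < config.alpha,
                    }
                )
        posthoc = pairwise_depth_comparisons(samples)
        (out / "anova.txt").write_text("\n".join(lines))
        pd.DataFrame(sme_rows).to_csv(out / "simple_effects.csv", index=False)
        pd.DataFrame(posthoc).to_csv(out / "posthoc.csv", index=False)
        summary["anova"] = {
            "interaction_F": anova.f_stats["interaction"],
            "interaction_df": [
                anova.df["interaction"],
                anova.df["error"],
            ],
            "interaction_p": anova.p_values["interaction"],
        }

    cfg = dataclasses.asdict(config)
    cfg["constants"] = dataclasses.asdict(config.constants)
    summary["config"] = cfg
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
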