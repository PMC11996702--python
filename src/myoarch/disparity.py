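"""Architectural disparity: per-species morphospace envelopes and outliers.

A species' muscles form a point cloud in normalized (Lf, PCSA) space. The
envelope is the convex hull of that cloud; architectural disparity is the
mean Euclidean distance of every muscle (hull vertex or not) from the cloud
centroid. High disparity indicates a functionally diversified musculature.
Per-species distance distributions are summarized with Tukey boxplot
statistics, flagging muscles beyond 1.5x (outlier) and 3x (far outlier) the
inter-quartile range from the hinges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .constants import DEFAULT_CONSTANTS, Constants
from .records import MorphospacePoint

__all__ = [
    "convex_hull",
    "envelope",
    "tukey_summary",
    "compare_species",
    "SpeciesEnvelope",
    "TukeySummary",
    "CENTROID_CONVENTIONS",
]

#: Supported centroid conventions for the envelope:
#: ``point-mean``   — arithmetic mean of all muscle points (default; matches
#:                    the mean-to-centroid disparity metric on observations),
#: ``hull-mean``    — arithmetic mean of the hull vertices only,
#: ``polygon-area`` — area centroid of the hull polygon.
CENTROID_CONVENTIONS = ("point-mean", "hull-mean", "polygon-area")


@dataclass(frozen=True)
class SpeciesEnvelope:
    """Convex envelope, centroid and per-muscle disparity of one species."""

    species: str
    hull_vertices: Tuple[Tuple[float, float], ...]
    centroid: Tuple[float, float]
    distances: Dict[str, float]  # muscle_code -> distance to centroid
    mean_disparity: float


@dataclass(frozen=True)
class TukeySummary:
    """Tukey five-number boxplot summary with outlier fences.

    Hinges are computed from median-inclusive data halves; whiskers are
    reported as mean +/- 1 SD (a plotting convention, independent of the
    fences). Outliers lie beyond ``hinge +/- 1.5*IQR``, far outliers beyond
    ``hinge +/- 3*IQR``; far outliers are also counted as outliers.
    """

    lower_hinge: float
    median: float
    upper_hinge: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: Tuple[str, ...]
    far_outliers: Tuple[str, ...]


def convex_hull(points: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    """Convex hull of 2D points, counter-clockwise from the lexicographic min.

    Collinear boundary points are not vertices. Degenerate inputs are
    handled explicitly: one point -> itself; all points collinear -> the
    two extreme endpoints (a segment).
    """
    if len(points) < 1:
        raise ValueError("convex_hull needs at least one point")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("convex_hull expects an (n, 2) array of points")
    uniq = np.unique(pts, axis=0)  # sorts lexicographically
    if len(uniq) == 1:
        return [tuple(uniq[0])]
    try:
        hull = ConvexHull(uniq)
    except QhullError:
        # Collinear cloud: the hull degenerates to the extreme segment.
        return [tuple(uniq[0]), tuple(uniq[-1])]
    # Qhull already returns 2D vertices in counter-clockwise order; rotate
    # the cycle to start at the lexicographically smallest vertex so output
    # files are bit-stable.
    verts = hull.points[hull.vertices]
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    verts = np.roll(verts, -start, axis=0)
    return [tuple(v) for v in verts]


def _polygon_area_centroid(verts: np.ndarray) -> Tuple[float, float]:
    """Area centroid of a simple polygon given CCW vertices."""
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-300:
        return tuple(verts.mean(axis=0))
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return (cx, cy)


def envelope(
    points: Iterable[MorphospacePoint],
    *,
    centroid: str = "point-mean",
) -> SpeciesEnvelope:
    """Per-species envelope: hull, centroid, distances, mean disparity.

    All muscles — interior points included — contribute a centroid distance,
    and the mean of those distances is the species' architectural disparity.
    ``centroid`` selects the convention (see :data:`CENTROID_CONVENTIONS`).
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("envelope needs at least two muscle points")
    species = {p.species for p in points}
    if len(species) != 1:
        raise ValueError(f"envelope expects one species, got {sorted(species)}")
    codes = [p.muscle_code for p in points]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate muscle labels in envelope input: {dupes}")
    if centroid not in CENTROID_CONVENTIONS:
        raise ValueError(
            f"unknown centroid convention {centroid!r}; "
            f"choose from {CENTROID_CONVENTIONS}"
        )
    coords = np.array([(p.norm_lf, p.norm_pcsa) for p in points])
    verts = convex_hull([tuple(c) for c in coords])
    varr = np.asarray(verts)
    if centroid == "point-mean":
        c = coords.mean(axis=0)
    elif centroid == "hull-mean":
        c = varr.mean(axis=0)
    else:  # polygon-area
        if len(verts) < 3:
            c = varr.mean(axis=0)
        else:
            c = np.asarray(_polygon_area_centroid(varr))
    dists = np.hypot(coords[:, 0] - c[0], coords[:, 1] - c[1])
    return SpeciesEnvelope(
        species=next(iter(species)),
        hull_vertices=tuple(tuple(v) for v in verts),
        centroid=(float(c[0]), float(c[1])),
        distances={code: float(d) for code, d in zip(codes, dists)},
        mean_disparity=float(dists.mean()),
    )


def _tukey_hinges(sorted_vals: np.ndarray) -> Tuple[float, float, float]:
    """Median and hinges from median-inclusive halves (Tukey's method)."""
    n = len(sorted_vals)
    med = float(np.median(sorted_vals))
    half = (n + 1) // 2  # include the median datum in each half when n odd
    lower = sorted_vals[:half]
    upper = sorted_vals[n - half:]
    return float(np.median(lower)), med, float(np.median(upper))


def tukey_summary(
    values: Dict[str, float] | Sequence[Tuple[str, float]],
    *,
    constants: Constants = DEFAULT_CONSTANTS,
) -> TukeySummary:
    """Tukey boxplot summary of a labelled set of values."""
    items = list(values.items()) if isinstance(values, dict) else list(values)
    if len(items) < 3:
        raise ValueError("tukey_summary needs at least three values")
    labels = [k for k, _ in items]
    arr = np.array([v for _, v in items], dtype=float)
    order = np.argsort(arr, kind="stable")
    lo_h, med, up_h = _tukey_hinges(arr[order])
    iqr = up_h - lo_h
    out_lo = lo_h - constants.tukey_fence * iqr
    out_hi = up_h + constants.tukey_fence * iqr
    far_lo = lo_h - constants.far_fence * iqr
    far_hi = up_h + constants.far_fence * iqr
    outliers, far = [], []
    for label, v in items:
        if v < far_lo or v > far_hi:
            far.append(label)
            outliers.append(label)
        elif v < out_lo or v > out_hi:
            outliers.append(label)
    mean, sd = float(arr.mean()), float(arr.std(ddof=1))
    return TukeySummary(
        lower_hinge=lo_h,
        median=med,
        upper_hinge=up_h,
        iqr=iqr,
        whisker_low=mean - sd,
        whisker_high=mean + sd,
        outliers=tuple(outliers),
        far_outliers=tuple(far),
    )


def compare_species(
    envelopes: Sequence[SpeciesEnvelope],
    *,
    constants: Constants = DEFAULT_CONSTANTS,
) -> List[dict]:
    """Rank species by mean architectural disparity (largest first).

    Each row carries the species' muscle count, mean disparity, and — when
    the species has enough muscles — the Tukey summary of its centroid
    distances with any outlier muscles named. Ties share a rank.
    """
    if len(envelopes) < 2:
        raise ValueError("compare_species needs at least two envelopes")
    rows = []
    for env in envelopes:
        summary = (
            tukey_summary(env.distances, constants=constants)
            if len(env.distances) >= 3
            else None
        )
        rows.append(
            {
                "species": env.species,
                "n_muscles": len(env.distances),
                "mean_disparity": env.mean_disparity,
                "tukey": summary,
                "outliers": summary.outliers if summary else (),
                "far_outliers": summary.far_outliers if summary else (),
            }
        )
    rows.sort(key=lambda r: (-r["mean_disparity"], r["species"]))
    rank, prev = 0, None
    for i, row in enumerate(rows, start=1):
        if prev is None or not math.isclose(
            row["mean_disparity"], prev, rel_tol=1e-12, abs_tol=1e-12
        ):
            rank = i
        row["rank"] = rank
        prev = row["mean_disparity"]
    return rows
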