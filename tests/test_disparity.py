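"""Tests for convex envelopes, centroid distances and Tukey outlier calls."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from myoarch.disparity import (
    compare_species,
    convex_hull,
    envelope,
    tukey_summary,
)
from myoarch.records import MorphospacePoint


def _pt(code, x, y, species="sp"):
    return MorphospacePoint(species=species, muscle_code=code, norm_lf=x, norm_pcsa=y)


# --- brute-force oracle -----------------------------------------------------


def brute_force_hull_vertices(points):
    """A point is a hull vertex iff it lies outside the convex hull of the
    remaining points (exhaustive half-plane test). O(n^3); oracle use only,
    exact for integer coordinates."""
    pts = [tuple(map(float, p)) for p in points]
    return {
        p
        for i, p in enumerate(pts)
        if not _inside_hull(p, pts[:i] + pts[i + 1:])
    }


def _inside_hull(p, pts):
    """Is p inside (or on the boundary of) the convex hull of pts?
    p is outside iff some directed line through two points of pts keeps
    every pts-point on its left while p is strictly on its right."""
    if len(pts) == 1:
        return p == pts[0]
    for a in pts:
        for b in pts:
            if a == b:
                continue
            all_left = all(
                (b[0] - a[0]) * (q[1] - a[1]) - (b[1] - a[1]) * (q[0] - a[0]) >= 0
                for q in pts
            )
            if all_left:
                cp = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                if cp < 0:
                    return False
    return True


class TestConvexHull:
    def test_square_with_interior_point(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)]
        hull = convex_hull(pts)
        assert len(hull) == 4
        assert (0.5, 0.5) not in hull

    def test_hull_is_ccw_from_lexicographic_min(self):
        hull = convex_hull([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert hull[0] == (0.0, 0.0)
        # shoelace area positive => counter-clockwise
        area = sum(
            hull[i][0] * hull[(i + 1) % 4][1] - hull[(i + 1) % 4][0] * hull[i][1]
            for i in range(4)
        )
        assert area > 0

    def test_triangle_is_itself(self):
        pts = [(0, 0), (2, 0), (1, 3)]
        assert set(convex_hull(pts)) == set((float(a), float(b)) for a, b in pts)

    def test_collinear_degenerates_to_segment(self):
        hull = convex_hull([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert hull == [(0.0, 0.0), (3.0, 3.0)]

    def test_single_point(self):
        assert convex_hull([(2.5, 1.0)]) == [(2.5, 1.0)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            convex_hull([])

    def test_collinear_boundary_point_excluded(self):
        pts = [(0, 0), (2, 0), (1, 0), (1, 2)]  # (1,0) lies on an edge
        hull = convex_hull(pts)
        assert (1.0, 0.0) not in hull
        assert len(hull) == 3

    @given(
        st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=3,
            max_size=12,
            unique=True,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, pts):
        """Hull vertices equal the exhaustive half-plane oracle's set.

        Integer coordinates keep both routes exact; fully collinear clouds
        are exercised by a dedicated degenerate-case test instead.
        """
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        collinear = all(
            (pts[1][0] - pts[0][0]) * (y - pts[0][1])
            == (pts[1][1] - pts[0][1]) * (x - pts[0][0])
            for x, y in pts
        )
        assume(not collinear)
        oracle = brute_force_hull_vertices(pts)
        ours = set(convex_hull(pts))
        assert ours == oracle

    def test_random_cloud_against_oracle(self):
        rng = np.random.default_rng(42)
        pts = [tuple(p) for p in rng.uniform(-1, 1, size=(50, 2))]
        hull = set(convex_hull(pts))
        # every input point must be inside the hull
        for p in pts:
            assert _inside_hull(p, list(hull))


class TestEnvelope:
    def test_unit_square(self):
        pts = [_pt(c, *xy) for c, xy in zip("ABCD", [(0, 0), (1, 0), (1, 1), (0, 1)])]
        env = envelope(pts)
        assert env.centroid == pytest.approx((0.5, 0.5))
        for d in env.distances.values():
            assert d == pytest.approx(math.sqrt(0.5))
        assert env.mean_disparity == pytest.approx(math.sqrt(0.5))

    def test_coincident_points_zero_disparity(self):
        pts = [_pt(c, 1.0, 2.0) for c in "ABC"]
        assert envelope(pts).mean_disparity == 0.0

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            envelope([_pt("A", 0, 0), _pt("A", 1, 1)])

    def test_mixed_species_rejected(self):
        with pytest.raises(ValueError, match="one species"):
            envelope([_pt("A", 0, 0, "x"), _pt("B", 1, 1, "y")])

    def test_interior_point_changes_centroid_not_hull(self):
        corners = [_pt(c, *xy) for c, xy in zip("ABCD", [(0, 0), (1, 0), (1, 1), (0, 1)])]
        with_interior = corners + [_pt("E", 0.9, 0.9)]
        env1 = envelope(corners)
        env2 = envelope(with_interior)
        assert env1.hull_vertices == env2.hull_vertices
        assert env1.centroid != env2.centroid
        assert env1.mean_disparity != env2.mean_disparity

    @pytest.mark.parametrize("conv", ["point-mean", "hull-mean", "polygon-area"])
    def test_similarity_invariances(self, conv):
        """Disparity is translation- and rotation-invariant and scales
        linearly with a uniform axis scaling."""
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 4, size=(9, 2))
        pts = [_pt(f"m{i}", *p) for i, p in enumerate(xy)]
        base = envelope(pts, centroid=conv).mean_disparity

        shifted = [_pt(f"m{i}", x + 11.0, y - 3.0) for i, (x, y) in enumerate(xy)]
        assert envelope(shifted, centroid=conv).mean_disparity == pytest.approx(
            base, rel=1e-9
        )

        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        rotated_xy = xy @ rot.T
        rotated = [_pt(f"m{i}", *p) for i, p in enumerate(rotated_xy)]
        assert envelope(rotated, centroid=conv).mean_disparity == pytest.approx(
            base, rel=1e-9
        )

        k = 2.75
        scaled = [_pt(f"m{i}", k * x, k * y) for i, (x, y) in enumerate(xy)]
        assert envelope(scaled, centroid=conv).mean_disparity == pytest.approx(
            k * base, rel=1e-9
        )

    def test_disparity_zero_iff_coincident(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 1, size=(5, 2))
        pts = [_pt(f"m{i}", *p) for i, p in enumerate(xy)]
        assert envelope(pts).mean_disparity > 0


class TestTukeySummary:
    def test_hand_computed_hinges_and_far_outlier(self):
        """n=11 values {1..10, 100}: hinges 3.5 / 8.5, IQR 5, and 100 is
        beyond the 3x far fence (8.5 + 15 < 100)."""
        values = {f"v{i}": float(v) for i, v in enumerate(list(range(1, 11)) + [100])}
        tk = tukey_summary(values)
        assert tk.lower_hinge == pytest.approx(3.5)
        assert tk.median == pytest.approx(6.0)
        assert tk.upper_hinge == pytest.approx(8.5)
        assert tk.iqr == pytest.approx(5.0)
        assert tk.far_outliers == ("v10",)
        assert tk.outliers == ("v10",)

    def test_constant_vector_no_outliers(self):
        tk = tukey_summary({c: 4.2 for c in "ABCDE"})
        assert tk.iqr == 0.0
        assert tk.outliers == ()

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            tukey_summary({"a": 1.0, "b": 2.0})

    def test_whiskers_are_mean_pm_sd(self):
        vals = {c: float(v) for c, v in zip("ABCDE", [1, 2, 3, 4, 5])}
        tk = tukey_summary(vals)
        assert tk.whisker_low == pytest.approx(3 - np.std([1, 2, 3, 4, 5], ddof=1))
        assert tk.whisker_high == pytest.approx(3 + np.std([1, 2, 3, 4, 5], ddof=1))

    def test_every_label_in_exactly_one_class(self):
        rng = np.random.default_rng(5)
        vals = {f"m{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 20))}
        vals["planted"] = 40.0
        tk = tukey_summary(vals)
        assert "planted" in tk.far_outliers
        assert set(tk.far_outliers) <= set(tk.outliers)


class TestCompareSpecies:
    def test_isometric_copies_tie(self):
        xy = [(0, 0), (2, 0), (1, 2), (1, 1)]
        a = envelope([_pt(f"m{i}", *p, "a") for i, p in enumerate(xy)])
        b = envelope([_pt(f"m{i}", *p, "b") for i, p in enumerate(xy)])
        rows = compare_species([a, b])
        assert rows[0]["rank"] == rows[1]["rank"] == 1

    def test_planted_spread_ranks_first(self):
        """A species generated at twice the coordinate spread ranks first."""
        from myoarch.synthetic import GeneratorConfig, generate_species

        cfg = GeneratorConfig(
            seed=11, n_species=4, n_specimens_per_species=1,
            spread_multipliers=(1.0, 1.0, 2.0, 1.0),
        )
        _, _, _, truth = generate_species(cfg)
        envs = []
        for species, info in truth["species"].items():
            pts = [
                _pt(code, m["norm_lf"], m["norm_pcsa"], species)
                for code, m in info["muscles"].items()
            ]
            envs.append(envelope(pts))
        rows = compare_species(envs)
        assert rows[0]["species"] == "species_02"

    def test_single_envelope_rejected(self):
        env = envelope([_pt("A", 0, 0), _pt("B", 1, 1)])
        with pytest.raises(ValueError):
            compare_species([env])

    def test_single_point_species_surfaces_species_name(self):
        with pytest.raises(ValueError, match="two muscle points"):
            envelope([_pt("only", 1.0, 1.0, species="lonely")])

    def test_planted_far_outlier_muscle_flagged(self):
        """Inflating one muscle's deviation from the species centroid makes
        it a Tukey far outlier of the distance distribution."""
        from myoarch.synthetic import GeneratorConfig, generate_species

        cfg = GeneratorConfig(
            seed=5, n_species=1, n_specimens_per_species=1,
            planted_outlier=(0, 7, 5.0),
        )
        _, _, _, truth = generate_species(cfg)
        info = truth["species"]["species_00"]
        pts = [
            _pt(code, m["norm_lf"], m["norm_pcsa"])
            for code, m in info["muscles"].items()
        ]
        env = envelope(pts)
        tk = tukey_summary(env.distances)
        assert "MUS07" in tk.outliers
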