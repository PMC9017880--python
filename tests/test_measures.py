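import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actomyosim import (
    Domain,
    Filament,
    Frame,
    MeasureSeries,
    concave_boundary,
    measure_all,
    measures_to_table,
    motor_boundary_area,
    motor_localization,
    normalize_series,
    orientational_order,
    radial_distribution,
    radius_of_gyration,
    sample_actin_points,
    segregation_centroid_distance,
    segregation_intersection,
    threshold_crossing_time,
)
from actomyosim.geometry import MotorMinifilament
from actomyosim.measures import default_r_grid
from conftest import make_random_frame


def frame_of_beads(beads, domain=None):
    beads = np.asarray(beads, dtype=float)
    return Frame(
        time=0.0,
        filaments=[Filament(id="f0", beads=beads)],
        motors=[],
        linkers=[],
        domain=domain or Domain(),
    )


def bound_motor(mid, center, species="myosin"):
    """Motor with the 'bound' flag and a synthetic position (no filament
    attachment is checked by the measures)."""
    c = np.asarray(center, dtype=float)
    m = MotorMinifilament(
        id=mid, species=species, state="bound",
        endpoints=np.vstack([c, c]), n_heads=20,
    )
    return m


class TestRadiusOfGyration:
    def test_coincident_beads(self):
        f = frame_of_beads([[500, 500, 100]] * 4)
        assert radius_of_gyration(f) == 0.0

    def test_two_beads_half_separation(self):
        f = frame_of_beads([[0, 0, 0], [2, 0, 0]])
        assert radius_of_gyration(f) == pytest.approx(1.0, abs=1e-12)

    def test_unit_square(self):
        f = frame_of_beads([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert radius_of_gyration(f) == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_matches_loop_oracle_and_invariances(self, rng):
        for _ in range(20):
            frame = make_random_frame(rng, n_fil=rng.integers(1, 5))
            beads = frame.actin_beads()
            gc = beads.mean(axis=0)
            oracle = math.sqrt(sum(np.sum((b - gc) ** 2) for b in beads) / len(beads))
            assert radius_of_gyration(frame) == pytest.approx(oracle, abs=1e-9)
        # translation invariance and linear scaling
        frame = make_random_frame(rng)
        rg = radius_of_gyration(frame)
        shifted = frame_of_beads(frame.actin_beads() + np.array([10.0, -20.0, 5.0]))
        scaled = frame_of_beads(frame.actin_beads() * 3.0)
        assert radius_of_gyration(shifted) == pytest.approx(rg, rel=1e-12)
        assert radius_of_gyration(scaled) == pytest.approx(3.0 * rg, rel=1e-12)

    def test_empty_frame_raises(self):
        empty = Frame(time=0.0, filaments=[], motors=[], linkers=[])
        with pytest.raises(ValueError):
            radius_of_gyration(empty)


class TestNormalizeSeries:
    def test_arithmetic(self):
        s = MeasureSeries(name="rg", times=[0, 1, 2], values=[2.0, 1.0, 4.0])
        np.testing.assert_allclose(normalize_series(s).scalars(), [1.0, 0.5, 2.0])

    def test_constant_series(self):
        s = MeasureSeries(name="rg", times=[0, 1], values=[7.0, 7.0])
        np.testing.assert_allclose(normalize_series(s).scalars(), [1.0, 1.0])

    def test_zero_first_value_raises(self):
        s = MeasureSeries(name="rg", times=[0, 1], values=[0.0, 1.0])
        with pytest.raises(ValueError):
            normalize_series(s)


class TestOrientationalOrder:
    def test_parallel_filaments(self):
        beads = lambda x0: [[x0, 100, 50], [x0 + 300, 100, 50]]
        fils = [Filament(id=f"f{i}", beads=beads(100 * i)) for i in range(5)]
        frame = Frame(time=0, filaments=fils, motors=[], linkers=[])
        assert orientational_order(frame) == pytest.approx(1.0, abs=1e-9)

    def test_antiparallel_still_fully_ordered(self):
        # nematic order: reversing half the filaments changes nothing
        fils = [
            Filament(id="a", beads=[[0, 0, 0], [100, 0, 0]]),
            Filament(id="b", beads=[[300, 50, 0], [200, 50, 0]]),
        ]
        frame = Frame(time=0, filaments=fils, motors=[], linkers=[])
        assert orientational_order(frame) == pytest.approx(1.0, abs=1e-9)

    def test_three_orthogonal_filaments(self):
        fils = [
            Filament(id="x", beads=[[0, 0, 0], [100, 0, 0]]),
            Filament(id="y", beads=[[0, 0, 0], [0, 100, 0]][::-1]),
            Filament(id="z", beads=[[10, 10, 0], [10, 10, 100]]),
        ]
        frame = Frame(time=0, filaments=fils, motors=[], linkers=[])
        # sum of outer products is I/3: Q vanishes, hand eigen-solve gives 0
        assert orientational_order(frame) == pytest.approx(0.0, abs=1e-12)

    def test_matches_characteristic_polynomial_oracle(self, rng):
        """Largest eigenvalue cross-checked through an independent eigen path
        (roots of the characteristic cubic, not the symmetric eigensolver)."""
        for _ in range(20):
            frame = make_random_frame(rng, n_fil=int(rng.integers(2, 8)))
            dirs = []
            for f in frame.filaments:
                v = f.beads[-1] - f.beads[0]
                dirs.append(v / np.linalg.norm(v))
            dirs = np.array(dirs)
            q = 1.5 * (dirs.T @ dirs / len(dirs) - np.eye(3) / 3)
            coeffs = np.poly(q)
            oracle = max(r.real for r in np.roots(coeffs))
            assert orientational_order(frame) == pytest.approx(oracle, abs=1e-8)

    def test_bounds(self, rng):
        for _ in range(10):
            frame = make_random_frame(rng, n_fil=int(rng.integers(1, 6)))
            s = orientational_order(frame)
            assert -0.5 - 1e-9 <= s <= 1.0 + 1e-9


class TestRadialDistribution:
    def test_two_beads_single_bin(self):
        f = frame_of_beads([[0, 0, 0], [300, 0, 0]])
        g = radial_distribution(f)
        assert g.sum() == pytest.approx(1.0, abs=1e-12)
        edges = np.linspace(0, f.domain.diagonal, 51)
        j = np.searchsorted(edges, 300.0, side="right") - 1
        assert g[j] == pytest.approx(1.0)
        assert np.count_nonzero(g) == 1

    def test_sums_to_one(self, rng):
        for _ in range(5):
            frame = make_random_frame(rng, n_fil=int(rng.integers(2, 6)))
            assert radial_distribution(frame).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        beads = rng.uniform(0, 1900, size=(20, 3)) * np.array([1, 1, 0.1])
        frame = frame_of_beads(beads)
        g = radial_distribution(frame)
        edges = np.linspace(0, frame.domain.diagonal, 51)
        oracle = np.zeros(50)
        n = len(beads)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = np.linalg.norm(beads[i] - beads[j])
                for b in range(50):
                    lo, hi = edges[b], edges[b + 1]
                    if (lo <= d < hi) or (b == 49 and d == hi):
                        oracle[b] += 1
        oracle /= n * (n - 1)
        np.testing.assert_allclose(g, oracle, atol=1e-12)

    def test_too_few_beads_raise(self):
        with pytest.raises(ValueError):
            radial_distribution(Frame(time=0, filaments=[], motors=[], linkers=[]))


class TestMotorLocalization:
    def make_frame(self, centers):
        motors = [bound_motor(f"m{i}", c) for i, c in enumerate(centers)]
        return Frame(time=0, filaments=[], motors=motors, linkers=[])

    def test_central_motor_first_bin(self):
        counts = motor_localization(self.make_frame([[1000, 1000, 100]]))
        assert counts[0] == 1 and counts.sum() == 1

    def test_interval_lookup(self):
        counts = motor_localization(self.make_frame([[1600, 1000, 0]]))  # r = 600
        assert counts[2] == 1  # third annulus [500, 750)

    def test_outside_last_radius(self):
        counts = motor_localization(self.make_frame([[2000, 2000, 0]]))  # r ~ 1414
        assert counts[-1] == 1

    def test_diffusing_motors_excluded(self):
        frame = self.make_frame([[1000, 1000, 0]])
        frame.motors.append(
            MotorMinifilament(id="d", species="myosin", state="diffusing",
                              endpoints=np.zeros((2, 3)), n_heads=10)
        )
        counts = motor_localization(frame)
        assert counts.sum() == 1

    def test_counts_sum_to_bound(self, rng):
        centers = rng.uniform([0, 0, 0], [2000, 2000, 200], size=(25, 3))
        counts = motor_localization(self.make_frame(list(centers)))
        assert counts.sum() == 25

    def test_bad_radii(self):
        with pytest.raises(ValueError):
            motor_localization(self.make_frame([]), radii=[100, 200])


class TestMotorBoundaryArea:
    def test_domain_corners_cover_everything(self):
        pts = [[0, 0], [2000, 0], [2000, 2000], [0, 2000]]
        res = motor_boundary_area(pts, shrink=0.5)
        assert res.valid
        assert res.area_fraction == pytest.approx(1.0, abs=1e-9)

    def test_centered_square_quarter_area(self):
        pts = [[500, 500], [1500, 500], [1500, 1500], [500, 1500]]
        res = motor_boundary_area(pts, shrink=0.5)
        assert res.area_fraction == pytest.approx(0.25, abs=1e-9)

    def test_shrink_zero_is_convex_hull(self, rng):
        from scipy.spatial import ConvexHull

        for _ in range(20):
            pts = rng.uniform(0, 2000, size=(int(rng.integers(4, 40)), 2))
            res = motor_boundary_area(pts, shrink=0.0)
            hull_area = ConvexHull(pts).volume  # 2-D: volume is the area
            assert res.area_fraction * 4e6 == pytest.approx(hull_area, rel=1e-9)

    def test_monotone_in_shrink(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 2000, size=(30, 2))
            areas = [
                motor_boundary_area(pts, shrink=s).area_fraction
                for s in (0.0, 0.25, 0.5, 0.75, 1.0)
            ]
            assert all(a + 1e-12 >= b for a, b in zip(areas, areas[1:]))
            assert areas[-1] > 0

    def test_boundary_contains_all_points(self, rng):
        from shapely.geometry import Point

        pts = rng.uniform(0, 2000, size=(40, 2))
        poly = concave_boundary(pts, shrink=0.5)
        assert all(poly.distance(Point(*p)) < 1e-6 for p in pts)

    def test_degenerate_inputs_flagged(self):
        assert not motor_boundary_area([[0, 0], [1, 1]]).valid
        collinear = [[i, i] for i in range(5)]
        res = motor_boundary_area(collinear)
        assert not res.valid and res.area_fraction == 0.0


class TestSegregation:
    def test_identical_sets(self, rng):
        pts = rng.uniform(0, 2000, size=(15, 2))
        assert segregation_intersection(pts, pts).area_fraction == pytest.approx(1.0)
        assert segregation_centroid_distance(pts, pts).area_fraction == pytest.approx(0.0)

    def test_disjoint_squares(self):
        a = [[0, 0], [300, 0], [300, 300], [0, 300]]
        b = [[1500, 1500], [1900, 1500], [1900, 1900], [1500, 1900]]
        assert segregation_intersection(a, b).area_fraction == 0.0

    def test_two_overlapping_squares_one_seventh(self):
        a = [[0, 0], [2, 0], [2, 2], [0, 2]]
        b = [[1, 1], [3, 1], [3, 3], [1, 3]]
        assert segregation_intersection(a, b).area_fraction == pytest.approx(1 / 7)

    def test_intersection_matches_clipping_oracle(self, rng):
        """Convex-polygon intersection re-derived by Sutherland-Hodgman
        clipping + shoelace, an independent geometry path from shapely."""

        def clip(subject, clipper):
            def inside(p, a, b):
                return (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0]) >= -1e-12

            def intersect(p1, p2, a, b):
                dc = (a[0] - b[0], a[1] - b[1])
                dp = (p1[0] - p2[0], p1[1] - p2[1])
                n1 = a[0] * b[1] - a[1] * b[0]
                n2 = p1[0] * p2[1] - p1[1] * p2[0]
                den = dc[0] * dp[1] - dc[1] * dp[0]
                return ((n1 * dp[0] - n2 * dc[0]) / den, (n1 * dp[1] - n2 * dc[1]) / den)

            out = list(subject)
            for i in range(len(clipper)):
                a, b = clipper[i], clipper[(i + 1) % len(clipper)]
                src, out = out, []
                if not src:
                    break
                s = src[-1]
                for e in src:
                    if inside(e, a, b):
                        if not inside(s, a, b):
                            out.append(intersect(s, e, a, b))
                        out.append(e)
                    elif inside(s, a, b):
                        out.append(intersect(s, e, a, b))
                    s = e
            return out

        def shoelace(poly):
            x = np.array([p[0] for p in poly])
            y = np.array([p[1] for p in poly])
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        from scipy.spatial import ConvexHull

        for _ in range(20):
            a = rng.uniform(0, 1500, size=(10, 2))
            b = rng.uniform(500, 2000, size=(10, 2))
            # convex-hull polygons so the clipping oracle applies (shrink 0)
            res = segregation_intersection(a, b, shrink=0.0)
            ha = a[ConvexHull(a).vertices]
            hb = b[ConvexHull(b).vertices]
            inter = shoelace(clip([tuple(p) for p in ha], [tuple(p) for p in hb])) if len(
                clip([tuple(p) for p in ha], [tuple(p) for p in hb])
            ) >= 3 else 0.0
            union = shoelace(ha) + shoelace(hb) - inter
            assert res.area_fraction == pytest.approx(inter / union, abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 2000, size=(12, 2))
        b = rng.uniform(0, 2000, size=(12, 2))
        assert segregation_intersection(a, b).area_fraction == pytest.approx(
            segregation_intersection(b, a).area_fraction
        )
        assert segregation_centroid_distance(a, b).area_fraction == pytest.approx(
            segregation_centroid_distance(b, a).area_fraction
        )

    def test_centroid_distance_normalization(self):
        # centroids at (500, 1000) and (1500, 1000): distance 1000, L = 2000
        a = [[400, 900], [600, 900], [600, 1100], [400, 1100]]
        b = [[1400, 900], [1600, 900], [1600, 1100], [1400, 1100]]
        res = segregation_centroid_distance(a, b)
        assert res.area_fraction == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_flagged(self):
        a = [[0, 0], [1, 1]]
        b = [[0, 0], [10, 0], [10, 10], [0, 10]]
        assert not segregation_intersection(a, b).valid


class TestSampleActinPoints:
    def test_full_fraction_keeps_everything(self, rng, random_frame):
        pts = sample_actin_points(random_frame, fraction=1.0, rng=rng)
        assert len(pts) == len(random_frame.actin_beads())
        assert pts.shape[1] == 2

    def test_ceil_rounding(self, rng):
        beads = np.c_[np.linspace(100, 1000, 10), np.full(10, 500), np.full(10, 100)]
        frame = frame_of_beads(beads)
        pts = sample_actin_points(frame, fraction=0.3, rng=rng)
        assert len(pts) == 3  # ceil(0.3 * 10)

    def test_seeded_reproducibility(self, random_frame):
        a = sample_actin_points(random_frame, 0.3, np.random.default_rng(5))
        b = sample_actin_points(random_frame, 0.3, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_bad_fraction(self, rng, random_frame):
        with pytest.raises(ValueError):
            sample_actin_points(random_frame, fraction=0.0, rng=rng)


class TestThresholdCrossing:
    def series(self, vals, times=None):
        times = times if times is not None else list(range(0, 10 * len(vals), 10))[: len(vals)]
        return MeasureSeries(name="rg_norm", times=times, values=list(vals))

    def test_downward_crossing(self):
        s = self.series([1.0, 0.97, 0.94, 0.89], [0, 10, 20, 30])
        assert threshold_crossing_time(s, 0.10, "down") == 30

    def test_upward_crossing(self):
        s = self.series([1.0, 1.02, 1.06], [0, 10, 20])
        assert threshold_crossing_time(s, 0.05, "up") == 20

    def test_never_crossed(self):
        s = self.series([1.0, 0.99, 1.01])
        assert threshold_crossing_time(s, 0.05) is None

    def test_either_takes_earliest(self):
        s = self.series([1.0, 1.06, 0.9], [0, 10, 20])
        assert threshold_crossing_time(s, 0.05, "either") == 10

    def test_unnormalized_rejected(self):
        s = self.series([2.0, 1.0])
        with pytest.raises(ValueError):
            threshold_crossing_time(s, 0.05)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=4, max_value=25),
    seed=st.integers(min_value=0, max_value=2**20),
    shrink=st.floats(min_value=0.0, max_value=1.0),
)
def test_boundary_area_never_exceeds_hull(n, seed, shrink):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 2000, size=(n, 2))
    hull = motor_boundary_area(pts, shrink=0.0).area_fraction
    res = motor_boundary_area(pts, shrink=shrink)
    if res.valid:
        assert res.area_fraction <= hull + 1e-12


class TestMeasureAll:
    def test_single_frame_trajectory(self, rng):
        from actomyosim import Trajectory

        frame = make_random_frame(rng, n_fil=4)
        series = measure_all(Trajectory(frames=[frame], seed=1))
        names = {s.name for s in series}
        assert {"rg", "rg_norm", "order_param", "rdf", "motor_localization",
                "amot", "ripley_h_area"} <= names
        for s in series:
            assert len(s.values) == 1

    def test_degenerate_motor_measures_flagged_not_fatal(self, rng):
        from actomyosim import Trajectory

        frame = make_random_frame(rng, n_fil=3)
        frame.motors.extend([bound_motor("m0", [500, 500, 50]),
                             bound_motor("m1", [700, 500, 50])])
        series = measure_all(Trajectory(frames=[frame], seed=1))
        amot = next(s for s in series if s.name == "amot")
        assert not amot.valid[0]          # 2 motors cannot form a polygon
        rg = next(s for s in series if s.name == "rg")
        assert rg.valid[0]

    def test_table_shape(self, rng):
        from actomyosim import Trajectory

        frames = []
        for t in (0.0, 25.0):
            f = make_random_frame(rng, n_fil=3)
            f.time = t
            frames.append(f)
        table = measures_to_table(measure_all(Trajectory(frames=frames, seed=3)))
        assert set(table.columns) == {"seed", "time_s", "measure", "component",
                                      "value", "valid"}
        assert (table["seed"] == 3).all()
        assert len(table[table["measure"] == "rdf"]) == 2 * 50
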