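import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairstair import (
    LabeledPoint,
    Orientation,
    ORIENTATIONS,
    PairstairError,
    Region,
    StaircaseModel,
    UpperSetBoundary,
    enumerate_monotone_oracle,
    fit_best_orientation,
    fit_binary_upper_set,
    fit_multiclass_staircase,
)
from pairstair.oracle import enumerate_monotone_oracle_arrays
from pairstair.staircase import fit_staircase_arrays


def pts(*triples):
    return [LabeledPoint(*t) for t in triples]


class TestBinaryFit:
    def test_separable_two_points(self):
        fit = fit_binary_upper_set(pts((1, 1, 0), (2, 2, 1)))
        assert fit.error == 0
        assert fit.boundary.corners == ((2.0, 2.0),)
        assert list(fit.in_upper) == [False, True]

    def test_all_ones_whole_plane(self):
        fit = fit_binary_upper_set(pts((1, 1, 1), (2, 2, 1)))
        assert fit.error == 0
        assert fit.boundary.corners == ((-np.inf, -np.inf),)
        assert fit.boundary.contains(-1e9, -1e9)

    def test_all_zeros_empty_set(self):
        fit = fit_binary_upper_set(pts((1, 1, 0), (2, 2, 0)))
        assert fit.error == 0
        assert fit.boundary.corners == ()
        assert not fit.boundary.contains(1e9, 1e9)

    def test_incomparable_triple_matches_oracle(self):
        # (1,2) and (2,1) are incomparable with (1.5,1.5) under (+,+), so a
        # monotone upper set CAN separate them: the oracle-certified minimum
        # is 0.  Under (+,-) the three points form a chain and the minimum
        # is 1.
        points = pts((1, 2, 1), (2, 1, 1), (1.5, 1.5, 0))
        assert enumerate_monotone_oracle(points, 2) == 0
        assert fit_binary_upper_set(points).error == 0
        assert fit_binary_upper_set(points, orientation=Orientation(1, -1)).error == 1

    def test_weighted_conflict(self):
        points = pts((0, 0, 1, 2.0), (1, 1, 0, 1.0))
        fit = fit_binary_upper_set(points)
        assert fit.error == 1.0  # flip the cheaper (unit-weight) point
        assert list(fit.in_upper) == [True, True]

    def test_smallest_optimal_set_tie_break(self):
        # A single point labeled 0 and one labeled 1 at the same location:
        # both in or both out costs 1; the smallest optimal set is empty.
        fit = fit_binary_upper_set(pts((1, 1, 0), (1, 1, 1)))
        assert fit.error == 1.0
        assert fit.boundary.corners == ()

    def test_empty_input_rejected(self):
        with pytest.raises(PairstairError):
            fit_binary_upper_set([])

    def test_negative_weight_rejected(self):
        with pytest.raises(PairstairError):
            fit_binary_upper_set(pts((0, 0, 1, -1.0)))

    def test_nonbinary_label_rejected(self):
        with pytest.raises(PairstairError):
            fit_binary_upper_set(pts((0, 0, 2)))

    def test_region_must_contain(self):
        outer = UpperSetBoundary(((0.0, 0.0),))
        points = pts((1, 1, 0), (2, 2, 0))
        fit = fit_binary_upper_set(points, region=Region(outer=outer))
        assert fit.error == 2.0  # both points forced inside
        assert list(fit.in_upper) == [True, True]

    def test_region_within(self):
        inner = UpperSetBoundary(((10.0, 10.0),))
        points = pts((1, 1, 1), (2, 2, 1))
        fit = fit_binary_upper_set(points, region=Region(inner=inner))
        assert fit.error == 2.0  # both points outside the allowed region
        assert not fit.in_upper.any()


class TestMulticlass:
    def test_chain_three_classes(self):
        model = fit_multiclass_staircase(
            pts((1, 1, 0), (2, 2, 1), (3, 3, 2)), 3, Orientation(1, 1)
        )
        assert model.training_error == 0
        assert len(model.boundaries) == 2
        assert model.boundaries[1].issubset(model.boundaries[0])
        assert model.predict(1, 1) == 0
        assert model.predict(2, 2) == 1
        assert model.predict(3, 3) == 2

    def test_p2_reduces_to_binary(self, rng):
        for _ in range(20):
            n = rng.integers(2, 9)
            points = [
                LabeledPoint(*map(float, rng.integers(0, 4, 2)), int(rng.integers(0, 2)))
                for _ in range(n)
            ]
            model = fit_multiclass_staircase(points, 2, Orientation(1, 1))
            binary = fit_binary_upper_set(points)
            assert model.training_error == binary.error
            assert model.boundaries[0] == binary.boundary

    def test_oracle_equivalence_seeded(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 11))
            p = int(rng.integers(2, 4))
            x1 = rng.integers(0, 5, n).astype(float)
            x2 = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, p, n)
            w = rng.choice([1.0, 2.0], n)
            model, _ = fit_staircase_arrays(x1, x2, y, p, Orientation(1, 1), w)
            oracle = enumerate_monotone_oracle_arrays(x1, x2, y, p, w)
            assert model.training_error == pytest.approx(oracle, abs=1e-9)

    def test_error_decomposes_over_thresholds(self, rng):
        n, p = 20, 4
        x1 = rng.integers(0, 6, n).astype(float)
        x2 = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, p, n)
        model, _ = fit_staircase_arrays(x1, x2, y, p, Orientation(1, 1))
        per_threshold = []
        for t in range(1, p):
            collapsed = [
                LabeledPoint(a, b, int(c >= t)) for a, b, c in zip(x1, x2, y)
            ]
            per_threshold.append(fit_binary_upper_set(collapsed).error)
        assert model.training_error == pytest.approx(sum(per_threshold))

    def test_label_out_of_range(self):
        with pytest.raises(PairstairError):
            fit_multiclass_staircase(pts((0, 0, 3)), 3, Orientation(1, 1))

    def test_p_below_two(self):
        with pytest.raises(PairstairError):
            fit_multiclass_staircase(pts((0, 0, 0)), 1, Orientation(1, 1))


class TestPredict:
    def test_extremes(self, rng):
        n, p = 15, 3
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = np.sort(rng.integers(0, p, n))
        model, _ = fit_staircase_arrays(np.sort(x1), np.sort(x2), y, p, Orientation(1, 1))
        assert model.predict(100.0, 100.0) == p - 1
        assert model.predict(-100.0, -100.0) == 0

    def test_zero_error_model_reproduces_labels(self):
        x1 = np.array([0.0, 1, 2, 3, 4, 5])
        x2 = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([0, 0, 1, 1, 2, 2])
        model, _ = fit_staircase_arrays(x1, x2, y, 3, Orientation(1, 1))
        assert model.training_error == 0
        assert (model.predict(x1, x2) == y).all()

    def test_nonfinite_input_rejected(self):
        model = fit_multiclass_staircase(pts((0, 0, 0), (1, 1, 1)), 2, Orientation(1, 1))
        with pytest.raises(PairstairError):
            model.predict(np.nan, 0.0)


class TestOrientation:
    def test_signs_validated(self):
        with pytest.raises(PairstairError):
            Orientation(0, 1)

    def test_double_application_is_identity(self):
        for o in ORIENTATIONS:
            x1, x2 = o.apply(*o.apply(3.0, -2.0))
            assert (x1, x2) == (3.0, -2.0)

    def test_monotone_decreasing_second_axis(self):
        # label increases with x1 - x2 over a full grid, so only (+,-) can
        # reach zero error (an anti-diagonal alone would be incomparable
        # under every orientation and thus uninformative)
        points = []
        for x1 in range(4):
            for x2 in range(4):
                s = x1 - x2
                label = 0 if s < -1 else (1 if s < 1 else 2)
                points.append(LabeledPoint(float(x1), float(x2), label))
        orientation, model = fit_best_orientation(points, 3)
        assert orientation == Orientation(1, -1)
        assert model.training_error == 0

    def test_label_reversal_symmetry(self, rng):
        for _ in range(10):
            n, p = 12, 3
            x1 = rng.integers(0, 5, n).astype(float)
            x2 = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, p, n)
            _, m1 = fit_best_orientation(
                [LabeledPoint(a, b, int(c)) for a, b, c in zip(x1, x2, y)], p
            )
            _, m2 = fit_best_orientation(
                [LabeledPoint(-a, -b, int(p - 1 - c)) for a, b, c in zip(x1, x2, y)], p
            )
            assert m1.training_error == m2.training_error

    def test_minimum_matches_oracle_over_sign_flips(self, rng):
        for _ in range(15):
            n, p = int(rng.integers(2, 9)), int(rng.integers(2, 4))
            x1 = rng.integers(0, 4, n).astype(float)
            x2 = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, p, n)
            _, model = fit_best_orientation(
                [LabeledPoint(a, b, int(c)) for a, b, c in zip(x1, x2, y)], p
            )
            oracle_best = min(
                enumerate_monotone_oracle_arrays(o.s1 * x1, o.s2 * x2, y, p)
                for o in ORIENTATIONS
            )
            assert model.training_error == pytest.approx(oracle_best)


class TestSerialization:
    def test_round_trip(self, rng):
        n, p = 18, 3
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = rng.integers(0, p, n)
        model, _ = fit_staircase_arrays(x1, x2, y, p, Orientation(-1, 1))
        clone = StaircaseModel.from_json(model.to_json())
        assert clone == model
        grid = rng.normal(size=(2, 30))
        assert (clone.predict(grid[0], grid[1]) == model.predict(grid[0], grid[1])).all()

    def test_whole_plane_round_trip(self):
        model = fit_multiclass_staircase(pts((0, 0, 1), (1, 1, 1)), 2, Orientation(1, 1))
        clone = StaircaseModel.from_json(model.to_json())
        assert clone.boundaries[0].corners == ((-np.inf, -np.inf),)


coord = st.integers(min_value=-3, max_value=3)
point_list = st.lists(
    st.tuples(coord, coord, st.integers(min_value=0, max_value=2)),
    min_size=1,
    max_size=12,
)


@settings(max_examples=60, deadline=None)
@given(point_list, st.sampled_from(ORIENTATIONS), st.tuples(coord, coord, coord, coord))
def test_predict_is_monotone(raw, orientation, query):
    points = [LabeledPoint(float(a), float(b), c) for a, b, c in raw]
    model = fit_multiclass_staircase(points, 3, orientation)
    a1, a2, d1, d2 = query
    b1 = a1 + orientation.s1 * abs(d1)  # move weakly up in oriented coords
    b2 = a2 + orientation.s2 * abs(d2)
    assert model.predict(float(a1), float(a2)) <= model.predict(float(b1), float(b2))


@settings(max_examples=60, deadline=None)
@given(point_list)
def test_boundaries_are_nested_on_grids(raw):
    points = [LabeledPoint(float(a), float(b), c) for a, b, c in raw]
    model = fit_multiclass_staircase(points, 3, Orientation(1, 1))
    grid = np.linspace(-4, 4, 9)
    g1, g2 = np.meshgrid(grid, grid)
    inner = model.boundaries[1].contains(g1.ravel(), g2.ravel())
    outer = model.boundaries[0].contains(g1.ravel(), g2.ravel())
    assert not (inner & ~outer).any()
    assert model.boundaries[1].issubset(model.boundaries[0])


def test_antichain_enforced():
    with pytest.raises(PairstairError):
        UpperSetBoundary(((0.0, 0.0), (1.0, 1.0)))


def test_binary_fit_subsecond_at_n500(rng):
    import time

    x1 = rng.normal(size=500)
    x2 = rng.normal(size=500)
    y = rng.integers(0, 2, 500)
    points = [LabeledPoint(a, b, int(c)) for a, b, c in zip(x1, x2, y)]
    start = time.perf_counter()
    fit_binary_upper_set(points)
    assert time.perf_counter() - start < 1.0
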