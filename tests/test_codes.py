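"""Codebook construction and closed-form code geometry."""

from math import comb, sqrt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixedcodes import (
    CodeSpec,
    StimulusSpace,
    build_codebook,
    count_at_distance,
    distance_ratio,
    empirical_representation_energy,
    feature_neighbors,
    hamming_distance,
    min_distance,
    neighbors_at_min_distance,
    pairwise_distance,
    population_size,
    representation_energy,
)
from mixedcodes.errors import InvalidStimulusError, UnsupportedGeometryError

from conftest import brute_force_distances


class TestStimulusSpace:
    def test_enumeration_is_exhaustive_and_ordered(self):
        space = StimulusSpace(2, 4)
        stim = space.stimuli()
        assert stim.shape == (16, 2)
        assert len({tuple(s) for s in stim}) == 16
        # lexicographic: first feature most significant
        assert [space.index_of(s) for s in stim] == list(range(16))

    def test_single_feature_space(self):
        space = StimulusSpace(1, 3)
        assert space.stimuli().tolist() == [[0], [1], [2]]

    def test_invalid_stimuli_rejected(self):
        space = StimulusSpace(3, 2)
        with pytest.raises(InvalidStimulusError):
            space.index_of([0, 1, 2])
        with pytest.raises(InvalidStimulusError):
            space.index_of([0, 1])


class TestEncoding:
    @pytest.mark.parametrize(
        "order,stimulus,expected",
        [
            # one unit per (feature, value); stimulus (0,0,0) activates the
            # first unit of each single-feature block
            (1, (0, 0, 0), [1, 0, 1, 0, 1, 0]),
            (3, (1, 1, 1), [0, 0, 0, 0, 0, 0, 0, 1]),
        ],
    )
    def test_known_codewords(self, worked_space, order, stimulus, expected):
        cb = build_codebook(worked_space, CodeSpec(order))
        assert cb.encode(stimulus).tolist() == expected

    def test_full_order_code_is_one_hot(self, worked_space):
        cb = build_codebook(worked_space, CodeSpec(3))
        assert (cb.words.sum(axis=1) == 1).all()
        assert cb.words.shape == (8, 8)

    def test_all_codewords_distinct(self, small_spaces):
        for space in small_spaces:
            for order in range(1, space.n_features + 1):
                cb = build_codebook(space, CodeSpec(order))
                assert len({tuple(r) for r in cb.words}) == space.n_stimuli

    def test_constant_weight(self, small_spaces):
        """Every codeword has exactly C(K, O) active units."""
        for space in small_spaces:
            for order in range(1, space.n_features + 1):
                cb = build_codebook(space, CodeSpec(order))
                expected = comb(space.n_features, order)
                assert (cb.words.sum(axis=1) == expected).all()


class TestPopulationSize:
    @pytest.mark.parametrize("order,expected", [(1, 6), (2, 12), (3, 8)])
    def test_worked_example(self, worked_space, order, expected):
        spec = CodeSpec(order)
        assert population_size(worked_space, spec) == expected
        assert build_codebook(worked_space, spec).n_units == expected

    def test_rf_width_formula(self):
        space = StimulusSpace(3, 4)
        assert population_size(space, CodeSpec(2, rf_width=2)) == 3 * 2 * 3**2
        # order 1 unaffected by RF width
        assert population_size(space, CodeSpec(1, rf_width=2)) == 12

    def test_rf_width_must_divide_n(self):
        with pytest.raises(UnsupportedGeometryError):
            population_size(StimulusSpace(3, 5), CodeSpec(2, rf_width=2))


class TestRepresentationEnergy:
    def test_squared_distance_variant(self):
        space = StimulusSpace(3, 2)
        spec = CodeSpec(2, energy_variant="squared_distance")
        assert representation_energy(space, spec) == 3.0
        assert representation_energy(space, CodeSpec(3, energy_variant="squared_distance")) == 1.0

    def test_variance_variant(self):
        space = StimulusSpace(3, 5)
        spec = CodeSpec(2, energy_variant="variance")
        assert representation_energy(space, spec) == pytest.approx(3 * (1 - 5.0**-2))

    def test_formulas_match_codebook(self, small_spaces):
        for space in small_spaces:
            for order in range(1, space.n_features + 1):
                cb = build_codebook(space, CodeSpec(order))
                for variant in ("squared_distance", "variance", "sum_of_spikes"):
                    formula = representation_energy(
                        space, CodeSpec(order, energy_variant=variant)
                    )
                    measured = empirical_representation_energy(cb, variant)
                    assert measured == pytest.approx(formula), (space, order, variant)


class TestDistanceGeometry:
    def test_spectrum_matches_brute_force(self, small_spaces):
        """d(K, O, v) equals exhaustive pairwise distances for every pair
        class, and the formulaic minimum and neighbor counts match."""
        for space in small_spaces:
            K = space.n_features
            for order in range(1, K + 1):
                dist, stimuli = brute_force_distances(space, order)
                vdiff = (stimuli[:, None, :] != stimuli[None, :, :]).sum(axis=2)
                for v in range(1, K + 1):
                    vals = np.unique(np.round(dist[vdiff == v], 9))
                    assert vals.size == 1
                    assert vals[0] == pytest.approx(pairwise_distance(K, order, v))
                off = dist[~np.eye(dist.shape[0], dtype=bool)]
                assert off.min() == pytest.approx(min_distance(K, order))
                counts = np.isclose(dist, off.min()).sum(axis=1)
                assert (counts == neighbors_at_min_distance(space, order)).all()

    def test_full_order_distance_is_sqrt2(self):
        for K in (1, 2, 5, 8):
            assert pairwise_distance(K, K, K) == pytest.approx(sqrt(2))

    @pytest.mark.parametrize(
        "K,order,expected",
        [(3, 2, 2.0), (3, 1, sqrt(2)), (6, 4, sqrt(20))],
    )
    def test_min_distance_values(self, K, order, expected):
        assert min_distance(K, order) == pytest.approx(expected)

    @settings(deadline=None, max_examples=60)
    @given(K=st.integers(1, 10), order=st.integers(1, 10), v=st.integers(1, 10))
    def test_spectrum_monotone_in_v(self, K, order, v):
        """Distance is non-decreasing in the number of differing features
        and its minimum sits at v = 1, strictly so below full order.

        Plateaus do occur deeper in the spectrum (e.g. K=4, O=2 at v=3, 4),
        so strict growth is only asserted for the first step.
        """
        if order > K or v > K:
            return
        if v > 1:
            lo, hi = pairwise_distance(K, order, v - 1), pairwise_distance(K, order, v)
            assert hi >= lo - 1e-12
        if K > 1 and order < K:
            assert pairwise_distance(K, order, 2) > pairwise_distance(K, order, 1)

    @settings(deadline=None, max_examples=60)
    @given(K=st.integers(1, 12), order=st.integers(1, 12))
    def test_ratio_law_exact(self, K, order):
        """Squared minimum distance per unit energy is exactly 2O/K."""
        if order > K:
            return
        p = comb(K, order)
        assert min_distance(K, order) ** 2 / p == pytest.approx(2 * order / K)
        assert distance_ratio(K, order) == 2 * order / K

    def test_ratio_strictly_increasing_with_order(self):
        for K in (2, 4, 6):
            ratios = [distance_ratio(K, O) for O in range(1, K + 1)]
            assert all(b > a for a, b in zip(ratios, ratios[1:]))
        assert distance_ratio(5, 5) == 2.0

    def test_distance_symmetry_across_stimuli(self, small_spaces):
        """Every stimulus sees the same multiset of distances to the rest."""
        for space in small_spaces:
            for order in range(1, space.n_features + 1):
                cb = build_codebook(space, CodeSpec(order))
                dist = cb.pairwise_distances()
                profiles = {tuple(sorted(np.round(row, 9))) for row in dist}
                assert len(profiles) == 1


class TestNeighborCounts:
    def test_count_at_distance(self):
        space = StimulusSpace(3, 5)
        assert count_at_distance(space, 1) == 12
        assert sum(count_at_distance(space, v) for v in (1, 2, 3)) == 124
        assert count_at_distance(StimulusSpace(1, 2), 1) == 1

    def test_neighbors_at_min_distance(self):
        space = StimulusSpace(3, 5)
        assert neighbors_at_min_distance(space, 2) == 12
        assert neighbors_at_min_distance(space, 3) == 124
        assert neighbors_at_min_distance(StimulusSpace(1, 2), 1) == 1

    @pytest.mark.parametrize(
        "K,n,order,expected",
        [(2, 2, 1, 1), (2, 2, 2, 2), (4, 3, 4, 54), (3, 5, 2, 4)],
    )
    def test_feature_neighbors(self, K, n, order, expected):
        assert feature_neighbors(StimulusSpace(K, n), order) == expected


def test_hamming_distance_utility():
    assert hamming_distance([1, 0, 1, 0], [0, 1, 1, 0]) == 2
    with pytest.raises(ValueError):
        hamming_distance([1, 0], [1, 0, 0])


def test_codebook_exports(worked_space, tmp_path):
    cb = build_codebook(worked_space, CodeSpec(2))
    frame = cb.to_frame()
    assert frame.shape == (8, 12)
    path = tmp_path / "book.csv"
    frame.to_csv(path)
    assert path.exists()
    meta = cb.metadata()
    assert meta["n_units"] == 12 and meta["K"] == 3
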