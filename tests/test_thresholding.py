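"""Class histograms and the excess-mass cutoff search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemoct.errors import FitError
from hemoct.thresholding import (
    IntensityHistogram,
    ThresholdModel,
    apply_threshold,
    class_histogram,
    fit_threshold,
    fit_threshold_from_volumes,
    make_bin_edges,
)
from hemoct.volumes import Volume


def brute_force_fit(edges, mass_a, mass_b, delta):
    """Independent exhaustive search over every bin edge.

    Evaluates the retained excess-mass fraction at each edge directly and
    returns the largest edge still retaining >= 1 - delta, with that fraction.
    """
    d = np.maximum(np.asarray(mass_b) - np.asarray(mass_a), 0.0)
    total = np.sum(d)
    best = None
    for i in range(len(edges)):
        r = np.sum(d[i:]) / total
        if r >= 1.0 - delta:
            best = (edges[i], r)
    return best


def _hist(edges, mass, label=None):
    return IntensityHistogram(
        bin_edges=np.asarray(edges, float),
        mass=np.asarray(mass, float),
        class_label=label,
        n_volumes=1,
    )


class TestClassHistogram:
    def test_point_mass_single_value(self):
        v = Volume(np.full((4, 4, 4), 30.0), label="N")
        h = class_histogram([v], np.linspace(0, 100, 11), background=None)
        assert h.mass[3] == 1.0  # bin [30, 40)
        assert h.mass.sum() == pytest.approx(1.0)

    def test_equal_weight_average_of_two_volumes(self):
        # volume sizes differ: equal per-volume weight, not voxel pooling
        v1 = Volume(np.full((2, 2, 2), 10.0), label="N")
        v2 = Volume(np.full((6, 6, 6), 50.0), label="N")
        edges = np.linspace(0, 100, 6)
        h = class_histogram([v1, v2], edges, background=None)
        np.testing.assert_allclose(h.mass, [0.5, 0, 0.5, 0, 0])
        pooled = class_histogram([v1, v2], edges, background=None, per_volume=False)
        assert pooled.mass[0] == pytest.approx(8 / 224)

    def test_mass_normalized_on_random_volumes(self, rng):
        vols = [
            Volume(rng.uniform(1, 99, size=(5, 5, 5)), label="SAH") for _ in range(10)
        ]
        h = class_histogram(vols, np.linspace(0, 100, 257))
        assert abs(h.mass.sum() - 1.0) < 1e-9

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            class_histogram([], np.linspace(0, 1, 3))

    def test_out_of_range_intensity_named(self):
        v = Volume(np.full((2, 2, 2), 150.0), label="N")
        with pytest.raises(ValueError, match="150"):
            class_histogram([v], np.linspace(0, 100, 11))

    def test_mixed_labels_rejected(self):
        a = Volume(np.ones((2, 2, 2)), label="N")
        b = Volume(np.ones((2, 2, 2)), label="SAH")
        with pytest.raises(ValueError):
            class_histogram([a, b], np.linspace(0, 2, 3))


class TestFitThreshold:
    def test_worked_example_against_oracle(self):
        # frozen from brute_force_fit: excess of b over a sits in bins 2 and 3,
        # so the whole signal survives up to the edge of bin 2
        edges = [0.0, 1.0, 2.0, 3.0, 4.0]
        a = [0.5, 0.5, 0.0, 0.0]
        b = [0.5, 0.3, 0.1, 0.1]
        model = fit_threshold(_hist(edges, a), _hist(edges, b), delta=0.05)
        assert model.cutoff == 2.0
        assert model.retained_difference_fraction == 1.0
        assert brute_force_fit(edges, a, b, 0.05) == (2.0, 1.0)

    def test_top_bin_difference(self):
        edges = np.linspace(0, 4, 5)
        a = [0.4, 0.3, 0.2, 0.1]
        b = [0.4, 0.3, 0.2 - 0.1, 0.1 + 0.1]
        model = fit_threshold(_hist(edges, a), _hist(edges, b), delta=0.05)
        assert model.cutoff == 3.0
        assert model.retained_difference_fraction == 1.0

    def test_identical_histograms_raise_fit_error(self):
        edges = np.linspace(0, 4, 5)
        h = _hist(edges, [0.25] * 4)
        with pytest.raises(FitError, match="no discriminative"):
            fit_threshold(h, _hist(edges, [0.25] * 4))

    def test_mismatched_bins_rejected(self):
        a = _hist([0, 1, 2], [0.5, 0.5])
        b = _hist([0, 2, 4], [0.5, 0.5])
        with pytest.raises(ValueError, match="bin_edges"):
            fit_threshold(a, b)

    def test_oracle_agreement_random_pairs(self, rng):
        edges = np.linspace(0, 10, 17)
        for _ in range(200):
            a = rng.dirichlet(np.ones(16))
            b = rng.dirichlet(np.ones(16))
            delta = rng.uniform(0.01, 0.5)
            model = fit_threshold(_hist(edges, a), _hist(edges, b), delta)
            exp_cut, exp_r = brute_force_fit(edges, a, b, delta)
            assert model.cutoff == exp_cut
            assert model.retained_difference_fraction == exp_r

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_cutoff_monotone_nonincreasing_in_delta(self, seed):
        r = np.random.default_rng(seed)
        edges = np.linspace(0, 5, 11)
        a = r.dirichlet(np.ones(10))
        b = r.dirichlet(np.ones(10))
        cuts = [
            fit_threshold(_hist(edges, a), _hist(edges, b), d).cutoff
            for d in (0.02, 0.1, 0.3, 0.6)
        ]
        assert all(c1 <= c2 for c1, c2 in zip(cuts, cuts[1:]))

    def test_model_json_round_trip(self, tmp_path):
        edges = np.linspace(0, 4, 5)
        model = fit_threshold(
            _hist(edges, [0.5, 0.5, 0, 0], "N"), _hist(edges, [0.5, 0.3, 0.1, 0.1], "SAH")
        )
        p = tmp_path / "m.json"
        model.to_json(p)
        back = ThresholdModel.from_json(p)
        assert back.cutoff == model.cutoff
        assert back.class_pair == model.class_pair
        np.testing.assert_array_equal(back.bin_edges, model.bin_edges)


class TestApplyThreshold:
    @pytest.fixture
    def model(self):
        edges = np.linspace(0, 100, 11)
        return ThresholdModel(
            cutoff=50.0,
            retained_difference_fraction=1.0,
            delta=0.05,
            bin_edges=edges,
            class_pair=(None, None),
        )

    def test_no_voxel_below_cutoff_is_identity(self, model, rng):
        v = Volume(rng.uniform(60, 90, size=(4, 4, 4)))
        out = apply_threshold(v, model)
        np.testing.assert_array_equal(out.intensities, v.intensities)

    def test_all_below_cutoff_zeroes_volume(self, model, rng):
        v = Volume(rng.uniform(1, 49, size=(4, 4, 4)))
        assert np.all(apply_threshold(v, model).intensities == 0.0)

    def test_idempotent_and_never_increases(self, model, rng):
        v = Volume(rng.uniform(0, 100, size=(5, 5, 5)))
        once = apply_threshold(v, model)
        twice = apply_threshold(once, model)
        np.testing.assert_array_equal(once.intensities, twice.intensities)
        assert np.all(once.intensities <= v.intensities)
        assert once.shape == v.shape and once.spacing == v.spacing


def test_fit_from_volumes_disjoint_bands_lands_between():
    """Tissue at 30, blood at 70: the cutoff must separate the bands."""
    vols_a = [Volume(np.full((6, 6, 6), 30.0), label="N") for _ in range(4)]
    vols_b = []
    for _ in range(4):
        arr = np.full((6, 6, 6), 30.0)
        arr[:2, :2, :2] = 70.0
        vols_b.append(Volume(arr, label="ASDH"))
    model = fit_threshold_from_volumes(vols_a, vols_b, n_bins=64, background=None)
    assert 30.0 < model.cutoff <= 70.0


def test_make_bin_edges_spans_foreground_only():
    v = Volume(np.array([[[0.0, 20.0], [40.0, 0.0]]]))
    edges = make_bin_edges([v], n_bins=4)
    assert edges[0] == 20.0 and edges[-1] == 40.0
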