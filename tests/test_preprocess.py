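"""Tolerances, binning, filters and blank subtraction, each checked against a
brute-force oracle on random instances plus its boundary contracts."""

import math

import numpy as np
import pytest

from msiadducts.msi_io import IntensityMatrix, PeakList
from msiadducts.preprocess import (
    ToleranceModel,
    bin_peaks,
    filter_frequency,
    filter_intensity,
    filter_topn,
    pair_tolerance,
    single_tolerance,
    subtract_blank,
)


def random_instance(rng, n_peaks=None, n_pixels=8, mz_lo=100, mz_hi=1000):
    n_peaks = n_peaks or rng.integers(2, 60)
    mz = np.sort(rng.uniform(mz_lo, mz_hi, size=n_peaks))
    mz = mz[np.concatenate([[True], np.diff(mz) > 0])]
    coords = np.column_stack([np.arange(1, n_pixels + 1), np.ones(n_pixels, dtype=int)])
    values = rng.lognormal(2, 1, size=(mz.size, n_pixels)) * (rng.random((mz.size, n_pixels)) < 0.7)
    return IntensityMatrix(mz, coords, values)


class TestTolerances:
    def test_linear_pair_tolerance(self):
        t = ToleranceModel(ppm=5, mode="linear")
        assert pair_tolerance(t, 1000, 1000) == pytest.approx(0.01)

    def test_quadrature_pair_tolerance(self):
        t = ToleranceModel(ppm=5, mode="quadrature")
        assert pair_tolerance(t, 1000, 1000) == pytest.approx(0.00707, abs=1e-5)

    def test_quadrature_tighter_than_linear(self):
        q = ToleranceModel(ppm=5, mode="quadrature")
        l = ToleranceModel(ppm=5, mode="linear")
        for ma, mb in [(100, 200), (500, 636), (900, 1000)]:
            assert pair_tolerance(q, ma, mb) < pair_tolerance(l, ma, mb)

    def test_single_tolerance_linearity(self):
        t = ToleranceModel(ppm=5)
        assert single_tolerance(t, 200) == pytest.approx(0.001)
        assert single_tolerance(t, 400) == pytest.approx(2 * single_tolerance(t, 200))
        assert single_tolerance(t, 0) == 0

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            ToleranceModel(ppm=0)
        with pytest.raises(ValueError):
            ToleranceModel(ppm=5, mode="cubic")


def brute_force_bin_labels(mz, width_fn):
    """Single-linkage merge: consecutive peaks closer than the width chain up."""
    labels = [0]
    for i in range(1, len(mz)):
        if mz[i] - mz[i - 1] < width_fn(mz[i - 1]):
            labels.append(labels[-1])
        else:
            labels.append(labels[-1] + 1)
    return np.array(labels)


class TestBinPeaks:
    def test_inside_width_merges(self):
        m = IntensityMatrix(np.array([500.0000, 500.0020]), np.array([[1, 1]]), np.ones((2, 1)))
        assert bin_peaks(m, ppm=5).n_peaks == 1

    def test_outside_width_stays(self):
        m = IntensityMatrix(np.array([500.0000, 500.0100]), np.array([[1, 1]]), np.ones((2, 1)))
        assert bin_peaks(m, ppm=5).n_peaks == 2

    def test_merged_mz_is_weighted_centroid(self):
        m = IntensityMatrix(
            np.array([500.0000, 500.0020]), np.array([[1, 1]]), np.array([[1.0], [3.0]])
        )
        out = bin_peaks(m, ppm=5)
        assert out.mz[0] == pytest.approx((500.0 * 1 + 500.002 * 3) / 4, abs=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, rng, trial):
        rng = np.random.default_rng(rng.integers(2**31) + trial)
        base = np.sort(rng.uniform(100, 1000, size=200))
        # clump some peaks tightly so merging actually happens
        mz = np.sort(np.concatenate([base, base[:50] + rng.uniform(0, 3e-3, 50)]))
        mz = mz[np.concatenate([[True], np.diff(mz) > 0])]
        values = rng.lognormal(0, 1, size=(mz.size, 4))
        m = IntensityMatrix(mz, np.array([[x, 1] for x in range(1, 5)]), values)
        out = bin_peaks(m, ppm=5)
        labels = brute_force_bin_labels(mz, lambda x: 5e-6 * x)
        assert out.n_peaks == labels[-1] + 1
        totals = values.sum(axis=1)
        for b in range(out.n_peaks):
            sel = labels == b
            expected = np.average(mz[sel], weights=totals[sel])
            assert out.mz[b] == pytest.approx(expected, abs=1e-9)
            np.testing.assert_allclose(out.values[b], values[sel].sum(axis=0))

    def test_conserves_total_intensity_per_pixel(self, random_matrix):
        out = bin_peaks(random_matrix, mda=50.0)
        np.testing.assert_allclose(
            out.values.sum(axis=0), random_matrix.values.sum(axis=0), rtol=1e-12
        )

    def test_argument_validation(self, small_matrix):
        with pytest.raises(ValueError):
            bin_peaks(small_matrix)
        with pytest.raises(ValueError):
            bin_peaks(small_matrix, ppm=-1)
        with pytest.raises(ValueError):
            bin_peaks(small_matrix, ppm=5, mda=1)


class TestFilters:
    def test_intensity_boundary_kept(self):
        values = np.array([[1e6, 0.0], [500.0, 0.0], [499.0, 0.0]])
        m = IntensityMatrix(np.array([100.0, 200.0, 300.0]), np.array([[1, 1], [2, 1]]), values)
        out = filter_intensity(m, 5e-4)
        assert out.mz.tolist() == [100.0, 200.0]  # 500 == threshold is kept

    def test_intensity_fraction_near_one_keeps_only_max(self, random_matrix):
        out = filter_intensity(random_matrix, 1 - 1e-12)
        assert out.n_peaks == 1

    def test_frequency_ceiling(self):
        # 100 pixels, 1% -> need ceil(1) = 1 pixel; 1000 pixels -> need 10
        coords100 = np.column_stack([np.arange(1, 101), np.ones(100, dtype=int)])
        v = np.zeros((1, 100)); v[0, 0] = 1.0
        m = IntensityMatrix(np.array([100.0]), coords100, v)
        assert filter_frequency(m, 0.01).n_peaks == 1
        coords1000 = np.column_stack([np.arange(1, 1001), np.ones(1000, dtype=int)])
        v = np.zeros((1, 1000)); v[0, :9] = 1.0
        m = IntensityMatrix(np.array([100.0]), coords1000, v)
        assert filter_frequency(m, 0.01).n_peaks == 0

    def test_frequency_zero_is_identity(self, random_matrix):
        out = filter_frequency(random_matrix, 0.0)
        np.testing.assert_array_equal(out.mz, random_matrix.mz)

    def test_topn_identity_when_n_large(self, random_matrix):
        out = filter_topn(random_matrix, random_matrix.n_peaks)
        np.testing.assert_array_equal(out.mz, random_matrix.mz)

    def test_topn_single_peak(self, random_matrix):
        out = filter_topn(random_matrix, 1)
        best = random_matrix.mz[np.argmax(random_matrix.values.sum(axis=1))]
        assert out.mz[0] == best

    @pytest.mark.parametrize("trial", range(10))
    def test_topn_matches_brute_force(self, rng, trial):
        rng = np.random.default_rng(rng.integers(2**31) + trial)
        m = random_instance(rng, n_peaks=50)
        n = int(rng.integers(1, 50))
        out = filter_topn(m, n)
        totals = m.values.sum(axis=1)
        keep = sorted(range(m.n_peaks), key=lambda i: (-totals[i], m.mz[i]))[:n]
        np.testing.assert_array_equal(out.mz, m.mz[np.sort(keep)])

    def test_topn_tie_prefers_lower_mz(self):
        m = IntensityMatrix(
            np.array([100.0, 200.0]), np.array([[1, 1]]), np.array([[5.0], [5.0]])
        )
        assert filter_topn(m, 1).mz.tolist() == [100.0]

    @pytest.mark.parametrize(
        "op",
        [
            lambda m: filter_intensity(m, 0.01),
            lambda m: filter_frequency(m, 0.25),
            lambda m: filter_topn(m, 20),
            lambda m: bin_peaks(m, ppm=20),
        ],
    )
    def test_idempotence(self, random_matrix, op):
        once = op(random_matrix)
        twice = op(once)
        np.testing.assert_array_equal(once.mz, twice.mz)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_filters_commute_with_pixel_reordering(self, random_matrix, rng):
        perm = rng.permutation(random_matrix.n_pixels)
        shuffled = IntensityMatrix(
            random_matrix.mz, random_matrix.coords[perm], random_matrix.values[:, perm]
        )
        a = filter_intensity(random_matrix, 0.01)
        b = filter_intensity(shuffled, 0.01)
        np.testing.assert_array_equal(a.mz, b.mz)


class TestSubtractBlank:
    def test_simple_removal(self):
        sample = PeakList(np.array([100.0, 200.0]), np.array([1.0, 1.0]))
        blank = PeakList(np.array([200.00005]), np.array([1.0]))
        out, rep = subtract_blank(sample, blank, ToleranceModel(ppm=5))
        assert out.mz.tolist() == [100.0]
        assert rep.n_removed == 1 and rep.n_kept == 1
        assert rep.matched_blank_mz.tolist() == [200.00005]

    def test_empty_blank_is_identity(self, peaklist):
        out, rep = subtract_blank(peaklist, PeakList(np.empty(0), np.empty(0)), ToleranceModel())
        assert rep.n_removed == 0
        np.testing.assert_array_equal(out.mz, peaklist.mz)

    def test_counts_partition_input(self, rng):
        sample = PeakList(np.sort(rng.uniform(100, 1000, 80)), np.ones(80))
        blank = PeakList(np.sort(rng.uniform(100, 1000, 30)), np.ones(30))
        out, rep = subtract_blank(sample, blank, ToleranceModel(ppm=200))
        assert rep.n_removed + rep.n_kept == sample.n_peaks

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force(self, rng, trial):
        rng = np.random.default_rng(rng.integers(2**31) + trial)
        t = ToleranceModel(ppm=float(rng.uniform(5, 500)))
        base = np.sort(rng.uniform(100, 1000, 60))
        sample = PeakList(base, np.ones(60))
        # half the blank overlaps sample masses with small offsets
        blank_mz = np.sort(np.concatenate([
            base[rng.choice(60, 20, replace=False)] + rng.normal(0, 1e-4, 20),
            rng.uniform(100, 1000, 15),
        ]))
        blank = PeakList(blank_mz, np.ones(blank_mz.size))
        out, rep = subtract_blank(sample, blank, t)
        expected_removed = np.array([
            any(abs(s - b) <= t.p * s for b in blank_mz) for s in base
        ])
        np.testing.assert_array_equal(out.mz, base[~expected_removed])
        assert rep.n_removed == expected_removed.sum()

    def test_output_rematches_nothing(self, rng):
        t = ToleranceModel(ppm=50)
        sample = PeakList(np.sort(rng.uniform(100, 1000, 100)), np.ones(100))
        blank = PeakList(np.sort(rng.uniform(100, 1000, 40)), np.ones(40))
        out, _ = subtract_blank(sample, blank, t)
        _, rep2 = subtract_blank(out, blank, t)
        assert rep2.n_removed == 0

    def test_matrix_input_drops_rows(self, small_matrix):
        blank = PeakList(np.array([150.0]), np.array([1.0]))
        out, rep = subtract_blank(small_matrix, blank, ToleranceModel(ppm=5))
        assert rep.n_removed == 1
        assert 150.0 not in out.mz
        assert out.values.shape == (3, 6)
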