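"""Free-energy landscape: histogram conventions, lookups, correction arithmetic."""

import math

import numpy as np
import pytest

from felbind.colvars import CVSample
from felbind.errors import EmptyInputError, OutOfLandscapeError, ValidationError
from felbind.landscape import (
    apply_correction,
    basin_gap,
    build_fel,
    correction_term,
    lookup,
    tail_conformations,
)
from felbind.synthetic import two_basin_cv

KT = 0.5922


def _samples(points):
    return [CVSample(time=10.0 * i, rg=x, rmsd=y)
            for i, (x, y) in enumerate(points)]


class TestBuildFel:
    def test_single_occupied_bin_is_zero_rest_flagged(self):
        fel = build_fel(_samples([(1.0, 0.2)] * 50), n_bins=(4, 4), kT=KT)
        occ = fel.occupied
        assert occ.sum() == 1
        assert fel.g[occ][0] == 0.0
        assert np.all(np.isnan(fel.g[~occ]))

    def test_equal_counts_give_flat_landscape(self):
        # four well-separated clusters, equal population
        pts = [(0.1, 0.1), (0.1, 0.9), (0.9, 0.1), (0.9, 0.9)] * 25
        fel = build_fel(_samples(pts), n_bins=(2, 2), kT=KT, pad_bins=0)
        assert np.nanmax(np.abs(fel.g)) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_is_zero_and_g_nonnegative(self):
        fel = build_fel(two_basin_cv(n=5000, seed=0), kT=KT)
        vals = fel.g[fel.occupied]
        assert vals.min() == 0.0
        assert np.all(vals >= 0.0)

    def test_two_basin_gap_recovers_population_ratio(self):
        # p = 0.8 / 0.2 -> gap of kT ln 4, read off matched basin blocks
        samples = two_basin_cv(populations=(0.8, 0.2), n=100_000, seed=3)
        fel = build_fel(samples, n_bins=(60, 60), kT=KT)
        gap = basin_gap(fel, CVSample(0, 1.10, 0.15), CVSample(0, 1.30, 0.45))
        assert gap == pytest.approx(KT * math.log(4.0), rel=0.03)

    def test_rebuild_is_bit_identical(self):
        samples = two_basin_cv(n=2000, seed=5)
        a = build_fel(samples, n_bins=(20, 20), kT=KT)
        b = build_fel(samples, n_bins=(20, 20), kT=KT)
        assert np.array_equal(a.g, b.g, equal_nan=True)
        assert np.array_equal(a.rg_edges, b.rg_edges)

    def test_uniform_extra_counts_shift_is_bounded_and_sign_consistent(self):
        samples = two_basin_cv(n=20_000, seed=7)
        fel = build_fel(samples, n_bins=(20, 20), kT=KT)
        extra = 5
        counts = fel.counts.copy()
        counts[fel.occupied] += extra
        with np.errstate(divide="ignore"):
            g2 = -KT * np.log(counts / counts.max())
        delta = g2[fel.occupied] - fel.g[fel.occupied]
        # regularisation compresses the landscape: deltas all <= 0, bounded
        assert np.all(delta <= 1e-12)
        assert np.all(np.abs(delta) <= KT * np.log(1 + extra))

    def test_separable_distribution_fel_is_sum_of_1d_profiles(self, rng):
        n = 100_000
        x = rng.normal(1.0, 0.05, n)
        y = rng.normal(0.3, 0.03, n)
        nb = 12
        fel = build_fel(np.column_stack([x, y]), n_bins=(nb, nb), kT=KT, pad_bins=0)
        cx, ex = np.histogram(x, bins=fel.rg_edges)
        cy, ey = np.histogram(y, bins=fel.rmsd_edges)
        gx = -KT * np.log(cx / cx.max())
        gy = -KT * np.log(cy / cy.max())
        # compare on well-populated bins only (counts large enough for 5%)
        for i in range(nb):
            for j in range(nb):
                if fel.counts[i, j] > 200:
                    assert fel.g[i, j] == pytest.approx(
                        gx[i] + gy[j], abs=0.05 * max(fel.g[i, j], KT))

    def test_bad_inputs_rejected(self):
        with pytest.raises(EmptyInputError):
            build_fel([], kT=KT)
        with pytest.raises(ValidationError):
            build_fel(_samples([(1, 1)]), n_bins=(1, 5), kT=KT)
        with pytest.raises(ValidationError):
            build_fel(_samples([(1, 1)]), kT=-1.0)


class TestLookup:
    @pytest.fixture
    def toy_fel(self):
        # 3x3 interior grid: heavy corner, light opposite corner
        pts = [(0.05, 0.05)] * 8 + [(0.25, 0.25)] * 2
        return build_fel(_samples(pts), n_bins=(3, 3), kT=1.0, pad_bins=0)

    def test_global_minimum_bin_is_zero(self, toy_fel):
        assert lookup(toy_fel, CVSample(0, 0.05, 0.05)) == 0.0

    def test_occupied_minor_bin_value(self, toy_fel):
        assert lookup(toy_fel, CVSample(0, 0.25, 0.25)) == pytest.approx(
            math.log(4.0), abs=1e-12)

    def test_interior_empty_bin_takes_nearest_occupied(self, toy_fel):
        # centre bin (1,1) is empty; both occupied bins are sqrt(2) away,
        # argmin takes the first in scan order: the (0,0) minimum
        val = lookup(toy_fel, CVSample(0, 0.15, 0.15), policy="nearest_occupied")
        assert val == 0.0

    def test_empty_bin_nearest_is_minor_basin_when_closer(self, toy_fel):
        # bin (2,1) is empty; nearest occupied is (2,2) at distance 1
        val = lookup(toy_fel, CVSample(0, 0.25, 0.15))
        assert val == pytest.approx(math.log(4.0), abs=1e-12)

    def test_outside_grid_clips_then_nearest(self, toy_fel):
        assert lookup(toy_fel, CVSample(0, 5.0, 5.0)) == pytest.approx(
            math.log(4.0), abs=1e-12)

    def test_policy_error_raises(self, toy_fel):
        with pytest.raises(OutOfLandscapeError):
            lookup(toy_fel, CVSample(0, 0.15, 0.15), policy="error")
        with pytest.raises(OutOfLandscapeError):
            lookup(toy_fel, CVSample(0, 5.0, 5.0), policy="error")


class TestCorrection:
    @pytest.fixture
    def fel(self):
        pts = [(0.05, 0.05)] * 8 + [(0.25, 0.25)] * 2
        return build_fel(_samples(pts), n_bins=(3, 3), kT=1.0, pad_bins=0)

    def test_all_at_minimum_mean_and_sem_zero(self, fel):
        confs = [CVSample(0, 0.05, 0.05)] * 5
        res = correction_term(fel, confs)
        assert res.mean == 0.0 and res.sem == 0.0

    def test_hand_arithmetic_mean_and_sem(self):
        # three clusters with counts 8:4:2 and kT = 1/ln 2 give exact bin
        # free energies 0, 1 and 2; conformations sample {1,1,1,1,2}
        pts = [(0.05, 0.05)] * 8 + [(0.45, 0.05)] * 4 + [(0.85, 0.05)] * 2
        fel = build_fel(_samples(pts), n_bins=(3, 2), kT=1.0 / math.log(2.0),
                        pad_bins=0)
        mid, high = CVSample(0, 0.45, 0.05), CVSample(0, 0.85, 0.05)
        res = correction_term(fel, [mid, mid, mid, mid, high])
        assert res.per_conformation == pytest.approx([1, 1, 1, 1, 2], abs=1e-12)
        assert res.mean == pytest.approx(1.2, abs=1e-12)
        assert res.sem == pytest.approx(0.2, abs=1e-12)

    def test_minor_basin_conformations_recover_population_gap(self):
        samples = two_basin_cv(populations=(0.8, 0.2), n=100_000, seed=11)
        fel = build_fel(samples, n_bins=(60, 60), kT=KT)
        confs = [CVSample(0, 1.30 + dx, 0.45 + dy)
                 for dx, dy in ((0, 0), (0.004, 0), (-0.004, 0.004),
                                (0, -0.004), (0.004, 0.004))]
        res = correction_term(fel, confs)
        assert res.mean == pytest.approx(KT * math.log(4.0), abs=0.15)

    def test_empty_conformations_rejected(self, fel):
        with pytest.raises(EmptyInputError):
            correction_term(fel, [])


class TestApplyCorrection:
    def test_published_rows(self):
        # two benchmark rows: the correction shifts the raw estimate upward
        dg, _ = apply_correction(-17.05, 1.04)
        assert dg == pytest.approx(-16.01, abs=1e-12)
        dg, _ = apply_correction(-12.52, 1.66)
        assert dg == pytest.approx(-10.86, abs=1e-12)

    def test_zero_correction_is_identity(self):
        dg, err = apply_correction(-9.5, 0.0)
        assert dg == -9.5 and err is None

    def test_quadrature_error_combination(self):
        from felbind.landscape import CorrectionResult
        corr = CorrectionResult(mean=1.0, sem=0.3, per_conformation=[1.0])
        dg, err = apply_correction(-10.0, corr, dg_stderr=0.4)
        assert dg == pytest.approx(-9.0)
        assert err == pytest.approx(0.5)


class TestTailConformations:
    def test_five_evenly_strided_from_last_100ps(self):
        series = [CVSample(float(t), 1.0, 0.1) for t in range(0, 1001, 10)]
        tail = tail_conformations(series, n=5, window=100.0)
        assert len(tail) == 5
        assert [s.time for s in tail] == [900.0, 920.0, 950.0, 980.0, 1000.0]
        assert all(s.time >= 900.0 for s in tail)

    def test_short_series_returned_whole(self):
        series = [CVSample(float(t), 1.0, 0.1) for t in (0.0, 10.0, 20.0)]
        assert tail_conformations(series, n=5, window=100.0) == series
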