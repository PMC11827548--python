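"""Behavioral statistics, bin-by-bin scans and Rüger-area correction."""

import numpy as np
import pandas as pd
import pytest

from caninesleep.stats import (
    PValueGrid,
    binwise_scan,
    cueing_benefit,
    latency_reduction,
    relative_latency_reduction,
    ruger_areas,
)


def trials_frame(rows):
    return pd.DataFrame(rows, columns=["dog_id", "phase", "trial_index", "cue_class", "correct", "latency_s"])


def make_trials(base_cued, test_cued, base_lat=None, test_lat=None):
    """Build a one-dog trials table from per-trial (correct, latency) specs."""
    rows = []
    for i, c in enumerate(base_cued):
        lat = base_lat[i] if base_lat else 5.0
        rows.append(("d0", "baseline", i + 1, "cued_left", c, lat))
    for i, c in enumerate(test_cued):
        lat = test_lat[i] if test_lat else 5.0
        rows.append(("d0", "test", i + 1, "cued_left", c, lat))
    return trials_frame(rows)


class TestCueingBenefit:
    def test_worked_example(self):
        t = make_trials([1, 1, 0, 0, 0], [1, 1, 1, 1, 0])
        assert cueing_benefit(t) == pytest.approx(0.4)

    def test_identity_and_extreme(self):
        assert cueing_benefit(make_trials([1, 0], [0, 1])) == 0.0
        assert cueing_benefit(make_trials([0, 0], [1, 1])) == 1.0

    def test_uncued_trials_ignored(self):
        t = make_trials([0, 0], [1, 1])
        extra = trials_frame([("d0", "baseline", 3, "uncued_right", 1, 5.0),
                              ("d0", "test", 3, "center", 0, 5.0)])
        assert cueing_benefit(pd.concat([t, extra])) == 1.0

    def test_missing_phase_gives_nan(self):
        t = trials_frame([("d0", "baseline", 1, "center", 1, 5.0),
                          ("d0", "test", 1, "cued_left", 1, 5.0)])
        assert np.isnan(cueing_benefit(t))


class TestLatencyReduction:
    def test_ratio_directions(self):
        t = make_trials([1, 1], [1, 1], base_lat=[6.0, 6.0], test_lat=[3.0, 3.0])
        assert latency_reduction(t, 1) == pytest.approx(2.0)
        t2 = make_trials([1], [1], base_lat=[3.0], test_lat=[6.0])
        assert latency_reduction(t2, 1) == pytest.approx(0.5)
        assert latency_reduction(make_trials([1], [1]), 1) == pytest.approx(1.0)

    def test_relative_reduction_and_scale_invariance(self):
        rows = [("d0", "baseline", 1, "cued_left", 1, 6.0),
                ("d0", "baseline", 2, "cued_left", 0, 5.0),
                ("d0", "test", 1, "cued_left", 1, 3.0),
                ("d0", "test", 2, "cued_left", 0, 4.0)]
        t = trials_frame(rows)
        assert relative_latency_reduction(t) == pytest.approx((6 / 3) / (5 / 4))
        t3 = t.assign(latency_s=t["latency_s"] * 7.3)
        assert relative_latency_reduction(t3) == pytest.approx(
            relative_latency_reduction(t)
        )

    def test_known_reductions_give_1_6(self):
        rows = [("d0", "baseline", 1, "cued_left", 1, 2.0),
                ("d0", "baseline", 2, "cued_left", 0, 1.25),
                ("d0", "test", 1, "cued_left", 1, 1.0),
                ("d0", "test", 2, "cued_left", 0, 1.0)]
        assert relative_latency_reduction(trials_frame(rows)) == pytest.approx(1.6)

    def test_missing_class_gives_nan(self):
        t = make_trials([1, 1], [1, 1])  # no incorrect trials at all
        assert np.isnan(relative_latency_reduction(t))


class TestBinwiseScan:
    def grid(self, n_bins=6):
        return [1.0 + 0.25 * i for i in range(n_bins)]

    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        freqs = self.grid()
        spectra = pd.DataFrame(rng.random((8, len(freqs))), columns=freqs)
        outcome = 3.0 * spectra[freqs[2]] + 1.0
        g = binwise_scan(spectra, outcome)
        assert g.r_values[2] == pytest.approx(1.0)
        assert g.p_values[2] < 1e-6
        assert np.all(g.n == 8)

    def test_sign_flip_negates_r(self):
        rng = np.random.default_rng(1)
        freqs = self.grid()
        spectra = pd.DataFrame(rng.random((10, len(freqs))), columns=freqs)
        outcome = pd.Series(rng.random(10), index=spectra.index)
        g1 = binwise_scan(spectra, outcome)
        g2 = binwise_scan(spectra, -outcome)
        assert np.allclose(g1.r_values, -g2.r_values)
        assert np.allclose(g1.p_values, g2.p_values)

    def test_missing_subjects_excluded_binwise(self):
        rng = np.random.default_rng(2)
        freqs = self.grid()
        spectra = pd.DataFrame(rng.random((8, len(freqs))), columns=freqs)
        spectra.iloc[0, 3] = np.nan
        outcome = pd.Series(rng.random(8), index=spectra.index)
        g = binwise_scan(spectra, outcome)
        assert g.n[3] == 7 and g.n[0] == 8

    def test_zero_variance_bin_is_nan(self):
        rng = np.random.default_rng(3)
        freqs = self.grid()
        spectra = pd.DataFrame(rng.random((6, len(freqs))), columns=freqs)
        spectra[freqs[1]] = 0.5
        g = binwise_scan(spectra, pd.Series(rng.random(6), index=spectra.index))
        assert np.isnan(g.r_values[1]) and np.isnan(g.p_values[1])

    def test_too_few_subjects_rejected(self):
        freqs = self.grid()
        spectra = pd.DataFrame(np.random.default_rng(0).random((3, len(freqs))), columns=freqs)
        with pytest.raises(ValueError):
            binwise_scan(spectra, pd.Series([1.0, 2.0, 3.0], index=spectra.index))


def brute_force_ruger(p_values, alpha=0.05):
    """Independent oracle: explicit run-finding + counting."""
    areas = []
    run = []
    for i, p in enumerate(list(p_values) + [np.nan]):
        if not np.isnan(p) and p < alpha:
            run.append((i, p))
        elif run:
            ps = [x for _, x in run]
            n = len(ps)
            n_half = sum(1 for x in ps if x < alpha / 2)
            n_third = sum(1 for x in ps if x < alpha / 3)
            areas.append((run[0][0], run[-1][0], n, n_half >= n / 2 and n_third >= n / 3))
            run = []
    return areas


class TestRugerAreas:
    def test_worked_examples(self):
        a = ruger_areas(p_values=[0.2, 0.01, 0.01, 0.04, 0.2])
        assert len(a) == 1
        assert (a[0].n_bins, a[0].n_below_half_alpha, a[0].n_below_third_alpha) == (3, 2, 2)
        assert a[0].significant

        b = ruger_areas(p_values=[0.2, 0.04, 0.04, 0.2])
        assert len(b) == 1 and b[0].n_bins == 2 and not b[0].significant

        c = ruger_areas(p_values=[0.01])
        assert len(c) == 1 and c[0].n_bins == 1 and c[0].significant

    def test_no_significant_bins(self):
        assert ruger_areas(p_values=[0.9, 0.5, 0.06]) == []

    def test_areas_cover_exactly_significant_bins(self):
        rng = np.random.default_rng(4)
        p = rng.random(117)
        freqs = 1.0 + 0.25 * np.arange(117)
        areas = ruger_areas(p_values=p, bin_freqs=freqs)
        covered = set()
        for a in areas:
            lo = int(round((a.start_freq - 1.0) / 0.25))
            hi = int(round((a.end_freq - 1.0) / 0.25))
            covered |= set(range(lo, hi + 1))
        assert covered == set(np.nonzero(p < 0.05)[0])

    @pytest.mark.parametrize("scale", [1.0, 0.1])
    def test_matches_brute_force_oracle(self, scale):
        """Implementation agrees with an independent run-finder + counter on
        random p-vectors of length 117 (including many boundary p-values)."""
        rng = np.random.default_rng(7)
        for _ in range(250):
            p = rng.random(117) * scale
            got = [
                (int(round((a.start_freq - 1.0) / 0.25)),
                 int(round((a.end_freq - 1.0) / 0.25)),
                 a.n_bins, a.significant)
                for a in ruger_areas(p_values=p, bin_freqs=1.0 + 0.25 * np.arange(117))
            ]
            assert got == brute_force_ruger(p)
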