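"""Synthetic-study generator: determinism, ground truth, study structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, sosfiltfilt

from caninesleep.hypnogram import DROWSINESS, NREM, REM, WAKE, Hypnogram
from caninesleep.simulate import (
    BAIT_BLOCKS,
    DEFAULT_DWELL_MIN,
    DEFAULT_TRANSITIONS,
    SimParams,
    SimulationError,
    gen_behavior,
    gen_eeg,
    gen_hypnogram,
    gen_study,
)
from conftest import small_params


class TestGenHypnogram:
    def test_determinism(self):
        p = SimParams(recording_minutes=30)
        assert gen_hypnogram(p, 9).labels == gen_hypnogram(p, 9).labels
        assert gen_hypnogram(p, 9).labels != gen_hypnogram(p, 10).labels

    def test_all_mass_on_wake_is_degenerate(self):
        p = SimParams(stage_dwell_means={"W": 5.0, "D": 0.0, "N": 0.0, "R": 0.0},
                      recording_minutes=10)
        h = gen_hypnogram(p, 0)
        assert set(h.labels) == {WAKE}

    def test_wake_first_and_drowsiness_before_nrem(self):
        p = SimParams(recording_minutes=60)
        for seed in range(10):
            labels = gen_hypnogram(p, seed).labels
            assert labels[0] == WAKE
            if NREM in labels:
                assert DROWSINESS in labels[: labels.index(NREM)]

    def test_occupancy_matches_chain_stationary(self):
        """Monte-Carlo occupancy over 200 hypnograms agrees within 10
        percentage points with the dwell-weighted stationary distribution of
        the embedded transition chain (computed independently by eig)."""
        p = SimParams()
        states = [WAKE, DROWSINESS, NREM, REM]
        P = np.array([[DEFAULT_TRANSITIONS.get(a, {}).get(b, 0.0) for b in states] for a in states])
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi /= pi.sum()
        occ = pi * np.array([DEFAULT_DWELL_MIN[s] for s in states])
        occ /= occ.sum()
        sim = np.zeros(4)
        for seed in range(200):
            h = gen_hypnogram(p, seed)
            sim += [h.labels.count(s) / len(h) for s in states]
        sim /= 200
        assert np.all(np.abs(sim - occ) < 0.10)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(SimulationError):
            SimParams(recording_minutes=0.0)


class TestGenEEG:
    def test_zero_density_zero_events(self):
        p = small_params(spindle_density_fast=0.0, spindle_density_slow=0.0,
                         recording_minutes=5)
        h = gen_hypnogram(p, 1)
        _, truth = gen_eeg(h, p, 2)
        assert truth.spindle_events == []

    def test_event_count_by_construction(self):
        """Density x NREM minutes events, all wholly inside NREM epochs and
        outside artifacts."""
        p = small_params(spindle_density_fast=4.0, spindle_density_slow=0.0,
                         recording_minutes=12)
        h = gen_hypnogram(p, 1)
        _, truth = gen_eeg(h, p, 2)
        assert len(truth.spindle_events) == round(4.0 * truth.nrem_minutes)
        for e in truth.spindle_events:
            assert h.stage_of_time(e.onset_s) == NREM
            assert h.stage_of_time(e.end_s - 1e-6) == NREM
            for a, b in truth.artifact_intervals:
                assert not (e.onset_s < b and a < e.end_s)

    def test_sigma_band_snr(self):
        """11-16 Hz RMS inside ground-truth events exceeds outside-event
        NREM RMS by at least a factor of 2 at the default amplitude."""
        p = small_params(recording_minutes=12)
        h = gen_hypnogram(p, 3)
        rec, truth = gen_eeg(h, p, 4)
        fs = p.sample_rate_hz
        sos = butter(4, (11, 16), btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, rec.channel("Fz"))
        inside = np.zeros(x.size, dtype=bool)
        for e in truth.spindle_events:
            inside[int(e.onset_s * fs) : int(e.end_s * fs)] = True
        nrem = h.sample_mask(NREM, fs, x.size)
        art = np.zeros(x.size, dtype=bool)
        for a, b in truth.artifact_intervals:
            art[int(a * fs) : int(b * fs)] = True
        outside = nrem & ~inside & ~art
        rms_in = np.sqrt(np.mean(x[inside] ** 2))
        rms_out = np.sqrt(np.mean(x[outside] ** 2))
        assert rms_in / rms_out >= 2.0

    def test_determinism_and_low_rate_rejected(self):
        p = small_params(recording_minutes=4)
        h = gen_hypnogram(p, 1)
        r1, _ = gen_eeg(h, p, 5)
        r2, _ = gen_eeg(h, p, 5)
        assert np.array_equal(r1.samples, r2.samples)
        with pytest.raises(SimulationError):
            gen_eeg(h, small_params(sample_rate_hz=100.0), 5)


class TestGenBehavior:
    def test_block_structure(self):
        """15 trials per phase; each location baited exactly five times and
        never twice in a row."""
        trials = gen_behavior(SimParams(n_dogs=2), 0)
        assert len(trials) == 2 * 2 * 15
        for (_, phase), sub in trials.groupby(["dog_id", "phase"]):
            locs = [c.split("_")[-1] if c != "center" else "center" for c in sub["cue_class"]]
            assert len(sub) == 15
            assert locs.count("center") == 5
            assert locs.count("left") == 5 and locs.count("right") == 5
            assert all(a != b for a, b in zip(locs, locs[1:]))

    def test_cued_side_alternates_by_parity(self):
        trials = gen_behavior(SimParams(n_dogs=2), 0)
        d0 = trials[trials["dog_id"] == "dog00"]["cue_class"].unique()
        d1 = trials[trials["dog_id"] == "dog01"]["cue_class"].unique()
        assert "cued_left" in d0 and "uncued_right" in d0
        assert "cued_right" in d1 and "uncued_left" in d1

    def test_unit_effect_gives_unit_ratio(self):
        """With both latency factors at 1 the pre/post ratio is ~1."""
        p = SimParams(n_dogs=200, cueing_latency_effect=(1.0, 1.0))
        trials = gen_behavior(p, 3)
        pre = trials[trials["phase"] == "baseline"]["latency_s"].mean()
        post = trials[trials["phase"] == "test"]["latency_s"].mean()
        assert pre / post == pytest.approx(1.0, abs=0.05)

    def test_latency_effect_monte_carlo_against_oracle(self):
        """Mean relative latency reduction over 500 dogs agrees with an
        independent numpy-only simulation of the same generative model and
        estimator.  (The ratio-of-means estimator is upward biased at ~6
        trials per class, so the mean sits above the generative 2.0/1.25 =
        1.6.)"""
        from caninesleep.stats import behavior_summary

        p = SimParams(n_dogs=500)
        got = behavior_summary(gen_behavior(p, 42))["relative_latency_reduction"].mean()

        rng = np.random.default_rng(2024)
        sigma = p.latency_sd_log
        mu = np.log(p.latency_mean_s) - sigma**2 / 2
        # cued trials get the accuracy shift post-sleep: 10/15 trials are
        # sided, half of those cued
        vals = []
        for _ in range(4000):
            rll = np.nan
            p_base = 1 / (1 + np.exp(-p.accuracy_logit_params[0]))
            p_cued = 1 / (1 + np.exp(-sum(p.accuracy_logit_params)))
            pre_c = rng.lognormal(mu, sigma, rng.binomial(15, p_base))
            pre_i = rng.lognormal(mu, sigma, 15 - pre_c.size)
            n_c = rng.binomial(5, p_cued) + rng.binomial(10, p_base)
            post_c = rng.lognormal(mu, sigma, n_c) / 2.0
            post_i = rng.lognormal(mu, sigma, 15 - n_c) / 1.25
            if min(pre_c.size, pre_i.size, post_c.size, post_i.size) > 0:
                rll = (pre_c.mean() / post_c.mean()) / (pre_i.mean() / post_i.mean())
            vals.append(rll)
        oracle = np.nanmean(vals)
        assert got == pytest.approx(oracle, abs=0.1)
        assert got > 1.6  # the generative ratio is a lower bound here


@pytest.fixture(scope="module")
def tiny_study():
    p = SimParams(n_dogs=3, recording_minutes=4, sample_rate_hz=128.0,
                  stage_dwell_means={"W": 0.3, "D": 0.3, "N": 6.0, "R": 0.4},
                  seed=11)
    return p, gen_study(p)


class TestGenStudy:
    def test_counts_and_cue_logs(self, tiny_study):
        p, bundle = tiny_study
        assert len(bundle.dogs) == 3
        assert len(bundle.trials) == 3 * 30
        for dog in bundle.dogs:
            assert dog.adaptation[0].samples.shape == dog.tmr[0].samples.shape
            assert len(dog.trials) == 30
            # adaptation recordings have no cue schedule attached
            assert dog.cue_schedule.cue_label == f"cued_{dog.cued_side}"

    def test_determinism(self, tiny_study):
        p, bundle = tiny_study
        again = gen_study(p)
        assert np.array_equal(bundle.dogs[1].tmr[0].samples, again.dogs[1].tmr[0].samples)
        pd.testing.assert_frame_equal(bundle.trials, again.trials)

    def test_trait_density_matches_injection(self, tiny_study):
        p, bundle = tiny_study
        for dog in bundle.dogs:
            for rec, truth in (dog.adaptation, dog.tmr):
                assert truth.injected_density_fast == pytest.approx(dog.trait_density_fast)
                n_fast = sum(1 for e in truth.spindle_events
                             if e.subtype == "fast" and e.channel == "Fz")
                assert n_fast == round(dog.trait_density_fast * truth.nrem_minutes)

    def test_round_trip_bit_exact(self, tiny_study, tmp_path):
        from caninesleep.io import read_raw_pair, read_trials
        from caninesleep.hypnogram import read_hypnogram
        from caninesleep.simulate import _write_bundle

        p, bundle = tiny_study
        _write_bundle(bundle, tmp_path, edf=False)
        dog = bundle.dogs[0]
        back = read_raw_pair(tmp_path / dog.dog_id / "tmr")
        assert np.array_equal(back.samples, dog.tmr[0].samples)
        h = read_hypnogram(tmp_path / dog.dog_id / "tmr_hypnogram.csv")
        assert h.labels == dog.tmr[1].hypnogram.labels
        tr = read_trials(tmp_path / "trials.csv")
        assert np.array_equal(tr["latency_s"].to_numpy(), bundle.trials["latency_s"].to_numpy())
        cues = pd.read_csv(tmp_path / dog.dog_id / "adaptation_cues.csv")
        assert len(cues) == 0

    def test_injected_trait_correlation(self):
        """Across many dogs the log trait density and log latency effect
        correlate at the configured value."""
        p = SimParams(n_dogs=400, recording_minutes=2, sample_rate_hz=128.0,
                      channels=("Fz",), spindle_channels=(),
                      stage_dwell_means={"W": 0.3, "D": 0.3, "N": 4.0, "R": 0.3},
                      seed=13)
        bundle = gen_study(p)
        d = np.log([dog.trait_density_fast for dog in bundle.dogs])
        e = np.log([dog.latency_effect_correct for dog in bundle.dogs])
        r = np.corrcoef(d, e)[0, 1]
        assert r == pytest.approx(p.density_effect_corr, abs=0.12)
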