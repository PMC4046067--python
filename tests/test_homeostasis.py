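import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnostat.errors import ComputationError, InputError, InsufficientDataError
from somnostat.homeostasis import (delta_timecourse, hourly_delta_energy,
                                   immediate_rebound, partition_equal_epochs,
                                   swe_accumulation, waking_band_timecourse)
from somnostat.spectral import BIN_FREQS, DELTA, N_BINS, SpectralFrame, UPPER_THETA, BETA_2
from somnostat.synthetic import simulate_hypnogram, simulate_spectra
from somnostat.vigilance import NREM_INTERVALS

from conftest import make_hypnogram

EPH = 900


class TestPartitionEqualEpochs:
    def test_exact_division(self):
        hyp = make_hypnogram(["N"] * 24)
        part = partition_equal_epochs(hyp, (0, 1), "N", 12)
        assert [len(g) for g in part.epoch_indices] == [2] * 12

    def test_remainder_goes_to_earliest(self):
        hyp = make_hypnogram(["N"] * 25)
        part = partition_equal_epochs(hyp, (0, 1), "N", 12)
        assert [len(g) for g in part.epoch_indices] == [3] + [2] * 11

    def test_configured_interval_counts(self):
        assert NREM_INTERVALS == {"BSL-L": 12, "BSL-D": 5, "Rec-D1": 9,
                                  "Rec-L": 11, "Rec-D2": 6}

    def test_too_few_epochs(self):
        hyp = make_hypnogram(["N"] * 5 + ["W"] * 20)
        with pytest.raises(InsufficientDataError):
            partition_equal_epochs(hyp, (0, 1), "N", 6)

    def test_artifact_epochs_excluded(self):
        art = [True, False] * 12
        hyp = make_hypnogram(["N"] * 24, artifact=art)
        part = partition_equal_epochs(hyp, (0, 1), "N", 4)
        assert len(part.all_epochs()) == 12

    def test_reconstruction_property(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(30, 200))
            k = int(rng.integers(1, 15))
            states = rng.choice(list("WNR"), size=n)
            if (states == "N").sum() < k:
                continue
            hyp = make_hypnogram(states)
            part = partition_equal_epochs(hyp, (0, n), "N", k)
            expect = np.nonzero(states == "N")[0]
            assert np.array_equal(part.all_epochs(), expect)
            sizes = [len(g) for g in part.epoch_indices]
            assert max(sizes) - min(sizes) <= 1


def _frame_with_delta(hyp, delta_values, base=1.0):
    """Uniform power with the delta bins set per epoch."""
    power = np.full((len(hyp), N_BINS), base)
    power[:, DELTA.bins()] = np.asarray(delta_values)[:, None]
    return SpectralFrame(power)


class TestDeltaTimecourse:
    def test_constant_delta_gives_100_everywhere(self):
        hyp = make_hypnogram(np.tile(list("NW"), 36 * EPH))
        frame = _frame_with_delta(hyp, np.full(len(hyp), 5.0))
        tc = delta_timecourse(frame, hyp)
        assert np.allclose(tc.table.delta_pct, 100.0)
        assert tc.reference == pytest.approx(5.0)

    def test_generator_decline_is_monotone(self, genotypes, quiet_config):
        params = genotypes["genotype_a"]
        hyp = simulate_hypnogram(params, quiet_config, subject_id=3)
        frame = simulate_spectra(hyp, params, quiet_config, subject_id=3)
        tc = delta_timecourse(frame, hyp)
        bsl = tc.window_values("BSL-L")
        # homeostatic decline across the baseline light period
        assert bsl[0] > bsl[-1]
        assert np.mean(np.diff(bsl) < 0) > 0.7

    def test_dark_delta_ratio_recovery(self, genotypes, quiet_config):
        params = genotypes["genotype_a"]
        hyp = simulate_hypnogram(params, quiet_config, subject_id=4)
        frame = simulate_spectra(hyp, params, quiet_config, subject_id=4)
        tc = delta_timecourse(frame, hyp)
        ratio = 100 * tc.window_values("BSL-D").mean() / tc.window_values("BSL-L").mean()
        assert ratio == pytest.approx(params.dark_delta_pct, rel=1e-3)

    def test_zero_reference_errors(self):
        hyp = make_hypnogram(np.tile(list("NW"), 36 * EPH))
        frame = _frame_with_delta(hyp, np.zeros(len(hyp)))
        with pytest.raises(ComputationError):
            delta_timecourse(frame, hyp)


class TestImmediateRebound:
    @staticmethod
    def _toy_timecourse(pre, post):
        hyp = make_hypnogram(np.tile(list("NW"), 36 * EPH))
        delta = np.full(len(hyp), pre)
        delta[hyp.zt_seconds >= 36 * 3600] = post
        tc = delta_timecourse(_frame_with_delta(hyp, delta), hyp)
        return tc

    def test_equal_gives_100(self):
        assert immediate_rebound(self._toy_timecourse(2.0, 2.0)) == pytest.approx(100.0)

    def test_doubling_gives_200(self):
        assert immediate_rebound(self._toy_timecourse(2.0, 4.0)) == pytest.approx(200.0)

    def test_generator_gain_recovered_exactly(self, genotypes, quiet_config):
        params = genotypes["genotype_c"]
        hyp = simulate_hypnogram(params, quiet_config, subject_id=0)
        frame = simulate_spectra(hyp, params, quiet_config, subject_id=0)
        tc = delta_timecourse(frame, hyp)
        assert immediate_rebound(tc) == pytest.approx(100 * params.rebound_gain,
                                                      rel=1e-9)


class TestSweAccumulation:
    def test_identical_days_accumulate_zero(self):
        hyp = make_hypnogram(np.tile(list("NW"), 36 * EPH))
        frame = _frame_with_delta(hyp, np.full(len(hyp), 3.0))
        swe = swe_accumulation(frame, hyp)
        assert np.allclose(swe.accumulated_pct, 0.0)

    def test_total_loss_identity(self):
        # baseline N/W alternation; SD hours 24-35 all W; then baseline pattern
        day1 = np.tile(list("NW"), 12 * EPH)
        sd = ["W"] * (12 * EPH)
        rest = np.tile(list("NW"), 18 * EPH)
        hyp = make_hypnogram(np.concatenate([day1, sd, rest]))
        frame = _frame_with_delta(hyp, np.full(len(hyp), 3.0))
        swe = swe_accumulation(frame, hyp)
        at_sd_end = swe[swe.hour == 35].accumulated_pct.iloc[0]
        assert at_sd_end == pytest.approx(-100 * 12 / 24)

    def test_three_hour_toy_matches_hand_sum(self):
        # 24 h baseline, then 3 h with known energies
        rng = np.random.default_rng(0)
        states = list(rng.choice(list("NW"), size=27 * EPH))
        hyp = make_hypnogram(states)
        delta = rng.random(len(hyp)) + 0.5
        frame = _frame_with_delta(hyp, delta)
        swe = swe_accumulation(frame, hyp)

        def hour_energy(h):
            mask = (hyp.zt_seconds // 3600 == h) & (hyp.states == "N")
            return delta[mask].sum()

        base_total = sum(hour_energy(h) for h in range(24))
        expect = np.cumsum([hour_energy(24 + i) - hour_energy(i) for i in range(3)])
        assert np.allclose(swe.accumulated_pct, 100 * expect / base_total)

    def test_telescoping_identity(self, genotypes, sim_config):
        params = genotypes["genotype_b"]
        hyp = simulate_hypnogram(params, sim_config, subject_id=5)
        frame = simulate_spectra(hyp, params, sim_config, subject_id=5)
        swe = swe_accumulation(frame, hyp)
        direct = (swe.delta_energy.sum() - swe.baseline_energy.sum())
        assert swe.accumulated_pct.iloc[-1] == pytest.approx(
            100 * direct / hourly_delta_energy(frame, hyp).loc[0:23].sum())

    def test_hours_without_nrems_contribute_zero(self):
        states = np.tile(list("NW"), 13 * EPH)
        states[25 * EPH : 26 * EPH] = "W"  # one hour of pure wakefulness
        hyp = make_hypnogram(states)
        energy = hourly_delta_energy(_frame_with_delta(hyp, np.ones(len(hyp))), hyp)
        assert set(energy.index) == set(range(26))
        assert energy.loc[25] == 0.0
        assert energy.loc[24] > 0.0


class TestScaleEquivariance:
    def test_all_normalized_outputs_unchanged(self, genotypes, sim_config):
        params = genotypes["genotype_a"]
        hyp = simulate_hypnogram(params, sim_config, subject_id=6)
        frame = simulate_spectra(hyp, params, sim_config, subject_id=6)
        scaled = SpectralFrame(frame.power * 7.3)
        tc1, tc2 = (delta_timecourse(f, hyp) for f in (frame, scaled))
        assert np.allclose(tc1.table.delta_pct, tc2.table.delta_pct)
        assert immediate_rebound(tc1) == pytest.approx(immediate_rebound(tc2))
        s1, s2 = (swe_accumulation(f, hyp) for f in (frame, scaled))
        assert np.allclose(s1.accumulated_pct, s2.accumulated_pct)
        w1, w2 = (waking_band_timecourse(f, hyp) for f in (frame, scaled))
        assert np.allclose(w1.pct_baseline, w2.pct_baseline)


class TestWakingBandTimecourse:
    def test_flat_when_sd_equals_baseline(self):
        hyp = make_hypnogram(np.tile(list("WN"), 36 * EPH))
        frame = SpectralFrame(np.ones((len(hyp), N_BINS)))
        wb = waking_band_timecourse(frame, hyp, mode="hourly")
        assert np.allclose(wb.pct_baseline, 100.0)

    def test_band_selectivity(self, genotypes, quiet_config):
        from dataclasses import replace

        from somnostat.synthetic import SDBandGains

        params = genotypes["genotype_a"]
        params = replace(params, sd_band_gains=SDBandGains(
            upper_theta=2.0, beta_2=1.0, gamma_1=1.0, onset_h=0.5))
        hyp = simulate_hypnogram(params, quiet_config, subject_id=7)
        frame = simulate_spectra(hyp, params, quiet_config, subject_id=7)
        wb = waking_band_timecourse(frame, hyp, mode="hourly")
        theta = wb[wb.band == "upper_theta"].pct_baseline
        beta = wb[wb.band == "beta_2"].pct_baseline
        assert theta.max() == pytest.approx(200.0, rel=1e-9)
        assert np.allclose(beta, 100.0)

    def test_interval_mode_has_36_intervals(self, genotypes, quiet_config):
        params = genotypes["genotype_a"]
        hyp = simulate_hypnogram(params, quiet_config, subject_id=8)
        frame = simulate_spectra(hyp, params, quiet_config, subject_id=8)
        wb = waking_band_timecourse(frame, hyp, mode="intervals",
                                    bands=(UPPER_THETA, BETA_2))
        assert (wb.groupby("band").interval.count() == 36).all()

    def test_bad_mode(self, uniform_power):
        hyp = make_hypnogram(np.tile(list("WN"), 36 * EPH))
        with pytest.raises(InputError):
            waking_band_timecourse(SpectralFrame(uniform_power(len(hyp))), hyp,
                                   mode="weekly")


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=12, max_value=400), st.integers(min_value=1, max_value=12))
def test_partition_sizes_property(m, k):
    if m < k:
        return
    hyp = make_hypnogram(["N"] * m)
    part = partition_equal_epochs(hyp, (0, m), "N", k)
    sizes = [len(g) for g in part.epoch_indices]
    assert sum(sizes) == m
    assert sorted(sizes, reverse=True) == sizes  # earliest-first remainder
    assert max(sizes) - min(sizes) <= 1
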