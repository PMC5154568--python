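"""Cycle detection, phase normalisation, and the eight pulse-waveform indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsfg.config import WaveformConfig
from lsfg.synthetic import generate_mbr_series, mbr_waveform
from lsfg.waveform import (
    MbrSeries,
    NoCycleError,
    PulseCycle,
    acceleration_time_index,
    blowout_score,
    blowout_time,
    composite_cycle,
    detect_cycles,
    falling_rate,
    flow_acceleration_index,
    indices_from_cycle,
    resistivity_index,
    rising_rate,
    skew,
    waveform_profile,
)
from tests.conftest import make_cycle, make_profile


# ---------------------------------------------------------------------------
# cycle detection
# ---------------------------------------------------------------------------


class TestDetectCycles:
    def test_zero_noise_hr60_cycle_length(self):
        prof = make_profile(heart_rate=60.0)
        series = generate_mbr_series(prof, 118, 30.0, 0, phase_offset=0.4)
        seg = detect_cycles(series)
        assert seg.n_cycles >= 3
        assert np.all(np.abs(seg.cycle_lengths - 30) <= 1)

    def test_constant_series_is_an_error(self):
        series = MbrSeries(values=np.full(118, 5.0), frame_rate=30.0)
        with pytest.raises(NoCycleError):
            detect_cycles(series)

    @pytest.mark.parametrize("hr", [55.0, 70.0, 90.0])
    def test_noisy_series_recovers_cycle_duration(self, hr):
        """Detected mean cycle duration within 5% of 60/HR at 5% noise."""
        prof = make_profile(heart_rate=hr, measurement_noise_sd=0.5)
        durations = []
        for seed in range(10):
            series = generate_mbr_series(prof, 118, 30.0, seed)
            seg = detect_cycles(series)
            durations.append(np.mean(seg.cycle_lengths) / 30.0)
        assert abs(np.mean(durations) - 60.0 / hr) < 0.05 * (60.0 / hr)

    def test_boundaries_strictly_increasing_and_admissible(self):
        prof = make_profile(measurement_noise_sd=0.4)
        series = generate_mbr_series(prof, 118, 30.0, 3)
        seg = detect_cycles(series)
        assert np.all(np.diff(seg.boundaries) > 0)
        lengths = seg.cycle_lengths / 30.0
        assert np.all((lengths >= 0.5) & (lengths <= 1.5))


class TestCompositeCycle:
    def test_identity_resampling_single_cycle(self):
        """One perfect cycle at n_phase_bins == cycle length reproduces it."""
        prof = make_profile(heart_rate=60.0)
        series = generate_mbr_series(prof, 118, 30.0, 0, phase_offset=0.0)
        seg = detect_cycles(series)
        s, e = seg.boundaries[0], seg.boundaries[1]
        one = MbrSeries(values=series.values[s : e + 1], frame_rate=30.0)
        from lsfg.waveform import CycleSegmentation

        seg1 = CycleSegmentation(boundaries=np.array([0, e - s]), frame_rate=30.0)
        cyc = composite_cycle(one, seg1, n_phase_bins=int(e - s))
        np.testing.assert_allclose(cyc.phase_values, one.values[: e - s])

    def test_mean_of_identical_cycles(self):
        prof = make_profile(heart_rate=60.0)
        series = generate_mbr_series(prof, 118, 30.0, 0, phase_offset=0.0)
        seg = detect_cycles(series)
        cyc_all = composite_cycle(series, seg, 30)
        # restrict to the first cycle only: identical periodic cycles
        from lsfg.waveform import CycleSegmentation

        seg1 = CycleSegmentation(boundaries=seg.boundaries[:2], frame_rate=30.0)
        cyc_one = composite_cycle(series, seg1, 30)
        np.testing.assert_allclose(cyc_all.phase_values, cyc_one.phase_values,
                                   atol=1e-9)

    def test_averaging_reduces_noise(self):
        """The composite of noisy cycles is closer to the analytic curve than
        the typical single cycle, aggregated over 100 seeds."""
        from lsfg.waveform import CycleSegmentation

        prof = make_profile(heart_rate=60.0, measurement_noise_sd=0.8)
        clean_prof = make_profile(heart_rate=60.0)
        comp_rmses, single_rmses, wins, n_seeds = [], [], 0, 100
        for seed in range(n_seeds):
            series = generate_mbr_series(prof, 118, 30.0, seed, phase_offset=0.0)
            seg = detect_cycles(series)
            if seg.n_cycles < 2:
                continue
            composite = composite_cycle(series, seg, 30)
            t = (seg.boundaries[0] + np.arange(30) / 30.0
                 * np.mean(seg.cycle_lengths)) / 30.0
            truth = mbr_waveform(clean_prof, t)
            rmse_comp = np.sqrt(np.mean((composite.phase_values - truth) ** 2))
            singles = []
            for k in range(seg.n_cycles):
                seg1 = CycleSegmentation(boundaries=seg.boundaries[k : k + 2],
                                         frame_rate=30.0)
                single = composite_cycle(series, seg1, 30)
                singles.append(
                    np.sqrt(np.mean((single.phase_values - truth) ** 2)))
            comp_rmses.append(rmse_comp)
            single_rmses.append(np.mean(singles))
            wins += rmse_comp < np.mean(singles)
        assert np.mean(comp_rmses) < np.mean(single_rmses)
        assert wins >= 0.9 * len(comp_rmses)

    def test_too_few_phase_bins_rejected(self):
        prof = make_profile()
        series = generate_mbr_series(prof, 118, 30.0, 0)
        seg = detect_cycles(series)
        with pytest.raises(ValueError):
            composite_cycle(series, seg, n_phase_bins=7)


# ---------------------------------------------------------------------------
# index examples (brute-force / hand-computed oracles)
# ---------------------------------------------------------------------------


class TestIndexExamples:
    def test_blowout_time_symmetric_triangle(self, triangle_cycle):
        assert blowout_time(triangle_cycle) == pytest.approx(50.0)

    def test_blowout_time_square_wave_duty_cycle(self):
        """30% duty at max: exactly the above-level bin count."""
        v = np.concatenate([np.ones(9), np.zeros(21)])
        assert blowout_time(make_cycle(v)) == pytest.approx(30.0)

    def test_blowout_time_flat_cycle_is_100_with_warning(self):
        with pytest.warns(UserWarning):
            assert blowout_time(make_cycle(np.full(30, 5.0))) == 100.0

    def test_blowout_score_flat_cycle(self):
        assert blowout_score(make_cycle(np.full(30, 5.0))) == pytest.approx(100.0)

    def test_blowout_score_direct_formula(self):
        """max 16, min 10, mean 12.8 → 100·(1 − 6/25.6) = 76.5625."""
        v = np.concatenate([[10.0, 16.0], np.full(6, 76.4 / 6)])
        cyc = make_cycle(v)
        assert cyc.phase_values.mean() == pytest.approx(12.8)
        assert blowout_score(cyc) == pytest.approx(100.0 * (1 - 6 / 25.6))

    def test_skew_zero_for_symmetric_triangle(self, triangle_cycle):
        assert skew(triangle_cycle) == pytest.approx(0.0, abs=1e-12)

    def test_skew_positive_for_early_peak(self):
        """An early-peaked pulse with a long diastolic tail spends most of the
        cycle at low values: a right-tailed value distribution, positive skew."""
        prof = make_profile()
        t = np.arange(30) / 30.0 * prof.period
        assert skew(make_cycle(mbr_waveform(prof, t))) > 0.5

    def test_skew_antisymmetry_under_time_mirroring(self):
        """A time-mirrored cycle (rightward waveform) has negated skew."""
        prof = make_profile()
        t = np.arange(30) / 30.0 * prof.period
        v = mbr_waveform(prof, t)
        assert skew(make_cycle(v[::-1])) == pytest.approx(
            -skew(make_cycle(v)), abs=1e-10)

    def test_ati_direct_ratio(self):
        v = np.zeros(40)
        v[10] = 1.0
        assert acceleration_time_index(make_cycle(v)) == pytest.approx(25.0)

    def test_ati_peak_at_start(self):
        v = np.zeros(30)
        v[0] = 1.0
        assert acceleration_time_index(make_cycle(v)) == 0.0

    def test_rising_equals_falling_for_symmetric_trapezoid(self):
        v = np.array([0, 0.25, 0.5, 0.75, 1, 1, 1, 1,
                      0.75, 0.5, 0.25, 0, 0, 0, 0, 0])
        cyc = make_cycle(v)
        assert rising_rate(cyc) == pytest.approx(falling_rate(cyc))

    def test_falling_rate_increases_with_faster_decay(self):
        """Halving the diastolic decay constant strictly raises FR (zero noise)."""
        frs = []
        for tau in (0.8, 0.4, 0.2):
            prof = make_profile(diastolic_decay_tau=tau)
            t = np.arange(30) / 30.0 * prof.period
            cyc = make_cycle(mbr_waveform(prof, t), prof.period)
            frs.append(falling_rate(cyc))
        assert frs[0] < frs[1] < frs[2]

    def test_flow_acceleration_direct_max_increment(self):
        v = np.array([1.0, 2.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.2])
        assert flow_acceleration_index(make_cycle(v)) == pytest.approx(2.0)

    def test_flow_acceleration_flat_cycle_zero(self):
        assert flow_acceleration_index(make_cycle(np.full(30, 5.0))) == 0.0

    def test_resistivity_direct_ratio(self):
        v = np.linspace(6, 10, 30)
        assert resistivity_index(make_cycle(v)) == pytest.approx(0.4)

    def test_resistivity_bounds(self):
        assert resistivity_index(make_cycle(np.full(30, 5.0))) == 0.0
        v = np.linspace(0, 10, 30)
        assert resistivity_index(make_cycle(v)) == pytest.approx(1.0)

    def test_degenerate_errors(self):
        flat = make_cycle(np.full(30, 5.0))
        with pytest.raises(ValueError):
            skew(flat)
        with pytest.raises(ValueError):
            rising_rate(flat)
        with pytest.raises(ValueError):
            blowout_score(make_cycle(np.zeros(30) + 0.0))


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


def _random_cycle(rng):
    v = rng.uniform(1.0, 20.0, size=rng.integers(8, 64))
    if np.unique(v).size < 3:
        v = v + np.arange(v.size) * 1e-3
    return make_cycle(v)


def _pulse_like_cycle(rng):
    """A random physiological pulse: analytic waveform + small noise."""
    prof = make_profile(
        heart_rate=float(rng.uniform(45, 115)),
        mbr_baseline=float(rng.uniform(4, 12)),
        pulse_amplitude=float(rng.uniform(3, 15)),
        systolic_rise_fraction=float(rng.uniform(0.15, 0.45)),
        diastolic_decay_tau=float(rng.uniform(0.2, 1.0)),
    )
    nb = int(rng.integers(12, 61))
    t = np.arange(nb) / nb * prof.period
    v = mbr_waveform(prof, t) + 0.1 * rng.standard_normal(nb)
    return make_cycle(np.maximum(v, 0.1), prof.period)


class TestIndexProperties:
    def test_bounds_on_random_cycles(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            cyc = _random_cycle(rng)
            assert 0 <= blowout_time(cyc) <= 100
            assert 0 <= blowout_score(cyc) <= 100
            assert 0 <= acceleration_time_index(cyc) < 100
            assert 0 <= resistivity_index(cyc) <= 1
            assert flow_acceleration_index(cyc) >= 0

    @given(scale=st.floats(min_value=0.1, max_value=50.0),
           seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale, seed):
        """Scaling MBR by c leaves shape indices unchanged, scales mean and FAI."""
        rng = np.random.default_rng(seed)
        cyc = _random_cycle(rng)
        scaled = make_cycle(cyc.phase_values * scale)
        assert blowout_time(scaled) == pytest.approx(blowout_time(cyc))
        assert blowout_score(scaled) == pytest.approx(blowout_score(cyc))
        assert skew(scaled) == pytest.approx(skew(cyc), abs=1e-8)
        assert acceleration_time_index(scaled) == pytest.approx(
            acceleration_time_index(cyc))
        assert rising_rate(scaled) == pytest.approx(rising_rate(cyc))
        assert falling_rate(scaled) == pytest.approx(falling_rate(cyc))
        assert resistivity_index(scaled) == pytest.approx(resistivity_index(cyc))
        assert flow_acceleration_index(scaled) == pytest.approx(
            scale * flow_acceleration_index(cyc))
        assert scaled.phase_values.mean() == pytest.approx(
            scale * cyc.phase_values.mean())

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_fai_equals_brute_force_pairwise_scan(self, seed):
        rng = np.random.default_rng(seed)
        cyc = _random_cycle(rng)
        v = cyc.phase_values
        brute = max(v[(i + 1) % v.size] - v[i] for i in range(v.size))
        assert flow_acceleration_index(cyc) == pytest.approx(max(brute, 0.0))

    def test_time_reversal_swaps_rr_fr_and_mirrors_ati(self):
        rng = np.random.default_rng(11)
        prof = make_profile()
        t = np.arange(30) / 30.0 * prof.period
        v = mbr_waveform(prof, t) + 0.05 * rng.standard_normal(30)
        fwd, rev = make_cycle(v), make_cycle(v[::-1])
        assert rising_rate(rev) == pytest.approx(falling_rate(fwd))
        assert falling_rate(rev) == pytest.approx(rising_rate(fwd))
        assert skew(rev) == pytest.approx(-skew(fwd))
        ati_sum = acceleration_time_index(fwd) + acceleration_time_index(rev)
        assert abs(ati_sum - 100.0) <= 100.0 / 30 + 1e-9
        assert blowout_time(rev) == pytest.approx(blowout_time(fwd))
        assert resistivity_index(rev) == pytest.approx(resistivity_index(fwd))

    def test_bos_ri_identity(self):
        """BOS = 100·(1 − RI·max/(2·mean)) to machine precision on 1000
        random physiological cycles."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            cyc = _pulse_like_cycle(rng)
            v = cyc.phase_values
            lhs = blowout_score(cyc)
            rhs = 100.0 * (1.0 - resistivity_index(cyc) * v.max() / (2 * v.mean()))
            assert lhs == pytest.approx(rhs, abs=1e-9)


# ---------------------------------------------------------------------------
# full profile vs analytic oracle
# ---------------------------------------------------------------------------


class TestWaveformProfile:
    @pytest.mark.parametrize("phase", [0.0, 0.13, 0.31, 0.52, 0.77])
    def test_matches_analytic_oracle_at_zero_noise(self, phase):
        """Pipeline indices match direct evaluation on the analytic cycle,
        within one phase bin of discretisation error."""
        prof = make_profile()
        nb = 30
        T = prof.period
        t = np.arange(nb) / nb * T  # exact phases from the trough
        ref = indices_from_cycle(PulseCycle(mbr_waveform(prof, t), T)).as_dict()
        series = generate_mbr_series(prof, 118, 30.0, 0, phase_offset=phase * T)
        got = waveform_profile(series).as_dict()
        one_bin = 100.0 / nb
        assert abs(got["BOT"] - ref["BOT"]) <= one_bin + 1e-9
        assert abs(got["ATI"] - ref["ATI"]) <= one_bin + 1e-9
        assert got["mean_mbr"] == pytest.approx(ref["mean_mbr"], rel=0.02)
        assert got["BOS"] == pytest.approx(ref["BOS"], rel=0.02)
        assert got["RI"] == pytest.approx(ref["RI"], rel=0.05)
        assert got["RR"] == pytest.approx(ref["RR"], rel=0.05)
        assert got["FR"] == pytest.approx(ref["FR"], rel=0.05)
        assert got["FAI"] == pytest.approx(ref["FAI"], rel=0.05)
        assert got["Skew"] == pytest.approx(ref["Skew"], abs=0.35)

    def test_flat_series_is_an_error(self):
        series = MbrSeries(values=np.full(118, 3.0), frame_rate=30.0)
        with pytest.raises(NoCycleError):
            waveform_profile(series)

    def test_two_noisy_scans_differ_but_both_valid(self):
        prof = make_profile(measurement_noise_sd=0.4)
        a = waveform_profile(generate_mbr_series(prof, 118, 30.0, 1))
        b = waveform_profile(generate_mbr_series(prof, 118, 30.0, 2))
        assert a.as_dict() != b.as_dict()
        for wp in (a, b):
            assert 0 <= wp.bot <= 100 and 0 <= wp.ri <= 1
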