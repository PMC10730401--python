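import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mitopath import assays
from mitopath.assays import InjectionSchedule, PlateTrace
from mitopath.synthetic import PulseModel, TraceSimConfig, generate_crc_trace, generate_ocr_trace

COUPLING_PHASES = (
    ("baseline", 50.0),
    ("ADP", 120.0),
    ("oligomycin", 40.0),
    ("FCCP", 130.0),
    ("antimycin", 10.0),
)

EFLOW_PHASES = (
    ("baseline", 100.0),
    ("rotenone", 20.0),
    ("succinate", 90.0),
    ("antimycinA", 10.0),
    ("ascTMPD", 150.0),
)


def _noiseless(phases, cycles=4, offset=0.0, kind="OCR_coupling"):
    shifted = tuple((lab, lvl + offset) for lab, lvl in phases)
    cfg = TraceSimConfig(phase_means=shifted, cycles_per_phase=cycles, noise_sd=0.0)
    return generate_ocr_trace(cfg, kind=kind)


class TestTraceTypes:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            PlateTrace(well="A1", times=(0.0, 0.0, 1.0), signal=(1.0, 2.0, 3.0))

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="two samples"):
            PlateTrace(well="A1", times=(0.0,), signal=(1.0,))

    def test_schedule_label_grammar_enforced(self):
        with pytest.raises(ValueError, match="not valid"):
            InjectionSchedule(events=(("baseline", 0.0), ("espresso", 10.0)), kind="OCR_coupling")

    def test_schedule_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            InjectionSchedule(events=(("baseline", 10.0), ("ADP", 10.0)), kind="OCR_coupling")


class TestSegmentPhases:
    def test_noiseless_phase_means_recovered(self):
        trace, schedule, _ = _noiseless(COUPLING_PHASES)
        phases = assays.segment_phases(trace, schedule)
        for label, level in COUPLING_PHASES:
            assert phases[label].mean == pytest.approx(level)
            assert phases[label].sd == pytest.approx(0.0)

    def test_discard_first_drops_post_injection_cycle(self):
        trace, schedule, _ = _noiseless(COUPLING_PHASES, cycles=3)
        # corrupt the first sample after the ADP injection
        y = list(trace.signal)
        adp_start = 3  # cycles=3, second phase starts at index 3
        y[adp_start] = 999.0
        corrupted = PlateTrace(well=trace.well, times=trace.times, signal=tuple(y), kind=trace.kind)
        with_discard = assays.segment_phases(corrupted, schedule, discard_first=1)
        without = assays.segment_phases(corrupted, schedule, discard_first=0)
        assert with_discard["ADP"].mean == pytest.approx(120.0)
        assert without["ADP"].mean != pytest.approx(120.0)

    def test_baseline_phase_not_discarded(self):
        trace, schedule, _ = _noiseless(COUPLING_PHASES, cycles=2)
        phases = assays.segment_phases(trace, schedule, discard_first=1)
        assert phases["baseline"].n == 2
        assert phases["ADP"].n == 1

    def test_phase_emptied_by_discard_errors(self):
        trace, schedule, _ = _noiseless(COUPLING_PHASES, cycles=1)
        with pytest.raises(ValueError, match="no samples"):
            assays.segment_phases(trace, schedule, discard_first=1)

    def test_event_beyond_trace_errors(self):
        trace, _, _ = _noiseless(COUPLING_PHASES)
        late = InjectionSchedule(events=(("baseline", 0.0), ("ADP", 1e6)), kind="OCR_coupling")
        with pytest.raises(ValueError, match="beyond"):
            assays.segment_phases(trace, late)


class TestRespStates:
    def test_forced_subtraction_example(self):
        means = dict(COUPLING_PHASES)
        states = assays.derive_resp_states(means)
        assert (states.state_ii, states.state_iii, states.state_ivo, states.state_iiiu) == (
            40.0, 110.0, 30.0, 120.0,
        )

    def test_rcr(self):
        states = assays.derive_resp_states(dict(COUPLING_PHASES))
        assert states.rcr == pytest.approx(110.0 / 30.0)

    def test_flooring_with_warning(self):
        means = dict(COUPLING_PHASES)
        means["oligomycin"] = 5.0  # below the residual of 10
        with pytest.warns(UserWarning, match="floored"):
            states = assays.derive_resp_states(means)
        assert states.state_ivo == 0.0
        assert "state_ivo" in states.floored
        assert math.isnan(states.rcr)

    def test_missing_phase_errors(self):
        means = dict(COUPLING_PHASES)
        del means["FCCP"]
        with pytest.raises(ValueError, match="missing"):
            assays.derive_resp_states(means)

    def test_location_equivariance(self):
        base = assays.derive_resp_states(dict(COUPLING_PHASES))
        shifted = assays.derive_resp_states({k: v + 37.5 for k, v in COUPLING_PHASES})
        assert shifted.state_ii == pytest.approx(base.state_ii)
        assert shifted.state_iii == pytest.approx(base.state_iii)
        assert shifted.state_iiiu == pytest.approx(base.state_iiiu)
        assert shifted.state_ivo == pytest.approx(base.state_ivo)


class TestComplexActivities:
    def test_defined_differences(self):
        cx = assays.derive_complex_activities(dict(EFLOW_PHASES))
        assert (cx.cx_i, cx.cx_ii, cx.cx_iii, cx.cx_iv) == (80.0, 70.0, 80.0, 140.0)

    def test_rotenone_noop_gives_zero_cx1(self):
        means = dict(EFLOW_PHASES)
        means["rotenone"] = means["baseline"]
        with pytest.warns(UserWarning):  # CxII goes negative when rotenone fails
            assert assays.derive_complex_activities(means).cx_i == 0.0

    def test_negative_difference_reported_and_flagged(self):
        means = dict(EFLOW_PHASES)
        means["rotenone"] = 120.0
        with pytest.warns(UserWarning, match="negative"):
            cx = assays.derive_complex_activities(means)
        assert cx.cx_i == pytest.approx(-20.0)
        assert "cx_i" in cx.negative

    def test_location_equivariance(self):
        base = assays.derive_complex_activities(dict(EFLOW_PHASES))
        shifted = assays.derive_complex_activities({k: v + 11.0 for k, v in EFLOW_PHASES})
        assert (shifted.cx_i, shifted.cx_ii, shifted.cx_iii, shifted.cx_iv) == (
            base.cx_i, base.cx_ii, base.cx_iii, base.cx_iv,
        )

    def test_missing_phase_errors(self):
        with pytest.raises(ValueError, match="missing"):
            assays.derive_complex_activities({"baseline": 1.0})


class TestCrcRetention:
    def test_flat_signal_zero_retention(self):
        t = tuple(float(i) for i in range(100))
        trace = PlateTrace(well="A1", times=t, signal=(5.0,) * 100, kind="CRC")
        assert assays.crc_retention(trace, [10.0, 50.0]) == 0.0

    def test_linear_decay_triangle_area(self):
        # pulse at t=0: peak 10 decaying linearly to 0 over 60 s, 1 s sampling
        times = tuple(float(i) for i in range(61))
        signal = tuple(10.0 - i / 6.0 for i in range(61))
        trace = PlateTrace(well="A1", times=times, signal=signal, kind="CRC")
        area = assays.crc_retention(trace, [0.0], mode="uptake")
        assert area == pytest.approx(10.0 * 60.0 / 2.0, rel=1e-9)

    def test_exponential_decay_closed_form_above_baseline(self):
        k, amp = 0.1, 10.0
        times = np.arange(0.0, 400.0, 0.5)
        signal = np.where(times < 50.0, 0.0, amp * np.exp(-k * np.clip(times - 50.0, 0, None)))
        trace = PlateTrace(well="A1", times=tuple(times), signal=tuple(signal), kind="CRC")
        area = assays.crc_retention(trace, [50.0], mode="above_baseline")
        assert area == pytest.approx(amp / k, rel=1e-2)

    def test_additive_over_pulses(self):
        trace, schedule, _ = self._pulsed_trace()
        pulses = [t for lab, t in schedule.events if lab.startswith("pulse")]
        total = assays.crc_retention(trace, pulses)
        parts = 0.0
        for i, p in enumerate(pulses):
            last = i + 1 == len(pulses)
            end = trace.times[-1] if last else pulses[i + 1]
            sub = self._slice(trace, p, end, include_end=last)
            parts += assays.crc_retention(sub, [p])
        assert total == pytest.approx(parts, rel=1e-9)

    def test_baseline_shift_invariance(self):
        trace, schedule, _ = self._pulsed_trace()
        pulses = [t for lab, t in schedule.events if lab.startswith("pulse")]
        shifted = PlateTrace(
            well=trace.well,
            times=trace.times,
            signal=tuple(s + 100.0 for s in trace.signal),
            kind="CRC",
        )
        for mode in ("uptake", "above_baseline"):
            assert assays.crc_retention(shifted, pulses, mode=mode) == pytest.approx(
                assays.crc_retention(trace, pulses, mode=mode), rel=1e-9
            )

    def test_pulse_after_trace_end_errors(self):
        trace, _, _ = self._pulsed_trace()
        with pytest.raises(ValueError, match="after the end"):
            assays.crc_retention(trace, [trace.times[-1] + 100.0])

    def test_no_pulses_errors(self):
        trace, _, _ = self._pulsed_trace()
        with pytest.raises(ValueError, match="at least one pulse"):
            assays.crc_retention(trace, [])

    @staticmethod
    def _pulsed_trace():
        cfg = TraceSimConfig(
            phase_means=(("baseline", 5.0),),
            cycles_per_phase=20,
            sample_interval=2.0,
            pulse_model=PulseModel(amplitude=10.0, uptake_rate=0.03, n_pulses=4, pulse_interval=120.0),
        )
        return generate_crc_trace(cfg)

    @staticmethod
    def _slice(trace, start, end, include_end=True):
        t = np.asarray(trace.times)
        keep = (t >= start) & ((t <= end) if include_end else (t < end))
        return PlateTrace(
            well=trace.well,
            times=tuple(np.asarray(trace.times)[keep]),
            signal=tuple(np.asarray(trace.signal)[keep]),
            kind=trace.kind,
        )


class TestH2o2Slope:
    def test_exact_line(self):
        trace = PlateTrace(well="A1", times=(0.0, 60.0, 120.0), signal=(0.0, 2.0, 4.0), kind="H2O2")
        fit = assays.h2o2_slope(trace)
        assert fit.slope_per_min == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_window_restricts_fit(self):
        times = tuple(float(t) for t in range(0, 600, 30))
        signal = tuple((2.0 if t < 300 else 10.0) * t / 60.0 for t in times)
        trace = PlateTrace(well="A1", times=times, signal=signal, kind="H2O2")
        fit = assays.h2o2_slope(trace, window=(0.0, 270.0))
        assert fit.slope_per_min == pytest.approx(2.0)

    def test_noisy_estimate_within_se(self):
        rng = np.random.default_rng(3)
        times = np.arange(40) * 30.0
        signal = 5.0 * times / 60.0 + rng.normal(0, 1.0, size=40)
        trace = PlateTrace(well="A1", times=tuple(times), signal=tuple(signal), kind="H2O2")
        fit = assays.h2o2_slope(trace)
        assert abs(fit.slope_per_min - 5.0) < 3 * fit.stderr

    def test_nonlinear_input_reports_r_squared(self):
        times = np.arange(0.0, 600.0, 30.0)
        signal = (times / 60.0) ** 2
        trace = PlateTrace(well="A1", times=tuple(times), signal=tuple(signal), kind="H2O2")
        fit = assays.h2o2_slope(trace)
        ref = stats.linregress(times / 60.0, signal)
        assert fit.slope_per_min == pytest.approx(ref.slope)
        assert fit.r_squared < 1.0


class TestAtpStandardCurve:
    STANDARDS = [(1.0, 1000.0), (0.1, 100.0), (0.01, 10.0)]

    def test_exact_interpolation(self):
        assert assays.atp_from_standard_curve(self.STANDARDS, 100.0) == pytest.approx(0.1)

    def test_inverted_fit_between_standards(self):
        assert assays.atp_from_standard_curve(self.STANDARDS, 316.2) == pytest.approx(0.3162, rel=1e-3)

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError, match="outside standard range"):
            assays.atp_from_standard_curve(self.STANDARDS, 1e6)

    def test_too_few_standards(self):
        with pytest.raises(ValueError, match="at least two"):
            assays.atp_from_standard_curve([(1.0, 1000.0)], 100.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            assays.atp_from_standard_curve([(1.0, 1000.0), (0.0, 10.0)], 100.0)


class TestErAspectRatio:
    def test_examples(self):
        assert assays.er_aspect_ratio(2.0, 1.0) == 2.0
        assert assays.er_aspect_ratio(1.0, 1.0) == 1.0

    def test_major_smaller_than_minor_rejected(self):
        with pytest.raises(ValueError):
            assays.er_aspect_ratio(1.0, 2.0)

    def test_zero_minor_rejected(self):
        with pytest.raises(ValueError):
            assays.er_aspect_ratio(1.0, 0.0)


def enumerate_mw_oracle(a, b):
    """Exhaustive labeling oracle for the two-sided Mann-Whitney p-value."""
    combined = np.asarray(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = stats.rankdata(combined)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    center = n_a * (len(combined) - n_a) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(combined)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


class TestMannWhitney:
    def test_separated_groups(self):
        res = assays.mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(2 / 20)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        res = assays.mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_matches_oracle_with_ties(self):
        a, b = [1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 4.0]
        res = assays.mann_whitney_exact(a, b)
        u_oracle, p_oracle = enumerate_mw_oracle(a, b)
        assert res.u == pytest.approx(u_oracle)
        assert res.p == pytest.approx(p_oracle)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=6), rng.normal(1.0, size=7)
        res = assays.mann_whitney_exact(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_vs_normal_approx_close_at_n10(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(size=10), rng.normal(0.8, size=10)
        exact = assays.mann_whitney_exact(a, b, exact_limit=25)
        approx = assays.mann_whitney_exact(a, b, exact_limit=0)
        assert approx.method == "normal"
        assert abs(exact.p - approx.p) < 0.01

    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=5),
        st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_matches_enumeration_property(self, a, b):
        res = assays.mann_whitney_exact(a, b)
        _, p_oracle = enumerate_mw_oracle(a, b)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assays.mann_whitney_exact([], [1.0])


class TestEffectSize:
    def test_difference_of_means(self):
        es = assays.effect_size([1, 2, 3], [4, 5, 6])
        assert es.difference == pytest.approx(3.0)

    def test_sem_quadrature(self):
        es = assays.effect_size([1, 2, 3], [4, 5, 6])
        assert es.sem == pytest.approx(math.sqrt(1 / 3 + 1 / 3))

    def test_equal_groups_zero_difference(self):
        es = assays.effect_size([2.0, 4.0], [2.0, 4.0])
        assert es.difference == 0.0
        # each group: sd = sqrt(2), se = 1; quadrature sem = sqrt(2)
        assert es.sem == pytest.approx(math.sqrt(2.0))


class TestMadOutliers:
    def test_flags_gross_outlier(self):
        mask = assays.mad_outlier_mask([1.0, 1.1, 0.9, 1.05, 50.0])
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_data_no_outliers(self):
        assert not assays.mad_outlier_mask([2.0, 2.0, 2.0]).any()
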