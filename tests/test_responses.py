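"""Window extrema, response metrics and the shape classifier."""

import numpy as np
import pytest

from asetrace import (
    ClassifierThresholds,
    NoiseModel,
    NormalizedTrace,
    ResponseTemplate,
    StimulusProtocol,
    WindowSpec,
    classify_response,
    classify_trace,
    default_template,
    normalize_trace,
    response_amplitudes,
    simulate_trace,
    window_extrema,
)
from asetrace.synthetic import transient_kernel


def _norm(dff, protocol):
    return NormalizedTrace(
        time_s=protocol.times(), dff_pct=np.asarray(dff, float), f0=100.0, protocol=protocol
    )


def brute_force_extrema(trace, t_ref, window):
    """Frame-by-frame scan oracle, independent of the vectorized path."""
    lo_pre = hi_post = lo_post = None
    for ti, di in zip(trace.time_s, trace.dff_pct):
        if t_ref - window <= ti <= t_ref:
            lo_pre = di if lo_pre is None else min(lo_pre, di)
        if t_ref < ti <= t_ref + window:
            hi_post = di if hi_post is None else max(hi_post, di)
            lo_post = di if lo_post is None else min(lo_post, di)
    return lo_pre, hi_post, lo_post


class TestWindowExtrema:
    def test_flat_zero_trace(self, protocol):
        out = window_extrema(_norm(np.zeros(120), protocol), protocol, WindowSpec())
        assert out == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("reference", ["ON_transition", "OFF_transition"])
    def test_matches_brute_force_on_random_traces(self, protocol, rng, reference):
        t_ref = protocol.t_on if reference == "ON_transition" else protocol.t_off
        for _ in range(200):
            trace = _norm(rng.normal(0, 30, size=120), protocol)
            got = window_extrema(trace, protocol, WindowSpec(10.0, reference))
            assert got == brute_force_extrema(trace, t_ref, 10.0)

    def test_on_peak_equals_kernel_maximum_in_window(self, protocol):
        raw, gt = simulate_trace(protocol, ResponseTemplate("ON", a_on=50.0), NoiseModel())
        norm = normalize_trace(raw, protocol)
        _, max_post, _ = window_extrema(norm, protocol, WindowSpec(10.0, "ON_transition"))
        frame_times = protocol.times()
        in_window = (frame_times > 10.0) & (frame_times <= 20.0)
        kernel_vals = transient_kernel(frame_times[in_window], 10.0, 50.0, 1.5, 8.0)
        assert max_post == pytest.approx(kernel_vals.max(), abs=1e-9)

    def test_transition_frame_belongs_to_pre_window(self, protocol):
        dff = np.zeros(120)
        dff[20] = 77.0  # t = 10.0 s exactly: pre-window (closed), not post
        min_pre, max_post, _ = window_extrema(_norm(dff, protocol), protocol, WindowSpec())
        assert max_post == 0.0
        assert min_pre == 0.0  # it's a max, not a min — pre min unaffected

    def test_empty_window_rejected(self):
        proto = StimulusProtocol(t_total=60.0)
        short = NormalizedTrace(
            time_s=np.array([0.0, 0.5]), dff_pct=np.zeros(2), f0=1.0, protocol=proto
        )
        with pytest.raises(ValueError, match="empty window"):
            window_extrema(short, proto, WindowSpec(10.0, "OFF_transition"))


class TestResponseAmplitudes:
    def test_flat_trace_zero_amplitudes(self, protocol):
        m = response_amplitudes(_norm(np.zeros(120), protocol), protocol)
        assert m.on_amplitude == m.off_amplitude == m.off_dip == 0.0
        assert m.sigma_baseline == 0.0

    def test_off_dip_matches_kernel_peak(self, protocol):
        raw, _ = simulate_trace(protocol, ResponseTemplate("OFF", a_off_dip=-30.0), NoiseModel())
        m = response_amplitudes(normalize_trace(raw, protocol), protocol)
        t = protocol.times()
        k = transient_kernel(t[(t > 30.0) & (t <= 40.0)], 30.0, -30.0, 1.5, 8.0)
        assert m.off_dip == pytest.approx(k.min(), abs=1e-9)
        assert m.on_amplitude == pytest.approx(0.0, abs=1e-9)

    def test_biphasic_window_maxima_track_kernel_peaks(self, protocol):
        tmpl = ResponseTemplate("ON_OFF", a_on=40.0, a_off_bump=25.0)
        raw, _ = simulate_trace(protocol, tmpl, NoiseModel())
        m = response_amplitudes(normalize_trace(raw, protocol), protocol)
        peak_factor = 0.5946  # kernel max for tau_r=1.5, tau_d=8
        assert m.afd_on_max == pytest.approx(40.0 * peak_factor, rel=0.01)
        # post-OFF max includes the decayed onset tail on top of the bump
        assert m.afd_off_max >= 25.0 * peak_factor

    def test_on_amplitude_monotone_in_template_amplitude(self, protocol):
        amps = []
        for a_on in (10.0, 20.0, 40.0, 80.0):
            raw, _ = simulate_trace(protocol, ResponseTemplate("ON", a_on=a_on), NoiseModel())
            amps.append(response_amplitudes(normalize_trace(raw, protocol), protocol).on_amplitude)
        assert all(b > a for a, b in zip(amps, amps[1:]))

    def test_truncated_trace_rejected_naming_missing_window(self, protocol):
        trunc = NormalizedTrace(
            time_s=protocol.times()[:70],
            dff_pct=np.zeros(70),
            f0=100.0,
            protocol=protocol,
        )
        with pytest.raises(ValueError, match="post-OFF window"):
            response_amplitudes(trunc, protocol)


class TestClassifier:
    def test_noiseless_templates_all_recovered(self, protocol, noiseless_traces):
        for label, (raw, _) in noiseless_traces.items():
            got = classify_trace(normalize_trace(raw, protocol), protocol)
            assert got.label == label, got.evidence

    def test_all_zero_trace_is_none(self, protocol):
        m = response_amplitudes(_norm(np.zeros(120), protocol), protocol)
        assert classify_response(m).label == "NONE"

    def test_label_exclusivity_on_random_metrics(self, protocol, rng):
        labels = {"ON", "OFF", "OFF2", "ON_OFF", "NONE"}
        for _ in range(300):
            trace = _norm(rng.normal(0, 20, size=120), protocol)
            got = classify_trace(trace, protocol)
            assert got.label in labels

    def test_evidence_records_each_comparison(self, protocol, noiseless_traces):
        raw, _ = noiseless_traces["ON_OFF"]
        got = classify_trace(normalize_trace(raw, protocol), protocol)
        assert len(got.evidence) == 4
        assert any("onset" in e for e in got.evidence)
        assert any("bump" in e for e in got.evidence)

    def test_threshold_scaling_changes_decision(self, protocol):
        raw, _ = simulate_trace(protocol, ResponseTemplate("ON", a_on=50.0), NoiseModel())
        norm = normalize_trace(raw, protocol)
        permissive = classify_trace(norm, protocol, ClassifierThresholds())
        strict = classify_trace(
            norm, protocol, ClassifierThresholds(min_amplitude_pct=100.0)
        )
        assert permissive.label == "ON" and strict.label == "NONE"

    def test_noisy_cohort_recovery_at_amplitude_sigma_five(self, protocol):
        from asetrace.calibration import classifier_recovery

        acc = classifier_recovery(n_per_class=20, sigma_shot=8.0, seed=31)
        assert acc >= 0.95


TABLE_HIGH_CONC = {
    # salt -> (left neuron label, right neuron label) at 250 mM
    "NH4Cl": ("ON", "OFF"),
    "NaCl": ("OFF2", "OFF"),
    "NH4I": ("ON", "ON_OFF"),
}


class TestLateralizedLabelFixture:
    @pytest.mark.parametrize("salt,expected", list(TABLE_HIGH_CONC.items()))
    def test_high_concentration_asel_aser_labels(self, protocol, salt, expected):
        """Synthetic shapes configured per the observed high-salt response
        taxonomy classify back to the expected left/right labels."""
        for side, label in zip(("ASEL", "ASER"), expected):
            raw, _ = simulate_trace(protocol, default_template(label), NoiseModel())
            got = classify_trace(normalize_trace(raw, protocol), protocol)
            assert got.label == label, (salt, side, got.label)
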