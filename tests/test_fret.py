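import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retbias.errors import CorrectionError, TraceError, WindowError
from retbias.fret import (
    AmplitudeRecord,
    CorrectionCoefficients,
    RatioTrace,
    RawRecording,
    aggregate_efficacies,
    baseline_correct,
    compute_ratio,
    correct_channels,
    estimate_correction_coefficients,
    extract_amplitude,
    extract_amplitudes,
    normalize_to_reference,
)
from retbias.protocol import ApplicationEvent, ApplicationProtocol
from retbias.synthetic import (
    FretGroundTruth,
    generate_fret_cohort,
    generate_fret_recording,
    standard_protocol,
)


def _flat_recording(protocol, donor=100.0, acceptor=100.0, direct=None):
    t = protocol.time_vector()
    return RawRecording(
        cell_id="c0",
        time=t,
        donor_em=np.full(t.size, donor),
        acceptor_em=np.full(t.size, acceptor),
        acceptor_direct=None if direct is None else np.full(t.size, direct),
        protocol=protocol,
    )


class TestCorrectChannels:
    def test_zero_coefficients_is_identity(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol)
        out = correct_channels(rec, CorrectionCoefficients())
        np.testing.assert_array_equal(out.donor_em, rec.donor_em)
        np.testing.assert_array_equal(out.acceptor_em, rec.acceptor_em)
        assert out.channels_corrected

    def test_recovers_latent_channels_from_known_mixing(
        self, single_pulse_protocol, dirty_truth, dirty_coeff
    ):
        # oracle: the same seeded generation without cross-talk/background
        # is exactly the latent signal the correction must recover
        import dataclasses

        clean_truth = dataclasses.replace(
            dirty_truth,
            bleedthrough_frac=0.0,
            false_excitation_frac=0.0,
            background_donor=0.0,
            background_acceptor=0.0,
        )
        mixed = generate_fret_recording(single_pulse_protocol, dirty_truth)
        latent = generate_fret_recording(single_pulse_protocol, clean_truth)
        out = correct_channels(mixed, dirty_coeff)
        np.testing.assert_allclose(out.donor_em, latent.donor_em, atol=1e-10)
        np.testing.assert_allclose(out.acceptor_em, latent.acceptor_em, atol=1e-10)

    def test_background_only_recording_corrects_to_zero(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol, donor=10.0, acceptor=8.0)
        coeff = CorrectionCoefficients(background_donor=10.0, background_acceptor=8.0)
        out = correct_channels(rec, coeff)
        np.testing.assert_allclose(out.donor_em, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.acceptor_em, 0.0, atol=1e-12)

    def test_overestimated_background_raises(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol, donor=10.0)
        with pytest.raises(CorrectionError, match="negative"):
            correct_channels(rec, CorrectionCoefficients(background_donor=50.0))

    def test_false_excitation_requires_direct_channel(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol)
        with pytest.raises(CorrectionError, match="acceptor_direct"):
            correct_channels(
                rec, CorrectionCoefficients(false_excitation_frac=0.05)
            )

    def test_fraction_bounds_enforced(self):
        with pytest.raises(CorrectionError):
            CorrectionCoefficients(bleedthrough_frac=1.0)
        with pytest.raises(CorrectionError):
            CorrectionCoefficients(background_donor=-1.0)


class TestComputeRatio:
    def test_equal_channels_ratio_one(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol)
        rec.channels_corrected = True
        trace = compute_ratio(rec)
        np.testing.assert_allclose(trace.ratio, 1.0)

    def test_double_acceptor_ratio_two(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol, donor=50.0, acceptor=100.0)
        rec.channels_corrected = True
        np.testing.assert_allclose(compute_ratio(rec).ratio, 2.0)

    def test_step_recording_reproduces_configured_step(
        self, single_pulse_protocol, clean_truth
    ):
        rec = generate_fret_recording(single_pulse_protocol, clean_truth)
        trace = compute_ratio(correct_channels(rec, CorrectionCoefficients()))
        r0 = clean_truth.baseline_ratio
        plateau = (r0 + clean_truth.acceptor_gain) / (1 - clean_truth.fret_scale)
        assert trace.ratio[0] == pytest.approx(r0, rel=1e-12)
        mid = int(85 * 2)  # deep inside the application
        assert trace.ratio[mid] == pytest.approx(plateau, rel=1e-9)

    def test_few_masked_samples_warn(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol)
        rec.channels_corrected = True
        rec.donor_em[:3] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            trace = compute_ratio(rec)
        assert trace.n_masked == 3

    def test_many_masked_samples_error(self, single_pulse_protocol):
        rec = _flat_recording(single_pulse_protocol)
        rec.channels_corrected = True
        rec.donor_em[: rec.donor_em.size // 2] = -1.0
        with pytest.raises(TraceError, match="non-positive donor"):
            compute_ratio(rec)


class TestBaselineCorrect:
    def test_drift_free_trace_unchanged(self, two_pulse_protocol):
        t = two_pulse_protocol.time_vector()
        trace = RatioTrace("c0", t, np.full(t.size, 1.25), two_pulse_protocol)
        out = baseline_correct(trace)
        np.testing.assert_allclose(out.ratio, trace.ratio, atol=1e-9)
        assert out.baseline_corrected

    def test_pure_bleach_becomes_constant(self, two_pulse_protocol):
        # generator truth: exponential ratio drift, no agonist response
        truth = FretGroundTruth(
            efficacies={"ACh": 0.0, "Pilo": 0.0},
            donor_bleach_rate=1e-4,
            acceptor_bleach_rate=6e-4,
        )
        rec = generate_fret_recording(two_pulse_protocol, truth)
        trace = compute_ratio(correct_channels(rec, CorrectionCoefficients()))
        out = baseline_correct(trace)
        assert np.ptp(out.ratio) < 1e-7

    def test_bleach_plus_responses_recovers_truth(
        self, two_pulse_protocol, dirty_truth, dirty_coeff
    ):
        rec = generate_fret_recording(two_pulse_protocol, dirty_truth)
        trace = baseline_correct(compute_ratio(correct_channels(rec, dirty_coeff)))
        amps = {
            a.agonist_id: a.raw_amplitude for a in extract_amplitudes(trace)
        }
        for agonist, eff in dirty_truth.efficacies.items():
            assert amps[agonist] == pytest.approx(
                dirty_truth.expected_amplitude(eff), rel=1e-4
            )

    def test_single_buffer_segment_falls_back_to_linear(self):
        proto = ApplicationProtocol(
            events=(ApplicationEvent("ACh", 1e-6, 60.0, 175.0),),
            total_duration=180.0,
        )
        t = proto.time_vector()
        trace = RatioTrace("c0", t, 1.0 + 1e-4 * t, proto)
        with pytest.warns(UserWarning, match="linear"):
            out = baseline_correct(trace, washout_settle=30.0)
        # linear drift divided out: buffer portion flat again
        assert np.ptp(out.ratio[: int(55 * 2)]) < 1e-9


class TestExtractAmplitude:
    def test_constant_trace_zero_amplitude(self, single_pulse_protocol):
        t = single_pulse_protocol.time_vector()
        trace = RatioTrace("c0", t, np.ones(t.size), single_pulse_protocol)
        rec = extract_amplitude(trace, single_pulse_protocol.events[0])
        assert rec.raw_amplitude == 0.0

    def test_step_amplitude(self, single_pulse_protocol):
        ev = single_pulse_protocol.events[0]
        t = single_pulse_protocol.time_vector()
        ratio = np.where((t >= ev.t_start) & (t < ev.t_end), 1.2, 1.0)
        trace = RatioTrace("c0", t, ratio, single_pulse_protocol)
        rec = extract_amplitude(trace, ev)
        assert rec.raw_amplitude == pytest.approx(0.2, abs=1e-12)

    def test_windows_are_half_open_ten_samples(self, single_pulse_protocol):
        ev = single_pulse_protocol.events[0]
        t = single_pulse_protocol.time_vector()
        trace = RatioTrace("c0", t, np.ones(t.size), single_pulse_protocol)
        rec = extract_amplitude(trace, ev)
        for lo, hi in (rec.window_pre, rec.window_post):
            n = np.sum((t >= lo) & (t < hi))
            assert n == 10  # 5 s at 2 Hz

    def test_empty_window_names_event(self):
        proto = ApplicationProtocol(
            events=(ApplicationEvent("Guva", 1e-6, 2.0, 30.0),),
            total_duration=40.0,
            sampling_rate=0.1,
        )
        t = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        trace = RatioTrace("c0", t, np.ones(5), proto)
        with pytest.raises(WindowError, match="Guva"):
            extract_amplitude(trace, proto.events[0])

    def test_noisy_amplitude_within_statistical_tolerance(
        self, single_pulse_protocol, rng
    ):
        # independent window-mean oracle on the very same noisy samples
        ev = single_pulse_protocol.events[0]
        t = single_pulse_protocol.time_vector()
        noise_sd = 0.02
        clean = np.where((t >= ev.t_start) & (t < ev.t_end), 1.2, 1.0)
        noisy = clean + rng.normal(0.0, noise_sd, t.size)
        trace = RatioTrace("c0", t, noisy, single_pulse_protocol)
        rec = extract_amplitude(trace, ev)
        pre = noisy[(t >= ev.t_start - 5) & (t < ev.t_start)]
        post = noisy[(t >= ev.t_end - 5) & (t < ev.t_end)]
        assert rec.raw_amplitude == pytest.approx(
            post.mean() - pre.mean(), abs=1e-12
        )
        assert abs(rec.raw_amplitude - 0.2) < 3 * noise_sd * np.sqrt(2 / 10)

    @given(shift=st.floats(-5.0, 5.0, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, shift):
        proto = ApplicationProtocol(
            events=(ApplicationEvent("ACh", 1e-6, 30.0, 60.0),),
            total_duration=90.0,
        )
        t = proto.time_vector()
        ratio = 1.0 + 0.2 * np.sin(t / 7.0)
        base = extract_amplitude(
            RatioTrace("c", t, ratio, proto), proto.events[0]
        ).raw_amplitude
        shifted = extract_amplitude(
            RatioTrace("c", t, ratio + shift, proto), proto.events[0]
        ).raw_amplitude
        assert shifted == pytest.approx(base, abs=1e-9)


def _amp(cell, agonist, raw, idx=0):
    return AmplitudeRecord(
        cell_id=cell,
        agonist_id=agonist,
        concentration=1e-6,
        raw_amplitude=raw,
        window_pre=(0, 5),
        window_post=(25, 30),
        application_index=idx,
    )


class TestNormalize:
    def test_reference_normalizes_to_one(self):
        out = normalize_to_reference([_amp("c0", "ACh", 0.2)], "ACh")
        assert out[0].normalized_amplitude == 1.0

    def test_simple_arithmetic(self):
        recs = [_amp("c0", "ACh", 0.10), _amp("c0", "Pilo", 0.05)]
        out = normalize_to_reference(recs, "ACh")
        by = {r.agonist_id: r.normalized_amplitude for r in out}
        assert by == {"ACh": 1.0, "Pilo": 0.5}

    def test_nonpositive_reference_excludes_cell(self, caplog):
        recs = [_amp("c0", "ACh", 0.0), _amp("c0", "Pilo", 0.05)]
        with caplog.at_level("WARNING"):
            out = normalize_to_reference(recs, "ACh")
        assert out == []
        assert "excluded" in caplog.text

    def test_policy_first_vs_max(self):
        recs = [
            _amp("c0", "ACh", 0.10, idx=0),
            _amp("c0", "ACh", 0.20, idx=1),
            _amp("c0", "Pilo", 0.05),
        ]
        first = {
            r.agonist_id: r.normalized_amplitude
            for r in normalize_to_reference(recs, "ACh", "first")
            if r.agonist_id == "Pilo"
        }
        mx = {
            r.agonist_id: r.normalized_amplitude
            for r in normalize_to_reference(recs, "ACh", "max")
            if r.agonist_id == "Pilo"
        }
        assert first["Pilo"] == pytest.approx(0.5)
        assert mx["Pilo"] == pytest.approx(0.25)

    def test_idempotent_on_normalized_table(self):
        recs = [_amp("c0", "ACh", 1.0), _amp("c0", "Pilo", 0.4)]
        once = normalize_to_reference(recs, "ACh")
        again_in = [
            _amp(r.cell_id, r.agonist_id, r.normalized_amplitude) for r in once
        ]
        twice = normalize_to_reference(again_in, "ACh")
        for a, b in zip(once, twice):
            assert b.normalized_amplitude == pytest.approx(
                a.normalized_amplitude, abs=1e-15
            )

    def test_multicell_cohort_recovers_relative_efficacies(self):
        effs = {"ACh": 1.0, "Metha": 0.6, "Pilo": 0.08}
        proto = standard_protocol(list(effs))
        truth = FretGroundTruth(
            efficacies=effs, noise_sd=1.0, cell_scale_sd=0.1, seed=7
        )
        cohort = generate_fret_cohort(proto, truth, 10)
        records = []
        for rec in cohort:
            trace = baseline_correct(
                compute_ratio(correct_channels(rec, CorrectionCoefficients()))
            )
            records.extend(extract_amplitudes(trace))
        table = aggregate_efficacies(
            normalize_to_reference(records, "ACh"), "Gq"
        )
        for agonist, eff in effs.items():
            assert abs(table.means[agonist] - eff) < 0.05


class TestAggregate:
    def test_identical_values_sd_zero(self):
        recs = normalize_to_reference(
            [_amp("c0", "ACh", 0.2), _amp("c1", "ACh", 0.2)], "ACh"
        )
        table = aggregate_efficacies(recs, "Gq")
        assert table.summary["sd"].iloc[0] == 0.0

    def test_mean_and_sd_arithmetic(self):
        recs = [
            _amp("c0", "ACh", 1.0),
            _amp("c0", "Pilo", 0.4),
            _amp("c1", "ACh", 1.0),
            _amp("c1", "Pilo", 0.6),
        ]
        table = aggregate_efficacies(normalize_to_reference(recs, "ACh"), "Gq")
        row = table.summary.set_index("agonist").loc["Pilo"]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(np.std([0.4, 0.6], ddof=1))
        assert row["n"] == 2

    def test_repeat_applications_excluded(self):
        recs = [
            _amp("c0", "ACh", 0.2, idx=0),
            _amp("c0", "ACh", 0.1, idx=1),
        ]
        table = aggregate_efficacies(normalize_to_reference(recs, "ACh"), "Gq")
        assert table.values["ACh"].size == 1


class TestEstimateCoefficients:
    def test_recovers_generator_fractions(self, single_pulse_protocol):
        truth = FretGroundTruth(
            efficacies={"ACh": 0.0},
            bleedthrough_frac=0.15,
            false_excitation_frac=0.05,
        )
        t = single_pulse_protocol.time_vector()
        # donor-only cell: no acceptor, so acceptor channel is pure bleed-through
        donor_only = RawRecording(
            "d0",
            t,
            donor_em=np.full(t.size, 100.0),
            acceptor_em=np.full(t.size, 15.0),
            protocol=single_pulse_protocol,
        )
        acceptor_only = RawRecording(
            "a0",
            t,
            donor_em=np.zeros(t.size),
            acceptor_em=np.full(t.size, 5.0),
            acceptor_direct=np.full(t.size, 100.0),
            protocol=single_pulse_protocol,
        )
        coeff = estimate_correction_coefficients(donor_only, acceptor_only)
        assert coeff.bleedthrough_frac == pytest.approx(0.15, rel=1e-12)
        assert coeff.false_excitation_frac == pytest.approx(0.05, rel=1e-12)
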