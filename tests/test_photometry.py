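"""ΔF/F identities, refractory exclusion, peri-event extraction and
per-animal summaries, including recovery of generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pairbond import photometry as ph
from pairbond.synthetic import SimConfig, biexp_kernel, generate_photometry_session


def make_trace(values, fs=10.0):
    return ph.PhotometryTrace(samples=np.asarray(values, float), fs=fs)


def simple_epoch(onset=10.0, end=30.0):
    return ph.ExposureEpoch(stimulus_label="partner", stimulus_onset_s=onset, epoch_end_s=end)


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        trace = make_trace(np.full(301, 2.0))
        dff = ph.compute_dff(trace, simple_epoch())
        assert dff.f0 == pytest.approx(2.0)
        np.testing.assert_allclose(dff.values, 0.0)

    def test_printed_formula_arithmetic(self):
        """F0 = 1 and F = 1.5 at some sample → ΔF/F = 0.5 there."""
        samples = np.ones(301)
        samples[150] = 1.5
        dff = ph.compute_dff(make_trace(samples), simple_epoch())
        assert dff.values.max() == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(gain=hst.floats(min_value=0.1, max_value=100.0), data=hst.integers(0, 2**31 - 1))
    def test_gain_invariance(self, gain, data):
        rng = np.random.default_rng(data)
        samples = 1.0 + 0.1 * rng.random(301)
        base = ph.compute_dff(make_trace(samples), simple_epoch())
        scaled = ph.compute_dff(make_trace(gain * samples), simple_epoch())
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9, atol=1e-12)

    def test_f0_is_baseline_window_mean(self):
        samples = np.ones(301)
        samples[:100] = 3.0  # [0, 10) s at 10 Hz: the F0 window
        dff = ph.compute_dff(make_trace(samples), simple_epoch())
        assert dff.f0 == pytest.approx(3.0)

    def test_truncated_baseline_and_nonpositive_f0_raise(self):
        with pytest.raises(ph.InvalidBaselineError):
            ph.compute_dff(make_trace(np.ones(301)), simple_epoch(onset=5.0))
        with pytest.raises(ph.InvalidBaselineError):
            ph.compute_dff(make_trace(np.zeros(301)), simple_epoch())


class TestRefractoryExclusion:
    def bouts(self, spans):
        return [ph.BoutEvent("sniffing", s, e) for s, e in spans]

    def test_well_spaced_bouts_all_included(self):
        flags = ph.apply_refractory_exclusion(self.bouts([(0, 2), (10, 12), (20, 22)]))
        assert [keep for _, keep in flags] == [True, True, True]

    def test_short_gap_excludes_second_bout(self):
        """Offset 2 s to onset 5 s is a 3-s gap, under the 4-s rule."""
        flags = ph.apply_refractory_exclusion(self.bouts([(0, 2), (5, 7)]))
        assert [keep for _, keep in flags] == [True, False]

    def test_single_bout_included(self):
        flags = ph.apply_refractory_exclusion(self.bouts([(3, 4)]))
        assert flags[0][1] is True

    def test_excluded_bout_does_not_reset_clock(self):
        # gap to the last *included* bout governs: third bout measured from
        # the first bout's offset, not the excluded second one's
        flags = ph.apply_refractory_exclusion(self.bouts([(0, 2), (4, 9), (10, 11)]))
        assert [keep for _, keep in flags] == [True, False, True]

    def test_onset_reference_flag(self):
        flags = ph.apply_refractory_exclusion(
            self.bouts([(0, 2), (3.5, 5)]), reference="onset"
        )
        assert [keep for _, keep in flags] == [True, False]

    def test_exclusion_is_monotone_in_prefix(self):
        """Appending a bout never changes earlier inclusion flags."""
        spans = [(0, 2), (5, 7), (12, 13), (14, 15), (20, 21)]
        prev = None
        for n in range(1, len(spans) + 1):
            flags = [k for _, k in ph.apply_refractory_exclusion(self.bouts(spans[:n]))]
            if prev is not None:
                assert flags[: len(prev)] == prev
            prev = flags

    def test_unsorted_bouts_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            ph.apply_refractory_exclusion(self.bouts([(5, 6), (0, 2)]))


class TestPeriEvent:
    def flat_dff(self, fs=20.0, total=60.0):
        n = int(total * fs) + 1
        return ph.DffTrace(
            values=np.zeros(n), fs=fs, f0=1.0, t0_s=0.0, epoch=simple_epoch(10.0, total)
        )

    def test_grid_arithmetic(self):
        peri = ph.extract_peri_event(
            self.flat_dff(), [ph.BoutEvent("sniffing", 30.0, 31.0)], pre_s=10, post_s=10
        )
        assert peri.values.shape == (1, 401)
        assert peri.rel_time_s[0] == pytest.approx(-10.0)
        assert peri.rel_time_s[-1] == pytest.approx(10.0)

    def test_zero_dff_gives_zero_matrix(self):
        peri = ph.extract_peri_event(
            self.flat_dff(), [ph.BoutEvent("sniffing", 25.0, 26.0)]
        )
        np.testing.assert_array_equal(peri.values, 0.0)

    def test_empty_bout_list_is_empty_matrix_not_error(self):
        peri = ph.extract_peri_event(self.flat_dff(), [])
        assert peri.values.shape[0] == 0

    def test_uncovered_bout_dropped(self):
        peri = ph.extract_peri_event(
            self.flat_dff(), [ph.BoutEvent("sniffing", 58.0, 59.0)], pre_s=10, post_s=10
        )
        assert peri.values.shape[0] == 0


class TestBoutResponse:
    def matrix(self, row, fs=20.0):
        n = row.size
        rel = -10.0 + np.arange(n) / fs
        return ph.PeriEventMatrix(
            values=row[None, :],
            rel_time_s=rel,
            fs=fs,
            bouts=[ph.BoutEvent("sniffing", 0.0, 1.0)],
        )

    def test_constant_row(self):
        row = np.full(401, 0.1)
        (resp,) = ph.bout_response(self.matrix(row))
        assert resp.mean_dff == pytest.approx(0.1)

    def test_linear_ramp_mean(self):
        """ΔF/F ramping 0→0.4 over the 4-s window averages to 0.2."""
        fs = 20.0
        rel = -10.0 + np.arange(401) / fs
        row = np.clip(rel, 0.0, 4.0) * 0.1
        (resp,) = ph.bout_response(self.matrix(row))
        assert resp.mean_dff == pytest.approx(0.2, abs=0.005)

    def test_window_outside_span_raises(self):
        with pytest.raises(ValueError, match="window"):
            ph.bout_response(self.matrix(np.zeros(401)), window_s=(0.0, 20.0))


class TestSummarize:
    def resp(self, mean, included=True):
        return ph.BoutResponse(
            bout_index=0,
            bout=ph.BoutEvent("sniffing", 0.0, 1.0),
            mean_dff=mean,
            included=included,
            exclusion_reason="" if included else "refractory",
        )

    def test_single_bout(self):
        s = ph.summarize_session({"partner": [self.resp(0.3)]})
        assert s.stimulus_means["partner"] == pytest.approx(0.3)

    def test_excluded_bouts_ignored(self):
        s = ph.summarize_session(
            {"partner": [self.resp(0.1), self.resp(0.3), self.resp(9.9, included=False)]}
        )
        assert s.stimulus_means["partner"] == pytest.approx(0.2)
        assert s.n_bouts_included["partner"] == 2

    def test_missing_stimulus_flagged_not_zero(self):
        s = ph.summarize_session({"partner": [self.resp(0.3)]}, expected_stimuli=["partner", "object"])
        assert "object" in s.missing_stimuli
        assert "object" not in s.stimulus_means


class TestGroundTruthRecovery:
    def test_window_means_recover_true_amplitudes(self):
        """Peri-event row means over [0,4) s equal the generated amplitude
        times the kernel's window mean, up to noise and transient overlap."""
        cfg = SimConfig(seed=11, session_length_s=600.0, noise_sd_photometry=0.002)
        session, truth = generate_photometry_session(cfg, "day7:partner")
        dff = ph.compute_dff(session.trace, session.epoch)
        flags = ph.apply_refractory_exclusion(session.bouts)
        included_idx = [i for i, (_, keep) in enumerate(flags) if keep]
        included = [session.bouts[i] for i in included_idx]
        peri = ph.extract_peri_event(dff, included)
        responses = ph.bout_response(peri)
        # independent oracle: window-mean of the unit-peak transient kernel
        t = np.arange(0, 4.0, 1.0 / cfg.fs_photometry)
        kernel_factor = float(
            np.mean(
                biexp_kernel(t, cfg.transient_tau_rise_s, cfg.transient_tau_decay_s)
            )
        )
        kept_starts = {b.start_s for b in peri.bouts}
        all_starts = np.array([b.start_s for b in session.bouts])
        truth_by_start = {
            session.bouts[i].start_s: truth.true_bout_amplitudes[i] for i in included_idx
        }
        measured, expected = [], []
        for r in responses:
            s0 = r.bout.start_s
            if s0 not in kept_starts:
                continue
            # only windows free of other bout onsets isolate one transient
            others = all_starts[(all_starts > s0) & (all_starts < s0 + 4.0)]
            if others.size:
                continue
            measured.append(r.mean_dff)
            expected.append(truth_by_start[s0] * kernel_factor)
        measured, expected = np.array(measured), np.array(expected)
        assert measured.size >= 10
        assert np.corrcoef(measured, expected)[0, 1] > 0.9
        assert np.mean(measured - expected) == pytest.approx(0.0, abs=0.01)

    def test_flat_trace_pipeline_yields_exact_zero_summary(self):
        cfg = SimConfig(
            seed=3,
            session_length_s=120.0,
            transient_amp={k: 0.0 for k in SimConfig().transient_amp},
            noise_sd_photometry=0.0,
        )
        session, _ = generate_photometry_session(cfg, "day7:partner")
        dff = ph.compute_dff(session.trace, session.epoch)
        peri = ph.extract_peri_event(dff, [b for b, k in ph.apply_refractory_exclusion(session.bouts) if k])
        responses = ph.bout_response(peri)
        s = ph.summarize_session({"partner": responses})
        if "partner" in s.stimulus_means:
            assert s.stimulus_means["partner"] == 0.0
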