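"""Simulator tests: schedules, injected jitter, noise spectrum, round-trips."""

import numpy as np
import pytest
from scipy import signal, stats

from p300cble.simulate import (
    SimConfig,
    build_schedule,
    p300_template,
    pink_noise,
    read_session,
    synthesize_session,
    write_session,
)

from conftest import small_config


class TestBuildSchedule:
    def test_single_char_counts(self):
        cfg = small_config(sentences=("A",))
        ev = build_schedule(cfg, "A", np.random.default_rng(0))
        assert len(ev) == 120  # 12 codes x 10 sequences
        assert sum(e.is_target for e in ev) == 20  # one row + one col per sequence

    def test_onset_spacing_is_one_soa(self):
        cfg = small_config()
        ev = build_schedule(cfg, "AB", np.random.default_rng(0))
        onsets = np.array([e.sample_index for e in ev])
        assert np.all(np.diff(onsets) == round(167 * 600 / 1000))  # 100 samples

    def test_each_sequence_has_all_codes_once_and_two_targets(self):
        cfg = small_config()
        ev = build_schedule(cfg, "Q", np.random.default_rng(3))
        for s in range(cfg.n_sequences):
            seq = [e for e in ev if e.sequence_index == s]
            assert sorted(e.stim_code for e in seq) == list(range(1, 13))
            assert sum(e.is_target for e in seq) == 2
            codes = {e.stim_code for e in seq if e.is_target}
            assert len([c for c in codes if c <= 6]) == 1  # one row, one column
            assert len([c for c in codes if c >= 7]) == 1

    def test_deterministic_given_rng_seed(self):
        cfg = small_config()
        a = build_schedule(cfg, "AB", np.random.default_rng(42))
        b = build_schedule(cfg, "AB", np.random.default_rng(42))
        assert a == b

    def test_unmappable_character_raises_with_name(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="'#'"):
            build_schedule(cfg, "A#B", np.random.default_rng(0))

    @pytest.mark.parametrize("sentence,n_seq", [("AB", 3), ("HELLO", 5), ("X", 10)])
    def test_event_count_conservation(self, sentence, n_seq):
        cfg = small_config(n_sequences=n_seq)
        ev = build_schedule(cfg, sentence, np.random.default_rng(1))
        assert len(ev) == 12 * n_seq * len(sentence)


class TestSimConfig:
    def test_rejects_bad_timing(self):
        with pytest.raises(ValueError):
            small_config(soa_ms=50.0, stim_duration_ms=67.0)

    def test_rejects_empty_sentences(self):
        with pytest.raises(ValueError):
            small_config(sentences=())

    def test_rejects_unmappable_sentence(self):
        with pytest.raises(ValueError):
            small_config(sentences=("A?B",))


class TestSynthesizeSession:
    def test_truth_latencies_only_for_targets(self, small_session):
        is_tgt = np.array([e.is_target for e in small_session.events])
        assert np.all(np.isfinite(small_session.true_latency_ms[is_tgt]))
        assert np.all(np.isnan(small_session.true_latency_ms[~is_tgt]))

    def test_recording_covers_last_epoch(self, small_session):
        last = max(e.sample_index for e in small_session.events)
        assert small_session.n_samples >= last + 450

    def test_noiseless_session_equals_template_superposition(self):
        """Independent oracle: rebuild the signal by summing templates."""
        cfg = small_config(noise_level_uv=0.0, p300_jitter_sd_ms=10.0, rng_seed=5)
        s = synthesize_session(cfg)
        expected = np.zeros_like(s.eeg)
        topo = cfg.topography
        for ev, lat in zip(s.events, s.true_latency_ms):
            if not ev.is_target:
                continue
            peak = ev.sample_index + lat * cfg.fs / 1000.0
            t = np.arange(s.n_samples)
            sd = (cfg.p300_width_ms / 2.355) * cfg.fs / 1000.0
            tpl = cfg.p300_amplitude_uv * np.exp(-0.5 * ((t - peak) / sd) ** 2)
            tpl[np.abs(t - peak) >= 4 * sd + 2] = 0  # same support truncation
            expected += topo[:, None] * tpl[None, :]
        # identical up to the template's finite support truncation
        assert np.max(np.abs(s.eeg - expected)) < 1e-3 * cfg.p300_amplitude_uv

    @pytest.mark.parametrize("sd", [20.0, 60.0, 100.0])
    def test_injected_jitter_variance_matches_truncated_normal(self, sd):
        """Sample variance of truth latencies ~ variance of the +-3 sd
        truncated normal, within 3 standard errors."""
        cfg = small_config(
            sentences=("ABCDEFGHIJ",), p300_jitter_sd_ms=sd, noise_level_uv=0.0,
            rng_seed=int(sd),
        )
        s = synthesize_session(cfg)
        lats = s.true_latency_ms[~np.isnan(s.true_latency_ms)]
        assert len(lats) == 200  # 10 chars x 10 sequences x 2 targets
        # var of a normal truncated at +-a sd: sd^2 * (1 - 2a phi(a) / (2 Phi(a) - 1))
        a = 3.0
        phi, Phi = stats.norm.pdf(a), stats.norm.cdf(a)
        expected = sd**2 * (1 - 2 * a * phi / (2 * Phi - 1))
        sample_var = np.var(lats, ddof=1)
        se = expected * np.sqrt(2.0 / (len(lats) - 1))
        assert abs(sample_var - expected) < 3 * se

    def test_jitter_zero_gives_constant_latency(self):
        cfg = small_config(p300_jitter_sd_ms=0.0)
        s = synthesize_session(cfg)
        lats = s.true_latency_ms[~np.isnan(s.true_latency_ms)]
        assert np.all(lats == cfg.p300_mean_latency_ms)

    def test_zero_amplitude_null_calibration(self):
        """Without a P300, target and non-target epochs are indistinguishable:
        two-sample t-test p-values should be uniform over repeats."""
        pvals = []
        for seed in range(40):
            cfg = small_config(
                p300_amplitude_uv=0.0, n_channels=2, n_sequences=2,
                noise_level_uv=5.0, rng_seed=seed,
            )
            s = synthesize_session(cfg)
            onsets = np.array([e.sample_index for e in s.events])
            is_tgt = np.array([e.is_target for e in s.events])
            # one-SOA windows: disjoint across flashes, so the t-test's
            # independence assumption holds (full epochs overlap heavily)
            amp = np.array([s.eeg[:, o : o + 100].mean() for o in onsets])
            pvals.append(stats.ttest_ind(amp[is_tgt], amp[~is_tgt]).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("exponent", [1.0, 2.0])
    def test_background_spectral_slope(self, exponent):
        rng = np.random.default_rng(11)
        x = pink_noise(4, 2**16, 600.0, 10.0, exponent, rng)
        f, psd = signal.welch(x, fs=600.0, nperseg=4096, axis=1)
        band = (f >= 1.0) & (f <= 100.0)
        slope = np.polyfit(np.log(f[band]), np.log(psd[:, band].mean(axis=0)), 1)[0]
        assert abs(-slope - exponent) < 0.3

    def test_noise_rms_matches_config(self):
        rng = np.random.default_rng(0)
        x = pink_noise(3, 50000, 600.0, 7.5, 1.0, rng)
        assert np.allclose(np.sqrt((x**2).mean(axis=1)), 7.5, rtol=1e-6)

    def test_template_peak_and_width(self):
        fs = 600.0
        tpl = p300_template(900, 450.0, fs, 5.0, 150.0)
        assert np.argmax(tpl) == 450
        assert tpl.max() == pytest.approx(5.0)
        # FWHM: width at half maximum ~ 150 ms = 90 samples
        above = np.flatnonzero(tpl >= 2.5)
        assert abs((above[-1] - above[0]) - 90) <= 2


class TestSessionIO:
    def test_round_trip(self, small_session, tmp_path):
        p = tmp_path / "sess.h5"
        write_session(small_session, p)
        back = read_session(p)
        assert np.allclose(back.eeg, small_session.eeg)
        assert back.events == small_session.events
        assert back.char_labels == small_session.char_labels
        assert np.array_equal(
            back.true_latency_ms, small_session.true_latency_ms, equal_nan=True
        )
        assert back.fs == small_session.fs
        assert back.config == small_session.config

    def test_events_sidecar_is_delimited_text(self, small_session, tmp_path):
        p = tmp_path / "sess.h5"
        write_session(small_session, p)
        header = (tmp_path / "sess.h5.events.tsv").read_text().splitlines()[0]
        assert header.split("\t") == [
            "sample_index", "stim_code", "is_target",
            "char_index", "sequence_index", "true_latency_ms",
        ]

    def test_truncated_events_table_raises(self, small_session, tmp_path):
        p = tmp_path / "sess.h5"
        write_session(small_session, p)
        ev = tmp_path / "sess.h5.events.tsv"
        lines = ev.read_text().splitlines()
        ev.write_text("\n".join(lines[: len(lines) // 2]))
        with pytest.raises(ValueError, match="truncated"):
            read_session(p)

    def test_malformed_container_raises(self, tmp_path):
        p = tmp_path / "bad.h5"
        p.write_bytes(b"this is not hdf5")
        with pytest.raises(ValueError, match="malformed"):
            read_session(p)
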