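"""Shared fixtures: small synthetic sessions and hand-built recordings."""

import dataclasses

import numpy as np
import pytest

from p300cble.preprocess import downsample_epochs, epoch
from p300cble.simulate import (
    ContinuousSession,
    SimConfig,
    StimulusEvent,
    p300_template,
    synthesize_session,
)


def small_config(**over):
    """Cheap-but-complete session config (8 channels, short sentences)."""
    defaults = dict(
        n_channels=8,
        sentences=("AB",),
        n_sequences=10,
        p300_jitter_sd_ms=20.0,
        noise_level_uv=2.0,
        rng_seed=7,
    )
    defaults.update(over)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_session():
    return synthesize_session(small_config())


@pytest.fixture(scope="session")
def small_features(small_session):
    return downsample_epochs(epoch(small_session))


def split_train(epochs, n_train_chars):
    """Restrict an EpochSet to trials of the first ``n_train_chars`` characters."""
    m = epochs.char_index < n_train_chars
    return dataclasses.replace(
        epochs,
        data=epochs.data[m],
        is_target=epochs.is_target[m],
        stim_code=epochs.stim_code[m],
        char_index=epochs.char_index[m],
        sequence_index=epochs.sequence_index[m],
    )


def template_session(
    peak_latencies_ms,
    n_channels=2,
    fs=600.0,
    spacing=2000,
    amplitude=5.0,
    width_ms=150.0,
    noise_sd=0.0,
    seed=0,
):
    """Hand-built recording: isolated template responses, no flash overlap.

    One event per entry of ``peak_latencies_ms``; NaN entries are
    non-targets (no response added).  Spacing is wide enough that responses
    never overlap, so target epochs are exactly identical when latencies
    are equal — the controlled setting the CBLE oracles need.
    """
    lats = np.asarray(peak_latencies_ms, dtype=float)
    n = len(lats)
    n_samples = spacing * n + 900
    rng = np.random.default_rng(seed)
    eeg = noise_sd * rng.standard_normal((n_channels, n_samples)) if noise_sd else np.zeros(
        (n_channels, n_samples)
    )
    events = []
    for i, lat in enumerate(lats):
        onset = 600 + i * spacing
        is_tgt = not np.isnan(lat)
        events.append(
            StimulusEvent(
                sample_index=onset,
                stim_code=1 if is_tgt else 2,
                is_target=is_tgt,
                char_index=0,
                sequence_index=i,
            )
        )
        if is_tgt:
            peak = onset + lat * fs / 1000.0
            lo, hi = int(peak) - 400, int(peak) + 401
            seg = p300_template(hi - lo, peak - lo, fs, amplitude, width_ms)
            eeg[:, lo:hi] += seg[None, :]
    return ContinuousSession(
        eeg=eeg,
        fs=fs,
        channel_labels=[f"ch{i:02d}" for i in range(n_channels)],
        events=events,
        char_labels="A",
        sentence_of_char=np.array([0]),
        true_latency_ms=lats,
        config=None,
    )
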