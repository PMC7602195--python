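"""Synthetic oddball-paradigm EEG sessions with controlled P300 latency jitter.

The generator emulates a 6x6 row-column P300 speller recording: rows and
columns flash in random order (12 flashes = one sequence, 10 sequences per
character, 167 ms stimulus onset asynchrony at 600 Hz), and each target flash
elicits a positive, unimodal P300 deflection whose single-trial peak latency
is jittered around a mean.  The injected jitter is recorded per target event,
giving every downstream stage (classification, latency estimation) an exact
ground truth that real EEG cannot provide.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import fft as sfft

from .speller import default_layout, normalize_text, char_to_rowcol

__all__ = [
    "SimConfig",
    "StimulusEvent",
    "ContinuousSession",
    "build_schedule",
    "synthesize_session",
    "write_session",
    "read_session",
    "pink_noise",
    "p300_template",
    "default_topography",
]

#: number of flashes in one complete sequence (6 rows + 6 columns)
CODES_PER_SEQUENCE = 12
#: post-stimulus window (ms) that must remain inside the recording
EPOCH_WINDOW_MS = 750.0


def default_topography(n_channels: int) -> np.ndarray:
    """Smooth per-channel gain for the P300, peaking over centro-parietal sites.

    Channels are indexed front-to-back; the gain is a raised Gaussian bump
    centred at 60% of the array with a floor of 0.3, mimicking the broad
    parietal maximum of the P300.
    """
    i = np.arange(n_channels, dtype=float)
    centre = 0.6 * (n_channels - 1)
    width = max(0.15 * n_channels, 1.0)
    return 0.3 + 0.7 * np.exp(-0.5 * ((i - centre) / width) ** 2)


@dataclass
class SimConfig:
    """Recording- and signal-model parameters for one synthetic participant.

    Defaults mirror the emulated acquisition setup: 64 channels at 600 Hz,
    67 ms flashes with a 100 ms inter-stimulus interval (SOA 167 ms), ten
    sequences per character, and a 6x6 character matrix.
    """

    n_channels: int = 64
    fs: float = 600.0
    soa_ms: float = 167.0
    stim_duration_ms: float = 67.0
    n_sequences: int = 10
    matrix_rows: int = 6
    matrix_cols: int = 6
    sentences: tuple[str, ...] = (
        "THE QUICK BROWN FOX",
        "THANK YOU FOR YOUR HELP",
        "THE DOG BURIED THE BONE",
    )
    p300_mean_latency_ms: float = 300.0
    p300_jitter_sd_ms: float = 50.0
    p300_amplitude_uv: float = 5.0
    p300_width_ms: float = 150.0
    #: amplitude of an optional small early non-target deflection (off by default)
    nontarget_amplitude_uv: float = 0.0
    noise_level_uv: float = 6.0
    noise_exponent: float = 1.0
    p300_topography: np.ndarray | None = None
    #: silent gap inserted between sentences (ms)
    inter_sentence_gap_ms: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.soa_ms <= self.stim_duration_ms:
            raise ValueError("soa_ms must exceed stim_duration_ms")
        for name in ("fs", "n_channels", "n_sequences", "matrix_rows", "matrix_cols"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p300_jitter_sd_ms < 0:
            raise ValueError("p300_jitter_sd_ms must be non-negative")
        if not self.sentences:
            raise ValueError("sentences must be non-empty")
        layout = default_layout(self.matrix_rows, self.matrix_cols)
        for s in self.sentences:
            for ch in normalize_text(s):
                char_to_rowcol(ch, layout)  # raises on unmappable character

    @property
    def soa_samples(self) -> int:
        return int(round(self.soa_ms * self.fs / 1000.0))

    @property
    def topography(self) -> np.ndarray:
        if self.p300_topography is not None:
            g = np.asarray(self.p300_topography, dtype=float)
            if g.shape != (self.n_channels,):
                raise ValueError("p300_topography must have length n_channels")
            return g
        return default_topography(self.n_channels)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["p300_topography"] is not None:
            d["p300_topography"] = np.asarray(d["p300_topography"]).tolist()
        d["sentences"] = list(d["sentences"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("p300_topography") is not None:
            d["p300_topography"] = np.asarray(d["p300_topography"], dtype=float)
        d["sentences"] = tuple(d.get("sentences", cls.sentences))
        return cls(**d)


@dataclass
class StimulusEvent:
    """One row/column flash: codes 1-6 are rows, 7-12 are columns."""

    sample_index: int
    stim_code: int
    is_target: bool
    char_index: int
    sequence_index: int


@dataclass
class ContinuousSession:
    """Continuous multichannel EEG plus its stimulus event stream and truth."""

    eeg: np.ndarray  # channels x samples, microvolt
    fs: float
    channel_labels: list[str]
    events: list[StimulusEvent]
    #: normalized characters spelled in this session, in order
    char_labels: str
    #: sentence index of each character
    sentence_of_char: np.ndarray
    #: injected P300 peak latency (ms post-onset) per event; NaN for non-targets
    true_latency_ms: np.ndarray
    config: SimConfig | None = None

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    def target_event_indices(self) -> np.ndarray:
        return np.flatnonzero([e.is_target for e in self.events])


def build_schedule(
    config: SimConfig,
    sentence: str,
    rng: np.random.Generator,
    start_sample: int = 0,
    char_index_offset: int = 0,
) -> list[StimulusEvent]:
    """Flash schedule for one sentence: per character, ``n_sequences`` random
    permutations of the 12 stimulus codes, onsets spaced by one SOA.

    Raises ``ValueError`` naming any character that does not map into the
    matrix after normalization.
    """
    layout = default_layout(config.matrix_rows, config.matrix_cols)
    chars = normalize_text(sentence)
    if not chars:
        raise ValueError(f"sentence {sentence!r} is empty after normalization")
    events: list[StimulusEvent] = []
    onset = int(start_sample)
    spacing = config.soa_samples
    for ci, ch in enumerate(chars):
        row, col = char_to_rowcol(ch, layout)
        target_codes = {row + 1, col + 7}
        for seq in range(config.n_sequences):
            codes = rng.permutation(CODES_PER_SEQUENCE) + 1
            for code in codes:
                events.append(
                    StimulusEvent(
                        sample_index=onset,
                        stim_code=int(code),
                        is_target=int(code) in target_codes,
                        char_index=ci + char_index_offset,
                        sequence_index=seq,
                    )
                )
                onset += spacing
    return events


def pink_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    rms_uv: float,
    exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, scaled to a target RMS.

    Synthesized by spectrally shaping white noise in the frequency domain;
    the DC bin is zeroed so the background is mean-free.
    """
    if rms_uv == 0:
        return np.zeros((n_channels, n_samples))
    nfft = sfft.next_fast_len(n_samples)  # pad to an FFT-friendly length
    white = rng.standard_normal((n_channels, nfft))
    spec = sfft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = sfft.irfft(spec * shaping, n=nfft, axis=1)[:, :n_samples]
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped / rms * rms_uv


def p300_template(
    n_samples_out: int,
    peak_sample: float,
    fs: float,
    amplitude_uv: float,
    width_ms: float,
) -> np.ndarray:
    """Gaussian-windowed positive deflection; FWHM equals ``width_ms``."""
    sd_samples = (width_ms / 2.355) * fs / 1000.0
    t = np.arange(n_samples_out, dtype=float)
    return amplitude_uv * np.exp(-0.5 * ((t - peak_sample) / sd_samples) ** 2)


def synthesize_session(config: SimConfig) -> ContinuousSession:
    """Generate one continuous session for all sentences in ``config``.

    The EEG is 1/f background noise plus, for every target flash, a P300
    whose peak occurs at ``p300_mean_latency_ms + eps`` post-onset with
    ``eps ~ Normal(0, jitter_sd^2)`` truncated at +-3 sd.  Responses to
    flashes closer together than the epoch window overlap and sum linearly.
    The injected peak latency of every target event is recorded.
    """
    rng = np.random.default_rng(config.rng_seed)
    fs = config.fs
    gap = int(round(config.inter_sentence_gap_ms * fs / 1000.0))
    window = int(round(EPOCH_WINDOW_MS * fs / 1000.0))

    events: list[StimulusEvent] = []
    char_labels = ""
    sentence_of_char: list[int] = []
    onset = 0
    for si, sentence in enumerate(config.sentences):
        chars = normalize_text(sentence)
        ev = build_schedule(
            config, sentence, rng, start_sample=onset, char_index_offset=len(char_labels)
        )
        events.extend(ev)
        char_labels += chars
        sentence_of_char.extend([si] * len(chars))
        onset = ev[-1].sample_index + config.soa_samples + gap

    n_samples = events[-1].sample_index + window
    eeg = pink_noise(
        config.n_channels, n_samples, fs, config.noise_level_uv, config.noise_exponent, rng
    )

    topo = config.topography
    mean_lat = config.p300_mean_latency_ms
    sd = config.p300_jitter_sd_ms
    true_latency = np.full(len(events), np.nan)

    # support of the Gaussian template: +-4 sd around the peak
    half_support = int(np.ceil(4 * (config.p300_width_ms / 2.355) * fs / 1000.0))

    for i, ev in enumerate(events):
        if not ev.is_target:
            if config.nontarget_amplitude_uv:
                _add_deflection(
                    eeg, topo, ev.sample_index, 180.0, fs,
                    config.nontarget_amplitude_uv, config.p300_width_ms / 2, half_support,
                )
            continue
        eps = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        eps = float(np.clip(eps, -3 * sd, 3 * sd))
        latency = mean_lat + eps
        # keep the template inside the recording; record the clipped value
        max_latency = (n_samples - 1 - ev.sample_index) / fs * 1000.0
        latency = float(np.clip(latency, 0.0, max_latency))
        true_latency[i] = latency
        if config.p300_amplitude_uv:
            _add_deflection(
                eeg, topo, ev.sample_index, latency, fs,
                config.p300_amplitude_uv, config.p300_width_ms, half_support,
            )

    labels = [f"ch{i:02d}" for i in range(config.n_channels)]
    return ContinuousSession(
        eeg=eeg,
        fs=fs,
        channel_labels=labels,
        events=events,
        char_labels=char_labels,
        sentence_of_char=np.asarray(sentence_of_char),
        true_latency_ms=true_latency,
        config=config,
    )


def _add_deflection(eeg, topo, onset, latency_ms, fs, amplitude, width_ms, half_support):
    peak = onset + latency_ms * fs / 1000.0
    lo = max(int(np.floor(peak)) - half_support, 0)
    hi = min(int(np.ceil(peak)) + half_support + 1, eeg.shape[1])
    if hi <= lo:
        return
    seg = p300_template(hi - lo, peak - lo, fs, amplitude, width_ms)
    eeg[:, lo:hi] += topo[:, None] * seg[None, :]


# ---------------------------------------------------------------------------
# on-disk format: HDF5 container + sidecar tab-separated events table


EVENT_COLUMNS = [
    "sample_index",
    "stim_code",
    "is_target",
    "char_index",
    "sequence_index",
    "true_latency_ms",
]


def _events_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events.tsv")


def write_session(session: ContinuousSession, path: str | Path) -> None:
    """Write a session as ``path`` (HDF5) plus ``path.events.tsv`` (sidecar)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=session.eeg)
        f.attrs["fs"] = session.fs
        f.attrs["channel_labels"] = json.dumps(session.channel_labels)
        f.attrs["char_labels"] = session.char_labels
        f.attrs["n_events"] = len(session.events)
        f.create_dataset("sentence_of_char", data=session.sentence_of_char)
        if session.config is not None:
            f.attrs["config"] = json.dumps(session.config.to_dict())
    df = pd.DataFrame(
        {
            "sample_index": [e.sample_index for e in session.events],
            "stim_code": [e.stim_code for e in session.events],
            "is_target": [int(e.is_target) for e in session.events],
            "char_index": [e.char_index for e in session.events],
            "sequence_index": [e.sequence_index for e in session.events],
            "true_latency_ms": session.true_latency_ms,
        }
    )
    # %.17g guarantees float64 round-trip through the text sidecar
    df.to_csv(_events_path(path), sep="\t", index=False, float_format="%.17g")


def read_session(path: str | Path) -> ContinuousSession:
    """Read a session written by :func:`write_session`.

    Raises ``ValueError`` on truncated or malformed containers rather than
    returning a partial session.
    """
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            eeg = np.asarray(f["eeg"])
            fs = float(f.attrs["fs"])
            channel_labels = json.loads(f.attrs["channel_labels"])
            char_labels = str(f.attrs["char_labels"])
            n_events = int(f.attrs["n_events"])
            sentence_of_char = np.asarray(f["sentence_of_char"])
            cfg = None
            if "config" in f.attrs:
                cfg = SimConfig.from_dict(json.loads(f.attrs["config"]))
    except (OSError, KeyError) as exc:
        raise ValueError(f"malformed session container {path}: {exc}") from exc

    ev_path = _events_path(path)
    try:
        df = pd.read_csv(ev_path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface parse errors uniformly
        raise ValueError(f"malformed events table {ev_path}: {exc}") from exc
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events table {ev_path} missing columns: {sorted(missing)}")
    if len(df) != n_events:
        raise ValueError(
            f"events table {ev_path} truncated: expected {n_events} rows, found {len(df)}"
        )
    events = [
        StimulusEvent(
            sample_index=int(r.sample_index),
            stim_code=int(r.stim_code),
            is_target=bool(r.is_target),
            char_index=int(r.char_index),
            sequence_index=int(r.sequence_index),
        )
        for r in df.itertuples()
    ]
    return ContinuousSession(
        eeg=eeg,
        fs=fs,
        channel_labels=channel_labels,
        events=events,
        char_labels=char_labels,
        sentence_of_char=sentence_of_char,
        true_latency_ms=df["true_latency_ms"].to_numpy(dtype=float),
        config=cfg,
    )
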