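"""EEG preprocessing: bandpass filtering, epoching, moving-average
downsampling, channel selection and feature standardization.

The chain mirrors a standard offline P300 analysis: a linear-phase FIR
bandpass (0.5-70 Hz), 750 ms post-stimulus epochs, downsampling by 30 via a
block moving average (450 raw samples -> 15 time bins at 600 Hz), and
flattening channel x bin into one feature vector per flash.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .simulate import ContinuousSession

__all__ = [
    "EpochSet",
    "FeatureMatrix",
    "Standardizer",
    "bandpass",
    "epoch",
    "downsample_epochs",
    "select_channels",
]


@dataclass
class EpochSet:
    """Per-flash windowed trials at the raw sampling rate."""

    data: np.ndarray  # trials x channels x samples
    fs: float
    window_ms: tuple[float, float]
    is_target: np.ndarray
    stim_code: np.ndarray
    char_index: np.ndarray
    sequence_index: np.ndarray
    channel_labels: list[str]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, channel_labels: list[str]) -> "EpochSet":
        """Restrict to the given channels, in the given order."""
        if list(channel_labels) == list(self.channel_labels):
            return self  # identity selection: skip the (large) copy
        idx = [self.channel_labels.index(c) for c in channel_labels]
        return replace(self, data=self.data[:, idx, :], channel_labels=list(channel_labels))


@dataclass
class FeatureMatrix:
    """Flattened trial features ready for classification.

    ``X`` is trials x D with D = n_channels x n_time_bins, channel-major;
    ``y`` codes targets +1 and non-targets -1.  ``feature_layout`` maps each
    column back to its (channel label, time bin).
    """

    X: np.ndarray
    y: np.ndarray
    feature_layout: list[tuple[str, int]]
    stim_code: np.ndarray
    char_index: np.ndarray
    sequence_index: np.ndarray


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen on training data."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension mismatch: got {X.shape[1]}, expected {self.mean.shape[0]}"
            )
        return (X - self.mean) / self.scale


def bandpass(
    session: ContinuousSession,
    low: float = 0.5,
    high: float = 70.0,
    numtaps: int = 661,
) -> ContinuousSession:
    """Linear-phase FIR bandpass with group-delay compensation.

    A windowed-sinc (Hamming) design; an odd tap count makes the group delay
    an integer so 'same'-mode convolution keeps events aligned with the EEG.
    """
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= session.fs / 2:
        raise ValueError(
            f"high corner {high} Hz not below Nyquist ({session.fs / 2} Hz)"
        )
    if numtaps % 2 == 0:
        numtaps += 1
    taps = signal.firwin(numtaps, [low, high], fs=session.fs, pass_zero=False)
    # a ~1 s window cannot otherwise resolve the 0.5 Hz corner: force exact
    # zero DC gain (perturbs the response only below ~1/(numtaps/fs) Hz)
    taps -= taps.sum() / numtaps
    filtered = signal.oaconvolve(session.eeg, taps[None, :], mode="same", axes=1)
    return replace(session, eeg=filtered)


def epoch(session: ContinuousSession, window_ms: tuple[float, float] = (0.0, 750.0)) -> EpochSet:
    """Cut one half-open window ``[onset+w0, onset+w1)`` per stimulus event.

    Windows may overlap (the SOA is shorter than the epoch).  An event whose
    window would run past the end of the recording raises an error naming it.
    """
    w0, w1 = window_ms
    start_off = int(round(w0 * session.fs / 1000.0))
    n_samp = int(round((w1 - w0) * session.fs / 1000.0))
    n_ev = len(session.events)
    if n_ev == 0:
        empty = np.empty(0, dtype=int)
        return EpochSet(
            data=np.empty((0, session.eeg.shape[0], n_samp)),
            fs=session.fs,
            window_ms=window_ms,
            is_target=np.empty(0, dtype=bool),
            stim_code=empty,
            char_index=empty,
            sequence_index=empty,
            channel_labels=list(session.channel_labels),
        )
    onsets = np.array([e.sample_index for e in session.events]) + start_off
    bad = np.flatnonzero(onsets + n_samp > session.n_samples)
    if bad.size:
        raise ValueError(
            f"epoch window for event {bad[0]} (onset sample "
            f"{session.events[bad[0]].sample_index}) exceeds the recording"
        )
    idx = onsets[:, None] + np.arange(n_samp)[None, :]
    data = session.eeg[:, idx].transpose(1, 0, 2)  # trials x channels x samples
    return EpochSet(
        data=data,
        fs=session.fs,
        window_ms=window_ms,
        is_target=np.array([e.is_target for e in session.events]),
        stim_code=np.array([e.stim_code for e in session.events]),
        char_index=np.array([e.char_index for e in session.events]),
        sequence_index=np.array([e.sequence_index for e in session.events]),
        channel_labels=list(session.channel_labels),
    )


def downsample_epochs(epochs: EpochSet, factor: int = 30) -> FeatureMatrix:
    """Block moving average + decimation, then flatten channel-major.

    Each channel's samples are partitioned into consecutive blocks of
    ``factor`` samples and replaced by the block means; a trailing remainder
    that does not fill a block is dropped with a warning.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    data = epochs.data
    n_trials, n_ch, n_samp = data.shape
    n_bins = n_samp // factor
    if n_samp % factor:
        warnings.warn(
            f"dropping {n_samp % factor} trailing samples not filling a block of {factor}",
            stacklevel=2,
        )
        data = data[:, :, : n_bins * factor]
    binned = data.reshape(n_trials, n_ch, n_bins, factor).mean(axis=3)
    X = binned.reshape(n_trials, n_ch * n_bins)
    layout = [(ch, b) for ch in epochs.channel_labels for b in range(n_bins)]
    y = np.where(epochs.is_target, 1.0, -1.0)
    return FeatureMatrix(
        X=X,
        y=y,
        feature_layout=layout,
        stim_code=epochs.stim_code.copy(),
        char_index=epochs.char_index.copy(),
        sequence_index=epochs.sequence_index.copy(),
    )


def select_channels(
    train_epochs: EpochSet, n_select: int = 32, target_freq: float = 3.0
) -> list[str]:
    """Channels ranked by power near ``target_freq`` in the difference ERP.

    The average target ERP minus the average non-target ERP is computed per
    channel on the training epochs; a one-shot periodogram of that raw-rate
    difference waveform is evaluated and channels are ranked by the power in
    the frequency bin nearest ``target_freq`` (the P300's dominant band).
    Ties are broken by channel-label order.
    """
    if n_select > len(train_epochs.channel_labels):
        raise ValueError("n_select exceeds the number of channels")
    if not train_epochs.is_target.any() or train_epochs.is_target.all():
        raise ValueError("training epochs must contain both classes")
    diff_erp = (
        train_epochs.data[train_epochs.is_target].mean(axis=0)
        - train_epochs.data[~train_epochs.is_target].mean(axis=0)
    )  # channels x samples
    freqs, psd = signal.periodogram(diff_erp, fs=train_epochs.fs, axis=1)
    bin_idx = int(np.argmin(np.abs(freqs - target_freq)))
    power = psd[:, bin_idx]
    order = np.argsort(-power, kind="stable")  # stable: ties keep label order
    return [train_epochs.channel_labels[i] for i in order[:n_select]]
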