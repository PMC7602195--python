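"""Classifier-based latency estimation (CBLE).

A P300 classifier trained on fixed post-stimulus windows is sensitive to the
single-trial latency of the response: sliding the analysis window earlier or
later changes the score, and the shift that maximizes it estimates how far
that trial's P300 deviates from the training mean.  The sample variance of
those per-trial shifts (vCBLE) summarizes a dataset's latency jitter and is
used, via leave-one-participant-out linear regression, to predict spelling
accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import ContinuousSession
from .stats import pearson

__all__ = [
    "CbleResult",
    "AccuracyPrediction",
    "default_shift_grid",
    "shifted_feature_stack",
    "estimate_latencies",
    "vcble_of",
    "predict_accuracy_loo",
    "ideal_prediction_floor",
]

logger = logging.getLogger(__name__)


def default_shift_grid(limit_ms: float = 100.0, step_ms: float = 10.0) -> np.ndarray:
    """Symmetric shift grid, +-limit in step increments (includes 0).

    The default stays well inside one stimulus onset asynchrony (167 ms):
    shifts approaching the SOA re-align the window with the *neighboring*
    flash's response, producing spurious score maxima.
    """
    n = int(round(limit_ms / step_ms))
    return np.arange(-n, n + 1) * step_ms


@dataclass
class CbleResult:
    """Per-trial latency-shift estimates for one dataset and classifier."""

    per_trial_shift: np.ndarray  # ms, one per analyzed trial
    shift_grid: np.ndarray  # ms
    vcble: float  # ms^2
    event_indices: np.ndarray
    participant_id: str | None = None
    classifier_name: str | None = None


@dataclass
class AccuracyPrediction:
    """Leave-one-participant-out accuracy prediction from vCBLE."""

    vcble: np.ndarray
    true_accuracy: np.ndarray  # percent
    predicted_accuracy: np.ndarray  # percent
    coefficients: list[tuple[float, float]]  # (slope, intercept) per fold
    rmse: float  # accuracy-percentage units
    r_squared: float
    pearson_r: float
    pearson_p: float


def shifted_feature_stack(
    session: ContinuousSession,
    channel_labels: list[str] | None = None,
    shift_grid_ms: np.ndarray | None = None,
    event_indices: np.ndarray | None = None,
    window_ms: tuple[float, float] = (0.0, 750.0),
    downsample_factor: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Downsampled features of every epoch at every grid shift.

    Returns ``(feats, valid, shift_grid_ms, event_indices)`` with ``feats``
    of shape (n_shifts, n_trials, D) and ``valid`` (n_trials, n_shifts)
    flagging shifts whose window stays inside the recording.  Classifier
    independent, so one stack can be scored by several models.
    """
    if shift_grid_ms is None:
        shift_grid_ms = default_shift_grid()
    shift_grid_ms = np.asarray(shift_grid_ms, dtype=float)
    if event_indices is None:
        event_indices = session.target_event_indices()
    event_indices = np.asarray(event_indices, dtype=int)
    if channel_labels is None:
        channel_labels = list(session.channel_labels)
    ch_idx = [session.channel_labels.index(c) for c in channel_labels]

    fs = session.fs
    w0, w1 = window_ms
    n_samp = int(round((w1 - w0) * fs / 1000.0))
    base_onsets = (
        np.array([session.events[i].sample_index for i in event_indices])
        + int(round(w0 * fs / 1000.0))
    )
    eeg = session.eeg[ch_idx]

    n_trials = len(event_indices)
    n_shifts = len(shift_grid_ms)
    shift_samples = np.array([int(round(t * fs / 1000.0)) for t in shift_grid_ms])
    smin, smax = int(shift_samples.min()), int(shift_samples.max())
    width = n_samp + smax - smin
    if width > session.n_samples:
        raise ValueError("recording shorter than epoch window plus shift grid span")

    # one wide window per trial; every shifted epoch is a slice of it, and
    # the block-mean downsampling of every slice comes from one cumulative sum
    valid = (base_onsets[:, None] + shift_samples[None, :] >= 0) & (
        base_onsets[:, None] + shift_samples[None, :] + n_samp <= session.n_samples
    )
    starts = np.clip(base_onsets + smin, 0, session.n_samples - width)
    wide = np.ascontiguousarray(
        eeg[:, starts[:, None] + np.arange(width)[None, :]].transpose(1, 0, 2)
    )
    cs = np.pad(np.cumsum(wide, axis=2), ((0, 0), (0, 0), (1, 0)))

    n_bins = n_samp // downsample_factor
    bin0 = np.arange(n_bins) * downsample_factor
    feats = np.empty((n_shifts, n_trials, wide.shape[1] * n_bins))
    for k in range(n_shifts):
        off = shift_samples[k] - smin
        pos = off + bin0
        means = (cs[:, :, pos + downsample_factor] - cs[:, :, pos]) / downsample_factor
        feats[k] = means.reshape(n_trials, -1)
    return feats, valid, shift_grid_ms, event_indices


def estimate_latencies(
    model,
    session: ContinuousSession,
    channel_labels: list[str] | None = None,
    shift_grid_ms: np.ndarray | None = None,
    event_indices: np.ndarray | None = None,
    window_ms: tuple[float, float] = (0.0, 750.0),
    downsample_factor: int = 30,
    participant_id: str | None = None,
    feature_stack: tuple | None = None,
) -> CbleResult:
    """Score time-shifted copies of each epoch; argmax shift = latency estimate.

    For every shift tau in the grid, the post-stimulus window
    ``[onset + tau, onset + tau + 750 ms)`` is re-extracted from the
    continuous (already bandpassed) EEG, downsampled and scored with the
    trained model; the per-trial estimate is the score-maximizing tau.  Ties
    prefer the smallest magnitude, then negative before positive.  Shifts
    that push a window outside the recording are skipped for that trial.

    ``event_indices`` selects the analyzed trials; the default is all
    true-target events (supervised offline analysis).  A precomputed
    ``feature_stack`` (from :func:`shifted_feature_stack`) lets several
    classifiers share one extraction.
    """
    if feature_stack is None:
        feature_stack = shifted_feature_stack(
            session, channel_labels, shift_grid_ms, event_indices,
            window_ms, downsample_factor,
        )
    feats, valid, shift_grid_ms, event_indices = feature_stack
    n_shifts, n_trials, _ = feats.shape

    flat_scores = model.score(feats.reshape(n_shifts * n_trials, -1))
    scores = flat_scores.reshape(n_shifts, n_trials).T.copy()
    scores[~valid] = -np.inf
    for k in np.flatnonzero(~valid.any(axis=0)):
        logger.info("shift %+g ms: no valid trials, skipped", shift_grid_ms[k])

    usable = np.isfinite(scores).any(axis=1)
    if not usable.all():
        logger.info("dropping %d trials with no valid shift", int((~usable).sum()))
    scores = scores[usable]
    event_indices = event_indices[usable]

    # tie preference: smallest |tau|, then negative before positive;
    # argmax returns the first maximum in this preference order
    pref = np.lexsort((shift_grid_ms, np.abs(shift_grid_ms)))
    best = pref[np.argmax(scores[:, pref], axis=1)]
    shifts = shift_grid_ms[best]

    vc = float(np.var(shifts, ddof=1)) if len(shifts) >= 2 else 0.0
    return CbleResult(
        per_trial_shift=shifts,
        shift_grid=shift_grid_ms,
        vcble=vc,
        event_indices=event_indices,
        participant_id=participant_id,
        classifier_name=getattr(model, "method", type(model).__name__),
    )


def vcble_of(shifts: np.ndarray) -> float:
    """Unbiased sample variance of per-trial latency shifts (ms^2)."""
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size < 2:
        raise ValueError("vCBLE needs at least 2 latency estimates")
    return float(np.var(shifts, ddof=1))


def predict_accuracy_loo(vcble: np.ndarray, accuracy_pct: np.ndarray) -> AccuracyPrediction:
    """Predict each participant's accuracy from vCBLE, holding them out.

    For every participant, a simple linear regression
    ``accuracy ~ a * vcble + b`` is fit on all other participants and used
    to predict the held-out accuracy.  Reported are the RMSE of the
    predictions (accuracy-percentage units), the coefficient of
    determination of predicted vs. true accuracy, and the pooled Pearson
    correlation between vCBLE and accuracy.
    """
    v = np.asarray(vcble, dtype=float)
    a = np.asarray(accuracy_pct, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise ValueError("vcble and accuracy must be 1-d arrays of equal length")
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 participants")
    preds = np.empty(n)
    coefs: list[tuple[float, float]] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.var(v[mask]) == 0:
            raise ValueError("zero vCBLE variance in a training fold; regression degenerate")
        slope, intercept = np.polyfit(v[mask], a[mask], 1)
        coefs.append((float(slope), float(intercept)))
        preds[i] = slope * v[i] + intercept
    rmse = float(np.sqrt(np.mean((preds - a) ** 2)))
    ss_res = float(np.sum((a - preds) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    r, p = pearson(v, a)
    return AccuracyPrediction(
        vcble=v,
        true_accuracy=a,
        predicted_accuracy=preds,
        coefficients=coefs,
        rmse=rmse,
        r_squared=r2,
        pearson_r=r,
        pearson_p=p,
    )


def ideal_prediction_floor(
    true_ps: np.ndarray,
    n_chars: np.ndarray,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Error floor of an oracle that knows each dataset's true accuracy.

    Observed accuracy over ``n`` characters is Binomial(n, p)/n even when p
    is known exactly, so the RMSE of the perfect predictor (predict 100*p)
    is bounded below by binomial observation noise,
    ``100 * sqrt(mean_d p_d (1 - p_d) / n_d)``.  Returns the simulated
    (rmse, R^2) on the percent scale.
    """
    p = np.asarray(true_ps, dtype=float)
    n = np.asarray(n_chars, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    obs = rng.binomial(n[None, :], p[None, :], size=(reps, len(p))) / n[None, :] * 100.0
    pred = 100.0 * p[None, :]
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    ss_res = np.sum((obs - pred) ** 2, axis=1)
    ss_tot = np.sum((obs - obs.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = float(np.nanmean(1.0 - ss_res / ss_tot))
    return rmse, r2
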