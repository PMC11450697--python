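"""Deterministic preprocessing: filter, resample, detect onsets, epoch,
reject, re-reference.

Replaces the visual steps of a conventional EEG cleaning pipeline (manual
bad-channel marking, ICA component rejection) with a deterministic
peak-to-peak amplitude criterion, so the whole chain is reproducible from a
seed.  All filtering is zero-phase FIR so event timing is preserved.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording, EpochSet

RESTING_EPOCH_MS = 2000.0
EVENT_WINDOW_MS = (-2500.0, 4500.0)
TARGET_RATE = 500.0
MIN_TRIALS = 20


class ParticipantExcluded(Exception):
    """Raised when fewer trials survive rejection than the analysis floor."""


def bandpass_notch(
    rec: ContinuousRecording,
    low: float = 0.5,
    high: float = 95.0,
    notch: float = 50.0,
) -> ContinuousRecording:
    """Zero-phase FIR band-pass plus line-noise notch.

    The band-pass transition bands sit outside [low, high], so the stated
    passband (e.g. 1-90 Hz) is flat to well under 1 dB; the notch removes
    the 50 Hz mains component by >40 dB.  The force channel, if present, is
    left unfiltered (its threshold crossing defines movement onset).
    """
    if rec.rate <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.rate} Hz too low for a {high} Hz band edge"
        )
    from mne.filter import filter_data, notch_filter

    out = filter_data(
        rec.data, sfreq=rec.rate, l_freq=low, h_freq=high,
        method="fir", phase="zero", fir_design="firwin", verbose=False,
    )
    if notch is not None and notch < rec.rate / 2:
        out = notch_filter(
            out, Fs=rec.rate, freqs=notch, method="fir", phase="zero",
            fir_design="firwin", verbose=False,
        )
    return ContinuousRecording(
        data=out, rate=rec.rate, ch_names=list(rec.ch_names),
        force=None if rec.force is None else rec.force.copy(),
        onsets=None if rec.onsets is None else rec.onsets.copy(),
        meta=dict(rec.meta),
    )


def resample(rec: ContinuousRecording, target: float = TARGET_RATE) -> ContinuousRecording:
    """Polyphase anti-aliased resampling; onsets are re-indexed to the new
    rate (exact to within one output sample)."""
    if target > rec.rate:
        raise ValueError("upsampling not supported: target exceeds current rate")
    if target == rec.rate:
        return rec
    frac = Fraction(target / rec.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    force = None
    if rec.force is not None:
        force = signal.resample_poly(rec.force, up, down)
    onsets = None
    if rec.onsets is not None:
        onsets = np.round(rec.onsets * target / rec.rate).astype(np.int64)
    return ContinuousRecording(
        data=data, rate=target, ch_names=list(rec.ch_names),
        force=force, onsets=onsets, meta=dict(rec.meta),
    )


def detect_onsets(
    force: np.ndarray,
    threshold: float,
    rate: float,
    refractory_ms: float = 2000.0,
) -> np.ndarray:
    """Movement onsets as the first sample at which the force trace exceeds
    ``threshold``, with a refractory period to suppress re-triggers within
    one press.

    Returns sample indices (empty array if no crossing).
    """
    force = np.asarray(force, dtype=float)
    if force.size == 0:
        raise ValueError("empty force trace")
    above = force >= threshold
    rising = above & ~np.concatenate([[False], above[:-1]])
    candidates = np.flatnonzero(rising)
    refractory = int(round(refractory_ms / 1000.0 * rate))
    onsets: list[int] = []
    last = -refractory - 1
    for c in candidates:
        if c - last > refractory:
            onsets.append(int(c))
            last = c
    return np.asarray(onsets, dtype=np.int64)


def epoch(
    rec: ContinuousRecording,
    mode: str,
    onsets: np.ndarray | None = None,
    resting_ms: float = RESTING_EPOCH_MS,
    event_window_ms: tuple[float, float] = EVENT_WINDOW_MS,
) -> EpochSet:
    """Cut a continuous recording into equal-length trials.

    Resting mode tiles the recording with contiguous, non-overlapping
    ``resting_ms`` segments from the start (a 180 s recording yields 90).
    Event mode cuts one ``event_window_ms`` epoch per onset; epochs that
    would extend past either edge of the recording are dropped.  Epoch
    sample ranges are half-open ``[start, start + n)``.
    """
    meta_cols = {
        k: rec.meta.get(k, "") for k in ("participant", "intensity", "timepoint")
    }
    if mode == "resting":
        n = int(round(resting_ms / 1000.0 * rec.rate))
        if rec.n_samples < n:
            raise ValueError("recording shorter than one resting epoch")
        n_trials = rec.n_samples // n
        data = rec.data[:, : n_trials * n].reshape(rec.n_channels, n_trials, n)
        data = np.moveaxis(data, 1, 0)
        t0 = 0.0
    elif mode == "event":
        if onsets is None:
            onsets = rec.onsets
        if onsets is None:
            raise ValueError("event mode requires onsets")
        lo = int(round(event_window_ms[0] / 1000.0 * rec.rate))
        hi = int(round(event_window_ms[1] / 1000.0 * rec.rate))
        n = hi - lo
        if rec.n_samples < n:
            raise ValueError("recording shorter than one event epoch")
        starts = [int(o) + lo for o in onsets]
        starts = [s for s in starts if s >= 0 and s + n <= rec.n_samples]
        if not starts:
            raise ValueError("no onset leaves a complete epoch inside the recording")
        data = np.stack([rec.data[:, s : s + n] for s in starts])
        n_trials = len(starts)
        t0 = event_window_ms[0]
    else:
        raise ValueError(f"mode must be 'resting' or 'event', got {mode!r}")

    trial_meta = pd.DataFrame(
        {**meta_cols, "block": rec.meta.get("timepoint", ""), "trial": np.arange(n_trials)}
    )
    return EpochSet(
        data=data, rate=rec.rate, t0_ms=t0, ch_names=list(rec.ch_names),
        trial_meta=trial_meta,
    )


def reject_and_reference(
    epochs: EpochSet,
    ptp_limit: float,
    min_trials: int = MIN_TRIALS,
) -> EpochSet:
    """Peak-to-peak artifact rejection followed by average re-referencing.

    A trial is flagged when any channel's peak-to-peak amplitude exceeds
    ``ptp_limit``.  All trials (kept and flagged) are then re-referenced by
    subtracting the instantaneous cross-channel mean, which is idempotent.
    Raises :class:`ParticipantExcluded` when fewer than ``min_trials``
    trials survive — the conventional floor for a stable coherence
    estimate.
    """
    if ptp_limit <= 0:
        raise ValueError("ptp_limit must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, channels)
    bad = (ptp > ptp_limit).any(axis=1)
    rejected = epochs.rejected | bad
    reasons = [
        (r or (f"ptp>{ptp_limit:g}" if b else ""))
        for r, b in zip(epochs.rejection_reasons, bad)
    ]
    if rejected.all():
        raise ParticipantExcluded("all trials rejected")

    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    out = EpochSet(
        data=data, rate=epochs.rate, t0_ms=epochs.t0_ms,
        ch_names=list(epochs.ch_names), trial_meta=epochs.trial_meta.copy(),
        rejected=rejected, rejection_reasons=reasons, referenced=True,
    )
    if out.n_kept < min_trials:
        raise ParticipantExcluded(
            f"{out.n_kept} surviving trials < minimum of {min_trials}"
        )
    return out
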