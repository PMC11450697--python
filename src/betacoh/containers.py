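"""In-memory containers shared across pipeline stages.

Time conventions: continuous recordings index time in samples from the start
of the recording; epochs carry a time origin ``t0_ms`` in milliseconds
relative to the event (resting epochs use ``t0_ms = 0``). Event onsets are
stored as integer sample indices into the continuous recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ContinuousRecording:
    """Multichannel EEG with an optional force channel and event onsets.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        EEG signals in microvolt-scale arbitrary units.
    rate : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique channel labels (10-20 names for EEG channels).
    force : ndarray or None, shape (n_samples,)
        Force-transducer trace for event-related recordings.
    onsets : ndarray or None
        Movement onsets as sample indices into ``data``.
    meta : dict
        Free-form provenance (participant, intensity, timepoint, mode, ...).
    """

    data: np.ndarray
    rate: float
    ch_names: list[str]
    force: np.ndarray | None = None
    onsets: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.onsets is not None:
            self.onsets = np.asarray(self.onsets, dtype=np.int64)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def onset_times_s(self) -> np.ndarray:
        if self.onsets is None:
            return np.empty(0)
        return self.onsets / self.rate


@dataclass
class EpochSet:
    """Equal-length trials cut from a continuous recording.

    ``data`` is (n_trials, n_channels, n_samples); ``t0_ms`` gives the time of
    the first sample relative to the event (0 for resting epochs, -2500 for
    event epochs). ``rejected`` flags trials excluded from analysis; flagged
    trials stay in ``data`` so rejection is auditable and idempotent.
    """

    data: np.ndarray
    rate: float
    t0_ms: float
    ch_names: list[str]
    trial_meta: pd.DataFrame
    rejected: np.ndarray = None  # type: ignore[assignment]
    rejection_reasons: list[str] = field(default_factory=list)
    referenced: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.rejected is None:
            self.rejected = np.zeros(self.n_trials, dtype=bool)
            self.rejection_reasons = [""] * self.n_trials
        self.rejected = np.asarray(self.rejected, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_kept(self) -> int:
        return int((~self.rejected).sum())

    def times_ms(self) -> np.ndarray:
        """Per-sample timestamps in ms relative to the event."""
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.rate

    def select_channels(self, names: list[str]) -> "EpochSet":
        """View restricted to the named channels (in the given order)."""
        idx = [self.ch_names.index(n) for n in names]
        return EpochSet(
            data=self.data[:, idx],
            rate=self.rate,
            t0_ms=self.t0_ms,
            ch_names=list(names),
            trial_meta=self.trial_meta.copy(),
            rejected=self.rejected.copy(),
            rejection_reasons=list(self.rejection_reasons),
            referenced=self.referenced,
        )

    def kept(self) -> "EpochSet":
        """View restricted to non-rejected trials."""
        keep = ~self.rejected
        return EpochSet(
            data=self.data[keep],
            rate=self.rate,
            t0_ms=self.t0_ms,
            ch_names=list(self.ch_names),
            trial_meta=self.trial_meta.loc[keep].reset_index(drop=True),
            rejected=np.zeros(int(keep.sum()), dtype=bool),
            rejection_reasons=[""] * int(keep.sum()),
            referenced=self.referenced,
        )
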