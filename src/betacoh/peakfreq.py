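"""Peak beta frequency and the endogenous-exogenous frequency difference.

The peak beta frequency of a trial is the 13-30 Hz bin with the greatest
absolute baseline-subtracted connectivity deviation (ERD or ERS) averaged
over a movement-period window; subtracting the 20 Hz stimulation frequency
gives the endogenous-exogenous difference, the predictor fed to the
cluster-based correlation stage.
"""

from __future__ import annotations

import numpy as np

from .connectivity import BANDS, band_rows

STIM_FREQ_HZ = 20.0


def peak_beta(values: np.ndarray, freqs: np.ndarray) -> float:
    """Beta-band frequency with the greatest |value|.

    ``values`` are per-frequency baseline-subtracted values already
    averaged over the period window (1-D, aligned with ``freqs``).  Ties
    break toward the lower frequency.  Raises if every beta bin is missing.
    """
    values = np.asarray(values, dtype=float)
    rows = band_rows(freqs, "beta")
    v = np.abs(values[rows])
    if not np.isfinite(v).any():
        raise ValueError("all beta bins missing")
    v = np.where(np.isfinite(v), v, -np.inf)
    return float(freqs[rows][int(np.argmax(v))])


def peak_beta_trials(trial_freq: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Vector of per-trial peak beta frequencies from a (trials, freqs)
    array of period-averaged baseline-subtracted values."""
    return np.array([peak_beta(row, freqs) for row in trial_freq])


def endo_exo_diff(peak_hz: float, stim_hz: float = STIM_FREQ_HZ) -> float:
    """Endogenous minus exogenous frequency: peak_hz - 20 Hz."""
    lo, hi = BANDS["beta"]
    if not (lo <= peak_hz <= hi):
        raise ValueError(f"peak {peak_hz} Hz outside the beta band [{lo}, {hi}]")
    return float(peak_hz - stim_hz)
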