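"""Imaginary coherence between the C3 and C4 electrode clusters.

The estimator is |Im(S_ij / sqrt(S_ii S_jj))| where S_ij is the
cross-spectral density between the analytic wavelet signals of channels i
and j, and S_ii, S_jj the corresponding auto-spectra.  Because only the
imaginary part is kept, instantaneous (zero-lag) mixing of a common source
— volume conduction at the scalp — contributes nothing.

Two aggregation routes are provided:

* across-trial — S averaged over trials at each (frequency, time) point;
  yields a time-frequency connectivity map per condition.
* within-trial — S averaged over the time points of a window inside each
  trial; yields one value per (trial, frequency), the shape a trial-level
  mixed-model table needs.  (A single-trial single-timepoint coherence is
  identically 1, so trial-level values must pool over within-trial time.)

Cluster-level connectivity is the arithmetic mean over the 49 channel
pairs (i in cluster A, j in cluster B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import C3_CLUSTER, C4_CLUSTER
from .timefreq import BASELINE_WINDOW_MS, ComplexTFR

#: frequency bands in Hz, edges inclusive
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (60.0, 90.0),
}

#: movement periods in ms relative to onset, half-open [start, end)
PERIODS: dict[str, tuple[float, float]] = {
    "premove": (-500.0, 0.0),
    "move": (0.0, 500.0),
    "postmove": (1500.0, 4000.0),
}


@dataclass(frozen=True)
class ClusterDef:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) != 7:
            raise ValueError(f"cluster {self.name} must have 7 members")


LEFT_M1 = ClusterDef("C3", C3_CLUSTER)
RIGHT_M1 = ClusterDef("C4", C4_CLUSTER)


@dataclass
class ImCohMap:
    """(frequency x time) imaginary-coherence map.

    Unbaselined values lie in [0, 1]; after baseline subtraction they lie in
    [-1, 1].  NaN marks cells where an auto-spectrum vanished (undefined
    coherency) or that were excluded by the edge mask.
    """

    values: np.ndarray
    freqs: np.ndarray
    grid_ms: np.ndarray
    estimator: str
    baseline_ms: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)


def _auto_eps(sii: np.ndarray, sjj: np.ndarray) -> float:
    scale = max(float(np.nanmax(sii, initial=0.0)), float(np.nanmax(sjj, initial=0.0)))
    return scale * 1e-15


def _imcoh_from_spectra(sij: np.ndarray, sii: np.ndarray, sjj: np.ndarray) -> np.ndarray:
    denom = np.sqrt(sii * sjj)
    eps = _auto_eps(sii, sjj)
    bad = denom <= eps
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} (t,f) cells have zero auto-spectrum; emitted as NaN",
            RuntimeWarning, stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.abs(np.imag(sij) / denom)
    val = np.where(bad, np.nan, val)
    return val


def imcoh_across_trials(tfr: ComplexTFR, i: int | str, j: int | str) -> ImCohMap:
    """Across-trial imaginary coherence between two channels.

    At each (frequency, time) cell the cross- and auto-spectra are trial
    means of x_i conj(x_j), |x_i|^2, |x_j|^2.  Requires >= 2 trials.
    """
    if tfr.n_trials < 2:
        raise ValueError("across-trial estimator needs >= 2 trials")
    ii = tfr.ch_index(i) if isinstance(i, str) else i
    jj = tfr.ch_index(j) if isinstance(j, str) else j
    xi = tfr.values[:, ii].astype(np.complex128)
    xj = tfr.values[:, jj].astype(np.complex128)
    sij = (xi * np.conj(xj)).mean(axis=0)
    sii = (np.abs(xi) ** 2).mean(axis=0)
    sjj = (np.abs(xj) ** 2).mean(axis=0)
    return ImCohMap(
        values=_imcoh_from_spectra(sij, sii, sjj),
        freqs=tfr.freqs, grid_ms=tfr.grid_ms, estimator="across-trial",
    )


def _window_cols(grid_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    return np.flatnonzero((grid_ms >= lo) & (grid_ms < hi))


def imcoh_within_trial(
    tfr: ComplexTFR, i: int | str, j: int | str, window_ms: tuple[float, float]
) -> np.ndarray:
    """Per-trial imaginary coherence, pooling the grid points of a window.

    Returns (n_trials, n_freqs).  The window must contain at least two grid
    points: with a single point the coherency magnitude is identically 1.
    """
    cols = _window_cols(tfr.grid_ms, window_ms)
    if len(cols) == 0:
        raise ValueError(f"window {window_ms} outside the grid")
    if len(cols) < 2:
        raise ValueError("window must contain >= 2 grid points")
    ii = tfr.ch_index(i) if isinstance(i, str) else i
    jj = tfr.ch_index(j) if isinstance(j, str) else j
    xi = tfr.values[:, ii][:, :, cols].astype(np.complex128)
    xj = tfr.values[:, jj][:, :, cols].astype(np.complex128)
    sij = (xi * np.conj(xj)).mean(axis=-1)
    sii = (np.abs(xi) ** 2).mean(axis=-1)
    sjj = (np.abs(xj) ** 2).mean(axis=-1)
    return _imcoh_from_spectra(sij, sii, sjj)


def _cluster_indices(tfr: ComplexTFR, cluster: ClusterDef) -> np.ndarray:
    return np.array([tfr.ch_index(m) for m in cluster.members])


def cluster_imcoh(
    tfr: ComplexTFR,
    a: ClusterDef = LEFT_M1,
    b: ClusterDef = RIGHT_M1,
    estimator: str = "across-trial",
    window_ms: tuple[float, float] | None = None,
    apply_edge_mask: bool = True,
) -> ImCohMap | np.ndarray:
    """Mean imaginary coherence over the 49 (i in A, j in B) channel pairs.

    ``estimator="across-trial"`` returns an :class:`ImCohMap`;
    ``"within-trial"`` returns per-trial per-frequency values
    (n_trials, n_freqs) pooled over ``window_ms``.  NaN cells (vanishing
    auto-spectrum or edge-flagged) are excluded pairwise from the mean.
    """
    if set(a.members) & set(b.members):
        raise ValueError("clusters must be disjoint")
    ia = _cluster_indices(tfr, a)
    ib = _cluster_indices(tfr, b)

    if estimator == "across-trial":
        if tfr.n_trials < 2:
            raise ValueError("across-trial estimator needs >= 2 trials")
        xa = tfr.values[:, ia].astype(np.complex128)  # (t, 7, F, T)
        xb = tfr.values[:, ib].astype(np.complex128)
        saa = (np.abs(xa) ** 2).mean(axis=0)  # (7, F, T)
        sbb = (np.abs(xb) ** 2).mean(axis=0)
        n = tfr.n_trials
        maps = np.empty((7, 7) + xa.shape[2:])
        for p in range(7):
            sij = np.einsum("tfs,tbfs->bfs", xa[:, p], np.conj(xb)) / n
            maps[p] = _imcoh_from_spectra(
                sij, np.broadcast_to(saa[p], sbb.shape), sbb
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(maps, axis=(0, 1))
        if apply_edge_mask:
            vals = np.where(tfr.edge_ok, vals, np.nan)
        return ImCohMap(
            values=vals, freqs=tfr.freqs, grid_ms=tfr.grid_ms,
            estimator="across-trial",
        )

    if estimator == "within-trial":
        if window_ms is None:
            raise ValueError("within-trial estimator requires window_ms")
        acc = np.zeros((tfr.n_trials, len(tfr.freqs)))
        cnt = np.zeros_like(acc)
        for p in ia:
            for q in ib:
                v = imcoh_within_trial(tfr, int(p), int(q), window_ms)
                ok = np.isfinite(v)
                acc[ok] += v[ok]
                cnt += ok
        with np.errstate(invalid="ignore", divide="ignore"):
            out = acc / cnt
        return out

    raise ValueError(f"unknown estimator {estimator!r}")


def baseline_subtract(
    m: ImCohMap, baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> ImCohMap:
    """Subtract each frequency's mean value over the baseline window.

    The map's grid must cover the baseline window.  Output values may be
    negative; re-applying with the same window is a no-op on the baseline
    mean (it is already zero).
    """
    lo, hi = baseline_ms
    cols = np.flatnonzero((m.grid_ms >= lo) & (m.grid_ms <= hi))
    if len(cols) == 0:
        raise ValueError(f"grid does not cover baseline window {baseline_ms}")
    base = np.nanmean(m.values[:, cols], axis=1, keepdims=True)
    return ImCohMap(
        values=m.values - base, freqs=m.freqs, grid_ms=m.grid_ms,
        estimator=m.estimator, baseline_ms=baseline_ms, meta=dict(m.meta),
    )


def restrict_map(m: ImCohMap, window_ms: tuple[float, float]) -> ImCohMap:
    """Restrict a map to the grid points of a half-open time window."""
    cols = _window_cols(m.grid_ms, window_ms)
    if len(cols) == 0:
        raise ValueError(f"window {window_ms} outside the grid")
    return ImCohMap(
        values=m.values[:, cols], freqs=m.freqs, grid_ms=m.grid_ms[cols],
        estimator=m.estimator, baseline_ms=m.baseline_ms, meta=dict(m.meta),
    )


def band_rows(freqs: np.ndarray, band: str, bands: dict | None = None) -> np.ndarray:
    """Indices of the frequency bins inside a named band, edges inclusive."""
    bands = bands or BANDS
    if band not in bands:
        raise KeyError(f"unknown band {band!r}; known: {sorted(bands)}")
    lo, hi = bands[band]
    return np.flatnonzero((freqs >= lo) & (freqs <= hi))


def band_period_average(
    m: ImCohMap, band: str, period_ms: tuple[float, float], bands: dict | None = None
) -> float:
    """Mean map value over a band's bins (inclusive) and a period's grid
    points (half-open); NaN cells are excluded with a count kept in the
    return's companion (use :func:`np.isnan` on the map for auditing)."""
    rows = band_rows(m.freqs, band, bands)
    cols = _window_cols(m.grid_ms, period_ms)
    if len(cols) == 0:
        raise ValueError(f"period {period_ms} outside the grid")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(m.values[np.ix_(rows, cols)]))


def trial_band_values(
    trial_freq: np.ndarray,
    freqs: np.ndarray,
    meta: pd.DataFrame,
    period: str,
    bands: dict | None = None,
) -> pd.DataFrame:
    """Long-format rows: one per (trial, band), averaging trial-level
    per-frequency values over each band's bins."""
    bands = bands or BANDS
    rows = []
    for band in bands:
        cols = band_rows(freqs, band, bands)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanmean(trial_freq[:, cols], axis=1)
        for t in range(trial_freq.shape[0]):
            rec = dict(meta.iloc[t]) if len(meta) else {}
            rec.update(band=band, period=period, value=v[t])
            rows.append(rec)
    return pd.DataFrame(rows)


def percent_change(a: float, b: float, eps: float = 1e-9) -> float:
    """100 * (b - a) / |a|; NaN (flagged undefined) when |a| <= eps."""
    if not np.isfinite(a) or not np.isfinite(b) or abs(a) <= eps:
        return float("nan")
    return 100.0 * (b - a) / abs(a)
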