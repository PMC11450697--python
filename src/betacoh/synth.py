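"""Synthetic EEG studies with known phase-coupling ground truth.

Two seven-channel sensorimotor clusters are driven by a pair of 20 Hz
sources whose phase difference is redrawn every trial from a von-Mises
distribution: mean lag ``phi``, concentration ``kappa``.  For such a
generator the across-trial imaginary coherence at the carrier has the
closed form

    ImCoh = |sin(phi)| * R(kappa),    R(kappa) = I1(kappa) / I0(kappa),

where R is the mean resultant length of the von-Mises jitter.  That closed
form (:func:`expected_imcoh`) is the oracle every downstream estimator is
checked against.

A ``leakage`` coefficient mixes a shared zero-lag component into both
clusters, emulating volume conduction — the confound imaginary coherence is
designed to suppress.  Event-mode recordings add self-paced movements at
10 s spacing, a force-channel ramp at each onset, and a movement-locked
beta amplitude envelope emulating pre-movement/movement event-related
desynchronization (ERD) and a post-movement rebound (ERS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .containers import ContinuousRecording

#: 10-20 labels of the two analyzed electrode clusters (left/right M1).
C3_CLUSTER = ("C3", "FC3", "C1", "FC5", "CP1", "C5", "CP3")
C4_CLUSTER = ("C4", "CP2", "CP4", "C6", "C2", "FC6", "FC4")

#: background 10-20 sites carrying only noise.  Without them an average
#: reference over source-dominated channels alone would cancel the
#: inter-cluster lag structure (both clusters would become +/- the same
#: mixed signal), which no realistic high-density montage does.
EXTRA_10_20 = ("Fz", "Cz", "Pz", "Oz", "F3", "F4", "P3", "P4",
               "O1", "O2", "F7", "F8", "T7", "T8")

DEFAULT_RATE = 1000.0  # Hz, acquisition rate before preprocessing
FORCE_RISE_MS = 200.0  # half-cosine force ramp rise time


@dataclass(frozen=True)
class OscillatorParams:
    """Coupled-source parameters.

    f0 : carrier frequency in Hz.
    phi : mean phase lag of cluster B behind cluster A, radians, in (-pi, pi].
    kappa : von-Mises concentration of the trial-to-trial lag jitter
        (0 = uniform lag, ``inf`` = perfectly consistent lag).
    amp : source amplitude in the same arbitrary units as the channel data.
    """

    f0: float = 20.0
    phi: float = math.pi / 2
    kappa: float = 4.0
    amp: float = 1.0

    def __post_init__(self) -> None:
        if not (self.f0 > 0):
            raise ValueError("f0 must be positive")
        if not np.isfinite(self.phi):
            raise ValueError("phi must be finite")
        if not (-math.pi < self.phi <= math.pi):
            raise ValueError("phi must lie in (-pi, pi]")
        if not (self.kappa >= 0):  # allows +inf
            raise ValueError("kappa must be >= 0")
        if not (self.amp >= 0):
            raise ValueError("amp must be >= 0")


@dataclass(frozen=True)
class ERDProfile:
    """Movement-locked beta amplitude envelope, as gains relative to 1.

    Windows (ms relative to movement onset): baseline -2000..-1000,
    pre-movement -500..0, movement 0..500, rebound 1500..4000.  Gains are
    linearly cross-faded over ``transition_ms`` at each boundary.
    """

    baseline_gain: float = 1.0
    premove_gain: float = 0.5
    move_gain: float = 0.4
    rebound_gain: float = 1.5
    transition_ms: float = 200.0

    def __post_init__(self) -> None:
        for name in ("baseline_gain", "premove_gain", "move_gain", "rebound_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transition_ms < 0:
            raise ValueError("transition_ms must be >= 0")

    def envelope(self, t_ms: np.ndarray) -> np.ndarray:
        """Gain at each time (ms relative to onset), with linear cross-fades."""
        w = self.transition_ms / 2.0
        b, p, m, r = (
            self.baseline_gain,
            self.premove_gain,
            self.move_gain,
            self.rebound_gain,
        )
        # breakpoints: baseline -> premove @ -500, -> move @ 0, -> baseline
        # @ 500, -> rebound @ 1500, -> baseline @ 4000
        xp = [-500 - w, -500 + w, -w, w, 500 - w, 500 + w,
              1500 - w, 1500 + w, 4000 - w, 4000 + w]
        fp = [b, p, p, m, m, b, b, r, r, b]
        return np.interp(t_ms, xp, fp, left=b, right=b)


@dataclass(frozen=True)
class MixingModel:
    """Source-to-sensor mixing and background noise.

    Each channel of cluster A receives ``gains_A[i] * sA`` plus a shared
    zero-lag component weighted by ``leakage``; likewise for cluster B.  At
    ``leakage = 1`` both clusters carry only the shared component and are
    zero-lag copies of each other.  Background noise is Gaussian with a
    1/f**noise_exponent amplitude spectrum; ``snr`` is the ratio of source
    RMS to noise RMS per channel.
    """

    gains_A: tuple[float, ...] = (1.0, 0.9, 0.85, 0.8, 0.8, 0.75, 0.7)
    gains_B: tuple[float, ...] = (1.0, 0.9, 0.85, 0.8, 0.8, 0.75, 0.7)
    leakage: float = 0.0
    noise_exponent: float = 1.0
    snr: float = 1.0

    def __post_init__(self) -> None:
        if len(self.gains_A) != 7 or len(self.gains_B) != 7:
            raise ValueError("each cluster needs exactly 7 channel gains")
        if not (0.0 <= self.leakage <= 1.0):
            raise ValueError("leakage must lie in [0, 1]")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """Participant x intensity x timepoint factorial design.

    ``effect_map`` multiplies the oscillator's kappa per (intensity,
    timepoint) cell, standing in for a stimulation effect on phase-coupling
    consistency; sham cells default to 1 (no change).
    """

    n_participants: int = 2
    intensities: tuple[str, ...] = ("sham", "0.5mA", "1.0mA", "1.5mA")
    timepoints: tuple[str, ...] = ("pre", "post1", "post2")
    trials_resting: int = 90
    trials_event: int = 60
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_resting < 1 or self.trials_event < 1:
            raise ValueError("trial counts must be >= 1")
        filled = dict(self.effect_map)
        for i in self.intensities:
            for t in self.timepoints:
                filled.setdefault((i, t), 1.0)
        object.__setattr__(self, "effect_map", filled)

    def effect(self, intensity: str, timepoint: str) -> float:
        if intensity not in self.intensities:
            raise KeyError(f"unknown intensity {intensity!r}")
        if timepoint not in self.timepoints:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return self.effect_map[(intensity, timepoint)]


def resultant_length(kappa: float) -> float:
    """Mean resultant length R(kappa) = I1(kappa)/I0(kappa) of a von-Mises
    distribution; R(0) = 0, R(inf) = 1."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if math.isinf(kappa):
        return 1.0
    # exponentially scaled Bessels keep the ratio stable for large kappa
    return float(special.i1e(kappa) / special.i0e(kappa))


def expected_imcoh(phi: float, kappa: float) -> float:
    """Expected across-trial imaginary coherence at the carrier frequency.

    For per-trial lags delta ~ von Mises(phi, kappa), constant within trial,
    the trial-mean cross-spectrum has imaginary part E[sin delta]
    = sin(phi) R(kappa), hence ImCoh = |sin(phi)| R(kappa) in [0, 1].
    """
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    return abs(math.sin(phi)) * resultant_length(kappa)


def _von_mises(rng: np.random.Generator, mu: float, kappa: float, n: int) -> np.ndarray:
    if math.isinf(kappa):
        return np.full(n, mu)
    return rng.vonmises(mu, kappa, size=n)


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, exponent: float,
    rate: float, std: np.ndarray,
) -> np.ndarray:
    """Gaussian noise with 1/f**exponent amplitude spectrum, unit-std then
    scaled per channel."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_channels, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * np.asarray(std).reshape(-1, 1)


def _mix_sources(
    s_a: np.ndarray, s_b: np.ndarray, mixing: MixingModel
) -> np.ndarray:
    """Project the two sources onto the 14 channels with zero-lag leakage."""
    shared = 0.5 * (s_a + s_b)
    lam = mixing.leakage
    mixed_a = (1.0 - lam) * s_a + lam * shared
    mixed_b = (1.0 - lam) * s_b + lam * shared
    g_a = np.asarray(mixing.gains_A).reshape(-1, 1)
    g_b = np.asarray(mixing.gains_B).reshape(-1, 1)
    return np.concatenate([g_a * mixed_a, g_b * mixed_b], axis=0)


def _force_trace(n_samples: int, onsets: np.ndarray, rate: float) -> np.ndarray:
    """Zero baseline with a deterministic pulse at each onset: half-cosine
    rise over FORCE_RISE_MS to amplitude 1, 800 ms hold, half-cosine fall."""
    rise = int(round(FORCE_RISE_MS / 1000.0 * rate))
    hold = int(round(0.8 * rate))
    t = np.arange(rise) / rise
    up = 0.5 * (1.0 - np.cos(np.pi * t))
    pulse = np.concatenate([up, np.ones(hold), up[::-1]])
    force = np.zeros(n_samples)
    for o in onsets:
        seg = pulse[: max(0, n_samples - o)]
        force[o : o + len(seg)] = seg
    return force


def generate_recording(
    cell: tuple[str, str, str],
    mode: str,
    osc: OscillatorParams,
    mixing: MixingModel,
    erd: ERDProfile | None = None,
    *,
    n_trials: int = 90,
    effect: float = 1.0,
    rate: float = DEFAULT_RATE,
    seed: int,
) -> ContinuousRecording:
    """Simulate one continuous recording for one design cell.

    Parameters
    ----------
    cell : (participant, intensity, timepoint) labels, recorded in ``meta``.
    mode : ``"resting"`` (back-to-back 2 s trials) or ``"event"``
        (self-paced movements every 10 s, first onset at 5 s, plus a force
        channel and an explicit onset list).
    effect : multiplier applied to ``osc.kappa`` for this cell.
    n_trials : number of 2 s resting trials, or number of movements.

    The per-trial phase lag of cluster B behind cluster A is drawn from
    von Mises(phi, kappa * effect).  Identical ``(seed, params)`` give
    bit-identical output.

    Returns a 1000 Hz (by default), 14-channel recording named after the C3
    and C4 cluster electrodes.
    """
    if mode not in ("resting", "event"):
        raise ValueError(f"mode must be 'resting' or 'event', got {mode!r}")
    if mode == "event" and erd is None:
        raise ValueError("event mode requires an ERDProfile")
    if seed is None:
        raise ValueError("seed is required for a deterministic recording")

    kappa_eff = osc.kappa * effect
    rng = np.random.default_rng(seed)
    ch_names = list(C3_CLUSTER) + list(C4_CLUSTER) + list(EXTRA_10_20)

    if mode == "resting":
        block = int(round(2.0 * rate))  # 2000 ms trials
        n_samples = n_trials * block
        onsets = None
        force = None
        envelope = None
    else:
        block = int(round(10.0 * rate))  # one movement per 10 s block
        n_samples = n_trials * block
        onsets = (np.arange(n_trials) * block + block // 2).astype(np.int64)
        force = _force_trace(n_samples, onsets, rate)
        t_rel_ms = (np.arange(block) - block // 2) / rate * 1000.0
        envelope = erd.envelope(t_rel_ms)

    psis = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)  # common source phase
    deltas = _von_mises(rng, osc.phi, kappa_eff, n_trials)  # per-trial lag

    t = np.arange(block) / rate
    phase = 2.0 * np.pi * osc.f0 * t[None, :] + psis[:, None]
    s_a = osc.amp * np.cos(phase)
    s_b = osc.amp * np.cos(phase - deltas[:, None])
    if envelope is not None:
        s_a *= envelope[None, :]
        s_b *= envelope[None, :]
    s_a = s_a.reshape(-1)
    s_b = s_b.reshape(-1)

    data = _mix_sources(s_a[None, :], s_b[None, :], mixing)
    data = np.concatenate(
        [data, np.zeros((len(EXTRA_10_20), n_samples))], axis=0
    )

    gains = np.concatenate([mixing.gains_A, mixing.gains_B])
    source_rms = gains * osc.amp / math.sqrt(2.0)
    extra_rms = np.full(len(EXTRA_10_20), gains.mean() * osc.amp / math.sqrt(2.0))
    noise_std = np.concatenate([source_rms, extra_rms]) / mixing.snr
    data = data + _one_over_f_noise(
        rng, len(ch_names), n_samples, mixing.noise_exponent, rate, noise_std
    )

    participant, intensity, timepoint = cell
    meta = {
        "participant": participant,
        "intensity": intensity,
        "timepoint": timepoint,
        "mode": mode,
        "seed": int(seed),
        "f0": osc.f0,
        "phi": osc.phi,
        "kappa": osc.kappa,
        "kappa_eff": kappa_eff,
        "effect": effect,
        "expected_imcoh": expected_imcoh(osc.phi, kappa_eff),
    }
    return ContinuousRecording(
        data=data, rate=rate, ch_names=ch_names, force=force, onsets=onsets,
        meta=meta,
    )


def _cell_seed(master: int, p: int, i: int, t: int, mode: str) -> int:
    """Stable per-cell seed below 2**31, derived from the master seed."""
    ss = np.random.SeedSequence(
        entropy=int(master) % (2**31),
        spawn_key=(p, i, t, 0 if mode == "resting" else 1),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def iter_study(
    design: StudyDesign,
    osc: OscillatorParams | None = None,
    mixing: MixingModel | None = None,
    erd: ERDProfile | None = None,
):
    """Yield ``(entry, recording)`` for every cell x {resting, event}.

    ``entry`` is the ground-truth manifest row: labels, mode, seed, the
    effective kappa after the design's effect map, and the analytic expected
    imaginary coherence for that cell.
    """
    osc = osc or OscillatorParams()
    mixing = mixing or MixingModel()
    erd = erd or ERDProfile()
    for p in range(design.n_participants):
        participant = f"sub{p + 1:02d}"
        for ii, intensity in enumerate(design.intensities):
            for ti, timepoint in enumerate(design.timepoints):
                effect = design.effect(intensity, timepoint)
                for mode, n_trials in (
                    ("resting", design.trials_resting),
                    ("event", design.trials_event),
                ):
                    seed = _cell_seed(design.seed, p, ii, ti, mode)
                    rec = generate_recording(
                        (participant, intensity, timepoint), mode, osc, mixing,
                        erd if mode == "event" else None,
                        n_trials=n_trials, effect=effect, seed=seed,
                    )
                    entry = {
                        "participant": participant,
                        "intensity": intensity,
                        "timepoint": timepoint,
                        "mode": mode,
                        "seed": seed,
                        "n_trials": n_trials,
                        "phi": osc.phi,
                        "kappa": osc.kappa,
                        "effect": effect,
                        "kappa_eff": osc.kappa * effect,
                        "expected_imcoh": expected_imcoh(osc.phi, osc.kappa * effect),
                    }
                    yield entry, rec


def generate_study(
    design: StudyDesign,
    osc: OscillatorParams | None = None,
    mixing: MixingModel | None = None,
    erd: ERDProfile | None = None,
    out_dir=None,
) -> dict:
    """Generate a full synthetic study.

    Returns the ground-truth manifest ``{"design": ..., "recordings":
    [entry, ...]}``.  With ``out_dir`` set, each recording is written to
    EDF+ (``<participant>_<intensity>_<timepoint>_<mode>.edf``) and the
    manifest to ``manifest.json``; otherwise recordings are returned in
    memory under the ``"recordings"`` entries' ``"recording"`` key.
    """
    import json
    from pathlib import Path

    entries = []
    writer = None
    if out_dir is not None:
        from .edf import write_edf

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        writer = write_edf

    for entry, rec in iter_study(design, osc, mixing, erd):
        if writer is not None:
            name = "{participant}_{intensity}_{timepoint}_{mode}.edf".format(**entry)
            path = out_dir / name
            writer(rec, path)
            entry["path"] = name
        else:
            entry["recording"] = rec
        entries.append(entry)

    manifest = {
        "design": {
            "n_participants": design.n_participants,
            "intensities": list(design.intensities),
            "timepoints": list(design.timepoints),
            "trials_resting": design.trials_resting,
            "trials_event": design.trials_event,
            "effect_map": {f"{i}|{t}": v for (i, t), v in design.effect_map.items()},
            "seed": design.seed,
        },
        "recordings": entries,
    }
    if out_dir is not None:
        clean = {
            "design": manifest["design"],
            "recordings": [
                {k: v for k, v in e.items() if k != "recording"} for e in entries
            ],
        }
        (out_dir / "manifest.json").write_text(json.dumps(clean, indent=1))
    return manifest
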