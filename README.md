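# betacoh

Phase-based connectivity analysis between the left and right primary motor
cortex (M1) from multichannel EEG — for researchers studying how
neuromodulation (e.g. beta-frequency transcranial alternating current
stimulation) reshapes interhemispheric coupling, and for anyone who needs
a tested, reproducible imaginary-coherence pipeline with a synthetic
ground-truth generator.

## What it computes

The core statistic is **imaginary coherence** (ImCoh).  For analytic
signals `x_i(f,t)`, `x_j(f,t)` from complex Morlet wavelet convolution,

    ImCoh_ij(f,t) = | Im( S_ij / sqrt(S_ii * S_jj) ) |  in [0, 1],

with `S_ij` the trial-averaged cross-spectral density and `S_ii`, `S_jj`
the auto-spectra.  Only the imaginary part is kept, so instantaneous
(zero-lag) mixing of a shared source — volume conduction at the scalp —
contributes nothing.  Connectivity is averaged over the 49 channel pairs
between a 7-electrode cluster centered at C3 and one centered at C4.

Around that core the pipeline provides:

* **Synthetic studies** with analytic ground truth: two 20 Hz sources with
  per-trial von-Mises phase-lag jitter (mean lag `phi`, concentration
  `kappa`) drive the clusters; the across-trial carrier ImCoh is exactly
  `|sin(phi)| * I1(kappa)/I0(kappa)`.  Event mode adds self-paced
  movements, a force channel, and movement-locked beta ERD/ERS envelopes.
* **Preprocessing**: 0.5–95 Hz zero-phase band-pass, 50 Hz notch, 500 Hz
  resampling, force-threshold onset detection, 2 s resting / −2.5..4.5 s
  event epoching, peak-to-peak rejection, average re-referencing.
* **Time–frequency**: 87 Morlet wavelets (4–90 Hz, cycles geometric 3→13),
  sampled on 20 ms grids placed clear of epoch edges.
* **Aggregation**: across-trial maps (baselined to −2000..−1000 ms for
  event data), trial-level band × period values (theta/alpha/beta/gamma ×
  pre-movement/movement/post-movement/resting), per-trial peak beta
  frequency and its offset from the 20 Hz stimulation frequency.
* **Inference**: cluster-based permutation Spearman correlation between
  participants' pre-stimulation peak-frequency offsets and percent-change
  connectivity maps (α = 0.05 cluster forming, orthogonal
  spectro-temporal adjacency, |ρ|-mass, 97.5th percentile of the
  max-mass permutation null).

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and limitations.

## Worked example

The generator's closed form is the oracle for the whole estimator stack:

```pycon
>>> import numpy as np
>>> from betacoh import expected_imcoh
>>> expected_imcoh(np.pi/2, 2.0)          # |sin(pi/2)| * I1(2)/I0(2)
0.6977746579640082
>>> from betacoh.validation import carrier_recovery
>>> carrier_recovery(phi=np.pi/2, kappa=2.0, n_trials=500, seed=1)
{'phi': 1.5708..., 'kappa': 2.0, 'n_trials': 500,
 'estimate': 0.7099..., 'se': 0.0181..., 'expected': 0.6978...}
```

The simulated 500-trial estimate (0.710) sits within one jackknife
standard error (0.018) of the analytic expectation (0.698).

A small end-to-end study — two participants, sham vs 1.0 mA, pre vs post,
with the stimulated cell's coupling concentration reduced to a quarter:

```python
from betacoh.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo_study", seed=7,
    synthetic={
        "n_participants": 2,
        "intensities": ("sham", "1.0mA"),
        "timepoints": ("pre", "post1"),
        "trials_resting": 30, "trials_event": 8,
        "effect_map": {"1.0mA|post1": 0.25},
        "mixing": {"snr": 2.0},
    },
)
cfg.epochs.min_trials = 4     # floor scaled with the reduced trial count
run_pipeline(cfg)
```

This writes EDF+ raw data, HDF5 epoch and ImCoh stores, CSV trial tables,
and JSON cluster results.  Reading the resting-state maps back and
averaging at the 20 Hz carrier:

```text
sub01_sham_pre_resting     0.6548      sub02_sham_pre_resting     0.6797
sub01_sham_post1_resting   0.7260      sub02_sham_post1_resting   0.7264
sub01_1.0mA_pre_resting    0.6774      sub02_1.0mA_pre_resting    0.6964
sub01_1.0mA_post1_resting  0.3231      sub02_1.0mA_post1_resting  0.3434
```

Sham cells stay near the pre-stimulation level while the post-stimulation
1.0 mA cells drop by half — the quartered kappa lowers the analytic
expectation from R(4) = 0.86 to R(1) = 0.45, and the estimated maps track
that change through filtering, referencing, wavelets and cluster
averaging (the overall scale is attenuated relative to the oracle by
in-band noise at snr = 2 and by average re-referencing, identically in
all cells).

The same pipeline runs from the shell:

```sh
betacoh run-all config.json
```

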