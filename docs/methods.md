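# Methods

## The estimand: imaginary coherence between motor cortices

The pipeline quantifies phase coupling between the left and right primary
motor cortex (M1) at the sensor level.  For two analytic signals
`x_i(f,t)`, `x_j(f,t)` obtained by wavelet convolution, coherency is the
normalized cross-spectral density

    C_ij(f,t) = S_ij / sqrt(S_ii S_jj),

with `S_ij` the trial- (or time-) averaged product `x_i conj(x_j)` and
`S_ii`, `S_jj` the corresponding auto-spectra.  The connectivity index is
the magnitude of its imaginary part, ImCoh = |Im C_ij| ∈ [0, 1].  Because
an instantaneously (zero-lag) shared source contributes only to the real
part, ImCoh suppresses volume conduction — the dominant confound of
sensor-space connectivity.  The cost is blindness to genuine zero- or
π-lag coupling; ImCoh is a conservative index, not a complete one.

Connectivity is evaluated between two seven-electrode clusters centered at
C3 and C4 (10–20 system) and averaged over the 49 inter-cluster channel
pairs.

### Two aggregation routes

* **Across-trial**: `S` averaged over trials at each (frequency, time)
  cell; yields the time–frequency connectivity map of a condition.
* **Within-trial**: `S` averaged over the grid points of a time window
  inside each trial; yields one value per (trial, frequency).  A
  single-trial, single-timepoint coherency has magnitude 1 identically, so
  trial-level values *must* pool over within-trial time; the within-trial
  estimator makes that explicit.  Its expectation differs from the
  across-trial one (for von-Mises lag jitter it converges to E|sin δ|
  rather than |sin φ| R(κ)); the two are reported under distinct estimator
  tags and never mixed.

## Wavelet decomposition

Complex Morlet wavelets at 4–90 Hz in 1 Hz steps (87 frequencies), with
cycle counts interpolated geometrically over the frequency index from 3
cycles at 4 Hz to 13 at 90 Hz:

    cycles[k] = exp(log 3 + (log 13 − log 3) · k / 86),
    sigma_t[k] = cycles[k] / (2π f[k]).

Whether the original cycle progression was geometric in index or in
frequency is not derivable from its endpoints; index-geometric is used
(the endpoints are identical either way, interior values differ by <4%).
Convolution is frequency-domain multiplication with zero padding
(numerically the full linear convolution); kernels are truncated at 5
sigma_t and normalized so a unit-amplitude sinusoid at a bank frequency
returns magnitude 1.  ImCoh is invariant to any per-channel positive
rescaling, so this normalization cannot influence results (asserted by
test).  Analytic values are sampled on sparse 20 ms grids: 400–1600 ms
inside 2 s resting epochs (61 points) and −500–4000 ms inside
−2500..4500 ms event epochs (226 points; the map used for baselining
extends the grid back to −2000 ms).  A per-frequency `edge_ok` mask flags
any grid point within 3 sigma_t of an epoch edge; on the default grids no
point is flagged at any of the 87 frequencies.

## Preprocessing

Zero-phase FIR band-pass 0.5–95 Hz plus a 50 Hz notch (delegated to MNE's
firwin designs; transition bands sit outside the stated passband),
polyphase resampling to 500 Hz, epoching (2000 ms contiguous resting
segments; −2500..4500 ms around movement onset), deterministic
peak-to-peak amplitude rejection, and average re-referencing.  Movement
onset is the first sample at which the force trace exceeds a threshold,
with a 2 s refractory period.  Fewer than 20 surviving trials raises a
participant-exclusion signal (the conventional floor for a stable
coherence estimate); the floor is configurable and is lowered
proportionally in scaled-down test studies.

Manual bad-channel marking and ICA-based artifact subtraction were
deliberately replaced by the peak-to-peak criterion: visual steps are not
reproducible, and the synthetic data contain no ocular or myogenic
components for ICA to find.  Consequently no channel interpolation is
implemented.  Passing tests therefore say nothing about ICA-dependent
artifact regimes in real recordings.

## Synthetic studies and the analytic oracle

Each design cell (participant × intensity × timepoint) is simulated as two
sources at the 20 Hz carrier driving the C3- and C4-cluster channels
through fixed per-channel gains.  The phase of cluster B lags cluster A by
δ drawn once per trial from von Mises(φ, κ).  Because δ is constant within
a trial, the across-trial carrier ImCoh has the closed form

    ImCoh = |sin φ| · R(κ),   R(κ) = I1(κ)/I0(κ),

the mean resultant length of the jitter distribution.  This is the oracle
for every estimator test.  Design-cell effects multiply κ (sham cells
default to ×1), so stimulation-induced coupling changes have known ground
truth recorded in the study manifest.

Additional generator features: a `leakage` coefficient mixes a shared
zero-lag component into both clusters (leakage = 1 makes the clusters
zero-lag copies — the volume-conduction stress test); background noise is
Gaussian with a 1/f amplitude spectrum and per-channel RMS set by an `snr`
parameter; event mode adds movements every 10 s with a deterministic
half-cosine force ramp (200 ms rise) and a movement-locked beta envelope
(pre-movement and movement suppression, post-movement rebound) with linear
cross-fades.  Default study conditions mirror the emulated experiment:
1000 Hz acquisition, 14 channels, 3 min resting (90 two-second epochs), 60
self-paced movements, four intensities × three timepoints.

What the generator does **not** emulate: biophysical head geometry,
ocular/myogenic artifacts, non-stationary amplitude dynamics, cross-
frequency structure, or the stimulation waveform.  Passing recovery tests
show the estimators are correct for phase-jittered narrowband coupling in
1/f noise — not that the pipeline is robust to everything real EEG does.

Parameter-recovery runs use snr = 1000 and leakage = 0: the oracle
describes the noise-free limit, and broadband noise inside the wavelet
band attenuates ImCoh by an snr-dependent factor the closed form does not
model.  Tolerances are 3 leave-one-trial-out (jackknife) standard errors.

## Trial-level aggregation, peak beta, percent change

Within-trial values are averaged over inclusive 1 Hz band bins (theta 4–7,
alpha 8–12, beta 13–30, gamma 60–90 Hz) and half-open period windows on
the 20 ms grid (pre-movement [−500, 0), movement [0, 500), post-movement
[1500, 4000) ms; resting uses the full 400–1600 ms grid).  Event-related
values are baselined per trial against the within-trial −2000..−1000 ms
estimate; maps are baselined per frequency against the same window.

The peak beta frequency of a trial is the 13–30 Hz bin with the greatest
absolute baseline-subtracted deviation (desynchronization or rebound count
equally), ties broken toward the lower frequency; subtracting the 20 Hz
stimulation frequency gives the endogenous–exogenous difference, bounded
in [−7, +10] Hz by construction.  Percent change between measurement
blocks is 100·(b − a)/|a| with values flagged undefined (NaN, never
silently large) when |a| falls below 10⁻⁶ of the map's dynamic range.

## Cluster-based permutation correlation

Per (frequency, time) cell, Spearman's ρ between the participants' pre-
stimulation frequency differences and their percent-change maps; p-values
from the t approximation on n−2 degrees of freedom (adequate for n ≈ 20;
an exact cell-level permutation p would multiply cost for no change in the
cluster statistic's behaviour).  Cells with p < 0.05 are clustered by
orthogonal (4-neighbour) spectro-temporal adjacency, separately for
positive and negative ρ; cluster mass is Σ|ρ|.  The null is the maximum
cluster mass over permutations of the subject order of the predictor
(1000 by default; when n! is smaller, every distinct permutation is used
exactly once).  Clusters whose mass strictly exceeds the null's 97.5th
percentile are significant; an exact-style permutation p,
(1 + #{null ≥ obs})/(1 + n_perm), is reported alongside.  Applying the
97.5th-percentile rule to both signs against the pooled max-null yields a
two-sided family-wise error near 5%; this is verified by simulation
(500 independent null datasets, n = 20, 27 × 26 grid, 500 permutations:
observed rate must fall in [2%, 8%]), not assumed.  Power is checked by
planting a Spearman-0.8 correlated beta-band block and requiring ≥90%
detection over 100 datasets.

Degenerate inputs: constant predictors raise; constant response cells are
NaN-flagged and can never seed a cluster; subjects with any missing map
cell are dropped pairwise, with fewer than 4 complete subjects an error.

## Orchestration and determinism

The pipeline writes EDF+ recordings (own fixed-layout writer, since the
environment provides no EDF writer; MNE's reader is the cross-check),
HDF5 epoch and ImCoh stores, long-format CSV trial tables, and JSON
cluster results, each stamped with a hash of the scientific configuration
(paths excluded).  All randomness flows from one master seed through
per-cell `SeedSequence` spawns, so a rerun with the same configuration is
byte-identical in its CSV/JSON artifacts.  The CLI's `tfr` and `peaks`
subcommands alias the `connectivity` stage: per-trial wavelet coefficients
are streamed in memory and only reduced maps and tables are persisted
(raw per-trial coefficient stores would run to hundreds of MB per
recording with no downstream consumer).

## Problem sizes

Estimator identity and recovery checks run at 300–500 trials (the scale at
which Monte-Carlo error is a few percent); calibration uses 500 null
datasets × 500 permutations and 100 power datasets; end-to-end runs use a
scaled-down study (2 participants × 2 intensities × 2 timepoints, 12
resting / 6 event trials) — large enough to exercise every stage and the
determinism contract, small enough to iterate on.  The cluster-correlation
stage needs ≥4 participants and is reported as skipped, not silently
omitted, below that.

## Known limitations

* Sensor-space only; no source localization, no leakage correction beyond
  the ImCoh definition itself.
* The within-trial estimator's expectation under trial-constant lag is
  E|sin δ|, which exceeds |E sin δ| at low κ; trial-level and map-level
  values are therefore not directly comparable and carry estimator tags.
* The t-approximate cell p-values are slightly conservative at very small
  n; only the cluster-forming threshold, not the family-wise control,
  depends on them.
* Group-level mixed-model inference is out of scope; the trial table is
  exported in the long format such models consume.
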