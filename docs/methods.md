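# Methods notes

This note records the models behind meakit, the parameter choices that
matter, and what the synthetic data does and does not emulate.

## Recording model and conventions

A `Recording` is a channels × samples float32 matrix in microvolts with
acquisition metadata (sampling rate, amplifier band, software high-pass).
Defaults mirror the acquisition settings of the 60-channel INTAN-based
system the toolkit targets: 20 kSamples/s, 1–10000 Hz amplifier bandwidth,
5 Hz software high-pass, 0.195 µV ADC step. Voltages are converted to µV
on import and raw integer codes are not retained, because every downstream
statistic is defined in µV. Time is seconds from recording start;
time→index conversion is floor-based. The high-pass setting is carried as
metadata only: the analysis stages treat the trace they are given as
already filtered, since detection thresholds scale with whatever noise
statistics the input actually has.

The HDF5 container stores `/recording/data` (+ attributes),
`/layout/positions`, and `/ground_truth/*` groups written only by the
simulator. The RHD2000 reader supports v1.x files only; v2/.rhs files are
rejected explicitly rather than half-parsed.

## Synthetic recordings

The simulator emulates a spontaneously beating cardiomyocyte monolayer on
an 8×8-minus-corners grid (700 µm pitch, 100 µm electrodes):

- **Wavefronts.** Activity is a train of planar wavefront events at
  `firing_rate` (default 1.94 events/s), quasi-periodic with Gaussian
  timing jitter (`jitter_sd`, default 10 ms) — beating monolayers are
  pacemaker-driven and quasi-periodic, not Poisson. Each event crosses the
  grid as a plane wave: the spike on electrode *e* lags the event by
  ((pos_e − origin)·direction)/velocity. Default velocity 0.1 m/s, inside
  the 0.047–0.32 m/s range reported for cardiomyocyte monolayers. A radial
  description was considered and rejected as default: over a 4.9 mm grid
  far from the focus, the planar approximation is what activation maps of
  confluent monolayers show.
- **Waveforms.** The extracellular template is a sum of three Gaussian
  lobes (positive peak, dominant negative peak, positive hump) with a
  linear end-correction so it starts and ends at exactly zero, normalized
  so the sampled minimum equals the requested amplitude exactly. Default
  proportions keep both positive phases under 100 µV at typical
  amplitudes, matching the triphasic morphology of HL-1 extracellular
  potentials. Only morphology is modelled; there is no biophysics.
- **Amplitudes are hierarchical.** Each electrode draws its mean negative
  peak once from N(−123.4, 39.12²) µV — the across-electrode distribution
  reported for real arrays is a distribution of *per-electrode average*
  amplitudes — and individual spikes scatter around that mean with
  relative SD `amp_rel_sd` (default 0.15, a typical spike-to-spike
  variability). A flat per-spike SD of 39.12 µV would instead push every
  electrode's residual noise to ~13 µV and pin all SNRs near 9 dB,
  contradicting the observed 8.9–17.6 dB spread across electrodes.
- **Noise.** Additive white Gaussian noise at `noise_rms` (default
  5.0 µV: a Gaussian baseline with ~34 µV observed peak-to-peak amplitude
  has an RMS near 5 µV), optionally quantized to the 0.195 µV ADC step.
  Real MEA baselines also contain 50 Hz pickup, electrode drift and
  shared-mode noise, none of which is simulated — so passing recovery
  tests demonstrate correctness of the estimators under the stated noise
  model, not robustness to every artifact class of a wet rig.
- **Electroporation.** After a pulse at `t_onset`, spikes on the target
  electrode are a mixture m·intracellular + (1−m)·extracellular with
  m = exp(−(t−t_onset)/reseal_tau). Membrane resealing takes "a few
  minutes" in nanopillar electroporation experiments, hence the 60 s
  default time constant. The intracellular template has a dominant
  negative deflection, a smoothstep-edged plateau (flat over its stated
  width) and no trailing hump.
- **Impedance tables.** Per-electrode impedances are drawn log-normally
  (median anchored at the per-frequency means 1235.4 / 160.06 / 39.28 kΩ
  at 100 / 1000 / 7500 Hz, shape scaled from the observed SDs), log-log
  interpolated at other frequencies — the log-linear |Z|(f) behaviour of
  gold microelectrodes. A configurable affine distortion produces the
  "raw" instrument readings that the calibration module must undo.
- **Determinism.** One `numpy.random.default_rng(seed)` generator drives
  every draw in a fixed order; identical seeds give bit-identical output.
  This is part of the public contract and is tested.

## Detection

σ is the plain sample SD over the full session (a robust MAD-based option
exists but is not default, since the reference procedure is the plain SD;
note that with spikes present the session SD slightly exceeds the noise
SD, making the 4σ threshold mildly conservative). Crossings within a
dead time (default 3 ms — below any plausible cardiac inter-spike interval,
above the template main lobe) are merged. The event amplitude is the
signed extreme within −2/+6 ms around the crossing; the snippet window is
sized to contain the full triphasic waveform.

The amplitude filter keeps events in the closed window [−400, −80] µV,
i.e. negative-peak magnitudes between 80 and 400 µV. Stated as a pair of
signed inequalities this rule is self-contradictory ("smaller than −80 µV
or larger than −400 µV" discards everything or nothing depending on the
reading); the magnitude-window reading is the only one consistent with a
reported mean amplitude of −123.4 µV surviving the filter. Boundaries are
inclusive and the filter is idempotent.

Electrode selection defaults to "more than 20 spikes per session". The
literal criterion "more than 20 spikes/second" cannot be what produced the
published per-electrode statistics (mean rate 1.94 spikes/s would leave no
electrode standing), so the count-per-session reading is the default and
the literal rate reading is available via `min_rate`. Neither intent is
guessed beyond providing both.

Recovery evaluation convention: recall is measured against ground-truth
spikes whose *true* amplitude lies in the keep window (spikes the filter
is designed to discard are not misses), while precision counts a detected
event as correct if it matches any ground-truth spike, filtered or not.
Matching is greedy one-to-one within ±1 ms.

## SNR

Alignment maximizes normalized cross-correlation against an iterated
template, starting from the medoid waveform; the description "minimizing
the cross-correlation" of waveforms is read as minimizing *misalignment* —
literally minimizing correlation would anti-align the ensemble and destroy
the template average. Shifts are integer samples only (50 µs granularity at
20 kHz, below any feature width of these waveforms); out-shifted samples
are edge-padded. `A_noise` pools all residual samples across spikes into
one RMS per electrode (per-spike averaging differs only at second order);
an ensemble of identical waveforms raises a "degenerate ensemble" error
rather than returning +∞.

## Propagation

Grouping is single-linkage in time with a 50 ms window — comfortably above
the one-pitch traversal time at the slowest reference velocity (15 ms) and
far below the default beat interval (515 ms). An event that chains longer
than (layout diagonal)/(0.01 m/s) is split, guarding against bridging
successive beats on sparse arrays. Pairwise mode uses consecutive-in-time
pairs, matching how inter-electrode delays are usually annotated on
activation maps; the plane-wave regression is the statistically better
estimator and is exact on noise-free planar waves. Off-axis electrode
pairs geometrically overestimate speed (apparent velocity = true/cosθ),
which is why the pairwise summary is a median and the plane fit is
preferred for quantitative work. Distances are centre-to-centre; electrode
diameter plays no role.

## Impedance

Calibration regresses measured on true in linear impedance space (the
reference resistors span 1–100 kΩ per frequency; log-space fitting would
reweight the small resistors) and inverts the line at application time.
The fit correlation `r` is Pearson's r with `r²` also exposed, since
reported fit qualities of the form "R > 0.98" are ambiguous between the
two; r < 0.98 warns but does not reject. Summaries use two-pass
compensated (fsum) statistics so that degenerate tables summarize exactly.

## Stimulation

Pulse trains are validated, not clipped: both output levels must lie
within the ±3.3 V analog range or the train is refused, because silently
clipping a stimulus would misrepresent the charge delivered to the
electrode. Derived quantities are period = width/duty and
n_pulses = floor(duration/period) (with a 1e-9 guard against float-division
dust). Rendering is exact: high samples equal offset + amplitude, low
samples equal offset, and for integer samples-per-period the high-sample
fraction equals the duty cycle exactly. An optional DAC quantization step
is available with no default: the hardware's nominal stimulation
resolution figure is implausible as printed and is not encoded.

## Problem sizes and numerical choices

The test-suite and acceptance-script problem sizes are chosen so each
check is statistically meaningful at desk scale: 60 electrodes × 60 s for
detection recovery (~7000 ground-truth spikes), 200-spike ensembles × 20
conditions for SNR recovery, 10⁷ samples for false-positive calibration
(~320 expected crossings, SD ≈ 5.6%, compared at 10% tolerance), 64
electrodes × 3 frequencies for impedance. Alignment caps at 10 template
passes; ties in the lag search go to the smaller |lag|. Constant traces,
empty trains, simultaneous activations, zero-slope calibrations and
degenerate ensembles are all defined error or flag paths rather than NaNs.

## Known limitations

- No spike sorting, overlapping-spike decomposition or template matching;
  coincident wavefronts superpose linearly (with a warning from the
  simulator).
- The simulator's noise is white and Gaussian; electrode-specific
  impedance-dependent noise spectra are not modelled.
- Complex impedance (phase) and equivalent-circuit models are out of
  scope; calibration is magnitude-only.
- The RHD reader targets v1.x amplifier data; auxiliary/ADC streams are
  skipped rather than exposed.
- Conduction analysis assumes a single coherent wavefront per event;
  re-entry/rotor patterns are not handled.
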