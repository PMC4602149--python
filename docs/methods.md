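# Methods

This package reimplements, end to end and on synthetic ground truth, a
functional-typing workflow for retinal ganglion cells (RGCs) recorded on a
high-density CMOS microelectrode array: standardized visual stimulus
protocols, per-cell response indices, and unsupervised clustering of those
indices into functional types, together with the spike-sorting and
activity-scan stages that precede them in a real experiment.

## Stimulus protocols (`rgctyping.stimuli`)

Four protocols are generated as exact timed event sequences on a 1 x 1 mm
projected field (origin at the lower-left corner; directions in degrees,
0 = motion toward +x, counterclockwise positive):

| protocol | events | factors |
|---|---|---|
| marching square | 405 | 9 x 9 grid of 100 um squares over 900 x 900 um, 5 repetitions, 2 s bright per presentation |
| narrow bars | 48 | 8 directions x 3 lateral offsets (-250/0/+250 um) x speeds {600, 1200} um/s; bar 1000 um along motion, 500 um across |
| width test | 80 | widths {75, 150, 300, 600, 900} um x 2 contrasts x 4 directions x speeds {150, 900} um/s |
| speed test | 96 | widths {150, 600} um x 2 contrasts x 4 directions x speeds {150 ... 1800} um/s |

Presentation order is a seeded pseudo-random permutation. The
marching-square inter-event gap is 2 s so that the 1.5 s OFF-response
window after square disappearance falls entirely on background; bar
protocols use a 0.5 s gap. Every bar fully traverses the field:
traversal time = (field extent along the motion axis + bar width) / speed.

## Generative cell model (`rgctyping.synthetic`)

Each synthetic cell responds through a separable firing rate

    lambda(t) = baseline + peak * G_spatial * S(speed) * W(width) * D(theta) * K(t - t_drive)

* `G_spatial`: overlap of the stimulus footprint with an isotropic Gaussian
  receptive field. The Gaussian SD is `diameter / (2 sqrt(2 ln(1/0.33)))`
  (~ diameter/2.97), so the 33 %-of-maximum contour of the noiseless
  response profile has the cell's nominal diameter — the convention the
  receptive-field estimator assumes.
* `K`: unit-peak temporal kernel — 50 ms raised-cosine rise peaking at the
  cell's latency, then exponential decay. The decay constant is calibrated
  per cell by root-finding so that the measured transience index of the
  noiseless 1.5 s PSTH equals the archetype's target. This makes parameter
  recovery a well-posed contract rather than a loose analogy.
* `S`, `W`: unit-peak log-Gaussian speed and width tunings (bandwidth 1.0
  natural-log unit by default).
* `D`: von-Mises-shaped direction gain `exp(kappa (cos(dtheta) - 1))`,
  identically 1 for non-DS cells. The default concentration is calibrated
  so the noiseless 8-direction DS index is 0.6.

Polarity gates the drives: a positive-contrast transition (square onset,
bright-bar leading edge, dark-bar trailing edge) drives ON and ON-OFF
cells; a negative-contrast transition (square offset, bright-bar trailing
edge, dark-bar leading edge) drives OFF and ON-OFF cells. Each bar sweep
contributes one drive per gated edge at the moment that edge crosses the
receptive-field centre, with a lateral gain equal to the receptive-field
mass within the bar's lateral span.

The default archetype table has one row per functional type: OFF brisk
transient, OFF sluggish transient, ON-OFF brisk transient, ON-OFF sluggish
sustained, ON-OFF DS, ON brisk transient, ON DS. Brisk types peak at
0.12 s, sluggish at 0.30 s (per-cell SD 0.02 s); transient types target a
transience of 0.2, sustained 0.7; DS types get kappa for DSI 0.6 with
per-cell uniform preferred directions, the ON-OFF DS type preferring fast
bars (1200 um/s), the ON DS type slow ones (300 um/s); receptive-field
diameters are 270 +/- 60 um; drive amplitude 120 Hz over a 1 Hz baseline.
These magnitudes are package defaults for simulation and recovery testing,
chosen as physiologically plausible values, not measured claims about any
retina.

Spike trains are drawn by inhomogeneous-Poisson thinning against a grid
upper bound (1 ms grid, 5 % safety margin — safe because the kernel's rise
and decay scales are 50x the grid step), with a 2 ms absolute refractory
period applied by deletion. An independent time-rescaling implementation
serves as the distributional oracle in the tests.

Extracellular traces are rendered at 20 kHz on a 126-electrode block
(6 x 21 at 17.5 um pitch — the layout is a rectangular stand-in for the
device's non-rectangular block) as one biphasic template per cell with
exponential spatial decay (length constant 25 um) around the soma, plus
white noise at 2.4 uV RMS. Each cell draws its own waveform shape (trough
width, repolarisation-peak delay/width/ratio) and a peak amplitude in
50-300 uV, as real cells do; somata keep a 30 um minimum spacing.

## Response parameters (`rgctyping.params`)

Seven indices per cell, computed identically from analytic (noiseless)
responses and from spike trains:

* **Bias index** `(ON - OFF)/(ON + OFF)` from baseline-subtracted spike
  counts in the 1.5 s windows after square onset and offset at the most
  responsive grid location.
* **Latency**: time to the maximum of the rate smoothed with a centred
  25 ms boxcar on 5 ms bins; ties resolve to the earliest bin. ON cells use
  the onset-anchored PSTH, OFF cells the offset-anchored one, ON-OFF cells
  whichever has the larger peak.
* **Transience**: PSTH area over [0, 1.5] s, peak-normalised, divided by
  1.5 — 1.0 for a sustained response. Inside the orchestrated extraction
  the normalising peak is read from the 25 ms-smoothed profile; the raw
  single-bin peak is unbiased only for noiseless profiles.
* **Receptive field**: the 9 x 9 response map is upsampled 9-fold per axis
  (bilinear), thresholded at 33 % of maximum; the supra-threshold pixel
  fraction times 810 000 um^2 gives the area A and `d = sqrt(4A/pi)` the
  equivalent-circle diameter; the centre is the response-weighted centroid.
* **DS index**: `|sum r_i u(theta_i)| / sum r_i` over the eight narrow-bar
  directions, using for each direction the lateral offset whose path passes
  nearest the receptive-field centre, rates averaged over the two speeds
  and baseline-subtracted.
* **Preferred speed / width indices**: response-weighted mean of the tested
  values divided by the maximum tested value, the response per condition
  being the peak smoothed rate maximised over contrast, direction and the
  other kinematic factor.

A cell is *responsive* to a protocol when its peak smoothed rate exceeds
baseline + 3 SD of the background rate (trivially satisfied by any driven
noiseless response, since the noiseless background SD is zero); cells
failing any protocol are discarded before clustering, with the failing
protocols reported.

Known estimator biases, inherited from the measurement design and visible
in the recovery tests: the 100 um square limits spatial resolution, so
receptive fields well below ~200 um are over-estimated by more than 15 %;
cells whose fields extend past the 900 um mapping grid are under-estimated;
mean firing rates over a bar traversal truncate the response of cells
crossed near the field exit, which puts a small spurious DS index
(up to ~0.1) on untuned cells away from the field centre. The recovery
contract is therefore stated at each archetype's canonical parameters with
the field centred, and tolerances of +/-0.1 (bias, DSI), +/-15 ms
(latency), +/-0.05 (transience) and +/-15 % (diameter) elsewhere.

## Spike sorting (`rgctyping.sorting`)

Zero-phase 300-8000 Hz band-pass (513-tap FIR applied by overlap-add with
the group delay removed); per-electrode negative-threshold detection at
3.5 robust SDs (median |x| / 0.6745) with a 1 ms dead time; simultaneous
detections on neighbouring electrodes consolidated to the loudest one.
At a 3.5-sigma threshold, band-limited Gaussian noise alone crosses at
several events per second per electrode (the Rice level-crossing rate);
these events are eliminated later, not at detection.

Demixing runs per peak electrode on its seven-electrode neighbourhood
(centre + 6 nearest): snippets (-0.5/+1.0 ms) are projected onto 3
principal components and clustered by a Gaussian mixture with BIC-selected
component count (1-5). Clusters below 20 events are dropped, as are
clusters whose mean waveform stays below 7 noise SDs peak-to-peak — the
spike-triggered average of >= 20 genuine spikes sits at the cell's full
amplitude, whereas averaged noise crossings remain near the single-event
threshold.

Each surviving cluster yields a multi-electrode STA template (footprint =
7 largest-amplitude electrodes). Matching scores each candidate event by
residual reduction `1 - RSS/TSS` on the footprint, sliding the template
within +/-0.5 ms, accepting scores >= 0.6 best-score-first with a 1 ms
per-unit exclusion. Matching proceeds by greedy *peeling*: units are
processed loudest-first and each unit's fitted spikes are subtracted from
a working copy of the traces; a second pass re-detects on the residual,
recovering spikes masked by a coincident larger spike. Quality control
compares templates pairwise (Pearson correlation over the union of
footprints, peak-aligned); pairs above 0.9 merge when the combined train —
after collapsing co-detections within 0.5 ms, which are one action
potential seen twice — keeps refractory violations (< 2 ms intervals) at
or below 1 %. Merging is a transitive closure; units with fewer matched
spikes than the 20-event template minimum, or over 1 % violations, are
rejected.

On the standing benchmark (12 cells, 8 Hz, 60 s, 126 electrodes, default
noise) the chain recovers every cell with exactly one unit, spike-time
recall >= 0.99 and precision 1.0 at +/-0.5 ms.

## Activity scan (`rgctyping.scan`)

Per-electrode maps of the maximum detected peak-to-peak amplitude;
putative somata are counted as electrodes above a 30 uV floor that
strictly exceed their 8-neighbourhood; among candidate configurations the
one with the most such maxima wins, ties broken by summed amplitude, then
lowest id.

## Cell typing (`rgctyping.celltypes`)

Clustering uses five parameters (bias index, latency, transience, DS
index, speed index); latency (and receptive-field diameter, in the
optional 7-parameter mode) is min-max scaled to [0, 1], bounded indices
pass through. k-means (squared-Euclidean, best of `restarts`
initialisations) runs for each k in 4..25 and the k with the highest mean
silhouette `S_i = (b_i - a_i)/max(a_i, b_i)` is selected (singletons score
0; ties go to the smaller k). Pairwise cluster validity is the separation
coefficient: both groups projected on the axis joining their means, the
centre-to-centre distance divided by the average of the two projected
sample SDs — the number of standard deviations between the groups. Sample
moments replace histogram Gaussian fits: deterministic and bin-free.
Diagnostics: per-cluster parameter means with a suggested type label
(polarity at bias +/-0.33, DS above index 0.2, brisk/sluggish and
transient/sustained by median splits — labels only, never membership);
receptive-field tiling coverage/overlap; and circular-kernel-density mode
counts (bandwidth 20 deg, modes above half peak) for DS clusters'
preferred directions.

On the default 7-archetype synthetic population (40 cells per archetype,
noiseless responses), the silhouette-selected k equals 7 — the generating
type count — in >= 90 % of seeded runs at 200 restarts, with
cluster-to-archetype purity >= 0.9.

## Orchestration (`rgctyping.pipeline`, `rgctyping.io`, CLI)

A single `RunConfig` carries the root seed and every threshold; per-stage
seeds are spawned from the root via `SeedSequence`, so a run is
bit-reproducible (the manifest records the config snapshot, spawned seeds,
artifact SHA-256 checksums and timings). Artifacts are plain formats: TSV
event logs, CSV tables, HDF5 population/trace archives (traces as int16
with a 0.01 uV scale). In the default noiseless mode parameters come from
analytic responses; in stochastic mode from Poisson spike trains. The
sorting stage, when enabled, validates the sorter on a dedicated rendered
block; rendering the full four-protocol timeline (~1 h of 126-electrode
20 kHz data) is out of desk scale, so sorted trains do not feed the typing
stage.

## What the synthetic data does and does not emulate

Emulated: polarity classes, Gaussian receptive fields at the ~270 um
scale, calibrated latency/transience kernels, von-Mises direction tuning,
log-Gaussian speed/width tuning, Poisson spiking with refractoriness,
multi-electrode extracellular waveforms with realistic amplitudes, spacing
and shape diversity, white noise at the device's noise floor.

Not emulated: light adaptation and gain control, correlated (shared) noise
and burstiness, electrode drift, overlapping dendritic signals, the
photoreceptor-to-ganglion-cell circuit, and any claim about true RGC type
counts or densities. Passing tests therefore demonstrate that the
*analysis chain* is correct and self-consistent under the generative
model's assumptions — not that seven types exist in any real retina.
Sustained archetypes expose one deliberate model simplification: a pure
exponential decay calibrated to transience 0.7 keeps firing across the
inter-event gap, so in stochastic mode their baseline estimate inflates
and their indices blur; the noiseless route is the reference for recovery.

## Problem sizes

Test-suite and acceptance runs use: 280-cell populations (40 per
archetype) for cluster-count recovery over 20 seeds at 200 k-means
restarts; one canonical cell per archetype for parameter recovery; a
60 s, 126-electrode, 12-cell block for sorting recovery; 10^4 random rate
vectors and random instances up to n = 50 for the oracle equivalences.
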