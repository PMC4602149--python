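# rgctyping

Functional classification of retinal ganglion cells (RGCs) from
multi-electrode recordings, rebuilt as a tested pipeline that runs
entirely on synthetic data with known ground truth.

Retinal ganglion cells come in dozens of functional types — ON, OFF and
ON-OFF cells, brisk and sluggish, transient and sustained,
direction-selective (DS) — and a standard way to survey them is to project
a battery of simple visual stimuli onto an isolated retina lying on a
high-density microelectrode array, sort the extracellular traces into
single-cell spike trains, reduce each cell to a handful of response
indices, and cluster those indices. This package implements that whole
chain for anyone who wants to study, test or extend the analysis without
access to a rig:

* **`rgctyping.stimuli`** — the four stimulus protocols as exact event
  sequences: a marching 100 µm square over a 9×9 grid (receptive-field
  mapping, ON/OFF bias, latency, transience), narrow moving bars in eight
  directions (direction selectivity), and bar width/speed batteries.
* **`rgctyping.synthetic`** — a generative retina: archetype-based model
  cells with Gaussian receptive fields, calibrated latency/transience
  kernels, von-Mises direction tuning and log-Gaussian speed/width tuning,
  firing inhomogeneous-Poisson spikes; optionally rendered as 20 kHz
  voltage traces on a 126-electrode, 17.5 µm-pitch block.
* **`rgctyping.sorting`** — spike sorting: band-pass filtering, 3.5 σ
  threshold detection, PCA + Gaussian-mixture demixing on seven-electrode
  groups, spike-triggered-average (STA) templates, template matching with
  subtractive peeling, and duplicate merging under a 1 % refractory-
  violation rule.
* **`rgctyping.scan`** — the experiment-time activity scan that picks the
  most cell-rich 126-electrode configuration from amplitude maps.
* **`rgctyping.params`** — the seven response indices per cell.
* **`rgctyping.celltypes`** — k-means over the five clustered indices with
  silhouette-based selection of k, Fisher-style separation coefficients,
  and tiling / direction-polar diagnostics.
* **`rgctyping.pipeline` / CLI `rgctyping`** — seeded, manifest-recorded
  orchestration of the whole chain.

## The indices and the clustering

For each cell, from its responses to the protocols:

* bias index `BI = (ON − OFF)/(ON + OFF)` ∈ [−1, 1], from flashed-square
  spike counts after square appearance (ON) and disappearance (OFF);
* latency: time to the peak of the firing rate smoothed with a 25 ms
  sliding window;
* transience: area of the peak-normalised 1.5 s post-stimulus time
  histogram divided by 1.5 (1 = sustained);
* receptive-field diameter `d = √(4A/π)`, where A is the area of the
  response map upsampled 9× and thresholded at 33 % of maximum;
* DS index `D = |Σ rᵢ·ûᵢ| / Σ rᵢ` over eight bar directions (0 = untuned,
  1 = unidirectional);
* preferred-speed and preferred-width indices: response-weighted mean of
  the tested speeds/widths, normalised by the maximum tested value.

Cells responsive to all protocols are clustered with k-means
(k = 4…25, thousands of restarts) on {BI, latency, transience, DS index,
speed index}; the k maximising the mean silhouette
`Sᵢ = (bᵢ − aᵢ)/max(aᵢ, bᵢ)` is selected, and pairwise cluster validity is
the separation coefficient — the distance between two cluster means
divided by the mean SD of both groups projected on the centre-to-centre
axis. Full model details, defaults and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from rgctyping.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=1, out_dir="demo_run", n_per_archetype=10, restarts=200)
manifest = run_pipeline(cfg)
print("cells:", manifest.summary["n_cells"],
      "responsive:", manifest.summary["n_responsive"])
print("selected k:", manifest.summary["selected_k"])
print("mean silhouette:", round(manifest.summary["mean_silhouette"], 3))
print("min separation:", round(manifest.summary["min_separation"], 2))
```

prints

```
cells: 70 responsive: 70
selected k: 7
mean silhouette: 0.827
min separation: 9.28
```

Seventy synthetic cells (ten per archetype) were simulated through the
four protocols, all seventy passed the responsiveness filter, and the
silhouette sweep recovered k = 7 — one cluster per generating archetype —
with a mean silhouette of 0.83; the least-separated pair of clusters still
sits 9.3 projected standard deviations apart. `demo_run/` then contains
the stimulus event log, the population archive, `parameters.csv` (the
seven indices per cell), `clusters.csv` with suggested type labels
(e.g. `cell_id 0 → cluster 7, "OFF brisk transient"`), the separation
matrix, per-k silhouettes and a JSON manifest with seeds and artifact
checksums. The same run is available from the shell:

```bash
rgctyping all --seed 1 --out demo_run
```

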