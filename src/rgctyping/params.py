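"""Response-parameter extraction for retinal ganglion cells.

Seven parameters summarise each cell's visual responses:

* **bias index** ``(ON - OFF) / (ON + OFF)`` from flashed-square spike counts,
  -1 for a pure OFF cell, +1 for a pure ON cell, 0 for a balanced ON-OFF cell;
* **latency** -- time from stimulus onset to the maximum of the firing rate
  smoothed with a sliding 25 ms integration window;
* **transience** -- area under the peak-normalised 1.5 s post-stimulus time
  histogram divided by 1.5, so a sustained (constant) response scores 1.0;
* **receptive-field diameter** ``d = sqrt(4A/pi)`` where A is the area of the
  response map upsampled nine-fold and thresholded at 33 % of its maximum;
* **direction-selectivity index** -- length of the rate-weighted vector
  average over eight motion directions, 0 (untuned) to 1 (unidirectional);
* **preferred-speed index** and **preferred-width index** -- response-weighted
  mean of the tested speeds/widths normalised by the maximum tested value.

All extractors operate on a :class:`ProtocolResponses` bundle, which can be
produced either from recorded/simulated spike trains
(:func:`responses_from_spikes`) or analytically from a noiseless model cell
(see :mod:`rgctyping.synthetic`); the extraction math is shared by both
routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .stimuli import (
    FieldGeometry,
    GRID_EXTENT_UM,
    GRID_N,
    SquareFlashEvent,
    StimulusSet,
)

__all__ = [
    "PSTH",
    "ProtocolResponses",
    "CellParameterVector",
    "bias_index",
    "latency",
    "transience",
    "receptive_field",
    "ds_index",
    "select_bar_responses",
    "preferred_index",
    "compute_cell_parameters",
    "responses_from_spikes",
    "responsiveness_filter",
    "parameters_to_frame",
]

PSTH_WINDOW_S = 1.5
DEFAULT_BIN_S = 0.005
SMOOTH_WINDOW_S = 0.025


class NonResponsiveError(ValueError):
    """Raised when a parameter is undefined because the cell did not respond."""


@dataclass
class PSTH:
    """Repetition-averaged post-stimulus firing profile.

    `rates` holds the mean firing rate per bin (Hz, baseline-subtracted for
    extraction purposes) over the window ``[0, 1.5]`` s after the anchoring
    stimulus transition.
    """

    rates: np.ndarray
    bin_width: float = DEFAULT_BIN_S
    n_repetitions: int = 1

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("PSTH rates must be non-negative")

    @property
    def duration(self) -> float:
        return len(self.rates) * self.bin_width

    def smoothed(self, window_s: float = SMOOTH_WINDOW_S) -> np.ndarray:
        size = max(1, round(window_s / self.bin_width))
        return ndimage.uniform_filter1d(self.rates, size=size, mode="nearest")

    @property
    def peak(self) -> float:
        return float(self.rates.max()) if len(self.rates) else 0.0


@dataclass
class ProtocolResponses:
    """Per-protocol response aggregates for one cell, the common input of the
    parameter extractors.

    on_map / off_map
        9 x 9 baseline-subtracted mean spike counts per square location for
        the ON (square onset) and OFF (square offset) windows.
    on_psth / off_psth
        PSTHs at the most responsive square location, anchored to onset and
        offset respectively.
    on_count / off_count
        baseline-subtracted mean spike counts per presentation in the ON and
        OFF windows at the most responsive location (the bias-index inputs).
    bar_table
        one row per narrow-bar condition: direction, lateral_offset, speed,
        mean_rate (baseline-subtracted mean rate over the traversal).
    speed_table / width_table
        one row per bar of the speed/width test: the kinematic factors plus
        peak_rate, the baseline-subtracted peak smoothed rate.
    protocol_peaks
        per-protocol peak smoothed rate including baseline, used by the
        responsiveness criterion.
    """

    on_map: np.ndarray
    off_map: np.ndarray
    on_psth: PSTH
    off_psth: PSTH
    bar_table: pd.DataFrame
    speed_table: pd.DataFrame
    width_table: pd.DataFrame
    on_count: float = 0.0
    off_count: float = 0.0
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    protocol_peaks: dict = dc_field(default_factory=dict)
    map_origin: tuple[float, float] = (50.0, 50.0)


@dataclass
class CellParameterVector:
    """The seven extracted response parameters plus responsiveness flags."""

    cell_id: int
    bias_index: float
    latency_s: float
    transience: float
    rf_diameter_um: float
    ds_index: float
    speed_index: float
    width_index: float
    responded_all: bool
    responded: dict = dc_field(default_factory=dict)
    rf_center: tuple[float, float] | None = None
    archetype: str | None = None


# ---------------------------------------------------------------------------
# individual extractors

def bias_index(on_count: float, off_count: float) -> float:
    """ON-OFF bias ``(ON - OFF) / (ON + OFF)`` in [-1, 1]."""
    if on_count < 0 or off_count < 0:
        raise ValueError("spike counts must be non-negative")
    total = on_count + off_count
    if total == 0:
        raise NonResponsiveError("no spikes in either polarity window")
    return (on_count - off_count) / total


def latency(psth: PSTH, window_s: float = SMOOTH_WINDOW_S) -> float:
    """Time to the maximum of the boxcar-smoothed firing rate.

    The rate is integrated over a centred sliding 25 ms window; ties at the
    maximum resolve to the earliest bin, and the returned time is the centre
    of that bin.
    """
    if psth.peak <= 0:
        raise NonResponsiveError("empty PSTH")
    smooth = psth.smoothed(window_s)
    i = int(np.argmax(smooth))
    return (i + 0.5) * psth.bin_width


def transience(psth: PSTH, window_s: float = PSTH_WINDOW_S,
               smooth_s: float | None = None) -> float:
    """Normalised persistence of the response over the 1.5 s window.

    The PSTH is scaled to unit peak, integrated, and the area divided by
    1.5 s, so an infinitely brief response scores ~0 and a constant response
    scores exactly 1.  With `smooth_s` set, the peak is taken from the
    boxcar-smoothed profile, which makes the normalisation robust to
    single-bin Poisson noise on repetition-averaged histograms (the area is
    unaffected by the smoothing).
    """
    if abs(psth.duration - window_s) > psth.bin_width:
        raise ValueError(
            f"transience requires a {window_s} s PSTH, got {psth.duration} s")
    peak = psth.peak if smooth_s is None else float(psth.smoothed(smooth_s).max())
    if peak <= 0:
        raise NonResponsiveError("empty PSTH")
    area = float(np.sum(psth.rates / peak)) * psth.bin_width
    return min(area / window_s, 1.0)


def receptive_field(
    response_map: np.ndarray,
    *,
    upsample: int = 9,
    threshold: float = 0.33,
    order: int = 1,
    grid_extent_um: float = GRID_EXTENT_UM,
    map_origin: Sequence[float] = (50.0, 50.0),
) -> tuple[float, float, np.ndarray]:
    """Receptive-field area, equivalent-circle diameter and centre.

    The 9 x 9 response map is upsampled `upsample`-fold per axis (bilinear by
    default; ``order=0`` gives the blocky nearest-neighbour variant) and
    thresholded at 33 % of its maximum.  The supra-threshold pixel fraction
    times the 900 x 900 um stimulus area gives the area A, and the diameter
    is that of the circle of equal area, ``d = sqrt(4A/pi)``.  The centre is
    the response-weighted centroid of the supra-threshold pixels, in field
    coordinates (um).
    """
    m = np.asarray(response_map, dtype=float)
    if m.max() <= 0:
        raise NonResponsiveError("response map has no positive entries")
    up = ndimage.zoom(m, upsample, order=order, mode="nearest", grid_mode=True)
    mask = up >= threshold * up.max()
    area = mask.mean() * grid_extent_um**2
    diameter = float(np.sqrt(4.0 * area / np.pi))
    # pixel centres in field coordinates; map rows index x, columns y
    n = up.shape[0]
    coords = (np.arange(n) + 0.5) * grid_extent_um / n
    xx = coords[:, None] + map_origin[0] - 0.0
    yy = coords[None, :] + map_origin[1] - 0.0
    w = np.where(mask, up, 0.0)
    center = np.array([np.sum(w * xx), np.sum(w * yy)]) / np.sum(w)
    return float(area), diameter, center


def ds_index(rates: Sequence[float], directions_deg: Sequence[float]) -> float:
    """Vector-average direction-selectivity index in [0, 1]."""
    r = np.asarray(rates, dtype=float)
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    total = r.sum()
    if total == 0:
        raise NonResponsiveError("no firing in any direction")
    vec = np.sum(r * np.exp(1j * th))
    return float(np.abs(vec) / total)


def select_bar_responses(
    cell_center: Sequence[float],
    bar_table: pd.DataFrame,
    field: FieldGeometry | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-direction firing rates using the bar nearest the receptive field.

    For each direction the lateral offset whose motion axis passes closest to
    the cell's receptive-field centre is chosen, and the rates of that bar
    are averaged over the tested speeds.  Returns (directions, rates).
    """
    field = field or FieldGeometry()
    p = np.asarray(cell_center, dtype=float) - field.center
    directions = np.sort(bar_table["direction"].unique())
    rates = np.zeros(len(directions))
    for k, d in enumerate(directions):
        th = np.deg2rad(d)
        lateral = float(p @ np.array([-np.sin(th), np.cos(th)]))
        sub = bar_table[bar_table["direction"] == d]
        offsets = sub["lateral_offset"].unique()
        best = offsets[np.argmin(np.abs(offsets - lateral))]
        rates[k] = sub.loc[sub["lateral_offset"] == best, "mean_rate"].mean()
    return directions, rates


def preferred_index(
    responses: Sequence[float], condition_values: Sequence[float]
) -> float:
    """Response-weighted preferred value, normalised by the maximum tested.

    ``v* = sum(v_i r_i) / sum(r_i)``; the index ``v*/max(v)`` lies in (0, 1]
    and equals 1 for a cell responding only at the largest tested value.
    """
    r = np.asarray(responses, dtype=float)
    v = np.asarray(condition_values, dtype=float)
    if len(r) < 2 or len(r) != len(v):
        raise ValueError("need responses for at least two conditions")
    if np.any(r < 0):
        raise ValueError("responses must be non-negative")
    if r.sum() == 0:
        raise NonResponsiveError("no response at any condition")
    preferred = float(np.sum(v * r) / np.sum(r))
    return preferred / float(v.max())


# ---------------------------------------------------------------------------
# orchestration

def _condition_responses(table: pd.DataFrame, by: str) -> tuple[np.ndarray, np.ndarray]:
    """Peak response per condition, maximised over the remaining factors
    (contrast, direction, and the other kinematic variable)."""
    grouped = table.groupby(by)["peak_rate"].max()
    return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)


def compute_cell_parameters(
    resp: ProtocolResponses,
    cell_id: int = -1,
    field: FieldGeometry | None = None,
    archetype: str | None = None,
) -> CellParameterVector:
    """Extract the full seven-parameter vector from one cell's responses.

    Undefined parameters (non-responsive cell) are reported as NaN with the
    corresponding responsiveness flag cleared.  Latency and transience use
    the polarity window with the larger peak (which for pure ON/OFF cells is
    the matching-polarity window).
    """
    field = field or FieldGeometry()
    responded: dict[str, bool] = {}
    floor = resp.baseline_mean + 3.0 * resp.baseline_sd
    for proto in ("marching_square", "narrow_bars", "width_test", "speed_test"):
        responded[proto] = bool(resp.protocol_peaks.get(proto, 0.0) > floor)

    out = dict(bias_index=np.nan, latency_s=np.nan, transience=np.nan,
               rf_diameter_um=np.nan, ds_index=np.nan, speed_index=np.nan,
               width_index=np.nan)
    rf_center = None
    try:
        out["bias_index"] = bias_index(resp.on_count, resp.off_count)
    except NonResponsiveError:
        responded["marching_square"] = False

    try:
        combined = resp.on_map + resp.off_map
        _, out["rf_diameter_um"], rf_center = receptive_field(
            combined, map_origin=resp.map_origin)
    except NonResponsiveError:
        responded["marching_square"] = False

    psth = resp.on_psth if resp.on_psth.peak >= resp.off_psth.peak else resp.off_psth
    try:
        out["latency_s"] = latency(psth)
        out["transience"] = transience(psth, smooth_s=SMOOTH_WINDOW_S)
    except NonResponsiveError:
        responded["marching_square"] = False

    try:
        center = rf_center if rf_center is not None else field.center
        dirs, rates = select_bar_responses(center, resp.bar_table, field)
        out["ds_index"] = ds_index(rates, dirs)
    except NonResponsiveError:
        responded["narrow_bars"] = False

    try:
        speeds, r = _condition_responses(resp.speed_table, "speed")
        out["speed_index"] = preferred_index(r, speeds)
    except NonResponsiveError:
        responded["speed_test"] = False
    try:
        widths, r = _condition_responses(resp.width_table, "width")
        out["width_index"] = preferred_index(r, widths)
    except NonResponsiveError:
        responded["width_test"] = False

    return CellParameterVector(
        cell_id=cell_id, responded=responded,
        responded_all=all(responded.values()),
        rf_center=None if rf_center is None else tuple(rf_center),
        archetype=archetype, **out)


def responsiveness_filter(
    cells: Sequence[CellParameterVector],
) -> tuple[list[CellParameterVector], list[tuple[int, list[str]]]]:
    """Keep cells that responded to all four protocols.

    Returns (kept, discarded) where each discarded entry is
    ``(cell_id, [failing protocols])``.
    """
    kept, discarded = [], []
    for c in cells:
        if c.responded_all:
            kept.append(c)
        else:
            failing = [p for p, ok in c.responded.items() if not ok]
            discarded.append((c.cell_id, failing))
    return kept, discarded


def parameters_to_frame(cells: Sequence[CellParameterVector]) -> pd.DataFrame:
    """Tabulate parameter vectors (one row per cell)."""
    rows = []
    for c in cells:
        rows.append({
            "cell_id": c.cell_id, "bias_index": c.bias_index,
            "latency_s": c.latency_s, "transience": c.transience,
            "rf_diameter_um": c.rf_diameter_um, "ds_index": c.ds_index,
            "speed_index": c.speed_index, "width_index": c.width_index,
            "responded_all": c.responded_all,
            "archetype": c.archetype if c.archetype is not None else "",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spike-train route

def _smoothed_peak_rate(times: np.ndarray, t0: float, t1: float,
                        bin_s: float = DEFAULT_BIN_S) -> float:
    """Peak of the 25 ms boxcar-smoothed rate of spikes in [t0, t1)."""
    n = max(1, int(np.ceil((t1 - t0) / bin_s)))
    counts, _ = np.histogram(times, bins=n, range=(t0, t0 + n * bin_s))
    size = max(1, round(SMOOTH_WINDOW_S / bin_s))
    sm = ndimage.uniform_filter1d(counts.astype(float), size=size, mode="nearest")
    return float(sm.max()) / bin_s


def responses_from_spikes(
    spike_times: np.ndarray,
    protocols: Mapping[str, StimulusSet],
    bin_s: float = DEFAULT_BIN_S,
) -> ProtocolResponses:
    """Build the extraction bundle from one spike train and the event logs.

    Spike times are seconds on each protocol's own clock; `protocols` maps
    protocol names to stimulus sets (or, for externally supplied data, to
    sets reconstructed from an event log).  The baseline rate is estimated
    from the stimulus-free background intervals and subtracted from every
    response measure.
    """
    spike_times = {k: np.asarray(v, dtype=float)
                   for k, v in spike_times.items()} if isinstance(spike_times, dict) \
        else {k: np.asarray(spike_times, dtype=float) for k in protocols}

    # baseline rate and its variability from background periods
    bg_counts, bg_total_t, bg_total_n = [], 0.0, 0
    for name, stim in protocols.items():
        t = spike_times[name]
        for a, b in stim.background_intervals():
            if b - a < SMOOTH_WINDOW_S:
                continue
            n = int((b - a) / SMOOTH_WINDOW_S)
            c, _ = np.histogram(t, bins=n, range=(a, a + n * SMOOTH_WINDOW_S))
            bg_counts.append(c)
            bg_total_t += n * SMOOTH_WINDOW_S
            bg_total_n += int(c.sum())
    if bg_total_t > 0:
        baseline_mean = bg_total_n / bg_total_t
        allc = np.concatenate(bg_counts) / SMOOTH_WINDOW_S
        baseline_sd = float(allc.std())
    else:
        baseline_mean, baseline_sd = 0.0, 0.0

    peaks: dict[str, float] = {}

    # --- marching square: maps + PSTHs
    ms = protocols["marching_square"]
    t = spike_times["marching_square"]
    n_bins = int(round(PSTH_WINDOW_S / bin_s))
    loc_index: dict[tuple[float, float], int] = {}
    on_counts = np.zeros(GRID_N * GRID_N)
    off_counts = np.zeros(GRID_N * GRID_N)
    reps = np.zeros(GRID_N * GRID_N)
    events_by_loc: dict[int, list[SquareFlashEvent]] = {}
    for ev in ms.events:
        key = (round(ev.center[0], 3), round(ev.center[1], 3))
        if key not in loc_index:
            loc_index[key] = len(loc_index)
        i = loc_index[key]
        on_counts[i] += np.count_nonzero((t >= ev.onset) & (t < ev.onset + PSTH_WINDOW_S))
        off_counts[i] += np.count_nonzero((t >= ev.offset) & (t < ev.offset + PSTH_WINDOW_S))
        reps[i] += 1
        events_by_loc.setdefault(i, []).append(ev)
    reps = np.maximum(reps, 1)
    base_per_window = baseline_mean * PSTH_WINDOW_S
    on_mean = np.clip(on_counts / reps - base_per_window, 0.0, None)
    off_mean = np.clip(off_counts / reps - base_per_window, 0.0, None)
    # map rows index x, columns y (location keys were laid out x-fastest)
    centers = np.array(list(loc_index.keys()))
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    side = int(round(np.sqrt(len(order))))
    on_map = on_mean[order].reshape(side, side)
    off_map = off_mean[order].reshape(side, side)
    map_origin = (float(centers[:, 0].min() - GRID_EXTENT_UM / GRID_N / 2),
                  float(centers[:, 1].min() - GRID_EXTENT_UM / GRID_N / 2))

    best = int(np.argmax(on_mean + off_mean))

    def _psth(anchor: str) -> PSTH:
        acc = np.zeros(n_bins)
        evs = events_by_loc.get(best, [])
        for ev in evs:
            t0 = ev.onset if anchor == "on" else ev.offset
            c, _ = np.histogram(t, bins=n_bins, range=(t0, t0 + PSTH_WINDOW_S))
            acc += c
        n_rep = max(1, len(evs))
        rates = np.clip(acc / n_rep / bin_s - baseline_mean, 0.0, None)
        return PSTH(rates, bin_width=bin_s, n_repetitions=n_rep)

    on_psth, off_psth = _psth("on"), _psth("off")
    on_count = max(0.0, float(on_counts[best] / reps[best]) - base_per_window)
    off_count = max(0.0, float(off_counts[best] / reps[best]) - base_per_window)
    peaks["marching_square"] = max(
        on_psth.smoothed().max() if on_psth.rates.size else 0.0,
        off_psth.smoothed().max() if off_psth.rates.size else 0.0,
    ) + baseline_mean

    # --- narrow bars: mean rate per traversal
    nb = protocols["narrow_bars"]
    t = spike_times["narrow_bars"]
    rows = []
    peak_nb = 0.0
    for ev in nb.events:
        dur = ev.offset - ev.onset
        n_sp = np.count_nonzero((t >= ev.onset) & (t < ev.offset))
        rate = max(0.0, n_sp / dur - baseline_mean)
        rows.append((ev.direction, ev.lateral_offset, ev.speed, rate))
        peak_nb = max(peak_nb, _smoothed_peak_rate(t, ev.onset, ev.offset, bin_s))
    bar_table = (pd.DataFrame(rows, columns=["direction", "lateral_offset",
                                             "speed", "mean_rate"])
                 .groupby(["direction", "lateral_offset", "speed"], as_index=False)
                 .mean())
    peaks["narrow_bars"] = peak_nb

    # --- width / speed tests: peak smoothed rate per bar
    def _bar_peaks(name: str) -> pd.DataFrame:
        stim = protocols[name]
        tt = spike_times[name]
        rows = []
        pk = 0.0
        for ev in stim.events:
            p = _smoothed_peak_rate(tt, ev.onset, ev.offset, bin_s)
            pk = max(pk, p)
            rows.append((ev.speed, ev.bar_width, ev.contrast, ev.direction,
                         max(0.0, p - baseline_mean)))
        peaks[name] = pk
        return pd.DataFrame(rows, columns=["speed", "width", "contrast",
                                           "direction", "peak_rate"])

    width_table = _bar_peaks("width_test")
    speed_table = _bar_peaks("speed_test")

    return ProtocolResponses(
        on_map=on_map, off_map=off_map, on_psth=on_psth, off_psth=off_psth,
        bar_table=bar_table, speed_table=speed_table, width_table=width_table,
        on_count=on_count, off_count=off_count,
        baseline_mean=baseline_mean, baseline_sd=baseline_sd,
        protocol_peaks=peaks, map_origin=map_origin)
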