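"""Synthetic retina: model ganglion-cell populations with known ground truth.

Each cell belongs to an *archetype* (ON/OFF/ON-OFF polarity, latency,
transience, direction/speed/width tuning, receptive-field size) and responds
to a stimulus protocol through a separable firing-rate model

    lambda(t) = baseline + peak * G_spatial * S(speed) * W(width) * D(theta)
                         * K(t - t_drive)

where ``G_spatial`` is the overlap of the stimulus footprint with an
isotropic Gaussian receptive field, ``S`` and ``W`` are log-Gaussian speed
and width tunings, ``D`` is a von-Mises-shaped direction gain (identically 1
for non-DS cells) and ``K`` is a unit-peak temporal kernel with a 50 ms
raised-cosine rise peaking at the cell's latency and an exponential decay
whose time constant is calibrated by root-finding so that the measured
transience index of the noiseless response equals the archetype's target.
ON cells are driven by positive-contrast transitions (square/bright-bar
appearance), OFF cells by negative-contrast transitions (square
disappearance, dark-bar arrival), ON-OFF cells by both.

Spike trains are drawn from the rate by inhomogeneous-Poisson thinning with
an optional absolute refractory period; multi-electrode voltage traces can
be rendered on a 17.5 um-pitch electrode block with additive noise for the
spike-sorting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from . import params as rp
from .stimuli import (
    FieldGeometry,
    GRID_N,
    GRID_EXTENT_UM,
    MovingBarEvent,
    StimulusSet,
    bar_crossing_time,
)

__all__ = [
    "ArchetypeSpec",
    "SyntheticCell",
    "RateFunction",
    "TraceBlock",
    "ElectrodeConfig",
    "default_archetypes",
    "sample_population",
    "drive",
    "spikes_from_rate",
    "render_traces",
    "noiseless_responses",
    "calibrate_decay",
    "vonmises_direction_gain",
    "vonmises_dsi",
    "kappa_for_dsi",
]

#: raised-cosine rise time of the temporal kernel (s)
RISE_S = 0.05
#: threshold contour fraction matched by the receptive-field SD convention
RF_CONTOUR_FRACTION = 0.33
#: SD = diameter / RF_SIGMA_DIVISOR makes the 33 %-of-max contour of the
#: noiseless Gaussian response profile have the nominal diameter
RF_SIGMA_DIVISOR = 2.0 * np.sqrt(2.0 * np.log(1.0 / RF_CONTOUR_FRACTION))

ELECTRODE_PITCH_UM = 17.5
TRACE_SAMPLE_RATE = 20_000.0
DEFAULT_NOISE_RMS_UV = 2.4


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative description of one functional cell type."""

    name: str
    polarity: str  # ON | OFF | ON_OFF
    latency_mean: float
    latency_sd: float
    transience_target: float
    is_ds: bool = False
    ds_concentration: float = 0.0
    preferred_direction: float | None = None  # degrees; None = per-cell uniform
    speed_pref: float = 600.0
    speed_bandwidth: float = 1.0  # SD of log-speed tuning (natural-log units)
    width_pref: float = 300.0
    width_bandwidth: float = 1.0
    rf_diameter_mean: float = 270.0
    rf_diameter_sd: float = 60.0
    peak_rate: float = 120.0
    baseline_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF", "ON_OFF"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not (0 < self.transience_target <= 1):
            raise ValueError("transience_target must lie in (0, 1]")
        if self.peak_rate <= self.baseline_rate or self.baseline_rate < 0:
            raise ValueError("need peak_rate > baseline_rate >= 0")
        if self.rf_diameter_mean <= 0:
            raise ValueError("rf_diameter_mean must be positive")


def default_archetypes() -> list[ArchetypeSpec]:
    """The seven default functional types.

    Brisk types have a 0.12 s latency, sluggish types 0.30 s; transient types
    target a transience of 0.2, sustained types 0.7.  The two DS types get a
    direction-tuning concentration giving a noiseless DS index of about 0.6,
    and opposite speed preferences (ON-OFF DS fast, ON DS slow).  Receptive
    fields are 270 +/- 60 um across.  These magnitudes are package defaults
    for simulation and recovery testing, not measured biological claims.
    """
    kappa = kappa_for_dsi(0.6)
    return [
        ArchetypeSpec("OFF brisk transient", "OFF", 0.12, 0.02, 0.2),
        ArchetypeSpec("OFF sluggish transient", "OFF", 0.30, 0.02, 0.2),
        ArchetypeSpec("ON-OFF brisk transient", "ON_OFF", 0.12, 0.02, 0.2),
        ArchetypeSpec("ON-OFF sluggish sustained", "ON_OFF", 0.30, 0.02, 0.7),
        ArchetypeSpec("ON-OFF DS", "ON_OFF", 0.12, 0.02, 0.3, is_ds=True,
                      ds_concentration=kappa, speed_pref=1200.0),
        ArchetypeSpec("ON brisk transient", "ON", 0.12, 0.02, 0.2),
        ArchetypeSpec("ON DS", "ON", 0.15, 0.02, 0.4, is_ds=True,
                      ds_concentration=kappa, speed_pref=300.0),
    ]


@dataclass(frozen=True)
class SyntheticCell:
    """One realised model cell (a draw from its archetype)."""

    cell_id: int
    archetype: str
    polarity: str
    rf_center: tuple[float, float]
    latency: float
    transience_target: float
    rf_diameter: float
    is_ds: bool
    ds_concentration: float
    preferred_direction: float
    speed_pref: float
    speed_bandwidth: float
    width_pref: float
    width_bandwidth: float
    peak_rate: float
    baseline_rate: float
    rng_seed: int

    @property
    def rf_sigma(self) -> float:
        return self.rf_diameter / RF_SIGMA_DIVISOR

    @property
    def decay_tau(self) -> float:
        return calibrate_decay(self.latency, self.transience_target)


# ---------------------------------------------------------------------------
# kernel calibration and tuning curves

def _kernel_area(latency: float, tau: float, window: float = rp.PSTH_WINDOW_S,
                 rise: float = RISE_S) -> float:
    """Area of the unit-peak kernel over [0, window] s after the drive."""
    if window <= latency - rise:
        return 0.0
    if window < latency:
        # partial raised-cosine rise: integral of 0.5(1 - cos(pi x / r))
        x = window - (latency - rise)
        return 0.5 * (x - (rise / np.pi) * np.sin(np.pi * x / rise))
    rise_area = rise / 2.0  # full raised-cosine rise integrates to rise/2
    decay_area = tau * (1.0 - np.exp(-(window - latency) / tau))
    return rise_area + decay_area


def calibrate_decay(latency: float, transience_target: float,
                    window: float = rp.PSTH_WINDOW_S, rise: float = RISE_S) -> float:
    """Decay constant tau such that the noiseless measured transience equals
    the target (root-finding on the closed-form kernel area)."""
    if latency < rise:
        raise ValueError(f"latency must be at least the rise time {rise} s")
    if latency >= window:
        raise ValueError("latency must fall inside the 1.5 s PSTH window")
    target_area = transience_target * window

    def f(tau: float) -> float:
        return _kernel_area(latency, tau, window, rise) - target_area

    lo, hi = 1e-6, 1e6
    if f(lo) > 0:
        raise ValueError("transience_target below the minimum reachable "
                         "with the fixed kernel rise time")
    if f(hi) < 0:
        raise ValueError(
            f"transience_target {transience_target} unreachable for latency "
            f"{latency}: even a sustained response cannot fill the window")
    return float(brentq(f, lo, hi, xtol=1e-10))


def temporal_kernel(t: np.ndarray, latency: float, tau: float,
                    rise: float = RISE_S) -> np.ndarray:
    """Unit-peak kernel: raised-cosine rise over [latency - rise, latency],
    exponential decay with constant tau afterwards."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    in_rise = (t >= latency - rise) & (t < latency)
    out[in_rise] = 0.5 * (1.0 - np.cos(np.pi * (t[in_rise] - latency + rise) / rise))
    in_decay = t >= latency
    out[in_decay] = np.exp(-(t[in_decay] - latency) / tau)
    return out


def vonmises_direction_gain(direction_deg, preferred_deg: float,
                            kappa: float) -> np.ndarray:
    """Unit-peak von-Mises direction gain exp(kappa (cos(dtheta) - 1))."""
    d = np.deg2rad(np.asarray(direction_deg, dtype=float) - preferred_deg)
    return np.exp(kappa * (np.cos(d) - 1.0))


def vonmises_dsi(kappa: float, n_directions: int = 8) -> float:
    """Closed-form DS index of the von-Mises gain sampled at n directions."""
    th = np.arange(n_directions) * 2 * np.pi / n_directions
    w = np.exp(kappa * (np.cos(th) - 1.0))
    return float(np.abs(np.sum(w * np.exp(1j * th))) / np.sum(w))


def kappa_for_dsi(dsi: float, n_directions: int = 8) -> float:
    """Concentration giving a prescribed noiseless DS index."""
    if not (0 <= dsi < 1):
        raise ValueError("dsi must lie in [0, 1)")
    if dsi == 0:
        return 0.0
    return float(brentq(lambda k: vonmises_dsi(k, n_directions) - dsi,
                        1e-9, 1e3, xtol=1e-12))


def log_gaussian_tuning(value, pref: float, bandwidth: float) -> np.ndarray:
    """Unit-peak log-Gaussian tuning curve."""
    x = np.log(np.asarray(value, dtype=float) / pref)
    return np.exp(-(x**2) / (2.0 * bandwidth**2))


# ---------------------------------------------------------------------------
# spatial gains

def _gauss_mass_1d(lo, hi, mu: float, sigma: float) -> np.ndarray:
    return ndtr((np.asarray(hi) - mu) / sigma) - ndtr((np.asarray(lo) - mu) / sigma)


def square_overlap_gain(cell: SyntheticCell, center: Sequence[float],
                        side: float) -> float:
    """Gaussian receptive-field mass under a flashed square."""
    cx, cy = center
    x0, y0 = cell.rf_center
    s = cell.rf_sigma
    gx = _gauss_mass_1d(cx - side / 2, cx + side / 2, x0, s)
    gy = _gauss_mass_1d(cy - side / 2, cy + side / 2, y0, s)
    return float(gx * gy)


def bar_lateral_gain(cell: SyntheticCell, event: MovingBarEvent) -> float:
    """Receptive-field mass within the bar's lateral span as it crosses."""
    th = np.deg2rad(event.direction)
    n = np.array([-np.sin(th), np.cos(th)])
    rel = np.asarray(cell.rf_center) - event.field.center
    lateral = float(rel @ n) - event.lateral_offset
    return float(_gauss_mass_1d(-event.bar_length / 2, event.bar_length / 2,
                                lateral, cell.rf_sigma))


def _drives_on(cell_polarity: str, contrast: float) -> tuple[bool, bool]:
    """Whether (onset-like, offset-like) transitions drive this polarity."""
    on_like = contrast > 0
    drive_now = (cell_polarity in ("ON", "ON_OFF")) if on_like else \
                (cell_polarity in ("OFF", "ON_OFF"))
    return drive_now, on_like


def _bar_drive_times(cell: SyntheticCell, event: MovingBarEvent) -> list[float]:
    """Drive times as a bar crosses the receptive-field centre.

    The leading edge of a bright bar is a luminance increment (drives ON and
    ON-OFF cells), its trailing edge a decrement (drives OFF and ON-OFF
    cells); a dark bar is the mirror case.
    """
    try:
        t_lead = bar_crossing_time(event, cell.rf_center)
    except ValueError:
        return []
    t_trail = t_lead + event.bar_width / event.speed
    bright = event.contrast > 0
    out = []
    if cell.polarity in ("ON", "ON_OFF"):
        out.append(t_lead if bright else t_trail)
    if cell.polarity in ("OFF", "ON_OFF"):
        out.append(t_trail if bright else t_lead)
    return sorted(out)


# ---------------------------------------------------------------------------
# population sampling

def sample_population(
    archetypes: Sequence[ArchetypeSpec],
    n_per_archetype: int,
    field: FieldGeometry | None = None,
    seed: int = 0,
    margin: float = 0.0,
) -> list[SyntheticCell]:
    """Draw a population with receptive-field centres uniform over the field.

    `margin` keeps centres at least that far from the field border, e.g. so
    mapped receptive fields stay inside the marching-square grid.
    """
    if not archetypes:
        raise ValueError("archetype list must not be empty")
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be >= 1")
    field = field or FieldGeometry()
    rng = np.random.default_rng(seed)
    cells: list[SyntheticCell] = []
    cid = 0
    for arch in archetypes:
        for _ in range(n_per_archetype):
            x = rng.uniform(field.origin[0] + margin,
                            field.origin[0] + field.width - margin)
            y = rng.uniform(field.origin[1] + margin,
                            field.origin[1] + field.height - margin)
            lat = float(np.clip(rng.normal(arch.latency_mean, arch.latency_sd),
                                RISE_S + 0.01, rp.PSTH_WINDOW_S - 0.2))
            dia = float(np.clip(rng.normal(arch.rf_diameter_mean,
                                           arch.rf_diameter_sd), 80.0, None))
            pref = (arch.preferred_direction if arch.preferred_direction is not None
                    else float(rng.uniform(0.0, 360.0)))
            cells.append(SyntheticCell(
                cell_id=cid, archetype=arch.name, polarity=arch.polarity,
                rf_center=(float(x), float(y)), latency=lat,
                transience_target=arch.transience_target,
                rf_diameter=dia, is_ds=arch.is_ds,
                ds_concentration=arch.ds_concentration if arch.is_ds else 0.0,
                preferred_direction=pref, speed_pref=arch.speed_pref,
                speed_bandwidth=arch.speed_bandwidth, width_pref=arch.width_pref,
                width_bandwidth=arch.width_bandwidth, peak_rate=arch.peak_rate,
                baseline_rate=arch.baseline_rate,
                rng_seed=int(rng.integers(0, 2**31 - 1))))
            cid += 1
    return cells


def scatter_cells_on_block(config: "ElectrodeConfig", n: int, seed: int = 0,
                           min_spacing: float = 30.0,
                           archetype: ArchetypeSpec | None = None,
                           ) -> list[SyntheticCell]:
    """Place `n` cells over an electrode block with a soma-scale minimum
    spacing (somata do not overlap), for sorting and activity-scan work."""
    config = config or ElectrodeConfig()
    arch = archetype or default_archetypes()[0]
    pos = config.positions
    lo, hi = pos.min(axis=0) - 10.0, pos.max(axis=0) + 10.0
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= min_spacing for q in placed):
            placed.append(p)
        attempts += 1
        if attempts > 10000 * n:
            raise ValueError(f"cannot place {n} cells with spacing "
                             f"{min_spacing} um on this block")
    field = FieldGeometry(width=float(hi[0] - lo[0] + 20),
                          height=float(hi[1] - lo[1] + 20),
                          origin=(float(lo[0] - 10), float(lo[1] - 10)))
    base = sample_population([arch], n, field, seed)
    return [replace(c, rf_center=(float(p[0]), float(p[1])))
            for c, p in zip(base, placed)]


def population_to_frame(cells: Sequence[SyntheticCell]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) if not hasattr(c, "__dataclass_fields__")
                         else {f: getattr(c, f) for f in c.__dataclass_fields__}
                         for c in cells])


# ---------------------------------------------------------------------------
# rate model

@dataclass
class RateFunction:
    """Piecewise firing rate: baseline plus a sum of driven kernel transients.

    Each drive is (time, amplitude, latency, tau); the kernel is evaluated
    lazily so long protocols stay cheap.
    """

    baseline: float
    drives: list[tuple[float, float, float, float]]
    duration: float
    rise: float = RISE_S

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, self.baseline)
        for t0, amp, lat, tau in self.drives:
            span = lat + tau * np.log(1e4)  # truncate below 1e-4 of peak
            sel = (t >= t0) & (t <= t0 + span)
            if np.any(sel):
                out[sel] += amp * temporal_kernel(t[sel] - t0, lat, tau, self.rise)
        return out

    def max_rate(self, grid_dt: float = 0.001) -> float:
        """Upper bound on the rate (grid max with a safety margin; the kernel
        rise/decay scales are far longer than the grid step)."""
        if not self.drives:
            return self.baseline
        grid = np.arange(0.0, self.duration, grid_dt)
        return float(self(grid).max()) * 1.05 + 1e-9


def drive(cell: SyntheticCell, stimulus: StimulusSet) -> RateFunction:
    """Firing-rate response of one cell to one protocol run."""
    tau = cell.decay_tau
    drives: list[tuple[float, float, float, float]] = []
    for ev in stimulus.events:
        if ev.kind == "square":
            g = cell.peak_rate * square_overlap_gain(cell, ev.center, ev.side)
            if g <= 0:
                continue
            on_driven, _ = _drives_on(cell.polarity, ev.contrast)
            off_driven, _ = _drives_on(cell.polarity, -ev.contrast)
            if on_driven:
                drives.append((ev.onset, g, cell.latency, tau))
            if off_driven:
                drives.append((ev.offset, g, cell.latency, tau))
        else:
            times = _bar_drive_times(cell, ev)
            if not times:
                continue
            amp = _bar_amplitude(cell, ev)
            if amp > 0:
                for t_d in times:
                    drives.append((float(t_d), float(amp), cell.latency, tau))
    return RateFunction(cell.baseline_rate, drives, stimulus.total_duration)


def _bar_amplitude(cell: SyntheticCell, ev: MovingBarEvent) -> float:
    """Separable response amplitude of one bar sweep (Hz above baseline)."""
    return float(
        cell.peak_rate
        * bar_lateral_gain(cell, ev)
        * log_gaussian_tuning(ev.speed, cell.speed_pref, cell.speed_bandwidth)
        * log_gaussian_tuning(ev.bar_width, cell.width_pref,
                              cell.width_bandwidth)
        * (vonmises_direction_gain(ev.direction, cell.preferred_direction,
                                   cell.ds_concentration)
           if cell.is_ds else 1.0))


def spikes_from_rate(rate: RateFunction, seed: int = 0,
                     refractory: float = 0.002) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning, with an optional
    absolute refractory period applied by post-hoc deletion."""
    rng = np.random.default_rng(seed)
    lam_max = rate.max_rate()
    if lam_max <= 0:
        return np.array([])
    n_cand = rng.poisson(lam_max * rate.duration)
    cand = np.sort(rng.uniform(0.0, rate.duration, n_cand))
    keep = rng.uniform(0.0, 1.0, n_cand) < rate(cand) / lam_max
    times = cand[keep]
    if refractory > 0 and len(times) > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.asarray(kept)
    return times


# ---------------------------------------------------------------------------
# analytic (noiseless) responses

def noiseless_responses(cell: SyntheticCell,
                        protocols: dict[str, StimulusSet]) -> rp.ProtocolResponses:
    """Exact response aggregates of the rate model, bypassing spiking noise.

    Every aggregate is the baseline-subtracted idealised response to each
    event in isolation (no cross-event kernel bleed), which is what the
    extractor round-trip contract is defined against.
    """
    tau = cell.decay_tau
    kernel_area = _kernel_area(cell.latency, tau)
    peaks: dict[str, float] = {}

    # marching square: maps + PSTH at the best location
    ms = protocols["marching_square"]
    arr = np.array(sorted({(round(ev.center[0], 3), round(ev.center[1], 3))
                           for ev in ms.events}))
    xs, ys = np.unique(arr[:, 0]), np.unique(arr[:, 1])
    side_len = ms.events[0].side
    s = cell.rf_sigma
    # separable Gaussian-square overlap: outer product of 1-D masses
    gx = _gauss_mass_1d(xs - side_len / 2, xs + side_len / 2, cell.rf_center[0], s)
    gy = _gauss_mass_1d(ys - side_len / 2, ys + side_len / 2, cell.rf_center[1], s)
    amp_map = cell.peak_rate * np.outer(gx, gy)  # rows index x, cols y
    on_gate = cell.polarity in ("ON", "ON_OFF")
    off_gate = cell.polarity in ("OFF", "ON_OFF")
    on_map = amp_map * kernel_area * (1.0 if on_gate else 0.0)
    off_map = amp_map * kernel_area * (1.0 if off_gate else 0.0)
    amp = amp_map.ravel()
    map_origin = (float(xs.min() - GRID_EXTENT_UM / GRID_N / 2),
                  float(ys.min() - GRID_EXTENT_UM / GRID_N / 2))

    n_bins = int(round(rp.PSTH_WINDOW_S / rp.DEFAULT_BIN_S))
    t_bins = (np.arange(n_bins) + 0.5) * rp.DEFAULT_BIN_S
    best_amp = float(amp.max())
    k = temporal_kernel(t_bins, cell.latency, tau)
    on_psth = rp.PSTH(best_amp * k * (1.0 if on_gate else 0.0))
    off_psth = rp.PSTH(best_amp * k * (1.0 if off_gate else 0.0))
    peaks["marching_square"] = best_amp + cell.baseline_rate

    # narrow bars: mean rate per traversal
    rows = []
    pk = 0.0
    for ev in protocols["narrow_bars"].events:
        rate = 0.0
        times = _bar_drive_times(cell, ev)
        if times:
            a = _bar_amplitude(cell, ev)
            dur = ev.offset - ev.onset
            # kernel area available between each drive and end of traversal
            rate = a * sum(_kernel_area(cell.latency, tau,
                                        window=ev.offset - t_d)
                           for t_d in times) / dur
            pk = max(pk, a + cell.baseline_rate)
        rows.append((ev.direction, ev.lateral_offset, ev.speed, float(rate)))
    bar_table = (pd.DataFrame(rows, columns=["direction", "lateral_offset",
                                             "speed", "mean_rate"])
                 .groupby(["direction", "lateral_offset", "speed"],
                          as_index=False).mean())
    peaks["narrow_bars"] = pk

    def _bar_peak_table(name: str) -> pd.DataFrame:
        rows = []
        pk = 0.0
        for ev in protocols[name].events:
            peak = 0.0
            if _bar_drive_times(cell, ev):
                peak = _bar_amplitude(cell, ev)
                pk = max(pk, peak + cell.baseline_rate)
            rows.append((ev.speed, ev.bar_width, ev.contrast, ev.direction,
                         float(peak)))
        peaks[name] = pk
        return pd.DataFrame(rows, columns=["speed", "width", "contrast",
                                           "direction", "peak_rate"])

    width_table = _bar_peak_table("width_test")
    speed_table = _bar_peak_table("speed_test")

    return rp.ProtocolResponses(
        on_map=on_map, off_map=off_map, on_psth=on_psth, off_psth=off_psth,
        bar_table=bar_table, speed_table=speed_table, width_table=width_table,
        on_count=float(amp.max() * kernel_area * (1.0 if on_gate else 0.0)),
        off_count=float(amp.max() * kernel_area * (1.0 if off_gate else 0.0)),
        baseline_mean=cell.baseline_rate, baseline_sd=0.0,
        protocol_peaks=peaks, map_origin=map_origin)


# ---------------------------------------------------------------------------
# extracellular trace rendering

@dataclass(frozen=True)
class ElectrodeConfig:
    """A contiguous rectangular electrode block on the 17.5 um-pitch grid."""

    rows: int = 6
    cols: int = 21
    origin: tuple[float, float] = (300.0, 450.0)
    pitch: float = ELECTRODE_PITCH_UM

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) electrode positions in um, row-major (row*cols + col)."""
        jj, ii = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        x = self.origin[0] + jj.ravel() * self.pitch
        y = self.origin[1] + ii.ravel() * self.pitch
        return np.column_stack([x, y]).astype(float)


@dataclass
class TraceBlock:
    """Multi-electrode voltage traces with embedded ground truth."""

    samples: np.ndarray  # (n_electrodes, n_samples) uV
    sample_rate: float
    config: ElectrodeConfig
    ground_truth: dict = dc_field(default_factory=dict)  # cell_id -> spike times
    footprints: dict = dc_field(default_factory=dict)  # cell_id -> per-electrode amp

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate


def spike_waveform(sample_rate: float = TRACE_SAMPLE_RATE,
                   pre_s: float = 0.0005, post_s: float = 0.001,
                   trough_sd: float = 1.2e-4, peak_delay: float = 3.5e-4,
                   peak_sd: float = 2.0e-4, peak_ratio: float = 0.35,
                   ) -> np.ndarray:
    """Unit peak-to-peak biphasic extracellular waveform (negative-leading).

    The trough width, repolarisation-peak delay/width and peak-to-trough
    ratio parameterise the cell-to-cell shape differences seen in real
    extracellular action potentials."""
    t = np.arange(-round(pre_s * sample_rate),
                  round(post_s * sample_rate) + 1) / sample_rate
    w = (-np.exp(-(t / trough_sd) ** 2)
         + peak_ratio * np.exp(-((t - peak_delay) / peak_sd) ** 2))
    return w / np.ptp(w)


def render_traces(
    cells: Sequence[SyntheticCell],
    trains: Sequence[np.ndarray],
    config: ElectrodeConfig | None = None,
    duration: float | None = None,
    noise_rms: float = DEFAULT_NOISE_RMS_UV,
    seed: int = 0,
    amplitude_range: tuple[float, float] = (50.0, 300.0),
    decay_length: float = 25.0,
    shape_variation: bool = True,
) -> TraceBlock:
    """Render extracellular traces: one biphasic template per cell with
    exponential spatial decay around its soma, plus additive white noise.

    The soma (footprint centre) is placed at the cell's receptive-field
    centre; cells outside the block contribute only weakly through the decay.
    With `shape_variation` each cell draws its own waveform shape (trough
    width, repolarisation peak), as real cells do; turning it off gives
    every cell the identical canonical waveform.
    """
    config = config or ElectrodeConfig()
    if len(cells) != len(trains):
        raise ValueError("need one spike train per cell")
    if duration is None:
        duration = max((float(t[-1]) for t in trains if len(t)), default=1.0) + 0.01
    n_samp = int(round(duration * TRACE_SAMPLE_RATE))
    rng = np.random.default_rng(seed)
    traces = rng.normal(0.0, noise_rms, (config.n_electrodes, n_samp)).astype(np.float32)

    pre = round(0.0005 * TRACE_SAMPLE_RATE)
    pos = config.positions
    ground_truth, footprints = {}, {}
    for cell, times in zip(cells, trains):
        if shape_variation:
            wf = spike_waveform(trough_sd=rng.uniform(0.9e-4, 1.6e-4),
                                peak_delay=rng.uniform(3.0e-4, 4.5e-4),
                                peak_sd=rng.uniform(1.6e-4, 2.6e-4),
                                peak_ratio=rng.uniform(0.25, 0.45))
        else:
            wf = spike_waveform()
        amp = rng.uniform(*amplitude_range)
        dist = np.linalg.norm(pos - np.asarray(cell.rf_center), axis=1)
        foot = (amp * np.exp(-dist / decay_length)).astype(np.float32)
        active = np.flatnonzero(foot > 0.5)  # skip sub-noise contributions
        times = np.asarray(times, dtype=float)
        times = times[(times > 0.001) & (times < duration - 0.0015)]
        idx = np.round(times * TRACE_SAMPLE_RATE).astype(int)
        if len(idx) == 0 or len(active) == 0:
            ground_truth[cell.cell_id] = times
            footprints[cell.cell_id] = foot
            continue
        # windows of one cell never overlap (refractory period > window)
        cols = idx[:, None] - pre + np.arange(len(wf))[None, :]
        for e in active:
            traces[e, cols.ravel()] += np.broadcast_to(
                (wf * foot[e]).astype(np.float32), cols.shape).ravel()
        ground_truth[cell.cell_id] = times
        footprints[cell.cell_id] = foot
    return TraceBlock(traces, TRACE_SAMPLE_RATE, config,
                      ground_truth=ground_truth, footprints=footprints)
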