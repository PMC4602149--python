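"""End-to-end orchestration: simulate, extract, cluster, report.

One :class:`RunConfig` carries the root seed and every tunable threshold;
per-stage seeds are spawned deterministically from the root seed so a run is
bit-reproducible from its manifest.  The sorting stage, when enabled, runs
on a dedicated synthetic validation block (rendering full-protocol voltage
traces is far beyond desk scale); response parameters are extracted from the
simulator's spike trains (or, in noiseless mode, from the analytic
responses).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .celltypes import (
    group_characteristics,
    normalize,
    separation_matrix,
    sweep_k,
)
from .io import save_population_h5, save_traces_h5, write_table
from .params import (
    compute_cell_parameters,
    parameters_to_frame,
    responses_from_spikes,
    responsiveness_filter,
)
from .sorting import sort_traces, units_to_qc_frame
from .stimuli import (
    FieldGeometry,
    make_marching_square,
    make_narrow_bars,
    make_speed_test,
    make_width_test,
    write_event_log,
)
from .synthetic import (
    default_archetypes,
    drive,
    noiseless_responses,
    render_traces,
    sample_population,
    spikes_from_rate,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_protocols"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    seed: int = 0
    out_dir: str = "run_output"
    n_per_archetype: int = 10
    field_margin: float = 150.0
    noiseless: bool = True  # analytic responses instead of Poisson spiking
    sort_stage: bool = False
    sort_duration_s: float = 30.0
    sort_rate_hz: float = 8.0
    # stimulus settings
    square_gap_s: float = 2.0
    bar_gap_s: float = 0.5
    # extraction
    psth_bin_s: float = 0.005
    # sorting thresholds
    detect_k_sd: float = 3.5
    match_threshold: float = 0.6
    merge_r_threshold: float = 0.9
    refractory_s: float = 0.002
    # clustering
    k_min: int = 4
    k_max: int = 25
    restarts: int = 5000

    def validate(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError(f"invalid k range [{self.k_min}, {self.k_max}]")
        if self.n_per_archetype < 1:
            raise ValueError("n_per_archetype must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    artifacts: dict = dc_field(default_factory=dict)  # name -> sha256
    timings_s: dict = dc_field(default_factory=dict)
    summary: dict = dc_field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_protocols(seeds: dict[str, int], field: FieldGeometry | None = None,
                   square_gap: float = 2.0, bar_gap: float = 0.5) -> dict:
    field = field or FieldGeometry()
    return {
        "marching_square": make_marching_square(field, seeds["marching_square"],
                                                gap=square_gap),
        "narrow_bars": make_narrow_bars(field, seed=seeds["narrow_bars"],
                                        gap=bar_gap),
        "width_test": make_width_test(field, seeds["width_test"], gap=bar_gap),
        "speed_test": make_speed_test(field, seeds["speed_test"], gap=bar_gap),
    }


def _stage_seeds(root: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root)
    names = ["marching_square", "narrow_bars", "width_test", "speed_test",
             "population", "spiking", "sorting", "clustering"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate -> (optional sort validation) -> extract -> cluster.

    Artifacts (event log, population archive, parameter and cluster tables,
    QC report) are written under ``config.out_dir``; the manifest records
    the config snapshot, spawned seeds, artifact checksums and timings.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(config=asdict(config), version=__version__,
                           seeds=seeds)
    field = FieldGeometry()

    def _record(name: str, path: Path) -> None:
        manifest.artifacts[name] = _sha256(path)

    t0 = time.perf_counter()
    protocols = make_protocols(seeds, field, config.square_gap_s, config.bar_gap_s)
    ev_path = out / "stimulus_events.tsv"
    write_event_log(protocols.values(), ev_path)
    _record("stimulus_events", ev_path)
    manifest.timings_s["stimuli"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cells = sample_population(default_archetypes(), config.n_per_archetype,
                              field, seeds["population"],
                              margin=config.field_margin)
    spikes: dict[str, dict[int, np.ndarray]] = {}
    vectors = []
    spike_rng = np.random.default_rng(seeds["spiking"])
    for cell in cells:
        if config.noiseless:
            resp = noiseless_responses(cell, protocols)
        else:
            trains = {}
            for name, stim in protocols.items():
                rate = drive(cell, stim)
                trains[name] = spikes_from_rate(
                    rate, seed=int(spike_rng.integers(2**31 - 1)),
                    refractory=config.refractory_s)
                spikes.setdefault(name, {})[cell.cell_id] = trains[name]
            resp = responses_from_spikes(trains, protocols,
                                         bin_s=config.psth_bin_s)
        vectors.append(compute_cell_parameters(resp, cell.cell_id, field,
                                               archetype=cell.archetype))
    pop_path = out / "population.h5"
    save_population_h5(pop_path, cells, spikes if spikes else None)
    _record("population", pop_path)
    params_frame = parameters_to_frame(vectors)
    par_path = out / "parameters.csv"
    write_table(params_frame, par_path)
    _record("parameters", par_path)
    manifest.timings_s["simulate_extract"] = time.perf_counter() - t0

    if config.sort_stage:
        t0 = time.perf_counter()
        from .synthetic import ElectrodeConfig, scatter_cells_on_block
        sort_cells = scatter_cells_on_block(ElectrodeConfig(),
                                            max(10, len(cells) // 4),
                                            seed=seeds["sorting"])
        rng = np.random.default_rng(seeds["sorting"])
        trains = [np.sort(rng.uniform(0, config.sort_duration_s,
                                      rng.poisson(config.sort_rate_hz
                                                  * config.sort_duration_s)))
                  for _ in sort_cells]
        block = render_traces(sort_cells, trains,
                              duration=config.sort_duration_s,
                              seed=seeds["sorting"])
        tr_path = out / "sort_validation_traces.h5"
        save_traces_h5(tr_path, block)
        _record("sort_traces", tr_path)
        units = sort_traces(block, k_sd=config.detect_k_sd,
                            match_threshold=config.match_threshold,
                            seed=seeds["sorting"],
                            refractory=config.refractory_s)
        qc_path = out / "sorting_qc.csv"
        write_table(units_to_qc_frame(units), qc_path)
        _record("sorting_qc", qc_path)
        manifest.summary["n_sorted_units"] = len(units)
        manifest.timings_s["sorting"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    kept, discarded = responsiveness_filter(vectors)
    manifest.summary["n_cells"] = len(vectors)
    manifest.summary["n_responsive"] = len(kept)
    matrix = normalize(kept)
    model = sweep_k(matrix, range(config.k_min, config.k_max + 1),
                    restarts=config.restarts, seed=seeds["clustering"])
    kept_frame = parameters_to_frame(kept)
    chars = group_characteristics(kept_frame, model.labels)
    label_map = dict(zip(chars["cluster"], chars["suggested_label"]))
    assign = kept_frame[["cell_id"]].copy()
    assign["cluster"] = model.labels
    assign["suggested_label"] = [label_map[c] for c in model.labels]
    cl_path = out / "clusters.csv"
    write_table(assign, cl_path)
    _record("clusters", cl_path)
    sep = separation_matrix(matrix, model.labels)
    sep_path = out / "separation_matrix.csv"
    sep.to_csv(sep_path, float_format="%.17g")
    _record("separation_matrix", sep_path)
    sil_path = out / "silhouette_by_k.csv"
    with open(sil_path, "w") as f:
        f.write("k,mean_silhouette\n")
        for k, s in sorted(model.silhouette_by_k.items()):
            f.write(f"{k},{s:.17g}\n")
    _record("silhouette_by_k", sil_path)
    chars_path = out / "group_characteristics.csv"
    write_table(chars, chars_path)
    _record("group_characteristics", chars_path)
    manifest.summary.update(
        selected_k=model.k, mean_silhouette=model.mean_silhouette,
        n_discarded=len(discarded),
        min_separation=float(np.min(sep.values[np.triu_indices(len(sep), 1)]))
        if len(sep) > 1 else float("nan"))
    manifest.timings_s["clustering"] = time.perf_counter() - t0

    manifest.save(out / "manifest.json")
    return manifest
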