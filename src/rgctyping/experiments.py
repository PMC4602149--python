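"""Benchmark experiments on synthetic ground truth.

Two standing experiments validate the pipeline end to end:

* :func:`select_k_once` — generate a population from the default archetype
  table, extract the five clustered parameters from noiseless responses, and
  report the silhouette-selected cluster count (the population analogue of
  finding the number of functional types in a recording);
* :func:`spike_sorting_benchmark` — render a multi-electrode block from
  cells with known spike trains, run the full sorting chain, and score
  per-cell spike-time recall and precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .celltypes import ClusterModel, normalize, sweep_k
from .params import compute_cell_parameters, responsiveness_filter
from .pipeline import make_protocols
from .sorting import sort_traces
from .stimuli import FieldGeometry
from .synthetic import (
    ElectrodeConfig,
    default_archetypes,
    noiseless_responses,
    render_traces,
    sample_population,
    scatter_cells_on_block,
)

__all__ = ["select_k_once", "archetype_parameter_table",
           "spike_sorting_benchmark", "SortingScore"]


def archetype_parameter_table(seed: int, n_per_archetype: int = 40,
                              margin: float = 150.0):
    """Sample a population and extract parameters from noiseless responses.

    Returns (cells, kept parameter vectors after the responsiveness filter).
    """
    field = FieldGeometry()
    rng = np.random.default_rng(seed)
    proto_seeds = {name: int(rng.integers(2**31 - 1))
                   for name in ("marching_square", "narrow_bars",
                                "width_test", "speed_test")}
    protocols = make_protocols(proto_seeds, field)
    cells = sample_population(default_archetypes(), n_per_archetype, field,
                              seed=int(rng.integers(2**31 - 1)), margin=margin)
    vectors = [compute_cell_parameters(noiseless_responses(c, protocols),
                                       c.cell_id, field, archetype=c.archetype)
               for c in cells]
    kept, _ = responsiveness_filter(vectors)
    return cells, kept


def select_k_once(seed: int, n_per_archetype: int = 40, restarts: int = 200,
                  k_range=range(4, 26)) -> ClusterModel:
    """One cluster-count selection run on a fresh synthetic population."""
    _, kept = archetype_parameter_table(seed, n_per_archetype)
    matrix = normalize(kept)
    return sweep_k(matrix, k_range, restarts=restarts,
                   seed=int(np.random.default_rng(seed + 1).integers(2**31 - 1)))


def cluster_purity(kept, labels: np.ndarray) -> float:
    """Majority-archetype purity of a cluster assignment."""
    arch = np.array([v.archetype for v in kept])
    correct = 0
    for c in np.unique(labels):
        members = arch[labels == c]
        _, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / len(arch)


@dataclass
class SortingScore:
    n_cells: int
    n_units: int
    per_cell_recall: dict
    per_cell_precision: dict
    per_cell_units: dict
    max_violation: float

    @property
    def min_recall(self) -> float:
        return min(self.per_cell_recall.values())

    @property
    def min_precision(self) -> float:
        return min(self.per_cell_precision.values())


def spike_sorting_benchmark(seed: int, n_cells: int = 12,
                            duration: float = 60.0, rate_hz: float = 8.0,
                            config: ElectrodeConfig | None = None,
                            tolerance: float = 0.0005,
                            min_spikes: int = 100) -> SortingScore:
    """Render a synthetic block and score the full sorting chain.

    Cells fire homogeneous-Poisson trains with a 2 ms refractory period;
    recall/precision count matched spikes within `tolerance` seconds.  Only
    ground-truth cells with at least `min_spikes` spikes are scored.
    """
    config = config or ElectrodeConfig()
    cells = scatter_cells_on_block(config, n_cells, seed=seed)
    rng = np.random.default_rng(seed + 1)
    trains = []
    for _ in cells:
        t = np.sort(rng.uniform(0.0, duration, rng.poisson(rate_hz * duration)))
        keep = np.insert(np.diff(t) >= 0.002, 0, True)
        trains.append(t[keep])
    block = render_traces(cells, trains, config, duration=duration,
                          seed=seed + 2)
    units = sort_traces(block, seed=seed + 3)

    recall: dict[int, float] = {}
    precision: dict[int, float] = {}
    unit_count: dict[int, int] = {}
    max_viol = max((u.refractory_violation_fraction for u in units), default=0.0)
    assigned: dict[int, int] = {}
    for u in units:
        best_cell, best_hits = None, -1
        for cid, gt in block.ground_truth.items():
            if len(gt) == 0 or len(u.spike_times) == 0:
                continue
            hits = int(np.sum(np.min(np.abs(u.spike_times[:, None] - gt[None, :]),
                                     axis=1) < tolerance))
            if hits > best_hits:
                best_cell, best_hits = cid, hits
        if best_cell is not None:
            assigned[u.unit_id] = best_cell
    for cid, gt in block.ground_truth.items():
        if len(gt) < min_spikes:
            continue
        my_units = [u for u in units if assigned.get(u.unit_id) == cid]
        unit_count[cid] = len(my_units)
        if not my_units:
            recall[cid] = precision[cid] = 0.0
            continue
        u = max(my_units, key=lambda u: len(u.spike_times))
        d_gt = np.min(np.abs(gt[:, None] - u.spike_times[None, :]), axis=1)
        d_unit = np.min(np.abs(u.spike_times[:, None] - gt[None, :]), axis=1)
        recall[cid] = float(np.mean(d_gt < tolerance))
        precision[cid] = float(np.mean(d_unit < tolerance))
    return SortingScore(n_cells=len(cells), n_units=len(units),
                        per_cell_recall=recall, per_cell_precision=precision,
                        per_cell_units=unit_count, max_violation=max_viol)
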