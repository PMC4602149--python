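"""Activity scan: choosing the most active electrode configuration.

Before an experiment, candidate 126-electrode blocks are recorded briefly
under an arbitrary spike-bearing stimulus; per-electrode maps of the maximum
spike peak-to-peak amplitude are computed, and the block with the greatest
number of local amplitude maxima (putative ganglion-cell somata) is chosen
for the session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .sorting import bandpass, detect
from .synthetic import TraceBlock

__all__ = [
    "AmplitudeMap",
    "amplitude_map",
    "count_local_maxima",
    "select_configuration",
    "scan_report",
]

DEFAULT_MIN_AMPLITUDE_UV = 30.0


@dataclass
class AmplitudeMap:
    """Maximum spike peak-to-peak amplitude per electrode of one block."""

    amplitudes: np.ndarray  # (rows, cols) uV
    configuration_id: int = 0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def total(self) -> float:
        return float(self.amplitudes.sum())


def amplitude_map(block: TraceBlock, configuration_id: int = 0,
                  k_sd: float = 3.5, prefiltered: bool = False) -> AmplitudeMap:
    """Per-electrode maximum peak-to-peak amplitude over detected spikes;
    electrodes without detections map to zero."""
    filtered = block if prefiltered else bandpass(block)
    amps = np.zeros(filtered.samples.shape[0])
    for d in detect(filtered, k_sd=k_sd):
        amps[d.peak_electrode] = max(amps[d.peak_electrode], d.peak_to_peak)
    shape = (block.config.rows, block.config.cols)
    return AmplitudeMap(amps.reshape(shape), configuration_id)


def count_local_maxima(amap: AmplitudeMap,
                       min_amplitude: float = DEFAULT_MIN_AMPLITUDE_UV) -> int:
    """Electrodes above `min_amplitude` that strictly exceed all of their
    8-neighbours."""
    if min_amplitude < 0:
        raise ValueError("min_amplitude must be >= 0")
    a = amap.amplitudes
    # strict 8-neighbourhood maximum: larger than the max of the neighbours
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_only = ndimage.maximum_filter(a, footprint=footprint,
                                        mode="constant", cval=-np.inf)
    is_max = (a > neigh_only) & (a > min_amplitude)
    return int(np.count_nonzero(is_max))


def select_configuration(maps: Sequence[AmplitudeMap],
                         min_amplitude: float = DEFAULT_MIN_AMPLITUDE_UV,
                         ) -> tuple[int, pd.DataFrame]:
    """Pick the configuration with the most local maxima.

    Ties break by larger summed amplitude, then by lowest configuration id.
    Returns the winning configuration id and the full report table.
    """
    if not maps:
        raise ValueError("need at least one amplitude map")
    report = scan_report(maps, min_amplitude)
    best = report.sort_values(
        ["n_local_maxima", "sum_amplitude", "configuration_id"],
        ascending=[False, False, True]).iloc[0]
    if best["n_local_maxima"] == 0:
        import warnings
        warnings.warn("no local maxima in any configuration; "
                      "falling back to the first block", stacklevel=2)
    return int(best["configuration_id"]), report


def scan_report(maps: Sequence[AmplitudeMap],
                min_amplitude: float = DEFAULT_MIN_AMPLITUDE_UV) -> pd.DataFrame:
    rows = [{
        "configuration_id": m.configuration_id,
        "n_local_maxima": count_local_maxima(m, min_amplitude),
        "sum_amplitude": m.total,
    } for m in maps]
    df = pd.DataFrame(rows)
    winner = df.sort_values(
        ["n_local_maxima", "sum_amplitude", "configuration_id"],
        ascending=[False, False, True]).iloc[0]["configuration_id"]
    df["selected"] = df["configuration_id"] == winner
    return df
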