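"""File-format plumbing: HDF5 population/trace archives and CSV tables.

All artifacts round-trip exactly: writing then reading reproduces the
in-memory object, floats at full precision.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .synthetic import ElectrodeConfig, SyntheticCell, TraceBlock

__all__ = [
    "save_population_h5",
    "load_population_h5",
    "save_traces_h5",
    "load_traces_h5",
    "write_table",
    "read_table",
]

TRACE_SCALE_UV = 0.01  # int16 LSB in uV


def save_population_h5(path, cells: Sequence[SyntheticCell],
                       spikes: Mapping[str, Mapping[int, np.ndarray]] | None = None,
                       ) -> None:
    """Archive a synthetic population and its spike trains.

    Layout: ``/cells`` (one column per cell attribute) and
    ``/spikes/<protocol>/<cell_id>`` (float64 seconds).
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("cells")
        names = [fld.name for fld in dc_fields(SyntheticCell)]
        for name in names:
            vals = [getattr(c, name) for c in cells]
            if name in ("archetype", "polarity"):
                g.create_dataset(name, data=np.array(vals, dtype="S64"))
            elif name == "rf_center":
                g.create_dataset(name, data=np.array(vals, dtype=float))
            else:
                g.create_dataset(name, data=np.array(vals))
        if spikes:
            sg = f.create_group("spikes")
            for proto, trains in spikes.items():
                pg = sg.create_group(proto)
                for cid, t in trains.items():
                    pg.create_dataset(str(cid), data=np.asarray(t, dtype=float))


def load_population_h5(path) -> tuple[list[SyntheticCell], dict]:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"cannot read HDF5 population file {path}: {exc}") from exc
    with f:
        g = f["cells"]
        n = len(g["cell_id"])
        cells = []
        for i in range(n):
            kw = {}
            for fld in dc_fields(SyntheticCell):
                v = g[fld.name][i]
                if fld.name in ("archetype", "polarity"):
                    kw[fld.name] = v.decode()
                elif fld.name == "rf_center":
                    kw[fld.name] = tuple(map(float, v))
                elif fld.name in ("cell_id", "rng_seed"):
                    kw[fld.name] = int(v)
                elif fld.name == "is_ds":
                    kw[fld.name] = bool(v)
                else:
                    kw[fld.name] = float(v)
            cells.append(SyntheticCell(**kw))
        spikes: dict[str, dict[int, np.ndarray]] = {}
        if "spikes" in f:
            for proto in f["spikes"]:
                spikes[proto] = {int(cid): np.asarray(f["spikes"][proto][cid])
                                 for cid in f["spikes"][proto]}
    return cells, spikes


def save_traces_h5(path, block: TraceBlock) -> None:
    """Store traces as int16 with a uV scale factor, plus ground truth."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            "traces", data=np.round(block.samples / TRACE_SCALE_UV).astype(np.int16))
        d.attrs["scale_uv"] = TRACE_SCALE_UV
        d.attrs["sample_rate"] = block.sample_rate
        cfg = f.create_group("config")
        cfg.attrs.update(rows=block.config.rows, cols=block.config.cols,
                         pitch=block.config.pitch,
                         origin=list(block.config.origin))
        gt = f.create_group("ground_truth")
        for cid, times in block.ground_truth.items():
            gt.create_dataset(str(cid), data=np.asarray(times, dtype=float))


def load_traces_h5(path) -> TraceBlock:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"cannot read HDF5 trace file {path}: {exc}") from exc
    with f:
        d = f["traces"]
        samples = d[...].astype(np.float32) * d.attrs["scale_uv"]
        cfg = f["config"].attrs
        config = ElectrodeConfig(rows=int(cfg["rows"]), cols=int(cfg["cols"]),
                                 origin=tuple(cfg["origin"]),
                                 pitch=float(cfg["pitch"]))
        gt = {int(cid): np.asarray(f["ground_truth"][cid])
              for cid in f.get("ground_truth", {})}
        return TraceBlock(samples, float(d.attrs["sample_rate"]), config,
                          ground_truth=gt)


def write_table(frame: pd.DataFrame, path, sep: str = ",") -> None:
    # default float formatting is repr-based and round-trips exactly
    frame.to_csv(path, sep=sep, index=False)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
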