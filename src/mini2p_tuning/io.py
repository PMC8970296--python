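"""Session container I/O: HDF5 traces, CSV tables, TIFF images."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd


def write_tracking_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=["frame", "part", "x", "y", "likelihood"])


def read_tracking_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_session(path, session) -> None:
    """Write a synthetic session (traces, truth, tracking) to HDF5."""
    from .synthetic import SyntheticSession

    assert isinstance(session, SyntheticSession)
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = session.seed
        f.attrs["n_planes"] = session.n_planes
        f.attrs["arena"] = json.dumps({
            "width_cm": session.arena.width_cm,
            "height_cm": session.arena.height_cm,
            "frame_rate_hz": session.arena.frame_rate_hz,
            "duration_s": session.arena.duration_s,
        })
        f.attrs["calcium"] = json.dumps({
            "decay_s": session.calcium.decay_s,
            "amplitude_scale": session.calcium.amplitude_scale,
            "noise_sd": session.calcium.noise_sd,
            "neuropil_fraction": session.calcium.neuropil_fraction,
            "baseline_f": session.calcium.baseline_f,
            "neuropil_baseline_f": session.calcium.neuropil_baseline_f,
        })
        tr = f.create_group("tracking")
        for col in ("frame", "x", "y", "likelihood"):
            tr.create_dataset(col, data=session.table[col].to_numpy())
        tr.create_dataset("part", data=session.table["part"].to_numpy(dtype="S"))
        for cell in session.cells:
            g = f.create_group(f"cells/{cell.cell_id:04d}")
            g.attrs["plane"] = cell.plane
            g.attrs["model"] = json.dumps(
                {"kind": cell.model.kind,
                 "baseline_rate_hz": cell.model.baseline_rate_hz,
                 "params": {k: (list(v) if isinstance(v, (tuple, list, np.ndarray)) else v)
                            for k, v in cell.model.params.items()
                            if k != "escape_mask"}})
            g.create_dataset("raw", data=cell.raw)
            g.create_dataset("neuropil", data=cell.neuropil)
            g.create_dataset("event_frames", data=cell.event_frames)
            g.create_dataset("event_amplitudes", data=cell.event_amplitudes)


def load_session(path):
    """Read a session container written by :func:`save_session`."""
    from .synthetic import (ArenaSpec, CalciumModel, SyntheticCell,
                            SyntheticSession, TuningModel)
    from .tracking import head_kinematics

    with h5py.File(path, "r") as f:
        arena = ArenaSpec(**json.loads(f.attrs["arena"]))
        calcium = CalciumModel(**json.loads(f.attrs["calcium"]))
        table = pd.DataFrame({
            "frame": f["tracking/frame"][:],
            "part": [p.decode() for p in f["tracking/part"][:]],
            "x": f["tracking/x"][:],
            "y": f["tracking/y"][:],
            "likelihood": f["tracking/likelihood"][:],
        })
        cells = []
        for key in sorted(f.get("cells", {}).keys()):
            g = f[f"cells/{key}"]
            md = json.loads(g.attrs["model"])
            params = {k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in md["params"].items()}
            cells.append(SyntheticCell(
                cell_id=int(key),
                model=TuningModel(kind=md["kind"], params=params,
                                  baseline_rate_hz=md["baseline_rate_hz"]),
                event_frames=g["event_frames"][:],
                event_amplitudes=g["event_amplitudes"][:],
                raw=g["raw"][:], neuropil=g["neuropil"][:],
                plane=int(g.attrs["plane"])))
        seed = int(f.attrs["seed"])
        n_planes = int(f.attrs["n_planes"])
    tracking = head_kinematics(table, arena.frame_rate_hz)
    return SyntheticSession(arena=arena, table=table, tracking=tracking,
                            cells=cells, calcium=calcium, seed=seed,
                            n_planes=n_planes)


def write_tiff(path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
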