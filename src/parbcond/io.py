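"""Plain-text I/O: extended-XYZ trajectories, CSV observables, YAML configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .polymer_core import ForceField, UnitMap
from .parb_kinetics import KineticParams
from .bridge_model import BridgeParams

__all__ = [
    "write_xyz", "read_xyz", "write_observables", "write_event_log",
    "write_bridge_list", "save_config", "load_config",
    "load_image_stack", "save_image_stack",
]


def load_image_stack(path) -> np.ndarray:
    """Image stack (frames, y, x) from a TIFF file or a CSV matrix.

    A CSV holds one frame per block of rows, blocks separated by blank
    lines; a single-block CSV is read as a one-frame stack."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        stack = np.asarray(tifffile.imread(path), dtype=float)
    else:
        blocks = [b for b in path.read_text().split("\n\n") if b.strip()]
        stack = np.stack([np.loadtxt(b.strip().splitlines(), delimiter=",")
                          for b in blocks])
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def save_image_stack(path, stack) -> Path:
    """Write a (frames, y, x) stack as TIFF or CSV (by file extension)."""
    path = Path(path)
    stack = np.asarray(stack)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, stack.astype(np.float32))
    else:
        with path.open("w") as fh:
            for k, frame in enumerate(stack):
                if k:
                    fh.write("\n")
                np.savetxt(fh, frame, delimiter=",", fmt="%.4f")
    return path

_CONFIG_SECTIONS = {
    "force_field": ForceField,
    "units": UnitMap,
    "kinetics": KineticParams,
    "bridging": BridgeParams,
}


def write_xyz(path, frames, occupancy_frames=None, seed=None,
              comment: str = ""):
    """Extended XYZ, one frame per dump, with a per-bead occupancy column."""
    path = Path(path)
    with path.open("w") as fh:
        for k, pos in enumerate(frames):
            pos = np.asarray(getattr(pos, "positions", pos))
            occ = None if occupancy_frames is None else \
                np.asarray(occupancy_frames[k], dtype=int)
            fh.write(f"{len(pos)}\n")
            props = "species:S:1:pos:R:3" + (":occ:I:1" if occ is not None else "")
            head = f'Properties={props} frame={k}'
            if seed is not None:
                head += f" seed={seed}"
            if comment:
                head += f" comment={comment!r}"
            fh.write(head + "\n")
            for i, p in enumerate(pos):
                line = f"DNA {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
                if occ is not None:
                    line += f" {occ[i]:d}"
                fh.write(line + "\n")
    return path


def read_xyz(path):
    """Read back frames (positions, occupancy-or-None) from write_xyz."""
    frames, occs = [], []
    with Path(path).open() as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            fh.readline()
            pos = np.empty((n, 3))
            occ = np.zeros(n, dtype=int)
            has_occ = False
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(x) for x in parts[1:4]]
                if len(parts) > 4:
                    occ[i] = int(parts[4])
                    has_occ = True
            frames.append(pos)
            occs.append(occ if has_occ else None)
    return frames, occs


def write_observables(path, result) -> Path:
    """CSV time series (time_tauB, rg2, n_bound, n_bridges) of a run."""
    path = Path(path)
    result.observables_frame().to_csv(path, index=False)
    return path


def write_event_log(path, occ) -> Path:
    """CSV event log (sweep, event_type, bead_from, bead_to)."""
    df = pd.DataFrame(occ.event_log,
                      columns=["sweep", "event_type", "bead_from", "bead_to"])
    df.to_csv(path, index=False)
    return Path(path)


def write_bridge_list(path, result) -> Path:
    """CSV bridge list per dumped frame: (frame, bead_i, bead_j, r)."""
    rows = []
    for k, pairs in enumerate(result.bridge_frames):
        pos = result.position_frames[k] if result.position_frames else None
        for i, j in pairs:
            r = np.nan if pos is None else float(np.linalg.norm(pos[i] - pos[j]))
            rows.append((int(result.frame_times[k]), int(i), int(j), r))
    pd.DataFrame(rows, columns=["frame", "bead_i", "bead_j", "r"]) \
        .to_csv(path, index=False)
    return Path(path)


def save_config(path, force_field=None, units=None, kinetics=None,
                bridging=None) -> Path:
    """YAML config with every force-field/unit/kinetic/bridging field;
    omitted sections are written with their defaults (the reference values)."""
    objs = {
        "force_field": force_field or ForceField(),
        "units": units or UnitMap(),
        "kinetics": kinetics or KineticParams(),
        "bridging": bridging or BridgeParams(),
    }
    doc = {k: dataclasses.asdict(v) for k, v in objs.items()}
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_config(path) -> dict:
    """Load a YAML config back into the typed parameter objects."""
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for key, cls in _CONFIG_SECTIONS.items():
        if key in doc:
            out[key] = cls(**doc[key])
    return out
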