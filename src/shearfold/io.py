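"""Plain-text trajectory and table I/O.

Trajectories are written as multi-frame XYZ plus a CSV time index
(``frame,time_ns``); first-passage event tables as tidy CSV
(``condition,time_ns,status``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import TrajectoryRecord

__all__ = ["write_trajectory", "read_trajectory", "write_events", "read_events"]


def write_trajectory(traj: TrajectoryRecord, out_dir: str | Path,
                     name: str = "traj") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    xyz = out / f"{name}.xyz"
    with xyz.open("w") as fh:
        for t, frame in zip(traj.times_ns, traj.positions):
            fh.write(f"{len(frame)}\n")
            fh.write(f"t_ns={t:.9g}\n")
            for x, y, z in frame:
                fh.write(f"X {x:.6f} {y:.6f} {z:.6f}\n")
    pd.DataFrame({"frame": np.arange(traj.n_frames),
                  "time_ns": traj.times_ns}).to_csv(
        out / f"{name}.index.csv", index=False)
    (out / f"{name}.meta.json").write_text(
        json.dumps(traj.metadata, indent=1, sort_keys=True, default=str))
    return xyz


def read_trajectory(out_dir: str | Path, name: str = "traj") -> TrajectoryRecord:
    out = Path(out_dir)
    times = pd.read_csv(out / f"{name}.index.csv")["time_ns"].values
    frames = []
    with (out / f"{name}.xyz").open() as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            fh.readline()  # comment
            frame = np.array([[float(v) for v in fh.readline().split()[1:4]]
                              for _ in range(n)])
            frames.append(frame)
    meta_path = out / f"{name}.meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TrajectoryRecord(times_ns=np.asarray(times, float),
                            positions=np.array(frames), metadata=meta)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"condition", "time_ns", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"events file lacks columns: {sorted(missing)}")
    return df
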