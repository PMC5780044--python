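"""Reading and writing the package's on-disk formats.

Midlines travel as WCON (Worm tracker Commons Object Notation, a JSON
dialect with per-frame x/y point arrays) or as a wide CSV
(frame, x_0..x_{P-1}, y_0..y_{P-1}); fluorescence and current traces as
plain CSV; kymograms as TSV matrices with body coordinates in the header;
ground truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import DualChannelTrace
from .ephys import CurrentTrace
from .posture import CurvatureKymogram, MidlineSeries, StateSequence

__all__ = [
    "write_wcon", "read_wcon",
    "write_midline_csv", "read_midline_csv",
    "write_kymogram_tsv", "read_kymogram_tsv",
    "write_states_csv",
    "write_calcium_csv", "read_calcium_csv",
    "write_current_csv", "read_current_csv",
    "write_ground_truth", "read_ground_truth",
]


def write_wcon(m: MidlineSeries, path: str | Path, worm_id: str = "1") -> None:
    t = (np.arange(m.n_frames) / m.frame_rate).tolist()
    data = {
        "units": {"t": "s", "x": "px", "y": "px"},
        "metadata": {"frame_rate": m.frame_rate},
        "data": [{
            "id": worm_id,
            "t": t,
            "x": [row[:, 0].tolist() for row in m.points],
            "y": [row[:, 1].tolist() for row in m.points],
        }],
    }
    Path(path).write_text(json.dumps(data))


def read_wcon(path: str | Path) -> MidlineSeries:
    doc = json.loads(Path(path).read_text())
    rec = doc["data"][0]
    x = np.asarray(rec["x"], dtype=float)
    y = np.asarray(rec["y"], dtype=float)
    t = np.asarray(rec["t"], dtype=float)
    if t.size > 1:
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    else:
        frame_rate = float(doc.get("metadata", {}).get("frame_rate", 1.0))
    points = np.stack([x, y], axis=-1)
    valid = np.all(np.isfinite(points.reshape(points.shape[0], -1)), axis=1)
    return MidlineSeries(points=points, frame_rate=frame_rate, valid=valid)


def write_midline_csv(m: MidlineSeries, path: str | Path) -> None:
    p = m.n_points
    cols = {"frame": np.arange(m.n_frames)}
    for i in range(p):
        cols[f"x_{i}"] = m.points[:, i, 0]
    for i in range(p):
        cols[f"y_{i}"] = m.points[:, i, 1]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={m.frame_rate}\n")
        df.to_csv(fh, index=False)


def read_midline_csv(path: str | Path) -> MidlineSeries:
    frame_rate = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for part in first[1:].split(","):
                key, _, val = part.strip().partition("=")
                if key == "frame_rate":
                    frame_rate = float(val)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    xs = sorted((c for c in df.columns if c.startswith("x_")),
                key=lambda c: int(c[2:]))
    ys = sorted((c for c in df.columns if c.startswith("y_")),
                key=lambda c: int(c[2:]))
    points = np.stack([df[xs].to_numpy(), df[ys].to_numpy()], axis=-1)
    valid = np.all(np.isfinite(points.reshape(points.shape[0], -1)), axis=1)
    return MidlineSeries(points=points, frame_rate=frame_rate, valid=valid)


def write_kymogram_tsv(k: CurvatureKymogram, path: str | Path) -> None:
    header = "\t".join(f"{c:.6f}" for c in k.body_coords)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={k.frame_rate}\n")
        fh.write(header + "\n")
        np.savetxt(fh, k.values, delimiter="\t", fmt="%.8g")


def read_kymogram_tsv(path: str | Path) -> CurvatureKymogram:
    with open(path) as fh:
        first = fh.readline()
        frame_rate = 1.0
        if first.startswith("#"):
            frame_rate = float(first.strip().split("=")[1])
            header = fh.readline()
        else:
            header = first
        body_coords = np.array([float(x) for x in header.split()])
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return CurvatureKymogram(values=values, body_coords=body_coords,
                             frame_rate=frame_rate)


def write_states_csv(s: StateSequence, velocity: np.ndarray,
                     path: str | Path) -> None:
    t = np.arange(len(s.labels)) / s.frame_rate
    df = pd.DataFrame({
        "frame": np.arange(len(s.labels)),
        "time_s": t,
        "velocity_px_per_s": velocity,
        "state": [x if x is not None else "missing" for x in s.labels],
    })
    df.to_csv(path, index=False)


def write_calcium_csv(traces: list[DualChannelTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "time_s": tr.time, "gcamp": tr.gcamp, "rfp": tr.rfp,
            "neuron": tr.neuron}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_calcium_csv(path: str | Path) -> list[DualChannelTrace]:
    df = pd.read_csv(path)
    out = []
    for neuron, grp in df.groupby("neuron", sort=False):
        out.append(DualChannelTrace(
            time=grp["time_s"].to_numpy(), gcamp=grp["gcamp"].to_numpy(),
            rfp=grp["rfp"].to_numpy(), neuron=str(neuron)))
    return out


def write_current_csv(t: CurrentTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={t.sample_rate}\n")
        pd.DataFrame({"time_s": t.time, "current_pA": t.current}).to_csv(
            fh, index=False)


def read_current_csv(path: str | Path) -> CurrentTrace:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            sample_rate = float(first.strip().split("=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
            sample_rate = 1.0 / float(np.median(np.diff(df["time_s"])))
    return CurrentTrace(time=df["time_s"].to_numpy(),
                        current=df["current_pA"].to_numpy(),
                        sample_rate=sample_rate)


def write_ground_truth(truth, path: str | Path) -> None:
    """JSON sidecar for a GroundTruth (numpy arrays become lists)."""
    def conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x
    doc = {k: conv(v) for k, v in vars(truth).items() if v is not None}
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
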