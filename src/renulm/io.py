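"""File I/O: multi-frame TIFF stacks with JSON sidecars, ground-truth and
track CSVs, label images, summary tables, and simple figures."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import FrameStack, Track

GT_COLUMNS = ("trajectory_id", "frame", "x_mm", "y_mm", "speed_mm_s", "bed")


def save_frame_stack(stack: FrameStack, path, metadata: dict | None = None) -> None:
    """Write a stack as multi-frame TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32),
                     photometric="minisblack")
    sidecar = {
        "pixel_pitch": stack.pixel_pitch,
        "frame_rate": stack.frame_rate,
        "channel": stack.channel,
        "n_frames": stack.n_frames,
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_frame_stack(path) -> FrameStack:
    """Read a multi-frame TIFF + JSON sidecar back into a FrameStack."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FrameStack(frames, pixel_pitch=meta["pixel_pitch"],
                      frame_rate=meta["frame_rate"], channel=meta["channel"])


def load_label_map(path) -> np.ndarray:
    """Read a region label image (TIFF/PNG, integer values 0-3)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        labels = iio.imread(path)
    labels = np.asarray(labels)
    if labels.ndim == 3:
        labels = labels[..., 0]
    return labels.astype(np.uint8)


def ground_truth_to_csv(trajectories, path) -> None:
    """Write ground-truth trajectories as a per-position CSV."""
    rows = []
    for traj in trajectories:
        for k in range(len(traj)):
            rows.append((traj.id, int(traj.frames[k]), traj.x[k], traj.y[k],
                         traj.speeds[k], traj.bed))
    pd.DataFrame(rows, columns=list(GT_COLUMNS)).to_csv(path, index=False)


def tracks_to_csv(tracks, path) -> None:
    """Write tracks as a per-position CSV (step speed on the later position)."""
    rows = []
    for tr in tracks:
        speeds = np.concatenate([[np.nan], tr.speeds]) if len(tr) > 1 else [np.nan]
        for k in range(len(tr)):
            rows.append((tr.id, int(tr.frames[k]), tr.x[k], tr.y[k],
                         speeds[k], tr.bed or ""))
    pd.DataFrame(rows, columns=list(GT_COLUMNS)).to_csv(path, index=False)


def tracks_from_csv(path) -> list:
    """Load a per-position track CSV back into Track objects."""
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("trajectory_id"):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        tr = Track(id=int(tid), frames=frames, times=frames / 54.0,
                   x=grp["x_mm"].to_numpy(), y=grp["y_mm"].to_numpy())
        bed = grp["bed"].iloc[0]
        tr.bed = bed if isinstance(bed, str) and bed else None
        tracks.append(tr)
    return tracks


def save_map_trace(t, values, path) -> None:
    pd.DataFrame({"t": t, "map_mmHg": values}).to_csv(path, index=False)


def load_map_trace(path):
    df = pd.read_csv(path)
    return df["t"].to_numpy(), df["map_mmHg"].to_numpy()


def plot_moving_averages(series_by_bed: dict, path, t_inj: float | None = None) -> None:
    """Moving-average velocity figure, one panel per bed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beds = list(series_by_bed)
    fig, axes = plt.subplots(max(1, (len(beds) + 1) // 2), 2,
                             figsize=(10, 2.5 * max(1, (len(beds) + 1) // 2)),
                             squeeze=False)
    for ax, bed in zip(axes.ravel(), beds):
        s = series_by_bed[bed]
        ax.plot(s["t"], s["mean"], lw=1.2)
        if t_inj is not None:
            ax.axvline(t_inj, ls=":", c="k", lw=0.8)
        ax.set_title(bed)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("MB velocity (mm/s)")
    for ax in axes.ravel()[len(beds):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
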