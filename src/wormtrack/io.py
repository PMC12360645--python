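"""Shared file I/O: video stacks (multi-page TIFF / HDF5), skeleton tables
(HDF5 / CSV) and clip collections.

Conventions: coordinates are 0-based pixels with x = column, y = row, origin
top-left; skeleton tables are lossless on a write -> read round trip.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .simulate import Clip

__all__ = [
    "SkeletonRecord",
    "read_video",
    "write_video",
    "read_skeletons",
    "write_skeletons",
    "write_clips",
    "read_clips",
    "records_to_trajectories",
    "trajectories_to_records",
]

CSV_HEADER_COMMENT = (
    "# skeleton table: 0-based pixel coordinates, x = column, y = row, "
    "origin top-left\n"
)


@dataclasses.dataclass
class SkeletonRecord:
    frame: int
    worm_id: int
    points: np.ndarray  # (N, 2)
    confidence: float = 1.0
    latent: Optional[np.ndarray] = None


def _is_tiff(path) -> bool:
    return os.path.splitext(str(path))[1].lower() in (".tif", ".tiff")


def _is_hdf5(path) -> bool:
    return os.path.splitext(str(path))[1].lower() in (".h5", ".hdf5")


def read_video(path) -> np.ndarray:
    """Read a (T, H, W) grayscale stack from multi-page TIFF or HDF5."""
    if _is_tiff(path):
        stack = tifffile.imread(str(path))
    elif _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise ValueError(f"{path}: no 'frames' dataset")
            stack = f["frames"][...]
    else:
        raise ValueError(f"unsupported video format: {path}")
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a (T, H, W) stack, got {stack.shape}")
    return stack


def write_video(path, frames: np.ndarray) -> None:
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be (T, H, W)")
    if _is_tiff(path):
        tifffile.imwrite(str(path), frames.astype(np.float32))
    elif _is_hdf5(path):
        with h5py.File(path, "a") as f:
            if "frames" in f:
                del f["frames"]
            f.create_dataset("frames", data=frames.astype(np.float32))
    else:
        raise ValueError(f"unsupported video format: {path}")


def write_skeletons(path, records: Sequence[SkeletonRecord], group: str = "skeletons") -> None:
    """Write a skeleton table (HDF5 group or CSV, chosen by extension)."""
    records = list(records)
    if _is_hdf5(path):
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.attrs["coordinates"] = "0-based px, x=column, y=row, origin top-left"
            if not records:
                g.attrs["n_records"] = 0
                return
            g.attrs["n_records"] = len(records)
            g.create_dataset("frame", data=np.array([r.frame for r in records], dtype=np.int64))
            g.create_dataset("worm_id", data=np.array([r.worm_id for r in records], dtype=np.int64))
            g.create_dataset(
                "points",
                data=np.stack([np.asarray(r.points, dtype=float) for r in records]),
            )
            g.create_dataset(
                "confidence", data=np.array([r.confidence for r in records], dtype=float)
            )
            if records[0].latent is not None:
                g.create_dataset(
                    "latent",
                    data=np.stack([np.asarray(r.latent, dtype=float) for r in records]),
                )
    elif str(path).lower().endswith(".csv"):
        rows = []
        for r in records:
            for k, (x, y) in enumerate(np.asarray(r.points, dtype=float)):
                rows.append((r.frame, r.worm_id, k, x, y))
        df = pd.DataFrame(rows, columns=["frame", "worm_id", "point_index", "x", "y"])
        with open(path, "w") as f:
            f.write(CSV_HEADER_COMMENT)
            df.to_csv(f, index=False)
    else:
        raise ValueError(f"unsupported skeleton table format: {path}")


def read_skeletons(path, group: str = "skeletons") -> list[SkeletonRecord]:
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if group not in f:
                raise ValueError(f"{path}: no '{group}' group")
            g = f[group]
            if int(g.attrs.get("n_records", len(g.get("frame", [])))) == 0:
                return []
            frames = g["frame"][...]
            wids = g["worm_id"][...]
            points = g["points"][...]
            conf = g["confidence"][...]
            latent = g["latent"][...] if "latent" in g else None
            return [
                SkeletonRecord(
                    frame=int(frames[i]),
                    worm_id=int(wids[i]),
                    points=points[i],
                    confidence=float(conf[i]),
                    latent=None if latent is None else latent[i],
                )
                for i in range(len(frames))
            ]
    if str(path).lower().endswith(".csv"):
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"cannot parse skeleton CSV {path}: {exc}") from exc
        needed = {"frame", "worm_id", "point_index", "x", "y"}
        if not needed.issubset(df.columns):
            raise ValueError(
                f"{path}: missing columns {sorted(needed - set(df.columns))}"
            )
        out = []
        for (frame, wid), grp in df.groupby(["frame", "worm_id"], sort=True):
            grp = grp.sort_values("point_index")
            out.append(
                SkeletonRecord(
                    frame=int(frame),
                    worm_id=int(wid),
                    points=grp[["x", "y"]].to_numpy(dtype=float),
                )
            )
        return out
    raise ValueError(f"unsupported skeleton table format: {path}")


def write_clips(path, clips: Sequence[Clip]) -> None:
    with h5py.File(path, "a") as f:
        if "clips" in f:
            del f["clips"]
        root = f.create_group("clips")
        for i, clip in enumerate(clips):
            g = root.create_group(f"clip_{i:05d}")
            g.create_dataset("frames", data=clip.frames.astype(np.float32))
            g.attrs["fps"] = clip.fps
            g.attrs["pixel_size_um"] = clip.pixel_size_um
            if clip.annotations:
                if not all(isinstance(a[0], (int, np.integer)) for a in clip.annotations):
                    raise ValueError(
                        "clip files store integer worm ids; relabel stacked-"
                        "clip tuple ids before writing"
                    )
                g.create_dataset(
                    "ann_worm_id",
                    data=np.array([int(a[0]) for a in clip.annotations], dtype=np.int64),
                )
                g.create_dataset(
                    "ann_frame",
                    data=np.array([a[1] for a in clip.annotations], dtype=np.int64),
                )
                g.create_dataset(
                    "ann_skeleton",
                    data=np.stack([np.asarray(a[2], dtype=float) for a in clip.annotations]),
                )


def read_clips(path) -> list[Clip]:
    clips = []
    with h5py.File(path, "r") as f:
        if "clips" not in f:
            raise ValueError(f"{path}: no 'clips' group")
        root = f["clips"]
        for name in sorted(root):
            g = root[name]
            annotations = []
            if "ann_worm_id" in g:
                wids = g["ann_worm_id"][...]
                afr = g["ann_frame"][...]
                skels = g["ann_skeleton"][...]
                annotations = [
                    (int(wids[i]), int(afr[i]), skels[i]) for i in range(len(wids))
                ]
            clips.append(
                Clip(
                    frames=g["frames"][...],
                    annotations=annotations,
                    pixel_size_um=float(g.attrs["pixel_size_um"]),
                    fps=float(g.attrs["fps"]),
                )
            )
    return clips


def records_to_trajectories(records: Sequence[SkeletonRecord]):
    """Group table records by worm id into Trajectory objects."""
    from .tracking import TrackEntry, Trajectory

    by_worm: dict = {}
    for r in records:
        by_worm.setdefault(r.worm_id, []).append(
            TrackEntry(
                frame=r.frame,
                skeleton=np.asarray(r.points, dtype=float),
                confidence=r.confidence,
                latent=r.latent,
            )
        )
    return [Trajectory(worm_id=wid, entries=entries) for wid, entries in sorted(by_worm.items())]


def trajectories_to_records(trajectories) -> list[SkeletonRecord]:
    out = []
    for tr in trajectories:
        for e in tr.entries:
            out.append(
                SkeletonRecord(
                    frame=e.frame,
                    worm_id=tr.worm_id,
                    points=e.skeleton,
                    confidence=e.confidence,
                    latent=e.latent,
                )
            )
    return out
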