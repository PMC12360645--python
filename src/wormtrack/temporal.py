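"""Temporal downsampling and smoothing-spline interpolation of skeleton
trajectories.

"3D" interpolation is over (x, y, t): each skeleton point index is traced as
two one-dimensional splines in time, fitted with a shared smoothing
parameter.  With ``smoothing=None`` the penalty is chosen by generalised
cross-validation per series.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .shapespace import resample_equal_arclength

__all__ = [
    "SkeletonTimeSeries",
    "downsample_frames",
    "interpolate_spline",
    "split_on_gaps",
]


@dataclasses.dataclass
class SkeletonTimeSeries:
    frames: np.ndarray  # (F,) strictly increasing integer frame indices
    skeletons: np.ndarray  # (F, N, 2)
    worm_id: Union[int, str, tuple, None] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.skeletons = np.asarray(self.skeletons, dtype=float)
        if self.frames.ndim != 1:
            raise ValueError("frames must be 1-D")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if (
            self.skeletons.ndim != 3
            or self.skeletons.shape[0] != len(self.frames)
            or self.skeletons.shape[2] != 2
        ):
            raise ValueError("skeletons must be (F, N, 2) matching frames")

    @property
    def n_points(self) -> int:
        return self.skeletons.shape[1]


def downsample_frames(frame_indices, k: int = 3) -> np.ndarray:
    """Keep every k-th frame index starting at the first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = np.asarray(frame_indices)
    return idx[::k].copy()


def split_on_gaps(series: SkeletonTimeSeries, max_gap: int = 25) -> list[SkeletonTimeSeries]:
    """Split a series wherever consecutive observed frames are more than
    ``max_gap`` frames apart (such gaps are not bridged by interpolation)."""
    if len(series.frames) == 0:
        return []
    cuts = np.where(np.diff(series.frames) > max_gap)[0] + 1
    pieces = []
    for chunk in np.split(np.arange(len(series.frames)), cuts):
        pieces.append(
            SkeletonTimeSeries(
                frames=series.frames[chunk],
                skeletons=series.skeletons[chunk],
                worm_id=series.worm_id,
            )
        )
    return pieces


def interpolate_spline(
    series: SkeletonTimeSeries,
    target_frames,
    smoothing: Optional[float] = None,
    renormalize: bool = True,
) -> SkeletonTimeSeries:
    """Interpolate a skeleton time series onto ``target_frames``.

    ``smoothing`` is the spline penalty weight shared by every coordinate
    series (0 = pure interpolation); ``None`` selects it by generalised
    cross-validation.  Extrapolation outside the observed frame range is
    refused.  Output skeletons are re-normalised to equal point spacing
    unless ``renormalize`` is False.
    """
    target = np.asarray(target_frames, dtype=int)
    frames = series.frames
    if len(frames) < 4:
        raise ValueError("need at least 4 observed frames to fit a spline")
    if target.min() < frames[0] or target.max() > frames[-1]:
        raise ValueError(
            f"target frames [{target.min()}, {target.max()}] extend outside "
            f"the observed range [{frames[0]}, {frames[-1]}]; "
            "extrapolation is not supported"
        )
    t = frames.astype(float)
    tt = target.astype(float)
    f, n, _ = series.skeletons.shape
    coords = series.skeletons.reshape(f, n * 2)
    out = np.empty((len(target), n * 2))
    use_cubic = (smoothing is not None and smoothing == 0) or len(frames) < 5
    for c in range(n * 2):
        y = coords[:, c]
        if use_cubic:
            out[:, c] = CubicSpline(t, y)(tt)
        else:
            spl = make_smoothing_spline(t, y, lam=smoothing)
            out[:, c] = spl(tt)
    skels = out.reshape(len(target), n, 2)
    if renormalize:
        skels = np.stack([resample_equal_arclength(s, n) for s in skels])
    return SkeletonTimeSeries(frames=target, skeletons=skels, worm_id=series.worm_id)
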