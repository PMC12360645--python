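"""Static background estimation by rank-1 SVD of temporally subsampled frames."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["BackgroundModel", "estimate_background", "subtract_background"]


@dataclasses.dataclass
class BackgroundModel:
    image: np.ndarray  # (H, W) background estimate, intensity units
    n_frames_used: int
    subsample_step: int

    def __post_init__(self):
        if self.image.ndim != 2:
            raise ValueError("background image must be 2-D")
        if self.n_frames_used < 1:
            raise ValueError("n_frames_used must be >= 1")


def estimate_background(video: np.ndarray, subsample_step: int = 400) -> BackgroundModel:
    """Estimate the static background of a video.

    Frames are subsampled 1:``subsample_step`` in time (all frames are used
    when the video is shorter than one step), stacked into a frames-by-pixels
    matrix, and the highest-energy singular triplet gives the background:
    the unit-norm spatial mode scaled by the singular value times the mean
    temporal coefficient, so the result lives in intensity units.  The sign
    ambiguity is fixed by requiring a non-negative spatial-mode mean.
    """
    video = np.asarray(video)
    if video.ndim != 3 or video.shape[0] < 1:
        raise ValueError("video must be a non-empty (T, H, W) stack")
    if subsample_step < 1:
        raise ValueError("subsample_step must be >= 1")
    if video.shape[0] < subsample_step:
        sampled = video
    else:
        sampled = video[::subsample_step]
    n, h, w = sampled.shape
    mat = sampled.reshape(n, h * w).astype(np.float64)
    # rank-1 SVD via the small (frames x frames) Gram matrix: with far fewer
    # sampled frames than pixels this is much cheaper than a full SVD
    gram = mat @ mat.T
    evals, evecs = np.linalg.eigh(gram)
    s0 = float(np.sqrt(max(evals[-1], 0.0)))
    temporal = evecs[:, -1]
    if s0 <= 0:
        spatial = np.zeros(h * w)
        s0 = 1.0
    else:
        spatial = (mat.T @ temporal) / s0
    s = np.array([s0])
    if spatial.mean() < 0:
        spatial = -spatial
        temporal = -temporal
    image = (s[0] * temporal.mean()) * spatial
    return BackgroundModel(
        image=image.reshape(h, w),
        n_frames_used=n,
        subsample_step=subsample_step,
    )


def subtract_background(video: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Per-pixel residual ``frame - background`` for every frame."""
    video = np.asarray(video)
    single = video.ndim == 2
    if single:
        video = video[None]
    if video.shape[1:] != model.image.shape:
        raise ValueError(
            f"frame shape {video.shape[1:]} does not match background "
            f"{model.image.shape}"
        )
    residual = video.astype(np.float64) - model.image[None]
    return residual[0] if single else residual
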