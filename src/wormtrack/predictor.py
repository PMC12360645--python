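"""Grid-based skeleton prediction contract.

Images are padded to a multiple of the cell size; each grid cell owns up to
``K`` detection slots, and each active slot carries one set of shape-space
coefficients per central frame, a confidence score, and a latent vector.
Training targets are assigned by centroid-to-cell-centre distance with a
fixed pixel cutoff, and grid outputs are decoded back into skeletons through
the shape space with the cell centre as the offset.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .shapespace import ShapeSpace, decode as ss_decode, encode as ss_encode

__all__ = [
    "GridGeometry",
    "PadInfo",
    "PredictionGrid",
    "Detection",
    "TargetTensors",
    "pad_to_multiple",
    "assign_targets",
    "annotations_by_worm",
    "decode_grid",
    "deduplicate",
    "skeleton_distance",
]

logger = logging.getLogger(__name__)

DEFAULT_CELL_SIZE = 16
DEFAULT_CUTOFF = 48.0
DEFAULT_SLOTS = 8
DEFAULT_LATENT_DIM = 8
DEFAULT_CONF_THRESHOLD = 0.5
N_CENTRAL_FRAMES = 3


@dataclasses.dataclass
class PadInfo:
    original_shape: tuple[int, int]
    padded_shape: tuple[int, int]

    @property
    def pad(self) -> tuple[int, int]:
        return (
            self.padded_shape[0] - self.original_shape[0],
            self.padded_shape[1] - self.original_shape[1],
        )


def pad_to_multiple(image: np.ndarray, multiple: int = DEFAULT_CELL_SIZE):
    """Zero-pad the trailing two dimensions up to the nearest multiple.

    Padding is appended bottom/right so coordinates are unchanged; the
    returned :class:`PadInfo` records the original shape for cropping back.
    Zero is the natural fill for background-subtracted frames.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3) or image.size == 0:
        raise ValueError("image must be a non-empty 2-D or 3-D array")
    h, w = image.shape[-2:]
    hp = int(np.ceil(h / multiple)) * multiple
    wp = int(np.ceil(w / multiple)) * multiple
    pad = [(0, 0)] * (image.ndim - 2) + [(0, hp - h), (0, wp - w)]
    padded = np.pad(image, pad, mode="constant")
    return padded, PadInfo(original_shape=(h, w), padded_shape=(hp, wp))


@dataclasses.dataclass
class GridGeometry:
    """Cell layout of the prediction grid over a padded image."""

    padded_shape: tuple[int, int]
    cell_size: int = DEFAULT_CELL_SIZE

    def __post_init__(self):
        h, w = self.padded_shape
        if h % self.cell_size or w % self.cell_size:
            raise ValueError("padded shape must be a multiple of cell_size")

    @classmethod
    def for_image(cls, shape: tuple[int, int], cell_size: int = DEFAULT_CELL_SIZE):
        _, info = pad_to_multiple(np.empty(shape, dtype=np.uint8), cell_size)
        return cls(padded_shape=info.padded_shape, cell_size=cell_size)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            self.padded_shape[0] // self.cell_size,
            self.padded_shape[1] // self.cell_size,
        )

    def cell_centers(self) -> np.ndarray:
        """(Gy, Gx, 2) array of cell-centre (x, y) pixel coordinates."""
        gy, gx = self.grid_shape
        s = self.cell_size
        cx = (np.arange(gx) + 0.5) * s
        cy = (np.arange(gy) + 0.5) * s
        out = np.empty((gy, gx, 2))
        out[:, :, 0] = cx[None, :]
        out[:, :, 1] = cy[:, None]
        return out


@dataclasses.dataclass
class TargetTensors:
    """Training targets for one clip."""

    coeffs: np.ndarray  # (Gy, Gx, K, 3, D)
    confidence: np.ndarray  # (Gy, Gx, K) in {0, 1}
    worm_ids: np.ndarray  # (Gy, Gx, K) object array, None when empty
    geometry: GridGeometry


@dataclasses.dataclass
class PredictionGrid:
    """Raw grid output: coefficients, confidences and latents per slot."""

    coeffs: np.ndarray  # (Gy, Gx, K, 3, D)
    confidence: np.ndarray  # (Gy, Gx, K) in [0, 1]
    latent: np.ndarray  # (Gy, Gx, K, L)
    geometry: GridGeometry

    def __post_init__(self):
        gy, gx = self.geometry.grid_shape
        if self.coeffs.shape[:2] != (gy, gx):
            raise ValueError("coeffs grid shape mismatch")
        if self.confidence.shape != self.coeffs.shape[:3]:
            raise ValueError("confidence shape mismatch")
        if self.latent.shape[:3] != self.coeffs.shape[:3]:
            raise ValueError("latent shape mismatch")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValueError("confidence must lie in [0, 1]")


@dataclasses.dataclass
class Detection:
    skeleton: np.ndarray  # (N, 2)
    confidence: float
    latent: np.ndarray  # (L,)
    frame: int  # central-frame index, 0..2 (or absolute if relabelled)
    cell: tuple[int, int] = (0, 0)
    slot: int = 0

    def centroid(self) -> np.ndarray:
        return self.skeleton.mean(axis=0)


def annotations_by_worm(annotations) -> dict:
    """Group clip annotations ``(worm_id, frame, skeleton)`` into
    ``{worm_id: {local_frame_rank: skeleton}}`` with ranks 0..2."""
    frames = sorted({fi for _, fi, _ in annotations})
    rank = {fi: i for i, fi in enumerate(frames)}
    out: dict = {}
    for wid, fi, skel in annotations:
        out.setdefault(wid, {})[rank[fi]] = np.asarray(skel, dtype=float)
    return out


def assign_targets(
    annotations,
    geometry: GridGeometry,
    space: ShapeSpace,
    cutoff: float = DEFAULT_CUTOFF,
    n_slots: int = DEFAULT_SLOTS,
) -> TargetTensors:
    """Build training target tensors from central-frame annotations.

    A worm is assigned to every cell whose centre lies within ``cutoff`` of
    the worm's central-frame centroid, nearest worms first, at most
    ``n_slots`` per cell.  Assigned slots carry the encoded coefficients for
    each of the 3 central frames and confidence 1.
    """
    by_worm = annotations_by_worm(annotations)
    for wid, per_frame in by_worm.items():
        if len(per_frame) != N_CENTRAL_FRAMES:
            raise ValueError(
                f"worm {wid!r} must be annotated on all {N_CENTRAL_FRAMES} "
                f"central frames, got {sorted(per_frame)}"
            )
    gy, gx = geometry.grid_shape
    d = space.n_components
    coeffs = np.zeros((gy, gx, n_slots, N_CENTRAL_FRAMES, d))
    conf = np.zeros((gy, gx, n_slots))
    worm_ids = np.full((gy, gx, n_slots), None, dtype=object)

    centers = geometry.cell_centers()
    wids = list(by_worm)
    if not wids:
        return TargetTensors(coeffs, conf, worm_ids, geometry)
    centroids = np.array(
        [by_worm[wid][1].mean(axis=0) for wid in wids]
    )  # middle central frame
    dists = np.linalg.norm(
        centers[:, :, None, :] - centroids[None, None, :, :], axis=-1
    )  # (Gy, Gx, n_worms)
    for i in range(gy):
        for j in range(gx):
            order = np.argsort(dists[i, j], kind="stable")
            within = [k for k in order if dists[i, j, k] <= cutoff]
            if len(within) > n_slots:
                logger.warning(
                    "cell (%d, %d): %d worms within cutoff, keeping %d nearest",
                    i,
                    j,
                    len(within),
                    n_slots,
                )
                within = within[:n_slots]
            for slot, k in enumerate(within):
                wid = wids[k]
                conf[i, j, slot] = 1.0
                worm_ids[i, j, slot] = wid
                for f in range(N_CENTRAL_FRAMES):
                    coeffs[i, j, slot, f] = ss_encode(
                        by_worm[wid][f], space, offset=centers[i, j]
                    )
    return TargetTensors(coeffs, conf, worm_ids, geometry)


def decode_grid(
    grid: PredictionGrid,
    space: ShapeSpace,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    pad_info: Optional[PadInfo] = None,
) -> list[Detection]:
    """Decode all slots above the confidence threshold into detections.

    Each active slot yields one skeleton per central frame, reconstructed as
    ``coefficients x basis + mean`` plus the cell-centre offset.  With a
    :class:`PadInfo`, detections whose skeleton centroid falls entirely in
    the padding margin are dropped.
    """
    if grid.coeffs.shape[-1] != space.n_components:
        raise ValueError(
            f"grid carries {grid.coeffs.shape[-1]} coefficients but the shape "
            f"space has {space.n_components}"
        )
    centers = grid.geometry.cell_centers()
    detections: list[Detection] = []
    idx = np.argwhere(grid.confidence > conf_threshold)
    for i, j, k in idx:
        for f in range(grid.coeffs.shape[3]):
            skel = ss_decode(grid.coeffs[i, j, k, f], space, offset=centers[i, j])
            if pad_info is not None:
                cx, cy = skel.mean(axis=0)
                h, w = pad_info.original_shape
                if cx >= w or cy >= h:
                    continue
            detections.append(
                Detection(
                    skeleton=skel,
                    confidence=float(grid.confidence[i, j, k]),
                    latent=np.asarray(grid.latent[i, j, k], dtype=float),
                    frame=f,
                    cell=(int(i), int(j)),
                    slot=int(k),
                )
            )
    return detections


def skeleton_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean point-to-point distance, minimised over head-tail orientation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("skeletons must share a shape")
    fwd = np.mean(np.linalg.norm(a - b, axis=1))
    rev = np.mean(np.linalg.norm(a[::-1] - b, axis=1))
    return float(min(fwd, rev))


def deduplicate(
    detections: Sequence[Detection], min_separation: float = 12.0
) -> list[Detection]:
    """Greedy non-maximum suppression by confidence within one frame.

    A detection is suppressed when its orientation-minimised mean
    point-to-point distance to an already-kept detection is below
    ``min_separation``.
    """
    frames = {d.frame for d in detections}
    if len(frames) > 1:
        raise ValueError("deduplicate expects detections from a single frame")
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].confidence, i),
    )
    kept: list[Detection] = []
    for i in order:
        d = detections[i]
        if all(
            skeleton_distance(d.skeleton, k.skeleton) >= min_separation
            for k in kept
        ):
            kept.append(d)
    return kept
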