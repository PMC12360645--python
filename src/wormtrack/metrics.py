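"""Evaluation metrics: skeleton RMSD with head-tail alignment, nearest-segment
midline distance, per-method failure classification, and tracking fidelity."""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .shapespace import resample_equal_arclength

__all__ = [
    "TrackMatchResult",
    "rmsd",
    "nearest_segment_distance",
    "classify_failure",
    "tracking_fidelity",
    "detection_recall",
    "FAILURE_METHODS",
]

FAILURE_METHODS = ("tierpsy", "dtc", "paf", "omnipose")


def rmsd(
    predicted,
    truth,
    resample_to: Optional[int] = None,
    orientation: str = "min",
) -> float:
    """Root mean squared point-to-point deviation between two skeletons.

    Both skeletons are resampled to equal spacing (``resample_to`` points, or
    their own count when None).  With ``orientation='min'`` the head-tail
    orientation minimising the value is used (for when head labels are
    unavailable); ``'fixed'`` trusts the given point order.
    """
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(truth, dtype=float)
    if resample_to is not None:
        a = resample_equal_arclength(a, resample_to)
        b = resample_equal_arclength(b, resample_to)
    if a.shape != b.shape:
        raise ValueError(
            f"skeletons must have the same point count, got {a.shape[0]} vs "
            f"{b.shape[0]}; pass resample_to"
        )
    fwd = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
    if orientation == "fixed":
        return float(fwd)
    if orientation != "min":
        raise ValueError("orientation must be 'min' or 'fixed'")
    rev = np.sqrt(np.mean(np.sum((a[::-1] - b) ** 2, axis=1)))
    return float(min(fwd, rev))


def _point_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest location on the polyline
    (projected onto segments, endpoints clamped)."""
    a = poly[:-1]
    d = np.diff(poly, axis=0)
    dd = np.sum(d * d, axis=1)
    dd[dd == 0] = 1e-300
    t = ((points[:, None, :] - a[None]) * d[None]).sum(-1) / dd[None]
    t = np.clip(t, 0.0, 1.0)
    closest = a[None] + t[:, :, None] * d[None]
    dist = np.linalg.norm(points[:, None, :] - closest, axis=-1)
    return dist.min(axis=1)


def nearest_segment_distance(predicted, truth) -> float:
    """Mean distance from each predicted point to the nearest portion of the
    truth midline (asymmetric: predicted against truth)."""
    pred = np.asarray(predicted, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if tru.ndim != 2 or tru.shape[0] < 2:
        raise ValueError("truth skeleton needs at least 2 points")
    if pred.ndim != 2 or pred.shape[1] != 2:
        raise ValueError("predicted skeleton must be (N, 2)")
    return float(np.mean(_point_to_polyline(pred, tru)))


def _turning_angles(contour: np.ndarray) -> np.ndarray:
    """Absolute turning angle at each vertex of a closed contour."""
    prev = np.roll(contour, 1, axis=0)
    nxt = np.roll(contour, -1, axis=0)
    v1 = contour - prev
    v2 = nxt - contour
    a1 = np.arctan2(v1[:, 1], v1[:, 0])
    a2 = np.arctan2(v2[:, 1], v2[:, 0])
    diff = (a2 - a1 + np.pi) % (2 * np.pi) - np.pi
    return np.abs(diff)


def classify_failure(
    method: str,
    raw_output: Mapping,
    conf_threshold: float = 0.5,
    min_landmarks: int = 14,
    curvature_threshold: float = 1.0,
    width_ratio_max: float = 3.0,
) -> tuple[bool, str]:
    """Apply the method-specific failed-prediction rule.

    Returns ``(ok, reason)``.  Rules:

    * ``dtc`` — fails when no skeleton confidence exceeds ``conf_threshold``
      (``raw_output['confidences']``).
    * ``paf`` — fails when fewer than ``min_landmarks`` landmark points were
      detected (``raw_output['points']``).
    * ``tierpsy`` / ``omnipose`` — the segmented contour must have exactly
      two high-curvature vertices (turning angle above
      ``curvature_threshold`` rad: the head and the tail) and the max/min
      width ratio must not exceed ``width_ratio_max``
      (``raw_output['contour']``, ``raw_output['widths']``).
    """
    if method not in FAILURE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {FAILURE_METHODS}")
    if method == "dtc":
        confs = np.asarray(raw_output.get("confidences", []), dtype=float)
        if confs.size == 0 or confs.max() <= conf_threshold:
            return False, f"no skeleton above confidence {conf_threshold}"
        return True, "ok"
    if method == "paf":
        pts = raw_output.get("points")
        n = len(pts) if pts is not None else 0
        if n < min_landmarks:
            return False, f"only {n} landmark points (< {min_landmarks})"
        return True, "ok"
    # tierpsy and omnipose share the contour heuristics
    contour = np.asarray(raw_output.get("contour", []), dtype=float)
    if contour.ndim != 2 or len(contour) < 4:
        return False, "no usable contour"
    angles = _turning_angles(contour)
    n_sharp = int(np.sum(angles > curvature_threshold))
    if n_sharp != 2:
        return False, f"{n_sharp} high-curvature points (expected exactly 2)"
    widths = raw_output.get("widths")
    if widths is not None:
        widths = np.asarray(widths, dtype=float)
        if widths.min() <= 0:
            return False, "non-positive width"
        if widths.max() / widths.min() > width_ratio_max:
            return False, "width ratio above threshold"
    return True, "ok"


@dataclasses.dataclass
class TrackMatchResult:
    """Per-frame mismatch counts against ground truth and the resulting
    tracking fidelity ``1 - sum(mme_t) / sum(g_t)``."""

    frames: np.ndarray
    mme_t: np.ndarray
    g_t: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.mme_t = np.asarray(self.mme_t, dtype=int)
        self.g_t = np.asarray(self.g_t, dtype=int)
        if np.any(self.mme_t < 0) or np.any(self.mme_t > self.g_t):
            raise ValueError("0 <= mme_t <= g_t must hold")

    @property
    def fidelity(self) -> float:
        total = self.g_t.sum()
        if total == 0:
            raise ValueError("no ground-truth objects")
        return float(1.0 - self.mme_t.sum() / total)


def _per_frame_entries(trajectories) -> dict:
    out: dict = {}
    for tr in trajectories:
        for e in tr.entries:
            out.setdefault(e.frame, []).append((tr.worm_id, np.asarray(e.skeleton)))
    return out


def _match_distance(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape == b.shape:
        fwd = np.mean(np.linalg.norm(a - b, axis=1))
        rev = np.mean(np.linalg.norm(a[::-1] - b, axis=1))
        return float(min(fwd, rev))
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


def tracking_fidelity(
    predicted_trajectories: Sequence,
    truth_trajectories: Sequence,
    max_match_dist: float = np.inf,
) -> TrackMatchResult:
    """Tracking fidelity of predicted trajectories against ground truth.

    Per frame, ground-truth objects are matched to predicted tracks by
    minimum total skeleton distance (gated at ``max_match_dist``).  A
    ground-truth object counts as a mismatch at frame ``t`` when it is
    unmatched, or when its matched predicted track ID differs from the ID it
    was matched to at its first matched frame.
    """
    if not truth_trajectories:
        raise ValueError("empty ground truth")
    gt = _per_frame_entries(truth_trajectories)
    pred = _per_frame_entries(predicted_trajectories)
    frames = sorted(gt)
    reference: dict = {}
    mme, g = [], []
    for t in frames:
        gt_objs = gt[t]
        pr_objs = pred.get(t, [])
        g.append(len(gt_objs))
        matched: dict = {}
        if pr_objs:
            cost = np.empty((len(gt_objs), len(pr_objs)))
            for i, (_, gs) in enumerate(gt_objs):
                for j, (_, ps) in enumerate(pr_objs):
                    cost[i, j] = _match_distance(gs, ps)
            big = 1e12
            gated = np.where(cost <= max_match_dist, cost, big)
            rows, cols = linear_sum_assignment(gated)
            for i, j in zip(rows, cols):
                if gated[i, j] < big / 2:
                    matched[gt_objs[i][0]] = pr_objs[j][0]
        m = 0
        for gid, _ in gt_objs:
            pid = matched.get(gid)
            if pid is None:
                m += 1
            elif gid not in reference:
                reference[gid] = pid
            elif reference[gid] != pid:
                m += 1
        mme.append(m)
    return TrackMatchResult(frames=np.array(frames), mme_t=np.array(mme), g_t=np.array(g))


def detection_recall(
    detections: Sequence,
    truth_skeletons: Sequence[np.ndarray],
    max_dist: float,
    n_points: Optional[int] = None,
) -> float:
    """Fraction of ground-truth skeletons matched by at least one detection
    whose orientation-minimised mean point distance is below ``max_dist``."""
    if len(truth_skeletons) == 0:
        raise ValueError("no ground-truth skeletons")
    hits = 0
    for truth in truth_skeletons:
        tru = np.asarray(truth, dtype=float)
        n = n_points or len(tru)
        tru_r = resample_equal_arclength(tru, n)
        for det in detections:
            skel = resample_equal_arclength(np.asarray(det.skeleton, dtype=float), n)
            if _match_distance(skel, tru_r) < max_dist:
                hits += 1
                break
    return hits / len(truth_skeletons)
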