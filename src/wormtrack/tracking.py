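"""Linking per-frame detections into identity-preserving trajectories.

The full linker solves an optimal bipartite assignment per frame pair with a
cost combining skeleton distance and latent-space distance, and can bridge
short detection gaps.  A greedy centroid nearest-neighbour baseline (no
latents, no gap bridging) is provided for ablation studies.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .predictor import Detection, skeleton_distance

__all__ = ["TrackEntry", "Trajectory", "link_detections", "nearest_neighbour_link"]

_INFEASIBLE = 1e12


@dataclasses.dataclass
class TrackEntry:
    frame: int
    skeleton: np.ndarray
    confidence: float = 1.0
    latent: np.ndarray | None = None


@dataclasses.dataclass
class Trajectory:
    worm_id: int
    entries: list  # of TrackEntry, sorted by frame

    def __post_init__(self):
        frames = [e.frame for e in self.entries]
        if len(set(frames)) != len(frames):
            raise ValueError("at most one entry per frame")
        self.entries.sort(key=lambda e: e.frame)

    @property
    def frames(self) -> np.ndarray:
        return np.array([e.frame for e in self.entries])

    @property
    def last(self) -> TrackEntry:
        return self.entries[-1]

    def skeleton_at(self, frame: int):
        for e in self.entries:
            if e.frame == frame:
                return e.skeleton
        return None


def _entry(frame: int, det: Detection) -> TrackEntry:
    return TrackEntry(
        frame=frame,
        skeleton=np.asarray(det.skeleton, dtype=float),
        confidence=det.confidence,
        latent=None if det.latent is None else np.asarray(det.latent, dtype=float),
    )


def _worm_length(det: Detection) -> float:
    return float(np.linalg.norm(np.diff(det.skeleton, axis=0), axis=1).sum())


def link_detections(
    detections_by_frame: Mapping[int, Sequence[Detection]],
    w_spatial: float = 1.0,
    w_latent: float = 1.0,
    max_gap: int = 12,
    gate_factor: float = 3.0,
) -> list[Trajectory]:
    """Link detections into trajectories by optimal per-frame assignment.

    Cost between a live track and a detection is ``w_spatial`` times the
    orientation-minimised mean skeleton distance plus ``w_latent`` times the
    Euclidean latent distance; pairs further apart than ``gate_factor`` worm
    lengths are forbidden.  Tracks missing up to ``max_gap`` frames remain
    eligible; unmatched detections seed new trajectories.
    """
    if w_spatial < 0 or w_latent < 0:
        raise ValueError("weights must be non-negative")
    frames = sorted(detections_by_frame)
    tracks: list[Trajectory] = []
    next_id = 0
    for t in frames:
        dets = list(detections_by_frame[t])
        live = [
            tr
            for tr in tracks
            if 0 <= t - tr.last.frame - 1 <= max_gap
        ]
        assigned_det = set()
        if live and dets:
            gate = gate_factor * np.median([_worm_length(d) for d in dets])
            cost = np.full((len(live), len(dets)), _INFEASIBLE)
            for i, tr in enumerate(live):
                for j, d in enumerate(dets):
                    sd = skeleton_distance(tr.last.skeleton, d.skeleton)
                    if sd > gate:
                        continue
                    c = w_spatial * sd
                    if w_latent > 0 and tr.last.latent is not None and d.latent is not None:
                        c += w_latent * float(
                            np.linalg.norm(tr.last.latent - d.latent)
                        )
                    cost[i, j] = c
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] >= _INFEASIBLE / 2:
                    continue
                live[i].entries.append(_entry(t, dets[j]))
                assigned_det.add(j)
        for j, d in enumerate(dets):
            if j not in assigned_det:
                tracks.append(Trajectory(worm_id=next_id, entries=[_entry(t, d)]))
                next_id += 1
    return tracks


def nearest_neighbour_link(
    detections_by_frame: Mapping[int, Sequence[Detection]],
    gate_factor: float = 3.0,
) -> list[Trajectory]:
    """Greedy centroid nearest-neighbour baseline.

    Matches each frame against the previous frame only (no gap bridging),
    repeatedly taking the globally closest centroid pair; no latent term.
    """
    frames = sorted(detections_by_frame)
    tracks: list[Trajectory] = []
    next_id = 0
    for t in frames:
        dets = list(detections_by_frame[t])
        live = [tr for tr in tracks if tr.last.frame == t - 1]
        assigned_det = set()
        if live and dets:
            gate = gate_factor * np.median([_worm_length(d) for d in dets])
            dist = np.full((len(live), len(dets)), np.inf)
            for i, tr in enumerate(live):
                tc = tr.last.skeleton.mean(axis=0)
                for j, d in enumerate(dets):
                    dist[i, j] = np.linalg.norm(tc - d.centroid())
            used_track = set()
            while True:
                i, j = np.unravel_index(np.argmin(dist), dist.shape)
                if not np.isfinite(dist[i, j]) or dist[i, j] > gate:
                    break
                live[i].entries.append(_entry(t, dets[j]))
                used_track.add(i)
                assigned_det.add(j)
                dist[i, :] = np.inf
                dist[:, j] = np.inf
                if len(used_track) == len(live) or len(assigned_det) == len(dets):
                    break
        for j, d in enumerate(dets):
            if j not in assigned_det:
                tracks.append(Trajectory(worm_id=next_id, entries=[_entry(t, d)]))
                next_id += 1
    return tracks
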