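"""Skeleton normalisation and the linear (PCA) posture shape space.

A skeleton is an ``(N, 2)`` float array of ordered midline points in pixel
coordinates (``x`` = column, ``y`` = row), first point = head.  The shape
space encodes a skeleton as ``D`` linear coefficients relative to a spatial
offset (usually the centre of the grid cell making the prediction), and
decodes coefficients back into pixel coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "ShapeSpace",
    "resample_equal_arclength",
    "orient_head_tail",
    "orient_track",
    "fit_shape_space",
    "encode",
    "decode",
    "project",
    "pca_residual_rmsd",
]


def _as_skeleton(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"skeleton must be (N, 2), got {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("skeleton needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("skeleton contains non-finite coordinates")
    return pts


def _dedupe(pts: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices (zero-length segments)."""
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    return pts[keep]


def _walk_equal_chords(pts: np.ndarray, chord: float, n_points: int):
    """Place points along the polyline ``pts`` at Euclidean distance ``chord``
    from one another, starting at ``pts[0]``.

    Returns ``(placed, deficit)`` where ``deficit`` > 0 means the walk ended
    before the polyline did (arclength left over), < 0 means the polyline was
    exhausted with steps remaining (shortfall measured in chord units).
    """
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]

    placed = np.empty((n_points, 2))
    placed[0] = pts[0]
    p = pts[0]
    j = 0  # current segment index
    t = 0.0  # fractional position within segment j
    c2 = chord * chord
    for k in range(1, n_points):
        found = False
        while j < len(seg):
            a = pts[j] + t * seg[j]
            d = seg[j] * (1.0 - t)
            # solve ||a + u d - p||^2 = chord^2 for u in (0, 1]
            w = a - p
            A = d @ d
            B = 2.0 * (w @ d)
            C = w @ w - c2
            if A == 0.0:
                j += 1
                t = 0.0
                continue
            disc = B * B - 4.0 * A * C
            if disc >= 0.0:
                u = (-B + np.sqrt(disc)) / (2.0 * A)
                if 0.0 <= u <= 1.0:
                    p = a + u * d
                    t = t + u * (1.0 - t)
                    if t >= 1.0:
                        j += 1
                        t = 0.0
                    placed[k] = p
                    found = True
                    break
            j += 1
            t = 0.0
        if not found:
            # polyline exhausted: shortfall = remaining steps plus how far
            # the endpoint is from closing the current chord
            short = (n_points - k - 1) + np.linalg.norm(pts[-1] - p) / max(chord, 1e-300)
            return placed, -short
    s_last = cum[j] + (t if j < len(seg) else 0.0) * (seglen[j] if j < len(seg) else 0.0)
    return placed, total - s_last


def resample_equal_arclength(points, n_points: int = 49) -> np.ndarray:
    """Resample a polyline to ``n_points`` with equal consecutive chord
    lengths, preserving both endpoints.

    Uses a bisection on the common chord length: points are walked along the
    polyline at a fixed Euclidean step, and the step is tuned until the final
    point lands on the tail endpoint.
    """
    pts = _dedupe(_as_skeleton(points))
    if len(pts) < 2:
        raise ValueError("zero-length skeleton cannot be resampled")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seglen.sum())
    if total <= 0:
        raise ValueError("zero-length skeleton cannot be resampled")

    # fast path: input already has the right count and equal chords
    if len(pts) == n_points:
        chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.ptp(chords) <= 1e-12 * chords.mean():
            return pts.copy()

    hi = total / (n_points - 1)  # chord <= arc, so the solution is <= hi
    lo = np.linalg.norm(pts[-1] - pts[0]) / (n_points - 1)
    lo = min(lo, hi) * 0.5
    # ensure bracket
    for _ in range(60):
        _, f_lo = _walk_equal_chords(pts, max(lo, 1e-300), n_points)
        if f_lo >= 0:
            break
        lo *= 0.5
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        placed, f = _walk_equal_chords(pts, mid, n_points)
        if f > 0:
            lo = mid
        else:
            hi = mid
        if (hi - lo) <= 1e-15 * total:
            break
    placed, _ = _walk_equal_chords(pts, 0.5 * (lo + hi), n_points)
    placed[-1] = pts[-1]
    return placed


def orient_head_tail(skeleton, reference_skeleton=None) -> np.ndarray:
    """Return the skeleton, possibly reversed, oriented against a reference.

    With a reference skeleton, the orientation minimising the point-to-point
    RMSD is chosen; ties (and no reference) leave the input unflipped.
    """
    skel = _as_skeleton(skeleton)
    if reference_skeleton is None:
        return skel.copy()
    ref = _as_skeleton(reference_skeleton)
    if ref.shape != skel.shape:
        raise ValueError("reference skeleton must have the same shape")
    fwd = np.mean(np.sum((skel - ref) ** 2, axis=1))
    rev = np.mean(np.sum((skel[::-1] - ref) ** 2, axis=1))
    return skel[::-1].copy() if rev < fwd else skel.copy()


def orient_track(skeletons: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Orient a time series of skeletons consistently, head first.

    Consecutive frames are flipped to match their predecessor, then a global
    flip is applied so that the endpoint with the larger total frame-to-frame
    displacement (the head, which leads and casts) comes first.
    """
    if len(skeletons) == 0:
        return []
    out = [_as_skeleton(skeletons[0])]
    for s in skeletons[1:]:
        out.append(orient_head_tail(s, out[-1]))
    arr = np.stack(out)
    disp_first = np.linalg.norm(np.diff(arr[:, 0, :], axis=0), axis=1).sum()
    disp_last = np.linalg.norm(np.diff(arr[:, -1, :], axis=0), axis=1).sum()
    if disp_last > disp_first:
        out = [s[::-1].copy() for s in out]
    return out


@dataclasses.dataclass
class ShapeSpace:
    """Linear posture model: mean shape plus an orthonormal basis.

    The first two basis rows are exact x/y translation directions so that a
    skeleton encoded relative to any nearby offset (e.g. a grid-cell centre
    within the assignment cutoff) is representable; the remaining rows are
    principal components of centred shapes, ordered by decreasing explained
    variance.
    """

    mean: np.ndarray  # (2N,) flattened [x0, y0, x1, y1, ...]
    basis: np.ndarray  # (D, 2N), orthonormal rows
    explained_variance: np.ndarray  # (D,)
    n_points: int

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        two_n = 2 * self.n_points
        if self.mean.shape != (two_n,):
            raise ValueError("mean must have length 2*n_points")
        if self.basis.ndim != 2 or self.basis.shape[1] != two_n:
            raise ValueError("basis must be (D, 2*n_points)")
        if self.basis.shape[0] > two_n:
            raise ValueError("D cannot exceed 2*n_points")
        gram = self.basis @ self.basis.T
        if not np.allclose(gram, np.eye(self.basis.shape[0]), atol=1e-8):
            raise ValueError("basis rows must be orthonormal")

    def save(self, path, group: str = "shape_space") -> None:
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("mean", data=self.mean)
            g.create_dataset("basis", data=self.basis)
            g.create_dataset("explained_variance", data=self.explained_variance)
            g.attrs["n_points"] = self.n_points

    @classmethod
    def load(cls, path, group: str = "shape_space") -> "ShapeSpace":
        with h5py.File(path, "r") as f:
            g = f[group]
            return cls(
                mean=g["mean"][...],
                basis=g["basis"][...],
                explained_variance=g["explained_variance"][...],
                n_points=int(g.attrs["n_points"]),
            )


def _translation_rows(n_points: int) -> np.ndarray:
    two_n = 2 * n_points
    tx = np.zeros(two_n)
    ty = np.zeros(two_n)
    tx[0::2] = 1.0 / np.sqrt(n_points)
    ty[1::2] = 1.0 / np.sqrt(n_points)
    return np.vstack([tx, ty])


def fit_shape_space(skeletons, n_components: int = 72) -> ShapeSpace:
    """Fit the posture shape space on normalised skeletons.

    ``skeletons`` is an ``(M, N, 2)`` array (or a sequence of ``(N, 2)``
    arrays of equal N).  Each skeleton is centred on its centroid; the first
    two components are fixed translation directions, the rest are principal
    components of the centred shapes.
    """
    X = np.asarray([_as_skeleton(s) for s in skeletons], dtype=float)
    m, n_points, _ = X.shape
    two_n = 2 * n_points
    if n_components > two_n:
        raise ValueError(f"D={n_components} exceeds 2N={two_n}")
    if m < n_components:
        raise ValueError(
            f"need at least D={n_components} skeletons to fit, got {m}"
        )
    flat = X.reshape(m, two_n)
    centroids = flat.reshape(m, n_points, 2).mean(axis=1)
    flat = flat - np.repeat(centroids, n_points, axis=0).reshape(m, two_n)
    mean = flat.mean(axis=0)
    xc = flat - mean

    trans = _translation_rows(n_points)
    # centred data is orthogonal to translations by construction;
    # SVD gives shape components ordered by decreasing variance
    _, svals, vt = np.linalg.svd(xc, full_matrices=True)
    var = np.zeros(vt.shape[0])
    var[: len(svals)] = svals**2 / max(m - 1, 1)

    rows = [trans[0], trans[1]]
    variances = [0.0, 0.0]
    for r, v in zip(vt, var):
        if len(rows) == n_components:
            break
        # re-orthogonalise against everything kept so far (null-space rows
        # returned by the SVD are not guaranteed orthogonal to translations)
        q = r.copy()
        for b in rows:
            q -= (q @ b) * b
        nq = np.linalg.norm(q)
        if nq < 1e-10:
            continue
        rows.append(q / nq)
        variances.append(v)
    # degenerate data may not span D directions: complete with unit vectors
    i = 0
    while len(rows) < n_components and i < two_n:
        q = np.zeros(two_n)
        q[i] = 1.0
        for b in rows:
            q -= (q @ b) * b
        nq = np.linalg.norm(q)
        if nq > 1e-10:
            rows.append(q / nq)
            variances.append(0.0)
        i += 1

    return ShapeSpace(
        mean=mean,
        basis=np.vstack(rows),
        explained_variance=np.asarray(variances),
        n_points=n_points,
    )


def encode(skeleton, space: ShapeSpace, offset=(0.0, 0.0)) -> np.ndarray:
    """Encode a skeleton as ``D`` coefficients relative to ``offset``."""
    skel = _as_skeleton(skeleton)
    if skel.shape[0] != space.n_points:
        raise ValueError(
            f"skeleton has {skel.shape[0]} points, shape space expects {space.n_points}"
        )
    off = np.asarray(offset, dtype=float)
    v = (skel - off).reshape(-1) - space.mean
    return space.basis @ v


def decode(coeffs, space: ShapeSpace, offset=(0.0, 0.0)) -> np.ndarray:
    """Decode ``D`` coefficients back into an ``(N, 2)`` skeleton."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (space.n_components,):
        raise ValueError(
            f"expected {space.n_components} coefficients, got {c.shape}"
        )
    v = space.mean + space.basis.T @ c
    return v.reshape(space.n_points, 2) + np.asarray(offset, dtype=float)


def project(skeleton, space: ShapeSpace, offset=(0.0, 0.0)) -> np.ndarray:
    """Round-trip a skeleton through the shape space (its PCA projection)."""
    return decode(encode(skeleton, space, offset), space, offset)


def pca_residual_rmsd(skeleton, space: ShapeSpace, offset=(0.0, 0.0)) -> float:
    """Per-skeleton truncation error: RMSD between a skeleton and its
    shape-space projection."""
    skel = _as_skeleton(skeleton)
    rec = project(skel, space, offset)
    return float(np.sqrt(np.mean(np.sum((rec - skel) ** 2, axis=1))))
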