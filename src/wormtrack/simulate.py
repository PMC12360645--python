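"""Synthetic crawling-worm video generation with ground-truth skeletons.

Worms are path followers: the head traces a smooth, undulating path and the
body occupies a fixed arclength of that path behind the head, which makes the
midline inextensible by construction.  Rendering draws each worm as a dark,
tapered tube on a static non-uniform background (lawn gradient plus egg-like
blobs), so a rank-1 SVD background model can recover the background exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "WormState",
    "Recording",
    "Clip",
    "make_background",
    "simulate_recording",
    "sample_clip",
    "synthesize_overlaps",
    "width_profile",
]

DEFAULT_FPS = 25.0
DEFAULT_PIXEL_SIZE_UM = 12.4


@dataclasses.dataclass
class WormState:
    """Instantaneous state of one simulated worm."""

    midline: np.ndarray  # (N, 2) ordered points, head first (x, y) px
    width_profile: np.ndarray  # (N,) half-width per point, px
    phase: float  # undulation phase, rad
    speed: float  # centroid speed, px/frame

    def __post_init__(self):
        self.midline = np.asarray(self.midline, dtype=float)
        self.width_profile = np.asarray(self.width_profile, dtype=float)
        if self.midline.ndim != 2 or self.midline.shape[1] != 2:
            raise ValueError("midline must be (N, 2)")
        if self.midline.shape[0] < 3:
            raise ValueError("midline needs at least 3 points")
        if self.width_profile.shape != (self.midline.shape[0],):
            raise ValueError("width_profile must match midline length")
        if np.any(self.width_profile <= 0):
            raise ValueError("widths must be positive")


@dataclasses.dataclass
class Recording:
    """A simulated video plus per-frame ground truth for every worm."""

    frames: np.ndarray  # (T, H, W) float32
    skeletons: np.ndarray  # (T, n_worms, N, 2) float, (x, y) px
    background: np.ndarray  # (H, W) float32, the true static background
    fps: float = DEFAULT_FPS
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    worm_contrast: float = 0.5

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_worms(self) -> int:
        return self.skeletons.shape[1]


@dataclasses.dataclass
class Clip:
    """A short frame stack with the 3 central frames annotated.

    ``annotations`` is a list of ``(worm_id, frame_index, skeleton)`` tuples
    where ``frame_index`` is local to the clip and restricted to the 3
    central frames.
    """

    frames: np.ndarray  # (T, H, W)
    annotations: list  # [(worm_id, frame_index, (N, 2) array), ...]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    fps: float = DEFAULT_FPS

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        t, h, w = self.frames.shape
        if t % 2 == 0:
            raise ValueError("clip length T must be odd")
        if h <= 0 or w <= 0:
            raise ValueError("empty frames")
        lo, hi = self.central_frames
        for _, fi, _ in self.annotations:
            if not (lo <= fi <= hi):
                raise ValueError(
                    f"annotation frame {fi} outside central frames [{lo}, {hi}]"
                )

    @property
    def central_frames(self) -> tuple[int, int]:
        """Inclusive (first, last) indices of the 3 annotated central frames."""
        t = self.frames.shape[0]
        lo = (t - 3) // 2
        return lo, lo + 2

    def worm_ids(self) -> list:
        seen = []
        for wid, _, _ in self.annotations:
            if wid not in seen:
                seen.append(wid)
        return seen


def width_profile(n_points: int, max_half_width: float) -> np.ndarray:
    """Tapered half-width profile: widest mid-body, near zero at both ends."""
    u = np.linspace(0.0, 1.0, n_points)
    w = max_half_width * np.sin(np.pi * u) ** 0.6
    return np.maximum(w, 0.05)


def make_background(
    shape: tuple[int, int],
    rng: np.random.Generator,
    base_level: float = 0.75,
    lawn_amplitude: float = 0.08,
    n_eggs: int = 25,
    egg_depth: float = 0.18,
) -> np.ndarray:
    """Static non-uniform background: smooth lawn-edge gradient plus dark
    egg-like Gaussian blobs."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx = w * rng.uniform(0.3, 0.7)
    cy = h * rng.uniform(0.3, 0.7)
    r = np.hypot(xx - cx, yy - cy)
    bg = base_level - lawn_amplitude * (r / max(h, w))
    bg += lawn_amplitude * 0.3 * np.sin(2 * np.pi * xx / w) * np.cos(2 * np.pi * yy / h)
    for _ in range(n_eggs):
        ex, ey = rng.uniform(0, w), rng.uniform(0, h)
        sx = rng.uniform(1.5, 3.0)
        sy = sx * rng.uniform(0.5, 0.9)
        th = rng.uniform(0, np.pi)
        dx, dy = xx - ex, yy - ey
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        bg -= egg_depth * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    return np.clip(bg, 0.05, 1.0).astype(np.float32)


class _PathWorm:
    """Head-path follower with serpenoid-style heading oscillation."""

    def __init__(
        self,
        rng: np.random.Generator,
        frame_shape: tuple[int, int],
        length: float,
        n_points: int,
        max_half_width: float,
        speed: float,
        omega: float,
        amplitude: float,
        coiling: bool,
        dwell_prob: float,
        head_cast_amp: float,
    ):
        self.frame_shape = frame_shape
        self.length = length
        self.n_points = n_points
        self.widths = width_profile(n_points, max_half_width)
        self.speed0 = speed
        self.omega = omega
        self.amplitude = amplitude
        self.coiling = coiling
        self.dwell_prob = dwell_prob
        self.head_cast_amp = head_cast_amp
        self.rng = rng

        h, w = frame_shape
        margin = length + 4 * max_half_width
        if w <= 2 * margin or h <= 2 * margin:
            raise ValueError(
                f"frame {frame_shape} too small for a worm of length {length}"
            )
        head = np.array(
            [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
        )
        self.heading = rng.uniform(0, 2 * np.pi)
        self.phase = rng.uniform(0, 2 * np.pi)
        self.t = 0
        self.dwelling = False
        # seed a gently curved initial path, comfortably longer than the body
        step = length / (4 * n_points)
        n_init = int(np.ceil(1.5 * length / step)) + 2
        pts = [head.copy()]
        ang = self.heading + np.pi  # walk backwards from the head
        for _ in range(n_init):
            ang += rng.normal(0, 0.02) + 0.1 * self.amplitude * np.sin(
                self.phase
            ) * step / length * 2 * np.pi
            pts.append(pts[-1] + step * np.array([np.cos(ang), np.sin(ang)]))
        self.path = np.array(pts[::-1])  # oldest first, head last

    def step(self):
        self.t += 1
        self.phase += self.omega
        if self.dwell_prob > 0:
            if self.dwelling and self.rng.random() < 0.05:
                self.dwelling = False
            elif not self.dwelling and self.rng.random() < self.dwell_prob:
                self.dwelling = True
        speed = 0.0 if self.dwelling else self.speed0
        turn = self.rng.normal(0, 0.02)
        if self.coiling:
            turn += 2.5 * np.pi * speed / self.length  # curl radius < L/2pi
        # steer away from frame edges
        head = self.path[-1]
        h, w = self.frame_shape
        margin = self.length * 0.8
        if (
            head[0] < margin
            or head[0] > w - margin
            or head[1] < margin
            or head[1] > h - margin
        ):
            centre = np.array([w / 2, h / 2])
            want = np.arctan2(*(centre - head)[::-1])
            diff = (want - self.heading + np.pi) % (2 * np.pi) - np.pi
            turn += np.clip(diff, -0.15, 0.15)
        self.heading += turn
        if speed > 0:
            ang = self.heading + self.amplitude * np.sin(self.phase)
            new_head = head + speed * np.array([np.cos(ang), np.sin(ang)])
            self.path = np.vstack([self.path, new_head])
            max_keep = int(5 * self.length / max(speed, 1e-6)) + 10
            if len(self.path) > max_keep:
                self.path = self.path[-max_keep:]

    def skeleton(self) -> np.ndarray:
        """Sample the body at equal arclength spacing back along the head
        path (inextensible up to chord-vs-arc curvature effects), with an
        optional small head-cast wiggle decaying toward the tail."""
        path = self.path
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s_head = cum[-1]
        targets = s_head - np.linspace(0.0, self.length, self.n_points)
        targets = np.clip(targets, 0.0, s_head)
        skel = np.column_stack(
            [np.interp(targets, cum, path[:, 0]), np.interp(targets, cum, path[:, 1])]
        )
        if self.head_cast_amp > 0:
            t = self.t
            amp = self.head_cast_amp
            tangent = skel[0] - skel[1]
            tangent = tangent / max(np.linalg.norm(tangent), 1e-12)
            normal = np.array([-tangent[1], tangent[0]])
            off = (
                amp * (np.sin(0.55 * t) + 0.5 * np.sin(0.93 * t + 1.0)) * normal
                + 0.5 * amp * np.cos(0.71 * t) * tangent
            )
            decay = np.exp(-np.arange(self.n_points) / (self.n_points / 6))
            skel = skel + off[None, :] * decay[:, None]
        return skel

    def state(self) -> WormState:
        return WormState(
            midline=self.skeleton(),
            width_profile=self.widths.copy(),
            phase=self.phase % (2 * np.pi),
            speed=0.0 if self.dwelling else self.speed0,
        )


def render_worm(
    frame: np.ndarray,
    skeleton: np.ndarray,
    widths: np.ndarray,
    contrast: float,
    edge: float = 1.0,
) -> None:
    """Subtract a dark tapered tube along ``skeleton`` from ``frame`` in
    place.  Pixels outside midline +/- width are untouched."""
    h, w = frame.shape
    wmax = float(widths.max())
    x0 = max(int(np.floor(skeleton[:, 0].min() - wmax - 1)), 0)
    x1 = min(int(np.ceil(skeleton[:, 0].max() + wmax + 1)) + 1, w)
    y0 = max(int(np.floor(skeleton[:, 1].min() - wmax - 1)), 0)
    y1 = min(int(np.ceil(skeleton[:, 1].max() + wmax + 1)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    px = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    # densify the midline so nearest-point distance approximates (from
    # above) the distance to the polyline; over-estimating keeps rendered
    # pixels strictly inside the midline +/- width tube
    seg = np.linalg.norm(np.diff(skeleton, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s_dense = np.linspace(0.0, total, max(int(total / 0.25), 2))
    dense = np.column_stack(
        [np.interp(s_dense, cum, skeleton[:, 0]), np.interp(s_dense, cum, skeleton[:, 1])]
    )
    w_dense = np.interp(s_dense, cum, widths)
    dmin, j = cKDTree(dense).query(px)
    cov = np.clip((w_dense[j] - dmin) / edge, 0.0, 1.0)
    dip = (contrast * cov).reshape(y1 - y0, x1 - x0)
    frame[y0:y1, x0:x1] = np.maximum(frame[y0:y1, x0:x1] - dip, 0.0)


def simulate_recording(
    n_worms: int,
    duration_s: float,
    fps: float = DEFAULT_FPS,
    frame_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    worm_length: float = 80.0,
    n_points: int = 49,
    max_half_width: float = 2.0,
    contrast: float = 0.5,
    speed: float = 1.2,
    omega: float = 0.25,
    amplitude: float = 0.5,
    coiling: bool = False,
    dwell_prob: float = 0.0,
    head_cast_amp: float = 0.0,
    noise_sigma: float = 0.0,
    background: Optional[np.ndarray] = None,
    background_spec: Optional[dict] = None,
) -> Recording:
    """Simulate a recording of crawling worms on a static background.

    Deterministic for a given seed.  Raises ``ValueError`` when a worm of the
    requested length cannot be placed inside the frame.
    """
    if n_worms < 0:
        raise ValueError("n_worms must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    if background is None:
        background = make_background(frame_shape, rng, **(background_spec or {}))
    else:
        background = np.asarray(background, dtype=np.float32)
        if background.shape != tuple(frame_shape):
            raise ValueError("background shape mismatch")

    worms = [
        _PathWorm(
            rng,
            frame_shape,
            worm_length,
            n_points,
            max_half_width,
            speed,
            omega,
            amplitude,
            coiling,
            dwell_prob,
            head_cast_amp,
        )
        for _ in range(n_worms)
    ]

    frames = np.empty((n_frames,) + tuple(frame_shape), dtype=np.float32)
    skeletons = np.zeros((n_frames, n_worms, n_points, 2), dtype=float)
    for t in range(n_frames):
        frame = background.astype(np.float64).copy()
        for i, worm in enumerate(worms):
            skel = worm.skeleton()
            skeletons[t, i] = skel
            render_worm(frame, skel, worm.widths, contrast)
            worm.step()
        if noise_sigma > 0:
            frame = frame + rng.normal(0, noise_sigma, frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)
    return Recording(
        frames=frames,
        skeletons=skeletons,
        background=background,
        fps=fps,
        worm_contrast=contrast,
    )


def sample_clip(
    recording: Recording,
    duration_s: float,
    n_frames: int = 11,
    start: int = 0,
) -> Clip:
    """Extract ``n_frames`` uniformly spaced frames spanning ``duration_s``,
    annotating the 3 central sampled frames with ground-truth skeletons."""
    if n_frames % 2 == 0 or n_frames < 3:
        raise ValueError("n_frames must be odd and >= 3")
    span = duration_s * recording.fps
    stride = int(round(span / (n_frames - 1)))
    if stride < 1:
        raise ValueError("duration too short for the requested frame count")
    indices = start + stride * np.arange(n_frames)
    if indices[-1] >= recording.n_frames:
        raise ValueError(
            f"recording of {recording.n_frames} frames too short for a "
            f"{duration_s} s clip starting at frame {start}"
        )
    frames = recording.frames[indices]
    lo = (n_frames - 3) // 2
    annotations = []
    for k in range(3):
        src = indices[lo + k]
        for wid in range(recording.n_worms):
            annotations.append((wid, lo + k, recording.skeletons[src, wid].copy()))
    return Clip(
        frames=frames,
        annotations=annotations,
        pixel_size_um=recording.pixel_size_um,
        fps=recording.fps,
    )


def make_single_worm_clips(
    n_clips: int,
    seed: int = 0,
    frame_shape: tuple[int, int] = (64, 64),
    worm_length: float = 22.0,
    n_points: int = 17,
    max_half_width: float = 1.5,
    contrast: float = 0.6,
    clip_length: int = 11,
) -> list[Clip]:
    """Generate background-subtracted single-worm clips for desk-scale
    training: one short recording per clip, true background removed."""
    clips = []
    rng = np.random.default_rng(seed)
    duration = clip_length / DEFAULT_FPS
    for _ in range(n_clips):
        rec = simulate_recording(
            1,
            duration + 0.2,
            seed=int(rng.integers(0, 2**31 - 1)),
            frame_shape=frame_shape,
            worm_length=worm_length,
            n_points=n_points,
            max_half_width=max_half_width,
            contrast=contrast,
        )
        clip = sample_clip(rec, (clip_length - 1) / rec.fps, clip_length)
        residual = clip.frames.astype(np.float64) - rec.background[None]
        clips.append(
            Clip(
                frames=residual.astype(np.float32),
                annotations=clip.annotations,
                pixel_size_um=clip.pixel_size_um,
                fps=clip.fps,
            )
        )
    return clips


def synthesize_overlaps(clip_pool: Sequence[Clip], seed: int = 0) -> list[Clip]:
    """Pair clips at random and stack each pair into one overlap clip.

    Clips must be background-subtracted (worms are negative dips), so the
    pixelwise minimum mimics optical occlusion.  Returns ``len(pool) // 2``
    clips; the pairing changes with the seed.
    """
    if len(clip_pool) < 2:
        raise ValueError("need at least 2 clips to synthesise overlaps")
    shape = clip_pool[0].frames.shape
    for c in clip_pool:
        if c.frames.shape != shape:
            raise ValueError("all clips in the pool must share a frame shape")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clip_pool))
    out = []
    for k in range(len(clip_pool) // 2):
        a = clip_pool[order[2 * k]]
        b = clip_pool[order[2 * k + 1]]
        frames = np.minimum(a.frames, b.frames)
        ann = [((0, wid), fi, skel) for wid, fi, skel in a.annotations]
        ann += [((1, wid), fi, skel) for wid, fi, skel in b.annotations]
        out.append(
            Clip(
                frames=frames,
                annotations=ann,
                pixel_size_um=a.pixel_size_um,
                fps=a.fps,
            )
        )
    return out
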