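"""Tiny trainable reference predictor.

A deliberately small stand-in that exercises the grid training/decoding
contract at desk scale: one hidden-layer perceptron applied convolutionally
(shared weights across grid cells) to a patch around each cell centre of the
3 central frames of a background-subtracted clip.  It is trained with Adam
on a confidence cross-entropy, a masked coefficient regression, and a latent
consistency term, all implemented in numpy with manual gradients.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import h5py
import numpy as np

from .predictor import (
    GridGeometry,
    PredictionGrid,
    TargetTensors,
    assign_targets,
    pad_to_multiple,
)
from .shapespace import ShapeSpace

__all__ = ["TinyWormNet", "mini_train", "predict_clip", "extract_cell_features"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def extract_cell_features(
    frames: np.ndarray,
    geometry: GridGeometry,
    central: tuple[int, int, int],
    window: int = 64,
    pool: int = 2,
) -> np.ndarray:
    """Per-cell input features: a ``window x window`` patch of the 3 central
    (background-subtracted) frames centred on each cell centre, mean-pooled
    by ``pool`` and sign-flipped so worms are positive.

    Returns ``(Gy * Gx, 3 * (window // pool) ** 2)`` float32.
    """
    sub = -np.asarray(frames, dtype=np.float32)[list(central)]
    half = window // 2
    padded = np.pad(sub, ((0, 0), (half, half), (half, half)))
    gy, gx = geometry.grid_shape
    centers = geometry.cell_centers()
    m = window // pool
    feats = np.empty((gy * gx, 3 * m * m), dtype=np.float32)
    idx = 0
    for i in range(gy):
        for j in range(gx):
            cx, cy = centers[i, j]
            x0 = int(round(cx))  # + half - half
            y0 = int(round(cy))
            patch = padded[:, y0 : y0 + window, x0 : x0 + window]
            pooled = patch.reshape(3, m, pool, m, pool).mean(axis=(2, 4))
            feats[idx] = pooled.reshape(-1)
            idx += 1
    return feats


@dataclasses.dataclass
class TinyWormNet:
    """Weights plus the geometry/normalisation needed to apply them."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    coeff_scale: np.ndarray  # (3, D) target scaling
    cell_size: int
    n_slots: int
    latent_dim: int
    n_coeffs: int
    window: int
    pool: int
    feature_gain: float  # input scaling applied before the first layer

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]

    def _split(self, out: np.ndarray):
        k, d, l = self.n_slots, self.n_coeffs, self.latent_dim
        n = out.shape[0]
        conf = out[:, :k]
        coeff = out[:, k : k + k * 3 * d].reshape(n, k, 3, d)
        latent = out[:, k + k * 3 * d :].reshape(n, k, l)
        return conf, coeff, latent

    def forward(self, x: np.ndarray):
        z1 = x * self.feature_gain @ self.w1 + self.b1
        h = np.maximum(z1, 0.0)
        out = h @ self.w2 + self.b2
        return z1, h, out

    def save(self, path) -> None:
        with h5py.File(path, "a") as f:
            if "model" in f:
                del f["model"]
            g = f.create_group("model")
            for name in ("w1", "b1", "w2", "b2", "coeff_scale"):
                g.create_dataset(name, data=getattr(self, name))
            for name in (
                "cell_size",
                "n_slots",
                "latent_dim",
                "n_coeffs",
                "window",
                "pool",
            ):
                g.attrs[name] = getattr(self, name)
            g.attrs["feature_gain"] = self.feature_gain

    @classmethod
    def load(cls, path) -> "TinyWormNet":
        with h5py.File(path, "r") as f:
            g = f["model"]
            return cls(
                w1=g["w1"][...],
                b1=g["b1"][...],
                w2=g["w2"][...],
                b2=g["b2"][...],
                coeff_scale=g["coeff_scale"][...],
                cell_size=int(g.attrs["cell_size"]),
                n_slots=int(g.attrs["n_slots"]),
                latent_dim=int(g.attrs["latent_dim"]),
                n_coeffs=int(g.attrs["n_coeffs"]),
                window=int(g.attrs["window"]),
                pool=int(g.attrs["pool"]),
                feature_gain=float(g.attrs["feature_gain"]),
            )


def _init_model(
    n_features: int,
    n_coeffs: int,
    hidden: int,
    n_slots: int,
    latent_dim: int,
    cell_size: int,
    window: int,
    pool: int,
    feature_gain: float,
    rng: np.random.Generator,
) -> TinyWormNet:
    n_out = n_slots * (1 + 3 * n_coeffs + latent_dim)
    w1 = rng.normal(0, np.sqrt(2.0 / n_features), (n_features, hidden))
    w2 = rng.normal(0, np.sqrt(1.0 / hidden), (hidden, n_out))
    b1 = np.zeros(hidden)
    b2 = np.zeros(n_out)
    # calibrate the confidence prior toward "no worm" so an untrained model
    # makes no detections at the 0.5 threshold
    b2[:n_slots] = -4.0
    return TinyWormNet(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        coeff_scale=np.ones((3, n_coeffs)),
        cell_size=cell_size,
        n_slots=n_slots,
        latent_dim=latent_dim,
        n_coeffs=n_coeffs,
        window=window,
        pool=pool,
        feature_gain=feature_gain,
    )


def _prepare_dataset(
    clips,
    space: ShapeSpace,
    cell_size: int,
    cutoff: float,
    n_slots: int,
    window: int,
    pool: int,
):
    """Stack per-cell features, targets and latent groups over all clips."""
    xs, confs, coeffs, groups = [], [], [], []
    group_of: dict = {}
    for ci, clip in enumerate(clips):
        padded, info = pad_to_multiple(clip.frames, cell_size)
        geometry = GridGeometry(info.padded_shape, cell_size)
        lo, hi = clip.central_frames
        targets: TargetTensors = assign_targets(
            clip.annotations, geometry, space, cutoff=cutoff, n_slots=n_slots
        )
        x = extract_cell_features(padded, geometry, (lo, lo + 1, hi), window, pool)
        gy, gx = geometry.grid_shape
        conf = targets.confidence.reshape(gy * gx, n_slots)
        coeff = targets.coeffs.reshape(gy * gx, n_slots, 3, -1)
        grp = np.full(gy * gx, -1, dtype=int)
        flat_ids = targets.worm_ids.reshape(gy * gx, n_slots)
        for c in range(gy * gx):
            wid = flat_ids[c, 0]
            if wid is not None:
                key = (ci, wid)
                group_of.setdefault(key, len(group_of))
                grp[c] = group_of[key]
        xs.append(x)
        confs.append(conf)
        coeffs.append(coeff)
        groups.append(grp)
    return (
        np.concatenate(xs),
        np.concatenate(confs),
        np.concatenate(coeffs),
        np.concatenate(groups),
    )


def mini_train(
    clips: Sequence,
    space: ShapeSpace,
    epochs: int = 60,
    seed: int = 0,
    learning_rate: float = 1e-3,
    hidden: int = 96,
    n_slots: int = 2,
    latent_dim: int = 4,
    cell_size: int = 16,
    cutoff: float = 24.0,
    window: int = 64,
    pool: int = 2,
    batch_size: int = 512,
    coeff_weight: float = 1.0,
    latent_weight: float = 0.05,
):
    """Train the tiny reference predictor on background-subtracted clips.

    Returns ``(model, history)`` where ``history`` is the list of per-epoch
    mean losses.  Deterministic for a fixed seed.
    """
    if len(clips) == 0:
        raise ValueError("no clips to train on")
    shape = clips[0].frames.shape
    for c in clips:
        if c.frames.shape != shape:
            raise ValueError("all training clips must share a frame shape")
    rng = np.random.default_rng(seed)

    x, conf_t, coeff_t, groups = _prepare_dataset(
        clips, space, cell_size, cutoff, n_slots, window, pool
    )
    # scale coefficient targets to unit spread so the MSE is balanced
    mask = conf_t > 0.5
    if mask.any():
        assigned = coeff_t[mask]  # (n_assigned, 3, D)
        scale = assigned.std(axis=0)
        scale[scale < 1e-6] = 1.0
    else:
        scale = np.ones(coeff_t.shape[2:])
    coeff_t = coeff_t / scale
    gain = 1.0 / max(float(np.abs(x).max()), 1e-6)

    model = _init_model(
        x.shape[1],
        coeff_t.shape[-1],
        hidden,
        n_slots,
        latent_dim,
        cell_size,
        window,
        pool,
        gain,
        rng,
    )
    model.coeff_scale = scale

    params = ["w1", "b1", "w2", "b2"]
    m_adam = {p: np.zeros_like(getattr(model, p)) for p in params}
    v_adam = {p: np.zeros_like(getattr(model, p)) for p in params}
    step = 0
    n = x.shape[0]
    k, d, l = n_slots, coeff_t.shape[-1], latent_dim
    history = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s0 in range(0, n, batch_size):
            idx = order[s0 : s0 + batch_size]
            xb = x[idx].astype(np.float64)
            cb = conf_t[idx]
            tb = coeff_t[idx]
            gb = groups[idx]
            z1, h, out = model.forward(xb)
            conf_logit, coeff, latent = model._split(out)

            p = _sigmoid(conf_logit)
            loss_conf = float(
                np.mean(
                    np.logaddexp(0.0, conf_logit) - cb * conf_logit
                )
            )
            d_conf = (p - cb) / cb.size

            mb = cb > 0.5
            n_assigned = max(int(mb.sum()), 1)
            diff = (coeff - tb) * mb[:, :, None, None]
            loss_coeff = float(np.sum(diff**2) / (n_assigned * 3 * d))
            d_coeff = coeff_weight * 2.0 * diff / (n_assigned * 3 * d)

            d_latent = np.zeros_like(latent)
            loss_lat = 0.0
            live = gb >= 0
            if live.any():
                z0 = latent[:, 0, :]
                uniq = np.unique(gb[live])
                cnt = 0
                for g in uniq:
                    sel = gb == g
                    if sel.sum() < 2:
                        continue
                    zg = z0[sel]
                    dev = zg - zg.mean(axis=0)
                    loss_lat += float(np.sum(dev**2))
                    d_latent[sel, 0, :] += 2.0 * dev
                    cnt += sel.sum()
                if cnt:
                    loss_lat /= cnt * l
                    d_latent /= cnt * l

            loss = loss_conf + coeff_weight * loss_coeff + latent_weight * loss_lat
            losses.append(loss)

            d_out = np.concatenate(
                [
                    d_conf,
                    d_coeff.reshape(len(idx), -1),
                    (latent_weight * d_latent).reshape(len(idx), -1),
                ],
                axis=1,
            )
            g_w2 = h.T @ d_out
            g_b2 = d_out.sum(axis=0)
            d_h = d_out @ model.w2.T
            d_z1 = d_h * (z1 > 0)
            g_w1 = (xb * gain).T @ d_z1
            g_b1 = d_z1.sum(axis=0)
            grads = {"w1": g_w1, "b1": g_b1, "w2": g_w2, "b2": g_b2}

            step += 1
            for pname in params:
                g = grads[pname]
                m_adam[pname] = 0.9 * m_adam[pname] + 0.1 * g
                v_adam[pname] = 0.999 * v_adam[pname] + 0.001 * g * g
                mhat = m_adam[pname] / (1 - 0.9**step)
                vhat = v_adam[pname] / (1 - 0.999**step)
                setattr(
                    model,
                    pname,
                    getattr(model, pname)
                    - learning_rate * mhat / (np.sqrt(vhat) + 1e-8),
                )
        history.append(float(np.mean(losses)))
    return model, history


def predict_clip(
    model: TinyWormNet, clip, space: Optional[ShapeSpace] = None
) -> PredictionGrid:
    """Run the reference predictor on one background-subtracted clip and
    return the raw prediction grid."""
    padded, info = pad_to_multiple(clip.frames, model.cell_size)
    geometry = GridGeometry(info.padded_shape, model.cell_size)
    lo, hi = clip.central_frames
    x = extract_cell_features(
        padded, geometry, (lo, lo + 1, hi), model.window, model.pool
    )
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"clip produces {x.shape[1]} features per cell, model expects "
            f"{model.n_features}"
        )
    if space is not None and space.n_components != model.n_coeffs:
        raise ValueError("shape-space dimension does not match the model")
    _, _, out = model.forward(x.astype(np.float64))
    conf_logit, coeff, latent = model._split(out)
    gy, gx = geometry.grid_shape
    return PredictionGrid(
        coeffs=(coeff * model.coeff_scale).reshape(
            gy, gx, model.n_slots, 3, model.n_coeffs
        ),
        confidence=_sigmoid(conf_logit).reshape(gy, gx, model.n_slots),
        latent=latent.reshape(gy, gx, model.n_slots, model.latent_dim),
        geometry=geometry,
    )
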