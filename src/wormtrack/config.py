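"""Run configuration: every tunable default in one place, with YAML I/O."""

from __future__ import annotations

import dataclasses

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclasses.dataclass
class RunConfig:
    # detection / grid
    conf_threshold: float = 0.5  # decode threshold on slot confidence
    cutoff: float = 48.0  # px, centroid-to-cell-centre assignment radius
    cell_size: int = 16  # px per grid cell
    n_components: int = 72  # shape-space dimension D
    n_slots: int = 8  # max skeletons per cell K
    latent_dim: int = 8  # latent vector length L
    clip_length: int = 11  # frames per clip T
    n_points: int = 49  # skeleton points N
    min_separation: float = 12.0  # px, duplicate-detection suppression radius
    # video
    subsample_step: int = 400  # background SVD temporal subsampling
    downsample: int = 3  # inference temporal downsampling 1:k
    fps: float = 25.0
    pixel_size_um: float = 12.4
    # tracking / interpolation
    max_gap: int = 12  # frames a track may skip and still be linked
    spline_max_gap: int = 25  # frames; longer gaps split the trajectory
    w_spatial: float = 1.0
    w_latent: float = 1.0

    def validate(self) -> "RunConfig":
        for name in (
            "conf_threshold",
            "cutoff",
            "cell_size",
            "n_components",
            "n_slots",
            "latent_dim",
            "clip_length",
            "n_points",
            "min_separation",
            "subsample_step",
            "downsample",
            "fps",
            "pixel_size_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_components > 2 * self.n_points:
            raise ValueError(
                f"n_components={self.n_components} exceeds 2*n_points="
                f"{2 * self.n_points}"
            )
        if self.clip_length % 2 == 0:
            raise ValueError("clip_length must be odd")
        if self.w_spatial < 0 or self.w_latent < 0:
            raise ValueError("tracking weights must be non-negative")
        return self


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data).validate()
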