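"""Labeled synthetic dataset generation.

Defaults are tuned so a 64**3 volume carries a vessel fraction of order
2% with centerline and bifurcation fractions one-plus orders of magnitude
smaller, mimicking the extreme class imbalance of angiographic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..volume import Volume3D
from .raster import bifurcation_mask, rasterize_centerline, render_intensities, voxelize
from .tree import VesselTree, sample_tree

__all__ = ["SynthConfig", "LabeledVolume", "generate_volume", "generate_dataset", "class_fractions"]


@dataclass
class SynthConfig:
    """Knobs for tree growth, rasterization, and intensity rendering."""

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    root_radius: tuple[float, float] = (2.0, 3.0)
    gamma: float = 3.0
    asymmetry_range: tuple[float, float] = (0.6, 1.0)
    length_ratio: float = 7.0
    length_jitter: float = 0.25
    min_terminal_radius: float = 0.7
    radius_scale: float = 1.0
    trees_per_volume: int = 3
    max_nodes: int = 2000
    vessel_intensity: tuple[float, float] = (128.0, 255.0)
    background_intensity: tuple[float, float] = (0.0, 100.0)
    noise: bool = True
    noise_mean: tuple[float, float] = (-5.0, 5.0)
    noise_std_offset: tuple[float, float] = (-15.0, 30.0)
    base_noise_std: float = 20.0
    bifurcation_cube: int = 5
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 1:
            raise ValueError(f"invalid volume shape {self.volume_shape}")
        for name in (
            "root_radius",
            "asymmetry_range",
            "vessel_intensity",
            "background_intensity",
            "noise_mean",
            "noise_std_offset",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval {lo, hi} is not well-ordered")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.length_ratio <= 0:
            raise ValueError("length_ratio must be positive")
        if not 0 <= self.length_jitter < 1:
            raise ValueError("length_jitter must lie in [0, 1)")
        if self.min_terminal_radius <= 0:
            raise ValueError("min_terminal_radius must be positive")
        if self.trees_per_volume < 1:
            raise ValueError("trees_per_volume must be >= 1")
        if self.bifurcation_cube < 1 or self.bifurcation_cube % 2 == 0:
            raise ValueError("bifurcation_cube must be odd and >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class LabeledVolume:
    """An intensity image plus the three binary ground-truth masks."""

    image: Volume3D
    vessel_mask: Volume3D
    centerline_mask: Volume3D
    bifurcation_mask: Volume3D
    trees: list[VesselTree] = field(default_factory=list)
    seed: int | None = None

    def fractions(self) -> dict[str, float]:
        return class_fractions(self)


def class_fractions(volume: LabeledVolume) -> dict[str, float]:
    n = volume.vessel_mask.data.size
    return {
        "vessel": float(np.count_nonzero(volume.vessel_mask.data)) / n,
        "centerline": float(np.count_nonzero(volume.centerline_mask.data)) / n,
        "bifurcation": float(np.count_nonzero(volume.bifurcation_mask.data)) / n,
    }


def generate_volume(config: SynthConfig, seed=None) -> LabeledVolume:
    """Grow trees, rasterize all three label masks, and render the image."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    tree_seeds = ss.spawn(config.trees_per_volume)
    render_seed = ss.spawn(1)[0]
    shape = config.volume_shape

    trees = [sample_tree(config, s) for s in tree_seeds]
    vessel = np.zeros(shape, dtype=bool)
    center = np.zeros(shape, dtype=bool)
    bif = np.zeros(shape, dtype=bool)
    for tree in trees:
        vessel |= voxelize(tree, shape)
        center |= rasterize_centerline(tree, shape)
        bif |= bifurcation_mask(tree, shape, config.bifurcation_cube)
    # a centerline is by definition inside its vessel; rounding can push
    # rasterized voxels of sub-voxel-radius terminals outside the cylinder
    center &= vessel
    # keep every bifurcation-cube center on both masks (the node lies on
    # the axis, so its voxel belongs to vessel and centerline by definition)
    dims = np.asarray(shape)
    for tree in trees:
        for node in tree.bifurcation_nodes():
            c = np.rint(node.position).astype(int)
            if np.all(c >= 0) and np.all(c < dims):
                vessel[tuple(c)] = True
                center[tuple(c)] = True
    image = render_intensities(vessel, config, render_seed)

    sp = config.spacing
    return LabeledVolume(
        image=Volume3D(image, sp),
        vessel_mask=Volume3D(vessel.astype(np.uint8), sp),
        centerline_mask=Volume3D(center.astype(np.uint8), sp),
        bifurcation_mask=Volume3D(bif.astype(np.uint8), sp),
        trees=trees,
        seed=seed,
    )


def generate_dataset(
    config: SynthConfig, n_volumes: int, seed: int | None = None
) -> list[LabeledVolume]:
    """Reproducible list of labeled volumes (one spawned seed per volume)."""
    if n_volumes < 1:
        raise ValueError(f"n_volumes must be >= 1, got {n_volumes}")
    child_seeds = np.random.SeedSequence(seed).spawn(n_volumes)
    return [generate_volume(config, s) for s in child_seeds]
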