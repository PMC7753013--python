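"""Voxel rendering of vessel trees: masks, centerlines, and intensities.

Vessel segments are rendered as finite cylinders with hemispherical caps
(capsules); a voxel is foreground iff its center lies within the segment
radius. Centerlines are 26-connected rasterized segment axes, and
bifurcation labels are odd-sided cubes centered on the nearest voxel to
each bifurcation node.
"""

from __future__ import annotations

import numpy as np

from .tree import VesselTree

__all__ = [
    "voxelize",
    "rasterize_centerline",
    "bifurcation_mask",
    "render_intensities",
]


def _segment_endpoints(tree: VesselTree):
    for seg in tree.segments:
        yield (
            tree.nodes[seg.parent].position,
            tree.nodes[seg.child].position,
            seg.radius,
        )


def voxelize(tree: VesselTree, shape) -> np.ndarray:
    """Binary vessel mask: union of capsules over all segments.

    Works segment-by-segment on a padded bounding box so large volumes are
    never densely scanned per segment.
    """
    shape = tuple(int(n) for n in shape)
    mask = np.zeros(shape, dtype=bool)
    for p0, p1, radius in _segment_endpoints(tree):
        lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1), 0).astype(int)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1), np.array(shape) - 1).astype(int)
        if np.any(hi < lo):
            continue
        grids = np.meshgrid(
            *(np.arange(lo[ax], hi[ax] + 1, dtype=np.float64) for ax in range(3)),
            indexing="ij",
        )
        pts = np.stack(grids, axis=-1)  # (...,3) voxel centers
        v = p1 - p0
        vv = float(np.dot(v, v))
        if vv < 1e-18:
            d2 = np.sum((pts - p0) ** 2, axis=-1)
        else:
            t = np.clip(np.einsum("...k,k->...", pts - p0, v) / vv, 0.0, 1.0)
            nearest = p0 + t[..., np.newaxis] * v
            d2 = np.sum((pts - nearest) ** 2, axis=-1)
        sub = d2 <= radius * radius
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= sub
    return mask


def _line_voxels(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """26-connected voxel rasterization of the straight segment p0->p1."""
    n = int(np.ceil(np.max(np.abs(p1 - p0))))
    ts = np.linspace(0.0, 1.0, n + 1)
    pts = np.rint(p0[np.newaxis, :] + ts[:, np.newaxis] * (p1 - p0)).astype(int)
    return pts


def rasterize_centerline(tree: VesselTree, shape) -> np.ndarray:
    """Binary centerline mask: 26-connected axis rasterization per segment."""
    shape = tuple(int(n) for n in shape)
    mask = np.zeros(shape, dtype=bool)
    for p0, p1, _ in _segment_endpoints(tree):
        pts = _line_voxels(p0, p1)
        keep = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[keep]
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return mask


def bifurcation_mask(tree: VesselTree, shape, cube: int = 5) -> np.ndarray:
    """Cube labels of odd side ``cube`` centered on each bifurcation node."""
    if cube < 1 or cube % 2 == 0:
        raise ValueError(f"cube side must be odd and >= 1, got {cube}")
    shape = tuple(int(n) for n in shape)
    mask = np.zeros(shape, dtype=bool)
    half = cube // 2
    for node in tree.bifurcation_nodes():
        c = np.rint(node.position).astype(int)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half, np.array(shape) - 1)
        if np.any(hi < lo):
            continue
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return mask


def render_intensities(vessel_mask: np.ndarray, config, seed: int | None = None) -> np.ndarray:
    """Render a noisy intensity image from a binary vessel mask.

    One foreground and one background intensity are drawn per volume from
    the configured intervals, then additive Gaussian noise is applied with
    a per-volume random mean offset and a per-volume random standard
    deviation ``max(0, base_noise_std + offset)``. Output is clipped to
    [0, 255].
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(vessel_mask, dtype=bool)
    fg = rng.uniform(*config.vessel_intensity)
    bg = rng.uniform(*config.background_intensity)
    image = np.where(mask, fg, bg).astype(np.float64)
    if config.noise:
        mean = rng.uniform(*config.noise_mean)
        std = max(0.0, config.base_noise_std + rng.uniform(*config.noise_std_offset))
        image += rng.normal(mean, std, size=image.shape) if std > 0 else mean
        image = np.clip(image, 0.0, 255.0)
    return image
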