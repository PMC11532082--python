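"""Projection of 3D neuron reconstructions to multi-view 2D rasters.

The CNN branch consumes each neuron as a 3-channel image: the skeleton is
drawn on the x-y, y-z and x-z planes after PCA axis normalization, with a
single isotropic fit-to-frame scale shared by the three views so relative
arbor proportions are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line_aa

from ._geom import pca_canonical_frame
from .swc import NeuronTree

__all__ = ["ProjectionStack", "pca_normalize", "render_views", "project", "VIEW_ORDER"]

#: axis-index pairs drawn in each channel, in order
VIEW_ORDER: tuple[tuple[int, int], ...] = ((0, 1), (1, 2), (0, 2))  # x-y, y-z, x-z


@dataclass(frozen=True)
class ProjectionStack:
    """3 x H x W raster of skeleton drawings, intensities in [0, 1].

    Channel order is fixed: x-y, y-z, x-z.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[0] != 3 or p.shape[1] != p.shape[2]:
            raise ValueError(f"expected (3, H, H) pixel array, got {p.shape}")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")

    @property
    def resolution(self) -> int:
        return self.pixels.shape[1]


def pca_normalize(tree: NeuronTree) -> NeuronTree:
    """Center coordinates on the centroid and rotate onto principal axes.

    Axes come out in descending-variance order with a deterministic sign
    convention (non-negative skewness per axis, farthest-node fallback), so
    any rigidly rotated/translated copy of a neuron maps to the same
    normalized coordinates.  Radii are unchanged.
    """
    xyz = tree.coordinates()
    centroid, R = pca_canonical_frame(xyz)
    return tree.with_coordinates((xyz - centroid) @ R)


def render_views(
    tree: NeuronTree,
    resolution: int = 224,
    pad_fraction: float = 0.05,
    invert: bool = False,
) -> ProjectionStack:
    """Rasterize a (normalized) tree into its 3-view projection stack.

    Parent-child segments are drawn as 1-pixel anti-aliased lines.  A single
    isotropic scale maps the largest coordinate extent onto
    ``(1 - 2 * pad_fraction) * resolution`` pixels in every view; each axis is
    centered on its mid-range.  Background is 0 and foreground up to 1
    (flip with ``invert=True``).  A single-node tree renders as one dot at
    the image center.
    """
    if resolution < 8:
        raise ValueError("resolution must be at least 8 pixels")
    if not 0 <= pad_fraction < 0.5:
        raise ValueError("pad_fraction must lie in [0, 0.5)")
    xyz = tree.coordinates()
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    span = float((hi - lo).max())
    usable = (1.0 - 2.0 * pad_fraction) * (resolution - 1)
    scale = usable / span if span > 0 else 0.0
    center = 0.5 * (lo + hi)
    # pixel coordinates per axis, image-centered
    pix = (xyz - center) * scale + (resolution - 1) / 2.0

    index = tree._index()
    stack = np.zeros((3, resolution, resolution))
    pos = {n.id: i for i, n in enumerate(tree.nodes)}
    for ch, (a, b) in enumerate(VIEW_ORDER):
        img = stack[ch]
        drew = False
        for n in tree.nodes:
            if n.parent_id == -1:
                continue
            i, j = pos[n.parent_id], pos[n.id]
            r0, c0 = int(round(pix[i, b])), int(round(pix[i, a]))
            r1, c1 = int(round(pix[j, b])), int(round(pix[j, a]))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < resolution) & (cc >= 0) & (cc < resolution)
            np.maximum.at(img, (rr[keep], cc[keep]), val[keep])
            drew = True
        if not drew:  # single node: one dot at its projected position
            i = pos[tree.root.id]
            img[int(round(pix[i, b])), int(round(pix[i, a]))] = 1.0
    np.clip(stack, 0.0, 1.0, out=stack)
    if invert:
        stack = 1.0 - stack
    return ProjectionStack(stack)


def project(
    tree: NeuronTree,
    resolution: int = 224,
    pad_fraction: float = 0.05,
    normalize: bool = True,
) -> ProjectionStack:
    """PCA-normalize (optionally) and render in one call."""
    if normalize:
        tree = pca_normalize(tree)
    return render_views(tree, resolution=resolution, pad_fraction=pad_fraction)
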