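"""Separation of touching spores via structure-tensor junction detection.

Where two spores touch, the outlines of both meet in two acute-angled
corners flanking the contact point.  The structure tensor (the
window-averaged outer product of the intensity gradient) separates the two
situations by its eigenvalues: along a lone smooth outline all gradient
energy shares one orientation, so the smaller eigenvalue stays near zero,
while at a junction corner two outline orientations coexist inside the
integration window and the smaller eigenvalue shoots up.  The smaller
eigenvalue is therefore the corner detector used here (the larger one
responds to every edge and cannot distinguish corners from outlines).
Thresholding that map yields small regions at the junction corners;
centroids of regions close enough to belong to one contact are joined by a
one-pixel-wide line painted in background color, which disconnects the
touching pair without eroding either spore.

The eigenvalue threshold is calibrated on a rendered isolated-disk tile:
an isolated outline defines the response level that must *not* trigger
junctions, and the threshold is placed a safety factor above that map's
maximum (junction corners respond several-fold higher).  Lines are
rasterized 8-connected; combined with 4-connected labeling downstream, a
1-px cut is guaranteed to disconnect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.feature import structure_tensor, structure_tensor_eigenvalues

from .imaging_io import CalibratedImage

__all__ = [
    "SeparationParams", "JunctionSet", "SeparationLines",
    "structure_eigen_map", "junction_regions", "link_junctions",
    "apply_separation", "separate_mask", "calibrate_eigen_threshold",
]


@dataclass
class SeparationParams:
    """Tunables of the junction detector.

    ``smoothing_scale`` (px) smooths the image before differentiation;
    ``integration_scale`` (px) is the tensor window and should span the
    junction corner pair; ``eigen_threshold`` is in squared-intensity units
    (None = calibrate from an isolated-disk fixture at run time);
    ``max_radius_px`` limits which junction centroids may be linked —
    roughly one chord of the expected spore (0.6 x modal diameter in px).
    """

    smoothing_scale: float = 1.0
    integration_scale: float = 4.0
    eigen_threshold: float | None = None
    max_radius_px: float = 30.0
    threshold_factor: float = 3.0        # safety factor over the calibration map

    def __post_init__(self) -> None:
        if self.smoothing_scale <= 0 or self.integration_scale <= 0:
            raise ValueError("scales must be > 0")
        if self.max_radius_px <= 0:
            raise ValueError("max_radius_px must be > 0")


@dataclass
class JunctionSet:
    eigen_threshold: float
    regions: np.ndarray                      # labeled eigenvalue regions
    centroids: list[tuple[float, float]]     # (x, y) px

    @property
    def n(self) -> int:
        return len(self.centroids)


@dataclass
class SeparationLines:
    segments: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list)                # ((x0, y0), (x1, y1)) px
    line_width: int = 1

    @property
    def n(self) -> int:
        return len(self.segments)


def structure_eigen_map(image: CalibratedImage | np.ndarray,
                        smoothing_scale: float = 1.0,
                        integration_scale: float = 4.0) -> np.ndarray:
    """Corner-selective structure-tensor eigenvalue map (non-negative).

    Returns the smaller eigenvalue of the structure tensor integrated at
    ``integration_scale``: near zero along isolated outlines, large where
    outlines of touching objects meet at a corner.  Mirror boundary
    handling avoids spurious responses at the tile border.
    """
    if smoothing_scale <= 0 or integration_scale <= 0:
        raise ValueError("scales must be > 0")
    gray = (image.grayscale() if isinstance(image, CalibratedImage)
            else np.asarray(image, dtype=np.float64))
    smooth = ndi.gaussian_filter(gray, smoothing_scale)
    tensor = structure_tensor(smooth, sigma=integration_scale, order="rc",
                              mode="mirror")
    eigs = structure_tensor_eigenvalues(tensor)
    return np.clip(eigs[-1], 0.0, None)


def junction_regions(eig_map: np.ndarray, eigen_threshold: float,
                     foreground: np.ndarray | None = None,
                     foreground_reach_px: int = 3) -> JunctionSet:
    """Connected components of {eigenvalue >= threshold} with centroids.

    Components farther than ``foreground_reach_px`` from any foreground
    pixel (when a mask is supplied) are discarded: a junction must sit on
    or immediately beside spore material.  The reach matters because the
    corner response peaks in the background wedge just outside the mask
    boundary of a touching pair.
    """
    if eigen_threshold <= 0:
        raise ValueError("eigen_threshold must be > 0")
    hot = eig_map >= eigen_threshold
    labels, n = ndi.label(hot)
    if n and foreground is not None:
        fg = foreground
        if foreground_reach_px > 0:
            fg = ndi.binary_dilation(
                foreground, iterations=foreground_reach_px)
        touching = np.unique(labels[(labels > 0) & fg])
        keep = np.zeros(n + 1, dtype=bool)
        keep[touching] = True
        labels = np.where(keep[labels], labels, 0)
        labels, n = ndi.label(labels > 0)
    centroids: list[tuple[float, float]] = []
    if n:
        for cy, cx in ndi.center_of_mass(hot, labels, range(1, n + 1)):
            centroids.append((float(cx), float(cy)))
    return JunctionSet(eigen_threshold=eigen_threshold, regions=labels,
                       centroids=centroids)


def link_junctions(junctions: JunctionSet, max_radius_px: float
                   ) -> SeparationLines:
    """Pair junction centroids greedily by ascending distance.

    Each centroid is used at most once and only pairs within
    ``max_radius_px`` are linked, so corner regions of one contact join
    while unrelated junctions stay apart.
    """
    if max_radius_px <= 0:
        raise ValueError("max_radius_px must be > 0")
    pts = junctions.centroids
    pairs = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            if d <= max_radius_px:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    lines = SeparationLines()
    for _, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        (x0, y0), (x1, y1) = pts[i], pts[j]
        lines.segments.append(((int(round(x0)), int(round(y0))),
                               (int(round(x1)), int(round(y1)))))
    return lines


def apply_separation(mask: np.ndarray, lines: SeparationLines) -> np.ndarray:
    """Paint each segment as a 1-px background-colored line into the mask.

    Foreground can only shrink; pixels off the segments are untouched.
    """
    out = np.asarray(mask, dtype=bool).copy()
    h, w = out.shape
    for (x0, y0), (x1, y1) in lines.segments:
        for x, y in (((x0, y0)), ((x1, y1))):
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"segment endpoint ({x}, {y}) outside image")
        rr, cc = draw_line(y0, x0, y1, x1)
        out[rr, cc] = False
    return out


def calibrate_eigen_threshold(diameter_px: float,
                              params: SeparationParams,
                              background_level: float = 0.9,
                              object_level: float = 0.30,
                              noise_sd: float = 3.0,
                              max_intensity: int = 255,
                              seed: int = 12345) -> float:
    """Eigenvalue threshold from an isolated-disk calibration tile.

    Renders one isolated disk of the expected modal diameter at the scene's
    contrast and noise, computes its eigenvalue map and returns
    ``threshold_factor`` x its maximum: comfortably above anything a lone
    outline produces, below the several-fold higher junction response of a
    touching pair.
    """
    side = int(max(4 * diameter_px, 64))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side]
    r = diameter_px / 2
    dist = np.hypot(xx - side / 2, yy - side / 2) - r
    cov = np.clip(0.5 - dist, 0.0, 1.0)
    img = background_level * max_intensity * (1 - cov) \
        + object_level * max_intensity * cov
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, max_intensity)
    emap = structure_eigen_map(img, params.smoothing_scale,
                               params.integration_scale)
    return float(params.threshold_factor * emap.max())


def separate_mask(image: CalibratedImage, mask: np.ndarray,
                  params: SeparationParams,
                  eigen_threshold: float | None = None
                  ) -> tuple[np.ndarray, SeparationLines, JunctionSet]:
    """Full separation pass on one tile: eigenvalues -> junctions -> cuts."""
    thr = eigen_threshold if eigen_threshold is not None else params.eigen_threshold
    if thr is None:
        raise ValueError("eigen_threshold not set; calibrate it first "
                         "(calibrate_eigen_threshold) or pass it explicitly")
    emap = structure_eigen_map(image, params.smoothing_scale,
                               params.integration_scale)
    junctions = junction_regions(emap, thr, foreground=mask)
    lines = link_junctions(junctions, params.max_radius_px)
    return apply_separation(mask, lines), lines, junctions
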