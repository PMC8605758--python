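"""Trainable two-class pixel segmentation (spore vs. background).

A scribble-trained random forest classifies every pixel from a small filter
bank (grayscale plus, per smoothing scale, a Gaussian blur, a gradient
magnitude and a difference of Gaussians).  The model deliberately has only
two classes: contaminants are not segmented away here but excluded later by
shape filters, which is far more robust than teaching a pixel classifier
the difference between a spore wall and a bubble wall.

For high-contrast slides a classifier-free fallback thresholds the
grayscale by between-class variance maximization (Otsu); the dark side is
foreground by brightfield convention.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology
from sklearn.ensemble import RandomForestClassifier

from .imaging_io import CalibratedImage

__all__ = [
    "DEFAULT_SCALES", "Scribble", "ScribbleSet", "PixelModel",
    "compute_features", "train_pixel_classifier", "classify_pixels",
    "binarize", "threshold_fallback", "clean_mask",
]

DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.0, 4.0)

CLASS_BACKGROUND = 0
CLASS_SPORE = 1


def compute_features(image: CalibratedImage | np.ndarray,
                     scales: tuple[float, ...] = DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature stack, shape H x W x (1 + 3·len(scales)).

    Plane 0 is the raw grayscale; each scale s contributes a Gaussian
    smoothing, the gradient magnitude of that smoothing, and a difference
    of Gaussians between s and 1.6·s.
    """
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be > 0")
    gray = (image.grayscale() if isinstance(image, CalibratedImage)
            else np.asarray(image, dtype=np.float64))
    planes = [gray]
    for s in scales:
        smooth = ndi.gaussian_filter(gray, s)
        gx = ndi.sobel(smooth, axis=1)
        gy = ndi.sobel(smooth, axis=0)
        planes.append(smooth)
        planes.append(np.hypot(gx, gy))
        planes.append(smooth - ndi.gaussian_filter(gray, 1.6 * s))
    return np.stack(planes, axis=-1)


@dataclass
class Scribble:
    """One annotation stroke: pixel coordinates plus a class label."""

    tile: tuple[int, int]
    rows: np.ndarray          # y coordinates
    cols: np.ndarray          # x coordinates
    label: int                # CLASS_SPORE or CLASS_BACKGROUND

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.rows.shape != self.cols.shape:
            raise ValueError("rows and cols must have equal length")
        if self.label not in (CLASS_BACKGROUND, CLASS_SPORE):
            raise ValueError("label must be 0 (background) or 1 (spore)")


@dataclass
class ScribbleSet:
    strokes: list[Scribble] = field(default_factory=list)

    def labels_present(self) -> set[int]:
        return {s.label for s in self.strokes}

    def n_pixels(self, label: int) -> int:
        return sum(s.rows.size for s in self.strokes if s.label == label)

    @classmethod
    def from_csv(cls, path) -> "ScribbleSet":
        """Load scribbles from CSV with columns x, y, tile_row, tile_col, class."""
        import pandas as pd
        df = pd.read_csv(path)
        strokes = []
        for (tr, tc, lab), grp in df.groupby(["tile_row", "tile_col", "class"]):
            strokes.append(Scribble(tile=(int(tr), int(tc)),
                                    rows=grp["y"].to_numpy(),
                                    cols=grp["x"].to_numpy(),
                                    label=int(lab)))
        return cls(strokes)

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = []
        for s in self.strokes:
            for y, x in zip(s.rows, s.cols):
                rows.append({"x": int(x), "y": int(y),
                             "tile_row": s.tile[0], "tile_col": s.tile[1],
                             "class": s.label})
        pd.DataFrame(rows).to_csv(path, index=False)


def scribbles_from_mask(mask: np.ndarray, tile: tuple[int, int],
                        n_per_class: int = 200,
                        margin_px: int = 2,
                        seed: int | np.random.Generator = 0) -> ScribbleSet:
    """Sample training scribbles from a known foreground mask.

    Emulates a user marking confident object interiors and clear
    background: candidate pixels are eroded away from the class boundary by
    ``margin_px`` before sampling.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    selem = morphology.disk(margin_px)
    strokes = []
    for label, region in ((CLASS_SPORE, morphology.erosion(mask, selem)),
                          (CLASS_BACKGROUND,
                           morphology.erosion(~mask, selem))):
        ys, xs = np.nonzero(region)
        if ys.size == 0:
            continue
        pick = rng.choice(ys.size, size=min(n_per_class, ys.size),
                          replace=False)
        strokes.append(Scribble(tile=tile, rows=ys[pick], cols=xs[pick],
                                label=label))
    return ScribbleSet(strokes)


@dataclass
class PixelModel:
    """Trained two-class pixel classifier plus its feature configuration."""

    classifier: RandomForestClassifier
    scales: tuple[float, ...]
    n_trees: int
    seed: int
    classes: tuple[str, str] = ("background", "spore")
    training_accuracy: float = float("nan")

    def save(self, path) -> None:
        with open(Path(path), "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PixelModel":
        with open(Path(path), "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a PixelModel")
        return model


def train_pixel_classifier(images: list[CalibratedImage],
                           scribbles: ScribbleSet,
                           n_trees: int = 100,
                           seed: int = 0,
                           scales: tuple[float, ...] = DEFAULT_SCALES,
                           min_pixels_per_class: int = 50) -> PixelModel:
    """Fit the random forest on scribbled pixels of one or more tiles."""
    present = scribbles.labels_present()
    if present != {CLASS_BACKGROUND, CLASS_SPORE}:
        raise ValueError(
            "scribbles must cover both classes (spore and background), "
            f"got labels {sorted(present)}")
    for label in (CLASS_BACKGROUND, CLASS_SPORE):
        n = scribbles.n_pixels(label)
        if n < min_pixels_per_class:
            raise ValueError(
                f"need >= {min_pixels_per_class} scribbled pixels per class, "
                f"class {label} has {n}")
    by_tile = {img.tile: img for img in images}
    feats, labels = [], []
    feature_cache: dict[tuple[int, int], np.ndarray] = {}
    for s in scribbles.strokes:
        if s.tile not in by_tile:
            raise ValueError(f"scribble references tile {s.tile} with no image")
        if s.tile not in feature_cache:
            feature_cache[s.tile] = compute_features(by_tile[s.tile], scales)
        stack = feature_cache[s.tile]
        feats.append(stack[s.rows, s.cols])
        labels.append(np.full(s.rows.size, s.label))
    X = np.concatenate(feats)
    y = np.concatenate(labels)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 n_jobs=1)
    clf.fit(X, y)
    acc = float((clf.predict(X) == y).mean())
    return PixelModel(classifier=clf, scales=tuple(scales), n_trees=n_trees,
                      seed=seed, training_accuracy=acc)


def classify_pixels(model: PixelModel, image: CalibratedImage) -> np.ndarray:
    """Per-pixel class probabilities, shape H x W x 2 (background, spore)."""
    stack = compute_features(image, model.scales)
    h, w, f = stack.shape
    if f != model.classifier.n_features_in_:
        raise ValueError(
            f"feature configuration mismatch: image yields {f} features, "
            f"model expects {model.classifier.n_features_in_}")
    proba = model.classifier.predict_proba(stack.reshape(-1, f))
    out = np.zeros((h * w, 2))
    for j, cls in enumerate(model.classifier.classes_):
        out[:, int(cls)] = proba[:, j]
    return out.reshape(h, w, 2)


def clean_mask(mask: np.ndarray, min_speck_px: int = 20,
               max_hole_px: int | None = 64) -> np.ndarray:
    """Remove sub-speck components and fill small interior holes.

    Hole filling is area-limited: spore interiors only contain pinhole
    noise, while the bright lens center of an air bubble is a large hole
    that must stay open so the bubble keeps its ring shape for the
    downstream circularity filter.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_speck_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_speck_px - 1)
    if max_hole_px:
        mask = morphology.remove_small_holes(mask, max_size=max_hole_px)
    return mask


def binarize(prob_map: np.ndarray, threshold: float = 0.5,
             min_speck_px: int = 20, max_hole_px: int | None = 64) -> np.ndarray:
    """Foreground mask = spore probability >= threshold, then cleanup."""
    prob_map = np.asarray(prob_map)
    if prob_map.ndim != 3 or prob_map.shape[2] != 2:
        raise ValueError("prob_map must be H x W x 2")
    return clean_mask(prob_map[:, :, CLASS_SPORE] >= threshold,
                      min_speck_px, max_hole_px)


def threshold_fallback(image: CalibratedImage, min_speck_px: int = 20,
                       max_hole_px: int | None = 64,
                       min_contrast: float = 0.1) -> np.ndarray:
    """Classifier-free segmentation by automatic grayscale thresholding.

    Between-class variance maximization (Otsu) finds the two classes, then
    the cut is moved to the midpoint of the class means: with strongly
    unequal class sizes Otsu's own cut bites into the minority (spore)
    class, while the mean midpoint crosses an anti-aliased edge at 50%
    coverage and keeps pixel-count areas unbiased.  Foreground is the dark
    class (brightfield spores on a bright field).

    Raises on a constant image; returns an empty mask (with a warning) when
    the class separation is below ``min_contrast`` of the intensity range,
    i.e. the tile has no real dark class, only noise.
    """
    gray = image.grayscale()
    if np.ptp(gray) == 0:
        raise ValueError("degenerate image: constant intensity, no threshold")
    t = filters.threshold_otsu(gray)
    lo, hi = gray[gray < t], gray[gray >= t]
    if lo.size == 0 or hi.size == 0 \
            or hi.mean() - lo.mean() < min_contrast * image.max_intensity:
        import warnings
        warnings.warn("no dark class found (contrast below threshold); "
                      "returning an empty mask", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    t = (lo.mean() + hi.mean()) / 2.0
    return clean_mask(gray < t, min_speck_px, max_hole_px)
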