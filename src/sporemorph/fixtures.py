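"""Synthetic brightfield slide generator with exact ground truth.

Emulates a tile-scanned microscope slide of a myxomycete spore monolayer:
a bright, near-uniform background (default 90% of the 8-bit maximum, the
acquisition setting the pipeline is calibrated for), dark quasi-circular
spores whose diameters follow a one- or two-component gamma mixture, an
adjustable fraction of spores placed tangent to a neighbour, and three
non-target contaminant classes (elongated capillitium-like fibers,
bright-centered air-bubble rings, small amorphous debris).

Every generated object is recorded in a ground-truth table, so each
downstream stage (QC, segmentation, separation, morphometry, statistics)
can be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging_io import CalibratedImage, TileGrid, write_tile_grid

SPORE_CLASSES = ("spore_normal", "spore_oversized")
CONTAMINANT_CLASSES = ("fiber", "bubble", "debris")

GROUND_TRUTH_COLUMNS = [
    "id", "klass", "center_x_um", "center_y_um", "diameter_um",
    "axis_ratio", "orientation_rad", "tile_row", "tile_col",
]


# ---------------------------------------------------------------------------
# size model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaComponent:
    """One gamma component of the diameter mixture (diameter in µm)."""

    shape: float          # k, dimensionless
    rate: float           # β, 1/µm
    weight: float = 1.0
    klass: str = "spore_normal"

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError(f"gamma shape and rate must be > 0, got "
                             f"shape={self.shape}, rate={self.rate}")
        if self.weight < 0:
            raise ValueError("component weight must be >= 0")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) / self.rate

    @property
    def mode(self) -> float:
        if self.shape <= 1:
            return 0.0
        return (self.shape - 1) / self.rate


def gamma_from_mode_sd(mode: float, sd: float, weight: float = 1.0,
                       klass: str = "spore_normal") -> GammaComponent:
    """Gamma component with a given mode (peak diameter, µm) and sd (µm).

    Solves mode=(k-1)/β, sd=√k/β for k>1.
    """
    if mode <= 0 or sd <= 0:
        raise ValueError("mode and sd must be > 0")
    # β = √k/sd and k - 1 = mode·β  ⇒  k - (mode/sd)·√k - 1 = 0
    m = mode / sd
    sqrt_k = (m + math.sqrt(m * m + 4)) / 2
    k = sqrt_k ** 2
    return GammaComponent(shape=k, rate=sqrt_k / sd, weight=weight, klass=klass)


def default_size_model() -> list[GammaComponent]:
    """Unimodal normal-sized spores: mode ≈ 12.0 µm, sd ≈ 0.49 µm."""
    return [GammaComponent(shape=600.0, rate=50.0, weight=1.0,
                           klass="spore_normal")]


def bimodal_size_model(weight_oversized: float = 0.2) -> list[GammaComponent]:
    """Two-component mixture: normal-sized (mode 12.9 µm, sd 0.6) plus
    oversized (mode 15.9 µm, sd 0.5) spores."""
    return [
        gamma_from_mode_sd(12.9, 0.6, weight=1 - weight_oversized,
                           klass="spore_normal"),
        gamma_from_mode_sd(15.9, 0.5, weight=weight_oversized,
                           klass="spore_oversized"),
    ]


# ---------------------------------------------------------------------------
# scene configuration
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Geometry, optics and content of one synthetic slide.

    Defaults mirror the acquisition this pipeline targets: a 12 × 12 grid
    of 2,880 × 2,048 px tiles at 0.12 µm/px with the background set to 90%
    of the 8-bit maximum.  Tests and demos typically shrink the geometry.
    """

    tile_rows: int = 12
    tile_cols: int = 12
    tile_width_px: int = 2880
    tile_height_px: int = 2048
    um_per_px: float = 0.12
    background_level: float = 0.9      # fraction of max intensity
    noise_sd: float = 3.0              # additive Gaussian, intensity units
    spores_per_tile_mean: float = 100.0
    contact_fraction: float = 0.0      # fraction of spores with a tangential neighbour
    size_model: list[GammaComponent] = field(default_factory=default_size_model)
    contaminant_rates: dict[str, float] = field(
        default_factory=lambda: {"fiber": 0.0, "bubble": 0.0, "debris": 0.0})
    spore_intensity_level: float = 0.30   # fraction of max, mean spore darkness
    spore_intensity_jitter: float = 0.04  # per-object sd, fraction of max
    clustered_classes: tuple[str, ...] = ()   # classes with a central density hotspot
    cluster_sigma_frac: float = 0.22      # hotspot sd, fraction of slide extent
    cluster_mix: float = 0.5              # fraction of a clustered class in the hotspot
    max_axis_ratio: float = 1.05          # spores are quasi-spherical
    max_intensity: int = 255
    sample_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tile_rows", "tile_cols", "tile_width_px", "tile_height_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spores_per_tile_mean < 0:
            raise ValueError("spores_per_tile_mean must be >= 0")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must lie in [0, 1]")
        if not self.size_model:
            raise ValueError("size_model needs at least one component")
        total_w = sum(c.weight for c in self.size_model)
        if not math.isclose(total_w, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {total_w}")
        unknown = set(self.contaminant_rates) - set(CONTAMINANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown contaminant classes: {sorted(unknown)}")

    @property
    def slide_width_um(self) -> float:
        return self.tile_cols * self.tile_width_px * self.um_per_px

    @property
    def slide_height_um(self) -> float:
        return self.tile_rows * self.tile_height_px * self.um_per_px

    def tile_of(self, x_um: float, y_um: float) -> tuple[int, int]:
        """Tile (row, col) containing a slide-coordinate point."""
        col = min(int(x_um / (self.tile_width_px * self.um_per_px)),
                  self.tile_cols - 1)
        row = min(int(y_um / (self.tile_height_px * self.um_per_px)),
                  self.tile_rows - 1)
        return max(row, 0), max(col, 0)


@dataclass
class GroundTruthObject:
    """One generated object in slide coordinates (µm)."""

    id: int
    klass: str
    center_um: tuple[float, float]
    diameter_um: float            # spores/bubbles/debris: diameter; fibers: length
    axis_ratio: float             # major/minor, >= 1
    orientation: float            # radians, major axis vs +x
    tile: tuple[int, int]

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be > 0")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1")

    @property
    def radius_um(self) -> float:
        """Bounding (semi-major) radius in µm."""
        return self.diameter_um / 2

    @property
    def minor_um(self) -> float:
        return self.diameter_um / self.axis_ratio


class PlacementError(RuntimeError):
    """Raised when dart-throwing cannot place an object within its retry budget."""


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_diameters(model: list[GammaComponent], n: int,
                     seed: int | np.random.Generator = 0
                     ) -> list[tuple[float, str]]:
    """Draw n (diameter_um, klass) pairs i.i.d. from a gamma mixture."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not model:
        raise ValueError("empty mixture")
    weights = np.array([c.weight for c in model], dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if n == 0:
        return []
    comp = rng.choice(len(model), size=n, p=weights)
    out: list[tuple[float, str]] = []
    for i, c in enumerate(model):
        idx = np.flatnonzero(comp == i)
        if idx.size == 0:
            continue
        draws = rng.gamma(shape=c.shape, scale=1.0 / c.rate, size=idx.size)
        for j, d in zip(idx, draws):
            out.append((j, float(d), c.klass))
    out.sort(key=lambda t: t[0])       # restore draw order
    return [(d, k) for _, d, k in out]


# ---------------------------------------------------------------------------
# placement (dart throwing with spatial hashing)
# ---------------------------------------------------------------------------

class _SpatialHash:
    """Uniform-grid neighbour lookup for circle packing in µm coordinates."""

    def __init__(self, cell_um: float) -> None:
        self.cell = cell_um
        self.cells: dict[tuple[int, int], list[int]] = {}
        self.centers: list[tuple[float, float]] = []
        self.radii: list[float] = []

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return int(x // self.cell), int(y // self.cell)

    def add(self, x: float, y: float, r: float) -> int:
        i = len(self.centers)
        self.centers.append((x, y))
        self.radii.append(r)
        self.cells.setdefault(self._key(x, y), []).append(i)
        return i

    def neighbours(self, x: float, y: float, reach: float) -> list[int]:
        kx, ky = self._key(x, y)
        span = int(reach // self.cell) + 1
        out: list[int] = []
        for dx in range(-span, span + 1):
            for dy in range(-span, span + 1):
                out.extend(self.cells.get((kx + dx, ky + dy), ()))
        return out

    def min_gap(self, x: float, y: float, r: float,
                exclude: int | None = None) -> float:
        """Smallest (distance - sum of radii) to any stored circle."""
        reach = r + (max(self.radii) if self.radii else 0.0) + self.cell
        best = math.inf
        for i in self.neighbours(x, y, reach):
            if i == exclude:
                continue
            cx, cy = self.centers[i]
            gap = math.hypot(x - cx, y - cy) - r - self.radii[i]
            best = min(best, gap)
        return best


#: sub-pixel interpenetration (in px) used for tangential contacts so that
#: rasterized masks of touching spores actually connect
_TOUCH_OVERLAP_PX = 0.5

_RETRY_BUDGET = 2000


def place_objects(diameters: list[tuple[float, str]], scene: SceneConfig,
                  seed: int | np.random.Generator | None = None
                  ) -> list[GroundTruthObject]:
    """Place spores on the slide without overlap beyond tangency.

    A fraction ``scene.contact_fraction`` of spores is arranged in tangent
    pairs (emulating the near-touching monolayer a dense preparation
    produces); the rest keep a positive clearance from every neighbour.
    Classes listed in ``scene.clustered_classes`` draw part of their
    positions from a central Gaussian hotspot (emulating size-dependent
    transport during mounting); everything else is uniform over the slide.
    Contaminants are added afterwards by :func:`add_contaminants`.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(scene.seed if seed is None else seed))
    n = len(diameters)
    if n == 0:
        return []
    radii = [d / 2 for d, _ in diameters]
    max_d = max(d for d, _ in diameters)
    if max_d >= min(scene.slide_width_um, scene.slide_height_um):
        raise PlacementError("slide smaller than the largest object")

    clearance = 2.0 * scene.um_per_px     # isolated spores stay > tangency apart
    hash_ = _SpatialHash(cell_um=max_d + clearance)
    n_pairs = int(round(scene.contact_fraction * n / 2))
    n_isolated = n - n_pairs

    order = rng.permutation(n)
    objs: list[GroundTruthObject | None] = [None] * n
    placed_isolated: list[int] = []   # hash indices eligible as contact partners
    hash_to_obj: list[int] = []

    def _mk(obj_i: int, x: float, y: float) -> GroundTruthObject:
        d, klass = diameters[obj_i]
        ar = 1.0 + rng.uniform(0.0, scene.max_axis_ratio - 1.0)
        return GroundTruthObject(
            id=int(obj_i), klass=klass, center_um=(x, y), diameter_um=d,
            axis_ratio=ar, orientation=float(rng.uniform(0, math.pi)),
            tile=scene.tile_of(x, y))

    def _draw_position(obj_i: int, lo_x, hi_x, lo_y, hi_y):
        klass = diameters[obj_i][1]
        if (klass in scene.clustered_classes
                and rng.uniform() < scene.cluster_mix):
            sx = scene.cluster_sigma_frac * scene.slide_width_um
            sy = scene.cluster_sigma_frac * scene.slide_height_um
            x = rng.normal(scene.slide_width_um / 2, sx)
            y = rng.normal(scene.slide_height_um / 2, sy)
            return (min(max(x, lo_x), hi_x), min(max(y, lo_y), hi_y))
        return rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)

    # pass 1: isolated spores by dart throwing
    for obj_i in order[:n_isolated]:
        r = radii[obj_i]
        lo_x, hi_x = r, scene.slide_width_um - r
        lo_y, hi_y = r, scene.slide_height_um - r
        for _ in range(_RETRY_BUDGET):
            x, y = _draw_position(obj_i, lo_x, hi_x, lo_y, hi_y)
            if hash_.min_gap(x, y, r) > clearance:
                hi = hash_.add(x, y, r)
                placed_isolated.append(hi)
                hash_to_obj.append(obj_i)
                objs[obj_i] = _mk(obj_i, x, y)
                break
        else:
            raise PlacementError(
                f"could not place spore {obj_i} within {_RETRY_BUDGET} retries; "
                "density too high for the requested scene")

    # pass 2: tangent partners attached to distinct isolated spores
    touch = _TOUCH_OVERLAP_PX * scene.um_per_px
    for obj_i in order[n_isolated:]:
        r = radii[obj_i]
        placed = False
        for _ in range(_RETRY_BUDGET):
            if not placed_isolated:
                break
            pick = int(rng.integers(len(placed_isolated)))
            hi_partner = placed_isolated[pick]
            px, py = hash_.centers[hi_partner]
            pr = hash_.radii[hi_partner]
            theta = rng.uniform(0, 2 * math.pi)
            dist = pr + r - touch
            x = px + dist * math.cos(theta)
            y = py + dist * math.sin(theta)
            if not (r <= x <= scene.slide_width_um - r
                    and r <= y <= scene.slide_height_um - r):
                continue
            if hash_.min_gap(x, y, r, exclude=hi_partner) > clearance:
                hash_.add(x, y, r)
                hash_to_obj.append(obj_i)
                objs[obj_i] = _mk(obj_i, x, y)
                placed_isolated.pop(pick)   # partner now touching: not reusable
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not attach tangent spore {obj_i} within "
                f"{_RETRY_BUDGET} retries")

    return [o for o in objs if o is not None]


def add_contaminants(objects: list[GroundTruthObject], scene: SceneConfig,
                     seed: int | np.random.Generator | None = None
                     ) -> list[GroundTruthObject]:
    """Append fiber / bubble / debris objects at Poisson per-tile rates.

    Contaminants keep clearance from every existing object so they never
    merge with spores (overlapping contamination is a slide-preparation
    failure mode outside this generator's scope).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(
               scene.seed + 104729 if seed is None else seed))
    n_tiles = scene.tile_rows * scene.tile_cols
    out = list(objects)
    next_id = (max((o.id for o in out), default=-1)) + 1
    hash_ = _SpatialHash(cell_um=max(
        [o.radius_um for o in out], default=10.0) * 2 + 4)
    for o in out:
        hash_.add(o.center_um[0], o.center_um[1], o.radius_um)
    clearance = 2.0 * scene.um_per_px

    for klass in CONTAMINANT_CLASSES:
        rate = scene.contaminant_rates.get(klass, 0.0)
        count = int(rng.poisson(rate * n_tiles)) if rate > 0 else 0
        for _ in range(count):
            if klass == "fiber":
                length = rng.uniform(25.0, 70.0)
                width = rng.uniform(1.8, 3.0)
                d, ar = length, length / width
            elif klass == "bubble":
                d = rng.uniform(22.0, 40.0)     # outer diameter
                ar = 1.0 + rng.uniform(0, 0.05)
            else:  # debris
                d = rng.uniform(1.5, 4.5)
                ar = 1.0 + rng.uniform(0, 0.6)
            r = d / 2
            placed = False
            for _ in range(_RETRY_BUDGET):
                x = rng.uniform(r, scene.slide_width_um - r)
                y = rng.uniform(r, scene.slide_height_um - r)
                if hash_.min_gap(x, y, r) > clearance:
                    hash_.add(x, y, r)
                    out.append(GroundTruthObject(
                        id=next_id, klass=klass, center_um=(x, y),
                        diameter_um=d, axis_ratio=ar,
                        orientation=float(rng.uniform(0, math.pi)),
                        tile=scene.tile_of(x, y)))
                    next_id += 1
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place {klass} within {_RETRY_BUDGET} retries")
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _coverage_patch(obj: GroundTruthObject, scene: SceneConfig,
                    tile: tuple[int, int]
                    ) -> tuple[np.ndarray, int, int] | None:
    """The object's area-coverage footprint clipped to one tile.

    Coverage is an anti-aliased area fraction per pixel computed from the
    signed distance to the object outline, so pixel-count areas track the
    analytic areas to sub-percent accuracy.  Returns (patch, y0, x0) in
    tile pixel coordinates, or None when the object misses the tile.
    """
    s = scene.um_per_px
    row, col = tile
    ox = col * scene.tile_width_px * s    # tile origin, µm
    oy = row * scene.tile_height_px * s
    cx, cy = obj.center_um

    if obj.klass == "fiber":
        half_len = obj.diameter_um / 2
        half_w = obj.diameter_um / obj.axis_ratio / 2
        reach = half_len + half_w
    else:
        reach = obj.radius_um
    # bounding box in tile pixel coords, 1-px guard band
    x0 = int(math.floor((cx - reach - ox) / s)) - 1
    x1 = int(math.ceil((cx + reach - ox) / s)) + 1
    y0 = int(math.floor((cy - reach - oy) / s)) - 1
    y1 = int(math.ceil((cy + reach - oy) / s)) + 1
    x0, x1 = max(x0, 0), min(x1, scene.tile_width_px - 1)
    y0, y1 = max(y0, 0), min(y1, scene.tile_height_px - 1)
    if x0 > x1 or y0 > y1:
        return None

    xs = (ox + (np.arange(x0, x1 + 1) + 0.5) * s) - cx
    ys = (oy + (np.arange(y0, y1 + 1) + 0.5) * s) - cy
    X, Y = np.meshgrid(xs, ys)
    ct, st = math.cos(obj.orientation), math.sin(obj.orientation)
    U = X * ct + Y * st        # object frame, µm
    V = -X * st + Y * ct

    if obj.klass == "fiber":
        seg = obj.diameter_um / 2 - obj.diameter_um / obj.axis_ratio / 2
        du = np.clip(np.abs(U) - seg, 0.0, None)
        dist = np.hypot(du, V) - obj.diameter_um / obj.axis_ratio / 2
    elif obj.klass == "bubble":
        r_out = obj.radius_um
        thick = max(1.5, 0.08 * obj.diameter_um)   # ring wall, µm
        r_mid = r_out - thick / 2
        dist = np.abs(np.hypot(U, V) - r_mid) - thick / 2
    else:
        a = obj.radius_um           # semi-major
        b = obj.minor_um / 2        # semi-minor
        rho = np.hypot(U / a, V / b)
        # signed distance approximated via the local radius
        dist = (rho - 1.0) * math.sqrt(a * b)

    frac = np.clip(0.5 - dist / s, 0.0, 1.0)
    if not frac.any():
        return None
    return frac, y0, x0


def _object_rgb(obj: GroundTruthObject, scene: SceneConfig) -> np.ndarray:
    """Deterministic per-object RGB paint level (fraction of max)."""
    orng = np.random.default_rng((scene.seed, 7919, obj.id))
    base = scene.spore_intensity_level + orng.normal(
        0.0, scene.spore_intensity_jitter)
    rgb = base + orng.normal(0.0, 0.015, size=3)   # mild channel imbalance
    return np.clip(rgb, 0.02, 0.85)


def render_tile(objects: list[GroundTruthObject], scene: SceneConfig,
                tile: tuple[int, int],
                seed: int | None = None) -> CalibratedImage:
    """Render one tile; objects straddling its boundary are drawn clipped.

    Noise is seeded per (scene seed, tile), so tiles are reproducible
    independently of rendering order.
    """
    row, col = tile
    if not (0 <= row < scene.tile_rows and 0 <= col < scene.tile_cols):
        raise ValueError(f"tile {tile} outside the {scene.tile_rows}x"
                         f"{scene.tile_cols} grid")
    h, w = scene.tile_height_px, scene.tile_width_px
    maxi = float(scene.max_intensity)
    img = np.full((h, w, 3), scene.background_level * maxi, dtype=np.float64)

    for obj in objects:
        hit = _coverage_patch(obj, scene, tile)
        if hit is None:
            continue
        cov, y0, x0 = hit
        if obj.klass == "bubble":
            # dark ring wall; the lens center stays at background (the ring
            # coverage footprint excludes it), i.e. a bright-centered ring
            rgb = np.full(3, 0.25)
        else:
            rgb = _object_rgb(obj, scene)
        ph, pw = cov.shape
        window = img[y0:y0 + ph, x0:x0 + pw]
        window -= cov[..., None] * (window - rgb[None, None, :] * maxi)

    base_seed = scene.seed if seed is None else seed
    if scene.noise_sd > 0:
        nrng = np.random.default_rng((base_seed, 15485863, row, col))
        img += nrng.normal(0.0, scene.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, scene.max_intensity).astype(np.uint8)
    return CalibratedImage(pixels=pixels, um_per_px=scene.um_per_px,
                           tile=(row, col), sample_id=scene.sample_id,
                           max_intensity=scene.max_intensity)


def ground_truth_mask(objects: list[GroundTruthObject], scene: SceneConfig,
                      tile: tuple[int, int],
                      classes: tuple[str, ...] = SPORE_CLASSES) -> np.ndarray:
    """Boolean foreground mask (coverage ≥ 0.5) of the given classes on one tile."""
    cov = np.zeros((scene.tile_height_px, scene.tile_width_px))
    for obj in objects:
        if obj.klass not in classes:
            continue
        hit = _coverage_patch(obj, scene, tile)
        if hit is None:
            continue
        patch, y0, x0 = hit
        ph, pw = patch.shape
        np.maximum(cov[y0:y0 + ph, x0:x0 + pw], patch,
                   out=cov[y0:y0 + ph, x0:x0 + pw])
    return cov >= 0.5


def _objects_near_tile(objects: list[GroundTruthObject], scene: SceneConfig,
                       tile: tuple[int, int]) -> list[GroundTruthObject]:
    row, col = tile
    s = scene.um_per_px
    x_lo = col * scene.tile_width_px * s
    x_hi = x_lo + scene.tile_width_px * s
    y_lo = row * scene.tile_height_px * s
    y_hi = y_lo + scene.tile_height_px * s
    out = []
    for o in objects:
        r = o.radius_um + 2 * s
        x, y = o.center_um
        if x_lo - r <= x <= x_hi + r and y_lo - r <= y <= y_hi + r:
            out.append(o)
    return out


def objects_from_table(truth: pd.DataFrame) -> list[GroundTruthObject]:
    """Rebuild GroundTruthObject instances from a ground-truth table."""
    return [GroundTruthObject(
        id=int(r.id), klass=r.klass, center_um=(r.center_x_um, r.center_y_um),
        diameter_um=r.diameter_um, axis_ratio=r.axis_ratio,
        orientation=r.orientation_rad, tile=(int(r.tile_row), int(r.tile_col)))
        for r in truth.itertuples()]


def ground_truth_table(objects: list[GroundTruthObject]) -> pd.DataFrame:
    rows = [{
        "id": o.id, "klass": o.klass,
        "center_x_um": o.center_um[0], "center_y_um": o.center_um[1],
        "diameter_um": o.diameter_um, "axis_ratio": o.axis_ratio,
        "orientation_rad": o.orientation,
        "tile_row": o.tile[0], "tile_col": o.tile[1],
    } for o in objects]
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def make_tile_grid(scene: SceneConfig, out_dir=None
                   ) -> tuple[TileGrid, pd.DataFrame]:
    """Generate a full slide: sample, place, render all tiles.

    Returns the in-memory tile grid plus the ground-truth table; when
    ``out_dir`` is given, tiles (TIFF) and the table (CSV) are also written
    with the ``<sample>_r<row>_c<col>`` naming convention.
    """
    rng = np.random.default_rng(scene.seed)
    n_tiles = scene.tile_rows * scene.tile_cols
    n_spores = int(rng.poisson(scene.spores_per_tile_mean * n_tiles))
    diam = sample_diameters(scene.size_model, n_spores, rng)
    objects = place_objects(diam, scene, rng)
    objects = add_contaminants(objects, scene, rng)

    tiles: dict[tuple[int, int], CalibratedImage] = {}
    for row in range(scene.tile_rows):
        for col in range(scene.tile_cols):
            near = _objects_near_tile(objects, scene, (row, col))
            tiles[(row, col)] = render_tile(near, scene, (row, col))
    grid = TileGrid(rows=scene.tile_rows, cols=scene.tile_cols,
                    tiles=tiles, sample_id=scene.sample_id)
    truth = ground_truth_table(objects)
    if out_dir is not None:
        write_tile_grid(grid, out_dir)
        import pathlib
        truth.to_csv(pathlib.Path(out_dir) / f"{scene.sample_id}_ground_truth.csv",
                     index=False)
    return grid, truth


def scaled_scene(scene: SceneConfig, **overrides) -> SceneConfig:
    """Convenience: a copy of ``scene`` with fields replaced."""
    return replace(scene, **overrides)
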