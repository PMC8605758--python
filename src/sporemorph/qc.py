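"""Per-tile quality scores and exclusion rules.

Two proxies decide whether a tile enters the analysis:

* **IScore** — background-intensity consistency.  RGB values are mixed to a
  grayscale, the background is estimated as a high percentile (spores are a
  minority of dark pixels, so a high percentile sees past them) and scored
  as percent of the intensity maximum.  Tiles whose IScore strays from the
  slide median by more than a relative tolerance indicate illumination
  drift and are excluded.

* **BScore** — spore-density proxy.  Dense spore cover darkens the mean
  grayscale, so the mean is mapped linearly between two anchor intensities
  (no spores vs. a field nearly filled with spores) onto 0–100.  Overdense
  tiles (massive clusters, amorphous fill) score low and are excluded
  below a minimum BScore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import CalibratedImage, TileGrid

__all__ = ["QCThresholds", "QCResult", "iscore", "bscore", "qc_filter",
           "qc_report"]


@dataclass
class QCThresholds:
    """Exclusion rules: IScore relative variation and minimum BScore.

    Anchors: ``bright_ref`` defaults to the background acquisition setting
    (90% of max); ``dark_ref`` to 30% of max, the typical spore paint level
    of a fully covered field.  Both are configurable because they delimit
    empirical extreme conditions of a given acquisition setup.
    """

    max_iscore_rel_variation: float = 0.10
    min_bscore: float = 50.0
    bright_ref: float = 0.9 * 255
    dark_ref: float = 0.3 * 255
    background_percentile: float = 95.0

    def __post_init__(self) -> None:
        if not 0 < self.max_iscore_rel_variation < 1:
            raise ValueError("max_iscore_rel_variation must lie in (0, 1)")
        if not 0 <= self.min_bscore <= 100:
            raise ValueError("min_bscore must lie in [0, 100]")
        if self.dark_ref >= self.bright_ref:
            raise ValueError("dark_ref must be below bright_ref")


@dataclass
class QCResult:
    tile: tuple[int, int]
    iscore: float
    bscore: float
    keep: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.keep and not self.reasons:
            raise ValueError("an excluded tile must carry at least one reason")


def iscore(image: CalibratedImage, thresholds: QCThresholds | None = None) -> float:
    """Background-intensity score, 0–100.

    Score = 100 x (high percentile of the grayscale) / max intensity.
    """
    t = thresholds or QCThresholds()
    gray = image.grayscale()
    if gray.size == 0:
        raise ValueError("empty image")
    background = np.percentile(gray, t.background_percentile)
    return float(100.0 * background / image.max_intensity)


def bscore(image: CalibratedImage, thresholds: QCThresholds | None = None) -> float:
    """Brightness score, 0–100; decreases monotonically with spore coverage.

    Score = 100 x clamp((mean grayscale - dark_ref) / (bright_ref - dark_ref)).
    Depends only on the intensity histogram, not on pixel arrangement.
    """
    t = thresholds or QCThresholds()
    mean = float(image.grayscale().mean())
    frac = (mean - t.dark_ref) / (t.bright_ref - t.dark_ref)
    return float(100.0 * min(max(frac, 0.0), 1.0))


def qc_filter(grid: TileGrid, thresholds: QCThresholds | None = None
              ) -> list[QCResult]:
    """Score every tile and apply the exclusion rules.

    A tile is excluded iff its BScore falls below ``min_bscore`` or its
    IScore deviates from the per-slide *median* IScore by more than
    ``max_iscore_rel_variation`` (median, so the outliers being flagged do
    not drag the reference).  Every exclusion lists its rule identifiers.
    """
    t = thresholds or QCThresholds()
    scored = [(tile, iscore(img, t), bscore(img, t))
              for tile, img in grid.items()]
    if not scored:
        return []
    med = float(np.median([i for _, i, _ in scored]))
    results = []
    for tile, i, b in scored:
        reasons = []
        if b < t.min_bscore:
            reasons.append("bscore")
        if med > 0 and abs(i - med) / med > t.max_iscore_rel_variation:
            reasons.append("iscore_variation")
        results.append(QCResult(tile=tile, iscore=i, bscore=b,
                                keep=not reasons, reasons=reasons))
    return results


def qc_report(results: list[QCResult]):
    """QC results as a flat table (tile_row, tile_col, IScore, BScore, keep, reasons)."""
    import pandas as pd
    return pd.DataFrame([{
        "tile_row": r.tile[0], "tile_col": r.tile[1],
        "IScore": r.iscore, "BScore": r.bscore,
        "keep": r.keep, "reasons": ";".join(r.reasons),
    } for r in results])
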