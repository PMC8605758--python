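"""Statistical analysis of spore diameter distributions.

Per-object equivalent diameters (µm) are turned into:

* a Gaussian-kernel frequency-density curve (the R ``density()`` analogue),
* its local extrema above a high-pass threshold, with the analysis interval
  delimited by the outermost threshold crossings,
* a type classification per object (Type 1 normal-sized, Type 2 oversized,
  Types 0/3 out-of-interval non-targets) split at the minimal local
  frequency between the two peaks,
* maximum-likelihood gamma fits per type — spore size distributions are
  right-skewed, and the gamma peak (mode = (k−1)/β) is the preferred
  central measure — plus the spherical volume ratio of the two peaks,
* the mean absolute deviation (MAD) of sporocarp mean diameters, the
  within-region variability measure.

The high-pass threshold is published on a per-count frequency-density
scale tied to sample size; densities here integrate to 1, so the
count-scale default (4e-6) is converted as threshold = 4e-6 · n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .morphometry import sphere_volume

__all__ = [
    "DensityCurve", "ExtremaSet", "TypeSplit", "GammaFit", "SampleSummary",
    "COUNT_SCALE_HIPASS", "density_estimate", "hipass_threshold_norm",
    "find_extrema", "type_split", "classify_types", "fit_gamma",
    "decompose_bimodal", "mad_between", "summarize_sample",
]

#: default high-pass threshold on the count-proportional density scale
COUNT_SCALE_HIPASS = 4e-6

#: relative prominence below which a KDE ripple is not a real maximum
_MIN_RELATIVE_PROMINENCE = 0.01


class NoSignalError(ValueError):
    """No density maximum survives the high-pass threshold."""


@dataclass
class DensityCurve:
    """Kernel density on a regular grid; integrates to 1."""

    grid: np.ndarray          # diameters, µm
    density: np.ndarray
    bandwidth: float          # µm
    n: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class ExtremaSet:
    """Surviving extrema of a density curve plus the analysis interval."""

    maxima: list[tuple[float, float]]     # (diameter, density), ascending
    minima: list[tuple[float, float]]     # between surviving maxima
    hipass_threshold: float
    left_limit: float
    right_limit: float

    @property
    def no_signal(self) -> bool:
        return not self.maxima


@dataclass
class TypeSplit:
    """Diameter interval split between normal-sized and oversized spores."""

    boundary: float | None                # µm; None for unimodal samples
    type1_interval: tuple[float, float]
    type2_interval: tuple[float, float] | None


@dataclass
class GammaFit:
    """Two-parameter gamma fit of a diameter sample (shape k, rate β)."""

    shape: float
    rate: float
    n: int

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be > 0")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) / self.rate

    @property
    def peak_diameter(self) -> float:
        """Mode (k−1)/β for k > 1 — the preferred average spore size."""
        if self.shape <= 1:
            raise ValueError("mode undefined for shape <= 1")
        return (self.shape - 1) / self.rate

    @property
    def skewness(self) -> float:
        return 2.0 / math.sqrt(self.shape)


def _nrd0_bandwidth(values: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth (the R density() default)."""
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate sample: zero spread, bandwidth undefined")
    return 0.9 * spread * n ** (-0.2)


def density_estimate(values, bandwidth: float | None = None,
                     n_grid: int = 512) -> DensityCurve:
    """Gaussian KDE on a regular grid spanning the data range ± 3 bandwidths."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    bw = bandwidth if bandwidth is not None else _nrd0_bandwidth(values)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    kde = stats.gaussian_kde(values, bw_method=bw / values.std(ddof=1))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=bw,
                        n=values.size)


def hipass_threshold_norm(n: int, count_scale: float = COUNT_SCALE_HIPASS
                          ) -> float:
    """Convert the count-scale high-pass threshold to the normalized scale."""
    return count_scale * n


def find_extrema(curve: DensityCurve,
                 hipass_threshold: float | None = None) -> ExtremaSet:
    """Locate density maxima/minima and the threshold-delimited interval.

    Maxima need a relative prominence of at least 1% of the curve maximum
    (KDE micro-ripples are not peaks) and must clear the high-pass
    threshold; minima are retained only between surviving maxima; the
    interval limits are the outermost crossings of density = threshold.
    """
    d = curve.density
    thr = (hipass_threshold if hipass_threshold is not None
           else hipass_threshold_norm(curve.n))
    peaks, _ = signal.find_peaks(
        d, prominence=_MIN_RELATIVE_PROMINENCE * float(d.max()))
    peaks = [p for p in peaks if d[p] >= thr]
    if not peaks:
        return ExtremaSet(maxima=[], minima=[], hipass_threshold=thr,
                          left_limit=float("nan"), right_limit=float("nan"))

    def _refine(i: int) -> tuple[float, float]:
        # quadratic sub-grid interpolation around an interior extremum
        if 0 < i < d.size - 1:
            y0, y1, y2 = d[i - 1], d[i], d[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                off = 0.5 * (y0 - y2) / denom
                if abs(off) <= 1:
                    step = curve.grid[1] - curve.grid[0]
                    return (float(curve.grid[i] + off * step),
                            float(y1 - 0.25 * (y0 - y2) * off))
        return float(curve.grid[i]), float(d[i])

    maxima = [_refine(p) for p in peaks]
    minima = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        m = a + int(np.argmin(d[a:b + 1]))
        minima.append(_refine(m))
    above = d >= thr
    left = int(np.argmax(above))
    right = len(d) - 1 - int(np.argmax(above[::-1]))
    return ExtremaSet(maxima=maxima, minima=minima, hipass_threshold=thr,
                      left_limit=float(curve.grid[left]),
                      right_limit=float(curve.grid[right]))


def type_split(extrema: ExtremaSet) -> TypeSplit:
    """Boundary at the minimal local frequency between the two highest peaks."""
    if extrema.no_signal:
        raise NoSignalError("no density maximum above the high-pass threshold")
    if len(extrema.maxima) < 2:
        return TypeSplit(boundary=None,
                         type1_interval=(extrema.left_limit,
                                         extrema.right_limit),
                         type2_interval=None)
    boundary = min(extrema.minima, key=lambda m: m[1])[0]
    return TypeSplit(boundary=boundary,
                     type1_interval=(extrema.left_limit, boundary),
                     type2_interval=(boundary, extrema.right_limit))


def classify_types(records: pd.DataFrame, extrema: ExtremaSet,
                   diameter_col: str = "diameter_um") -> pd.DataFrame:
    """Assign the Type code per record from the extrema of its sample.

    Type 1: [left_limit, boundary) — normal-sized spores; Type 2:
    [boundary, right_limit] — oversized spores (boundary itself is Type 2);
    Type 0 below the interval, Type 3 above (non-target size classes).
    Unimodal samples have no boundary: every in-interval object is Type 1.
    """
    split = type_split(extrema)
    d = records[diameter_col].to_numpy()
    types = np.full(d.size, 1, dtype=int)
    types[d < extrema.left_limit] = 0
    types[d > extrema.right_limit] = 3
    if split.boundary is not None:
        types[(d >= split.boundary) & (d <= extrema.right_limit)] = 2
    out = records.copy()
    out["Type"] = types
    return out


def fit_gamma(values, min_n: int = 30) -> GammaFit:
    """Maximum-likelihood two-parameter gamma fit (no location shift)."""
    values = np.asarray(values, dtype=float)
    if values.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {values.size}")
    if np.any(values <= 0):
        raise ValueError("gamma fit requires strictly positive values")
    shape, _, scale = stats.gamma.fit(values, floc=0)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0
            and scale > 0):
        raise RuntimeError(
            f"gamma MLE did not converge: shape={shape}, scale={scale}, "
            f"n={values.size}, mean={values.mean():.4g}")
    return GammaFit(shape=float(shape), rate=float(1.0 / scale),
                    n=values.size)


def decompose_bimodal(values, extrema: ExtremaSet
                      ) -> tuple[GammaFit, GammaFit, float]:
    """Split a bimodal sample at the between-peak minimum and fit each side.

    Returns the two gamma fits plus the ratio of spherical volumes at the
    two fitted peaks (reported as 1:r, r rounded to 2 decimals).
    """
    if len(extrema.maxima) < 2:
        raise ValueError("bimodal decomposition needs 2 surviving maxima")
    split = type_split(extrema)
    values = np.asarray(values, dtype=float)
    in_int = (values >= extrema.left_limit) & (values <= extrema.right_limit)
    left = values[in_int & (values < split.boundary)]
    right = values[in_int & (values >= split.boundary)]
    fit1 = fit_gamma(left)
    fit2 = fit_gamma(right)
    ratio = float(sphere_volume(fit2.peak_diameter)
                  / sphere_volume(fit1.peak_diameter))
    return fit1, fit2, round(ratio, 2)


def mad_between(values) -> float:
    """Mean absolute deviation about the arithmetic mean:
    MAD = (1/n) Σ |xᵢ − x̄|."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("MAD of an empty sample is undefined")
    return float(np.abs(values - values.mean()).mean())


@dataclass
class SampleSummary:
    """Per-sporocarp diameter statistics and the between-sporocarp MAD."""

    per_sporocarp: pd.DataFrame     # sporocarp, type, n, mean, sd, skewness, fit
    mad_um: float                   # across sporocarp means, Type 2 excluded
    grand_mean_um: float
    fits: dict[tuple[str, int], GammaFit] = field(default_factory=dict)


def summarize_sample(records: pd.DataFrame, group_col: str = "Indiv",
                     diameter_col: str = "diameter_um",
                     min_fit_n: int = 30) -> SampleSummary:
    """Summarize diameters per sporocarp and compute the between-sporocarp MAD.

    Per sporocarp and spore type (1 and 2): count, mean, sd, bias-corrected
    empirical skewness, and a gamma fit where the group is large enough.
    The MAD is computed across sporocarp mean diameters with Type 2
    (oversized) spores excluded, so one variability number describes the
    normal-sized population.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    rows = []
    fits: dict[tuple[str, int], GammaFit] = {}
    spore_types = [t for t in sorted(records["Type"].unique()) if t in (1, 2)]
    for sporocarp, grp in records.groupby(group_col):
        for t in spore_types:
            vals = grp.loc[grp["Type"] == t, diameter_col].to_numpy()
            if vals.size == 0:
                continue
            row = {
                group_col: sporocarp, "type": t, "n": vals.size,
                "mean_um": vals.mean(),
                "sd_um": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "skewness": (float(stats.skew(vals, bias=False))
                             if vals.size > 2 else float("nan")),
            }
            if vals.size >= min_fit_n:
                fit = fit_gamma(vals, min_n=min_fit_n)
                fits[(sporocarp, t)] = fit
                row.update(gamma_shape=fit.shape, gamma_rate=fit.rate,
                           gamma_peak_um=(fit.peak_diameter
                                          if fit.shape > 1 else float("nan")),
                           gamma_skewness=fit.skewness)
            rows.append(row)
    per = pd.DataFrame(rows)
    normal = records[records["Type"] != 2]
    means = normal.groupby(group_col)[diameter_col].mean().to_numpy()
    return SampleSummary(per_sporocarp=per, mad_um=mad_between(means),
                         grand_mean_um=float(normal[diameter_col].mean()),
                         fits=fits)
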