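"""Ground-truth benchmarking of the full pipeline on synthetic slides.

Defines the package's reference desk-scale benchmark scene — a 12 × 12
grid of 1,280 × 960 px tiles at 0.5 µm/px carrying ≈ 20,000 spores (80/20
normal/oversized gamma mixture, 30% of spores in tangent contact, ≈ 5%
contaminants, normal-sized spores clustered in a central hotspot while
oversized spores scatter uniformly) — and the scoring that matches kept
records back to ground-truth objects:

* recovery: fraction of ground-truth spores yielding exactly one kept record,
* diameter accuracy: per-object error of the equivalent-circle diameter
  (ground truth uses d/√AR, the equivalent-circle diameter of the drawn
  ellipse),
* contact separation: fraction of touching pairs whose members both end up
  as distinct single records,
* false splits: isolated spores matched by more than one record,
* contaminant specificity: fraction of contaminants yielding no kept record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fixtures import SceneConfig, bimodal_size_model
from .pipeline import PipelineConfig, PipelineResult

__all__ = ["benchmark_scene", "benchmark_config", "BenchmarkScores",
           "score_against_truth"]


def benchmark_scene(seed: int = 0, tile_rows: int = 12, tile_cols: int = 12
                    ) -> SceneConfig:
    """The reference synthetic slide the pipeline is benchmarked on."""
    return SceneConfig(
        tile_rows=tile_rows, tile_cols=tile_cols,
        tile_width_px=1280, tile_height_px=960, um_per_px=0.5,
        spores_per_tile_mean=139.0, contact_fraction=0.3,
        size_model=bimodal_size_model(0.2),
        clustered_classes=("spore_normal",),
        contaminant_rates={"fiber": 2.4, "bubble": 2.4, "debris": 2.2},
        sample_id="benchmark", seed=seed)


def benchmark_config(seed: int = 0) -> PipelineConfig:
    """Pipeline settings matched to the benchmark scene's scale."""
    return PipelineConfig(um_per_px=0.5, expected_diameter_um=12.9,
                          seed=seed, n_sims=25_000)


@dataclass
class BenchmarkScores:
    n_truth_spores: int
    n_kept_records: int
    exactly_one_rate: float
    diameter_within_tol_rate: float      # |error| <= tol_um among 1:1 matches
    median_diameter_error_um: float
    pair_separation_rate: float          # touching pairs -> two single records
    false_split_rate: float              # isolated spores with > 1 record
    contaminant_specificity: float       # contaminants with 0 kept records
    n_touching_pairs: int
    n_contaminants: int


def _slide_coords(records: pd.DataFrame, scene: SceneConfig) -> np.ndarray:
    s = scene.um_per_px
    gx = records["X"].to_numpy() * scene.tile_width_px * s \
        + records["centroid_x_px"].to_numpy() * s
    gy = records["Y"].to_numpy() * scene.tile_height_px * s \
        + records["centroid_y_px"].to_numpy() * s
    return np.column_stack([gx, gy])


def score_against_truth(result: PipelineResult, truth: pd.DataFrame,
                        scene: SceneConfig,
                        tol_um: float = 0.25) -> BenchmarkScores:
    """Match kept records to ground truth and score every benchmark metric.

    A ground-truth spore matches the records whose centroid falls within
    45% of its equivalent diameter; a spore is recovered when exactly one
    record matches it.
    """
    rec = result.records
    pts = _slide_coords(rec, scene)
    tree = cKDTree(pts) if len(rec) else None

    spores = truth[truth["klass"].str.startswith("spore")].copy()
    spores["eq_d"] = spores["diameter_um"] / np.sqrt(spores["axis_ratio"])
    centers = spores[["center_x_um", "center_y_um"]].to_numpy()
    eq_d = spores["eq_d"].to_numpy()

    n_matches = np.zeros(len(spores), dtype=int)
    errors = np.full(len(spores), np.nan)
    for k in range(len(spores)):
        if tree is None:
            break
        idx = tree.query_ball_point(centers[k], r=eq_d[k] * 0.45)
        n_matches[k] = len(idx)
        if len(idx) == 1:
            errors[k] = rec.iloc[idx[0]]["diameter_um"] - eq_d[k]

    # touching pairs from ground truth geometry
    radii = spores["diameter_um"].to_numpy() / 2
    st = cKDTree(centers)
    reach = float(2 * radii.max()) if len(spores) else 1.0
    touching_pairs = []
    touching_members = set()
    for i, j in st.query_pairs(r=reach):
        d = np.hypot(*(centers[i] - centers[j]))
        if d <= radii[i] + radii[j] + 1e-6:
            touching_pairs.append((i, j))
            touching_members.update((i, j))
    pair_ok = sum(1 for i, j in touching_pairs
                  if n_matches[i] == 1 and n_matches[j] == 1)

    isolated = np.array([k for k in range(len(spores))
                         if k not in touching_members], dtype=int)
    false_splits = int((n_matches[isolated] > 1).sum()) if isolated.size else 0

    cont = truth[~truth["klass"].str.startswith("spore")]
    cont_hit = 0
    for _, c in cont.iterrows():
        if tree is not None and tree.query_ball_point(
                [c["center_x_um"], c["center_y_um"]],
                r=max(c["diameter_um"] * 0.5, 5.0)):
            cont_hit += 1

    matched = ~np.isnan(errors)
    return BenchmarkScores(
        n_truth_spores=len(spores),
        n_kept_records=len(rec),
        exactly_one_rate=float((n_matches == 1).mean()),
        diameter_within_tol_rate=float(
            (np.abs(errors[matched]) <= tol_um).mean()) if matched.any() else 0.0,
        median_diameter_error_um=float(np.median(errors[matched]))
        if matched.any() else float("nan"),
        pair_separation_rate=(pair_ok / len(touching_pairs)
                              if touching_pairs else 1.0),
        false_split_rate=(false_splits / isolated.size if isolated.size else 0.0),
        contaminant_specificity=(1.0 - cont_hit / len(cont)
                                 if len(cont) else 1.0),
        n_touching_pairs=len(touching_pairs),
        n_contaminants=len(cont))
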