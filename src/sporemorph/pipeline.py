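"""End-to-end orchestration: QC → segmentation → separation → morphometry
→ distribution statistics → spatial statistics.

`run_pipeline` is the library entry point the command-line interface wraps:
it takes a calibrated tile grid and a `PipelineConfig` and returns every
stage's output plus a run manifest (config hash, seed, per-stage object
counts) so a batch of specimens can be processed reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distributions import (SampleSummary, classify_types, density_estimate,
                            find_extrema, hipass_threshold_norm,
                            summarize_sample, type_split)
from .imaging_io import TileGrid, write_records
from .morphometry import FilterRules, label_objects, measure_objects
from .qc import QCThresholds, qc_filter, qc_report
from .segmentation import PixelModel, binarize, classify_pixels, threshold_fallback
from .separation import (SeparationParams, calibrate_eigen_threshold,
                         separate_mask)
from .spatial import monte_carlo_test, tile_field

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the processing chain, YAML-serializable.

    The expected modal spore diameter (µm) drives the scale-dependent
    defaults: the junction-link radius (0.6 x modal diameter in px) and the
    minimum-area filter (5.25 µm equivalent diameter at any pixel scale).
    """

    um_per_px: float = 0.12
    expected_diameter_um: float = 12.0
    seed: int = 0
    # qc
    qc: QCThresholds = field(default_factory=QCThresholds)
    # segmentation
    model_path: str | None = None        # None -> Otsu threshold fallback
    prob_threshold: float = 0.5
    min_speck_px: int = 20
    max_hole_px: int = 64
    # separation
    smoothing_scale: float = 1.0
    integration_scale: float | None = None   # None -> diameter_px / 6
    eigen_threshold: float | None = None     # None -> calibrate on a disk tile
    threshold_factor: float = 5.0
    # morphometry
    measure_mode: str = "outline"
    min_diameter_um: float = 5.25
    max_ar: float = 2.0
    min_circ: float = 0.7
    exclude_border_objects: bool = False
    # distributions
    hipass_count_scale: float = 4e-6
    # spatial
    n_sims: int = 25_000
    weights_scheme: str = "queen"

    def separation_params(self) -> SeparationParams:
        d_px = self.expected_diameter_um / self.um_per_px
        integ = (self.integration_scale if self.integration_scale is not None
                 else min(max(d_px / 10.0, 1.5), 5.0))
        return SeparationParams(
            smoothing_scale=self.smoothing_scale,
            integration_scale=integ,
            eigen_threshold=self.eigen_threshold,
            max_radius_px=0.6 * d_px,
            threshold_factor=self.threshold_factor)

    def filter_rules(self) -> FilterRules:
        return FilterRules.for_scale(
            self.um_per_px, min_diameter_um=self.min_diameter_um,
            max_ar=self.max_ar, min_circ=self.min_circ,
            exclude_border_objects=self.exclude_border_objects)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        import yaml
        data = asdict(self)
        data["qc"] = asdict(self.qc)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        if "qc" in data and isinstance(data["qc"], dict):
            data["qc"] = QCThresholds(**data["qc"])
        return cls(**data)


@dataclass
class PipelineResult:
    records: pd.DataFrame                 # kept objects, Type assigned
    rejected: pd.DataFrame
    qc: pd.DataFrame
    summary: SampleSummary | None
    extrema: object
    spatial: dict[int, object]            # spore type -> MoranResult
    manifest: dict


def _segment_tile(img, model: PixelModel | None, cfg: PipelineConfig):
    if model is not None:
        prob = classify_pixels(model, img)
        return binarize(prob, cfg.prob_threshold, cfg.min_speck_px,
                        cfg.max_hole_px)
    return threshold_fallback(img, cfg.min_speck_px, cfg.max_hole_px)


def run_pipeline(grid: TileGrid, config: PipelineConfig | None = None,
                 model: PixelModel | None = None,
                 out_dir=None) -> PipelineResult:
    """Run the full chain on one specimen's tile grid.

    Stages run in acquisition order; excluded tiles contribute no records.
    When ``out_dir`` is set, the object table, QC report, summary and
    spatial report are written there with the seed and config hash in a
    manifest sidecar.
    """
    cfg = config or PipelineConfig(um_per_px=grid.um_per_px)
    if model is None and cfg.model_path:
        model = PixelModel.load(cfg.model_path)
    manifest = {
        "sporemorph_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "sample_id": grid.sample_id,
        "stages": {},
    }

    # --- QC ------------------------------------------------------------
    qc_results = qc_filter(grid, cfg.qc)
    keep = {r.tile for r in qc_results if r.keep}
    bscores = {r.tile: r.bscore for r in qc_results}
    manifest["stages"]["qc"] = {
        "tiles": len(qc_results), "kept": len(keep),
        "excluded": len(qc_results) - len(keep)}

    # --- separation calibration ----------------------------------------
    sep = cfg.separation_params()
    eigen_thr = sep.eigen_threshold
    if eigen_thr is None:
        eigen_thr = calibrate_eigen_threshold(
            cfg.expected_diameter_um / cfg.um_per_px, sep,
            seed=cfg.seed + 1)

    # --- per-tile segmentation, separation, measurement ----------------
    tile_tables = []
    n_labels = 0
    for (row, col), img in grid.items():
        if (row, col) not in keep:
            continue
        mask = _segment_tile(img, model, cfg)
        mask, _, _ = separate_mask(img, mask, sep, eigen_threshold=eigen_thr)
        labels = label_objects(mask)
        n_labels += int(labels.max())
        tile_tables.append(measure_objects(
            labels, img, mode=cfg.measure_mode,
            tile_index=grid.tile_index(row, col),
            bscore=bscores[(row, col)]))
    if tile_tables:
        measured = pd.concat(tile_tables, ignore_index=True)
    else:
        from .imaging_io import empty_records
        measured = empty_records()
    manifest["stages"]["morphometry"] = {"labeled": n_labels,
                                         "measured": len(measured)}

    # --- shape filtering ------------------------------------------------
    from .morphometry import filter_records
    kept, rejected = filter_records(measured, cfg.filter_rules())
    manifest["stages"]["filter"] = {"kept": len(kept),
                                    "rejected": len(rejected)}

    # --- distribution statistics ---------------------------------------
    extrema = None
    summary = None
    spatial_results: dict[int, object] = {}
    if len(kept) >= 2:
        curve = density_estimate(kept["diameter_um"].to_numpy())
        extrema = find_extrema(
            curve, hipass_threshold_norm(curve.n, cfg.hipass_count_scale))
        if not extrema.no_signal:
            kept = classify_types(kept, extrema)
            split = type_split(extrema)
            try:
                summary = summarize_sample(kept[kept["Type"].isin((1, 2))])
            except ValueError:
                summary = None
            # --- spatial statistics per spore type ----------------------
            intervals = {1: split.type1_interval}
            if split.type2_interval is not None:
                intervals[2] = split.type2_interval
            for t, interval in intervals.items():
                fld = tile_field(kept, interval, (grid.rows, grid.cols))
                if np.ptp(fld.values) > 0:
                    spatial_results[t] = monte_carlo_test(
                        fld, n_sims=cfg.n_sims, seed=cfg.seed + 2 + t,
                        scheme=cfg.weights_scheme)
    manifest["stages"]["distributions"] = {
        "n_analyzed": int(len(kept)),
        "n_maxima": 0 if extrema is None else len(extrema.maxima)}

    result = PipelineResult(records=kept, rejected=rejected,
                            qc=qc_report(qc_results), summary=summary,
                            extrema=extrema, spatial=spatial_results,
                            manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, grid, out_dir)
    return result


def _write_outputs(result: PipelineResult, grid: TileGrid, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_records(result.records, out / f"{grid.sample_id}_records.csv")
    if len(result.rejected):
        result.rejected.to_csv(out / f"{grid.sample_id}_rejected.csv",
                               index=False)
    result.qc.to_csv(out / f"{grid.sample_id}_qc.csv", index=False)
    if result.summary is not None:
        result.summary.per_sporocarp.to_csv(
            out / f"{grid.sample_id}_summary.csv", index=False)
    if result.spatial:
        rows = [{"type": t, "I_obs": r.I_obs,
                 "expected_null": r.expected_null, "p_value": r.p_value,
                 "n_sims": r.n_sims, "weights_scheme": r.weights_scheme,
                 "seed": r.seed}
                for t, r in result.spatial.items()]
        pd.DataFrame(rows).to_csv(out / f"{grid.sample_id}_spatial.csv",
                                  index=False)
    (out / f"{grid.sample_id}_manifest.json").write_text(
        json.dumps(result.manifest, indent=2))
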