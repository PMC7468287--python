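"""End-to-end orchestration of both analysis arms from one configuration.

The growth arm runs, for every consecutive week pair: (optional) affine
pre-alignment, diffeomorphic registration, raw Jacobian map, global
volume ratio, normalised Jacobian map, per-region growth summary,
displacement magnitude/arrow exports and Dice validation.  The contrast
arm generates (or reads) a layered expression table and produces the
per-layer percentile fold-change report.

Every artifact is listed in a manifest JSON with a checksum computed on
value arrays rounded to 1e-6, so repeated runs with the same seed are
checksum-identical across platforms.  The log records each convention
default actually used (direction, normalisation mode, pseudocount,
percentile rule) so they are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .core import DisplacementField, GrowthSeries
from .displacement import SliceSpec, arrow_plot, magnitude_map
from .errors import PipelineError
from .growth import (global_growth, global_growth_from_jacobian,
                     jacobian_determinant, normalize_jacobian, region_growth_summary)
from .registration import RegistrationParams, register_pair, warp_volume
from .synthetic import ExpressionSpec, PhantomSpec, generate_expression, generate_phantom
from .transcriptome import RegionSetConfig, contrast_report
from .validation import multiclass_dice, validate_registration

__all__ = ["PipelineConfig", "run_growth_pipeline", "run_contrast_pipeline", "load_config"]

log = logging.getLogger("morphogrowth")


@dataclass
class PipelineConfig:
    """One config drives both arms; every convention gap has a named key."""

    output_dir: str = "morphogrowth_out"
    seed: int = 0
    # growth arm
    phantom: Optional[PhantomSpec] = None
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    affine_first: bool = True
    direction: str = "forward"          # forward: Jacobian > 1 encodes growth
    normalization: str = "mask_ratio"   # or "jacobian_geomean"
    arrow_stride: int = 4
    # contrast arm
    expression: Optional[ExpressionSpec] = None
    expression_path: Optional[str] = None
    regions: Optional[RegionSetConfig] = None
    percentile: float = 99.9
    pseudocount: float = 0.5

    def __post_init__(self):
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        if self.normalization not in ("mask_ratio", "jacobian_geomean"):
            raise ValueError("normalization must be 'mask_ratio' or 'jacobian_geomean'")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "phantom" in kwargs and kwargs["phantom"] is not None:
        ph = dict(kwargs["phantom"])
        for key in ("grid_shape", "spacing_mm"):
            if key in ph:
                ph[key] = tuple(ph[key])
        kwargs["phantom"] = PhantomSpec(**ph)
    if "registration" in kwargs and kwargs["registration"] is not None:
        rg = dict(kwargs["registration"])
        for key in ("iterations", "sigma_update_vox", "interp_order"):
            if key in rg:
                rg[key] = tuple(rg[key])
        kwargs["registration"] = RegistrationParams(**rg)
    if "expression" in kwargs and kwargs["expression"] is not None:
        ex = dict(kwargs["expression"])
        for key in ("layers", "target_regions", "contrast_regions", "planted_fold_range"):
            if key in ex:
                ex[key] = tuple(ex[key])
        kwargs["expression"] = ExpressionSpec(**ex)
    if "regions" in kwargs and kwargs["regions"] is not None:
        rc = dict(kwargs["regions"])
        for key in ("target_structures", "contrast_structures", "layers"):
            if key in rc:
                rc[key] = tuple(rc[key])
        kwargs["regions"] = RegionSetConfig(**rc)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------


def _checksum_array(arr: np.ndarray) -> str:
    rounded = np.round(np.asarray(arr, dtype=np.float64), 6) + 0.0  # normalise -0.0
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(rounded.tobytes())
    return h.hexdigest()


def _checksum_frame(df: pd.DataFrame) -> str:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(6) + 0.0
    return hashlib.sha256(out.to_csv(index=False).encode()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: List[Dict] = []

    def add(self, path: Path, kind: str, checksum: str) -> None:
        self.entries.append({
            "path": str(path.relative_to(self.out_dir)),
            "kind": kind,
            "sha256": checksum,
        })

    def write(self, name: str, extra: Dict | None = None) -> Path:
        payload = {"artifacts": self.entries}
        if extra:
            payload.update(extra)
        path = self.out_dir / name
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return path


def _build_series(cfg: PipelineConfig) -> GrowthSeries:
    if cfg.phantom is None:
        raise PipelineError("input", "no phantom spec configured (user-volume input "
                                     "is supplied programmatically via run_growth_pipeline(series=...))")
    spec = cfg.phantom
    if spec.seed != cfg.seed:
        spec = PhantomSpec(**{**asdict(spec), "seed": cfg.seed})
    return generate_phantom(spec)


def run_growth_pipeline(cfg: PipelineConfig, series: GrowthSeries | None = None) -> Dict:
    """Run the full imaging arm; returns the manifest payload."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    log.info("growth arm: direction=%s normalization=%s affine_first=%s",
             cfg.direction, cfg.normalization, cfg.affine_first)

    if series is None:
        series = _build_series(cfg)

    fields: List[DisplacementField] = []
    for k in range(series.n_weeks - 1):
        stage = "registration"
        try:
            if cfg.direction == "forward":
                moving, fixed = series.volumes[k + 1], series.volumes[k]
            else:
                moving, fixed = series.volumes[k], series.volumes[k + 1]
            disp, aff = register_pair(moving, fixed, cfg.registration,
                                      affine_first=cfg.affine_first)
            fields.append(disp)
            fpath = out / f"field_{k}to{k + 1}.nii.gz"
            mio.write_field(disp, fpath)
            manifest.add(fpath, "displacement_field", _checksum_array(disp.vectors))
            apath = out / f"affine_{k}to{k + 1}.txt"
            aff.save(apath)
            manifest.add(apath, "affine", _checksum_array(aff.to_matrix()))

            stage = "jacobian"
            jraw = jacobian_determinant(disp)
            jr_path = out / f"jacobian_raw_{k}to{k + 1}.nii.gz"
            mio.write_volume(jraw.as_volume(), jr_path)
            manifest.add(jr_path, "jacobian_raw", _checksum_array(jraw.values))

            stage = "normalization"
            src_lab, tgt_lab = series.labels[k], series.labels[k + 1]
            if cfg.normalization == "mask_ratio":
                ratio = global_growth(src_lab, tgt_lab)
            else:
                ratio = global_growth_from_jacobian(jraw, src_lab.mask())
            jnorm = normalize_jacobian(jraw, ratio)
            jn_path = out / f"jacobian_norm_{k}to{k + 1}.nii.gz"
            mio.write_volume(jnorm.as_volume(), jn_path)
            manifest.add(jn_path, "jacobian_norm", _checksum_array(jnorm.values))
            log.info("pair %d->%d: global volume ratio R=%.4f", k, k + 1, ratio)

            stage = "region_summary"
            summary = region_growth_summary(jnorm, src_lab, global_growth_fraction=ratio - 1.0)
            sm_path = out / f"region_growth_{k}to{k + 1}.csv"
            summary.to_csv(sm_path, index=False)
            manifest.add(sm_path, "region_growth", _checksum_frame(summary))

            stage = "displacement_maps"
            mag = magnitude_map(disp)
            mg_path = out / f"magnitude_{k}to{k + 1}.nii.gz"
            mio.write_volume(mag, mg_path)
            manifest.add(mg_path, "magnitude", _checksum_array(mag.values))
            spec = SliceSpec(plane="coronal", index=disp.shape[1] // 2, stride=cfg.arrow_stride)
            fig_path = out / f"arrows_{k}to{k + 1}.png"
            csv_path = out / f"arrows_{k}to{k + 1}.csv"
            data = arrow_plot(disp, src_lab, spec, fig_path, export_path=csv_path)
            manifest.add(csv_path, "arrow_data", _checksum_frame(data))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc), pair=k) from exc

    try:
        dice = validate_registration(series, fields)
    except Exception as exc:
        raise PipelineError("validation", str(exc)) from exc
    dice_path = out / "dice_validation.csv"
    dice.to_csv(dice_path, index=False)
    manifest.add(dice_path, "dice", _checksum_frame(dice))

    payload_extra = {
        "settings": {
            "direction": cfg.direction,
            "normalization": cfg.normalization,
            "affine_first": cfg.affine_first,
            "seed": cfg.seed,
        }
    }
    manifest.write("growth_manifest.json", payload_extra)
    return {"artifacts": manifest.entries, **payload_extra}


def run_contrast_pipeline(cfg: PipelineConfig) -> Dict:
    """Run the transcriptome arm; returns the manifest payload including
    per-layer cutoffs."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    log.info("contrast arm: percentile=%.2f pseudocount=%.2f", cfg.percentile, cfg.pseudocount)

    if cfg.expression_path:
        table = mio.read_expression(cfg.expression_path)
        if cfg.regions is None:
            raise PipelineError("contrast", "expression_path requires an explicit regions config")
        regions = cfg.regions
    else:
        spec = cfg.expression or ExpressionSpec()
        if spec.seed != cfg.seed:
            spec = ExpressionSpec(**{**asdict(spec), "seed": cfg.seed})
        table, truth = generate_expression(spec)
        truth_path = out / "planted_truth.csv"
        truth.to_csv(truth_path, index=False)
        manifest.add(truth_path, "planted_truth", _checksum_frame(truth))
        regions = cfg.regions or RegionSetConfig(
            target_structures=spec.target_regions,
            contrast_structures=spec.contrast_regions,
            layers=spec.layers,
        )

    result = contrast_report(table, regions, percentile=cfg.percentile,
                             pseudocount=cfg.pseudocount)
    for warning in result.warnings:
        log.warning("contrast: %s", warning)

    report_path = out / "contrast_selection.csv"
    mio.write_contrast_report(result, report_path)
    manifest.add(report_path, "contrast_selection",
                 hashlib.sha256(report_path.read_bytes()).hexdigest())

    cutoff_rows = [
        {"layer": layer, "cutoff_fold": lc.cutoff_fold, "n_selected": lc.n_selected,
         "n_dropped_genes": lc.n_dropped_genes}
        for layer, lc in result.layers.items()
    ]
    cutoffs = pd.DataFrame(cutoff_rows)
    cut_path = out / "layer_cutoffs.csv"
    cutoffs.to_csv(cut_path, index=False)
    manifest.add(cut_path, "layer_cutoffs", _checksum_frame(cutoffs))

    extra = {"cutoffs": {r["layer"]: round(r["cutoff_fold"], 6) for r in cutoff_rows},
             "settings": {"percentile": cfg.percentile, "pseudocount": cfg.pseudocount,
                          "seed": cfg.seed}}
    manifest.write("contrast_manifest.json", extra)
    return {"artifacts": manifest.entries, **extra}
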