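"""End-to-end orchestration: preprocess -> ensemble predict -> CRF -> area.

`segment_slice` runs one gray slice through the configured stages and
`run_on_samples` maps it over a slice set, collecting per-slice reports and
aggregate metrics.  Stage toggles mirror the ablation rows of the method
(base network / + CRF / + preprocessing): with every optional stage off, the
output is exactly the thresholded rotation-ensemble prediction.  A single
top-level seed drives every stochastic stage (the boundary smoother); file
I/O (PNG/NIfTI in, PNG/JSON/CSV out) lives at the edges so the core remains
array-in/array-out.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .area import SmootherConfig, estimate_area
from .crf import CrfParams, refine
from .metrics import MetricReport, evaluate_masks
from .sepunet import EnsembleWeights, SepUNet, predict, rotation_ensemble

logger = logging.getLogger("osteoseg")

__all__ = ["PipelineConfig", "SliceReport", "segment_slice", "run_on_samples",
           "ablation_run", "run_pipeline", "load_slices"]


@dataclass
class PipelineConfig:
    use_preprocess: bool = True
    use_crf: bool = True
    use_ensemble: bool = True
    pixel_spacing: float = 1.0  # mm/pixel
    mask_threshold: float = 0.5
    plane: str = "axial"  # axial | coronal | sagittal (metadata tag)
    seed: int = 0
    ensemble: EnsembleWeights = field(default_factory=EnsembleWeights)
    crf: CrfParams = field(default_factory=CrfParams)
    threshold_params: pp.ThresholdParams = field(default_factory=pp.ThresholdParams)
    min_spot_px: int = 9
    smoother: str = "pf"
    cell_side_mm: float = 4.0
    boundary_spacing_mm: float = 1.0

    def validate(self) -> None:
        if self.plane not in ("axial", "coronal", "sagittal"):
            raise ValueError("plane must be axial, coronal or sagittal")
        self.ensemble.validate()
        self.crf.validate()


@dataclass
class SliceReport:
    slice_id: str
    plane: str
    S_os: float  # mm^2
    metrics: MetricReport | None
    provenance: dict


def segment_slice(image: np.ndarray, model: SepUNet, config: PipelineConfig):
    """One slice through the configured stages.

    Returns ``(mask, prob, region, area_result)``; ``region`` is None when
    preprocessing is off or the binarized slice is empty.
    """
    config.validate()
    img = np.asarray(image)
    region = None
    prov = {}
    t0 = time.perf_counter()

    target = img
    if config.use_preprocess:
        T = pp.compute_threshold(img, config.threshold_params)
        body = pp.clean_mask(pp.binarize(img, T), config.min_spot_px, True)
        prov["threshold"] = T
        if body.any():
            region = pp.credible_region(body)
            target = pp.apply_region(img, region, mode="zero-outside")

    if config.use_ensemble:
        prob = rotation_ensemble(
            model, target, config.ensemble, spacing=config.pixel_spacing
        ).values
    else:
        prob = predict(model, target, spacing=config.pixel_spacing).values

    if region is not None:
        keep = np.zeros_like(prob)
        sl = (slice(region.min_y, region.max_y + 1), slice(region.min_x, region.max_x + 1))
        keep[sl] = prob[sl]
        prob = keep

    if config.use_crf:
        _, prob = refine(prob, img, config.crf)

    mask = (prob >= config.mask_threshold).astype(np.uint8)
    area_res = estimate_area(
        mask,
        config.pixel_spacing,
        cell_side=config.cell_side_mm,
        sample_spacing=config.boundary_spacing_mm,
        smoother=config.smoother,
        smoother_cfg=SmootherConfig(seed=config.seed),
    )
    prov["elapsed_s"] = round(time.perf_counter() - t0, 4)
    prov["seed"] = config.seed
    prov["stages"] = {
        "preprocess": config.use_preprocess,
        "ensemble": config.use_ensemble,
        "crf": config.use_crf,
    }
    return mask, prob, region, area_res, prov


def run_on_samples(samples, model: SepUNet, config: PipelineConfig):
    """Run the pipeline over slices with optional ground truth.

    ``samples``: objects with ``.image`` and optionally ``.mask``.  Returns
    ``(reports, aggregate)`` where aggregate holds the mean of each defined
    metric over slices with ground truth.
    """
    reports = []
    for i, s in enumerate(samples):
        mask, prob, region, area_res, prov = segment_slice(s.image, model, config)
        gt = getattr(s, "mask", None)
        rep = SliceReport(
            slice_id=str(getattr(s, "seed", i)),
            plane=config.plane,
            S_os=area_res.S_os,
            metrics=evaluate_masks(mask, gt) if gt is not None else None,
            provenance=prov,
        )
        logger.info("slice %s: S_os=%.1f mm^2 (%.2fs)", rep.slice_id, rep.S_os,
                    prov["elapsed_s"])
        reports.append(rep)
    agg = {}
    scored = [r.metrics for r in reports if r.metrics is not None]
    if scored:
        for name in ("Acc", "Pre", "Re", "F1", "IOU", "DSC"):
            vals = [getattr(m, name) for m in scored]
            agg[name] = float(np.nanmean(vals))
        agg["n_scored"] = len(scored)
    return reports, agg


_ABLATION_ROWS = {
    "base": dict(use_crf=False, use_preprocess=False),
    "+crf": dict(use_crf=True, use_preprocess=False),
    "+prop": dict(use_crf=True, use_preprocess=True),
}


def ablation_run(samples, model: SepUNet, config: PipelineConfig,
                 rows=("base", "+crf", "+prop")) -> pd.DataFrame:
    """Metric table over stage-toggle configurations on one evaluation set."""
    records = []
    for row in rows:
        if row not in _ABLATION_ROWS:
            raise ValueError(f"unknown ablation row: {row!r}")
        cfg = PipelineConfig(**{**_cfg_dict(config), **_ABLATION_ROWS[row]})
        _, agg = run_on_samples(samples, model, cfg)
        records.append(
            {
                "Model": row,
                "Pr": agg.get("Pre"),
                "Re": agg.get("Re"),
                "F1": agg.get("F1"),
                "IOU": agg.get("IOU"),
                "DSC": agg.get("DSC"),
            }
        )
    return pd.DataFrame.from_records(records)


def _cfg_dict(config: PipelineConfig) -> dict:
    return {
        "use_preprocess": config.use_preprocess,
        "use_crf": config.use_crf,
        "use_ensemble": config.use_ensemble,
        "pixel_spacing": config.pixel_spacing,
        "mask_threshold": config.mask_threshold,
        "plane": config.plane,
        "seed": config.seed,
        "ensemble": config.ensemble,
        "crf": config.crf,
        "threshold_params": config.threshold_params,
        "min_spot_px": config.min_spot_px,
        "smoother": config.smoother,
        "cell_side_mm": config.cell_side_mm,
        "boundary_spacing_mm": config.boundary_spacing_mm,
    }


# ---------------------------------------------------------------------------
# file-based entry point
# ---------------------------------------------------------------------------

def load_slices(input_dir) -> list:
    """Load gray PNG (or single-slice .nii) slices, with *_mask.png truth."""
    import imageio.v3 as iio

    class _Slice:
        def __init__(self, slice_id, image, mask):
            self.slice_id = slice_id
            self.image = image
            self.mask = mask
            self.seed = slice_id

    out = []
    input_dir = Path(input_dir)
    for p in sorted(input_dir.glob("*.png")):
        if p.stem.endswith("_mask"):
            continue
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img[..., 0]
        mp = input_dir / f"{p.stem}_mask.png"
        mask = (np.asarray(iio.imread(mp)) > 127).astype(np.uint8) if mp.exists() else None
        out.append(_Slice(p.stem, img, mask))
    for p in sorted(input_dir.glob("*.nii")):
        import nibabel as nib

        vol = np.asarray(nib.load(str(p)).dataobj)
        out.append(_Slice(p.stem, np.squeeze(vol), None))
    return out


def run_pipeline(config: PipelineConfig, model: SepUNet, input_dir, output_dir):
    """Directory-in, directory-out run; writes masks, 16-bit probabilities,
    per-slice area JSON and a metrics CSV."""
    import imageio.v3 as iio

    slices = load_slices(input_dir)
    if not slices:
        raise FileNotFoundError(f"no readable slices under {input_dir}")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    for s in slices:
        try:
            mask, prob, region, area_res, prov = segment_slice(s.image, model, config)
        except Exception:
            logger.exception("slice %s unreadable/failed: skipped", s.slice_id)
            continue
        iio.imwrite(output_dir / f"{s.slice_id}_mask.png", (mask * 255).astype(np.uint8))
        iio.imwrite(
            output_dir / f"{s.slice_id}_prob.png",
            np.round(np.clip(prob, 0, 1) * 65535).astype(np.uint16),
        )
        (output_dir / f"{s.slice_id}_area.json").write_text(
            json.dumps({"S_os_mm2": area_res.S_os, "M1": area_res.M1,
                        "M2": area_res.M2, **area_res.metadata}, indent=2)
        )
        rep = SliceReport(
            slice_id=s.slice_id,
            plane=config.plane,
            S_os=area_res.S_os,
            metrics=evaluate_masks(mask, s.mask) if s.mask is not None else None,
            provenance=prov,
        )
        reports.append(rep)
    rows = []
    for r in reports:
        row = {"slice": r.slice_id, "plane": r.plane, "S_os_mm2": r.S_os}
        if r.metrics:
            row.update({k: getattr(r.metrics, k) for k in ("Acc", "Pre", "Re", "F1", "IOU", "DSC")})
        rows.append(row)
    pd.DataFrame(rows).to_csv(output_dir / "report.csv", index=False)
    return reports
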