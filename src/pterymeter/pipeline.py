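"""End-to-end orchestration: images/masks -> measurements -> agreement report.

The pipeline mirrors the three-stage system: obtain a cornea mask (from a
trained network or supplied ground truth), regularize it with a direct
least-squares ellipse fit, obtain a pterygium mask (network or ground
truth), smooth its edges, bring both masks to a common 512x512 working
resolution, and run the geometric measurement.  A ground-truth-mask mode is
first-class so the geometric and statistical layers can be exercised and
validated without any trained network.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from skimage.transform import resize

from .geometry import (DEFAULT_DIAMETER_MM, DEFAULT_SURGERY_THRESHOLD_MM,
                       extract_boundary, fit_ellipse, rasterize_ellipse, measure)
from .segmentation import (load_checkpoint, preprocess, prob_to_mask,
                           smooth_edges)
from .nn import Tensor
from .stats import (BinaryConfusion, CrossTab, binary_metrics, bland_altman,
                    chi_square_with_C, cohen_kappa, roc_auc_youden)

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_report",
           "MEASUREMENT_COLUMNS"]

log = logging.getLogger("pterymeter.pipeline")

MEASUREMENT_COLUMNS = ["Images", "RD", "MD", "WP_mm", "CLASS", "Area_mm2"]


@dataclass
class PipelineConfig:
    dataset_dir: str | Path = "."
    output_dir: str | Path = "out"
    diameter_mm: float = DEFAULT_DIAMETER_MM
    surgery_threshold_mm: float = DEFAULT_SURGERY_THRESHOLD_MM
    md_mode: str = "global_min"          # global_min | transverse
    use_networks: bool = False
    cornea_checkpoint: str | Path | None = None
    pterygium_checkpoint: str | Path | None = None
    ellipse_regularize: bool = True
    smooth_radius: int = 2
    working_size: int = 512
    seed: int = 0
    save_json: bool = True

    def validate(self):
        if self.surgery_threshold_mm <= 0:
            raise ValueError("surgery threshold must be positive")
        if not (5.0 <= self.diameter_mm <= 20.0):
            raise ValueError("diameter_mm outside sane range [5, 20] mm")
        lo, hi = 10.7, 12.58
        if not (lo <= self.diameter_mm <= hi):
            warnings.warn(
                f"diameter {self.diameter_mm} mm outside the anatomical "
                f"range [{lo}, {hi}] mm", stacklevel=2)
        if self.use_networks and (self.cornea_checkpoint is None
                                  or self.pterygium_checkpoint is None):
            raise ValueError("network mode requires both checkpoints")


def _read_mask(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def _regularize_cornea(mask: np.ndarray) -> np.ndarray:
    try:
        pts = extract_boundary(mask)
        e = fit_ellipse(pts)
        return rasterize_ellipse(e, mask.shape)
    except ValueError:
        log.warning("ellipse fit failed; using raw cornea mask")
        return mask


def _predict_mask(model, image: np.ndarray, stage: str) -> np.ndarray:
    prepped = preprocess(image, stage) / 255.0
    x = prepped.transpose(2, 0, 1)[None]
    probs = model(Tensor(x)).sigmoid().data[0, 0]
    return prob_to_mask(probs)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Measure every sample of a dataset directory; returns the table.

    Expects the layout written by ``synthetic.make_dataset`` (``images/``,
    ``masks/``, ``manifest.csv``); with ``use_networks=True`` the masks come
    from the checkpoints instead of the ``masks/`` directory.  Writes
    ``measurements.csv`` (schema: Images, RD, MD, WP_mm, CLASS, Area_mm2)
    and optionally one JSON per sample.  Per-sample failures are logged and
    skipped; their count is reported in the summary.
    """
    config.validate()
    root = Path(config.dataset_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.csv"
    if manifest_path.exists():
        sample_ids = list(pd.read_csv(manifest_path)["sample_id"])
    else:
        sample_ids = sorted(p.stem for p in (root / "images").glob("*.png"))
    cornea_model = pterygium_model = None
    if config.use_networks:
        cornea_model, _, _ = load_checkpoint(config.cornea_checkpoint)
        pterygium_model, _, _ = load_checkpoint(config.pterygium_checkpoint)

    rows, failures = [], 0
    s = config.working_size
    for sid in sample_ids:
        t0 = time.perf_counter()
        try:
            if config.use_networks:
                image = iio.imread(root / "images" / f"{sid}.png")
                cornea = _predict_mask(cornea_model, image, "cornea")
                pterygium_small = _predict_mask(pterygium_model, image, "pterygium")
            else:
                cornea = _read_mask(root / "masks" / f"{sid}_cornea.png")
                pterygium_small = _read_mask(root / "masks" / f"{sid}_pterygium.png")
            if config.ellipse_regularize:
                cornea = _regularize_cornea(cornea)
            if config.smooth_radius and config.use_networks:
                pterygium_small = smooth_edges(pterygium_small,
                                               config.smooth_radius)
            cornea = resize(cornea.astype(float), (s, s), order=0,
                            anti_aliasing=False) > 0.5
            pterygium = resize(pterygium_small.astype(float), (s, s), order=0,
                               anti_aliasing=False) > 0.5
            result = measure(cornea, pterygium,
                             diameter_mm=config.diameter_mm,
                             surgery_threshold_mm=config.surgery_threshold_mm,
                             md_mode=config.md_mode)
            rows.append(result.as_row(sid))
            if config.save_json:
                payload = result.as_row(sid)
                payload["area_ratio"] = result.area_ratio
                (out / f"{sid}.json").write_text(json.dumps(payload, indent=2))
            log.info("stage=measure sample=%s elapsed=%.3fs status=%d",
                     sid, time.perf_counter() - t0, result.status)
        except Exception as exc:  # per-sample robustness
            failures += 1
            log.error("stage=measure sample=%s outcome=failed error=%s", sid, exc)
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    table.to_csv(out / "measurements.csv", index=False)
    counts = table["CLASS"].value_counts().to_dict() if len(table) else {}
    summary = {"n_samples": len(sample_ids), "n_measured": len(table),
               "n_failed": failures,
               "class_counts": {str(k): int(v) for k, v in sorted(counts.items())}}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline done: %s", summary)
    return table


def _id_column(df: pd.DataFrame) -> str:
    for cand in ("Images", "sample_id"):
        if cand in df.columns:
            return cand
    raise ValueError("table needs an 'Images' or 'sample_id' column")


def evaluate_report(pred_table: pd.DataFrame, reference_table: pd.DataFrame,
                    surgery_threshold_mm: float = DEFAULT_SURGERY_THRESHOLD_MM,
                    out_path: str | Path | None = None) -> dict:
    """Agreement statistics between predicted and reference staging tables.

    Both tables need an id column (``Images`` or ``sample_id``) and a class
    column (``CLASS`` or ``class``); the prediction additionally a ``WP_mm``
    (or ``wp_mm``) column for the ROC analysis and, when available in both,
    an area column for Bland-Altman.  Builds the 3x3 crosstab (reference in
    rows), runs the chi-square/contingency-coefficient and kappa tests,
    collapses to the surgery-vs-observe binary task over reference pterygium
    patients, and computes ROC/AUC with the Youden-optimal WP cutoff.
    """
    def norm(df):
        df = df.copy()
        df.columns = [{"class": "CLASS", "wp_mm": "WP_mm",
                       "area_mm2": "Area_mm2"}.get(c, c) for c in df.columns]
        return df

    pred = norm(pred_table)
    ref = norm(reference_table)
    pid, rid = _id_column(pred), _id_column(ref)
    merged = pred.merge(ref, left_on=pid, right_on=rid,
                        suffixes=("_pred", "_ref"))
    missing = set(ref[rid]) - set(pred[pid])
    if missing:
        raise ValueError(f"prediction table is missing ids: {sorted(missing)[:10]}")
    pred_cls = merged["CLASS_pred"].to_numpy()
    ref_cls = merged["CLASS_ref"].to_numpy()
    tab = CrossTab.from_labels(ref_cls, pred_cls, labels=[0, 1, 2])
    report: dict = {"n": tab.n, "crosstab": tab.counts.tolist()}
    chi = chi_square_with_C(tab)
    report["chi_square"] = {"chi2": chi.chi2, "df": chi.df,
                            "p_value": chi.p_value, "C": chi.C,
                            "C_max": chi.C_max}
    kap = cohen_kappa(tab)
    report["kappa"] = {"Po": kap.po, "Pe": kap.pe, "kappa": kap.kappa}
    conf = BinaryConfusion.from_crosstab_surgery(tab)
    bm = binary_metrics(conf)
    report["binary"] = {"TP": conf.tp, "TN": conf.tn, "FP": conf.fp,
                        "FN": conf.fn, "accuracy": bm.accuracy,
                        "specificity": bm.specificity,
                        "sensitivity": bm.sensitivity,
                        "precision": bm.precision, "f1": bm.f1}
    # ROC over pterygium patients: WP score, surgery as positive
    sel = np.isin(ref_cls, (1, 2))
    if "WP_mm_pred" in merged.columns:
        wp_col = "WP_mm_pred"
    elif "WP_mm" in merged.columns:
        wp_col = "WP_mm"
    else:
        wp_col = None
    if wp_col is not None and sel.any():
        wp = merged.loc[sel, wp_col].to_numpy(dtype=float)
        labels = (ref_cls[sel] == 2).astype(int)
        if labels.min() != labels.max():
            roc = roc_auc_youden(wp, labels)
            report["roc"] = {"auc": roc.auc,
                             "youden_threshold": roc.youden_threshold,
                             "youden_index": roc.youden_index}
    if {"Area_mm2_pred", "Area_mm2_ref"} <= set(merged.columns):
        ba = bland_altman(merged["Area_mm2_pred"].to_numpy(dtype=float),
                          merged["Area_mm2_ref"].to_numpy(dtype=float))
        report["bland_altman"] = {"mean_diff": ba.mean_diff,
                                  "sd_diff": ba.sd_diff, "loa_low": ba.loa_low,
                                  "loa_high": ba.loa_high,
                                  "n_outside": ba.n_outside}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
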