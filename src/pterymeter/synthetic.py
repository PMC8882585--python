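"""Synthetic anterior-segment eye phantoms with exact ground truth.

Each phantom is an RGB image of a bright sclera, an elliptical textured
cornea/iris disk, and an optional wedge-shaped pterygium entering from the
nasal or temporal side along the transverse axis, together with
pixel-exact cornea and pterygium masks and closed-form truth measurements
(RD, MD, WP, area).  The wedge has its apex on the transverse axis at a
distance ``a * (1 - invasion_fraction)`` from the center, so the minimum
center-to-edge distance of the residual cornea is exactly that apex
distance and the truth invasion width follows in closed form:

    WP = (diameter_mm / 2) * invasion_fraction        (circular cornea)

The wedge area inside the cornea also has a closed form (triangle-plus-
elliptical-segment decomposition), so the truth area needs no rasterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy.optimize import brentq

from .geometry import (
    DEFAULT_DIAMETER_MM,
    DEFAULT_SURGERY_THRESHOLD_MM,
    MeasurementResult,
    classify_status,
    compute_wp,
)

__all__ = ["EyePhantomParams", "PhantomSample", "generate_phantom",
           "truth_measurements", "make_dataset"]

ANATOMICAL_DIAMETER_RANGE_MM = (10.7, 12.58)


@dataclass
class EyePhantomParams:
    """Generative parameters of one eye phantom.

    ``invasion_fraction`` is the fraction of the transverse semi-axis
    invaded by the pterygium; ``pterygium_side`` is 'left', 'right' or
    'none'.  Defaults give a 256x256 image with a circular cornea of radius
    100 px, which keeps the downstream rasterization error well below the
    0.15 mm tolerance used in validation.
    """

    image_height: int = 256
    image_width: int = 256
    cornea_center: tuple[float, float] = (128.0, 128.0)
    semi_axis_a: float = 100.0
    semi_axis_b: float = 100.0
    rotation: float = 0.0
    pterygium_side: str = "none"
    invasion_fraction: float = 0.0
    wedge_half_angle: float = 0.35
    cornea_diameter_mm: float = DEFAULT_DIAMETER_MM
    noise_sd: float = 4.0
    texture_seed: int = 0

    def validate(self):
        if self.semi_axis_b <= 0 or self.semi_axis_a < self.semi_axis_b:
            raise ValueError("require 0 < semi_axis_b <= semi_axis_a")
        if self.pterygium_side not in ("left", "right", "none"):
            raise ValueError(f"bad pterygium_side {self.pterygium_side!r}")
        if not (0.0 <= self.invasion_fraction < 1.0):
            raise ValueError("invasion_fraction must lie in [0, 1)")
        if (self.invasion_fraction == 0.0) != (self.pterygium_side == "none"):
            raise ValueError("invasion_fraction == 0 iff pterygium_side == 'none'")
        if not (0.0 < self.wedge_half_angle < math.pi / 2):
            raise ValueError("wedge_half_angle must lie in (0, pi/2)")
        cy, cx = self.cornea_center
        ext = max(self.semi_axis_a, self.semi_axis_b)
        if (cy - ext < 0 or cx - ext < 0 or cy + ext > self.image_height - 1
                or cx + ext > self.image_width - 1):
            raise ValueError("cornea ellipse does not fit inside the image")
        if not (5.0 <= self.cornea_diameter_mm <= 20.0):
            raise ValueError("cornea_diameter_mm outside plausible range [5, 20]")

    @property
    def is_circular(self) -> bool:
        return math.isclose(self.semi_axis_a, self.semi_axis_b)


@dataclass
class PhantomSample:
    image: np.ndarray
    cornea_mask: np.ndarray
    pterygium_mask: np.ndarray
    truth: MeasurementResult
    params: EyePhantomParams = field(repr=False)


def _local_frame(params: EyePhantomParams, shape: tuple[int, int]):
    """(u, v) coordinates of pixel centers in the ellipse frame (u transverse)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = params.cornea_center
    ct, st = math.cos(params.rotation), math.sin(params.rotation)
    u = (cols - cx) * ct + (rows - cy) * st
    v = -(cols - cx) * st + (rows - cy) * ct
    return u, v


def _wedge_mask(params: EyePhantomParams, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    a = params.semi_axis_a
    d = a * (1.0 - params.invasion_fraction)
    tan_phi = math.tan(params.wedge_half_angle)
    uu = u if params.pterygium_side == "right" else -u
    return (uu >= d) & (np.abs(v) <= (uu - d) * tan_phi)


def generate_phantom(params: EyePhantomParams, seed: int = 0) -> PhantomSample:
    """Render one phantom; deterministic for fixed (params, seed)."""
    params.validate()
    shape = (params.image_height, params.image_width)
    u, v = _local_frame(params, shape)
    a, b = params.semi_axis_a, params.semi_axis_b
    cornea = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if params.pterygium_side == "none":
        pterygium = np.zeros(shape, dtype=bool)
    else:
        pterygium = cornea & _wedge_mask(params, u, v)

    rng = np.random.default_rng(np.random.SeedSequence([params.texture_seed, seed]))
    img = np.empty(shape + (3,), dtype=float)
    img[...] = 205.0  # sclera: bright gray
    # iris: textured darker disk with a radial falloff and a dark pupil
    r2 = (u / a) ** 2 + (v / b) ** 2
    iris = 95.0 - 25.0 * r2
    texture = rng.normal(0.0, 6.0, size=shape)
    base = np.where(cornea, iris + texture, img[..., 0])
    img[..., 0] = base
    img[..., 1] = np.where(cornea, base * 0.95, img[..., 1])
    img[..., 2] = np.where(cornea, base * 1.05, img[..., 2])
    pupil = r2 <= 0.35**2
    img[pupil] = 35.0
    if pterygium.any():  # pinkish fleshy overlay
        blend = 0.85
        tint = np.array([225.0, 172.0, 168.0])
        img[pterygium] = (1 - blend) * img[pterygium] + blend * tint
    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return PhantomSample(image=img, cornea_mask=cornea, pterygium_mask=pterygium,
                         truth=truth_measurements(params), params=params)


def _wedge_area(params: EyePhantomParams) -> float:
    """Closed-form area of the wedge clipped to the cornea ellipse.

    Splits at the abscissa u* where the wedge ray meets the ellipse:
    a triangle piece for u in [d, u*] plus an elliptical segment beyond.
    """
    a, b = params.semi_axis_a, params.semi_axis_b
    d = a * (1.0 - params.invasion_fraction)
    tan_phi = math.tan(params.wedge_half_angle)

    def gap(uu):  # wedge half-width minus ellipse half-width
        return (uu - d) * tan_phi - b * math.sqrt(max(1.0 - (uu / a) ** 2, 0.0))

    if gap(a) < 0:  # ray exits through u = a edge-case; numerically ~impossible
        u_star = a
    else:
        u_star = brentq(gap, d, a, xtol=1e-12)
    tri = tan_phi * (u_star - d) ** 2 / 2.0
    t = min(max(u_star / a, -1.0), 1.0)
    seg = (a * b / 2.0) * (math.acos(t) - t * math.sqrt(1.0 - t * t))
    return 2.0 * (tri + seg)


def truth_measurements(params: EyePhantomParams,
                       surgery_threshold_mm: float = DEFAULT_SURGERY_THRESHOLD_MM,
                       ) -> MeasurementResult:
    """Analytic RD/MD/WP/area for a phantom, without any rasterization.

    For circular corneas the wedge apex is the closest residual-boundary
    point, so MD = a*(1-f) exactly.  For eccentric corneas the global
    minimum may instead be the vertical semi-axis b (the documented
    eccentricity caveat); the reported MD takes the minimum of the two.
    """
    params.validate()
    a, b = params.semi_axis_a, params.semi_axis_b
    rd = a
    if params.pterygium_side == "none":
        md = rd
        area_px = 0.0
    else:
        md = a * (1.0 - params.invasion_fraction)
        if not params.is_circular:
            md = min(md, b)
        area_px = _wedge_area(params)
    wp = compute_wp(rd, md, params.cornea_diameter_mm)
    ac_px = math.pi * a * b
    ratio = area_px / ac_px
    area_mm2 = math.pi * (params.cornea_diameter_mm / 2.0) ** 2 * ratio
    return MeasurementResult(rd_px=rd, md_px=md, wp_mm=wp, area_ratio=ratio,
                             area_mm2=area_mm2,
                             status=classify_status(wp, surgery_threshold_mm),
                             diameter_mm=params.cornea_diameter_mm,
                             center=params.cornea_center)


DEFAULT_PARAM_RANGES = {
    "semi_axis_frac": (0.31, 0.43),    # cornea radius as a fraction of image size
    "center_jitter_frac": 0.03,
    "invasion_fraction": (0.1, 0.9),
    "wedge_half_angle": (0.25, 0.5),
    "noise_sd": 4.0,
}


def sample_params(rng: np.random.Generator, with_pterygium: bool,
                  param_ranges: dict | None = None,
                  image_size: int = 256) -> EyePhantomParams:
    """Draw one phantom's parameters (circular cornea).

    ``param_ranges`` may override the fractional defaults, or give absolute
    pixel values via ``semi_axis_px`` / ``center_jitter_px``.
    """
    pr = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        pr.update(param_ranges)
    lo, hi = pr.get("semi_axis_px",
                    tuple(f * image_size for f in pr["semi_axis_frac"]))
    a = rng.uniform(lo, hi)
    j = pr.get("center_jitter_px", pr["center_jitter_frac"] * image_size)
    cy = image_size / 2.0 + rng.uniform(-j, j)
    cx = image_size / 2.0 + rng.uniform(-j, j)
    if with_pterygium:
        side = "left" if rng.random() < 0.5 else "right"
        frac = rng.uniform(*pr["invasion_fraction"])
        phi = rng.uniform(*pr["wedge_half_angle"])
    else:
        side, frac, phi = "none", 0.0, 0.35
    return EyePhantomParams(
        image_height=image_size, image_width=image_size,
        cornea_center=(cy, cx), semi_axis_a=a, semi_axis_b=a,
        pterygium_side=side, invasion_fraction=frac, wedge_half_angle=phi,
        noise_sd=pr["noise_sd"],
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_dataset(out_dir, n_normal: int, n_pterygium: int,
                 param_ranges: dict | None = None, seed: int = 0,
                 image_size: int = 256) -> pd.DataFrame:
    """Write a phantom dataset (images, masks, manifest.csv); returns manifest.

    Layout: ``images/<id>.png``, ``masks/<id>_cornea.png``,
    ``masks/<id>_pterygium.png`` (masks as 0/255 PNG), ``manifest.csv`` with
    one row per sample carrying the truth measurements and all parameters.
    Deterministic per seed.
    """
    out = Path(out_dir)
    rows = []
    labels = ["normal"] * n_normal + ["pterygium"] * n_pterygium
    if labels:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels))
    for k, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        params = sample_params(rng, label == "pterygium", param_ranges, image_size)
        sample = generate_phantom(params, seed=int(rng.integers(0, 2**31 - 1)))
        sid = f"sample_{k:04d}"
        iio.imwrite(out / "images" / f"{sid}.png", sample.image)
        iio.imwrite(out / "masks" / f"{sid}_cornea.png",
                    sample.cornea_mask.astype(np.uint8) * 255)
        iio.imwrite(out / "masks" / f"{sid}_pterygium.png",
                    sample.pterygium_mask.astype(np.uint8) * 255)
        t = sample.truth
        row = {
            "sample_id": sid, "label": label, "class": t.status,
            "rd_px": t.rd_px, "md_px": t.md_px, "wp_mm": t.wp_mm,
            "area_ratio": t.area_ratio, "area_mm2": t.area_mm2,
        }
        p = asdict(params)
        p["cornea_center_row"], p["cornea_center_col"] = p.pop("cornea_center")
        row.update(p)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
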