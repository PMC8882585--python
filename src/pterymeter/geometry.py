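"""Mask-based morphometry of pterygium invasion.

Given a binary cornea mask and a binary pterygium mask, this module derives
the clinical quantities used to stage pterygium progression:

* ``RD`` — the pixel radius of the cornea along its transverse (horizontal)
  axis, taken as half the longest horizontal chord of the cornea mask;
* ``MD`` — the minimum Euclidean pixel distance from the cornea center to
  the boundary of the *residual* cornea (cornea with the pterygium removed
  by a pixel-wise XOR);
* ``WP`` — the invasion width in millimetres,
  ``WP = (diameter_mm / 2) * (1 - MD / RD)``, under the assumption that the
  transverse corneal diameter is ``diameter_mm`` (default 11.5 mm, the
  population mean; anatomically 10.7-12.58 mm);
* the pterygium area in mm^2, ``pi * (diameter_mm / 2)^2 * (AP / AC)``,
  treating the cornea as a circle of that diameter;
* a three-class status: 0 normal (WP = 0), 1 to-be-observed
  (0 < WP < threshold), 2 surgery-indicated (WP >= threshold, default 3 mm).

A direct least-squares ellipse fit to the cornea boundary regularizes the
jagged edges of network segmentations before measurement.

Conventions: 0-based (row, col) coordinates, distances are Euclidean on
pixel centers; masks are boolean arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "EllipseParams",
    "MeasurementResult",
    "EmptyMaskError",
    "extract_boundary",
    "fit_ellipse",
    "rasterize_ellipse",
    "xor_masks",
    "center_and_rd",
    "min_center_distance",
    "compute_wp",
    "compute_area_mm2",
    "classify_status",
    "measure",
]

DEFAULT_DIAMETER_MM = 11.5
DEFAULT_SURGERY_THRESHOLD_MM = 3.0
_WP_ZERO_EPS = 1e-9


class EmptyMaskError(ValueError):
    pass


@dataclass
class EllipseParams:
    """Geometric ellipse: center (row, col), semi-axes in px, rotation in rad.

    ``semi_axis_a`` is the semi-axis whose direction is closest to horizontal
    (the transverse axis); ``rotation`` is the angle of that axis measured
    from the column axis, normalized to (-pi/2, pi/2].
    """

    center: tuple[float, float]
    semi_axis_a: float
    semi_axis_b: float
    rotation: float = 0.0

    def __post_init__(self):
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass
class MeasurementResult:
    rd_px: float
    md_px: float
    wp_mm: float
    area_ratio: float
    area_mm2: float
    status: int
    diameter_mm: float = DEFAULT_DIAMETER_MM
    center: tuple[float, float] | None = field(default=None, repr=False)

    def as_row(self, image_name: str = "") -> dict:
        """Row in the measurement-table schema (Images, RD, MD, WP, CLASS, Area)."""
        return {
            "Images": image_name,
            "RD": self.rd_px,
            "MD": self.md_px,
            "WP_mm": self.wp_mm,
            "CLASS": self.status,
            "Area_mm2": self.area_mm2,
        }


def _as_bool(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    return m > 0 if m.dtype != bool else m


def extract_boundary(mask) -> np.ndarray:
    """Foreground pixels with a 4-neighbor background pixel (or on the border).

    Returns an (n, 2) array of (row, col) coordinates.
    """
    m = _as_bool(mask)
    if not m.any():
        raise EmptyMaskError("cannot extract boundary of an empty mask")
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(m, structure=cross, border_value=0)
    return np.argwhere(m & ~interior)


def fit_ellipse(points) -> EllipseParams:
    """Direct least-squares ellipse fit (smallest algebraic distance).

    Stable Halir-Flusser formulation of the Fitzgibbon direct fit: solves
    the conic coefficients minimizing the algebraic distance subject to the
    ellipse constraint ``4ac - b^2 = 1``, then converts to geometric
    parameters.  Requires at least 5 non-degenerate (row, col) points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (row, col) points")
    y, x = pts[:, 0], pts[:, 1]
    # center/scale for conditioning
    mx, my = x.mean(), y.mean()
    sx = x.std() or 1.0
    sy = y.std() or 1.0
    xn, yn = (x - mx) / sx, (y - my) / sy

    d1 = np.column_stack([xn * xn, xn * yn, yn * yn])
    d2 = np.column_stack([xn, yn, np.ones_like(xn)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate point configuration") from exc
    m = s1 + s2 @ t
    c_inv = np.array([[0, 0, 0.5], [0, -1.0, 0], [0.5, 0, 0]])
    eigval, eigvec = np.linalg.eig(c_inv @ m)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.where(np.isreal(eigval) & (cond > 0))[0]
    if valid.size == 0:
        raise ValueError("no elliptical solution (degenerate or collinear points)")
    a1 = np.real(eigvec[:, valid[0]])
    a2 = t @ a1
    # un-normalize conic A x^2 + B xy + C y^2 + D x + E y + F = 0
    A = a1[0] / sx**2
    B = a1[1] / (sx * sy)
    C = a1[2] / sy**2
    D = a2[0] / sx - 2 * a1[0] * mx / sx**2 - a1[1] * my / (sx * sy)
    E = a2[1] / sy - 2 * a1[2] * my / sy**2 - a1[1] * mx / (sx * sy)
    F = (a2[2] - a2[0] * mx / sx - a2[1] * my / sy
         + a1[0] * mx**2 / sx**2 + a1[1] * mx * my / (sx * sy) + a1[2] * my**2 / sy**2)
    return _conic_to_geometric(A, B, C, D, E, F)


def _conic_to_geometric(A, B, C, D, E, F) -> EllipseParams:
    if A + C < 0:  # conic coefficients have an arbitrary overall sign
        A, B, C, D, E, F = -A, -B, -C, -D, -E, -F
    den = 4 * A * C - B * B
    if den <= 0:
        raise ValueError("conic is not an ellipse")
    cx = (B * E - 2 * C * D) / den
    cy = (B * D - 2 * A * E) / den
    # value of the quadratic form at the center; sign fixes the scale
    mu = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    quad = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(quad)
    if mu >= 0 or np.any(lam <= 0):
        raise ValueError("conic is not a real ellipse")
    radii = np.sqrt(-mu / lam)
    angles = np.arctan2(vec[1], vec[0])  # angle of each eigenvector vs x-axis
    # wrap to (-pi/2, pi/2] and pick the more horizontal axis as transverse
    angles = np.where(angles > math.pi / 2, angles - math.pi, angles)
    angles = np.where(angles <= -math.pi / 2, angles + math.pi, angles)
    order = np.argsort(np.abs(angles))
    ra, rb = radii[order[0]], radii[order[1]]
    tha = float(angles[order[0]])
    return EllipseParams(center=(cy, cx), semi_axis_a=float(ra),
                         semi_axis_b=float(rb), rotation=tha)


def rasterize_ellipse(e: EllipseParams, shape: tuple[int, int]) -> np.ndarray:
    """Filled-ellipse boolean mask on pixel centers."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = e.center
    ct, st = math.cos(e.rotation), math.sin(e.rotation)
    u = (cols - cx) * ct + (rows - cy) * st
    v = -(cols - cx) * st + (rows - cy) * ct
    return (u / e.semi_axis_a) ** 2 + (v / e.semi_axis_b) ** 2 <= 1.0


def xor_masks(cornea, pterygium) -> np.ndarray:
    """Pixel-wise XOR; equals cornea AND NOT pterygium when nested."""
    c, p = _as_bool(cornea), _as_bool(pterygium)
    if c.shape != p.shape:
        raise ValueError(f"shape mismatch: {c.shape} vs {p.shape}")
    return np.logical_xor(c, p)


def center_and_rd(cornea_mask) -> tuple[tuple[float, float], float]:
    """Cornea center and transverse radius from the longest chords.

    The center column is the midpoint of the longest horizontal chord's
    extremes, the center row the midpoint of the longest vertical chord's;
    RD is half the longest horizontal chord length.
    """
    m = _as_bool(cornea_mask)
    if not m.any():
        raise EmptyMaskError("empty cornea mask")
    rows_any = np.where(m.any(axis=1))[0]
    cols_any = np.where(m.any(axis=0))[0]
    best_len, best_mid = -1.0, 0.0
    for r in rows_any:
        cs = np.where(m[r])[0]
        length = cs[-1] - cs[0]
        if length > best_len:
            best_len, best_mid = length, (cs[0] + cs[-1]) / 2.0
    center_col, rd = best_mid, best_len / 2.0
    best_len, best_mid = -1.0, 0.0
    for c in cols_any:
        rs = np.where(m[:, c])[0]
        length = rs[-1] - rs[0]
        if length > best_len:
            best_len, best_mid = length, (rs[0] + rs[-1]) / 2.0
    center_row = best_mid
    if rd <= 0:
        raise ValueError("cornea mask has no horizontal extent")
    return (center_row, center_col), rd


def min_center_distance(residual_mask, center, mode: str = "global_min") -> float:
    """Minimum Euclidean distance from ``center`` to the residual boundary.

    ``mode='global_min'`` (the default) minimizes over the whole boundary.
    ``mode='transverse'`` restricts to boundary pixels on the horizontal
    line through the center; for uninvaded but eccentric corneas the global
    minimum is the *vertical* semi-axis, which would report a spurious
    nonzero WP — the transverse mode avoids that (see package docs).
    """
    m = _as_bool(residual_mask)
    if not m.any():
        return 0.0
    boundary = extract_boundary(m)
    cy, cx = center
    if mode == "transverse":
        row = int(round(cy))
        sel = boundary[boundary[:, 0] == row]
        if sel.size:
            boundary = sel
    elif mode != "global_min":
        raise ValueError(f"unknown MD mode: {mode!r}")
    d = np.hypot(boundary[:, 0] - cy, boundary[:, 1] - cx)
    return float(d.min())


def compute_wp(rd_px: float, md_px: float,
               diameter_mm: float = DEFAULT_DIAMETER_MM) -> float:
    """Invasion width WP = (diameter/2) * (1 - MD/RD), in mm."""
    if rd_px <= 0:
        raise ValueError("RD must be positive")
    if md_px < 0 or md_px > rd_px:
        raise ValueError(f"MD must lie in [0, RD]; got MD={md_px}, RD={rd_px}")
    return (diameter_mm / 2.0) * (1.0 - md_px / rd_px)


def compute_area_mm2(ap_px: float, ac_px: float,
                     diameter_mm: float = DEFAULT_DIAMETER_MM) -> float:
    """Pterygium area = pi*(d/2)^2 * (AP/AC), cornea treated as a circle."""
    if ac_px <= 0:
        raise ValueError("cornea pixel area must be positive")
    if ap_px < 0 or ap_px > ac_px:
        raise ValueError("pterygium pixel area must lie in [0, AC]")
    return math.pi * (diameter_mm / 2.0) ** 2 * (ap_px / ac_px)


def classify_status(wp_mm: float,
                    surgery_threshold_mm: float = DEFAULT_SURGERY_THRESHOLD_MM) -> int:
    """0 normal (WP=0), 1 observe (0<WP<thr), 2 surgery (WP>=thr)."""
    if wp_mm < -_WP_ZERO_EPS:
        raise ValueError("WP must be non-negative")
    if wp_mm <= _WP_ZERO_EPS:
        return 0
    return 2 if wp_mm >= surgery_threshold_mm else 1


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def measure(cornea_mask, pterygium_mask,
            diameter_mm: float = DEFAULT_DIAMETER_MM,
            surgery_threshold_mm: float = DEFAULT_SURGERY_THRESHOLD_MM,
            md_mode: str = "global_min",
            resize_to: int | None = None) -> MeasurementResult:
    """Full measurement chain on a cornea/pterygium mask pair.

    XOR out the pterygium, locate the cornea center and transverse radius,
    take the minimum center-to-edge distance of the residual cornea, and
    convert to WP, area and status.  Only the largest 8-connected component
    of each mask is measured.  ``resize_to`` optionally resizes both masks
    (nearest-neighbor) to a square working resolution first, as the
    end-to-end pipeline does with 512.
    """
    c, p = _as_bool(cornea_mask), _as_bool(pterygium_mask)
    if c.shape != p.shape:
        raise ValueError(f"mask shapes differ: {c.shape} vs {p.shape}")
    if not c.any():
        raise EmptyMaskError("empty cornea mask")
    if resize_to is not None and c.shape != (resize_to, resize_to):
        c = resize(c.astype(float), (resize_to, resize_to), order=0,
                   anti_aliasing=False) > 0.5
        p = resize(p.astype(float), (resize_to, resize_to), order=0,
                   anti_aliasing=False) > 0.5
    c = _largest_component(c)
    if p.any():
        p = _largest_component(p)
    p = p & c  # pterygium area is defined within the cornea
    residual = xor_masks(c, p)
    center, rd = center_and_rd(c)
    md = min_center_distance(residual, center, mode=md_mode) if p.any() else rd
    md = min(md, rd)
    wp = compute_wp(rd, md, diameter_mm)
    ac = int(c.sum())
    ap = int(p.sum())
    area_ratio = ap / ac
    area = compute_area_mm2(ap, ac, diameter_mm)
    status = classify_status(wp, surgery_threshold_mm)
    assert 0.0 <= wp <= diameter_mm / 2.0 + 1e-9
    assert 0.0 <= area <= math.pi * (diameter_mm / 2.0) ** 2 + 1e-9
    return MeasurementResult(rd_px=float(rd), md_px=float(md), wp_mm=float(wp),
                             area_ratio=float(area_ratio), area_mm2=float(area),
                             status=status, diameter_mm=diameter_mm, center=center)
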