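"""Per-ROI temperature features and GLCM texture statistics.

Temperature features summarize an ROI by its mean temperature and by the
means of its warmest and coldest 5% tails (``m = ceil(0.05 N)`` pixels, so a
single extreme pixel never dominates):

    T_mean = (1/N) sum(T_i),   T_max = mean of top m,   T_min = mean of bottom m.

Texture is captured by gray-level co-occurrence matrices (GLCM): the ROI is
min-max quantized to G gray levels, and for an offset distance Δ and
direction θ the matrix entry P(i, j) is the probability that a pixel of
level i has a neighbor of level j at that offset.  Counting is ordered
(non-symmetric), one displacement per direction, normalized by the number
of valid pairs R.  Offsets follow the image convention (row, col):

    0° → (0, +Δ)   45° → (−Δ, +Δ)   90° → (−Δ, 0)   135° → (−Δ, −Δ)

Four second-order statistics are derived per GLCM — contrast, correlation,
energy (angular second moment), homogeneity — over the full parameter grid
Δ ∈ {2, 5} × G ∈ {16, 32} × θ ∈ {0°, 45°, 90°, 135°} (16 GLCMs per ROI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SizeError, ValidationError
from .thermal_io import GrayImage, normalize_gray

DELTAS = (2, 5)
GRAY_LEVELS = (16, 32)
THETAS = (0, 45, 90, 135)
MINKOWSKI_ORDERS = (1, 2)
TEXTURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")

#: (row, col) unit offsets per direction, scaled by delta
THETA_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMParams:
    delta: int
    theta: int
    g: int

    def __post_init__(self):
        if self.theta not in THETA_OFFSETS:
            raise ParameterError(f"theta must be one of {THETAS}")
        if self.delta < 1:
            raise ParameterError("delta must be >= 1")
        if self.g < 2:
            raise ParameterError("g must be >= 2")


def param_grid() -> list[GLCMParams]:
    """The 16-member parameter grid in deterministic (delta, g, theta) order."""
    return [GLCMParams(d, t, g) for d in DELTAS for g in GRAY_LEVELS for t in THETAS]


@dataclass
class TemperatureFeatures:
    t_mean: float
    t_max: float
    t_min: float
    n: int
    m: int

    def __post_init__(self):
        if not (self.t_min <= self.t_mean + 1e-12 and self.t_mean <= self.t_max + 1e-12):
            raise ValidationError("t_min <= t_mean <= t_max violated")


@dataclass
class GLCM:
    p: np.ndarray
    r: int
    params: GLCMParams

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.r < 1:
            raise SizeError("GLCM computed from zero valid pairs")
        if (self.p < 0).any() or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValidationError("GLCM entries must be a probability distribution")


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    params: GLCMParams

    def value(self, name: str) -> float:
        return getattr(self, name)


def temperature_features(roi_values) -> TemperatureFeatures:
    """Mean / top-5%-mean / bottom-5%-mean of an ROI's temperatures."""
    values = np.asarray(roi_values, dtype=float).ravel()
    n = values.size
    if n < 20:
        raise SizeError(f"ROI has {n} pixels; need >= 20 for 5% tails")
    m = math.ceil(0.05 * n)
    srt = np.sort(values)
    return TemperatureFeatures(
        t_mean=float(srt.mean()),
        t_max=float(srt[-m:].mean()),
        t_min=float(srt[:m].mean()),
        n=n,
        m=m,
    )


def quantize_roi(roi, g: int, lo_hi: tuple[float, float] | None = None) -> GrayImage:
    """Min-max quantize an ROI to g gray levels.

    Per-ROI min-max by default so texture reflects the spatial *shape* of the
    temperature field, independent of the absolute offset that the ΔT
    features already capture; pass ``lo_hi`` for a shared range instead.
    A constant ROI quantizes to all-zero levels with the degenerate flag set.
    """
    roi = np.asarray(roi, dtype=float)
    lo, hi = (float(roi.min()), float(roi.max())) if lo_hi is None else lo_hi
    if hi <= lo:
        return GrayImage(np.zeros(roi.shape, dtype=np.int64), g, lo, lo + 1.0,
                         degenerate=True)
    return normalize_gray(roi, g, (lo, hi))


def compute_glcm(gray_roi: GrayImage, params: GLCMParams) -> GLCM:
    """Ordered pair counts at one (Δ, θ) offset, normalized to probabilities."""
    levels = gray_roi.levels
    dr, dc = (o * params.delta for o in THETA_OFFSETS[params.theta])
    rows, cols = levels.shape
    if rows <= abs(dr) or cols <= abs(dc):
        raise SizeError(f"ROI {rows}x{cols} too small for offset ({dr},{dc})")
    # source window such that source+offset stays inside the ROI
    r_lo, r_hi = max(0, -dr), rows - max(0, dr)
    c_lo, c_hi = max(0, -dc), cols - max(0, dc)
    src = levels[r_lo:r_hi, c_lo:c_hi]
    dst = levels[r_lo + dr:r_hi + dr, c_lo + dc:c_hi + dc]
    g = params.g
    counts = np.bincount((src * g + dst).ravel(), minlength=g * g).reshape(g, g)
    r = int(counts.sum())
    return GLCM(p=counts / r, r=r, params=params)


def texture_stats(glcm: GLCM) -> TextureFeatures:
    """Contrast, correlation, energy, homogeneity of one GLCM.

    Correlation uses the row/column marginal means and SDs; when either
    marginal is degenerate (zero SD) the sentinel value 0 is reported.
    """
    p = glcm.p
    g = p.shape[0]
    i = np.arange(g)[:, None]
    j = np.arange(g)[None, :]
    diff2 = (i - j) ** 2
    contrast = float((diff2 * p).sum())
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + diff2)).sum())
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(g) * px).sum())
    mu_y = float((np.arange(g) * py).sum())
    var_x = float(((np.arange(g) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(g) - mu_y) ** 2 * py).sum())
    if var_x <= 1e-24 or var_y <= 1e-24:
        correlation = 0.0
    else:
        correlation = float(((i * j * p).sum() - mu_x * mu_y) / math.sqrt(var_x * var_y))
        correlation = min(1.0, max(-1.0, correlation))
    return TextureFeatures(contrast=contrast, correlation=correlation,
                           energy=energy, homogeneity=homogeneity,
                           params=glcm.params)


def all_texture_features(roi, lo_hi: tuple[float, float] | None = None) -> list[TextureFeatures]:
    """Texture statistics for the full 16-member parameter grid.

    Returns exactly one :class:`TextureFeatures` per grid member, ordered by
    (delta, g, theta).  The ROI is re-quantized once per gray-level count.
    """
    roi = np.asarray(roi, dtype=float)
    quantized = {g: quantize_roi(roi, g, lo_hi) for g in GRAY_LEVELS}
    out = []
    for params in param_grid():
        out.append(texture_stats(compute_glcm(quantized[params.g], params)))
    return out
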