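"""Temperature-matrix I/O, gray quantization, and pseudo-color rendering.

A thermogram is a plain matrix of surface temperatures in degrees Celsius,
row 0 at the top of the face and column 0 at the subject's anatomical RIGHT
(the viewer's left), as produced by a frontal camera.  Two interchange
formats are supported:

* ``csv`` — comma-separated floats, one image row per line, no header;
* ``png16`` — single-channel 16-bit PNG plus a mandatory JSON sidecar
  ``{"scale": s, "offset": o}`` mapping stored counts to ``count*s + o`` °C
  (PNG itself carries no temperature semantics).

Temperatures outside a plausibility window of [10, 45] °C are rejected to
catch unit mistakes; set ``meta["unchecked"]`` to bypass validation for
deliberately extreme synthetic inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    DegenerateRangeError,
    FormatError,
    ParameterError,
    ValidationError,
)

PLAUSIBLE_LO = 10.0
PLAUSIBLE_HI = 45.0
MIN_SIDE = 32

PSEUDOCOLOR_LAYERS = (64, 32, 16, 8)


@dataclass
class ThermalImage:
    """A temperature matrix in °C with free-form provenance metadata."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("temperature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("temperature matrix contains non-finite values")
        if not self.meta.get("unchecked"):
            if self.n_rows < MIN_SIDE or self.n_cols < MIN_SIDE:
                raise ValidationError(
                    f"image {self.n_rows}x{self.n_cols} smaller than "
                    f"{MIN_SIDE}x{MIN_SIDE}; set meta['unchecked'] to override"
                )
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < PLAUSIBLE_LO or hi > PLAUSIBLE_HI:
                raise ValidationError(
                    f"temperatures [{lo:.2f}, {hi:.2f}] outside plausibility "
                    f"window [{PLAUSIBLE_LO}, {PLAUSIBLE_HI}] °C; "
                    "set meta['unchecked'] to override"
                )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class GrayImage:
    """Quantized gray levels 0..L-1 with the temperature range they map."""

    levels: np.ndarray
    L: int
    lo: float
    hi: float
    degenerate: bool = False

    def __post_init__(self):
        self.levels = np.asarray(self.levels)
        if self.L < 2:
            raise ParameterError("L must be >= 2")
        if not self.degenerate and not (self.lo < self.hi):
            raise DegenerateRangeError(f"lo={self.lo} must be < hi={self.hi}")
        if self.levels.size and (
            self.levels.min() < 0 or self.levels.max() > self.L - 1
        ):
            raise ValidationError("levels outside [0, L-1]")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_thermal(path, fmt: str | None = None, *, unchecked: bool = False) -> ThermalImage:
    """Read a temperature matrix from ``csv`` or ``png16``.

    ``fmt`` is inferred from the suffix when omitted.  png16 requires the
    ``<file>.png.json`` sidecar with linear ``scale``/``offset``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt is None:
        fmt = "png16" if path.suffix.lower() == ".png" else "csv"
    if fmt == "csv":
        try:
            values = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
        except ValueError as exc:
            raise FormatError(f"malformed CSV grid in {path}: {exc}") from exc
    elif fmt == "png16":
        with Image.open(path) as im:
            if im.mode not in ("I", "I;16", "I;16B"):
                raise FormatError(f"{path} is not a single-channel 16-bit PNG")
            raw = np.asarray(im, dtype=np.float64)
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"png16 requires sidecar {sidecar}")
        cal = json.loads(sidecar.read_text())
        values = raw * float(cal["scale"]) + float(cal["offset"])
    else:
        raise ParameterError(f"unknown format {fmt!r}")
    meta = {"source": str(path), "format": fmt}
    if unchecked:
        meta["unchecked"] = True
    return ThermalImage(values, meta)


def write_thermal(img: ThermalImage, path, fmt: str | None = None,
                  scale: float = 0.01, offset: float = 0.0) -> None:
    """Write a ThermalImage as CSV or png16 (+ JSON sidecar)."""
    path = Path(path)
    if fmt is None:
        fmt = "png16" if path.suffix.lower() == ".png" else "csv"
    if fmt == "csv":
        np.savetxt(path, img.values, delimiter=",", fmt="%.6f")
    elif fmt == "png16":
        counts = np.round((img.values - offset) / scale)
        if counts.min() < 0 or counts.max() > 65535:
            raise ValidationError("values not representable with given scale/offset")
        Image.fromarray(counts.astype(np.uint16)).save(path)
        _sidecar_path(path).write_text(json.dumps({"scale": scale, "offset": offset}))
    else:
        raise ParameterError(f"unknown format {fmt!r}")


def normalize_gray(img: ThermalImage | np.ndarray, L: int,
                   lo_hi: tuple[float, float] | None = None) -> GrayImage:
    """Quantize temperatures to integer levels 0..L-1.

    ``level = floor((t - lo) / (hi - lo) * L)`` with ``t == hi`` clamped to
    ``L-1``; monotone non-decreasing in t.  The range defaults to the image's
    own min/max (the camera's absolute offset carries no shape information).
    """
    values = img.values if isinstance(img, ThermalImage) else np.asarray(img, dtype=float)
    if L < 2:
        raise ParameterError("L must be >= 2")
    if lo_hi is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = float(lo_hi[0]), float(lo_hi[1])
    if not (hi > lo):
        raise DegenerateRangeError("degenerate range: hi <= lo (constant image?)")
    levels = np.floor((values - lo) / (hi - lo) * L).astype(np.int64)
    np.clip(levels, 0, L - 1, out=levels)
    return GrayImage(levels, L, lo, hi)


def render_pseudocolor(img: ThermalImage, n_layers: int,
                       lo_hi: tuple[float, float] | None = None,
                       cmap: str = "inferno") -> np.ndarray:
    """Layered pseudo-color rendering: temperatures are divided from low to
    high into ``n_layers`` bands and each band is painted one color.

    Returns an (rows, cols, 3) uint8 raster, writable as PNG.
    """
    if n_layers not in PSEUDOCOLOR_LAYERS:
        raise ParameterError(f"n_layers must be one of {PSEUDOCOLOR_LAYERS}")
    from matplotlib import colormaps

    try:
        layers = normalize_gray(img, n_layers, lo_hi).levels
    except DegenerateRangeError:
        layers = np.zeros_like(img.values, dtype=np.int64)
    palette = colormaps[cmap](np.linspace(0.0, 1.0, n_layers))[:, :3]
    return (palette[layers] * 255).astype(np.uint8)


def write_png(rgb: np.ndarray, path) -> None:
    Image.fromarray(rgb, mode="RGB").save(path)
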