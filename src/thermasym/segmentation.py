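"""Automatic bilateral ROI segmentation of frontal facial thermograms.

The face is first separated from the cooler background by Otsu thresholding
of the gray-quantized image.  Facial key points (nostrils, pupils, inner
canthi, mouth corners, eyebrows) are then localized by fusing Harris corner
responses, Canny edges, and gray-projection profiles inside anthropometric
search windows expressed as fractions of the face bounding box.  Finally ten
rectangular ROIs — forehead (R1), orbital (R2), infraorbital (R3), nasal
(R4), and mouth (R5), each in an anatomical left/right pair — are laid out
around the key points and symmetrized about the facial midline so paired
rectangles are exact mirror images of identical size.

Anatomical convention: column 0 is the subject's anatomical RIGHT, so for
every landmark pair ``left.col > midline_col > right.col``.

None of the operator parameters (Harris k/sigma, Canny thresholds,
morphology radii, window fractions) is canonical; all live in
:class:`SegmentationConfig` with conventional defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import morphology as skmorph

from .errors import (
    DegenerateHistogramError,
    LandmarkError,
    LayoutError,
    ParameterError,
    SegmentationError,
)
from .thermal_io import GrayImage, ThermalImage, normalize_gray

PAIR_LABELS = ("R1", "R2", "R3", "R4", "R5")
SIDES = ("L", "R")


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation chain."""

    gray_levels: int = 256
    # Harris corner detector
    harris_k: float = 0.05
    harris_sigma: float = 2.0
    corner_quantile: float = 0.99
    # Canny edge detector (hysteresis thresholds as gradient quantiles)
    canny_sigma: float = 2.0
    canny_low_q: float = 0.60
    canny_high_q: float = 0.85
    # morphology
    erode_radius: int = 3       # before masking corner responses
    edge_erode_radius: int = 6  # before masking Canny edges (face rim is wider)
    # anthropometric search windows, fractions of face-box height H from its top
    eye_window: tuple[float, float] = (0.20, 0.45)
    nose_window: tuple[float, float] = (0.45, 0.70)
    mouth_window: tuple[float, float] = (0.70, 0.90)
    eyebrow_window: tuple[float, float] = (0.10, 0.30)
    # minimum projection-dip depth (gray levels) for a nostril candidate
    nostril_min_depth: float = 3.0
    # nostril search: columns within this fraction of face width of the midline
    nostril_max_offset: float = 0.25
    # canthus search: columns within this fraction of face width of the midline
    canthus_max_offset: float = 0.15
    # pupil/eyebrow search: lateral column band, fractions of face width from
    # the midline (excludes both the warm medial axis and the cool face rim)
    eye_col_band: tuple[float, float] = (0.08, 0.30)
    # eyebrow search: narrower lateral band (the face narrows toward the top,
    # so the wide eye band would graze the cool rim there)
    eyebrow_col_band: tuple[float, float] = (0.06, 0.22)
    # ROI layout fractions
    forehead_height: float = 0.15
    forehead_width: float = 0.20  # of face width, per side
    orbital_width_ipd: float = 0.45  # of inter-pupil distance
    orbital_height: float = 0.12
    infraorbital_height: float = 0.12
    nasal_size: float = 0.10
    mouth_size: float = 0.12
    smooth_sigma: float = 2.0  # pre-smoothing for projection extrema


@dataclass
class FaceMask:
    """Binary face-foreground mask with its bounding rectangle (half-open)."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # row_lo, row_hi, col_lo, col_hi

    @property
    def height(self) -> int:
        return self.bbox[1] - self.bbox[0]

    @property
    def width(self) -> int:
        return self.bbox[3] - self.bbox[2]


@dataclass
class KeyPoints:
    """Facial landmarks as (row, col) pixel coordinates."""

    nostril_l: tuple[int, int]
    nostril_r: tuple[int, int]
    pupil_l: tuple[int, int]
    pupil_r: tuple[int, int]
    mouth_corner_l: tuple[int, int]
    mouth_corner_r: tuple[int, int]
    canthus_inner_l: tuple[int, int]
    canthus_inner_r: tuple[int, int]
    eyebrow_l: tuple[int, int]
    eyebrow_r: tuple[int, int]
    midline_col: float  # half-integer allowed: the axis may lie between columns

    PAIRS = (
        ("nostril_l", "nostril_r"),
        ("pupil_l", "pupil_r"),
        ("mouth_corner_l", "mouth_corner_r"),
        ("canthus_inner_l", "canthus_inner_r"),
        ("eyebrow_l", "eyebrow_r"),
    )

    def validate(self) -> None:
        for lname, rname in self.PAIRS:
            l, r = getattr(self, lname), getattr(self, rname)
            if not (l[1] > self.midline_col > r[1]):
                raise LandmarkError(
                    lname, f"pair straddle violated: {l[1]} / {self.midline_col} / {r[1]}"
                )
        pupil_row = (self.pupil_l[0] + self.pupil_r[0]) / 2
        nostril_row = (self.nostril_l[0] + self.nostril_r[0]) / 2
        mouth_row = (self.mouth_corner_l[0] + self.mouth_corner_r[0]) / 2
        if not (pupil_row < nostril_row < mouth_row):
            raise LandmarkError(
                "ordering",
                f"rows pupil={pupil_row} nostril={nostril_row} mouth={mouth_row}",
            )

    def as_dict(self) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()}


@dataclass
class ROIRect:
    """A labeled rectangle, half-open 0-based (row_lo, row_hi, col_lo, col_hi)."""

    label: str  # e.g. "R1.L"
    rect: tuple[int, int, int, int]

    @property
    def area(self) -> int:
        r0, r1, c0, c1 = self.rect
        return max(0, r1 - r0) * max(0, c1 - c0)

    def extract(self, values: np.ndarray) -> np.ndarray:
        r0, r1, c0, c1 = self.rect
        return values[r0:r1, c0:c1]


@dataclass
class FacialROISet:
    """Ten ROIs in five mirrored left/right pairs plus their landmarks."""

    rois: dict[str, ROIRect]
    midline_col: float
    keypoints: KeyPoints | None = None

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(f"{p}.L", f"{p}.R") for p in PAIR_LABELS]

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if sorted(self.rois) != sorted(f"{p}.{s}" for p in PAIR_LABELS for s in SIDES):
            raise LayoutError(f"expected 10 labeled ROIs, got {sorted(self.rois)}")
        for lname, rname in self.pairs:
            lr, rr = self.rois[lname].rect, self.rois[rname].rect
            if (lr[1] - lr[0], lr[3] - lr[2]) != (rr[1] - rr[0], rr[3] - rr[2]):
                raise LayoutError(f"pair {lname}/{rname} differ in size")
            # mirror of [c0, c1) about axis m is [2m - c1 + 1, 2m - c0 + 1)
            two_m = int(round(2 * self.midline_col))
            exp = (two_m - lr[3] + 1, two_m - lr[2] + 1)
            if abs(exp[0] - rr[2]) > 2 or abs(exp[1] - rr[3]) > 2:
                raise LayoutError(f"pair {lname}/{rname} not mirrored about midline")
        for side in SIDES:
            boxes = [self.rois[f"{p}.{side}"].rect for p in PAIR_LABELS]
            for i in range(len(boxes)):
                for j in range(i + 1, len(boxes)):
                    a, b = boxes[i], boxes[j]
                    if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                        raise LayoutError(
                            f"same-side overlap {PAIR_LABELS[i]}.{side}/{PAIR_LABELS[j]}.{side}"
                        )
        for roi in self.rois.values():
            r0, r1, c0, c1 = roi.rect
            if roi.area < 64:
                raise LayoutError(f"{roi.label} area {roi.area} < 64 px")
            if r0 < 0 or c0 < 0:
                raise LayoutError(f"{roi.label} outside image bounds")
            if shape is not None and (r1 > shape[0] or c1 > shape[1]):
                raise LayoutError(f"{roi.label} outside image bounds")

    def to_json(self, path=None) -> str:
        payload = {
            "midline_col": float(self.midline_col),
            "rois": [
                {
                    "label": r.label,
                    "row_lo": int(r.rect[0]),
                    "row_hi": int(r.rect[1]),
                    "col_lo": int(r.rect[2]),
                    "col_hi": int(r.rect[3]),
                }
                for r in self.rois.values()
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FacialROISet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        rois = {
            d["label"]: ROIRect(d["label"], (d["row_lo"], d["row_hi"], d["col_lo"], d["col_hi"]))
            for d in payload["rois"]
        }
        return cls(rois=rois, midline_col=float(payload["midline_col"]))


# ---------------------------------------------------------------------------
# stage operators


def otsu_face_mask(gray: GrayImage) -> FaceMask:
    """Threshold the gray image by Otsu's criterion and keep the warm face.

    The threshold maximizes between-class variance over candidate levels;
    the foreground is the warmer class.  The largest connected component is
    kept and its holes (cold nostrils/eyes) are filled.
    """
    levels = gray.levels
    if np.unique(levels).size < 2:
        raise DegenerateHistogramError()
    thresh = skfilters.threshold_otsu(levels, nbins=gray.L)
    fg = levels > thresh
    if not fg.any():
        raise DegenerateHistogramError("empty foreground after thresholding")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum(fg, lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return FaceMask(mask=fg, bbox=bbox)


def harris_corner_map(gray: GrayImage, k: float = 0.05, sigma: float = 2.0) -> np.ndarray:
    """Per-pixel Harris corner response R = det(M) - k * trace(M)^2.

    The mean level is subtracted first so the zero padding of the gradient
    filters does not manufacture responses along the image border (a
    constant image then has exactly zero response everywhere).
    """
    if min(gray.levels.shape) < 7:
        raise ParameterError("image must be at least 7x7 for corner detection")
    arr = gray.levels.astype(float)
    return skfeature.corner_harris(arr - arr.mean(), k=k, sigma=sigma)


def corner_peaks(response: np.ndarray, quantile: float = 0.99,
                 mask: np.ndarray | None = None, min_distance: int = 3) -> np.ndarray:
    """Local maxima of the corner response above a quantile of its positive
    values, optionally restricted to a mask.  Returns (n, 2) row/col array."""
    r = response.copy()
    if mask is not None:
        r[~mask] = 0.0
    pos = r[r > 0]
    if pos.size == 0:
        return np.empty((0, 2), dtype=int)
    thresh = np.quantile(pos, quantile)
    return skfeature.corner_peaks(r, min_distance=min_distance,
                                  threshold_abs=thresh, threshold_rel=0.0)


def morph_clean(binary: np.ndarray, radius_erode: int, radius_dilate: int) -> np.ndarray:
    """Erosion then dilation with disk structuring elements.

    Pixels outside the image count as background, so erosion also shrinks
    regions touching the border (the behaviour wanted for discarding the
    facial contour).
    """
    out = np.asarray(binary, dtype=bool)
    if radius_erode > 0:
        out = ndimage.binary_erosion(out, skmorph.disk(radius_erode), border_value=0)
    if radius_dilate > 0:
        out = ndimage.binary_dilation(out, skmorph.disk(radius_dilate), border_value=0)
    return out


def canny_edge_map(gray: GrayImage, sigma: float = 2.0,
                   low: float = 0.60, high: float = 0.85,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Canny edges (gradient, non-maximum suppression, quantile hysteresis),
    restricted to ``mask`` when given."""
    if not low < high:
        raise ParameterError("canny: low threshold must be < high")
    img = gray.levels.astype(float) / max(gray.L - 1, 1)
    edges = skfeature.canny(img, sigma=sigma, low_threshold=low,
                            high_threshold=high, use_quantiles=True,
                            mode="nearest")
    if mask is not None:
        edges &= mask
    return edges


def gray_projection(gray: GrayImage | np.ndarray, axis: str,
                    window: tuple[int, int, int, int]):
    """Mean-gray profile of a sub-rectangle along rows or columns.

    ``axis='cols'`` averages over rows giving one value per column (the
    profile whose minima localize the cold nostrils); ``axis='rows'`` is the
    transpose.  Returns ``(profile, minima_idx, maxima_idx)`` where the
    extrema indices are relative to the window.
    """
    arr = gray.levels if isinstance(gray, GrayImage) else np.asarray(gray)
    r0, r1, c0, c1 = window
    if not (0 <= r0 < r1 <= arr.shape[0] and 0 <= c0 < c1 <= arr.shape[1]):
        raise ParameterError(f"empty or out-of-bounds window {window}")
    sub = arr[r0:r1, c0:c1].astype(float)
    profile = sub.mean(axis=0) if axis == "cols" else sub.mean(axis=1)
    minima = _local_extrema(profile, np.less_equal)
    maxima = _local_extrema(profile, np.greater_equal)
    return profile, minima, maxima


def _local_extrema(profile: np.ndarray, cmp) -> np.ndarray:
    """Indices of strict-neighborhood local extrema (plateau centers kept)."""
    if profile.size < 3:
        return np.array([], dtype=int)
    left = cmp(profile[1:-1], profile[:-2])
    right = cmp(profile[1:-1], profile[2:])
    idx = np.flatnonzero(left & right) + 1
    # drop flat runs except one representative
    keep = []
    for i in idx:
        if not keep or i - keep[-1] > 1 or profile[i] != profile[keep[-1]]:
            keep.append(int(i))
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# key-point localization


def _window_rows(bbox, frac_lo, frac_hi):
    r0, r1, _, _ = bbox
    H = r1 - r0
    return int(round(r0 + frac_lo * H)), int(round(r0 + frac_hi * H))


def _argmin2d(arr: np.ndarray) -> tuple[int, int]:
    i = int(np.argmin(arr))
    return i // arr.shape[1], i % arr.shape[1]


def _argmax2d(arr: np.ndarray) -> tuple[int, int]:
    i = int(np.argmax(arr))
    return i // arr.shape[1], i % arr.shape[1]


def _snap_to_corner(point, corners: np.ndarray, radius: float = 3.0):
    """Move a candidate point to the nearest corner maximum within radius."""
    if corners.size == 0:
        return point
    d = np.hypot(corners[:, 0] - point[0], corners[:, 1] - point[1])
    j = int(np.argmin(d))
    if d[j] <= radius:
        return int(corners[j, 0]), int(corners[j, 1])
    return point


def locate_keypoints(gray: GrayImage, mask: FaceMask, corners: np.ndarray,
                     edges: np.ndarray, config: SegmentationConfig | None = None) -> KeyPoints:
    """Fuse projections, corner maxima, and edge runs into the ten landmarks.

    Search windows are anthropometric fractions of the face bounding box.
    Nostrils are the two deepest column-projection minima of the nose window
    (one per side); pupils and inner canthi are smoothed gray extrema in the
    per-side eye windows refined by the nearest Harris corner; mouth corners
    are the lateral extremes of the longest edge run in the mouth window;
    eyebrows are the coldest compact structures above the pupils.
    """
    cfg = config or SegmentationConfig()
    bbox = mask.bbox
    r0, r1, c0, c1 = bbox
    H = r1 - r0
    if H < 16 or (c1 - c0) < 16:
        raise SegmentationError("keypoints", "face bounding box degenerate")
    # midline kept at half-pixel resolution: for an even-width face the
    # mirror axis falls between two columns
    midline = round(2.0 * ndimage.center_of_mass(mask.mask)[1]) / 2.0
    ml = int(np.floor(midline))          # last column of the right half
    left_start = ml + 1                  # first column of the left half
    right_end = int(np.ceil(midline))    # exclusive end of the right half

    smooth = ndimage.gaussian_filter(gray.levels.astype(float), cfg.smooth_sigma)
    smooth_masked = np.where(mask.mask, smooth, np.inf)  # for minima searches
    smooth_masked_max = np.where(mask.mask, smooth, -np.inf)

    peaks = corners if corners.ndim == 2 and corners.shape[1] == 2 else np.empty((0, 2), int)

    # --- nostrils: column-projection minima in the nose window, one per side
    # (searched near the midline only; the cool face rim would otherwise
    # dominate the projection baseline)
    nr0, nr1 = _window_rows(bbox, *cfg.nose_window)
    nspan = max(6, int(round(cfg.nostril_max_offset * (c1 - c0))))
    nostrils = []
    for side, (w0, w1) in (
        ("l", (left_start, min(left_start + nspan, c1))),
        ("r", (max(right_end - nspan, c0), right_end)),
    ):
        if w1 - w0 < 3:
            raise LandmarkError(f"nostril_{side}", "window too narrow")
        profile, minima, _ = gray_projection(gray, "cols", (nr0, nr1, w0, w1))
        base = float(np.median(profile))
        cand = [i for i in minima if base - profile[i] >= cfg.nostril_min_depth]
        if not cand:
            raise LandmarkError(f"nostril_{side}", "no projection dip deep enough")
        col = w0 + min(cand, key=lambda i: profile[i])
        strip = smooth_masked[nr0:nr1, max(col - 2, 0):col + 3]
        row = nr0 + _argmin2d(strip)[0]
        nostrils.append((int(row), int(col)))
    nostril_l, nostril_r = nostrils

    # --- pupils and inner canthi in per-side eye windows
    er0, er1 = _window_rows(bbox, *cfg.eye_window)
    W = c1 - c0
    canthus_span = max(3, int(round(cfg.canthus_max_offset * W)))
    band_lo = int(round(cfg.eye_col_band[0] * W))
    band_hi = int(round(cfg.eye_col_band[1] * W))
    eye_bands = {
        "l": (min(left_start - 1 + band_lo, c1 - 1), min(left_start + band_hi, c1)),
        "r": (max(right_end - band_hi, c0), max(right_end - band_lo, c0 + 1)),
    }
    eye_points = {}
    for side, (w0, w1) in eye_bands.items():
        win = smooth_masked[er0:er1, w0:w1]
        if not np.isfinite(win).any():
            raise LandmarkError(f"pupil_{side}", "eye window outside face mask")
        pr, pc = _argmin2d(win)
        pupil = (er0 + pr, w0 + pc)
        if side == "l":
            cw0, cw1 = left_start, min(left_start + canthus_span, c1)
        else:
            cw0, cw1 = max(right_end - canthus_span, c0), right_end
        cwin = smooth_masked_max[er0:er1, cw0:cw1]
        if not np.isfinite(cwin).any():
            raise LandmarkError(f"canthus_inner_{side}", "canthus window outside face mask")
        kr, kc = _argmax2d(cwin)
        canthus = (er0 + kr, cw0 + kc)
        eye_points[f"pupil_{side}"] = _snap_to_corner(pupil, peaks)
        eye_points[f"canthus_inner_{side}"] = _snap_to_corner(canthus, peaks)

    # --- mouth corners: the warm mouth band must raise Canny edges in the
    # window (presence check); its lateral ends are then read off the
    # half-maximum crossings of the gray projections, which are insensitive
    # to stray edge fragments
    mr0, mr1 = _window_rows(bbox, *cfg.mouth_window)
    if not edges[mr0:mr1, c0:c1].any():
        raise LandmarkError("mouth_corner", "no edges in mouth window")
    # the warm band row: detrended row-projection maximum near the midline
    mid_w = max(4, int(round(0.20 * (c1 - c0))))
    row_prof, _, _ = gray_projection(
        gray, "rows", (mr0, mr1, max(ml - mid_w, c0), min(ml + 1 + mid_w, c1)))
    row_detr = row_prof - ndimage.gaussian_filter1d(row_prof, 10.0)
    if row_detr.max() < cfg.nostril_min_depth / 2:
        raise LandmarkError("mouth_corner", "no warm band in mouth window")
    above = np.flatnonzero(row_detr >= 0.5 * row_detr.max())
    mouth_row = mr0 + int(round(above.mean()))
    # column profile over the band rows only; the band ends are the
    # half-maximum crossings of the background-subtracted bump (the sloping
    # medial-lateral gradient would otherwise bias the crossings inward)
    band_half = max(3, int(round(0.02 * H)))
    b0 = max(mouth_row - band_half, 0)
    b1 = min(mouth_row + band_half + 1, gray.levels.shape[0])
    col_prof, _, _ = gray_projection(gray, "cols", (b0, b1, c0, c1))
    prof_s = ndimage.gaussian_filter1d(col_prof, 2.0)
    # baseline windows anchored on the midline (the band straddles it);
    # an argmax anchor could wander along the band's flat top into them
    center = int(round(midline)) - c0
    W_face = c1 - c0
    base_lo = int(round(0.15 * W_face))
    base_hi = int(round(0.22 * W_face))

    def side_baseline(direction):
        b_from = center + direction * base_lo
        b_to = center + direction * base_hi
        sl = slice(max(0, min(b_from, b_to)), min(col_prof.size, max(b_from, b_to)))
        if sl.stop - sl.start < 2:
            raise LandmarkError("mouth_corner", "mouth band at window edge")
        return float(np.median(prof_s[sl]))

    x_r, x_l = center - base_lo, center + base_lo
    b_r, b_l = side_baseline(-1), side_baseline(+1)
    cols_idx = np.arange(col_prof.size)
    background = b_r + (b_l - b_r) * (cols_idx - x_r) / max(x_l - x_r, 1)
    bump = prof_s - background
    peak_val = float(np.median(bump[max(center - 3, 0):center + 4]))
    if peak_val < cfg.nostril_min_depth:
        raise LandmarkError("mouth_corner", "no warm band in mouth window")
    half = 0.5 * peak_val

    def crossing(direction):
        # walk out along the half-max run (one sub-half column does not stop
        # the walk), then refine by a least-squares line through the steep
        # flank points around the crossing
        col = center
        while abs(col - center) <= base_hi:
            nxt, nxt2 = col + direction, col + 2 * direction
            if not (0 <= nxt < col_prof.size):
                break
            if bump[nxt] >= half:
                col = nxt
                continue
            if 0 <= nxt2 < col_prof.size and bump[nxt2] >= half:
                col = nxt2
                continue
            break
        if abs(col - center) > base_hi:
            raise LandmarkError("mouth_corner", "mouth band edge not found")
        flank = np.arange(col - 3 * direction, col + 4 * direction, direction)
        flank = flank[(flank >= 0) & (flank < col_prof.size)]
        flank = flank[(bump[flank] >= 0.15 * peak_val) & (bump[flank] <= 0.85 * peak_val)]
        if flank.size >= 3:
            slope, intercept = np.polyfit(flank, bump[flank], 1)
            if abs(slope) > 1e-9:
                est = (half - intercept) / slope
                if abs(est - col) <= 3:
                    return int(round(est))
        return col

    lo, hi = crossing(-1), crossing(+1)
    mouth_corner_l = (mouth_row, c0 + hi)
    mouth_corner_r = (mouth_row, c0 + lo)
    if not (mouth_corner_l[1] > midline > mouth_corner_r[1]):
        raise LandmarkError("mouth_corner", "mouth band does not straddle the midline")

    # --- eyebrows: coldest structure above the pupils, per side
    br0, _ = _window_rows(bbox, *cfg.eyebrow_window)
    brows = {}
    for side in ("l", "r"):
        pupil = eye_points[f"pupil_{side}"]
        br1 = max(br0 + 2, pupil[0] - max(2, int(0.03 * H)))
        bb_lo = int(round(cfg.eyebrow_col_band[0] * W))
        bb_hi = int(round(cfg.eyebrow_col_band[1] * W))
        if side == "l":
            w0, w1 = min(left_start - 1 + bb_lo, c1 - 1), min(left_start + bb_hi, c1)
        else:
            w0, w1 = max(right_end - bb_hi, c0), max(right_end - bb_lo, c0 + 1)
        win = smooth_masked[br0:br1, w0:w1]
        if not np.isfinite(win).any():
            raise LandmarkError(f"eyebrow_{side}", "window outside face mask")
        rr, cc = _argmin2d(win)
        brows[side] = (br0 + rr, w0 + cc)

    kp = KeyPoints(
        nostril_l=nostril_l, nostril_r=nostril_r,
        pupil_l=tuple(map(int, eye_points["pupil_l"])),
        pupil_r=tuple(map(int, eye_points["pupil_r"])),
        mouth_corner_l=mouth_corner_l, mouth_corner_r=mouth_corner_r,
        canthus_inner_l=tuple(map(int, eye_points["canthus_inner_l"])),
        canthus_inner_r=tuple(map(int, eye_points["canthus_inner_r"])),
        eyebrow_l=tuple(map(int, brows["l"])), eyebrow_r=tuple(map(int, brows["r"])),
        midline_col=midline,
    )
    kp.validate()
    return kp


# ---------------------------------------------------------------------------
# ROI layout


def _mirror_rect(rect, midline):
    r0, r1, c0, c1 = rect
    two_m = int(round(2 * midline))
    return (r0, r1, two_m - c1 + 1, two_m - c0 + 1)


def layout_rois(kp: KeyPoints, mask: FaceMask,
                config: SegmentationConfig | None = None) -> FacialROISet:
    """Place the 10 ROIs from the landmarks by fractional anthropometric
    rules, then symmetrize each pair about the midline (the right box is the
    exact mirror of the left) so paired rectangles share size exactly."""
    cfg = config or SegmentationConfig()
    kp.validate()
    r0, r1, c0, c1 = mask.bbox
    H, W = r1 - r0, c1 - c0
    m = kp.midline_col

    def clip_to_face(rect):
        a0, a1, b0, b1 = rect
        return (max(a0, r0), min(a1, r1), max(b0, c0), min(b1, c1))

    ipd = kp.pupil_l[1] - kp.pupil_r[1]
    brow_row = int(round((kp.eyebrow_l[0] + kp.eyebrow_r[0]) / 2))
    nostril_row = int(round((kp.nostril_l[0] + kp.nostril_r[0]) / 2))

    left: dict[str, tuple[int, int, int, int]] = {}

    # R1 forehead: band above the eyebrows, split at the midline
    fh = int(round(cfg.forehead_height * H))
    fw = int(round(cfg.forehead_width * W))
    m_left = int(np.floor(m)) + 1  # first column of the anatomical-left half
    left["R1"] = (brow_row - fh, brow_row - 2, m_left + 1, m_left + 1 + fw)

    # R2 orbital: box around the left pupil
    ow = max(4, int(round(cfg.orbital_width_ipd * ipd)))
    oh = max(4, int(round(cfg.orbital_height * H)))
    pl = kp.pupil_l
    left["R2"] = (pl[0] - oh // 2, pl[0] - oh // 2 + oh,
                  pl[1] - ow // 2, pl[1] - ow // 2 + ow)

    # R3 infraorbital: same columns, directly below orbital
    ih = max(4, int(round(cfg.infraorbital_height * H)))
    left["R3"] = (left["R2"][1], left["R2"][1] + ih, left["R2"][2], left["R2"][3])

    # R4 nasal: box flanking the left nostril laterally
    ns = max(8, int(round(cfg.nasal_size * H)))
    left["R4"] = (nostril_row - ns // 2, nostril_row - ns // 2 + ns,
                  kp.nostril_l[1] + 3, kp.nostril_l[1] + 3 + ns)

    # R5 mouth: box centered on the left mouth corner
    ms = max(8, int(round(cfg.mouth_size * H)))
    left["R5"] = (kp.mouth_corner_l[0] - ms // 2, kp.mouth_corner_l[0] - ms // 2 + ms,
                  kp.mouth_corner_l[1] - ms // 2, kp.mouth_corner_l[1] - ms // 2 + ms)

    rois: dict[str, ROIRect] = {}
    for pair, lrect in left.items():
        lrect = clip_to_face(lrect)
        rrect = clip_to_face(_mirror_rect(lrect, m))
        # equalize after clipping: re-mirror the intersection back
        lrect2 = _mirror_rect(rrect, m)
        lrect = (max(lrect[0], lrect2[0]), min(lrect[1], lrect2[1]),
                 max(lrect[2], lrect2[2]), min(lrect[3], lrect2[3]))
        rrect = _mirror_rect(lrect, m)
        for side, rect in (("L", lrect), ("R", rrect)):
            if rect[1] <= rect[0] or rect[3] <= rect[2]:
                raise LayoutError(f"{pair}.{side} collapsed outside the face box")
            rois[f"{pair}.{side}"] = ROIRect(f"{pair}.{side}", rect)

    roi_set = FacialROISet(rois=rois, midline_col=m, keypoints=kp)
    roi_set.validate(shape=mask.mask.shape)
    return roi_set


def segment(img: ThermalImage, config: SegmentationConfig | None = None) -> FacialROISet:
    """Full segmentation chain: gray quantization, Otsu face mask, Harris
    corners (contour-cleaned by erosion), Canny edges, gray projections,
    key-point fusion, anthropometric ROI layout.  Deterministic."""
    cfg = config or SegmentationConfig()
    gray = normalize_gray(img, cfg.gray_levels)
    mask = otsu_face_mask(gray)
    inner = morph_clean(mask.mask, cfg.erode_radius, 0)
    response = harris_corner_map(gray, k=cfg.harris_k, sigma=cfg.harris_sigma)
    peaks = corner_peaks(response, cfg.corner_quantile, mask=inner)
    edge_mask = morph_clean(mask.mask, cfg.edge_erode_radius, 0)
    edges = canny_edge_map(gray, cfg.canny_sigma, cfg.canny_low_q,
                           cfg.canny_high_q, mask=edge_mask)
    kp = locate_keypoints(gray, mask, peaks, edges, cfg)
    return layout_rois(kp, mask, cfg)
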