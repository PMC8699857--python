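"""Synthetic frontal facial thermograms with ground truth, and labeled cohorts.

No clinical thermograms accompany the method, so this module is the test
substrate: it emulates the qualitative physics of a frontal facial
thermogram — an elliptical face at ~33.5 °C on a ~24.5 °C background, warm
medially and cooler laterally, with cold nostrils (air flow), warm inner
canthi (the warmest facial structures), cool pupils and eyebrows, and a warm
mouth band — plus spatially correlated measurement noise.  Every phantom
carries exact ground-truth landmarks and ROI boxes.

Unilateral paralysis is modeled as (a) per-ROI mean temperature offsets on
the affected side, whose defaults are the published control-vs-patient group
gaps (forehead 0.32 °C, orbital 0.24 °C, infraorbital 0.22 °C, and near-zero
nasal/mouth gaps), and (b) a texture perturbation that locally smooths the
affected side, raising its GLCM energy/homogeneity and hence the bilateral
texture distance.  Severity scales both, mapped monotonically from the
House-Brackmann grade (II = 0.4 … V = 1.0).  Healthy subjects receive small
random bilateral fluctuations so control-group asymmetries are nonzero, as
in real cohorts.

The default cohort reproduces the study template: 45 patients with HB grade
counts (II: 3, III: 8, IV: 14, V: 20, VI: 0) and 45 healthy controls, one
seeded random affected side per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .segmentation import (
    FaceMask,
    FacialROISet,
    KeyPoints,
    PAIR_LABELS,
    SegmentationConfig,
    layout_rois,
)
from .thermal_io import ThermalImage

HB_SEVERITY = {"II": 0.4, "III": 0.6, "IV": 0.8, "V": 1.0, "VI": 1.2}

DEFAULT_HB_DISTRIBUTION = {"II": 3, "III": 8, "IV": 14, "V": 20, "VI": 0}

#: control-vs-patient group gaps in mean-temperature asymmetry, °C per ROI
DEFAULT_ROI_OFFSETS = {"R1": 0.32, "R2": 0.24, "R3": 0.22, "R4": 0.05, "R5": 0.04}


@dataclass
class Organ:
    """A localized thermal anomaly at a face-box-fractional position."""

    row_frac: float           # of face-box height, from its top
    col_offset_frac: float    # of face-box width, from the midline (0 = midline)
    amplitude: float          # °C, negative = cold
    sigma_row: float          # px
    sigma_col: float          # px
    shape: str = "gauss"      # 'gauss' or 'band' (super-Gaussian, sharp edges)


@dataclass
class FacePhantomConfig:
    shape: tuple[int, int] = (256, 336)
    ambient: float = 24.5
    face_base: float = 33.5
    gradient_amp: float = 1.5      # °C medial-to-lateral drop
    noise_sd: float = 0.05         # °C, the camera's stated thermal sensitivity
    noise_corr_px: float = 3.0
    face_semiaxes_frac: tuple[float, float] = (0.42, 0.29)  # of rows / cols
    organs: dict[str, Organ] = field(default_factory=lambda: {
        "nostril": Organ(0.575, 0.055, -6.0, 2.5, 2.5),
        "canthus": Organ(0.330, 0.080, +1.5, 2.5, 2.5),
        "pupil": Organ(0.325, 0.170, -2.5, 3.0, 3.5),
        "eyebrow": Organ(0.200, 0.140, -2.0, 2.0, 7.0),
        "mouth": Organ(0.800, 0.0, +1.2, 4.0, 26.0, "band"),
    })
    # per-ROI healthy bilateral fluctuation SD, °C (nonzero control asymmetry)
    baseline_asym_sd: float = 0.15

    def __post_init__(self):
        if self.ambient >= self.face_base:
            raise ConfigError("ambient must be below face base temperature")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")


@dataclass
class ParalysisEffect:
    side: str = "L"
    roi_offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROI_OFFSETS))
    texture_alpha: float = 0.6     # blend weight of the smoothed field at severity 1
    texture_sigma: float = 2.0     # px, smoothing scale of the perturbation
    severity: float = 1.0
    hb_grade: str | None = None

    def __post_init__(self):
        if self.side not in ("L", "R"):
            raise ConfigError("side must be 'L' or 'R'")
        if self.severity < 0:
            raise ConfigError("severity must be >= 0")
        if self.hb_grade is not None:
            self.severity = HB_SEVERITY[self.hb_grade]


@dataclass
class GroundTruth:
    keypoints: KeyPoints
    rois: FacialROISet
    face_bbox: tuple[int, int, int, int]
    face_mask: np.ndarray


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                      # 'paralysis' | 'normal'
    hb_grade: str                   # 'I'..'VI'
    side: str | None
    severity: float
    image: ThermalImage
    truth: GroundTruth

    def __post_init__(self):
        if (self.group == "normal") != (self.hb_grade == "I"):
            raise ConfigError("normal subjects must have HB grade I and vice versa")


# ---------------------------------------------------------------------------


def _face_geometry(cfg: FacePhantomConfig):
    rows, cols = cfg.shape
    ar = cfg.face_semiaxes_frac[0] * rows
    ac = cfg.face_semiaxes_frac[1] * cols
    cr = rows / 2.0
    cc = (cols - 1) / 2.0  # exact mirror axis of the pixel grid
    return cr, cc, ar, ac


def _organ_centers(cfg: FacePhantomConfig):
    """Ground-truth (row, col) centers per organ and side (floats)."""
    cr, cc, ar, ac = _face_geometry(cfg)
    top = cr - ar
    H = 2 * ar
    W = 2 * ac
    centers = {}
    for name, organ in cfg.organs.items():
        row = top + organ.row_frac * H
        off = organ.col_offset_frac * W
        centers[name] = {"L": (row, cc + off), "R": (row, cc - off)}
    return centers


def generate_face(cfg: FacePhantomConfig | None = None, seed: int | None = 0,
                  seg_config: SegmentationConfig | None = None
                  ) -> tuple[ThermalImage, GroundTruth]:
    """One healthy frontal phantom plus its exact ground truth.

    With ``noise_sd == 0`` the image equals its own horizontal mirror
    exactly (all structures are placed symmetrically about the pixel-grid
    mirror axis).
    """
    cfg = cfg or FacePhantomConfig()
    rows, cols = cfg.shape
    cr, cc, ar, ac = _face_geometry(cfg)
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    d2 = ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2
    face = d2 <= 1.0

    # smooth warm plateau with a soft rim falling to ambient
    rim = 1.0 / (1.0 + np.exp((d2 - 1.0) * 25.0))
    lateral = cfg.gradient_amp * np.abs((c - cc) / ac) ** 1.5
    temp = cfg.ambient + (cfg.face_base - cfg.ambient - lateral) * rim

    centers = _organ_centers(cfg)
    for name, organ in cfg.organs.items():
        sides = ("L",) if organ.col_offset_frac == 0 else ("L", "R")
        bumps = []
        for side in sides:
            orow, ocol = centers[name][side]
            if ((orow - cr) / ar) ** 2 + ((ocol - cc) / ac) ** 2 > 0.95:
                raise ConfigError(f"organ {name} outside the face ellipse")
            dr = (r - orow) / organ.sigma_row
            dc = (c - ocol) / organ.sigma_col
            if organ.shape == "band":
                bumps.append(np.exp(-(dr ** 6) - (dc ** 6)))
            else:
                bumps.append(np.exp(-0.5 * (dr ** 2 + dc ** 2)))
        # both sides summed before accumulation: float addition commutes, so
        # a noise-free phantom is bitwise equal to its horizontal mirror
        temp += organ.amplitude * (bumps[0] + bumps[-1] if len(bumps) == 2 else bumps[0])

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, 1.0, size=cfg.shape)
        if cfg.noise_corr_px > 0:
            noise = ndimage.gaussian_filter(noise, cfg.noise_corr_px)
            noise /= noise.std()
        temp = temp + cfg.noise_sd * noise

    img = ThermalImage(temp, meta={"synthetic": True, "seed": seed})

    # ground truth: landmarks at organ centers, ROIs via the shared layout rules
    def pt(name, side):
        row, col = centers[name][side]
        return int(round(row)), int(round(col))

    mouth = cfg.organs["mouth"]
    mouth_row = int(round(cr - ar + mouth.row_frac * 2 * ar))
    # the band edge is soft; its ground-truth corner is the half-maximum end
    half_w = mouth.sigma_col * np.log(2.0) ** (1.0 / 6.0)
    midline = round(2.0 * cc) / 2.0
    kp = KeyPoints(
        nostril_l=pt("nostril", "L"), nostril_r=pt("nostril", "R"),
        pupil_l=pt("pupil", "L"), pupil_r=pt("pupil", "R"),
        mouth_corner_l=(mouth_row, int(round(cc + half_w))),
        mouth_corner_r=(mouth_row, int(round(cc - half_w))),
        canthus_inner_l=pt("canthus", "L"), canthus_inner_r=pt("canthus", "R"),
        eyebrow_l=pt("eyebrow", "L"), eyebrow_r=pt("eyebrow", "R"),
        midline_col=midline,
    )
    bbox = (int(np.floor(cr - ar)), int(np.ceil(cr + ar)) + 1,
            int(np.floor(cc - ac)), int(np.ceil(cc + ac)) + 1)
    mask = FaceMask(mask=face, bbox=bbox)
    rois = layout_rois(kp, mask, seg_config or SegmentationConfig())
    return img, GroundTruth(keypoints=kp, rois=rois, face_bbox=bbox, face_mask=face)


def _tapered_box(shape, rect, taper: float = 2.0) -> np.ndarray:
    """Indicator of a rectangle with Gaussian-tapered edges, normalized so
    its mean over the rectangle is exactly 1 (an offset scaled by this
    window shifts the ROI's mean temperature by exactly that offset)."""
    ind = np.zeros(shape)
    r0, r1, c0, c1 = rect
    ind[r0:r1, c0:c1] = 1.0
    if taper > 0:
        ind = ndimage.gaussian_filter(ind, taper)
        inside = ind[r0:r1, c0:c1].mean()
        if inside > 0:
            ind /= inside
    return ind


def apply_paralysis(img: ThermalImage, truth: GroundTruth,
                    effect: ParalysisEffect) -> ThermalImage:
    """Impose unilateral paralysis on a phantom.

    Adds severity-scaled mean offsets within the affected-side ROI
    footprints (edge-tapered so no sharp seams appear) and blends in a
    locally smoothed copy of the field there, which raises affected-side
    GLCM energy/homogeneity.  The unaffected side is untouched.
    """
    if effect.severity == 0:
        return ThermalImage(img.values.copy(), dict(img.meta))
    temp = img.values.copy()
    smoothed = ndimage.gaussian_filter(temp, effect.texture_sigma)
    alpha = min(1.0, effect.texture_alpha * effect.severity)
    for pair in PAIR_LABELS:
        roi = truth.rois.rois[f"{pair}.{effect.side}"]
        window = _tapered_box(temp.shape, roi.rect)
        offset = effect.roi_offsets.get(pair, 0.0) * effect.severity
        temp += offset * window
        temp += alpha * window * (smoothed - img.values)
    meta = dict(img.meta)
    meta.update(side=effect.side, severity=effect.severity)
    return ThermalImage(temp, meta)


def _healthy_fluctuation(img: ThermalImage, truth: GroundTruth,
                         rng: np.random.Generator, sd: float) -> ThermalImage:
    """Small random per-ROI one-sided offsets emulating normal physiological
    asymmetry (controls are not perfectly symmetric either)."""
    if sd <= 0:
        return img
    temp = img.values.copy()
    for pair in PAIR_LABELS:
        side = "L" if rng.random() < 0.5 else "R"
        roi = truth.rois.rois[f"{pair}.{side}"]
        temp += rng.normal(0.0, sd) * _tapered_box(temp.shape, roi.rect)
    return ThermalImage(temp, dict(img.meta))


def scale_hb_distribution(n_patients: int) -> dict[str, int]:
    """The default HB grade mix rescaled to ``n_patients`` by largest
    remainder, preserving the template's proportions."""
    total = sum(DEFAULT_HB_DISTRIBUTION.values())
    quotas = {g: n_patients * k / total for g, k in DEFAULT_HB_DISTRIBUTION.items() if k}
    out = {g: int(q) for g, q in quotas.items()}
    remainders = sorted(quotas, key=lambda g: quotas[g] - out[g], reverse=True)
    for g in remainders[: n_patients - sum(out.values())]:
        out[g] += 1
    return out


def generate_cohort(n_patients: int = 45, n_controls: int = 45,
                    hb_distribution: dict[str, int] | None = None,
                    phantom_cfg: FacePhantomConfig | None = None,
                    effect_template: ParalysisEffect | None = None,
                    seed: int = 0) -> list[SubjectRecord]:
    """A labeled cohort of seeded phantoms (default 45 + 45, HB grades
    II: 3, III: 8, IV: 14, V: 20).  Deterministic given the seed; affected
    sides are balanced in expectation."""
    cfg = phantom_cfg or FacePhantomConfig()
    template = effect_template or ParalysisEffect()
    if hb_distribution is None:
        hb_distribution = DEFAULT_HB_DISTRIBUTION if n_patients == 45 \
            else scale_hb_distribution(n_patients)
    hb = dict(hb_distribution)
    if sum(hb.values()) != n_patients:
        raise ConfigError(f"HB distribution {hb} does not sum to {n_patients}")
    rng = np.random.default_rng(seed)
    records = []
    grades = [g for g, k in hb.items() for _ in range(k)]
    for i, grade in enumerate(grades):
        sid = f"P{i:03d}"
        sub_seed = int(rng.integers(2 ** 31))
        img, truth = generate_face(cfg, seed=sub_seed)
        img = _healthy_fluctuation(img, truth, rng, cfg.baseline_asym_sd)
        side = "L" if rng.random() < 0.5 else "R"
        effect = replace(template, side=side, hb_grade=grade)
        img = apply_paralysis(img, truth, effect)
        records.append(SubjectRecord(sid, "paralysis", grade, side,
                                     effect.severity, img, truth))
    for i in range(n_controls):
        sid = f"C{i:03d}"
        sub_seed = int(rng.integers(2 ** 31))
        img, truth = generate_face(cfg, seed=sub_seed)
        img = _healthy_fluctuation(img, truth, rng, cfg.baseline_asym_sd)
        records.append(SubjectRecord(sid, "normal", "I", None, 0.0, img, truth))
    return records


def cohort_metadata(records: list[SubjectRecord]):
    """Manifest DataFrame (subject_id, group, hb_grade, side, severity)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"subject_id": r.subject_id, "group": r.group, "hb_grade": r.hb_grade,
             "side": r.side or "", "severity": r.severity}
            for r in records
        ]
    )
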