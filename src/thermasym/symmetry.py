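"""Bilateral feature-symmetry measures and the per-subject symmetry vector.

For each of the five left/right ROI pairs the asymmetry of the temperature
field is summarized by

* ``ΔT_mean = |T_L,mean − T_R,mean|`` — absolute mean-temperature difference;
* ``ΔT_max = max(T_L,max − T_R,min, T_R,max − T_L,min)`` — the larger
  cross-side extreme-temperature span, which combines the warm tail of one
  side with the cold tail of the other (and is therefore nonzero even for a
  perfectly symmetric face, but always ≥ ΔT_mean);

and the asymmetry of the texture by the Minkowski distance between the two
sides' texture-feature values collected over the four GLCM directions:

    ρ_(P,Δ,G) = ( Σ_θ |F_L(θ) − F_R(θ′)|^P )^(1/P),   P ∈ {1, 2}.

With ``mirror_mode`` on (the default), θ′ mirror-maps the diagonal
directions of the right side (45° ↔ 135°, 0°/90° fixed), so that an exactly
mirror-symmetric face yields ρ = 0 for every cell; with it off the same
direction is compared on both sides.

Per pair this yields 2 temperature symmetries and 4 features × 2 Δ × 2 G ×
2 P = 32 texture symmetries; over 5 pairs the full subject vector has
5 × 34 = 170 named dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .features import (
    DELTAS,
    GRAY_LEVELS,
    MINKOWSKI_ORDERS,
    TEXTURE_NAMES,
    THETAS,
    TemperatureFeatures,
    all_texture_features,
    temperature_features,
)
from .segmentation import PAIR_LABELS

MIRROR_THETA = {0: 0, 45: 135, 90: 90, 135: 45}

FULL_DIM = 170


def delta_t_mean(left: TemperatureFeatures, right: TemperatureFeatures) -> float:
    """Absolute difference of the two sides' mean temperatures (°C)."""
    return abs(left.t_mean - right.t_mean)


def delta_t_max(left: TemperatureFeatures, right: TemperatureFeatures) -> float:
    """Larger of the two cross-side extreme spans (°C); always >= ΔT_mean."""
    return max(left.t_max - right.t_min, right.t_max - left.t_min)


def minkowski_rho(f_left, f_right, p: int, mirror_mode: bool = True) -> float:
    """Minkowski distance between per-direction feature values of both sides.

    ``f_left``/``f_right`` map θ -> value for one (feature, Δ, G) cell.
    """
    if p not in MINKOWSKI_ORDERS:
        raise ParameterError(f"p must be one of {MINKOWSKI_ORDERS}")
    total = 0.0
    for theta in THETAS:
        tr = MIRROR_THETA[theta] if mirror_mode else theta
        total += abs(f_left[theta] - f_right[tr]) ** p
    return total ** (1.0 / p)


def rho_name(pair: str, feature: str, delta: int, g: int, p: int) -> str:
    return f"{pair}.rho.{feature}.d{delta}.g{g}.p{p}"


def vector_names(pairs=PAIR_LABELS) -> list[str]:
    """The canonical ordered name vocabulary of the symmetry vector."""
    names = []
    for pair in pairs:
        names.append(f"{pair}.dTmean")
        names.append(f"{pair}.dTmax")
        for feature in TEXTURE_NAMES:
            for delta in DELTAS:
                for g in GRAY_LEVELS:
                    for p in MINKOWSKI_ORDERS:
                        names.append(rho_name(pair, feature, delta, g, p))
    return names


@dataclass
class PairSymmetry:
    """All 34 symmetry values of one ROI pair."""

    pair_label: str
    dt_mean: float
    dt_max: float
    rho: dict[tuple[str, int, int, int], float]  # (feature, delta, g, p) -> value

    def __post_init__(self):
        if len(self.rho) != 32:
            raise ParameterError(f"expected 32 rho entries, got {len(self.rho)}")

    def named_values(self) -> dict[str, float]:
        out = {f"{self.pair_label}.dTmean": self.dt_mean,
               f"{self.pair_label}.dTmax": self.dt_max}
        for feature in TEXTURE_NAMES:
            for delta in DELTAS:
                for g in GRAY_LEVELS:
                    for p in MINKOWSKI_ORDERS:
                        out[rho_name(self.pair_label, feature, delta, g, p)] = \
                            self.rho[(feature, delta, g, p)]
        return out


@dataclass
class FeatureSymmetryVector:
    """Ordered named symmetry scalars for one subject (<= 170 dimensions)."""

    subject_id: str
    values: dict[str, float] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)

    def __len__(self) -> int:
        return len(self.values)


def pair_symmetry(left_roi, right_roi, pair_label: str = "R1",
                  mirror_mode: bool = True) -> PairSymmetry:
    """Temperature and texture symmetry of one equal-size ROI pair."""
    tl = temperature_features(left_roi)
    tr = temperature_features(right_roi)
    tex_l = {(f.params.theta, f.params.delta, f.params.g): f
             for f in all_texture_features(left_roi)}
    tex_r = {(f.params.theta, f.params.delta, f.params.g): f
             for f in all_texture_features(right_roi)}
    rho: dict[tuple[str, int, int, int], float] = {}
    for feature in TEXTURE_NAMES:
        for delta in DELTAS:
            for g in GRAY_LEVELS:
                fl = {t: tex_l[(t, delta, g)].value(feature) for t in THETAS}
                fr = {t: tex_r[(t, delta, g)].value(feature) for t in THETAS}
                for p in MINKOWSKI_ORDERS:
                    rho[(feature, delta, g, p)] = minkowski_rho(fl, fr, p, mirror_mode)
    return PairSymmetry(pair_label=pair_label,
                        dt_mean=delta_t_mean(tl, tr),
                        dt_max=delta_t_max(tl, tr), rho=rho)


def assemble_vector(pairs: list[PairSymmetry], subject_id: str = "",
                    subset: list[str] | None = None) -> FeatureSymmetryVector:
    """Concatenate 5 PairSymmetry values in canonical name order.

    Without a filter the vector has exactly 170 dimensions; ``subset``
    restricts it to the named features (stable canonical order).
    """
    if len(pairs) != len(PAIR_LABELS):
        raise ParameterError(f"expected {len(PAIR_LABELS)} pairs, got {len(pairs)}")
    by_label = {p.pair_label: p for p in pairs}
    if sorted(by_label) != sorted(PAIR_LABELS):
        raise ParameterError(f"pair labels must be {PAIR_LABELS}")
    values: dict[str, float] = {}
    for pair in PAIR_LABELS:
        values.update(by_label[pair].named_values())
    names = vector_names()
    if subset is not None:
        if len(set(subset)) != len(subset):
            raise ParameterError("duplicate names in subset filter")
        unknown = set(subset) - set(names)
        if unknown:
            raise ParameterError(f"unknown feature names: {sorted(unknown)}")
        names = [n for n in names if n in set(subset)]
    ordered = {n: float(values[n]) for n in names}
    if any(not np.isfinite(v) for v in ordered.values()):
        raise ParameterError("non-finite symmetry value")
    return FeatureSymmetryVector(subject_id=subject_id, values=ordered)


# --- name filters used by the evaluation protocol -------------------------


def names_delta_t(kind: str | None = None) -> list[str]:
    """ΔT feature names: kind None (both), 'mean', or 'max'."""
    suffix = {None: ("dTmean", "dTmax"), "mean": ("dTmean",), "max": ("dTmax",)}[kind]
    return [n for n in vector_names() if n.split(".")[-1] in suffix]


def names_texture(p: int | None = None) -> list[str]:
    """Texture rho names, optionally restricted to one Minkowski order."""
    names = [n for n in vector_names() if ".rho." in n]
    if p is not None:
        names = [n for n in names if n.endswith(f".p{p}")]
    return names
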