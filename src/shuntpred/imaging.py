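"""Scalar ventricular-geometry indices from raw landmark measurements.

Each index quantifies ventricular enlargement relative to skull or brain
size on a single MRI slice:

* Evans index (EI): maximal frontal-horn width / maximal internal skull
  diameter on the same axial slice; > 0.3 defines ventricular enlargement.
* z-Evans index (z-EI): maximal z-axial (vertical) frontal-horn length A /
  maximal cranial z-axial length B on the coronal slice at the anterior
  commissure; z-EI = A/B.
* Brain-per-ventricle ratio (BVR): z-axial brain thickness above the
  lateral ventricle relative to ventricle length, (B - A)/A.
* Posterior-horn ratio: maximal posterior-horn width / internal skull
  diameter at the same axial level.

Angles (callosal angle, splenium angle), the DESH sign, horn widths and
third-ventricle width are visual/manual measurements with no computable
extraction; they enter the cohort model as measured values with range
validation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DomainError",
    "LandmarkMeasurements",
    "evans_index",
    "z_evans_index",
    "brain_per_ventricle_ratio",
    "posterior_horn_ratio",
    "compute_indices",
]


class DomainError(ValueError):
    """An input lies outside the geometric domain of an index."""


@dataclass
class LandmarkMeasurements:
    """Raw per-subject landmark distances (mm) feeding the four indices."""

    frontal_horn_width: float
    skull_inner_diameter: float
    z_frontal_horn_length: float  # A in z-EI = A/B
    z_cranial_length: float  # B
    posterior_horn_width: float
    skull_inner_diameter_at_posterior: float


def evans_index(frontal_horn_width: float, skull_inner_diameter: float) -> float:
    """EI = frontal-horn width / internal skull diameter, in (0, 1)."""
    if frontal_horn_width <= 0 or skull_inner_diameter <= 0:
        raise DomainError("evans_index requires positive measurements")
    if frontal_horn_width >= skull_inner_diameter:
        raise DomainError("frontal-horn width must be smaller than the skull diameter")
    return frontal_horn_width / skull_inner_diameter


def z_evans_index(a: float, b: float) -> float:
    """z-EI = A/B with 0 < A < B (ventricle height / cranial height)."""
    if a <= 0 or b <= 0:
        raise DomainError("z_evans_index requires positive measurements")
    if a >= b:
        raise DomainError("ventricular z-length must be smaller than cranial z-length")
    return a / b


def brain_per_ventricle_ratio(a: float, b: float) -> float:
    """BVR = (B - A)/A: brain mantle above the ventricle per unit ventricle."""
    if a <= 0:
        raise DomainError("ventricular z-length must be positive")
    if b <= a:
        raise DomainError("cranial z-length must exceed ventricular z-length")
    return (b - a) / a


def posterior_horn_ratio(
    posterior_horn_width: float, skull_inner_diameter_at_posterior: float
) -> float:
    """Posterior-horn width / internal skull diameter at the same level."""
    if posterior_horn_width <= 0 or skull_inner_diameter_at_posterior <= 0:
        raise DomainError("posterior_horn_ratio requires positive measurements")
    if posterior_horn_width >= skull_inner_diameter_at_posterior:
        raise DomainError("posterior-horn width must be smaller than the skull diameter")
    return posterior_horn_width / skull_inner_diameter_at_posterior


_LANDMARK_COLS = [
    "frontal_horn_width",
    "skull_inner_diameter",
    "z_frontal_horn_length",
    "z_cranial_length",
    "posterior_horn_width",
    "skull_inner_diameter_at_posterior",
]


def compute_indices(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Batch landmark table -> index table (columns ei, z_ei, bvr,
    posterior_horn_ratio), row order preserved.

    Expects the six landmark columns named as in
    :class:`LandmarkMeasurements`; extra columns (ids) are passed through.
    """
    missing = [c for c in _LANDMARK_COLS if c not in landmarks.columns]
    if missing:
        raise DomainError(f"missing landmark column(s): {', '.join(missing)}")
    out = landmarks.drop(columns=_LANDMARK_COLS).copy()
    out["ei"] = [
        evans_index(w, d)
        for w, d in zip(landmarks["frontal_horn_width"], landmarks["skull_inner_diameter"])
    ]
    out["z_ei"] = [
        z_evans_index(a, b)
        for a, b in zip(landmarks["z_frontal_horn_length"], landmarks["z_cranial_length"])
    ]
    out["bvr"] = [
        brain_per_ventricle_ratio(a, b)
        for a, b in zip(landmarks["z_frontal_horn_length"], landmarks["z_cranial_length"])
    ]
    out["posterior_horn_ratio"] = [
        posterior_horn_ratio(w, d)
        for w, d in zip(
            landmarks["posterior_horn_width"],
            landmarks["skull_inner_diameter_at_posterior"],
        )
    ]
    return out
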