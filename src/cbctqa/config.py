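"""Validated configuration for the synthetic study and the analysis pipeline.

The configuration mirrors the study design it emulates: an electron-density
phantom with a liver-equivalent insert scanned on planning CT and CBCT, and
a prostate SBRT cohort (default 26 patients, one planning scan plus five
fractional CBCTs) with two observers rating each scan on a 5-point Likert
scale.

All HU values for soft tissues are generator parameters with textbook
defaults (the study reports no absolute patient HU); every default can be
overridden from YAML.  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io import CBCT, PLANNING_CT


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class InsertSpec(_Model):
    """A cylindrical phantom insert (axis along the slice direction)."""

    name: str = "insert"
    center_mm: tuple[float, float] = (0.0, 0.0)  # in-plane, relative to grid center
    diameter_mm: float = Field(30.0, gt=0)
    mean_hu: float = 60.0
    label: int = Field(3, ge=1)


class PhantomSpec(_Model):
    """Geometry and noise model of the electron-density QA phantom.

    The body is a water-equivalent cylinder; the central uniform region
    (no inlays) provides the contrast background; inserts model tissue
    surrogates.  The default single insert is the liver-equivalent inlay
    used as the signal source.
    """

    shape: tuple[int, int, int] = (128, 128, 24)
    spacing_mm: tuple[float, float, float] = (1.0507, 1.0507, 2.0)
    body_hu: float = 0.0
    body_diameter_mm: float = Field(120.0, gt=0)
    body_label: int = Field(1, ge=1)
    central_diameter_mm: float = Field(30.0, gt=0)
    central_label: int = Field(2, ge=1)
    inserts: list[InsertSpec] = Field(
        default_factory=lambda: [InsertSpec(name="liver", center_mm=(35.0, 0.0))]
    )
    air_hu: float = -1000.0
    noise_sd_hu: dict[str, float] = Field(
        default_factory=lambda: {PLANNING_CT: 10.0, CBCT: 18.0}
    )

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if any(s <= 0 for s in self.spacing_mm) or any(n <= 0 for n in self.shape):
            raise ValueError("shape and spacing must be positive")
        for sd in self.noise_sd_hu.values():
            if sd < 0:
                raise ValueError("noise SD must be >= 0")
        labels = [self.body_label, self.central_label] + [i.label for i in self.inserts]
        if len(set(labels)) != len(labels):
            raise ValueError(f"phantom labels must be unique, got {labels}")
        r_body = self.body_diameter_mm / 2
        for ins in self.inserts:
            cx, cy = ins.center_mm
            if (cx**2 + cy**2) ** 0.5 + ins.diameter_mm / 2 > r_body:
                raise ValueError(
                    f"insert {ins.name!r} does not lie fully inside the phantom body"
                )
        return self


class CompartmentSpec(_Model):
    label: int = Field(ge=1)
    mean_hu: float
    jitter_sd_hu: float = Field(0.0, ge=0)


def _default_compartments() -> dict[str, CompartmentSpec]:
    # Textbook soft-tissue HU; the study reports no absolute patient values.
    return {
        "pelvic_fat": CompartmentSpec(label=1, mean_hu=-100.0, jitter_sd_hu=5.0),
        "gluteal_muscle": CompartmentSpec(label=2, mean_hu=45.0, jitter_sd_hu=5.0),
        "prostate": CompartmentSpec(label=3, mean_hu=40.0, jitter_sd_hu=4.0),
        "seminal_vesicles": CompartmentSpec(label=4, mean_hu=35.0, jitter_sd_hu=4.0),
        "rectal_wall": CompartmentSpec(label=5, mean_hu=30.0, jitter_sd_hu=4.0),
        "bone": CompartmentSpec(label=6, mean_hu=700.0, jitter_sd_hu=20.0),
    }


class DriftModel(_Model):
    """Fraction-dependent attenuation change in the peri-target fat.

    The mean HU of fat voxels within 0-10 mm of each target region rises by
    ``slope_hu_per_fraction * fraction``; ``shell_sigma_hu`` adds an
    independent per-scan fluctuation of the same shell mean, emulating
    day-to-day variability of the treatment-induced tissue change (edema,
    inflammation).  Target organs and fat beyond 10 mm stay stationary.
    """

    slope_hu_per_fraction: float = 1.5
    shell_sigma_hu: float = Field(6.0, ge=0)
    shell_mm: float = Field(10.0, gt=0)
    regions: tuple[str, ...] = ("prostate", "seminal_vesicles")


class RatingModel(_Model):
    """Two-observer 5-point Likert model.

    Scores are a rounded, clamped latent Gaussian: observer intercept minus
    a per-fraction decline, plus a per-scan quality term shared by both
    observers (this carries the between-scan variance that inter-observer
    agreement measures) and independent ordinal noise.
    """

    observer_intercepts: dict[str, float] = Field(
        default_factory=lambda: {"R1": 4.6, "R2": 4.3}
    )
    decline_per_fraction: float = 0.12
    noise_sd: float = Field(0.5, ge=0)
    scan_sigma: float = Field(0.6, ge=0)
    parameters: tuple[str, ...] = (
        "tissue_differentiation",
        "prostate_contour_sharpness",
        "seminal_vesicle_contour_sharpness",
        "rectal_wall_contour_sharpness",
        "art_usability",
        "target_delineation_confidence",
        "oar_delineation_confidence",
    )
    parameter_groups: dict[str, tuple[str, ...]] = Field(
        default_factory=lambda: {
            "tissue_differentiation": (
                "tissue_differentiation",
                "prostate_contour_sharpness",
                "seminal_vesicle_contour_sharpness",
                "rectal_wall_contour_sharpness",
            ),
            "art_workflow": (
                "art_usability",
                "target_delineation_confidence",
                "oar_delineation_confidence",
            ),
        }
    )


class TimeModel(_Model):
    """Assessment-time model: base + increment x fraction + noise, floored."""

    base_s: float = Field(120.0, ge=0)
    increment_s_per_fraction: float = 20.0
    noise_sd_s: float = Field(15.0, ge=0)
    min_s: float = Field(1.0, gt=0)


class CohortSpec(_Model):
    """The longitudinal patient cohort the generator emulates."""

    n_patients: int = Field(26, ge=2)
    n_fractions: int = Field(5, ge=2)  # fractional CBCTs; plus one planning scan
    shape: tuple[int, int, int] = (72, 72, 36)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 3.0)
    compartments: dict[str, CompartmentSpec] = Field(default_factory=_default_compartments)
    air_hu: float = -1000.0
    noise_sd_hu: dict[str, float] = Field(
        default_factory=lambda: {PLANNING_CT: 10.0, CBCT: 18.0}
    )
    drift: DriftModel = Field(default_factory=DriftModel)
    rating: RatingModel = Field(default_factory=RatingModel)
    time: TimeModel = Field(default_factory=TimeModel)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if any(s <= 0 for s in self.spacing_mm) or any(n <= 0 for n in self.shape):
            raise ValueError("shape and spacing must be positive")
        for sd in self.noise_sd_hu.values():
            if sd < 0:
                raise ValueError("noise SD must be >= 0")
        labels = [c.label for c in self.compartments.values()]
        if len(set(labels)) != len(labels):
            raise ValueError(f"compartment labels must be unique, got {labels}")
        for region in self.drift.regions:
            if region not in self.compartments:
                raise ValueError(f"drift region {region!r} is not a compartment")
        if "pelvic_fat" not in self.compartments:
            raise ValueError("cohort requires a 'pelvic_fat' compartment")
        return self


class AnalysisOptions(_Model):
    """Knobs of the analysis itself (not of the data generator)."""

    alpha: float = Field(0.05, gt=0, lt=1)
    posthoc_baseline: Literal["pct", "all-pairs"] = "pct"
    roi1_rim_mm: float = Field(5.0, gt=0)
    shell_bounds_mm: tuple[float, float] = (10.0, 20.0)
    reference_fat_min_mm: float = Field(25.0, ge=0)
    phantom_roi_diameter_mm: float = Field(25.0, gt=0)
    phantom_n_repeats: int = Field(2, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "AnalysisOptions":
        lo, hi = self.shell_bounds_mm
        if not 0 < lo < hi:
            raise ValueError("shell bounds must satisfy 0 < lo < hi")
        return self


class Config(_Model):
    """Top-level run configuration."""

    phantom: PhantomSpec = Field(default_factory=PhantomSpec)
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)
    seed: int = 0


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Config:
    """Load and validate a YAML configuration; defaults fill missing keys.

    Unknown keys raise a validation error listing the offending location.
    ``overrides`` (e.g. a CLI --seed) are applied on top of the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    if overrides:
        raw = _deep_update(raw, overrides)
    cfg = Config.model_validate(raw)
    return cfg


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out
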