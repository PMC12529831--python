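"""Synthetic phantom, cohort and rating generator.

Emulates the study structure the analysis pipeline assumes: an
electron-density phantom with a liver-equivalent insert scanned on planning
CT and CBCT; a prostate SBRT cohort (planning scan + fractional CBCTs per
patient) rendered as nested simple solids (ellipsoids/boxes) in a pelvic
fat matrix; and two observers' 5-point Likert ratings with assessment
times.

The longitudinal mechanism of interest is injected explicitly: the mean HU
of fat within 0-10 mm of each target region rises linearly with fraction
number (treatment-induced tissue change), while the targets and the fat
10-20 mm away stay stationary.  All randomness derives from the master
seed via ``numpy.random.SeedSequence`` keyed on (seed, stream, patient,
fraction), so adding patients or fractions never perturbs existing scans.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import CohortSpec, PhantomSpec
from .io import CBCT, PLANNING_CT, Volume

# stream tags for independent RNG substreams
_S_JITTER, _S_SHELL, _S_VOXEL, _S_SCANQ, _S_RATING, _S_PHANTOM = 1, 2, 3, 4, 5, 6


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) & 0x7FFFFFFF for k in key]))


def _patient_index(patient: str | int) -> int:
    if isinstance(patient, (int, np.integer)):
        return int(patient)
    digits = "".join(ch for ch in str(patient) if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot derive a patient index from id {patient!r}")
    return int(digits)


def patient_id(index: int) -> str:
    return f"P{index:02d}"


# ---------------------------------------------------------------------------
# phantom


def _grid_mm(shape, spacing):
    """Voxel-center coordinates (mm) relative to the grid center, per axis."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]


def phantom_mask(spec: PhantomSpec) -> np.ndarray:
    """Label mask of the phantom: body, central region, inserts (cylinders)."""
    xs, ys, _ = _grid_mm(spec.shape, spec.spacing_mm)
    x = xs[:, None]
    y = ys[None, :]
    r2 = x**2 + y**2
    plane = np.zeros(spec.shape[:2], dtype=np.int32)
    plane[r2 <= (spec.body_diameter_mm / 2) ** 2] = spec.body_label
    plane[r2 <= (spec.central_diameter_mm / 2) ** 2] = spec.central_label
    for i, a in enumerate(spec.inserts):
        for b in spec.inserts[i + 1 :]:
            d = np.hypot(a.center_mm[0] - b.center_mm[0], a.center_mm[1] - b.center_mm[1])
            if d < (a.diameter_mm + b.diameter_mm) / 2:
                raise ValueError(f"inserts {a.name!r} and {b.name!r} overlap")
    for ins in spec.inserts:
        cx, cy = ins.center_mm
        d = np.hypot(cx, cy) + ins.diameter_mm / 2
        if d > spec.body_diameter_mm / 2:
            raise ValueError(f"insert {ins.name!r} lies outside the phantom body")
        sel = (x - cx) ** 2 + (y - cy) ** 2 <= (ins.diameter_mm / 2) ** 2
        if np.any(plane[sel] == spec.central_label):
            raise ValueError(f"insert {ins.name!r} overlaps the central region")
        plane[sel] = ins.label
    return np.repeat(plane[:, :, None], spec.shape[2], axis=2)


def make_phantom_volume(
    spec: PhantomSpec, modality: str, seed: int
) -> tuple[Volume, np.ndarray]:
    """Render one phantom scan: compartment means plus modality noise.

    Identical ``spec`` + ``modality`` + ``seed`` give bit-identical output.
    """
    if modality not in spec.noise_sd_hu:
        raise ValueError(f"no noise SD configured for modality {modality!r}")
    mask = phantom_mask(spec)
    vol = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    vol[mask == spec.body_label] = spec.body_hu
    vol[mask == spec.central_label] = spec.body_hu
    for ins in spec.inserts:
        vol[mask == ins.label] = ins.mean_hu
    sd = spec.noise_sd_hu[modality]
    if sd > 0:
        rng = _rng(seed, _S_PHANTOM, 0 if modality == PLANNING_CT else 1)
        vol = vol + rng.normal(0.0, sd, size=spec.shape)
    fraction = 0 if modality == PLANNING_CT else 1
    volume = Volume(
        data=vol.astype(np.float32),
        spacing=spec.spacing_mm,
        modality=modality,
        fraction=fraction,
        patient_id="PHANTOM",
        scan_id=f"PHANTOM_{modality}_s{seed}",
    )
    return volume, mask


# ---------------------------------------------------------------------------
# patient anatomy

# pelvic geometry in mm, relative to the grid center (x: left-right,
# y: anterior-posterior with posterior positive, z: inferior-superior)
_FAT_RADII = (85.0, 80.0, 50.0)
# The two target regions are spaced so their interface shells stay disjoint:
# the 10-20 mm shell of one region must not touch the 0-10 mm drift shell of
# the other (surface gap > 30 mm), matching the per-region independence the
# interface analysis assumes.
_PROSTATE = ((0.0, 5.0, -28.0), (16.0, 16.0, 12.0))
_SEMVES = ((0.0, 5.0, 26.0), (14.0, 10.0, 8.0))
_RECTUM_CENTER_Y = 38.0
_RECTUM_OUTER, _RECTUM_INNER, _RECTUM_HALF_Z = 16.0, 11.0, 40.0
_MUSCLE_X = (55.0, 80.0)
_MUSCLE_Y = (10.0, 70.0)
_MUSCLE_HALF_Z = 45.0
_BONE_CENTERS = ((-60.0, -10.0, 5.0), (60.0, -10.0, 5.0))
_BONE_RADII = (14.0, 14.0, 20.0)

_REGION_GEOMETRY = {"prostate": _PROSTATE, "seminal_vesicles": _SEMVES}

_anatomy_cache: dict[tuple, tuple[np.ndarray, dict]] = {}


def _ellipsoid(x, y, z, center, radii):
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def anatomy_mask(spec: CohortSpec) -> np.ndarray:
    """Shared pelvic label mask for the cohort (geometry is fixed in mm)."""
    mask, _ = _anatomy(spec)
    return mask.copy()


def _anatomy(spec: CohortSpec) -> tuple[np.ndarray, dict]:
    key = (
        tuple(spec.shape),
        tuple(spec.spacing_mm),
        tuple(sorted((n, c.label) for n, c in spec.compartments.items())),
        spec.drift.shell_mm,
        tuple(spec.drift.regions),
    )
    if key in _anatomy_cache:
        return _anatomy_cache[key]
    labels = {n: c.label for n, c in spec.compartments.items()}
    xs, ys, zs = _grid_mm(spec.shape, spec.spacing_mm)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    mask = np.zeros(spec.shape, dtype=np.int32)
    body = _ellipsoid(x, y, z, (0, 0, 0), _FAT_RADII)
    mask[body] = labels["pelvic_fat"]
    if "gluteal_muscle" in labels:
        mus = (
            (np.abs(x) >= _MUSCLE_X[0])
            & (np.abs(x) <= _MUSCLE_X[1])
            & (y >= _MUSCLE_Y[0])
            & (y <= _MUSCLE_Y[1])
            & (np.abs(z) <= _MUSCLE_HALF_Z)
        )
        mask[body & mus] = labels["gluteal_muscle"]
    if "bone" in labels:
        for c in _BONE_CENTERS:
            mask[body & _ellipsoid(x, y, z, c, _BONE_RADII)] = labels["bone"]
    r_rect2 = x**2 + (y - _RECTUM_CENTER_Y) ** 2
    in_z = np.abs(z) <= _RECTUM_HALF_Z
    lumen = (r_rect2 <= _RECTUM_INNER**2) & in_z
    mask[body & lumen] = 0  # air-filled lumen, outside the body partition
    if "rectal_wall" in labels:
        wall = (r_rect2 <= _RECTUM_OUTER**2) & ~lumen & in_z
        mask[body & wall] = labels["rectal_wall"]
    for name in ("prostate", "seminal_vesicles"):
        if name in labels:
            c, r = _REGION_GEOMETRY[name]
            mask[_ellipsoid(x, y, z, c, r)] = labels[name]

    fat = mask == labels["pelvic_fat"]
    shells: dict[str, np.ndarray] = {}
    s_mm = spec.drift.shell_mm
    for region in spec.drift.regions:
        region_mask = mask == labels[region]
        if not region_mask.any():
            raise ValueError(f"region {region!r} is empty on this grid")
        dist = ndimage.distance_transform_edt(~region_mask, sampling=spec.spacing_mm)
        inner = fat & (dist > 0) & (dist <= s_mm)
        outer = fat & (dist > s_mm) & (dist <= 2 * s_mm)
        if not inner.any():
            raise ValueError(
                f"geometry leaves an empty 0-{s_mm:g} mm fat shell around {region!r}"
            )
        if not outer.any():
            raise ValueError(
                f"geometry leaves an empty {s_mm:g}-{2 * s_mm:g} mm fat shell around {region!r}"
            )
        shells[region] = inner
    _anatomy_cache[key] = (mask, shells)
    return _anatomy_cache[key]


def _compartment_jitter(spec: CohortSpec, pidx: int) -> dict[str, float]:
    rng = _rng(spec.seed, _S_JITTER, pidx)
    # fixed (sorted) order so the draw sequence is stable
    return {
        name: float(rng.normal(0.0, spec.compartments[name].jitter_sd_hu))
        for name in sorted(spec.compartments)
    }


def make_patient_volume(
    spec: CohortSpec, patient: str | int, fraction: int, seed: int | None = None
) -> tuple[Volume, np.ndarray]:
    """Render one patient scan at one fraction.

    Fraction 0 is the planning CT (planning noise SD); fractions >= 1 are
    CBCTs.  Per-patient compartment jitter is drawn once per patient from
    the master seed; the peri-target fat shell receives the drift mean
    shift ``slope * fraction`` plus, at fractions >= 1, an independent
    per-scan fluctuation.
    """
    if not 0 <= fraction <= spec.n_fractions:
        raise ValueError(f"fraction {fraction} outside 0..{spec.n_fractions}")
    seed = spec.seed if seed is None else seed
    pidx = _patient_index(patient)
    mask, shells = _anatomy(spec)
    jitter = _compartment_jitter(spec, pidx)

    vol = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    for name, comp in spec.compartments.items():
        vol[mask == comp.label] = comp.mean_hu + jitter[name]

    drift = spec.drift
    for ridx, region in enumerate(drift.regions):
        shift = drift.slope_hu_per_fraction * fraction
        if fraction >= 1 and drift.shell_sigma_hu > 0:
            shift += float(
                _rng(seed, _S_SHELL, pidx, fraction, ridx).normal(0.0, drift.shell_sigma_hu)
            )
        if shift != 0.0:
            vol[shells[region]] += shift

    modality = PLANNING_CT if fraction == 0 else CBCT
    sd = spec.noise_sd_hu[modality]
    if sd > 0:
        vol += _rng(seed, _S_VOXEL, pidx, fraction).normal(0.0, sd, size=spec.shape)

    pid = patient if isinstance(patient, str) else patient_id(pidx)
    volume = Volume(
        data=vol.astype(np.float32),
        spacing=spec.spacing_mm,
        modality=modality,
        fraction=fraction,
        patient_id=str(pid),
        scan_id=f"{pid}_fx{fraction}",
    )
    return volume, mask


# ---------------------------------------------------------------------------
# cohort


@dataclasses.dataclass
class ScanEntry:
    patient: str
    fraction: int
    volume: Volume
    mask: np.ndarray


@dataclasses.dataclass
class LongitudinalDataset:
    """All scans of a simulated cohort plus the true generator parameters."""

    spec: CohortSpec
    entries: list[ScanEntry]

    @property
    def truth(self) -> dict:
        return {
            "drift_slope_hu_per_fraction": self.spec.drift.slope_hu_per_fraction,
            "shell_sigma_hu": self.spec.drift.shell_sigma_hu,
            "noise_sd_hu": dict(self.spec.noise_sd_hu),
            "compartment_mean_hu": {
                n: c.mean_hu for n, c in self.spec.compartments.items()
            },
        }

    def patients(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.patient not in seen:
                seen.append(e.patient)
        return seen

    def scans_for(self, patient: str) -> list[ScanEntry]:
        return [e for e in self.entries if e.patient == patient]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "patient": e.patient,
                "fraction": e.fraction,
                "modality": e.volume.modality,
                "scan_id": e.volume.scan_id,
                "drift_slope_hu_per_fraction": self.spec.drift.slope_hu_per_fraction,
                "noise_sd_hu": self.spec.noise_sd_hu[e.volume.modality],
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> LongitudinalDataset:
    """Simulate the full cohort: n patients x (planning + k fractions)."""
    entries = []
    for p in range(1, spec.n_patients + 1):
        pid = patient_id(p)
        for f in range(0, spec.n_fractions + 1):
            volume, mask = make_patient_volume(spec, pid, f)
            entries.append(ScanEntry(patient=pid, fraction=f, volume=volume, mask=mask))
    return LongitudinalDataset(spec=spec, entries=entries)


# ---------------------------------------------------------------------------
# ratings and times


def simulate_ratings(spec: CohortSpec) -> pd.DataFrame:
    """Two-observer Likert ratings with assessment times, one row per
    observer x patient x scan x parameter.

    Latent score = observer intercept - decline x fraction + per-scan
    quality (shared across observers and parameters) + ordinal noise;
    rounded and clamped to 1..5.  Assessment time = base + increment x
    fraction + noise, floored at a positive minimum.
    """
    rat = spec.rating
    tim = spec.time
    kmax = spec.n_fractions
    for obs, intercept in rat.observer_intercepts.items():
        if intercept - rat.decline_per_fraction * kmax < 1:
            warnings.warn(
                f"observer {obs!r}: expected score at fraction {kmax} falls below 1; "
                "scores will clamp",
                stacklevel=2,
            )
    params = list(rat.parameters)
    observers = sorted(rat.observer_intercepts)
    rows = []
    for p in range(1, spec.n_patients + 1):
        pid = patient_id(p)
        for f in range(0, kmax + 1):
            q = (
                float(_rng(spec.seed, _S_SCANQ, p, f).normal(0.0, rat.scan_sigma))
                if rat.scan_sigma > 0
                else 0.0
            )
            scan = f"{pid}_fx{f}"
            modality = PLANNING_CT if f == 0 else CBCT
            for oidx, obs in enumerate(observers):
                rng = _rng(spec.seed, _S_RATING, p, f, oidx)
                eps = rng.normal(0.0, rat.noise_sd, size=len(params))
                tnoise = rng.normal(0.0, tim.noise_sd_s, size=len(params))
                latent = rat.observer_intercepts[obs] - rat.decline_per_fraction * f + q + eps
                scores = np.clip(np.rint(latent), 1, 5).astype(int)
                times = np.maximum(
                    tim.min_s, tim.base_s + tim.increment_s_per_fraction * f + tnoise
                )
                for param, sc, t in zip(params, scores, times):
                    rows.append(
                        {
                            "observer": obs,
                            "patient": pid,
                            "scan": scan,
                            "fraction": f,
                            "modality": modality,
                            "parameter": param,
                            "score": int(sc),
                            "time_s": float(t),
                        }
                    )
    return pd.DataFrame(rows)
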