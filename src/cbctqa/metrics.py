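"""ROI placement and the four scalar image-quality metrics.

Metrics follow the ROI-statistics conventions of CT/CBCT QA:

* ``SNR = (mean + 1000) / SD`` — the +1000 HU offset aligns HU with linear
  attenuation across scanners and applies *only* inside SNR;
* ``C = mean_signal - mean_background`` (HU);
* ``CNR = 2 (mean_s - mean_b)^2 / (SD_s^2 + SD_b^2)`` — a non-linear form
  chosen for sensitivity to low-contrast detectability differences;
* ``CV = SD / mean * 100`` (%).

Phantom ROIs are circles of fixed diameter placed on a set of axial
slices; per-slice mean/SD are averaged unweighted across slices.  Patient
reference ROIs (muscle/fat) and interface shells are pooled voxel sets.
The interface analysis builds three nested regions per target: ROI1 = the
peripheral rim of the target organ, ROI2 = fat within the proximal 1 cm,
ROI3 = fat 1-2 cm away, with distances Euclidean in mm (anisotropic
spacing honoured) and half-open shell intervals (lo, hi].
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import Volume


class DegenerateRoiError(ValueError):
    """An ROI whose statistics make a metric undefined (e.g. SD = 0)."""


@dataclasses.dataclass(frozen=True)
class RoiGeometry:
    """A placed region: circle-on-slices, mask-label, or distance-shell.

    For shells produced by :func:`build_interface_shells` the voxel
    selection is precomputed and cached on the object.
    """

    kind: str  # "circle" | "label" | "shell"
    center_mm: tuple[float, float] | None = None
    diameter_mm: float | None = None
    slices: tuple[int, ...] | None = None
    label: int | None = None
    shell_mm: tuple[float, float] | None = None
    name: str = ""
    selection: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "label", "shell"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle":
            if self.diameter_mm is None or self.diameter_mm <= 0:
                raise ValueError("circle ROI needs a positive diameter")
            if not self.slices:
                raise ValueError("circle ROI needs at least one slice index")
            if self.center_mm is None:
                raise ValueError("circle ROI needs an in-plane center (mm)")
        if self.kind == "shell":
            if self.shell_mm is None:
                raise ValueError("shell ROI needs (lo, hi) bounds in mm")
            lo, hi = self.shell_mm
            if not 0 <= lo < hi:
                raise ValueError(f"shell bounds must satisfy 0 <= lo < hi, got {self.shell_mm}")


@dataclasses.dataclass(frozen=True)
class RoiStats:
    """Summary of one ROI: mean HU, SD HU, voxel count, per-slice breakdown."""

    mean: float
    sd: float
    n: int
    per_slice: tuple[tuple[int, float, float, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("RoiStats requires at least one voxel")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


@dataclasses.dataclass(frozen=True)
class MetricSet:
    """The four quality metrics of one scan."""

    snr: float
    contrast: float
    cnr: float
    cv: float


@dataclasses.dataclass(frozen=True)
class InterfaceTriplet:
    """ROI1/ROI2/ROI3 statistics and the two delta values for one region
    at one fraction.  delta12 = mean(ROI1) - mean(ROI2); delta23 =
    mean(ROI2) - mean(ROI3), both HU."""

    region: str
    fraction: int
    roi1: RoiStats
    roi2: RoiStats
    roi3: RoiStats
    delta12: float
    delta23: float


def _mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def circle_roi(
    center_mm: tuple[float, float], diameter_mm: float, slices: tuple[int, ...], name: str = ""
) -> RoiGeometry:
    """Circular ROI of given diameter on a set of axial slices.

    ``center_mm`` is in the volume's physical frame (voxel index x spacing,
    voxel-center convention).
    """
    return RoiGeometry(
        kind="circle",
        center_mm=tuple(center_mm),
        diameter_mm=diameter_mm,
        slices=tuple(slices),
        name=name,
    )


def label_roi(label: int, name: str = "") -> RoiGeometry:
    return RoiGeometry(kind="label", label=label, name=name)


def extract_roi_stats(
    volume: Volume, geometry: RoiGeometry, mask: np.ndarray | None = None
) -> RoiStats:
    """Extract mean/SD/count for one ROI.

    Circles: voxels whose in-plane center distance to the ROI center is
    <= diameter/2, per slice; slice statistics are averaged unweighted.
    Label and shell ROIs: pooled over all selected voxels.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if geometry.kind == "circle":
        sx, sy = volume.spacing[0], volume.spacing[1]
        cx, cy = geometry.center_mm  # type: ignore[misc]
        xs = np.arange(data.shape[0]) * sx
        ys = np.arange(data.shape[1]) * sy
        dist2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
        disk = dist2 <= (geometry.diameter_mm / 2) ** 2  # type: ignore[operator]
        per_slice = []
        for k in geometry.slices:  # type: ignore[union-attr]
            if not 0 <= k < data.shape[2]:
                raise ValueError(f"slice {k} outside volume (nz={data.shape[2]})")
            vals = data[:, :, k][disk]
            if vals.size == 0:
                raise ValueError(f"circle ROI selects no voxels on slice {k}")
            m, s, n = _mean_sd(vals)
            per_slice.append((int(k), m, s, n))
        mean = float(np.mean([m for _, m, _, _ in per_slice]))
        sd = float(np.mean([s for _, _, s, _ in per_slice]))
        n = int(sum(n for _, _, _, n in per_slice))
        return RoiStats(mean=mean, sd=sd, n=n, per_slice=tuple(per_slice))

    if geometry.selection is not None:
        sel = geometry.selection
    elif geometry.kind == "label":
        if mask is None:
            raise ValueError("label ROI requires a mask")
        sel = np.asarray(mask) == geometry.label
    else:
        raise ValueError("shell ROI must be built with build_interface_shells")
    if sel.shape != data.shape:
        raise ValueError(f"selection shape {sel.shape} does not match volume {data.shape}")
    vals = data[sel]
    if vals.size == 0:
        raise ValueError(f"ROI {geometry.name or geometry.kind} selects no voxels")
    m, s, n = _mean_sd(vals)
    return RoiStats(mean=m, sd=s, n=n)


# ---------------------------------------------------------------------------
# the four metrics


def snr(signal: RoiStats) -> float:
    """Signal-to-noise ratio, (mean + 1000) / SD."""
    if signal.sd == 0:
        raise DegenerateRoiError("degenerate ROI: SD = 0, SNR undefined")
    return (signal.mean + 1000.0) / signal.sd


def contrast(signal: RoiStats, background: RoiStats) -> float:
    """Contrast, mean difference in HU."""
    return signal.mean - background.mean


def cnr(signal: RoiStats, background: RoiStats) -> float:
    """Non-linear contrast-to-noise ratio, 2 (dMean)^2 / (SD1^2 + SD2^2)."""
    denom = signal.sd**2 + background.sd**2
    if denom == 0:
        raise DegenerateRoiError("degenerate ROI pair: both SDs are 0, CNR undefined")
    return 2.0 * (signal.mean - background.mean) ** 2 / denom


def cv(signal: RoiStats, eps: float = 1e-6) -> float:
    """Coefficient of variation, SD / mean * 100 (%)."""
    if abs(signal.mean) <= eps:
        raise DegenerateRoiError("CV undefined near zero mean")
    return signal.sd / signal.mean * 100.0


def metric_set(
    volume: Volume,
    signal_geometry: RoiGeometry,
    background_geometry: RoiGeometry,
    mask: np.ndarray | None = None,
) -> MetricSet:
    """All four metrics from one extraction pass per ROI."""
    sig = extract_roi_stats(volume, signal_geometry, mask)
    bg = extract_roi_stats(volume, background_geometry, mask)
    return MetricSet(snr=snr(sig), contrast=contrast(sig, bg), cnr=cnr(sig, bg), cv=cv(sig))


# ---------------------------------------------------------------------------
# interface shells


def build_interface_shells(
    mask: np.ndarray,
    region_label: int,
    fat_label: int,
    spacing: tuple[float, float, float],
    rim_mm: float = 5.0,
    shell_bounds_mm: tuple[float, float] = (10.0, 20.0),
    region_name: str = "",
) -> tuple[RoiGeometry, RoiGeometry, RoiGeometry]:
    """Build the ROI1/ROI2/ROI3 geometry around one target region.

    ROI1: target voxels within ``rim_mm`` (inward) of the target boundary.
    ROI2: fat voxels with Euclidean distance-to-target in (0, lo] mm.
    ROI3: fat voxels with distance in (lo, hi] mm.
    The three selections are pairwise disjoint by construction.
    """
    mask = np.asarray(mask)
    region = mask == region_label
    fat = mask == fat_label
    if not region.any():
        raise ValueError(f"region label {region_label} absent from mask")
    if not fat.any():
        raise ValueError(f"fat label {fat_label} absent from mask")
    lo, hi = shell_bounds_mm
    if not 0 < lo < hi:
        raise ValueError("shell bounds must satisfy 0 < lo < hi")
    spacing = tuple(float(s) for s in spacing)

    inward = ndimage.distance_transform_edt(region, sampling=spacing)
    roi1_sel = region & (inward <= rim_mm)
    dist = ndimage.distance_transform_edt(~region, sampling=spacing)
    roi2_sel = fat & (dist > 0) & (dist <= lo)
    roi3_sel = fat & (dist > lo) & (dist <= hi)
    for nm, sel in (("ROI1", roi1_sel), ("ROI2", roi2_sel), ("ROI3", roi3_sel)):
        if not sel.any():
            raise ValueError(f"{nm} is empty for region {region_name or region_label}")

    def _geom(nm: str, sel: np.ndarray, bounds: tuple[float, float]) -> RoiGeometry:
        return RoiGeometry(
            kind="shell",
            label=region_label,
            shell_mm=bounds,
            name=f"{region_name or region_label}:{nm}",
            selection=sel,
        )

    return (
        _geom("ROI1", roi1_sel, (0.0, rim_mm)),
        _geom("ROI2", roi2_sel, (0.0, lo)),
        _geom("ROI3", roi3_sel, (lo, hi)),
    )


def interface_triplet(
    volume: Volume,
    shells: tuple[RoiGeometry, RoiGeometry, RoiGeometry],
    region: str,
    fraction: int,
) -> InterfaceTriplet:
    """ROI statistics and delta values for one region at one fraction."""
    s1, s2, s3 = (extract_roi_stats(volume, g) for g in shells)
    return InterfaceTriplet(
        region=region,
        fraction=fraction,
        roi1=s1,
        roi2=s2,
        roi3=s3,
        delta12=s1.mean - s2.mean,
        delta23=s2.mean - s3.mean,
    )
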