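"""Replicate simulation studies: calibration, power and recovery.

These are the Monte-Carlo experiments that validate the pipeline's
statistical behaviour: type-I error of the longitudinal Friedman test
under an iid null, recovery of the injected peri-target fat drift slope,
power and directionality of the interface battery, and phantom metric
recovery against the closed-form population values.

Problem sizes default to a reduced grid (48 x 48 x 24 voxels at 4 mm
in-plane / 4 mm slices) so hundreds of replicate cohorts run on one CPU
in minutes; the geometry and statistical structure are unchanged.
"""

from __future__ import annotations

import numpy as np

from . import metrics as mx
from . import stats as st
from . import synthetic as syn
from .config import CohortSpec, PhantomSpec


def small_cohort_spec(**overrides) -> CohortSpec:
    """The reduced-grid cohort used by replicate studies."""
    base = dict(shape=(48, 48, 24), spacing_mm=(4.0, 4.0, 4.0))
    base.update(overrides)
    return CohortSpec(**base)


def friedman_null_calibration(
    n_subjects: int = 26,
    n_conditions: int = 6,
    n_replicates: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Friedman rejection rate on iid Gaussian null matrices."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 901]))
    rejections = 0
    for _ in range(n_replicates):
        values = rng.standard_normal((n_subjects, n_conditions))
        m = st.RepeatedMeasuresMatrix(
            values=values,
            subjects=[str(i) for i in range(n_subjects)],
            conditions=[str(j) for j in range(n_conditions)],
        )
        if st.friedman(m).p < alpha:
            rejections += 1
    rate = rejections / n_replicates
    return {
        "rejection_rate": rate,
        "se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def drift_recovery_study(
    spec: CohortSpec | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    region: str = "prostate",
    rim_mm: float = 5.0,
    shell_bounds_mm: tuple[float, float] = (10.0, 20.0),
) -> dict:
    """Recovery of the injected ROI2 drift over replicate cohorts.

    Per replicate cohort: the least-squares slope of the ROI2 mean vs
    fraction (averaged over patients), the longitudinal Friedman p per
    ROI, and the sign of the Spearman correlation of each delta with
    fraction number.  Only fractional CBCT scans enter, matching the
    interface analysis.
    """
    if spec is None:
        spec = small_cohort_spec(drift={"slope_hu_per_fraction": 4.0})
    labels = {n: c.label for n, c in spec.compartments.items()}
    mask = syn.anatomy_mask(spec)
    shells = mx.build_interface_shells(
        mask,
        region_label=labels[region],
        fat_label=labels["pelvic_fat"],
        spacing=spec.spacing_mm,
        rim_mm=rim_mm,
        shell_bounds_mm=shell_bounds_mm,
        region_name=region,
    )
    sels = [g.selection for g in shells]
    fractions = np.arange(1, spec.n_fractions + 1)
    fc = fractions - fractions.mean()
    ssx = float((fc**2).sum())

    slopes = []
    reject = {"ROI1": 0, "ROI2": 0, "ROI3": 0}
    sp23_pos = sp12_neg = 0
    for rep in range(n_replicates):
        rspec = spec.model_copy(deep=True)
        rspec.seed = (seed + 7919 * (rep + 1)) & 0x7FFFFFFF
        # means[roi, patient, fraction]
        means = np.empty((3, rspec.n_patients, len(fractions)))
        for p in range(1, rspec.n_patients + 1):
            for j, f in enumerate(fractions):
                vol, _ = syn.make_patient_volume(rspec, p, int(f))
                data = np.asarray(vol.data, dtype=np.float64)
                for i, sel in enumerate(sels):
                    means[i, p - 1, j] = data[sel].mean()
        roi2 = means[1]
        slopes.append(float((roi2 * fc).sum(axis=1).mean() / ssx))
        for i, roi_name in enumerate(("ROI1", "ROI2", "ROI3")):
            m = st.RepeatedMeasuresMatrix(
                values=means[i],
                subjects=[str(p) for p in range(rspec.n_patients)],
                conditions=[f"fx{f}" for f in fractions],
            )
            if st.friedman(m).p < alpha:
                reject[roi_name] += 1
        frac_long = np.tile(fractions, rspec.n_patients)
        delta12 = (means[0] - means[1]).ravel()
        delta23 = (means[1] - means[2]).ravel()
        if st.spearman(frac_long, delta23).statistic > 0:
            sp23_pos += 1
        if st.spearman(frac_long, delta12).statistic < 0:
            sp12_neg += 1

    slopes_arr = np.asarray(slopes)
    return {
        "true_slope": spec.drift.slope_hu_per_fraction,
        "mean_recovered_slope": float(slopes_arr.mean()),
        "slope_se": float(slopes_arr.std(ddof=1) / np.sqrt(n_replicates)),
        "friedman_reject_rate": {k: v / n_replicates for k, v in reject.items()},
        "spearman_delta23_positive_rate": sp23_pos / n_replicates,
        "spearman_delta12_negative_rate": sp12_neg / n_replicates,
        "n_replicates": n_replicates,
        "n_patients": spec.n_patients,
    }


def phantom_metric_recovery(
    insert_mean_hu: float = 60.0,
    background_hu: float = 0.0,
    noise_sd_hu: float = 10.0,
    n_replicates: int = 100,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    roi_diameter_mm: float = 25.0,
) -> dict:
    """Monte-Carlo phantom metric estimates vs the closed-form values.

    With insert mean m, background b and common noise SD s the population
    values are SNR = (m + 1000)/s, C = m - b, CNR = 2 (m - b)^2 / (2 s^2),
    CV = s/m x 100.
    """
    if spec is None:
        spec = PhantomSpec()
    spec = spec.model_copy(deep=True)
    spec.body_hu = background_hu
    spec.inserts[0].mean_hu = insert_mean_hu
    spec.noise_sd_hu = {"CBCT": noise_sd_hu}
    nz = spec.shape[2]
    slices = (nz // 4, nz // 2, (3 * nz) // 4)
    ins = spec.inserts[0]
    nx, ny = spec.shape[0], spec.shape[1]
    sx, sy = spec.spacing_mm[0], spec.spacing_mm[1]
    sig_center = ((nx - 1) / 2 * sx + ins.center_mm[0], (ny - 1) / 2 * sy + ins.center_mm[1])
    bg_center = ((nx - 1) / 2 * sx, (ny - 1) / 2 * sy)

    est = {"snr": [], "contrast": [], "cnr": [], "cv": []}
    for rep in range(n_replicates):
        vol, _ = syn.make_phantom_volume(spec, "CBCT", seed=(seed + 3571 * (rep + 1)))
        sig = mx.extract_roi_stats(vol, mx.circle_roi(sig_center, roi_diameter_mm, slices))
        bg = mx.extract_roi_stats(vol, mx.circle_roi(bg_center, roi_diameter_mm, slices))
        est["snr"].append(mx.snr(sig))
        est["contrast"].append(mx.contrast(sig, bg))
        est["cnr"].append(mx.cnr(sig, bg))
        est["cv"].append(mx.cv(sig))

    m, b, s = insert_mean_hu, background_hu, noise_sd_hu
    expected = {
        "snr": (m + 1000.0) / s,
        "contrast": m - b,
        "cnr": 2 * (m - b) ** 2 / (2 * s**2),
        "cv": s / m * 100.0,
    }
    out = {}
    for k, vals in est.items():
        arr = np.asarray(vals)
        out[k] = {
            "estimate": float(arr.mean()),
            "mc_se": float(arr.std(ddof=1) / np.sqrt(n_replicates)),
            "expected": expected[k],
        }
    out["n_replicates"] = n_replicates
    return out
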