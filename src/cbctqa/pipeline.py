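"""End-to-end orchestration: simulate -> extract -> test -> report.

A full run produces a fixed run-directory layout::

    run_dir/
      config.yaml          resolved configuration (defaults filled)
      manifest.csv         one row per scan (patient, fraction, modality, ...)
      metrics/             tidy CSVs: phantom, patient, interface, ratings
      stats/               flat CSV of every statistical comparison
      report.json          the four report sections + run metadata

Every number in the report is recomputed from the CSVs' source data in the
same run, and the config hash + seed in the report make runs replayable.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import metrics as mx
from . import stats as st
from . import synthetic as syn
from .config import Config
from .io import CBCT, PLANNING_CT, config_hash, logger, write_table

SCHEMA_VERSION = "1"


def _phys_center(spec, center_mm):
    """Convert a grid-center-relative in-plane point to the physical frame."""
    nx, ny = spec.shape[0], spec.shape[1]
    sx, sy = spec.spacing_mm[0], spec.spacing_mm[1]
    return (
        (nx - 1) / 2.0 * sx + center_mm[0],
        (ny - 1) / 2.0 * sy + center_mm[1],
    )


def _protocol_slices(nz: int) -> tuple[int, int, int]:
    """Top/middle/low evaluation slices of the phantom protocol."""
    return (nz // 4, nz // 2, (3 * nz) // 4)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return None  # voxel selections never belong in a report
    return obj


def _result_rows(results, section: str):
    rows = []
    for r in results:
        rows.append(
            {
                "section": section,
                "method": r.method,
                "comparison": r.comparison,
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                "p_adj": r.p_adj,
                "n": r.n,
                "note": r.note,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# phantom QA


def run_phantom_qa(
    config: Config, seed: int | None = None, repeat_specs: list | None = None
) -> dict:
    """Phantom metrics per modality per repeat plus repeat-scan stability.

    Metrics use the three-slice circular-ROI protocol (signal on the
    liver-equivalent insert, background on the central uniform region).
    The repeat-stability Wilcoxon pairs per-slice metric values across all
    slices, Bonferroni-corrected over the four metrics; instability is
    flagged at adjusted p < alpha.

    ``repeat_specs`` optionally supplies one PhantomSpec per repeat (same
    geometry, possibly different noise), emulating a scanner whose state
    changed between the two time points.
    """
    seed = config.seed if seed is None else seed
    spec = config.phantom
    ana = config.analysis
    if ana.phantom_n_repeats < 2:
        raise ValueError("phantom QA needs >= 2 repeats per modality")
    if repeat_specs is not None and len(repeat_specs) != ana.phantom_n_repeats:
        raise ValueError("repeat_specs must match phantom_n_repeats")
    if not spec.inserts:
        raise ValueError("phantom QA needs at least one insert")
    insert = spec.inserts[0]
    nz = spec.shape[2]
    slices3 = _protocol_slices(nz)
    all_slices = tuple(range(nz))
    sig_center = _phys_center(spec, insert.center_mm)
    bg_center = _phys_center(spec, (0.0, 0.0))
    diam = ana.phantom_roi_diameter_mm

    rows, results, section_metrics = [], [], {}
    for midx, modality in enumerate(sorted(spec.noise_sd_hu)):
        per_slice_metrics = []  # repeat -> metric -> per-slice values
        section_metrics[modality] = {}
        for rep in range(ana.phantom_n_repeats):
            rep_spec = spec if repeat_specs is None else repeat_specs[rep]
            vol, _ = syn.make_phantom_volume(
                rep_spec, modality, seed=(seed * 1000 + midx * 10 + rep)
            )
            sig = mx.extract_roi_stats(vol, mx.circle_roi(sig_center, diam, slices3, "insert"))
            bg = mx.extract_roi_stats(vol, mx.circle_roi(bg_center, diam, slices3, "central"))
            ms = mx.MetricSet(
                snr=mx.snr(sig), contrast=mx.contrast(sig, bg), cnr=mx.cnr(sig, bg), cv=mx.cv(sig)
            )
            section_metrics[modality][f"t{rep + 1}"] = ms
            rows.append(
                {
                    "modality": modality,
                    "repeat": rep + 1,
                    "snr": ms.snr,
                    "contrast_hu": ms.contrast,
                    "cnr": ms.cnr,
                    "cv_pct": ms.cv,
                    "signal_mean_hu": sig.mean,
                    "signal_sd_hu": sig.sd,
                    "background_mean_hu": bg.mean,
                    "background_sd_hu": bg.sd,
                }
            )
            # per-slice metric values across the whole insert for stability
            sig_all = mx.extract_roi_stats(vol, mx.circle_roi(sig_center, diam, all_slices))
            bg_all = mx.extract_roi_stats(vol, mx.circle_roi(bg_center, diam, all_slices))
            per_k = {"snr": [], "contrast": [], "cnr": [], "cv": []}
            for (k, m1, s1, _), (_, m2, s2, _) in zip(sig_all.per_slice, bg_all.per_slice):
                rs1 = mx.RoiStats(mean=m1, sd=s1, n=1)
                rs2 = mx.RoiStats(mean=m2, sd=s2, n=1)
                per_k["snr"].append(mx.snr(rs1))
                per_k["contrast"].append(mx.contrast(rs1, rs2))
                per_k["cnr"].append(mx.cnr(rs1, rs2))
                per_k["cv"].append(mx.cv(rs1))
            per_slice_metrics.append(per_k)

        unstable = []
        for metric in ("snr", "contrast", "cnr", "cv"):
            res = st.wilcoxon_signed_rank(
                per_slice_metrics[0][metric], per_slice_metrics[1][metric]
            )
            res = dataclasses.replace(
                res,
                p_adj=min(1.0, res.p * 4),
                comparison=f"{modality} {metric}: t1 vs t2",
                note=(res.note + "; family size 4").lstrip("; "),
            )
            results.append(res)
            if res.p_adj is not None and res.p_adj < ana.alpha:
                unstable.append(metric)
        section_metrics[modality]["unstable_metrics"] = unstable

    return {
        "metrics": section_metrics,
        "tests": results,
        "table": pd.DataFrame(rows),
        "stable": all(not section_metrics[m]["unstable_metrics"] for m in section_metrics),
    }


# ---------------------------------------------------------------------------
# patient QA


def _reference_fat(mask: np.ndarray, spec, min_mm: float) -> np.ndarray:
    """Fat voxels at least ``min_mm`` from every drift target region."""
    labels = {n: c.label for n, c in spec.compartments.items()}
    sel = mask == labels["pelvic_fat"]
    for region in spec.drift.regions:
        dist = ndimage.distance_transform_edt(mask != labels[region], sampling=spec.spacing_mm)
        sel &= dist > min_mm
    if not sel.any():
        raise ValueError("reference fat ROI is empty; lower reference_fat_min_mm")
    return sel


def run_patient_qa(config: Config, dataset: syn.LongitudinalDataset | None = None) -> dict:
    """Per-scan muscle/fat quality metrics and their longitudinal tests.

    Signal ROI: the gluteal-muscle compartment (pooled); background ROI:
    pelvic fat remote from both targets (so the reference is untouched by
    the injected interface drift).  Friedman across pCT + fractions per
    metric, with Bonferroni-adjusted post-hoc per the configured mode.
    """
    spec = config.cohort
    if dataset is None:
        dataset = syn.simulate_cohort(spec)
    labels = {n: c.label for n, c in spec.compartments.items()}
    conditions = ["pCT"] + [f"fx{f}" for f in range(1, spec.n_fractions + 1)]

    rows = []
    ref_cache: dict[int, np.ndarray] = {}
    for patient in dataset.patients():
        scans = dataset.scans_for(patient)
        mask = scans[0].mask
        key = id(mask)
        if key not in ref_cache:
            ref_cache[key] = _reference_fat(mask, spec, config.analysis.reference_fat_min_mm)
        fat_sel = ref_cache[key]
        fat_geom = mx.RoiGeometry(kind="shell", shell_mm=(0.0, 1.0), name="reference_fat",
                                  selection=fat_sel)
        for entry in scans:
            sig = mx.extract_roi_stats(
                entry.volume, mx.label_roi(labels["gluteal_muscle"], "muscle"), entry.mask
            )
            bg = mx.extract_roi_stats(entry.volume, fat_geom)
            rows.append(
                {
                    "patient": patient,
                    "fraction": entry.fraction,
                    "condition": conditions[entry.fraction],
                    "modality": entry.volume.modality,
                    "snr": mx.snr(sig),
                    "contrast_hu": mx.contrast(sig, bg),
                    "cnr": mx.cnr(sig, bg),
                    "cv_pct": mx.cv(sig),
                }
            )
    table = pd.DataFrame(rows)
    if table["patient"].nunique() < 2:
        raise ValueError("patient QA needs >= 2 patients")

    baseline = "pCT" if config.analysis.posthoc_baseline == "pct" else None
    tests, posthoc = [], []
    for metric in ("snr", "contrast_hu", "cnr", "cv_pct"):
        m = st.RepeatedMeasuresMatrix.from_long(
            table, "patient", "condition", metric, condition_order=conditions
        )
        fr = st.friedman(m)
        tests.append(dataclasses.replace(fr, comparison=f"{metric}: " + fr.comparison))
        for r in st.posthoc_pairwise(m, baseline=baseline):
            posthoc.append(dataclasses.replace(r, comparison=f"{metric}: " + r.comparison))

    summary = (
        table.groupby("condition", sort=False)[["snr", "contrast_hu", "cnr", "cv_pct"]]
        .agg(["mean", "std"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    return {
        "table": table,
        "summary": summary.reset_index(),
        "friedman": tests,
        "posthoc": posthoc,
        "posthoc_mode": "baseline pCT" if baseline else "all pairs",
    }


# ---------------------------------------------------------------------------
# interface analysis


def run_interface_analysis(config: Config, dataset: syn.LongitudinalDataset | None = None) -> dict:
    """The three-ROI target-interface attenuation battery on fractional CBCT.

    Per patient x fraction x region: ROI1/ROI2/ROI3 statistics and the two
    delta values; then, per region, within-fraction ROI comparisons,
    longitudinal Friedman per ROI across fractions, and Spearman
    correlation of each delta with fraction number.
    """
    spec = config.cohort
    if dataset is None:
        dataset = syn.simulate_cohort(spec)
    ana = config.analysis
    labels = {n: c.label for n, c in spec.compartments.items()}
    fractions = list(range(1, spec.n_fractions + 1))

    rows = []
    shell_cache: dict[tuple[int, str], tuple] = {}
    for patient in dataset.patients():
        scans = dataset.scans_for(patient)
        mask = scans[0].mask
        for region in spec.drift.regions:
            key = (id(mask), region)
            if key not in shell_cache:
                shell_cache[key] = mx.build_interface_shells(
                    mask,
                    region_label=labels[region],
                    fat_label=labels["pelvic_fat"],
                    spacing=spec.spacing_mm,
                    rim_mm=ana.roi1_rim_mm,
                    shell_bounds_mm=ana.shell_bounds_mm,
                    region_name=region,
                )
            shells = shell_cache[key]
            for entry in scans:
                if entry.fraction == 0:
                    continue  # interface analysis runs on fractional CBCT only
                trip = mx.interface_triplet(entry.volume, shells, region, entry.fraction)
                for roi_name, rs in (("ROI1", trip.roi1), ("ROI2", trip.roi2), ("ROI3", trip.roi3)):
                    rows.append(
                        {
                            "patient": patient,
                            "fraction": entry.fraction,
                            "region": region,
                            "roi": roi_name,
                            "mean_hu": rs.mean,
                            "sd_hu": rs.sd,
                            "n_voxels": rs.n,
                            "delta12_hu": trip.delta12,
                            "delta23_hu": trip.delta23,
                        }
                    )
    table = pd.DataFrame(rows)

    sections = {}
    for region in spec.drift.regions:
        sub = table[table["region"] == region]
        wide = sub.pivot_table(index=["patient", "fraction"], columns="roi", values="mean_hu")

        # within-fraction ROI-vs-ROI comparisons (family: all pairs x fractions)
        pairs = [("ROI1", "ROI2"), ("ROI1", "ROI3"), ("ROI2", "ROI3")]
        m_family = len(pairs) * len(fractions)
        within = []
        for f in fractions:
            at_f = wide.xs(f, level="fraction")
            for a, b in pairs:
                r = st.wilcoxon_signed_rank(at_f[a], at_f[b])
                within.append(
                    dataclasses.replace(
                        r,
                        p_adj=min(1.0, r.p * m_family),
                        comparison=f"{region} fx{f}: {a} vs {b}",
                        note=(r.note + f"; family size {m_family}").lstrip("; "),
                    )
                )

        # longitudinal Friedman per ROI across fractions, post-hoc all pairs
        longitudinal, long_posthoc = [], []
        for roi_name in ("ROI1", "ROI2", "ROI3"):
            roi_sub = sub[sub["roi"] == roi_name]
            m = st.RepeatedMeasuresMatrix.from_long(
                roi_sub, "patient", "fraction", "mean_hu", condition_order=fractions
            )
            fr = st.friedman(m)
            longitudinal.append(
                dataclasses.replace(fr, comparison=f"{region} {roi_name}: " + fr.comparison)
            )
            for r in st.posthoc_pairwise(m):
                long_posthoc.append(
                    dataclasses.replace(r, comparison=f"{region} {roi_name}: fx" + r.comparison)
                )

        # delta-vs-fraction correlations, pooled over patients
        deltas = sub[sub["roi"] == "ROI2"]
        sp12 = st.spearman(deltas["fraction"], deltas["delta12_hu"])
        sp23 = st.spearman(deltas["fraction"], deltas["delta23_hu"])
        sp12 = dataclasses.replace(sp12, comparison=f"{region}: delta12 vs fraction")
        sp23 = dataclasses.replace(sp23, comparison=f"{region}: delta23 vs fraction")

        sections[region] = {
            "within_fraction": within,
            "longitudinal_friedman": longitudinal,
            "longitudinal_posthoc": long_posthoc,
            "delta_correlations": [sp12, sp23],
        }
    return {"table": table, "regions": sections}


# ---------------------------------------------------------------------------
# agreement analysis


def run_agreement_analysis(config: Config, ratings: pd.DataFrame | None = None) -> dict:
    """Inter-observer agreement, observer comparison and time trends.

    ICC(3,k) is computed both pooled over all (patient, scan, parameter)
    rows and per parameter group / per parameter (the pooling convention
    is reported alongside).  Observer score difference: Wilcoxon
    signed-rank on paired rows.  Per observer: Friedman of the mean score
    across scans and Spearman of mean assessment time vs fraction number.
    """
    spec = config.cohort
    if ratings is None:
        ratings = syn.simulate_ratings(spec)
    if ratings.empty:
        raise ValueError("ratings table is empty")
    observers = sorted(ratings["observer"].unique())
    if len(observers) < 2:
        raise ValueError("agreement analysis needs >= 2 observers")
    conditions = ["pCT"] + [f"fx{f}" for f in range(1, spec.n_fractions + 1)]

    wide = ratings.pivot_table(
        index=["patient", "scan", "parameter"], columns="observer", values="score"
    )[observers].dropna()

    icc_pooled = st.icc_average_fixed(wide.to_numpy())
    icc_by_group = {}
    for group, params in spec.rating.parameter_groups.items():
        g = wide[wide.index.get_level_values("parameter").isin(params)]
        icc_by_group[group] = st.icc_average_fixed(g.to_numpy())
    icc_by_parameter = {}
    for param in ratings["parameter"].unique():
        g = wide[wide.index.get_level_values("parameter") == param]
        icc_by_parameter[param] = st.icc_average_fixed(g.to_numpy())

    obs_test = st.wilcoxon_signed_rank(wide[observers[0]], wide[observers[1]])
    obs_test = dataclasses.replace(
        obs_test, comparison=f"scores {observers[0]} vs {observers[1]}"
    )
    obs_summary = {
        o: {
            "mean": float(ratings.loc[ratings["observer"] == o, "score"].mean()),
            "sd": float(ratings.loc[ratings["observer"] == o, "score"].std()),
        }
        for o in observers
    }

    rating_trends, time_trends = [], []
    for o in observers:
        sub = ratings[ratings["observer"] == o].copy()
        sub["condition"] = sub["fraction"].map(dict(enumerate(conditions)))
        per_scan = sub.groupby(["patient", "condition"], sort=False)["score"].mean().reset_index()
        m = st.RepeatedMeasuresMatrix.from_long(
            per_scan, "patient", "condition", "score", condition_order=conditions
        )
        fr = st.friedman(m)
        rating_trends.append(
            dataclasses.replace(fr, comparison=f"{o} mean rating: " + fr.comparison)
        )
        fx = sub[sub["fraction"] >= 1]
        mean_t = fx.groupby("fraction")["time_s"].mean()
        sp = st.spearman(mean_t.index.to_numpy(), mean_t.to_numpy())
        time_trends.append(
            dataclasses.replace(sp, comparison=f"{o}: mean assessment time vs fraction")
        )

    return {
        "icc_pooled": icc_pooled,
        "icc_by_group": icc_by_group,
        "icc_by_parameter": icc_by_parameter,
        "observer_test": obs_test,
        "observer_summary": obs_summary,
        "rating_trends": rating_trends,
        "time_trends": time_trends,
        "ratings": ratings,
    }


# ---------------------------------------------------------------------------
# full run


def full_run(config: Config, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run all four analyses, write the run directory, return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.model_copy(deep=True)
        config.seed = seed
        config.cohort.seed = seed
    cfg_dict = config.model_dump(mode="json")
    chash = config_hash(cfg_dict)
    logger.info("full run: config hash %s, seed %d", chash, config.seed)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    dataset = syn.simulate_cohort(config.cohort)
    write_table(dataset.manifest(), out / "manifest.csv")
    ratings = syn.simulate_ratings(config.cohort)
    write_table(ratings, out / "metrics" / "ratings.csv")

    phantom = run_phantom_qa(config)
    patient = run_patient_qa(config, dataset)
    interface = run_interface_analysis(config, dataset)
    agreement = run_agreement_analysis(config, ratings)

    write_table(phantom["table"], out / "metrics" / "phantom_metrics.csv")
    write_table(patient["table"], out / "metrics" / "patient_metrics.csv")
    write_table(interface["table"], out / "metrics" / "interface_rois.csv")

    stat_rows = _result_rows(phantom["tests"], "phantom")
    stat_rows += _result_rows(patient["friedman"] + patient["posthoc"], "patient_qa")
    for region, sec in interface["regions"].items():
        stat_rows += _result_rows(
            sec["within_fraction"] + sec["longitudinal_friedman"]
            + sec["longitudinal_posthoc"] + sec["delta_correlations"],
            f"interface:{region}",
        )
    stat_rows += _result_rows(
        [agreement["observer_test"]] + agreement["rating_trends"] + agreement["time_trends"],
        "agreement",
    )
    write_table(pd.DataFrame(stat_rows), out / "stats" / "comparisons.csv")

    report = {
        "meta": {
            "schema_version": SCHEMA_VERSION,
            "config_hash": chash,
            "seed": config.seed,
            "alpha": config.analysis.alpha,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        "phantom": {
            "metrics": _jsonify(phantom["metrics"]),
            "tests": _jsonify(phantom["tests"]),
            "stable": phantom["stable"],
        },
        "patient": {
            "summary": _jsonify(patient["summary"].to_dict(orient="records")),
            "friedman": _jsonify(patient["friedman"]),
            "posthoc": _jsonify(patient["posthoc"]),
            "posthoc_mode": patient["posthoc_mode"],
        },
        "interface": {
            region: _jsonify(sec) for region, sec in interface["regions"].items()
        },
        "agreement": {
            "icc_pooled": _jsonify(agreement["icc_pooled"]),
            "icc_by_group": _jsonify(agreement["icc_by_group"]),
            "icc_by_parameter": _jsonify(agreement["icc_by_parameter"]),
            "observer_test": _jsonify(agreement["observer_test"]),
            "observer_summary": agreement["observer_summary"],
            "rating_trends": _jsonify(agreement["rating_trends"]),
            "time_trends": _jsonify(agreement["time_trends"]),
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def load_report(run_dir: str | Path) -> dict:
    path = Path(run_dir) / "report.json"
    if not path.exists():
        raise FileNotFoundError(f"no report.json in {run_dir}; run the pipeline first")
    with open(path) as fh:
        return json.load(fh)
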