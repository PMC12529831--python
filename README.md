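# cbctqa

Quantitative image-quality and tissue-interface QA for longitudinal
CT/CBCT imaging in adaptive radiotherapy.

Modern ring-gantry linacs re-plan treatment on the cone-beam CT (CBCT) of
the day. Whether that is safe hinges on two questions a physics/QA team
has to answer with numbers: *does CBCT image quality stay stable over the
treatment course?* and *does the tissue around the target change in a way
that erodes the visibility of its border?* `cbctqa` implements the ROI
metrics, the interface-shell analysis and the nonparametric statistical
battery used to answer both, together with a synthetic phantom/cohort
generator so every part of the pipeline is testable end to end without
patient data.

## What it computes

**ROI quality metrics.** For a signal ROI (phantom: liver-equivalent
insert, circular 2.5 cm ROI on three axial slices; patient: gluteal
muscle) and a background ROI (phantom: uniform central region; patient:
remote pelvic fat):

```
SNR = (mean_s + 1000) / SD_s          C   = mean_s − mean_b        [HU]
CNR = 2 (mean_s − mean_b)² / (SD_s² + SD_b²)
CV  = SD_s / mean_s × 100             [%]
```

The +1000 HU offset (aligning HU with linear attenuation across scanners)
applies only inside SNR. The CNR is the non-linear form, chosen for
sensitivity to low-contrast detectability differences.

**Interface analysis.** Around each target region (prostate, seminal
vesicles) three nested ROIs are built from the label mask with Euclidean
distances in mm: ROI1 = the peripheral 5 mm rim of the target, ROI2 = fat
within (0, 10] mm of the target surface, ROI3 = fat within (10, 20] mm.
Delta values `Δ12 = mean(ROI1) − mean(ROI2)` and `Δ23 = mean(ROI2) −
mean(ROI3)` are tracked against fraction number. Rising mean HU in ROI2
with stable ROI1/ROI3 is the signature of treatment-induced peri-target
tissue change.

**Statistics.** Friedman's test across timepoints (tie-corrected
chi-square), pairwise Wilcoxon signed-rank post-hoc with Bonferroni
adjustment (baseline-vs-planning-CT or all pairs), Wilcoxon signed-rank
(exact null enumeration for n ≤ 25 without ties), Spearman rank
correlation (exact permutation p for n ≤ 9), and the two-way
fixed-raters average-measures intraclass correlation ICC(3,k) with the
conventional bands (<0.50 poor, 0.50–0.75 moderate, 0.75–0.90 good,
≥0.90 excellent). α = 0.05, two-sided, throughout.

**Synthetic study.** The generator emulates the structure such a study
produces: an electron-density phantom (liver insert +60 HU, water body,
modality-specific noise), a 26-patient cohort with one planning CT plus
five fractional CBCTs rendered as simple pelvic solids, an injectable
linear HU drift confined to the 0–10 mm peri-target fat shell, and two
observers' 5-point Likert ratings with per-fraction decline and rising
assessment times.

## Worked example

```python
from cbctqa.config import Config
from cbctqa import pipeline

report = pipeline.full_run(Config(), "run", seed=1)

phantom = report["phantom"]["metrics"]["planning-CT"]["t1"]
print(f"SNR={phantom['snr']:.1f}  C={phantom['contrast']:.1f} HU  "
      f"CNR={phantom['cnr']:.1f}  CV={phantom['cv']:.1f} %")
```

prints, for the default configuration:

```
phantom planning-CT t1: SNR=104.4  C=60.5 HU  CNR=35.8  CV=16.9 %
phantom CBCT        t1: SNR=57.7   C=59.2 HU  CNR=10.5  CV=30.9 %
prostate ROI2 longitudinal Friedman: chi2=26.5, p=2.5e-05
prostate: delta12 vs fraction: rho=-0.32, p=0.00022
prostate: delta23 vs fraction: rho=0.39, p=3.7e-06
pooled inter-observer ICC(3,k) = 0.65 (moderate)
observer means: {'R1': 4.22, 'R2': 3.95}
```

Reading it: the planning CT has roughly double the SNR of the CBCT
(noise 10 vs 18 HU) at identical contrast — image quality differs between
modalities but, as the per-fraction tables in the run directory show,
stays stable across the treatment course. The fat shell directly at the
prostate border (ROI2) gains HU fraction by fraction (Friedman
p ≈ 2×10⁻⁵) while the target rim and the remote fat do not, so Δ23 rises
(ρ ≈ +0.4) and Δ12 falls (ρ ≈ −0.3): the organ–fat interface blurs as
treatment proceeds. The two simulated observers agree moderately
(ICC 0.65) and differ systematically in their mean rating.

The same pipeline runs from the shell:

```sh
cbctqa full-run --seed 1 --out-dir run      # all four analyses + report.json
cbctqa report run                           # human-readable summary
cbctqa simulate-cohort --out-dir data       # NIfTI volumes + manifest + ratings
```

Every reported number is traceable to a CSV under `run/metrics/` and
`run/stats/`, and `report.json` carries the config hash and seed that
replay the run.

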