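import numpy as np
import pytest

from cbctqa import stats as st
from cbctqa import synthetic as syn
from cbctqa.config import CohortSpec, InsertSpec, PhantomSpec

from conftest import quiet_cohort


class TestPhantom:
    def test_zero_noise_insert_exact(self, small_phantom):
        spec = small_phantom.model_copy(deep=True)
        spec.noise_sd_hu = {"CBCT": 0.0}
        vol, mask = syn.make_phantom_volume(spec, "CBCT", seed=0)
        insert = spec.inserts[0]
        assert np.all(vol.data[mask == insert.label] == insert.mean_hu)
        assert np.all(vol.data[mask == spec.central_label] == spec.body_hu)

    def test_noisy_insert_mean_within_standard_error(self):
        spec = PhantomSpec()  # full-resolution grid: insert holds >= 10^4 voxels
        vol, mask = syn.make_phantom_volume(spec, "CBCT", seed=3)
        insert = spec.inserts[0]
        vals = vol.data[mask == insert.label]
        assert vals.size >= 10_000
        sd = spec.noise_sd_hu["CBCT"]
        se = sd / np.sqrt(vals.size)
        assert abs(vals.mean() - insert.mean_hu) < 4 * se

    def test_determinism_and_seed_sensitivity(self, small_phantom):
        a1, _ = syn.make_phantom_volume(small_phantom, "CBCT", seed=5)
        a2, _ = syn.make_phantom_volume(small_phantom, "CBCT", seed=5)
        b, _ = syn.make_phantom_volume(small_phantom, "CBCT", seed=6)
        assert np.array_equal(a1.data, a2.data)
        assert not np.array_equal(a1.data, b.data)

    def test_overlapping_inserts_error_names_pair(self):
        spec = PhantomSpec(
            inserts=[
                InsertSpec(name="liver", center_mm=(30.0, 0.0), label=3),
                InsertSpec(name="bone", center_mm=(40.0, 10.0), label=4),
            ]
        )
        with pytest.raises(ValueError, match="liver.*bone"):
            syn.make_phantom_volume(spec, "CBCT", seed=0)

    def test_insert_outside_body_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            PhantomSpec(inserts=[InsertSpec(center_mm=(55.0, 0.0), diameter_mm=30.0)])


class TestPatientVolume:
    def test_zero_noise_compartments_exact(self):
        spec = quiet_cohort()
        vol, mask = syn.make_patient_volume(spec, "P01", 0)
        for name, comp in spec.compartments.items():
            sel = mask == comp.label
            if name == "pelvic_fat":
                continue  # fat holds the drift shells; checked separately
            assert np.all(vol.data[sel] == np.float32(comp.mean_hu)), name

    def test_null_drift_keeps_shell_mean_constant(self):
        spec = quiet_cohort()
        means = []
        _, mask = syn.make_patient_volume(spec, "P01", 0)
        from cbctqa.metrics import build_interface_shells

        shells = build_interface_shells(mask, 3, 1, spec.spacing_mm)
        for f in range(0, spec.n_fractions + 1):
            vol, _ = syn.make_patient_volume(spec, "P01", f)
            means.append(float(vol.data[shells[1].selection].mean()))
        assert np.allclose(means, means[0])

    def test_drift_slope_arithmetic_zero_noise(self):
        # +4 HU/fraction: shell mean at fx5 exceeds fx1 by exactly 16 HU
        spec = quiet_cohort(drift={"slope_hu_per_fraction": 4.0, "shell_sigma_hu": 0.0})
        from cbctqa.metrics import build_interface_shells

        _, mask = syn.make_patient_volume(spec, "P01", 0)
        shells = build_interface_shells(mask, 3, 1, spec.spacing_mm)
        sel = shells[1].selection
        v1, _ = syn.make_patient_volume(spec, "P01", 1)
        v5, _ = syn.make_patient_volume(spec, "P01", 5)
        assert float(v5.data[sel].mean()) - float(v1.data[sel].mean()) == pytest.approx(
            16.0, abs=1e-3
        )

    def test_drift_confined_to_inner_shell(self):
        spec = quiet_cohort(drift={"slope_hu_per_fraction": 4.0, "shell_sigma_hu": 0.0})
        from cbctqa.metrics import build_interface_shells

        _, mask = syn.make_patient_volume(spec, "P01", 0)
        shells = build_interface_shells(mask, 3, 1, spec.spacing_mm)
        v0, _ = syn.make_patient_volume(spec, "P01", 0)
        v5, _ = syn.make_patient_volume(spec, "P01", 5)
        assert np.all(v5.data[shells[0].selection] == v0.data[shells[0].selection])  # ROI1
        assert np.all(v5.data[shells[2].selection] == v0.data[shells[2].selection])  # ROI3

    def test_mask_partitions_body(self, small_cohort):
        mask = syn.anatomy_mask(small_cohort)
        labels = sorted(c.label for c in small_cohort.compartments.values())
        present = sorted(set(np.unique(mask)) - {0})
        assert present == labels

    def test_adding_patients_preserves_existing(self, small_cohort):
        bigger = small_cohort.model_copy(deep=True)
        bigger.n_patients = small_cohort.n_patients + 2
        v1, _ = syn.make_patient_volume(small_cohort, "P02", 3)
        v2, _ = syn.make_patient_volume(bigger, "P02", 3)
        assert np.array_equal(v1.data, v2.data)

    def test_fraction_out_of_range(self, small_cohort):
        with pytest.raises(ValueError, match="fraction"):
            syn.make_patient_volume(small_cohort, "P01", 9)

    def test_modality_assignment(self, small_cohort):
        v0, _ = syn.make_patient_volume(small_cohort, "P01", 0)
        v1, _ = syn.make_patient_volume(small_cohort, "P01", 1)
        assert v0.modality == "planning-CT"
        assert v1.modality == "CBCT"


class TestCohort:
    def test_scan_count(self):
        spec = quiet_cohort(n_patients=2)
        ds = syn.simulate_cohort(spec)
        assert len(ds.entries) == 2 * (spec.n_fractions + 1)

    def test_manifest_reproducible(self, small_cohort):
        m1 = syn.simulate_cohort(small_cohort).manifest()
        m2 = syn.simulate_cohort(small_cohort).manifest()
        assert m1.to_csv(index=False) == m2.to_csv(index=False)

    def test_truth_records_generator_parameters(self, small_cohort):
        ds = syn.simulate_cohort(small_cohort)
        assert ds.truth["drift_slope_hu_per_fraction"] == small_cohort.drift.slope_hu_per_fraction
        assert ds.truth["noise_sd_hu"]["CBCT"] == small_cohort.noise_sd_hu["CBCT"]


class TestRatings:
    def test_zero_noise_scores_exact(self):
        spec = quiet_cohort()
        spec.rating.observer_intercepts = {"R1": 4.0}
        spec.rating.decline_per_fraction = 0.0
        spec.rating.noise_sd = 0.0
        spec.rating.scan_sigma = 0.0
        df = syn.simulate_ratings(spec)
        assert set(df["score"]) == {4}

    def test_intercept_recovery_monte_carlo(self):
        spec = quiet_cohort(n_patients=26)
        spec.rating.observer_intercepts = {"R1": 4.3, "R2": 4.0}
        spec.rating.decline_per_fraction = 0.0
        spec.rating.noise_sd = 0.7
        spec.rating.scan_sigma = 0.0
        df = syn.simulate_ratings(spec)
        for obs, mu in (("R1", 4.3), ("R2", 4.0)):
            scores = df.loc[df["observer"] == obs, "score"]
            se = scores.std() / np.sqrt(len(scores))
            # clamping at 5 pulls the observed mean slightly below the latent
            # intercept, so allow that shift plus Monte-Carlo error
            assert scores.mean() == pytest.approx(mu, abs=0.15 + 3 * se)

    def test_monotone_time_gives_perfect_spearman(self):
        spec = quiet_cohort()
        spec.time.increment_s_per_fraction = 20.0
        spec.time.noise_sd_s = 0.0
        df = syn.simulate_ratings(spec)
        mean_t = df[df["fraction"] >= 1].groupby("fraction")["time_s"].mean()
        res = st.spearman(mean_t.index.to_numpy(), mean_t.to_numpy())
        assert res.statistic == pytest.approx(1.0)

    def test_excessive_decline_warns_and_clamps(self):
        spec = quiet_cohort()
        spec.rating.observer_intercepts = {"R1": 2.0}
        spec.rating.decline_per_fraction = 0.5
        with pytest.warns(UserWarning, match="clamp"):
            df = syn.simulate_ratings(spec)
        assert df["score"].between(1, 5).all()

    def test_reproducible_from_seed(self, small_cohort):
        d1 = syn.simulate_ratings(small_cohort)
        d2 = syn.simulate_ratings(small_cohort)
        assert d1.equals(d2)
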