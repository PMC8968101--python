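"""Generators: kinetics courses, MOLLI signals, phantoms, histology, cohorts."""

import numpy as np
import pytest

from myoecv.relaxometry import fit_molli
from myoecv.synthetic import (
    AcquisitionSchedule,
    KineticsParams,
    LABELS,
    default_schedule,
    load_field,
    render_histology_field,
    render_t1_phantom,
    save_field,
    simulate_cohort,
    simulate_molli_signal,
    simulate_r1_course,
)


class TestSchedule:
    def test_default_schedule_shape(self):
        s = default_schedule()
        t = np.array(s.times_min)
        assert t[0] == 0 and t[-1] == 60
        gaps = np.diff(t[1:])
        assert np.all(np.diff(gaps) >= 0)  # gaps grow 0.5 -> 5 min
        assert gaps[0] == 0.5 and gaps[-1] == 5

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule(times_min=(1, 2, 3))  # no pre-contrast anchor
        with pytest.raises(ValueError):
            AcquisitionSchedule(times_min=(0, 2, 1))


class TestKinetics:
    def test_native_values_at_t0(self):
        p = KineticsParams()
        course = simulate_r1_course(p, default_schedule())
        assert course["r1_blood"][0] == p.r1_blood_native
        assert course["r1_myo"][0] == p.r1_myo_native

    def test_instantaneous_equilibrium_ratio(self):
        p = KineticsParams(lambda_true=0.45, exchange_tau=0.0)
        c = simulate_r1_course(p, default_schedule())
        ratio = (c["r1_myo"][1:] - p.r1_myo_native) / (c["r1_blood"][1:] - p.r1_blood_native)
        assert np.allclose(ratio, 0.45, atol=1e-12)

    def test_blood_enhancement_strictly_decreasing_post_contrast(self):
        c = simulate_r1_course(KineticsParams(), default_schedule())
        post = c["r1_blood"][1:]
        assert np.all(np.diff(post) < 0)

    def test_ratio_converges_monotonically_toward_plateau(self):
        # the closed-form first-order lag: the enhancement ratio approaches
        # its quasi-steady plateau monotonically after the uptake phase
        p = KineticsParams(lambda_true=0.45, exchange_tau=1.5)
        c = simulate_r1_course(p, default_schedule())
        ratio = (c["r1_myo"][1:] - p.r1_myo_native) / (c["r1_blood"][1:] - p.r1_blood_native)
        t = c["t_min"][1:]
        late = ratio[t >= 5]
        assert np.all(np.diff(late) <= 0)  # decays toward the plateau
        plateau = 0.45 / (1 - p.clearance_slow_rate * p.exchange_tau)
        assert abs(late[-1] - plateau) < 1e-6

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            KineticsParams(lambda_true=-0.1)
        with pytest.raises(ValueError):
            KineticsParams(clearance_fast_rate=0.01, clearance_slow_rate=0.02)


class TestMolliSignal:
    def test_plateau_and_null_point_noiseless(self):
        sig = simulate_molli_signal(1200.0, "pre_4_7_3", 60.0, noise_sd=0.0)
        t1_star = sig.true_t1_star
        # recovery plateau: signed signal -> A as TI -> inf
        assert abs(sig.true_a - sig.true_b * np.exp(-1e9 / t1_star)) == sig.true_a
        # null point: signal is zero where A = B exp(-TI/T1*)
        ti_null = t1_star * np.log(sig.true_b / sig.true_a)
        s_null = abs(sig.true_a - sig.true_b * np.exp(-ti_null / t1_star))
        assert s_null < 1e-12

    def test_round_trip_with_fit(self):
        sig = simulate_molli_signal(1000.0, "post_4_3_3", 62.0, noise_sd=0.0)
        res = fit_molli(sig.inversion_times, sig.signals)
        assert abs(res.t1 - 1000.0) / 1000.0 < 1e-3

    def test_deterministic_given_seed(self):
        a = simulate_molli_signal(900.0, "pre_4_7_3", 60.0, noise_sd=0.02, seed=5)
        b = simulate_molli_signal(900.0, "pre_4_7_3", 60.0, noise_sd=0.02, seed=5)
        assert np.array_equal(a.signals, b.signals)

    def test_schedule_kinds_differ_and_t1_must_be_positive(self):
        pre = simulate_molli_signal(1000.0, "pre_4_7_3", 60.0)
        post = simulate_molli_signal(1000.0, "post_4_3_3", 60.0)
        assert pre.inversion_times.size == post.inversion_times.size == 7
        with pytest.raises(ValueError):
            simulate_molli_signal(-5.0)


class TestPhantom:
    def test_noiseless_roi_values_exact(self):
        t1, labels = render_t1_phantom(1200.0, 1900.0, noise_sd=0.0)
        assert np.all(t1[labels == LABELS["septum"]] == 1200.0)
        assert np.all(t1[labels == LABELS["blood_pool"]] == 1900.0)

    def test_labels_partition_raster(self):
        _, labels = render_t1_phantom(1200.0, 1900.0)
        assert set(np.unique(labels)) <= set(LABELS.values())

    def test_artifact_biases_free_wall_only(self):
        clean, labels = render_t1_phantom(1200.0, 1900.0, artifact=False, seed=1)
        dirty, _ = render_t1_phantom(1200.0, 1900.0, artifact=True, seed=1)
        septum = labels == LABELS["septum"]
        free = labels == LABELS["free_wall"]
        assert np.array_equal(clean[septum], dirty[septum])
        assert dirty[free].mean() > clean[free].mean()


class TestHistologyField:
    def test_truth_table_is_exhaustive_and_calibrated(self):
        f = render_histology_field(10.0, 1.5, um_per_px=1.0, cell_density_target=120, seed=0)
        assert f.image.shape == (266, 356, 3)
        assert len(f.truth) > 0
        assert (f.truth.breadth_um > 0).all()
        assert (f.truth.breadth_um <= f.truth.long_um).all()

    def test_truth_mean_near_requested(self):
        f = render_histology_field(10.0, 1.5, um_per_px=1.0, cell_density_target=150, seed=3)
        n = len(f.truth)
        se = 1.5 / np.sqrt(n)
        assert abs(f.truth.breadth_um.mean() - 10.0) < 3 * se + 0.05  # trunc-normal shift

    def test_tilt_stretches_long_diameter_only(self):
        flat = render_histology_field(10.0, 1.5, um_per_px=1.0, tilt_sd=0.0, seed=9)
        tilted = render_histology_field(10.0, 1.5, um_per_px=1.0, tilt_sd=30.0, seed=9)
        assert tilted.truth.long_um.mean() > flat.truth.long_um.mean()
        assert np.allclose(tilted.truth.breadth_um, flat.truth.breadth_um)

    def test_seed_determinism_byte_identical(self):
        a = render_histology_field(10.0, 1.5, um_per_px=1.0, seed=7)
        b = render_histology_field(10.0, 1.5, um_per_px=1.0, seed=7)
        assert np.array_equal(a.image, b.image)

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError):
            render_histology_field(30.0, 1.5, um_per_px=1.0, cell_density_target=200)

    def test_save_load_round_trip(self, tmp_path):
        f = render_histology_field(10.0, 1.5, um_per_px=1.0, seed=2)
        save_field(f, tmp_path, "field_0")
        g = load_field(tmp_path, "field_0")
        assert np.array_equal(f.image, g.image)
        assert g.um_per_px == f.um_per_px
        assert np.allclose(g.truth.breadth_um, f.truth.breadth_um)


class TestCohortGenerator:
    def test_construction_identity_exact(self):
        animals = simulate_cohort(n_animals=10, seed=1)
        for a in animals:
            assert a.true_ecv == a.kinetics.lambda_true * (1 - a.record.hematocrit)

    def test_requested_correlation_recovered_at_large_n(self):
        animals = simulate_cohort(n_animals=200, ecv_cmyb_corr=-0.73, seed=11)
        ecv = [a.true_ecv for a in animals]
        cmyb = [a.true_cmyb_mean for a in animals]
        r = np.corrcoef(ecv, cmyb)[0, 1]
        assert abs(r - (-0.73)) < 0.1  # Fisher-z sampling error at n=200

    def test_null_correlation(self):
        animals = simulate_cohort(n_animals=200, ecv_cmyb_corr=0.0, seed=12)
        r = np.corrcoef(
            [a.true_ecv for a in animals], [a.true_cmyb_mean for a in animals]
        )[0, 1]
        assert abs(r) < 0.2

    def test_minimum_cohort_size_and_corr_range(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_animals=2)
        with pytest.raises(ValueError):
            simulate_cohort(n_animals=5, ecv_cmyb_corr=1.2)

    def test_determinism_and_field_count(self):
        a = simulate_cohort(n_animals=4, seed=5)
        b = simulate_cohort(n_animals=4, seed=5)
        assert [x.true_ecv for x in a] == [x.true_ecv for x in b]
        assert all(x.n_fields == 8 and len(x.field_seeds) == 8 for x in a)
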