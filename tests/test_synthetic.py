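import numpy as np
import pytest
from scipy import stats as sstats

from mmspike.bootstrap import ensemble_signatures
from mmspike.errors import ValidationError
from mmspike.kinematics import head_excursion, linear_speed
from mmspike.mms import extract_mms
from mmspike.motion_io import read_cohort_table, read_motion_file
from mmspike.synthetic import GroupSpec, default_scenario, generate_cohort, generate_trace


def spec(**kw):
    base = dict(
        label="g", diagnosis="TD", age_range=(5, 10), n_subjects=5, frames=120,
        dt=2.0, speed_shape=2.0, speed_scale=0.05, seed=0,
    )
    base.update(kw)
    return GroupSpec(**base)


class TestGenerateTrace:
    def test_deterministic(self):
        t1 = generate_trace(spec(), 3)
        t2 = generate_trace(spec(), 3)
        np.testing.assert_array_equal(t1.translations, t2.translations)
        np.testing.assert_array_equal(t1.rotations, t2.rotations)

    def test_noise_free_limit_near_still(self):
        quiet = spec(speed_scale=1e-9, drift_amplitude=0.0)
        speed = linear_speed(generate_trace(quiet, 0))
        assert head_excursion(speed) < 1e-5

    def test_allometric_factor_scales_trace_exactly(self):
        t1 = generate_trace(spec(), 2, allometric_factor=1.0)
        t2 = generate_trace(spec(), 2, allometric_factor=3.0)
        np.testing.assert_allclose(t2.translations, 3.0 * t1.translations, rtol=1e-12)

    def test_allometric_factor_invisible_to_mms(self):
        t1 = generate_trace(spec(frames=200), 2, allometric_factor=0.7)
        t2 = generate_trace(spec(frames=200), 2, allometric_factor=2.1)
        m1 = extract_mms(linear_speed(t1))
        m2 = extract_mms(linear_speed(t2))
        np.testing.assert_array_equal(m1.peak_indices, m2.peak_indices)
        np.testing.assert_allclose(m1.amplitudes, m2.amplitudes, atol=1e-12)
        # while excursions scale with the factor
        e1 = head_excursion(linear_speed(t1))
        e2 = head_excursion(linear_speed(t2))
        assert e2 == pytest.approx(3.0 * e1, rel=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            spec(speed_shape=-1.0)
        with pytest.raises(ValidationError):
            spec(frames=10)


class TestGenerateCohort:
    def test_file_and_table_counts(self, tmp_path):
        specs = [spec(label="a", n_subjects=3), spec(label="b", diagnosis="ASD", n_subjects=4)]
        table = generate_cohort(specs, tmp_path)
        assert len(table) == 7
        assert len(list((tmp_path / "motion").glob("*.1D"))) == 7
        records = read_cohort_table(tmp_path / "cohort.csv")
        assert len(records) == 7

    def test_rerun_byte_identical(self, tmp_path):
        specs = [spec(label="a", n_subjects=2)]
        generate_cohort(specs, tmp_path / "c1")
        generate_cohort(specs, tmp_path / "c2")
        for f1 in sorted((tmp_path / "c1").rglob("*")):
            if f1.is_file():
                f2 = tmp_path / "c2" / f1.relative_to(tmp_path / "c1")
                assert f1.read_bytes() == f2.read_bytes()

    def test_written_files_reproduce_trace(self, tmp_path):
        s = spec(label="a", n_subjects=2)
        generate_cohort([s], tmp_path)
        trace = generate_trace(s, 0)
        back = read_motion_file(tmp_path / "motion" / "a_000.1D", dt=s.dt)
        np.testing.assert_allclose(back.translations, trace.translations, atol=1e-10)

    def test_duplicate_labels_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            generate_cohort([spec(label="a"), spec(label="a")], tmp_path)

    def test_default_scenario_layout(self):
        specs = default_scenario(seed=0)
        assert len(specs) == 14
        assert {s.diagnosis for s in specs} == {"TD", "ASD"}
        assert all(s.n_subjects == 30 and s.frames == 150 for s in specs)


class TestGroundTruthRecovery:
    def test_signatures_order_groups_by_generating_noise(self):
        """Dispersion-ordered generating laws (scale up, shape down, as in the
        cohort scenario) must come out in the same order in fitted ensemble NSR."""
        shapes = (3.0, 2.2, 1.6, 1.1)
        scales = (0.03, 0.06, 0.09, 0.12)
        mean_nsr = []
        for g, (a, b) in enumerate(zip(shapes, scales)):
            s = spec(label=f"g{g}", n_subjects=20, frames=150, speed_shape=a,
                     speed_scale=b, seed=12)
            trains = {}
            for i in range(s.n_subjects):
                sp = linear_speed(generate_trace(s, i))
                trains[sp.subject_id] = extract_mms(sp, source="mean_deviation")
            ens = ensemble_signatures(trains, cell=(s.label,), k=50, m=15, seed=g)
            mean_nsr.append(ens.values("nsr").mean())
        rho = sstats.spearmanr(scales, mean_nsr).statistic
        assert rho == pytest.approx(1.0)
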