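"""Reference frame, radial profiling, partitions, and normative flagging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lidmetrics.contour import (
    ContourProfile,
    ReferenceFrame,
    build_frame,
    fit_normative,
    flag_abnormal,
    make_scheme,
    radial_profile,
    segment_values,
    verification_sweep,
)
from lidmetrics.errors import MeasurementError, ParameterError
from lidmetrics.morphometry import calibrate, find_canthi, split_margins
from lidmetrics.synthetic_scene import Bump, SceneParams, generate_scene
from lidmetrics.pipeline import process_scene

from conftest import SEED, disk_mask

HORIZONTAL = ReferenceFrame(origin=(0.0, 0.0), tilt_deg=0.0, u=(0.0, 1.0), n=(-1.0, 0.0))


def flat_profile(values, subject_id=""):
    return ContourProfile(distances_mm=np.asarray(values, dtype=float),
                          frame=HORIZONTAL, subject_id=subject_id)


class TestBuildFrame:
    def test_foot_of_perpendicular_origin(self):
        # canthi on the row-0 horizontal line, reflex at (3, 5): foot = (3... )
        # in (row, col): canthi rows equal -> origin shares the canthus row,
        # at the reflex's column
        frame = build_frame(((0.0, 0.0), (0.0, 10.0)), (5.0, 3.0))
        assert frame.origin == pytest.approx((0.0, 3.0))
        assert frame.tilt_deg == pytest.approx(0.0)

    def test_midpoint_origin_option(self):
        frame = build_frame(((0.0, 0.0), (0.0, 10.0)), (5.0, 3.0),
                            origin="intercanthal_midpoint")
        assert frame.origin == pytest.approx((0.0, 5.0))

    def test_rotated_frame_levels_the_canthi(self):
        medial, lateral = (12.0, 30.0), (4.0, 2.0)
        frame = build_frame((medial, lateral), (8.0, 16.0))
        u, n, o = map(np.array, (frame.u, frame.n, frame.origin))
        # both canthi lie on the frame's x-axis: zero component along n
        for p in (medial, lateral):
            assert abs(np.dot(np.array(p) - o, n)) < 1e-9

    def test_n_points_toward_upper_lid(self):
        frame = build_frame(((10.0, 0.0), (10.0, 20.0)), (5.0, 7.0))
        assert frame.n[0] < 0  # decreasing row = up

    def test_coincident_canthi_rejected(self):
        with pytest.raises(ParameterError):
            build_frame(((1.0, 1.0), (1.0, 1.0)), (0.0, 0.0))


class TestRadialProfile:
    def circle_chains(self, radius=60):
        m = disk_mask(radius)
        canthi = find_canthi(m)
        upper, lower = split_margins(m, canthi)
        return m, canthi, upper, lower

    def test_circular_fissure_gives_constant_profile(self):
        radius = 60
        m, canthi, upper, lower = self.circle_chains(radius)
        center = (m.shape[0] / 2, m.shape[1] / 2)
        frame = build_frame(canthi, center)
        prof = radial_profile(upper, lower, frame, calibrate(9.0))  # 1 mm/px
        assert prof.distances_mm == pytest.approx(radius, abs=1.5)

    def test_origin_outside_rejected(self):
        m, canthi, upper, lower = self.circle_chains()
        frame = ReferenceFrame(origin=(1.0, 1.0), tilt_deg=0.0,
                               u=(0.0, 1.0), n=(-1.0, 0.0))
        with pytest.raises(MeasurementError):
            radial_profile(upper, lower, frame, calibrate(9.0))

    def test_profile_matches_generator_truth(self, default_scene, default_result):
        err = default_result.profile.distances_mm - default_scene.truth.true_profile_mm
        assert np.abs(err).max() < 0.35  # worst near the grazing canthus rays
        interior = np.r_[10:170, 190:350]
        assert np.abs(err[interior]).max() < 0.25

    def test_bump_recovered_in_measured_profile(self, default_result):
        sc = generate_scene(SceneParams(bumps=(Bump(90.0, 20.0, 2.0),)))
        res = process_scene(sc, "oracle")
        delta = res.profile.distances_mm[90] - default_result.profile.distances_mm[90]
        assert 1.7 <= delta <= 2.3

    def test_profile_must_have_360_samples(self):
        with pytest.raises(ParameterError):
            flat_profile(np.ones(359))


class TestPartitions:
    @pytest.mark.parametrize("k, interval", [(4, 90.0), (8, 45.0), (16, 22.5),
                                             (24, 15.0), (32, 11.25), (64, 5.625)])
    def test_interval_arithmetic(self, k, interval):
        assert make_scheme(k).interval_deg == interval

    @pytest.mark.parametrize("k, reported", [(16, 22.5), (24, 15.0), (32, 11.3),
                                             (64, 5.6), (128, 2.8), (256, 1.4)])
    def test_one_decimal_reporting_rounds_half_up(self, k, reported):
        assert make_scheme(k).interval_deg_reported == reported

    def test_four_partitions_from_the_two_lines(self):
        s = make_scheme(4)
        assert s.k == 4
        # the intercanthal (0/180) and orthogonal (90/270) lines bound the segments
        seg = s.segment_of_degree
        assert seg[0] == 0 and seg[89] == 0
        assert seg[90] == 1 and seg[179] == 1
        assert seg[180] == 2 and seg[270] == 3

    def test_every_degree_assigned(self):
        for k in (4, 24, 256, 360):
            seg = make_scheme(k).segment_of_degree
            assert seg.min() == 0 and seg.max() == k - 1

    def test_out_of_range_rejected(self):
        for k in (1, 361):
            with pytest.raises(ParameterError):
                make_scheme(k)


class TestSegmentValues:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.sampled_from([4, 8, 16, 24, 32, 64, 128, 256, 360]),
           st.floats(0.5, 50.0))
    def test_constant_profile_any_k(self, k, value):
        vals = segment_values(flat_profile(np.full(360, value)), make_scheme(k))
        assert vals == pytest.approx(value)

    def test_k360_is_identity(self):
        p = flat_profile(np.linspace(1, 10, 360))
        np.testing.assert_allclose(segment_values(p, make_scheme(360)), p.distances_mm)

    def test_piecewise_profile_k4(self):
        d = np.full(360, 2.0)
        d[:90] = 1.0
        np.testing.assert_allclose(segment_values(flat_profile(d), make_scheme(4)),
                                   [1.0, 2.0, 2.0, 2.0])


class TestNormativeModel:
    def test_identical_profiles_have_zero_sd(self):
        p = flat_profile(np.full(360, 5.0))
        model = fit_normative([p, p], make_scheme(24))
        assert model.sd_mm == pytest.approx(0.0)
        assert model.mean_mm == pytest.approx(5.0)

    def test_means_equal_cohort_means_exactly(self):
        rng = np.random.default_rng(SEED)
        profiles = [flat_profile(5 + rng.normal(0, 0.3, 360)) for _ in range(10)]
        scheme = make_scheme(24)
        model = fit_normative(profiles, scheme)
        manual = np.mean([segment_values(p, scheme) for p in profiles], axis=0)
        np.testing.assert_allclose(model.mean_mm, manual)

    def test_sd_recovers_generating_sigma(self):
        """Per-degree i.i.d. noise sigma -> segment SD approx sigma/sqrt(15) at k=24."""
        rng = np.random.default_rng(SEED)
        sigma = 0.5
        profiles = [flat_profile(6 + rng.normal(0, sigma, 360)) for _ in range(100)]
        model = fit_normative(profiles, make_scheme(24))
        expected = sigma / np.sqrt(15)
        assert model.sd_mm.mean() == pytest.approx(expected, rel=0.25)

    def test_single_profile_rejected(self):
        with pytest.raises(ParameterError):
            fit_normative([flat_profile(np.full(360, 5.0))], make_scheme(24))


class TestFlagging:
    def fit(self, n=50, sigma=0.3, seed=SEED):
        rng = np.random.default_rng(seed)
        profiles = [flat_profile(6 + rng.normal(0, sigma, 360)) for _ in range(n)]
        return fit_normative(profiles, make_scheme(24)), profiles

    def test_cohort_mean_profile_is_clean(self):
        model, _ = self.fit()
        clean = flat_profile(np.tile(np.repeat(model.mean_mm, 15), 1))
        report = flag_abnormal(clean, model)
        assert report.abnormal_segments == frozenset()
        assert not report.is_abnormal_subject

    def test_displaced_segment_is_flagged(self):
        model, _ = self.fit()
        d = np.repeat(model.mean_mm, 15).astype(float)
        d[15 * 7: 15 * 8] += 10 * model.sd_mm[7]
        report = flag_abnormal(flat_profile(d), model)
        assert report.abnormal_segments == frozenset({7})
        assert report.is_abnormal_subject

    def test_zero_sd_segment_accepts_only_exact_match(self):
        p = flat_profile(np.full(360, 5.0))
        model = fit_normative([p, p], make_scheme(24))
        assert not flag_abnormal(p, model).is_abnormal_subject
        off = flat_profile(np.full(360, 5.0 + 1e-6))
        assert len(flag_abnormal(off, model).abnormal_segments) == 24

    def test_infinite_z_never_flags(self):
        rng = np.random.default_rng(SEED)
        profiles = [flat_profile(6 + rng.normal(0, 0.3, 360)) for _ in range(30)]
        model = fit_normative(profiles, make_scheme(24), z_crit=np.inf)
        assert not any(flag_abnormal(p, model).is_abnormal_subject for p in profiles)

    def test_scheme_mismatch_rejected(self):
        model, profiles = self.fit()
        import dataclasses
        bad = dataclasses.replace(model, scheme=make_scheme(8))
        with pytest.raises(ParameterError):
            flag_abnormal(profiles[0], bad)

    def test_percentile_method_flags_extremes(self):
        model, profiles = self.fit(n=100)
        pmodel = fit_normative(profiles, make_scheme(24), method="percentile")
        d = np.repeat(pmodel.mean_mm if pmodel.mean_mm is not None else 6, 15).astype(float)
        d[:15] += 5.0
        assert 0 in flag_abnormal(flat_profile(d), pmodel).abnormal_segments


class TestVerificationSweep:
    def synthetic_cohort(self, n_normal=60, n_abnormal=10, sigma=0.3, amp=3.0):
        rng = np.random.default_rng(SEED)
        cohort = []
        for i in range(n_normal):
            cohort.append((flat_profile(6 + rng.normal(0, sigma, 360)), False))
        for i in range(n_abnormal):
            d = 6 + rng.normal(0, sigma, 360)
            c = int(rng.integers(10, 350))
            w = np.abs(np.arange(360) - c) < 5
            d[w] += amp
            cohort.append((flat_profile(d), True))
        return cohort

    def test_high_amplitude_bumps_found_at_fine_partitions(self):
        curve = verification_sweep(self.synthetic_cohort(), ks=(4, 24, 128))
        assert curve.sensitivity[4] <= curve.sensitivity[24] <= curve.sensitivity[128]
        assert curve.sensitivity[128] == 1.0

    def test_single_always_flagged_abnormal_gives_unit_sensitivity(self):
        cohort = self.synthetic_cohort(n_normal=30, n_abnormal=1, amp=50.0)
        curve = verification_sweep(cohort, ks=(4, 8, 24))
        assert all(v == 1.0 for v in curve.sensitivity.values())

    def test_empty_class_rejected(self):
        cohort = self.synthetic_cohort(n_normal=5, n_abnormal=0)
        with pytest.raises(ParameterError):
            verification_sweep(cohort, ks=(4,))

    def test_refinement_keeps_full_segment_displacement_flagged(self):
        """A subject whose whole coarse segment is displaced stays abnormal
        under any refining partition (the displacement survives averaging)."""
        rng = np.random.default_rng(SEED)
        normals = [flat_profile(6 + rng.normal(0, 0.1, 360)) for _ in range(40)]
        d = 6 + rng.normal(0, 0.1, 360)
        d[:90] += 2.0  # the entire first k=4 segment
        subject = flat_profile(d)
        for k in (4, 8, 16, 24):
            model = fit_normative(normals, make_scheme(k))
            assert flag_abnormal(subject, model).is_abnormal_subject, k
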