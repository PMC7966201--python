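"""Registration core: closed-form paired fit, ICP, FRE/TRE, session means."""

import numpy as np
import pytest

from holonav import (
    CorrespondenceError,
    DegenerateConfigurationError,
    FiducialSet,
    ICPRegistration,
    InvalidInputError,
    PairedPointRegistration,
    RigidTransform,
    compute_fre,
    compute_tre,
    register_icp,
    register_paired,
    summarize_sessions,
)
from conftest import random_fiducial_pair

from _oracles import best_permutation_fre, lsq_rigid_oracle

SQUARE = np.array([[0, 0, 0], [100, 0, 0], [100, 100, 0], [0, 100, 0]], float)


def _fids(points, frame, labels=None):
    labels = labels or [f"f{i}" for i in range(len(points))]
    return FiducialSet(labels, points, frame=frame)


class TestFiducialSet:
    def test_needs_three_points(self):
        with pytest.raises(DegenerateConfigurationError):
            _fids(SQUARE[:2], "image")

    def test_collinear_rejected_coplanar_allowed(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateConfigurationError):
            _fids(line, "image")
        _fids(SQUARE, "image")  # coplanar is fine

    def test_labels_must_be_unique_and_match_length(self):
        with pytest.raises(InvalidInputError):
            FiducialSet(["a", "a", "b", "c"], SQUARE, "image")
        with pytest.raises(InvalidInputError):
            FiducialSet(["a", "b", "c"], SQUARE, "image")


class TestPairedRegistration:
    def test_identical_sets_give_identity_and_zero_fre(self):
        fit = register_paired(_fids(SQUARE, "image"), _fids(SQUARE, "physical"))
        assert fit.transform.almost_equal(RigidTransform.identity(), atol=1e-9)
        assert fit.fre < 1e-12
        assert fit.method == "paired" and fit.iterations == 0

    def test_pure_translation_recovered_exactly(self):
        phys = _fids(SQUARE + [10, 0, 0], "physical")
        fit = register_paired(_fids(SQUARE, "image"), phys)
        assert np.allclose(fit.transform.translation, (10, 0, 0), atol=1e-12)
        assert np.allclose(fit.transform.rotation, np.eye(3), atol=1e-12)
        assert fit.fre < 1e-12

    def test_coplanar_out_of_plane_perturbation_matches_nonlinear_oracle(self):
        # one point pushed 2 mm along the plane normal: no exact fit exists
        phys_pts = SQUARE.copy()
        phys_pts[0, 2] += 2.0
        fit = register_paired(_fids(SQUARE, "image"), _fids(phys_pts, "physical"))
        _, _, fre_oracle = lsq_rigid_oracle(SQUARE, phys_pts)
        assert fit.fre == pytest.approx(fre_oracle, abs=1e-6)

    def test_noiseless_exact_recovery_random_motions(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            img, phys, motion = random_fiducial_pair(rng, n, sigma=0.0)
            fit = register_paired(img, phys)
            assert fit.fre < 1e-9
            assert fit.transform.almost_equal(motion, atol=1e-8)

    def test_noisy_fit_matches_nonlinear_oracle(self, rng):
        for k in range(10):
            n = int(rng.integers(3, 11))
            img, phys, _ = random_fiducial_pair(rng, n, sigma=3.0)
            fit = register_paired(img, phys)
            _, _, fre_oracle = lsq_rigid_oracle(img.points, phys.points, seed=k)
            assert fit.fre == pytest.approx(fre_oracle, abs=1e-6)

    def test_fre_invariant_under_common_rigid_motion(self, rng):
        img, phys, _ = random_fiducial_pair(rng, 6, sigma=2.0)
        base = register_paired(img, phys).fre
        for _ in range(5):
            from holonav import random_rigid

            extra = random_rigid(rng)
            moved = register_paired(
                img.transformed(extra), phys.transformed(extra)
            ).fre
            assert moved == pytest.approx(base, abs=1e-9)

    def test_label_permutation_invariance(self, rng):
        img, phys, _ = random_fiducial_pair(rng, 5, sigma=1.0)
        perm = rng.permutation(5)
        img_p = FiducialSet([img.labels[i] for i in perm], img.points[perm], "image")
        phys_p = FiducialSet([phys.labels[i] for i in perm], phys.points[perm], "physical")
        a, b = register_paired(img, phys), register_paired(img_p, phys_p)
        assert a.fre == pytest.approx(b.fre, abs=1e-9)
        assert a.transform.almost_equal(b.transform, atol=1e-9)

    def test_label_mismatch_raises(self):
        img = _fids(SQUARE, "image", labels=["a", "b", "c", "d"])
        phys = _fids(SQUARE, "physical", labels=["a", "b", "d", "c"])
        with pytest.raises(CorrespondenceError):
            register_paired(img, phys)

    def test_wrong_frames_raise(self):
        with pytest.raises(CorrespondenceError):
            register_paired(_fids(SQUARE, "physical"), _fids(SQUARE, "physical"))

    def test_result_invariant_fre_is_rms(self, rng):
        img, phys, _ = random_fiducial_pair(rng, 8, sigma=2.0)
        fit = register_paired(img, phys)
        assert fit.fre == pytest.approx(
            np.sqrt(np.mean(fit.residuals**2)), abs=1e-12
        )
        assert fit.residuals.min() - 1e-12 <= fit.fre <= fit.residuals.max() + 1e-12

    def test_summary_mentions_fre_and_fiducials(self, rng):
        img, phys, _ = random_fiducial_pair(rng, 4, sigma=1.0)
        text = PairedPointRegistration(img, phys).fit().summary()
        assert "FRE" in text and "paired" in text and "f0" in text


class TestICP:
    def test_identical_sets_converge_immediately(self):
        fit = register_icp(_fids(SQUARE, "image"), _fids(SQUARE, "physical"))
        assert fit.fre < 1e-12
        assert fit.iterations == 1
        assert fit.method == "icp"
        assert fit.transform.almost_equal(RigidTransform.identity(), atol=1e-9)

    def test_recovers_small_motion_with_shuffled_correspondence(self, rng):
        motion = RigidTransform.from_axis_angle((0, 1, 0), np.deg2rad(5.0), (3, 0, 0))
        img = _fids(SQUARE, "image")
        perm = rng.permutation(4)
        phys = FiducialSet(
            [f"p{i}" for i in range(4)], motion.apply(SQUARE)[perm], "physical"
        )
        fit = register_icp(img, phys)
        paired = register_paired(img, _fids(motion.apply(SQUARE), "physical"))
        assert fit.fre == pytest.approx(paired.fre, abs=1e-6)
        assert fit.transform.almost_equal(motion, atol=1e-6)

    def test_matches_exhaustive_correspondence_search(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 7))
            img, phys, _ = random_fiducial_pair(rng, n, sigma=0.0)
            # shrink to a small motion so identity-init ICP finds the optimum
            small = RigidTransform.from_axis_angle(
                rng.normal(size=3), np.deg2rad(rng.uniform(0, 8)),
                rng.uniform(-4, 4, 3),
            )
            noisy = small.apply(img.points) + rng.normal(0, 0.3, img.points.shape)
            perm = rng.permutation(n)
            phys = FiducialSet([f"p{i}" for i in range(n)], noisy[perm], "physical")
            fit = register_icp(img, phys)
            assert fit.fre == pytest.approx(
                best_permutation_fre(img.points, phys.points), abs=1e-7
            )

    def test_initialized_at_paired_solution_never_does_worse(self, rng):
        import warnings as _warnings

        for _ in range(10):
            img, phys, _ = random_fiducial_pair(rng, 6, sigma=2.0)
            paired = register_paired(img, phys)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # converged-to-start is fine here
                icp = register_icp(img, phys, init=paired.transform)
            assert icp.fre <= paired.fre + 1e-9

    def test_stuck_start_reports_warning_status(self, rng):
        img, phys, _ = random_fiducial_pair(rng, 6, sigma=2.0)
        paired = register_paired(img, phys)
        import warnings as _warnings

        with _warnings.catch_warnings(record=True):
            _warnings.simplefilter("ignore")
            icp = register_icp(img, phys, init=paired.transform)
        if icp.fre >= paired.fre - 1e-12:
            assert icp.status == "converged-to-start"


class TestErrorMetrics:
    def test_fre_zero_on_perfect_alignment(self):
        fre, res = compute_fre(
            RigidTransform.identity(), _fids(SQUARE, "image"), _fids(SQUARE, "physical")
        )
        assert fre == 0.0 and np.all(res == 0)

    def test_fre_of_constant_residuals(self):
        phys = SQUARE + np.array([0, 0, 2.0])  # four residuals of 2 mm
        fre, res = compute_fre(RigidTransform.identity(), SQUARE, phys)
        assert fre == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(res, 2.0)

    def test_fre_rms_of_two_residuals(self):
        img = np.array([[0, 0, 0], [10, 0, 0]], float)
        phys = img + np.array([[3, 0, 0], [0, 4, 0]], float)  # residuals 3, 4
        fre, _ = compute_fre(RigidTransform.identity(), img, phys)
        assert fre == pytest.approx(np.sqrt(12.5), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(CorrespondenceError):
            compute_fre(RigidTransform.identity(), SQUARE, SQUARE[:3])

    def test_tre_three_four_five(self):
        assert compute_tre(
            RigidTransform.identity(), (0.0, 0.0, 0.0), (0.0, 3.0, 4.0)
        ) == pytest.approx(5.0, abs=1e-12)

    def test_tre_zero_after_noiseless_fit(self, rng):
        from holonav import PhantomSpec, generate_phantom

        spec = PhantomSpec(fle_sigma=0.0, true_motion=RigidTransform.from_axis_angle(
            (1, 0, 1), 0.4, (20, -10, 5)), seed=3)
        img, phys, (tgt_img, tgt_phys) = generate_phantom(spec)
        fit = register_paired(img, phys)
        for a, b in zip(tgt_img, tgt_phys):
            assert compute_tre(fit.transform, a, b) < 1e-9

    def test_tre_rejects_nonfinite(self):
        with pytest.raises(InvalidInputError):
            compute_tre(RigidTransform.identity(), (np.inf, 0, 0), (0, 0, 0))


class TestSessionSummary:
    def test_mean_of_reported_registrations(self):
        # six per-registration FREs (two per case, three cases)
        assert summarize_sessions([10.0, 9.0, 8.4, 9.9, 7.0, 7.0]) == pytest.approx(
            8.55, abs=1e-12
        )

    @pytest.mark.parametrize("values,expected", [([5.0], 5.0), ([1.0, 3.0], 2.0)])
    def test_small_lists(self, values, expected):
        assert summarize_sessions(values) == pytest.approx(expected, abs=1e-12)

    def test_empty_and_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_sessions([])
        with pytest.raises(InvalidInputError):
            summarize_sessions([1.0, -0.5])
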