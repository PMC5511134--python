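"""Fluctuation, deformation-energy, collectivity and mode-trajectory math."""

import numpy as np
import pytest

from hingescan import (
    build_force_constants,
    build_hessian,
    collectivity,
    compute_modes,
    deformation_energy,
    mode_fluctuation,
    mode_trajectory,
    normalize_profile,
)
from hingescan.enm import EnmError, ModeSet

from conftest import bare_model


def two_body():
    m = bare_model([[0, 0, 0], [3.8, 0, 0]])
    build_force_constants(m)
    return m, compute_modes(build_hessian(m))


def uniform_modeset(n, localized_on=None):
    """Hand-built single-mode ModeSet for collectivity edge cases."""
    v = np.zeros(3 * n)
    if localized_on is None:
        v[0::3] = 1.0
    else:
        v[3 * localized_on] = 1.0
    v /= np.linalg.norm(v)
    return ModeSet(
        eigenvalues=np.array([1.0]),
        eigenvectors=v[:, None],
        rigid=np.array([False]),
    )


class TestFluctuation:
    def test_two_body_stretch_is_symmetric(self):
        m, modes = two_body()
        prof = mode_fluctuation(modes, modes.n_modes, m)
        assert prof.values[0] == pytest.approx(prof.values[1])
        assert prof.values.sum() == pytest.approx(1.0 / modes.eigenvalue(modes.n_modes))

    def test_sign_flip_invariance(self, dumbbell_solved):
        modes = dumbbell_solved.modes
        flipped = ModeSet(
            eigenvalues=modes.eigenvalues.copy(),
            eigenvectors=-modes.eigenvectors,
            rigid=modes.rigid.copy(),
        )
        a = mode_fluctuation(modes, 7)
        b = mode_fluctuation(flipped, 7)
        assert np.allclose(a.values, b.values)

    def test_rigid_mode_rejected(self, helix_solved):
        with pytest.raises(EnmError, match="rigid"):
            mode_fluctuation(helix_solved.modes, 1)

    def test_sum_over_modes_matches_hessian_pseudoinverse(self, cloud_model):
        h = build_hessian(cloud_model)
        modes = compute_modes(h)
        total = np.zeros(cloud_model.n_beads)
        for m in range(1, modes.n_modes + 1):
            if not modes.is_rigid(m):
                total += mode_fluctuation(modes, m).values
        pinv = np.linalg.pinv(h, rcond=1e-10)
        expected = np.array(
            [np.trace(pinv[3 * i:3 * i + 3, 3 * i:3 * i + 3])
             for i in range(cloud_model.n_beads)]
        )
        assert np.allclose(total, expected, rtol=1e-6)


class TestDeformationEnergy:
    def test_rigid_body_displacement_stores_no_energy(self, helix_solved):
        prof = deformation_energy(helix_solved.model, helix_solved.modes, 3)
        assert prof.rigid_mode
        assert np.abs(prof.values).max() < 1e-10

    def test_two_body_stretch_splits_k_over_beads(self):
        m, modes = two_body()
        prof = deformation_energy(m, modes, modes.n_modes)
        # stretch eigenvalue 2k: each bead carries k/2, total lambda/2 = k
        assert prof.values[0] == pytest.approx(500.0, rel=1e-9)
        assert prof.values[1] == pytest.approx(500.0, rel=1e-9)

    @pytest.mark.parametrize("mode_offset", [0, 1, 2])
    def test_total_equals_half_eigenvalue(self, cloud_model, mode_offset):
        modes = compute_modes(build_hessian(cloud_model))
        mi = modes.first_nonrigid + mode_offset
        prof = deformation_energy(cloud_model, modes, mi)
        assert np.all(prof.values >= -1e-15)
        assert prof.values.sum() == pytest.approx(
            0.5 * modes.eigenvalue(mi), rel=1e-9
        )

    def test_profile_invariant_under_global_rotation(self, cloud_model):
        from scipy.spatial.transform import Rotation

        modes = compute_modes(build_hessian(cloud_model))
        ref = deformation_energy(cloud_model, modes, modes.first_nonrigid)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        m2 = bare_model(cloud_model.coords @ rot.T)
        build_force_constants(m2, cloud_model.params)
        modes2 = compute_modes(build_hessian(m2))
        prof2 = deformation_energy(m2, modes2, modes2.first_nonrigid)
        assert np.allclose(np.sort(ref.values), np.sort(prof2.values), rtol=1e-6)


class TestCollectivity:
    def test_uniform_mode_is_fully_collective(self):
        assert collectivity(uniform_modeset(8), 1) == pytest.approx(1.0)

    def test_single_bead_mode_is_minimal(self):
        assert collectivity(uniform_modeset(8, localized_on=2), 1) == pytest.approx(1 / 8)

    def test_bounds_and_sign_invariance(self, dumbbell_solved):
        modes = dumbbell_solved.modes
        n = modes.n_beads
        for mi in range(modes.first_nonrigid, modes.first_nonrigid + 3):
            kappa = collectivity(modes, mi)
            assert 1 / n <= kappa <= 1 + 1e-12


class TestModeTrajectory:
    def test_zero_amplitude_keeps_reference(self, dumbbell_solved):
        traj = mode_trajectory(dumbbell_solved.model, dumbbell_solved.modes, 7,
                               amplitude=0.0, n_frames=5)
        assert np.all(traj.frames == dumbbell_solved.model.coords[None])

    def test_frame_zero_is_exact_reference(self, dumbbell_solved):
        traj = mode_trajectory(dumbbell_solved.model, dumbbell_solved.modes, 7)
        assert np.all(traj.frames[0] == dumbbell_solved.model.coords)

    def test_sinusoid_antisymmetry(self, dumbbell_solved):
        traj = mode_trajectory(dumbbell_solved.model, dumbbell_solved.modes, 7,
                               n_frames=21)
        ref = traj.frames[0]
        # phases pi/2 and 3pi/2 sit at frames 5 and 15 of 21
        assert np.allclose(traj.frames[5] - ref, -(traj.frames[15] - ref), atol=1e-9)

    def test_max_rmsd_matches_closed_form(self, dumbbell_solved):
        model, modes = dumbbell_solved.model, dumbbell_solved.modes
        amp = 7.3
        traj = mode_trajectory(model, modes, 7, amplitude=amp, n_frames=21)
        rmsd = np.sqrt(np.mean(
            np.sum((traj.frames - model.coords[None]) ** 2, axis=2), axis=1))
        assert rmsd.max() == pytest.approx(amp / np.sqrt(model.n_beads), abs=1e-9)

    def test_default_amplitude_calibrated_to_rmsd_target(self, dumbbell_solved):
        traj = mode_trajectory(dumbbell_solved.model, dumbbell_solved.modes, 7,
                               rmsd_target=1.25)
        rmsd = np.sqrt(np.mean(
            np.sum((traj.frames - traj.frames[0][None]) ** 2, axis=2), axis=1))
        assert rmsd.max() == pytest.approx(1.25, rel=1e-9)

    def test_rigid_mode_and_negative_amplitude_rejected(self, dumbbell_solved):
        with pytest.raises(EnmError, match="rigid"):
            mode_trajectory(dumbbell_solved.model, dumbbell_solved.modes, 1)
        with pytest.raises(EnmError, match="amplitude"):
            mode_trajectory(dumbbell_solved.model, dumbbell_solved.modes, 7,
                            amplitude=-1.0)


class TestNormalize:
    def test_example_values(self):
        from hingescan.profiles import ResidueProfile

        prof = normalize_profile(ResidueProfile(values=[2.0, 4.0, 6.0]))
        assert np.allclose(prof.values, [0.0, 0.5, 1.0])
        assert prof.normalization == "minmax"

    def test_idempotent(self):
        from hingescan.profiles import ResidueProfile

        rng = np.random.default_rng(5)
        prof = normalize_profile(ResidueProfile(values=rng.normal(size=20)))
        again = normalize_profile(prof)
        assert np.allclose(prof.values, again.values)

    def test_rank_order_preserved(self):
        from hingescan.profiles import ResidueProfile

        rng = np.random.default_rng(6)
        raw = rng.normal(size=40)
        prof = normalize_profile(ResidueProfile(values=raw))
        assert np.array_equal(np.argsort(raw), np.argsort(prof.values))

    def test_constant_profile_rejected(self):
        from hingescan.profiles import ResidueProfile

        with pytest.raises(EnmError, match="constant"):
            normalize_profile(ResidueProfile(values=np.ones(5)))
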