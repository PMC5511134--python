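"""Force-constant rules, Hessian assembly and normal-mode contracts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hingescan import ForceFieldParams, build_force_constants, build_hessian, compute_modes
from hingescan.enm import EnmError

from conftest import bare_model


def brute_force_constants(model, p):
    """Independent double-loop restatement of the spring rules."""
    n = model.n_beads
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = np.linalg.norm(model.coords[i] - model.coords[j])
            sep = abs(int(model.resnums[i]) - int(model.resnums[j]))
            val = p.c / r**6 if r <= p.r_cut else 0.0
            same_helix = (
                model.helix_id[i] >= 0 and model.helix_id[i] == model.helix_id[j]
            )
            if (same_helix and 2 <= sep <= 4) or (
                model.sheet[i] and model.sheet[j] and r <= p.r_bridge and sep >= 2
            ):
                val = p.gamma_sse * p.c / r**6
            if (min(i, j), max(i, j)) in [tuple(sorted(d)) for d in model.disulfides]:
                val = p.k_ss
            if model.chain_ids[i] == model.chain_ids[j] and sep == 1:
                val = p.k_bond
            k[i, j] = val
    return k


def enm_energy(coords, ref, k):
    """Pair-spring energy at displaced coordinates (finite-difference oracle)."""
    e = 0.0
    n = coords.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if k[i, j] == 0:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            r0 = np.linalg.norm(ref[i] - ref[j])
            e += 0.5 * k[i, j] * (r - r0) ** 2
    return e


class TestForceConstants:
    def test_chain_neighbours_get_bond_constant(self):
        m = bare_model([[0, 0, 0], [3.8, 0, 0]])
        k = build_force_constants(m)
        assert k[0, 1] == pytest.approx(1000.0)

    def test_disulfide_beats_distance_rule(self):
        m = bare_model(
            [[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 6.5, 0]],
            disulfides=[(0, 3)],
        )
        p = ForceFieldParams(r_cut=10.0)
        k = build_force_constants(m, p)
        assert np.linalg.norm(m.coords[0] - m.coords[3]) == pytest.approx(6.5)
        assert k[0, 3] == pytest.approx(p.k_ss)

    def test_matches_brute_force_on_random_cloud(self, cloud_model):
        p = cloud_model.params
        expected = brute_force_constants(cloud_model, p)
        assert np.allclose(cloud_model.k, expected, atol=1e-12)
        assert np.allclose(cloud_model.k, cloud_model.k.T)
        assert np.all(np.diag(cloud_model.k) == 0)

    def test_helix_one_four_rule_uses_span_identity(self):
        coords = [[3.8 * i, 0.6 * (i % 2), 0.1 * i] for i in range(6)]
        m = bare_model(coords, helix_id=[0, 0, 0, -1, 1, 1])
        p = ForceFieldParams()
        k = build_force_constants(m, p)
        r02 = np.linalg.norm(m.coords[0] - m.coords[2])
        assert k[0, 2] == pytest.approx(p.gamma_sse * p.c / r02**6)
        # beads 2 and 4 are in different spans: plain distance rule
        r24 = np.linalg.norm(m.coords[2] - m.coords[4])
        assert k[2, 4] == pytest.approx(p.c / r24**6)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(EnmError, match="k_bond"):
            ForceFieldParams(k_bond=0.0)

    def test_disconnected_network_names_components(self):
        m = bare_model(
            [[0, 0, 0], [3.8, 0, 0], [100.0, 0, 0], [103.8, 0, 0]],
            chain=None,
        )
        m.chain_ids = np.asarray(["A", "A", "B", "B"])
        with pytest.raises(EnmError, match="disconnected"):
            build_force_constants(m)


class TestHessian:
    def test_two_body_stretch_eigenvalue_is_2k(self):
        m = bare_model([[0, 0, 0], [3.8, 0, 0]])
        build_force_constants(m)
        h = build_hessian(m)
        ev = np.linalg.eigvalsh(h)
        assert ev[-1] == pytest.approx(2 * 1000.0, rel=1e-10)
        assert np.abs(ev[:-1]).max() < 1e-9

    def test_translation_is_null_vector(self, cloud_model):
        h = build_hessian(cloud_model)
        for ax in np.eye(3):
            t = np.tile(ax, cloud_model.n_beads)
            assert np.abs(h @ t).max() < 1e-9

    def test_matches_finite_differences_of_energy(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 8, (5, 3))
        m = bare_model(coords)
        build_force_constants(m, ForceFieldParams(r_cut=50.0))
        h = build_hessian(m)
        ref = m.coords.copy()
        step = 1e-4
        n3 = 15
        fd = np.zeros((n3, n3))
        for a in range(n3):
            for b in range(n3):
                for sa, sb, sign in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
                    x = ref.ravel().copy()
                    x[a] += sa * step
                    x[b] += sb * step
                    fd[a, b] += sign * enm_energy(x.reshape(-1, 3), ref, m.k)
        fd /= 4 * step**2
        assert np.abs(fd - h).max() < 1e-5

    def test_coincident_beads_error(self):
        m = bare_model([[0, 0, 0], [0, 0, 0], [3.8, 0, 0]])
        build_force_constants(m)
        with pytest.raises(EnmError, match="coincident"):
            build_hessian(m)


class TestModes:
    def test_generic_structure_has_exactly_six_rigid_modes(self, helix_solved):
        assert helix_solved.modes.n_rigid == 6
        assert helix_solved.modes.first_nonrigid == 7

    def test_collinear_beads_have_extra_null_modes(self):
        m = bare_model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        build_force_constants(m)
        with pytest.warns(RuntimeWarning, match="near-null"):
            modes = compute_modes(build_hessian(m))
        assert modes.n_rigid > 6

    def test_eigen_decomposition_contract(self, dumbbell_solved):
        modes = dumbbell_solved.modes
        v = modes.eigenvectors
        gram = v.T @ v
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8
        h = build_hessian(dumbbell_solved.model)
        resid = h @ v - v * modes.eigenvalues[None, :]
        assert np.abs(resid).max() < 1e-8
        assert np.all(np.diff(modes.eigenvalues) >= -1e-12)
        assert np.all(modes.eigenvalues[~modes.rigid] > 0)

    def test_energy_consistency_quadratic_form(self, cloud_model):
        h = build_hessian(cloud_model)
        rng = np.random.default_rng(11)
        u = rng.normal(size=3 * cloud_model.n_beads) * 1e-2
        quad = 0.5 * u @ h @ u
        x = cloud_model.coords
        total = 0.0
        for i in range(cloud_model.n_beads):
            for j in range(i + 1, cloud_model.n_beads):
                if cloud_model.k[i, j] == 0:
                    continue
                rhat = (x[j] - x[i]) / np.linalg.norm(x[j] - x[i])
                proj = rhat @ (u.reshape(-1, 3)[i] - u.reshape(-1, 3)[j])
                total += 0.5 * cloud_model.k[i, j] * proj**2
        assert quad == pytest.approx(total, rel=1e-8)

    def test_rotation_invariance_of_eigenvalues(self, cloud_model):
        h = build_hessian(cloud_model)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        rotated = bare_model(cloud_model.coords @ rot.T)
        rotated.k = cloud_model.k  # constants depend only on distances
        rotated.params = cloud_model.params
        h2 = build_hessian(rotated)
        ev1, ev2 = np.linalg.eigvalsh(h), np.linalg.eigvalsh(h2)
        assert np.abs(ev1 - ev2).max() < 1e-8 * max(1.0, np.abs(ev1).max())

    def test_mode_index_is_one_based(self, helix_solved):
        with pytest.raises(EnmError, match="1-based"):
            helix_solved.modes.eigenvalue(0)
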