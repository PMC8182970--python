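"""FE assembly, statics with contact, and Newmark dynamics."""
import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from vocalfem.errors import AssemblyError
from vocalfem.geometry import LayeredMesh, extract_channel
from vocalfem.solid_fem import (MaterialParams, SimState, SystemMatrices, assemble,
                                element_stresses, enforce_contact,
                                mechanical_energy, natural_frequencies,
                                plane_strain_C, precompress, shear_modulus, step)


def one_element_mesh():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    return LayeredMesh(node_coords=coords, triangles=np.array([[0, 1, 2]]),
                       layer_of_element=np.array(["body"], dtype=object),
                       gamma_f=np.array([1, 2]), gamma_fixed=np.array([0]),
                       contact_plane_x=10.0, depth=1.0)


class TestAssemble:
    def test_rigid_body_null_space(self, coarse_mesh, nominal_material):
        mats = assemble(coarse_mesh, nominal_material)
        n = coarse_mesh.n_nodes
        knorm = sp.linalg.norm(mats.K_full)
        for comp in (0, 1):
            t = np.zeros(2 * n)
            t[comp::2] = 1.0
            assert np.linalg.norm(mats.K_full @ t) / knorm < 1e-10

    def test_one_element_plane_strain_patch(self):
        mesh = one_element_mesh()
        mat = MaterialParams(E_body=11.8, nu=0.4995)
        # uniform plane-strain state: eps_xx = a, eps_zz = b, gamma = g
        a, b, g = 1e-3, -4e-4, 2e-4
        theta = np.zeros(6)
        for i, (x, z) in enumerate(mesh.node_coords):
            theta[2 * i] = a * x + g * z          # ux
            theta[2 * i + 1] = b * z              # uz
        C = plane_strain_C(11.8, 0.4995)          # kPa
        expected = C @ np.array([a, b, g])
        got = element_stresses(mesh, mat, theta)[0]
        assert np.allclose(got, expected, rtol=1e-8)

    def test_shear_modulus_value(self):
        mu = shear_modulus(11.8, 0.4995)
        assert mu == pytest.approx(11.8 / (2 * (1 + 0.4995)), rel=1e-12)
        C = plane_strain_C(11.8, 0.4995)
        assert C[2, 2] == pytest.approx(mu, rel=1e-12)

    def test_damping_shares_stiffness_sparsity(self, coarse_mesh):
        mats = assemble(coarse_mesh, MaterialParams(eta=0.5))
        K = mats.K.tocsr()
        D = mats.D.tocsr()
        assert np.array_equal(K.indptr, D.indptr)
        assert np.array_equal(K.indices, D.indices)

    def test_mass_positive_definite(self, coarse_mesh, nominal_material):
        mats = assemble(coarse_mesh, nominal_material)
        w = np.linalg.eigvalsh(mats.M.toarray())
        assert w.min() > 0

    def test_material_validation(self):
        with pytest.raises(AssemblyError):
            MaterialParams(nu=0.5)
        with pytest.raises(AssemblyError):
            MaterialParams(E_slp=-1.0)
        with pytest.raises(AssemblyError):
            MaterialParams(eta=-0.1)


class TestEigen:
    def test_frequencies_real_positive_and_scale(self, coarse_mesh):
        mat = MaterialParams()
        f1 = natural_frequencies(assemble(coarse_mesh, mat), 5)
        assert np.all(f1 > 0)
        mat2 = MaterialParams(E_body=2 * 11.8, E_slp=2 * 0.6, E_lig=2 * 2.0,
                              E_epi=2 * 45.0)
        f2 = natural_frequencies(assemble(coarse_mesh, mat2), 5)
        assert np.allclose(f2 / f1, np.sqrt(2.0), rtol=1e-6)


class TestPrecompress:
    def test_zero_compression_is_identity(self, coarse_mesh, nominal_material):
        st0 = precompress(coarse_mesh, nominal_material, 0.0)
        assert np.all(st0.theta == 0) and np.all(st0.theta_dot == 0)

    def test_full_compression_contact(self, coarse_mesh, nominal_material):
        st4 = precompress(coarse_mesh, nominal_material, 0.4, literal=False)
        x_def = coarse_mesh.node_coords[:, 0] + st4.theta[0::2]
        assert np.all(x_def <= coarse_mesh.contact_plane_x + 1e-9)
        on_plane = np.abs(x_def[coarse_mesh.gamma_f] - coarse_mesh.contact_plane_x) < 1e-9
        assert on_plane.sum() >= 1
        assert np.all(st4.theta_dot == 0) and np.all(st4.theta_ddot == 0)

    def test_literal_loop_matches_projection(self, coarse_mesh, nominal_material):
        # the penalty loop's limit is the active-set equilibrium
        fast = precompress(coarse_mesh, nominal_material, 0.05, literal=False)
        lit = precompress(coarse_mesh, nominal_material, 0.05, literal=True,
                          step_size=1e-3)
        assert np.allclose(fast.theta, lit.theta, atol=1e-8)

    def test_no_contact_matches_plain_shift(self, coarse_mesh, nominal_material):
        # move the wall out so a small shift engages nothing
        mesh = LayeredMesh(**{**coarse_mesh.__dict__, "contact_plane_x": 9.9})
        st_ = precompress(mesh, nominal_material, 0.3, literal=False)
        expect = np.zeros_like(st_.theta)
        expect[0::2] = 0.3
        assert np.allclose(st_.theta, expect, atol=1e-8)


class TestNewmark:
    def _single_dof(self, m=2.0, k=5.0, c=0.0):
        M = sp.csr_matrix(np.array([[m]]))
        K = sp.csr_matrix(np.array([[k]]))
        D = sp.csr_matrix(np.array([[c]]))
        full = sp.csr_matrix(np.diag([1.0, 1.0]))
        return SystemMatrices(M=M, D=D, K=K, M_full=full, D_full=full,
                              K_full=full, free=np.array([0]),
                              free_map=np.array([0, -1]), n_nodes=1)

    def test_equilibrium_fixed_point(self):
        mats = self._single_dof()
        theta0 = 0.7
        state = SimState(t=0.0, theta=np.array([theta0, 0.0]),
                         theta_dot=np.zeros(2), theta_ddot=np.zeros(2))
        force = np.array([5.0 * theta0, 0.0])      # F = K theta0
        new = step(mats, state, force, dt=0.05)
        assert new.theta[0] == pytest.approx(theta0, abs=1e-10)
        assert new.theta_dot[0] == pytest.approx(0.0, abs=1e-10)

    def test_harmonic_oscillator_period(self):
        m, k = 1.3, 11.0
        omega = np.sqrt(k / m)
        T = 2 * np.pi / omega
        dt = T / 1000
        mats = self._single_dof(m=m, k=k)
        state = SimState(t=0.0, theta=np.array([1.0, 0.0]),
                         theta_dot=np.zeros(2), theta_ddot=np.zeros(2))
        # consistent initial acceleration a0 = -k/m
        state.theta_ddot[0] = -k / m
        traj = []
        for _ in range(2000):
            state = step(mats, state, np.zeros(2), dt)
            traj.append(state.theta[0])
        traj = np.asarray(traj)
        # period from the second zero-crossing pair (one full cycle)
        sign = np.signbit(traj)
        crossings = np.flatnonzero(sign[1:] != sign[:-1])
        period = 2 * (crossings[2] - crossings[0]) * dt / 2
        assert abs(period - T) / T < 1e-3
        assert abs(traj[999] - 1.0) < 5e-3        # back near the start after T

    def test_energy_non_increasing_with_damping(self, coarse_mesh):
        mat = MaterialParams(eta=1.0)
        mats = assemble(coarse_mesh, mat)
        rng = np.random.default_rng(4)
        state = SimState.zero(coarse_mesh.n_nodes)
        state.theta[mats.free] = 1e-3 * rng.normal(size=mats.free.size)
        energies = [mechanical_energy(mats, state)]
        zero = np.zeros(2 * coarse_mesh.n_nodes)
        for _ in range(1000):
            state = step(mats, state, zero, dt=0.01)
            energies.append(mechanical_energy(mats, state))
        e = np.asarray(energies)
        assert np.all(np.diff(e) <= 1e-12 * e[0])
        assert e[-1] < e[0]


class TestContact:
    def test_no_crossing_unchanged(self, coarse_mesh):
        state = SimState.zero(coarse_mesh.n_nodes)
        assert enforce_contact(coarse_mesh, state) is state

    def test_projection_exact(self, coarse_mesh):
        state = SimState.zero(coarse_mesh.n_nodes)
        node = int(coarse_mesh.gamma_f[len(coarse_mesh.gamma_f) // 2])
        over = coarse_mesh.contact_plane_x - coarse_mesh.node_coords[node, 0] + 0.05
        state.theta[2 * node] = over
        state.theta_dot[2 * node] = 1.0
        new = enforce_contact(coarse_mesh, state)
        x_def = coarse_mesh.node_coords[node, 0] + new.theta[2 * node]
        assert x_def == coarse_mesh.contact_plane_x
        assert new.theta_dot[2 * node] == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_idempotent(self, seed):
        from vocalfem.geometry import build_m5_mesh
        mesh = getattr(self, "_mesh", None)
        if mesh is None:
            mesh = self._mesh = build_m5_mesh(1.0, require_all_layers=False)
        rng = np.random.default_rng(seed)
        state = SimState.zero(mesh.n_nodes)
        state.theta[:] = rng.normal(0, 0.3, state.theta.size)
        once = enforce_contact(mesh, state)
        twice = enforce_contact(mesh, once)
        assert np.array_equal(once.theta, twice.theta)
        assert np.array_equal(once.theta_dot, twice.theta_dot)

    def test_never_shrinks_gap(self, coarse_mesh):
        # projection only moves nodes away from the wall (-x), so no station
        # gap can shrink and penetrating stations land exactly on the plane
        rng = np.random.default_rng(9)
        state = SimState.zero(coarse_mesh.n_nodes)
        state.theta[:] = rng.normal(0, 0.5, state.theta.size)
        ch_before = extract_channel(coarse_mesh, state)
        ch_after = extract_channel(coarse_mesh, enforce_contact(coarse_mesh, state))
        assert np.all(ch_after.gap >= ch_before.gap - 1e-12)
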