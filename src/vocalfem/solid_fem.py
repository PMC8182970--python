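"""Damped linear-elastic plane-strain FEM of the layered fold cross-section.

The displacement field u(x, t) ~ H(x) theta(t) uses 3-node linear triangles
with consistent mass.  The constitutive operator is the plane-strain isotropic
matrix C(E, nu) = mu * Ct(nu) with shear modulus mu = E / (2 (1 + nu));
Kelvin-Voigt damping replaces mu by mu + eta d/dt, so per element
D_e = (eta / mu_e) K_e.  Semi-discrete system: M theta'' + D theta' + K theta = F,
with the lateral/inferior attachment eliminated and a rigid contact plane at
x = contact_plane_x enforced by projection.

Internally everything runs in the mm-g-ms system (stress in MPa); the public
API takes kPa / kg/m³ / Pa·s (see :mod:`vocalfem.units`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .errors import AssemblyError, IntegrationError, PrecompressionError
from .geometry import LayeredMesh

_NEWMARK_GAMMA = 0.5
_NEWMARK_BETA = 0.25


@dataclass
class MaterialParams:
    """Per-layer Young's moduli (kPa), shared Poisson ratio, density (kg/m³)
    and Kelvin-Voigt viscosity (Pa·s)."""

    E_body: float = 11.8
    E_slp: float = 0.6
    E_lig: float = 2.0
    E_epi: float = 45.0
    nu: float = 0.4995
    rho_b: float = 1070.0
    eta: float = 0.01

    def __post_init__(self):
        for name in ("E_body", "E_slp", "E_lig", "E_epi", "rho_b"):
            if getattr(self, name) <= 0:
                raise AssemblyError(f"{name} must be positive")
        if not 0.0 < self.nu < 0.5:
            raise AssemblyError("Poisson ratio must lie in (0, 0.5)")
        if self.eta < 0:
            raise AssemblyError("viscosity must be non-negative")

    def modulus_of_layer(self, layer: str) -> float:
        return {"body": self.E_body, "SLP": self.E_slp,
                "ligament": self.E_lig, "epithelium": self.E_epi}[layer]


def shear_modulus(E: float, nu: float) -> float:
    """mu(E, nu) = E / (2 (1 + nu)), same units as E."""
    return E / (2.0 * (1.0 + nu))


def plane_strain_C(E: float, nu: float) -> np.ndarray:
    """Plane-strain isotropic operator on [eps_xx, eps_zz, gamma_xz], units of E."""
    if nu >= 0.5:
        raise AssemblyError("nu >= 0.5 makes the plane-strain operator singular")
    mu = shear_modulus(E, nu)
    a = 2.0 * (1.0 - nu) / (1.0 - 2.0 * nu)
    b = 2.0 * nu / (1.0 - 2.0 * nu)
    return mu * np.array([[a, b, 0.0], [b, a, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class SimState:
    """Displacement coefficients and their first two time derivatives.

    ``theta`` is the full interleaved vector [ux0, uz0, ux1, ...] in mm; it
    may include a uniform support shift (medial compression) recorded in
    ``support_shift``, in which case the x-coefficient of every attachment
    node equals the shift while the elastic deformation is theta minus the
    shift field.
    """

    t: float
    theta: np.ndarray
    theta_dot: np.ndarray
    theta_ddot: np.ndarray
    support_shift: float = 0.0

    @classmethod
    def zero(cls, n_nodes: int, t: float = 0.0) -> "SimState":
        z = np.zeros(2 * n_nodes)
        return cls(t=t, theta=z, theta_dot=z.copy(), theta_ddot=z.copy())

    def deformed_coords(self, mesh: LayeredMesh) -> np.ndarray:
        u = self.theta.reshape(-1, 2)
        return mesh.node_coords + u


@dataclass
class SystemMatrices:
    """Assembled operators on the free (unconstrained) coefficient space.

    ``M``, ``D``, ``K`` act on free dofs; the ``*_full`` versions keep every
    dof (used e.g. for rigid-body-mode checks).  ``free`` lists the free dof
    indices into the full interleaved numbering and ``free_map`` maps full ->
    free index (-1 for constrained dofs).
    """

    M: sp.csr_matrix
    D: sp.csr_matrix
    K: sp.csr_matrix
    M_full: sp.csr_matrix
    D_full: sp.csr_matrix
    K_full: sp.csr_matrix
    free: np.ndarray
    free_map: np.ndarray
    n_nodes: int
    _factor_cache: dict = field(default_factory=dict, repr=False)

    def restrict(self, full_vec: np.ndarray) -> np.ndarray:
        return np.asarray(full_vec)[self.free]

    def expand(self, free_vec: np.ndarray) -> np.ndarray:
        out = np.zeros(2 * self.n_nodes)
        out[self.free] = free_vec
        return out

    def newmark_factor(self, dt: float):
        key = float(dt)
        if key not in self._factor_cache:
            A = (self.M + _NEWMARK_GAMMA * dt * self.D
                 + _NEWMARK_BETA * dt * dt * self.K).tocsc()
            try:
                self._factor_cache[key] = spla.splu(A)
            except RuntimeError as exc:  # pragma: no cover - singular operator
                raise IntegrationError(f"singular Newmark operator: {exc}") from exc
        return self._factor_cache[key]


def _element_geometry(mesh: LayeredMesh):
    p = mesh.node_coords[mesh.triangles]          # (T, 3, 2)
    x, z = p[..., 0], p[..., 1]
    b = np.stack([z[:, 1] - z[:, 2], z[:, 2] - z[:, 0], z[:, 0] - z[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = mesh.element_areas()
    return b, c, area


def element_B(mesh: LayeredMesh, e: int) -> np.ndarray:
    """Strain-displacement matrix of element ``e`` (strain per mm of dof)."""
    b, c, area = _element_geometry(mesh)
    B = np.zeros((3, 6))
    for i in range(3):
        B[0, 2 * i] = b[e, i]
        B[1, 2 * i + 1] = c[e, i]
        B[2, 2 * i] = c[e, i]
        B[2, 2 * i + 1] = b[e, i]
    return B / (2.0 * area[e])


def assemble(mesh: LayeredMesh, mat: MaterialParams) -> SystemMatrices:
    """Assemble mass, Kelvin-Voigt damping and stiffness with constraints.

    Element stiffness uses C(E, nu) per layer; damping replaces the shear
    modulus with the viscosity (D_e = (eta / mu_e) K_e); mass is consistent
    with uniform density.  Thickness equals the anterior-posterior depth.
    """
    if np.any(mesh.element_areas() <= 0):
        raise AssemblyError("mesh contains non-positively-oriented elements")
    T = mesh.n_elements
    b, c, area = _element_geometry(mesh)
    t = mesh.depth

    E_int = np.array([mat.modulus_of_layer(l) for l in mesh.layer_of_element]) * units.KPA
    nu = mat.nu
    mu = E_int / (2.0 * (1.0 + nu))
    eta_int = mat.eta * units.PA_S
    rho_int = mat.rho_b * units.KG_M3

    # B matrices, (T, 3, 6)
    B = np.zeros((T, 3, 6))
    inv2A = 1.0 / (2.0 * area)
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i]
        B[:, 1, 2 * i + 1] = c[:, i]
        B[:, 2, 2 * i] = c[:, i]
        B[:, 2, 2 * i + 1] = b[:, i]
    B *= inv2A[:, None, None]

    a_ = 2.0 * (1.0 - nu) / (1.0 - 2.0 * nu)
    b_ = 2.0 * nu / (1.0 - 2.0 * nu)
    Ct = np.array([[a_, b_, 0.0], [b_, a_, 0.0], [0.0, 0.0, 1.0]])

    BtCB = np.einsum("tki,kl,tlj->tij", B, Ct, B)          # unit-modulus stiffness
    scale = (t * area)
    Ke = BtCB * (mu * scale)[:, None, None]
    De = BtCB * (eta_int * scale)[:, None, None]

    mpat = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    Me_nodal = mpat[None, :, :] * (rho_int * t * area)[:, None, None]

    dofs = np.empty((T, 6), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.triangles
    dofs[:, 1::2] = 2 * mesh.triangles + 1

    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    n = 2 * mesh.n_nodes
    K_full = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    D_full = sp.coo_matrix((De.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    Me = np.zeros((T, 6, 6))
    Me[:, 0::2, 0::2] = Me_nodal
    Me[:, 1::2, 1::2] = Me_nodal
    M_full = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    fixed_dofs = np.concatenate([2 * mesh.gamma_fixed, 2 * mesh.gamma_fixed + 1])
    free_mask = np.ones(n, dtype=bool)
    free_mask[fixed_dofs] = False
    free = np.flatnonzero(free_mask)
    free_map = -np.ones(n, dtype=np.int64)
    free_map[free] = np.arange(free.size)

    return SystemMatrices(
        M=M_full[free][:, free].tocsr(), D=D_full[free][:, free].tocsr(),
        K=K_full[free][:, free].tocsr(),
        M_full=M_full, D_full=D_full, K_full=K_full,
        free=free, free_map=free_map, n_nodes=mesh.n_nodes)


def element_stresses(mesh: LayeredMesh, mat: MaterialParams, theta: np.ndarray) -> np.ndarray:
    """Per-element stress [sxx, szz, sxz] in kPa for displacement ``theta`` (mm)."""
    T = mesh.n_elements
    out = np.zeros((T, 3))
    for e in range(T):
        B = element_B(mesh, e)
        C = plane_strain_C(mat.modulus_of_layer(mesh.layer_of_element[e]) * units.KPA, mat.nu)
        nodes = mesh.triangles[e]
        ue = np.empty(6)
        ue[0::2] = theta[2 * nodes]
        ue[1::2] = theta[2 * nodes + 1]
        out[e] = C @ (B @ ue) * units.MPA_TO_KPA
    return out


def step(mats: SystemMatrices, state: SimState, force: np.ndarray, dt: float) -> SimState:
    """One implicit Newmark average-acceleration step.

    ``force`` is a full-size nodal force vector in N; entries at constrained
    dofs are ignored.  Exact at equilibrium for a constant force.
    """
    if dt <= 0:
        raise IntegrationError("dt must be positive")
    shift_field = np.zeros(2 * mats.n_nodes)
    shift_field[0::2] = state.support_shift
    d = mats.restrict(state.theta - shift_field)
    v = mats.restrict(state.theta_dot)
    a = mats.restrict(state.theta_ddot)
    f = mats.restrict(np.asarray(force, dtype=float))

    d_pred = d + dt * v + dt * dt * (0.5 - _NEWMARK_BETA) * a
    v_pred = v + dt * (1.0 - _NEWMARK_GAMMA) * a
    rhs = f - mats.K @ d_pred - mats.D @ v_pred
    a_new = mats.newmark_factor(dt).solve(rhs)
    d_new = d_pred + _NEWMARK_BETA * dt * dt * a_new
    v_new = v_pred + _NEWMARK_GAMMA * dt * a_new

    return SimState(
        t=state.t + dt,
        theta=mats.expand(d_new) + shift_field,
        theta_dot=mats.expand(v_new),
        theta_ddot=mats.expand(a_new),
        support_shift=state.support_shift)


def enforce_contact(mesh: LayeredMesh, state: SimState, zero_velocity: bool = True) -> SimState:
    """Project nodes beyond the contact plane back onto it.

    The x-displacement of each crossing node is reset so the deformed x equals
    ``contact_plane_x`` exactly; its x-velocity is zeroed (perfectly inelastic
    wall) unless ``zero_velocity`` is False.  Idempotent.
    """
    x_def = mesh.node_coords[:, 0] + state.theta[0::2]
    crossing = x_def > mesh.contact_plane_x
    if not np.any(crossing):
        return state
    theta = state.theta.copy()
    theta_dot = state.theta_dot.copy()
    idx = np.flatnonzero(crossing)
    theta[2 * idx] = mesh.contact_plane_x - mesh.node_coords[idx, 0]
    if zero_velocity:
        theta_dot[2 * idx] = 0.0
    return replace(state, theta=theta, theta_dot=theta_dot)


def mechanical_energy(mats: SystemMatrices, state: SimState) -> float:
    """Kinetic + elastic strain energy (N·mm) of the free coefficients."""
    shift_field = np.zeros(2 * mats.n_nodes)
    shift_field[0::2] = state.support_shift
    d = mats.restrict(state.theta - shift_field)
    v = mats.restrict(state.theta_dot)
    return float(0.5 * v @ (mats.M @ v) + 0.5 * d @ (mats.K @ d))


def natural_frequencies(mats: SystemMatrices, k: int = 6) -> np.ndarray:
    """First ``k`` undamped natural frequencies in kHz (cycles per ms)."""
    n = mats.K.shape[0]
    if n <= 600:
        import scipy.linalg as la
        w2 = la.eigh(mats.K.toarray(), mats.M.toarray(), eigvals_only=True)[:k]
    else:
        w2 = spla.eigsh(mats.K, k=k, M=mats.M, sigma=0, which="LM",
                        return_eigenvectors=False)[::-1]
    w2 = np.sort(w2)
    return np.sqrt(np.clip(w2, 0.0, None)) / (2.0 * np.pi)


def _active_set_solve(mesh: LayeredMesh, mats: SystemMatrices, shift: float,
                      max_iter: int = 80):
    """Static contact equilibrium after a rigid medial shift of the support.

    Solves K u = lambda with u_x fixed to the plane gap on the active contact
    set, activating penetrating nodes and releasing nodes whose reaction pulls
    on the wall.  Returns the free-displacement vector.
    """
    ref_x = mesh.node_coords[:, 0]
    plane = mesh.contact_plane_x
    n_free = mats.free.size
    # candidate contact dofs: free x-dofs
    cand_nodes = np.flatnonzero(mats.free_map[2 * np.arange(mesh.n_nodes)] >= 0)
    cand_free = mats.free_map[2 * cand_nodes]
    gap_ref = plane - (ref_x[cand_nodes] + shift)     # prescribed u_x when active

    def solve_with(active_mask):
        if not np.any(active_mask):
            return np.zeros(n_free)
        a_idx = cand_free[active_mask]
        u_a = gap_ref[active_mask]
        mask = np.ones(n_free, dtype=bool)
        mask[a_idx] = False
        Kff = mats.K[mask][:, mask].tocsc()
        rhs = -(mats.K[mask][:, a_idx] @ u_a)
        u = np.zeros(n_free)
        u[mask] = spla.splu(Kff).solve(rhs)
        u[a_idx] = u_a
        return u

    active = gap_ref < 0.0            # start from the kinematic penetration set
    reac_tol = 1e-12
    for _ in range(max_iter):
        u = solve_with(active)
        reac = (mats.K @ u)[cand_free]
        pen = u[cand_free] - gap_ref
        release = active & (reac > reac_tol)          # wall would have to pull
        add = (~active) & (pen > 1e-12)               # inactive node penetrates
        if not np.any(release) and not np.any(add):
            return u, active
        active = (active & ~release) | add
    raise PrecompressionError("active-set contact solve did not converge")


def precompress(mesh: LayeredMesh, mat: MaterialParams, m: float, *,
                step_size: float = 1e-4, penalty: float = 1e-4,
                literal: bool = True, tol: float = 1e-8) -> SimState:
    """Static equilibrium after pressing the fold ``m`` mm into the contact plane.

    The support (and the whole reference configuration) is shifted medially in
    increments of ``step_size`` mm; at each increment a penalty force of
    ``penalty`` N (in -x) is accumulated on every node crossing the plane and
    the static system re-solved.  A final active-set projection enforces
    non-penetration to machine tolerance; with ``literal=False`` only the
    projection runs (the equilibrium is identical, see docs).
    """
    if m < 0:
        raise PrecompressionError("medial compression must be non-negative")
    n = mesh.n_nodes
    if m == 0:
        return SimState.zero(n)
    mats = assemble(mesh, mat)

    if literal:
        lu = spla.splu(mats.K.tocsc())
        ref_x = mesh.node_coords[:, 0]
        cand_nodes = np.flatnonzero(mats.free_map[2 * np.arange(n)] >= 0)
        cand_free = mats.free_map[2 * cand_nodes]
        f = np.zeros(mats.free.size)
        u = np.zeros(mats.free.size)
        shift = 0.0
        n_steps = int(round(m / step_size))
        for _ in range(n_steps):
            shift += step_size
            crossing = ref_x[cand_nodes] + shift + u[cand_free] > mesh.contact_plane_x
            if np.any(crossing):
                f[cand_free[crossing]] -= penalty
                u = lu.solve(f)
        shift = m  # guard rounding

    u, active = _active_set_solve(mesh, mats, m)
    # residual check away from the contact set
    r = mats.K @ u
    cand_nodes = np.flatnonzero(mats.free_map[2 * np.arange(n)] >= 0)
    a_idx = mats.free_map[2 * cand_nodes][active]
    r_free = np.delete(r, a_idx)
    scale = max(float(np.abs(r).max()), 1.0)
    if r_free.size and np.abs(r_free).max() > tol * scale:
        raise PrecompressionError(
            f"static residual {np.abs(r_free).max():.3e} above tolerance")

    theta = mats.expand(u)
    theta[0::2] += m
    state = SimState(t=0.0, theta=theta, theta_dot=np.zeros(2 * n),
                     theta_ddot=np.zeros(2 * n), support_shift=m)
    return state
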