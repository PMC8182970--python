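"""Coupled fluid-structure time loop producing glottal-width waveforms.

Each step extracts the deformed glottal channel, solves the chosen flow model
for the intraglottal pressure, converts it to consistent nodal loads on the
fluid-loaded surface, advances the structure by one implicit Newmark step and
projects any contact-plane crossings.  The observable is the minimum channel
gap (the length-averaged glottal width of a 2D model), reported on a coarser
output grid emulating a high-speed-video frame rate.

Simulations start from the medially precompressed equilibrium with the
pressure load switched on at t = 0; onset occurs naturally because that state
is not a flow equilibrium.  ``run_forward`` drives the compiled kernel;
``run_forward_reference`` is a slow, instrumented pure-Python twin used for
validation and energy audits.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse.linalg as spla

from . import _kernel, units
from .errors import ConfigurationError, SimulationBlowupError
from .fluid_bernoulli import BernoulliParams, bernoulli_pressure
from .fluid_viscous import FlowSolution, ViscousFlowParams, alpha, solve_viscous_flow
from .geometry import ChannelProfile, LayeredMesh, extract_channel, surface_segment
from .solid_fem import (MaterialParams, assemble, enforce_contact,
                        mechanical_energy, precompress, step)

FLOW_MODELS = ("bernoulli_fixed", "bernoulli_estimated", "viscous")


@dataclass
class SimulationConfig:
    """Settings of one forward simulation.

    Times in ms, pressures in kPa, lengths in mm.  ``r_sep`` is used by the
    Bernoulli models (for ``bernoulli_estimated`` it is supplied per parameter
    sample); ``viscous`` carries the 1D viscous-flow constants.  ``output_dt``
    is the sampling interval of the returned waveform (video-rate analogue);
    the structural step ``dt`` stays much finer.
    """

    flow_model: str = "bernoulli_fixed"
    p_sub: float = 1.092
    p_sup: float = 0.0
    m: float = 0.4
    r_sep: float = 1.2
    dt: float = 0.01
    duration: float = 200.0
    transient_discard: float = 50.0
    output_dt: float = 0.25
    n_stations: int = 50
    resolution: float = 0.3
    viscous: ViscousFlowParams = field(default_factory=ViscousFlowParams)
    closed_gap_tol: float = 1e-6
    kick_amplitude: float = 0.0
    seed: int | None = None
    zero_contact_velocity: bool = True

    def __post_init__(self):
        if self.flow_model not in FLOW_MODELS:
            raise ConfigurationError(f"unknown flow model {self.flow_model!r}")
        if not self.duration > self.transient_discard >= 0:
            raise ConfigurationError("need duration > transient_discard >= 0")
        if self.dt <= 0 or self.output_dt < self.dt:
            raise ConfigurationError("need output_dt >= dt > 0")


@dataclass
class ObservationSeries:
    """Uniformly sampled length-averaged glottal width (mm) time series."""

    t: np.ndarray
    width: np.ndarray
    depth: float = 14.0
    noise_sigma_width: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if self.t.size != self.width.size:
            raise ConfigurationError("time and width lengths differ")
        if self.t.size > 1:
            dts = np.diff(self.t)
            if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
                raise ConfigurationError("observation grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# vocalfem observation series\n")
            fh.write(f"# depth_mm: {self.depth!r}\n")
            fh.write(f"# noise_sigma_width_mm: {self.noise_sigma_width!r}\n")
            fh.write(f"# metadata: {json.dumps(self.metadata, sort_keys=True)}\n")
            fh.write("time_ms,width_mm\n")
            for t, w in zip(self.t, self.width):
                fh.write(f"{t:.6f},{w:.9f}\n")

    @classmethod
    def from_csv(cls, path) -> "ObservationSeries":
        depth, sigma, meta = 14.0, 0.0, {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("depth_mm:"):
                        depth = float(body.split(":", 1)[1])
                    elif body.startswith("noise_sigma_width_mm:"):
                        sigma = float(body.split(":", 1)[1])
                    elif body.startswith("metadata:"):
                        meta = json.loads(body.split(":", 1)[1])
                elif line and not line.startswith("time_ms"):
                    a, b = line.split(",")
                    rows.append((float(a), float(b)))
        arr = np.asarray(rows)
        return cls(t=arr[:, 0], width=arr[:, 1], depth=depth,
                   noise_sigma_width=sigma, metadata=meta)


def _surface_edges(mesh: LayeredMesh):
    """Reference geometry of the fluid-loaded surface edges.

    Returns (n1, n2, z1, z2, wx, wz) where (wx, wz) = -n_outward * length *
    depth, the constant factor of the consistent inward-pressure load.
    """
    g = mesh.gamma_f
    p1 = mesh.node_coords[g[:-1]]
    p2 = mesh.node_coords[g[1:]]
    tvec = p2 - p1
    length = np.linalg.norm(tvec, axis=1)
    if np.any(length <= 0):
        raise ConfigurationError("degenerate surface edge")
    # boundary traversed CCW: outward normal is (t_z, -t_x)/L
    nx = tvec[:, 1] / length
    nz = -tvec[:, 0] / length
    wx = -nx * length * mesh.depth
    wz = -nz * length * mesh.depth
    return g[:-1], g[1:], p1[:, 1], p2[:, 1], wx, wz


def pressure_to_forces(channel: ChannelProfile, p: np.ndarray, mesh: LayeredMesh,
                       p_below: float | None = None,
                       p_above: float | None = None) -> np.ndarray:
    """Consistent nodal force vector (N, full interleaved size) from station
    pressures ``p`` (kPa).

    Pressure is interpolated linearly in (material) z to the surface-edge
    endpoints, clamped to ``p_below`` below the channel inlet and ``p_above``
    above the outlet (defaults: the end values of ``p``), applied as an
    inward-normal traction and integrated against the linear surface basis
    (1/3-1/6 edge splitting).
    """
    p = np.asarray(p, dtype=float)
    p_below = p[0] if p_below is None else p_below
    p_above = p[-1] if p_above is None else p_above
    n1, n2, z1, z2, wx, wz = _surface_edges(mesh)

    def p_at(z):
        out = np.interp(z, channel.z, p)
        out = np.where(z < channel.z[0], p_below, out)
        out = np.where(z > channel.z[-1], p_above, out)
        return out

    p1 = p_at(z1) * units.KPA
    p2 = p_at(z2) * units.KPA
    c1 = (2.0 * p1 + p2) / 6.0
    c2 = (p1 + 2.0 * p2) / 6.0
    F = np.zeros(2 * mesh.n_nodes)
    np.add.at(F, 2 * n1, c1 * wx)
    np.add.at(F, 2 * n1 + 1, c1 * wz)
    np.add.at(F, 2 * n2, c2 * wx)
    np.add.at(F, 2 * n2 + 1, c2 * wz)
    return F


def _station_pressure_profile(config: SimulationConfig, channel: ChannelProfile):
    """Station pressures (kPa) for the configured flow model (reference path)."""
    if config.flow_model in ("bernoulli_fixed", "bernoulli_estimated"):
        res = bernoulli_pressure(channel, BernoulliParams(
            p_sub=config.p_sub, p_sup=config.p_sup, r_sep=config.r_sep))
        return res.p
    sol: FlowSolution = solve_viscous_flow(channel, config.p_sub, config.p_sup,
                                           config.viscous)
    return sol.p


def _initial_state_and_system(config: SimulationConfig, mesh: LayeredMesh,
                              mat: MaterialParams):
    mats = assemble(mesh, mat)
    state = precompress(mesh, mat, config.m, literal=False)
    if config.kick_amplitude > 0.0:
        v = state.theta_dot.copy()
        v[2 * mesh.gamma_f] += config.kick_amplitude
        state = replace(state, theta_dot=v)
    # consistent initial acceleration with the flow switched on at t = 0
    ch = extract_channel(mesh, state, n_stations=config.n_stations)
    p = _station_pressure_profile(config, ch)
    F0 = pressure_to_forces(ch, p, mesh, p_below=config.p_sub, p_above=config.p_sup)
    shift_field = np.zeros(2 * mesh.n_nodes)
    shift_field[0::2] = state.support_shift
    d0 = mats.restrict(state.theta - shift_field)
    v0 = mats.restrict(state.theta_dot)
    rhs = mats.restrict(F0) - mats.K @ d0 - mats.D @ v0
    a0 = spla.splu(mats.M.tocsc()).solve(rhs)
    state = replace(state, theta_ddot=mats.expand(a0))
    return mats, state


def _decimate(widths: np.ndarray, config: SimulationConfig) -> ObservationSeries:
    stride = int(round(config.output_dt / config.dt))
    start = int(round(config.transient_discard / config.dt))
    w = widths[start::stride]
    t = np.arange(w.size) * (stride * config.dt)
    return ObservationSeries(t=t, width=w, depth=0.0)


def run_forward(config: SimulationConfig, mesh: LayeredMesh,
                mat: MaterialParams) -> ObservationSeries:
    """Run the coupled simulation and return the noise-free width waveform.

    Raises :class:`SimulationBlowupError` (with the failing step) if the
    displacement field diverges.
    """
    mats, state = _initial_state_and_system(config, mesh, mat)
    n_steps = int(round(config.duration / config.dt))

    lu = spla.splu((mats.M + 0.5 * config.dt * mats.D
                    + 0.25 * config.dt ** 2 * mats.K).tocsc())
    L = lu.L.tocsc()
    U = lu.U.tocsc()
    row_order = np.argsort(lu.perm_r).astype(np.int64)
    perm_c = lu.perm_c.astype(np.int64)

    seg = surface_segment(mesh, mesh.z_in, mesh.z_out)
    surf_nodes = mesh.gamma_f[seg]
    surf_zref = mesh.node_coords[surf_nodes, 1].astype(float)
    surf_xref = mesh.node_coords[surf_nodes, 0] + state.support_shift
    surf_xdof = mats.free_map[2 * surf_nodes]

    z_st = np.linspace(mesh.z_in, mesh.z_out, config.n_stations)
    alpha_st = np.asarray(alpha(z_st, config.viscous), dtype=float)

    n1, n2, z1, z2, wx, wz = _surface_edges(mesh)
    e_x1 = mats.free_map[2 * n1]
    e_z1 = mats.free_map[2 * n1 + 1]
    e_x2 = mats.free_map[2 * n2]
    e_z2 = mats.free_map[2 * n2 + 1]

    free_nodes = np.flatnonzero(mats.free_map[2 * np.arange(mesh.n_nodes)] >= 0)
    contact_xdof = mats.free_map[2 * free_nodes]
    contact_refx = mesh.node_coords[free_nodes, 0] + state.support_shift

    shift_field = np.zeros(2 * mesh.n_nodes)
    shift_field[0::2] = state.support_shift
    d0 = mats.restrict(state.theta - shift_field)
    v0 = mats.restrict(state.theta_dot)
    a0 = mats.restrict(state.theta_ddot)

    flow_code = _kernel.VISCOUS if config.flow_model == "viscous" else _kernel.BERNOULLI
    vp = config.viscous
    widths, fail = _kernel.simulate(
        L.data, L.indices.astype(np.int64), L.indptr.astype(np.int64),
        U.data, U.indices.astype(np.int64), U.indptr.astype(np.int64),
        row_order, perm_c,
        mats.K.data, mats.K.indices.astype(np.int64), mats.K.indptr.astype(np.int64),
        mats.D.data, mats.D.indices.astype(np.int64), mats.D.indptr.astype(np.int64),
        d0, v0, a0,
        config.dt, n_steps,
        surf_zref, surf_xref, surf_xdof,
        z_st, alpha_st,
        z1, z2, wx, wz, e_x1, e_z1, e_x2, e_z2,
        contact_xdof, contact_refx,
        mesh.contact_plane_x, mesh.depth, mesh.z_in, mesh.z_out,
        flow_code, config.p_sub * units.KPA, config.p_sup * units.KPA,
        config.r_sep, vp.rho_f * units.KG_M3, vp.mu_f * units.PA_S,
        vp.chi_min, config.closed_gap_tol,
        config.zero_contact_velocity,
    )
    if fail >= 0:
        raise SimulationBlowupError(
            f"simulation diverged at step {fail} (t = {fail * config.dt:.3f} ms)",
            step=fail)
    series = _decimate(widths, config)
    series.depth = mesh.depth
    series.metadata = {
        "flow_model": config.flow_model, "p_sub_kpa": config.p_sub,
        "r_sep": config.r_sep if config.flow_model != "viscous" else None,
        "m_mm": config.m, "dt_ms": config.dt, "duration_ms": config.duration,
        "transient_discard_ms": config.transient_discard,
    }
    return series


def run_forward_reference(config: SimulationConfig, mesh: LayeredMesh,
                          mat: MaterialParams, n_steps: int | None = None,
                          record_energy: bool = False) -> dict:
    """Pure-Python twin of :func:`run_forward` built from the module-level
    operations, with optional energy bookkeeping.  Returns a dict with the
    width series at every structural step and, if requested, the cumulative
    fluid work, viscous dissipation and contact losses.
    """
    mats, state = _initial_state_and_system(config, mesh, mat)
    if n_steps is None:
        n_steps = int(round(config.duration / config.dt))
    widths = np.empty(n_steps)
    work = diss = contact_loss = 0.0
    max_penetration = -np.inf
    energy0 = mechanical_energy(mats, state) if record_energy else 0.0
    F_prev = None
    shift_field = np.zeros(2 * mesh.n_nodes)
    shift_field[0::2] = state.support_shift
    for istep in range(n_steps):
        ch = extract_channel(mesh, state, n_stations=config.n_stations)
        widths[istep] = ch.gap[ch.i_min]
        p = _station_pressure_profile(config, ch)
        F = pressure_to_forces(ch, p, mesh, p_below=config.p_sub,
                               p_above=config.p_sup)
        new = step(mats, state, F, config.dt)
        if record_energy:
            dd = mats.restrict(new.theta - state.theta)
            vmid = 0.5 * (mats.restrict(new.theta_dot) + mats.restrict(state.theta_dot))
            Fm = 0.5 * (mats.restrict(F) + (mats.restrict(F_prev) if F_prev is not None
                                            else mats.restrict(F)))
            work += float(Fm @ dd)
            diss += float(vmid @ (mats.D @ dd))
            e_before = mechanical_energy(mats, new)
        projected = enforce_contact(mesh, new, config.zero_contact_velocity)
        if record_energy:
            contact_loss += e_before - mechanical_energy(mats, projected)
            F_prev = F
        state = projected
        pen = (state.deformed_coords(mesh)[:, 0] - mesh.contact_plane_x).max()
        max_penetration = max(max_penetration, pen)
        if not np.all(np.isfinite(state.theta)):
            raise SimulationBlowupError(f"reference simulation diverged at step {istep}",
                                        step=istep)
    out = {"widths": widths, "state": state, "mats": mats,
           "max_penetration": max_penetration}
    if record_energy:
        out.update(work=work, dissipation=diss, contact_loss=contact_loss,
                   energy0=energy0, energy=mechanical_energy(mats, state))
    return out
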