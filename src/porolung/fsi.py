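"""Coupled poroelastic flow-structure interaction solver.

Two fields are solved on the same linear-tetrahedron mesh:

* pore pressure ``p`` from the Richards-type storage/Darcy balance

      phi beta dp/dt = div[ k/mu (grad p + rho_air g) ] - d/dt(div u),

* displacement ``u = (u, v, w)`` from the quasi-static poroelastic Navier
  equation

      G lap(u) + G/(1-2 nu) grad(div u) = grad p - f,

  with orthotropic shear modulus: the shear contribution in each coordinate
  plane uses that plane's G (G_xy, G_yz, G_xz); the volumetric term uses the
  element mean G.

Discretization: Galerkin P1 tetrahedra for both fields, lumped storage,
backward-Euler time stepping.  The pressure load on the structure is the
integrated-by-parts Biot form ``int p div(v) dV`` — equivalently a ``-grad p``
body load plus pore pressure acting as traction on the otherwise
traction-free surface — so a uniform pore pressure inflates the body, which
is what makes tissue displacement track the inlet drive in phase.  The
reciprocal dilatation-rate source in the flow equation uses the transpose of
the same coupling matrix.

Each implicit step is solved by a staggered fixed-point loop (flow, then
elasticity, under-relaxed) with fixed-stress stabilization: the flow storage
is augmented by the inverse drained bulk modulus, and the same term applied
to the previous iterate is added to the right-hand side, so the augmentation
cancels at convergence.  Without it the plain drained split diverges here
because air compressibility (phi*beta ~ 1e-5/Pa) is tiny compared to the
skeleton compliance (~1/K_dr ~ 3e-3/Pa).

Both system matrices are constant in time (linear kinematics, fixed mesh) and
are LU-factorized once per simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import MaterialField
from .phantom import ZonedMesh, tet_volumes

logger = logging.getLogger("porolung")

__all__ = [
    "Waveform",
    "SolverConfig",
    "SimulationResult",
    "waveform_value",
    "shape_gradients",
    "darcy_stiffness",
    "storage_diagonals",
    "coupling_matrix",
    "elastic_stiffness",
    "assemble_flow_system",
    "assemble_elastic_system",
    "apply_dirichlet",
    "CoupledSolver",
    "step_coupled",
    "run_simulation",
    "export_result_vtk_series",
    "save_result_npz",
    "load_result_npz",
]

_COMP = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# driving waveform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Waveform:
    """Phasic inlet gauge pressure: amplitude * sin^2(pi (t - phase)/period).

    Non-negative, zero at cycle boundaries, peak = amplitude at mid-cycle
    (t = period/2 for zero phase).  Default period 4 s, one breath.
    """

    amplitude: float = 20.0    # Pa
    period: float = 4.0        # s
    phase_offset: float = 0.0  # s
    shape: str = "sinusoidal"

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be > 0, got {self.period}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.shape != "sinusoidal":
            raise ValueError(f"unknown waveform shape '{self.shape}'")

    def value(self, t) -> float | np.ndarray:
        s = np.sin(np.pi * (np.asarray(t, dtype=float) - self.phase_offset) / self.period)
        out = self.amplitude * s * s
        return float(out) if np.isscalar(t) else out

    @property
    def peak_time(self) -> float:
        """Mid-cycle drive peak time within the first cycle."""
        return self.phase_offset + self.period / 2.0


def waveform_value(w: Waveform, t) -> float | np.ndarray:
    """Inlet gauge pressure at time t (vectorized over t)."""
    return w.value(t)


# ---------------------------------------------------------------------------
# solver configuration and result container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.02                 # s
    n_cycles: int = 3
    coupling_tol: float = 1e-6       # relative update of (p, u) per step
    max_coupling_iters: int = 50
    relaxation: float = 0.7          # under-relaxation factor in (0, 1]
    body_force: tuple[float, float, float] = (0.0, 0.0, 0.0)  # N/m^3
    gravity: tuple[float, float, float] = (0.0, 0.0, 0.0)     # m/s^2
    inlet_patch: str = "inlet"
    fixed_patch: str = "fixed"
    linear_solver_tol: float = 1e-10
    record_stride: int = 1
    #: extra zero-valued displacement constraints: (boundary tag, component),
    #: e.g. (("all", "x"), ("all", "y")) for a 1D consolidation column
    extra_dirichlet: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.coupling_tol <= 0:
            raise ValueError("coupling_tol must be > 0")
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError(f"relaxation must lie in (0, 1], got {self.relaxation}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.max_coupling_iters < 1:
            raise ValueError("max_coupling_iters must be >= 1")
        for tag, comp in self.extra_dirichlet:
            if comp not in _COMP:
                raise ValueError(f"extra_dirichlet component must be x/y/z, got '{comp}'")


@dataclass
class SimulationResult:
    """Recorded state history of a coupled run.

    ``times[0] = 0`` with zero displacement and zero gauge pressure;
    ``pressure`` is (n_times, n_nodes), ``displacement`` (n_times, n_nodes, 3).
    """

    times: np.ndarray
    pressure: np.ndarray
    displacement: np.ndarray
    coupling_iterations: np.ndarray
    waveform: Waveform
    config: SolverConfig

    def __post_init__(self) -> None:
        nt = self.times.shape[0]
        if self.pressure.shape[0] != nt or self.displacement.shape[0] != nt:
            raise ValueError("result arrays inconsistent with time count")
        if self.displacement.shape[2] != 3:
            raise ValueError("displacement must have 3 components")

    @property
    def n_nodes(self) -> int:
        return self.pressure.shape[1]

    def displacement_magnitude(self, node: int) -> np.ndarray:
        return np.linalg.norm(self.displacement[:, node, :], axis=1)


# ---------------------------------------------------------------------------
# element-level quantities and assembly
# ---------------------------------------------------------------------------

def shape_gradients(mesh: ZonedMesh) -> tuple[np.ndarray, np.ndarray]:
    """Constant P1 shape-function gradients b (n_el, 4, 3) and volumes (n_el,)."""
    p = mesh.nodes[mesh.elements]
    edges = p[:, 1:, :] - p[:, :1, :]          # (n_el, 3, 3), rows are edge vectors
    vols = tet_volumes(mesh.nodes, mesh.elements)
    inv = np.linalg.inv(edges)                  # inv maps x-x0 to barycentric (L1,L2,L3)
    b = np.empty((mesh.n_elements, 4, 3))
    b[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    b[:, 0, :] = -b[:, 1:, :].sum(axis=1)
    return b, vols


def darcy_stiffness(mesh: ZonedMesh, mat: MaterialField,
                    b=None, vols=None) -> sp.csr_matrix:
    """Sparse Darcy diffusion matrix: (k/mu) int grad N_i . grad N_j."""
    if b is None:
        b, vols = shape_gradients(mesh)
    coef = mat.permeability / mat.air_viscosity * vols
    k_loc = np.einsum("e,eia,eja->eij", coef, b, b)
    i = np.repeat(mesh.elements, 4, axis=1).ravel()
    j = np.tile(mesh.elements, (1, 4)).ravel()
    return sp.coo_matrix(
        (k_loc.ravel(), (i, j)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()


def storage_diagonals(mesh: ZonedMesh, mat: MaterialField,
                      vols=None) -> tuple[np.ndarray, np.ndarray]:
    """Lumped storage diag (phi*beta) and fixed-stress stabilization diag (1/K_dr)."""
    if vols is None:
        vols = mesh.volumes()
    phi_beta = mat.porosity * mat.air_compressibility
    lam = mat.mean_shear / (1.0 - 2.0 * mat.poisson)
    k_dr = lam + 2.0 * mat.mean_shear / 3.0
    s = np.zeros(mesh.n_nodes)
    st = np.zeros(mesh.n_nodes)
    for col in range(4):
        np.add.at(s, mesh.elements[:, col], vols * phi_beta / 4.0)
        np.add.at(st, mesh.elements[:, col], vols / k_dr / 4.0)
    return s, st


def coupling_matrix(mesh: ZonedMesh, b=None, vols=None) -> sp.csr_matrix:
    """Sparse Q (n_nodes x 3 n_nodes): Q[i, 3j+a] = sum_e V_e/4 * b_{j,a}.

    ``Q @ vel`` is the dilatation-rate source of the flow equation (with a
    minus sign); ``Q.T @ p`` is the pore-pressure load on the structure.
    """
    if b is None:
        b, vols = shape_gradients(mesh)
    blocks = np.einsum("e,eja->eja", vols / 4.0, b)       # (n_el, 4, 3)
    blocks = np.broadcast_to(blocks[:, None, :, :], (mesh.n_elements, 4, 4, 3))
    rows = np.broadcast_to(
        mesh.elements[:, :, None, None], (mesh.n_elements, 4, 4, 3)
    )
    cols = (
        3 * np.broadcast_to(mesh.elements[:, None, :, None],
                            (mesh.n_elements, 4, 4, 3))
        + np.arange(3)[None, None, None, :]
    )
    return sp.coo_matrix(
        (blocks.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.n_nodes, 3 * mesh.n_nodes),
    ).tocsr()


def elastic_stiffness(mesh: ZonedMesh, mat: MaterialField,
                      b=None, vols=None) -> sp.csr_matrix:
    """Orthotropic Navier stiffness on P1 tetrahedra.

    Bilinear form: sum_a sum_d Gw(a,d) d(u_a)/dx_d d(v_a)/dx_d
                 + (Gbar/(1-2 nu)) (div u)(div v),
    with Gw(a,d) the plane modulus for a != d and the element mean modulus on
    the diagonal.
    """
    if b is None:
        b, vols = shape_gradients(mesh)
    n_el = mesh.n_elements
    gbar = mat.mean_shear
    gw = np.empty((n_el, 3, 3))
    gw[:, 0, 0] = gw[:, 1, 1] = gw[:, 2, 2] = gbar
    gw[:, 0, 1] = gw[:, 1, 0] = mat.g_xy
    gw[:, 1, 2] = gw[:, 2, 1] = mat.g_yz
    gw[:, 0, 2] = gw[:, 2, 0] = mat.g_xz
    lam = gbar / (1.0 - 2.0 * mat.poisson)

    k_loc = np.zeros((n_el, 4, 3, 4, 3))
    for a in range(3):
        k_loc[:, :, a, :, a] += np.einsum("e,ed,eid,ejd->eij", vols, gw[:, a, :], b, b)
    k_loc += np.einsum("e,eia,ejc->eiajc", vols * lam, b, b)

    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(n_el, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix(
        (k_loc.reshape(n_el, 144).ravel(), (rows, cols)), shape=(n, n)
    ).tocsr()


def assemble_flow_system(
    mesh: ZonedMesh,
    mat: MaterialField,
    displacement_rate: np.ndarray | None = None,
    gravity=(0.0, 0.0, 0.0),
    dt: float | None = None,
    p_old: np.ndarray | None = None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the pore-pressure system (no Dirichlet rows applied).

    With ``dt=None`` the steady Darcy balance is returned (diffusion vs
    gravity and dilatation-rate sources); with ``dt`` given, the lumped
    backward-Euler storage term and the previous pressure enter.  A spatially
    uniform pressure with zero sources has exactly zero residual.
    """
    mat.check_against(mesh)
    b, vols = shape_gradients(mesh)
    a_mat = darcy_stiffness(mesh, mat, b, vols)
    rhs = np.zeros(mesh.n_nodes)
    g = np.asarray(gravity, dtype=float)
    if np.any(g != 0.0):
        coef = mat.permeability / mat.air_viscosity * mat.air_density * vols
        contrib = np.einsum("e,eia,a->ei", coef, b, g)
        np.add.at(rhs, mesh.elements.ravel(), -contrib.ravel())
    if displacement_rate is not None:
        vel = np.asarray(displacement_rate, dtype=float).reshape(-1)
        if vel.shape[0] != 3 * mesh.n_nodes:
            raise ValueError("displacement_rate must supply 3 components per node")
        rhs -= coupling_matrix(mesh, b, vols) @ vel
    if dt is not None:
        s, _ = storage_diagonals(mesh, mat, vols)
        a_mat = a_mat + sp.diags(s / dt)
        if p_old is not None:
            rhs += s / dt * np.asarray(p_old, dtype=float)
    return a_mat, rhs


def assemble_elastic_system(
    mesh: ZonedMesh,
    mat: MaterialField,
    pressure: np.ndarray,
    f=(0.0, 0.0, 0.0),
    fixed_nodes: np.ndarray | None = None,
    apply_bc: bool = True,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the quasi-static orthotropic Navier system for (u, v, w).

    Load: pore-pressure coupling ``Q.T @ p`` (the by-parts Biot form) plus the
    body force ``f``.  With ``apply_bc`` the fixed-patch rows are replaced by
    homogeneous Dirichlet conditions; an empty fixed patch is rejected because
    the operator would retain rigid-body modes.
    """
    mat.check_against(mesh)
    if np.any(mat.poisson >= 0.5):
        raise ValueError("Poisson ratio 0.5 is not admissible (1/(1-2nu) singular)")
    b, vols = shape_gradients(mesh)
    k_mat = elastic_stiffness(mesh, mat, b, vols)
    rhs = coupling_matrix(mesh, b, vols).T @ np.asarray(pressure, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f != 0.0):
        contrib = np.einsum("e,a->ea", vols / 4.0, f)   # int N_i f dV per node
        for col in range(4):
            for a in range(3):
                np.add.at(rhs, 3 * mesh.elements[:, col] + a, contrib[:, a])
    if apply_bc:
        if fixed_nodes is None:
            fixed_nodes = mesh.boundary_tags.get("fixed", np.empty(0, dtype=int))
        fixed_nodes = np.asarray(fixed_nodes, dtype=int)
        if fixed_nodes.size == 0:
            raise ValueError("fixed patch is empty: elastic operator would be singular")
        dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
        k_mat, rhs = apply_dirichlet(k_mat, rhs, dofs, np.zeros(dofs.size))
    return k_mat, rhs


def apply_dirichlet(a_mat: sp.csr_matrix, rhs: np.ndarray,
                    dofs: np.ndarray, values: np.ndarray):
    """Impose a[dof] = value by row replacement (returns modified copies)."""
    dofs = np.asarray(dofs, dtype=int)
    a_mat = a_mat.tolil(copy=True)
    rhs = rhs.copy()
    rhs -= a_mat[:, dofs].tocsr() @ np.asarray(values, dtype=float)
    a_mat[dofs, :] = 0.0
    a_mat[:, dofs] = 0.0
    for d, v in zip(dofs, values):
        a_mat[d, d] = 1.0
        rhs[d] = v
    return a_mat.tocsr(), rhs


# ---------------------------------------------------------------------------
# coupled time stepping
# ---------------------------------------------------------------------------

class CoupledSolver:
    """Pre-assembled, pre-factorized staggered solver for one (mesh, mat, cfg).

    Both fields are linear with time-independent operators, so the reduced
    (Dirichlet-eliminated) flow and elasticity matrices are LU-factorized once
    and each coupling iteration costs two triangular solves.
    """

    def __init__(self, mesh: ZonedMesh, mat: MaterialField,
                 waveform: Waveform, cfg: SolverConfig):
        mat.check_against(mesh)
        self.mesh, self.mat, self.waveform, self.cfg = mesh, mat, waveform, cfg
        n = mesh.n_nodes

        b, vols = shape_gradients(mesh)
        self.q_mat = coupling_matrix(mesh, b, vols)
        self.s_diag, self.st_diag = storage_diagonals(mesh, mat, vols)
        k_darcy = darcy_stiffness(mesh, mat, b, vols)

        inlet = mesh.boundary_tags.get(cfg.inlet_patch, np.empty(0, dtype=int))
        if inlet.size == 0:
            raise ValueError(f"inlet patch '{cfg.inlet_patch}' is empty or missing")
        self.inlet = np.asarray(inlet, dtype=int)
        self.p_free = np.setdiff1d(np.arange(n), self.inlet)

        a_flow = sp.diags((self.s_diag + self.st_diag) / cfg.dt) + k_darcy
        a_flow = a_flow.tocsr()
        self._a_flow_fd = a_flow[self.p_free][:, self.inlet]
        self._flow_lu = splu(a_flow[self.p_free][:, self.p_free].tocsc())

        # gravity source (constant in time)
        self.rhs_grav = np.zeros(n)
        g = np.asarray(cfg.gravity, dtype=float)
        if np.any(g != 0.0):
            coef = mat.permeability / mat.air_viscosity * mat.air_density * vols
            contrib = np.einsum("e,eia,a->ei", coef, b, g)
            np.add.at(self.rhs_grav, mesh.elements.ravel(), -contrib.ravel())

        # elasticity: fixed patch + extra component-wise constraints
        fixed = mesh.boundary_tags.get(cfg.fixed_patch, np.empty(0, dtype=int))
        fixed = np.asarray(fixed, dtype=int)
        if fixed.size == 0:
            raise ValueError(f"fixed patch '{cfg.fixed_patch}' is empty or missing")
        dofs = [(3 * fixed[:, None] + np.arange(3)).ravel()]
        for tag, comp in cfg.extra_dirichlet:
            nodes = mesh.boundary_tags.get(tag)
            if nodes is None or nodes.size == 0:
                raise ValueError(f"extra_dirichlet tag '{tag}' is empty or missing")
            dofs.append(3 * np.asarray(nodes, dtype=int) + _COMP[comp])
        self.u_fixed = np.unique(np.concatenate(dofs))
        self.u_free = np.setdiff1d(np.arange(3 * n), self.u_fixed)

        k_el = elastic_stiffness(mesh, mat, b, vols)
        self._el_lu = splu(k_el[self.u_free][:, self.u_free].tocsc())

        self.f_body = np.zeros(3 * n)
        f = np.asarray(cfg.body_force, dtype=float)
        if np.any(f != 0.0):
            contrib = np.einsum("e,a->ea", vols / 4.0, f)
            for col in range(4):
                for a in range(3):
                    np.add.at(self.f_body, 3 * mesh.elements[:, col] + a, contrib[:, a])

    # -- single-field solves ----------------------------------------------
    def _solve_flow(self, p_old, p_iter, vel, p_inlet: float) -> np.ndarray:
        rhs = (
            self.s_diag / self.cfg.dt * p_old
            + self.st_diag / self.cfg.dt * p_iter
            - self.q_mat @ vel
            + self.rhs_grav
        )
        p = np.empty(self.mesh.n_nodes)
        p[self.inlet] = p_inlet
        b_f = rhs[self.p_free] - self._a_flow_fd @ p[self.inlet]
        p[self.p_free] = self._flow_lu.solve(b_f)
        return p

    def _solve_elastic(self, p: np.ndarray) -> np.ndarray:
        rhs = self.q_mat.T @ p + self.f_body
        u = np.zeros(3 * self.mesh.n_nodes)
        u[self.u_free] = self._el_lu.solve(rhs[self.u_free])
        return u

    # -- coupled step ------------------------------------------------------
    def step(self, p_old: np.ndarray, u_old: np.ndarray,
             t_new: float) -> tuple[np.ndarray, np.ndarray, int]:
        """One backward-Euler step of the coupled system to time ``t_new``."""
        cfg = self.cfg
        p_inlet = self.waveform.value(t_new)
        p_iter, u_iter = p_old, u_old
        n_it = 0
        for n_it in range(1, cfg.max_coupling_iters + 1):
            vel = (u_iter - u_old) / cfg.dt
            p_new = self._solve_flow(p_old, p_iter, vel, p_inlet)
            u_solved = self._solve_elastic(p_new)
            u_new = u_iter + cfg.relaxation * (u_solved - u_iter)
            du = np.linalg.norm(u_new - u_iter)
            dp = np.linalg.norm(p_new - p_iter)
            un = np.linalg.norm(u_new)
            pn = np.linalg.norm(p_new)
            converged = (du <= cfg.coupling_tol * max(un, 1e-300)
                         and dp <= cfg.coupling_tol * max(pn, 1e-300))
            p_iter, u_iter = p_new, u_new
            if converged:
                break
        else:
            logger.warning(
                "coupling loop not converged at t=%.4f after %d iterations "
                "(du/|u|=%.2e)", t_new, cfg.max_coupling_iters,
                du / max(un, 1e-300),
            )
        return p_iter, u_iter, n_it


def step_coupled(state, mesh: ZonedMesh, mat: MaterialField,
                 w: Waveform, cfg: SolverConfig, t: float):
    """Advance (p, u) from time t to t + dt; returns (p, u, iterations).

    Convenience wrapper that builds a solver on the fly; prefer CoupledSolver
    (or run_simulation) for multi-step runs, which factorize once.
    """
    p_old, u_old = state
    solver = CoupledSolver(mesh, mat, w, cfg)
    return solver.step(np.asarray(p_old, float), np.asarray(u_old, float).reshape(-1),
                       t + cfg.dt)


def run_simulation(mesh: ZonedMesh, mat: MaterialField,
                   w: Waveform, cfg: SolverConfig) -> SimulationResult:
    """Integrate ``n_cycles`` breathing cycles from a zero initial state.

    Deterministic for fixed inputs.  Rejects dt > period/20 (waveform
    under-resolution).  States are recorded every ``record_stride`` steps
    (the initial state and the final step always included).
    """
    if cfg.dt > w.period / 20.0:
        raise ValueError(
            f"dt={cfg.dt} under-resolves the {w.period} s waveform (need <= period/20)"
        )
    solver = CoupledSolver(mesh, mat, w, cfg)
    n_steps = int(round(cfg.n_cycles * w.period / cfg.dt))
    n = mesh.n_nodes

    times = [0.0]
    pressures = [np.zeros(n)]
    displacements = [np.zeros((n, 3))]
    iters = [0]
    p = np.zeros(n)
    u = np.zeros(3 * n)
    for k in range(1, n_steps + 1):
        t_new = k * cfg.dt
        p, u, n_it = solver.step(p, u, t_new)
        if k % cfg.record_stride == 0 or k == n_steps:
            times.append(t_new)
            pressures.append(p.copy())
            displacements.append(u.reshape(n, 3).copy())
            iters.append(n_it)
    logger.info(
        "simulation done: %d steps, mean coupling iterations %.1f",
        n_steps, float(np.mean(iters[1:])) if n_steps else 0.0,
    )
    return SimulationResult(
        times=np.asarray(times),
        pressure=np.asarray(pressures),
        displacement=np.asarray(displacements),
        coupling_iterations=np.asarray(iters),
        waveform=w,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# results export
# ---------------------------------------------------------------------------

def export_result_vtk_series(mesh: ZonedMesh, result: SimulationResult,
                             out_dir, stride: int = 1, prefix: str = "state") -> list[Path]:
    """Write one legacy-VTK file per recorded time (pressure + displacement)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ti in range(0, result.times.shape[0], stride):
        path = out_dir / f"{prefix}_{ti:05d}.vtk"
        lines = [
            "# vtk DataFile Version 3.0",
            f"porolung state t={result.times[ti]:.6f}",
            "ASCII",
            "DATASET UNSTRUCTURED_GRID",
            f"POINTS {mesh.n_nodes} double",
        ]
        lines += [" ".join(f"{v:.9g}" for v in row) for row in mesh.nodes]
        lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
        lines += ["4 " + " ".join(str(int(v)) for v in tet) for tet in mesh.elements]
        lines.append(f"CELL_TYPES {mesh.n_elements}")
        lines += ["10"] * mesh.n_elements
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("SCALARS pressure double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in result.pressure[ti]]
        lines.append("VECTORS displacement double")
        lines += [" ".join(f"{v:.9g}" for v in row) for row in result.displacement[ti]]
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def save_result_npz(result: SimulationResult, path) -> None:
    """Compact state dump consumed by the kinematics/analyze entry points."""
    np.savez_compressed(
        path,
        times=result.times,
        pressure=result.pressure,
        displacement=result.displacement,
        coupling_iterations=result.coupling_iterations,
        waveform_amplitude=result.waveform.amplitude,
        waveform_period=result.waveform.period,
        waveform_phase=result.waveform.phase_offset,
        dt=result.config.dt,
        n_cycles=result.config.n_cycles,
    )


def load_result_npz(path) -> SimulationResult:
    with np.load(path) as data:
        w = Waveform(
            amplitude=float(data["waveform_amplitude"]),
            period=float(data["waveform_period"]),
            phase_offset=float(data["waveform_phase"]),
        )
        cfg = SolverConfig(dt=float(data["dt"]), n_cycles=int(data["n_cycles"]))
        return SimulationResult(
            times=data["times"],
            pressure=data["pressure"],
            displacement=data["displacement"],
            coupling_iterations=data["coupling_iterations"],
            waveform=w,
            config=cfg,
        )
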