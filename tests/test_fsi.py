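"""Solver verification: waveform, assembly identities, FEM patch test,
uniform-inflation closed form, 1D consolidation oracle, and the coupled
run's consistency properties (zero drive, linearity, refinement)."""

from dataclasses import dataclass

import numpy as np
import pytest
import scipy.sparse.linalg as spla

import porolung as pl
from porolung.fsi import (apply_dirichlet, assemble_elastic_system,
                          assemble_flow_system, darcy_stiffness)
from porolung.materials import MaterialField


def uniform_material(n, ym=178.0, poisson=0.4, porosity=0.5, k=1e-7):
    g = ym / (2.0 * (1.0 + poisson))
    return MaterialField(
        g_xy=np.full(n, g), g_yz=np.full(n, g), g_xz=np.full(n, g),
        poisson=np.full(n, poisson), porosity=np.full(n, porosity),
        permeability=np.full(n, k), tissue_density=np.full(n, 700.0),
    )


@dataclass(frozen=True)
class StepDrive(pl.Waveform):
    """Constant (step) inlet pressure for consolidation tests."""

    def value(self, t):
        return self.amplitude if np.isscalar(t) else np.full_like(
            np.asarray(t, float), self.amplitude
        )


class TestWaveform:
    def test_reference_points(self):
        w = pl.Waveform(amplitude=300.0, period=4.0)
        assert pl.waveform_value(w, 0.0) == 0.0
        assert pl.waveform_value(w, 2.0) == pytest.approx(300.0, rel=1e-14)
        assert pl.waveform_value(w, 4.0) == pytest.approx(0.0, abs=1e-9)

    def test_periodic_and_nonnegative(self):
        w = pl.Waveform(amplitude=20.0, period=4.0, phase_offset=0.3)
        t = np.linspace(0, 12, 241)
        assert np.allclose(w.value(t), w.value(t + 4.0), atol=1e-12)
        assert np.all(w.value(t) >= 0.0)
        assert w.value(w.peak_time) == pytest.approx(20.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            pl.Waveform(period=0.0)
        with pytest.raises(ValueError):
            pl.Waveform(amplitude=-1.0)
        with pytest.raises(ValueError):
            pl.Waveform(shape="square")


class TestFlowAssembly:
    def test_uniform_pressure_in_kernel(self):
        mesh = pl.build_box_mesh((0.1, 0.1, 0.1), (2, 2, 2))
        mat = uniform_material(mesh.n_elements)
        a_mat, rhs = assemble_flow_system(mesh, mat)  # steady, no sources
        resid = a_mat @ np.full(mesh.n_nodes, 37.0) - rhs
        scale = np.abs(a_mat).sum(axis=1).max() * 37.0
        assert np.max(np.abs(resid)) <= 1e-12 * scale

    def test_steady_bar_linear_profile(self):
        """Fixed pressure at both bar ends at steady state: interior nodal
        pressure is linear in position (constant discrete Darcy flux)."""
        mesh = pl.build_box_mesh((0.2, 0.02, 0.02), (8, 1, 1))
        mat = uniform_material(mesh.n_elements)
        a_mat, rhs = assemble_flow_system(mesh, mat)
        d0 = mesh.boundary_tags["x0"]
        d1 = mesh.boundary_tags["x1"]
        dofs = np.concatenate([d0, d1])
        vals = np.concatenate([np.zeros(d0.size), np.full(d1.size, 5.0)])
        a_bc, b_bc = apply_dirichlet(a_mat, rhs, dofs, vals)
        p = spla.spsolve(a_bc.tocsc(), b_bc)
        expected = 5.0 * mesh.nodes[:, 0] / 0.2
        assert np.allclose(p, expected, atol=1e-9)


class TestElasticAssembly:
    def test_patch_test_linear_field_exact(self):
        """Standard FEM patch test: linear displacement prescribed on the
        boundary of a homogeneous box is reproduced at interior nodes to
        machine precision."""
        mesh = pl.build_box_mesh((0.1, 0.08, 0.06), (3, 3, 3))
        mat = uniform_material(mesh.n_elements)
        a_grad = np.array([[1e-3, 2e-4, -1e-4],
                           [0.0, -5e-4, 3e-4],
                           [2e-4, 1e-4, 8e-4]])
        exact = mesh.nodes @ a_grad.T + np.array([1e-4, -2e-4, 5e-5])
        k_mat, rhs = assemble_elastic_system(
            mesh, mat, np.zeros(mesh.n_nodes), apply_bc=False
        )
        bnodes = mesh.surface_nodes()
        dofs = (3 * bnodes[:, None] + np.arange(3)).ravel()
        k_bc, b_bc = apply_dirichlet(k_mat, rhs, dofs, exact[bnodes].ravel())
        u = spla.spsolve(k_bc.tocsc(), b_bc).reshape(-1, 3)
        assert np.allclose(u, exact, atol=1e-12 * np.abs(exact).max())

    def test_uniform_pressure_exact_dilation(self, tiny_mesh):
        """A uniform pore pressure with total-stress-free surface produces the
        exact homogeneous dilation u = alpha x, alpha = p/(G + 3 lambda) —
        linear in x, hence reproduced by P1 elements to machine precision."""
        mesh = tiny_mesh
        p0 = 10.0
        ym, nu = 178.0, 0.4
        g = ym / (2 * (1 + nu))
        lam = g / (1 - 2 * nu)
        alpha = p0 / (g + 3 * lam)
        exact = alpha * mesh.nodes
        k_mat, rhs = assemble_elastic_system(
            mesh, uniform_material(mesh.n_elements, ym=ym, poisson=nu),
            np.full(mesh.n_nodes, p0), apply_bc=False,
        )
        # pin translations/rotations with exact values at 4 nodes
        pins = np.unique(
            [0, mesh.n_nodes // 3, 2 * mesh.n_nodes // 3, mesh.n_nodes - 1]
        )
        dofs = (3 * pins[:, None] + np.arange(3)).ravel()
        k_bc, b_bc = apply_dirichlet(k_mat, rhs, dofs, exact[pins].ravel())
        u = spla.spsolve(k_bc.tocsc(), b_bc).reshape(-1, 3)
        assert np.allclose(u, exact, atol=1e-9 * np.abs(exact).max())
        # displacement is radial: outward expansion everywhere
        assert alpha > 0

    def test_empty_fixed_patch_rejected(self):
        mesh = pl.build_box_mesh((0.1, 0.1, 0.1), (2, 2, 2))
        mesh.boundary_tags.pop("all")
        with pytest.raises(ValueError, match="fixed patch"):
            assemble_elastic_system(
                mesh, uniform_material(mesh.n_elements), np.zeros(mesh.n_nodes)
            )


def _column_mesh(nz, h=0.2):
    mesh = pl.build_box_mesh((0.02, 0.02, h), (1, 1, nz))
    tags = mesh.boundary_tags
    tags["inlet"] = tags["z1"]   # drained, pressurized top
    tags["fixed"] = tags["z0"]   # anchored, impermeable bottom
    return mesh


def _terzaghi_series(z, t, h, c, p0, n_terms=200):
    """Pressure-driven 1D consolidation: column 0<z<h, p(h)=p0 step at t=0,
    no flux at z=0, p(z,0)=0.  Independent closed-form series oracle."""
    acc = np.zeros_like(z, dtype=float)
    for n in range(n_terms):
        m = 2 * n + 1
        acc += ((-1) ** n * 4.0 / (m * np.pi)
                * np.cos(m * np.pi * z / (2 * h))
                * np.exp(-(m * np.pi / (2 * h)) ** 2 * c * t))
    return p0 * (1.0 - acc)


class TestCoupledStep:
    def test_zero_drive_exact_nullity(self, tiny_mesh):
        mat = pl.generate_elasticity_field(
            tiny_mesh, pl.ElasticityFieldSpec(mode="isotropic")
        )
        res = pl.run_simulation(
            tiny_mesh, mat, pl.Waveform(amplitude=0.0), pl.SolverConfig(n_cycles=1)
        )
        assert np.all(res.pressure == 0.0)
        assert np.all(res.displacement == 0.0)

    def test_linearity_in_drive_amplitude(self, tiny_mesh):
        mat = pl.generate_elasticity_field(
            tiny_mesh, pl.ElasticityFieldSpec(mode="isotropic")
        )
        cfg = pl.SolverConfig(n_cycles=1, coupling_tol=1e-9)
        r1 = pl.run_simulation(tiny_mesh, mat, pl.Waveform(amplitude=10.0), cfg)
        r2 = pl.run_simulation(tiny_mesh, mat, pl.Waveform(amplitude=20.0), cfg)
        scale = np.abs(r2.displacement).max()
        assert np.abs(r2.displacement - 2.0 * r1.displacement).max() <= 1e-5 * scale

    def test_coupling_tolerance_self_consistency(self, tiny_mesh):
        mat = pl.generate_elasticity_field(
            tiny_mesh, pl.ElasticityFieldSpec(mode="isotropic")
        )
        loose = pl.run_simulation(
            tiny_mesh, mat, pl.Waveform(), pl.SolverConfig(n_cycles=1, coupling_tol=1e-5)
        )
        tight = pl.run_simulation(
            tiny_mesh, mat, pl.Waveform(), pl.SolverConfig(n_cycles=1, coupling_tol=1e-7)
        )
        scale = np.abs(tight.displacement).max()
        assert np.abs(loose.displacement - tight.displacement).max() <= 1e-3 * scale

    def test_step_coupled_matches_solver_class(self, tiny_mesh):
        mat = pl.generate_elasticity_field(
            tiny_mesh, pl.ElasticityFieldSpec(mode="isotropic")
        )
        cfg = pl.SolverConfig(n_cycles=1)
        w = pl.Waveform()
        n = tiny_mesh.n_nodes
        p, u, iters = pl.step_coupled(
            (np.zeros(n), np.zeros(3 * n)), tiny_mesh, mat, w, cfg, 0.0
        )
        solver = pl.CoupledSolver(tiny_mesh, mat, w, cfg)
        p2, u2, _ = solver.step(np.zeros(n), np.zeros(3 * n), cfg.dt)
        assert np.array_equal(p, p2)
        assert np.array_equal(u, u2)
        assert iters >= 1

    def test_dt_underresolution_rejected(self, tiny_mesh):
        mat = pl.generate_elasticity_field(
            tiny_mesh, pl.ElasticityFieldSpec(mode="isotropic")
        )
        with pytest.raises(ValueError, match="under-resolve"):
            pl.run_simulation(
                tiny_mesh, mat, pl.Waveform(period=4.0), pl.SolverConfig(dt=0.5)
            )

    @pytest.mark.parametrize("nz,tol", [(8, 0.08), (16, 0.04)])
    def test_terzaghi_consolidation_oracle(self, nz, tol):
        """Coupled step response of a laterally constrained column against the
        independent 1D consolidation series; the error bound tightens with
        mesh refinement."""
        h = 0.2
        mesh = _column_mesh(nz, h)
        ym, nu, phi, k = 178.0, 0.4, 0.5, 1e-7
        mat = uniform_material(mesh.n_elements, ym=ym, poisson=nu, porosity=phi, k=k)
        g = ym / (2 * (1 + nu))
        m_conf = 2.0 * g * (1 - nu) / (1 - 2 * nu)
        c = (k / mat.air_viscosity) / (phi * mat.air_compressibility + 1.0 / m_conf)
        p0 = 10.0
        cfg = pl.SolverConfig(
            dt=2e-4, n_cycles=1, fixed_patch="fixed", inlet_patch="inlet",
            extra_dirichlet=(("all", "x"), ("all", "y")), coupling_tol=1e-8,
        )
        drive = StepDrive(amplitude=p0, period=0.01)
        res = pl.run_simulation(mesh, mat, drive, cfg)
        t_end = res.times[-1]
        expected = _terzaghi_series(mesh.nodes[:, 2], t_end, h, c, p0)
        err = np.abs(res.pressure[-1] - expected).max() / p0
        assert err <= tol

    def test_time_step_refinement_insensitivity(self, phantom_mesh, iso_material,
                                                landmarks, waveform):
        """Halving dt changes landmark peak displacements by a small relative
        amount (first-order implicit scheme, 200 steps/cycle baseline)."""
        base = pl.run_simulation(
            phantom_mesh, iso_material, waveform, pl.SolverConfig(n_cycles=2, dt=0.02)
        )
        fine = pl.run_simulation(
            phantom_mesh, iso_material, waveform, pl.SolverConfig(n_cycles=2, dt=0.01)
        )
        for lm in landmarks:
            pk_base = base.displacement_magnitude(lm.node_index).max()
            pk_fine = fine.displacement_magnitude(lm.node_index).max()
            assert abs(pk_base - pk_fine) <= 0.05 * pk_fine

    def test_grid_refinement_insensitivity(self, waveform):
        """Peak landmark displacement is essentially independent of grid
        resolution beyond the default sizing."""
        peaks = []
        for scale in (1.0, 0.75):
            spec = pl.PhantomSpec(
                target_edge_length=tuple(scale * h for h in (0.018, 0.024, 0.030))
            )
            mesh = pl.build_multizone_phantom(spec, seed=0)
            mat = pl.generate_elasticity_field(
                mesh, pl.ElasticityFieldSpec(mode="isotropic")
            )
            res = pl.run_simulation(mesh, mat, waveform, pl.SolverConfig(n_cycles=2))
            lms = pl.default_landmarks(mesh)
            apex = next(lm for lm in lms if lm.id == "A")
            peaks.append(res.displacement_magnitude(apex.node_index).max())
        assert abs(peaks[1] - peaks[0]) <= 0.15 * peaks[1]

    def test_permeability_insensitivity_over_study_range(
        self, phantom_mesh, iso_material, landmarks, waveform
    ):
        """Scaling the normalized permeability across 0.01-0.1 changes peak
        landmark displacement only weakly (quasi-static pressure filling)."""
        peaks = {}
        for scale in (0.01, 0.1):
            mat = pl.scaled_permeability(iso_material, scale)
            res = pl.run_simulation(
                phantom_mesh, mat, waveform, pl.SolverConfig(n_cycles=2)
            )
            apex = next(lm for lm in landmarks if lm.id == "A")
            peaks[scale] = res.displacement_magnitude(apex.node_index).max()
        rel = abs(peaks[0.1] - peaks[0.01]) / peaks[0.1]
        assert rel <= 0.05
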