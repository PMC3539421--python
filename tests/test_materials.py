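"""Material-field construction: shear-modulus relation, branch-radius
permeability rule, and the synthetic Young's-modulus generator statistics."""

import numpy as np
import pandas as pd
import pytest

import porolung as pl
from porolung.materials import (airway_channel_permeability, scalar_ym,
                                shear_modulus)


class TestShearModulus:
    def test_reference_values(self):
        # independent arithmetic: YM / (2 (1 + nu))
        assert shear_modulus(178.0, 0.4) == pytest.approx(178.0 / 2.8, rel=1e-14)
        assert shear_modulus(500.0, 0.4) == pytest.approx(500.0 / 2.8, rel=1e-14)
        assert shear_modulus(0.0, 0.4) == 0.0

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError, match="Poisson"):
            shear_modulus(178.0, 0.5)
        with pytest.raises(ValueError):
            shear_modulus(-1.0, 0.4)


class TestPermeabilityProfile:
    def test_single_zone_value(self):
        mesh = pl.build_box_mesh((0.1, 0.1, 0.1), (2, 2, 2))
        k = pl.permeability_profile(mesh, [0.02], porosity=0.5)
        assert np.all(k == pytest.approx(0.5 * 0.02**2 / 8.0, rel=1e-14))  # 2.5e-5

    def test_zone_ratio_follows_radius_squared(self, phantom_mesh):
        k = pl.permeability_profile(phantom_mesh, [4e-3, 2e-3, 1e-3], porosity=0.5)
        kz = [k[phantom_mesh.zone_label == z][0] for z in (1, 2, 3)]
        assert kz[0] / kz[2] == pytest.approx(16.0, rel=1e-12)
        assert kz[1] / kz[2] == pytest.approx(4.0, rel=1e-12)
        # strictly decreasing core -> periphery
        assert kz[0] > kz[1] > kz[2]

    def test_invalid_inputs_rejected(self, phantom_mesh):
        with pytest.raises(ValueError):
            pl.permeability_profile(phantom_mesh, [4e-3, 2e-3, 0.0])
        with pytest.raises(ValueError, match="decrease"):
            pl.permeability_profile(phantom_mesh, [1e-3, 2e-3, 4e-3])
        with pytest.raises(ValueError, match="per zone"):
            pl.permeability_profile(phantom_mesh, [4e-3, 2e-3])
        with pytest.raises(ValueError, match="porosity"):
            pl.permeability_profile(phantom_mesh, [4e-3, 2e-3, 1e-3], porosity=1.5)

    def test_airway_channel_gets_core_permeability(self, phantom_mesh):
        base = pl.permeability_profile(phantom_mesh, [4e-3, 1.5e-3, 0.5e-3], 0.5)
        k = airway_channel_permeability(phantom_mesh, base, channel_radius=0.02)
        # channel elements upgraded to the maximum (core) permeability,
        # including some originally peripheral ones near the inlet
        changed = k != base
        assert np.all(k[changed] == base.max())
        assert np.any(phantom_mesh.zone_label[changed] == 3)


class TestElasticityGenerator:
    def test_isotropic_reference_case(self, phantom_mesh, iso_material):
        g_ref = 178.0 / 2.8
        for plane in (iso_material.g_xy, iso_material.g_yz, iso_material.g_xz):
            assert np.allclose(plane, g_ref, rtol=1e-14)
        assert np.allclose(iso_material.poisson, 0.4)
        assert np.allclose(iso_material.tissue_density, 700.0)

    def test_synthetic_statistics(self, phantom_mesh, aniso_material):
        ym = scalar_ym(aniso_material)
        vols = phantom_mesh.volumes()
        mean = float(np.average(ym, weights=vols))
        assert ym.min() >= 10.0 - 1e-9
        assert ym.max() <= 500.0 + 1e-9
        assert abs(mean - 178.0) <= 0.01 * 178.0

    def test_determinism_and_seed_sensitivity(self, phantom_mesh):
        spec = pl.ElasticityFieldSpec(mode="anisotropic_synthetic", seed=3)
        a = pl.generate_elasticity_field(phantom_mesh, spec)
        b = pl.generate_elasticity_field(phantom_mesh, spec)
        assert np.array_equal(a.g_xy, b.g_xy)
        c = pl.generate_elasticity_field(
            phantom_mesh, pl.ElasticityFieldSpec(mode="anisotropic_synthetic", seed=4)
        )
        assert not np.array_equal(a.g_xy, c.g_xy)

    def test_unit_axis_contrast_reduces_to_heterogeneous_isotropic(self, phantom_mesh):
        spec = pl.ElasticityFieldSpec(
            mode="anisotropic_synthetic", seed=0, axis_contrast=(1.0, 1.0, 1.0)
        )
        mat = pl.generate_elasticity_field(phantom_mesh, spec)
        assert np.array_equal(mat.g_xy, mat.g_yz)
        assert np.array_equal(mat.g_xy, mat.g_xz)

    def test_tumor_inclusion_pinned_rigid(self, phantom_mesh):
        spec = pl.ElasticityFieldSpec(
            mode="anisotropic_synthetic", seed=0,
            tumor_center=(0.0, 0.0, 0.0), tumor_radius=0.03,
        )
        mat = pl.generate_elasticity_field(phantom_mesh, spec)
        d = np.linalg.norm(phantom_mesh.centroids(), axis=1)
        inside = d <= 0.03
        assert inside.any()
        assert np.allclose(scalar_ym(mat)[inside], 500.0, rtol=1e-12)

    def test_correlation_length_increases_spatial_autocorrelation(self, phantom_mesh):
        """Neighbor-pair correlation of the field grows monotonically with the
        requested correlation length (averaged over seeds)."""
        neigh = phantom_mesh.element_neighbors()
        pairs = np.array(
            [(i, j) for i, nbs in enumerate(neigh) for j in nbs if j > i]
        )

        def neighbor_corr(length, seed):
            spec = pl.ElasticityFieldSpec(
                mode="anisotropic_synthetic", seed=seed, correlation_length=length
            )
            ym = scalar_ym(pl.generate_elasticity_field(phantom_mesh, spec))
            return np.corrcoef(ym[pairs[:, 0]], ym[pairs[:, 1]])[0, 1]

        for seed in (0, 1):
            corrs = [neighbor_corr(length, seed) for length in (0.0, 0.02, 0.06)]
            assert corrs[0] < corrs[1] < corrs[2]
            assert corrs[0] < 0.3  # zero length: (clipped) white noise

    def test_file_mode_roundtrip_and_errors(self, tiny_mesh, tmp_path):
        n = tiny_mesh.n_elements
        ym = np.linspace(20.0, 400.0, n)
        path = tmp_path / "ym.csv"
        pd.DataFrame({"element_id": np.arange(n), "ym": ym}).to_csv(path, index=False)
        spec = pl.ElasticityFieldSpec(mode="anisotropic_file", file_path=str(path))
        mat = pl.generate_elasticity_field(tiny_mesh, spec)
        assert np.allclose(scalar_ym(mat), ym, rtol=1e-12)

        short = tmp_path / "short.csv"
        pd.DataFrame({"element_id": np.arange(n - 1), "ym": ym[:-1]}).to_csv(
            short, index=False
        )
        with pytest.raises(ValueError, match="rows"):
            pl.generate_elasticity_field(
                tiny_mesh,
                pl.ElasticityFieldSpec(mode="anisotropic_file", file_path=str(short)),
            )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            pl.ElasticityFieldSpec(ym_min=200.0, ym_mean=178.0, ym_max=500.0)
        with pytest.raises(ValueError):
            pl.ElasticityFieldSpec(axis_contrast=(1.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            pl.ElasticityFieldSpec(mode="nonsense")

    def test_permeability_scale_helper(self, iso_material):
        scaled = pl.scaled_permeability(iso_material, 0.1)
        assert np.allclose(
            scaled.permeability, iso_material.permeability * (0.1 / 0.05), rtol=1e-14
        )
        with pytest.raises(ValueError):
            pl.scaled_permeability(iso_material, 0.0)
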