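"""Poroelastic material fields for the lung phantom.

Per-element properties: orthotropic shear moduli (one per coordinate plane,
G = YM / [2(1+nu)]), Poisson ratio, porosity, permeability and tissue
density, plus the scalar air properties (density, viscosity, isothermal
compressibility) entering the pore-pressure equation.

The permeability profile follows the branch-radius rule K = phi R^2 / 8:
zone-wise branch radii decrease from the conductive core to the periphery,
so permeability falls off as R^2 outward.  The elasticity field is either
homogeneous-isotropic (the reference linear case, YM = 178 Pa) or a seeded
smooth heterogeneous field with prescribed min / max / volume-averaged mean
(10 / 500 / 178 Pa) standing in for an image-derived Young's-modulus map;
plane-wise moduli are the scalar field times an axis-contrast triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phantom import ZonedMesh

logger = logging.getLogger("porolung")

__all__ = [
    "AIR_DENSITY",
    "AIR_VISCOSITY",
    "AIR_COMPRESSIBILITY",
    "LUNG_TISSUE_DENSITY",
    "DEFAULT_POISSON",
    "DEFAULT_POROSITY",
    "DEFAULT_YM_MEAN",
    "DEFAULT_BRANCH_RADII",
    "DEFAULT_PERMEABILITY_SCALE",
    "MaterialField",
    "ElasticityFieldSpec",
    "shear_modulus",
    "permeability_profile",
    "default_branch_radii",
    "airway_channel_permeability",
    "generate_elasticity_field",
    "scaled_permeability",
]

# Air at ambient conditions (SI); configurable via MaterialField fields.
AIR_DENSITY = 1.2            # kg/m^3
AIR_VISCOSITY = 1.8e-5       # Pa s
AIR_COMPRESSIBILITY = 1.0 / 101325.0  # 1/Pa (isothermal, ideal gas at 1 atm)

LUNG_TISSUE_DENSITY = 700.0  # kg/m^3
DEFAULT_POISSON = 0.4
DEFAULT_POROSITY = 0.5
DEFAULT_YM_MEAN = 178.0      # Pa, lung-wide average Young's modulus
DEFAULT_YM_MIN = 10.0        # Pa
DEFAULT_YM_MAX = 500.0       # Pa

#: zone-wise airway branch radii (m): main-bronchus scale in the core,
#: small-airway scale at the periphery
DEFAULT_BRANCH_RADII = (4.0e-3, 1.5e-3, 0.5e-3)
#: the default profile corresponds to this point of the normalized
#: permeability scale; the sensitivity range of interest is 0.01-0.1
DEFAULT_PERMEABILITY_SCALE = 0.05


def shear_modulus(ym: float, poisson: float) -> float:
    """Shear modulus from Young's modulus: G = YM / [2 (1 + nu)].

    Rejects nu >= 0.5 — the incompressible limit makes the volumetric
    1/(1-2 nu) stiffness term singular.
    """
    ym_arr = np.asarray(ym, dtype=float)
    if np.any(ym_arr < 0):
        raise ValueError("Young's modulus must be >= 0")
    if not 0.0 <= poisson < 0.5:
        raise ValueError(f"Poisson ratio must satisfy 0 <= nu < 0.5, got {poisson}")
    out = ym_arr / (2.0 * (1.0 + poisson))
    return float(out) if np.isscalar(ym) else out


@dataclass
class MaterialField:
    """Per-element poroelastic properties plus scalar air constants."""

    g_xy: np.ndarray          # Pa, shear modulus acting in the xy plane
    g_yz: np.ndarray          # Pa
    g_xz: np.ndarray          # Pa
    poisson: np.ndarray       # dimensionless, in (0, 0.5)
    porosity: np.ndarray      # dimensionless, in (0, 1)
    permeability: np.ndarray  # m^2
    tissue_density: np.ndarray  # kg/m^3
    air_density: float = AIR_DENSITY
    air_viscosity: float = AIR_VISCOSITY
    air_compressibility: float = AIR_COMPRESSIBILITY

    def __post_init__(self) -> None:
        for name in ("g_xy", "g_yz", "g_xz", "poisson", "porosity",
                     "permeability", "tissue_density"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), dtype=float))
        n = self.g_xy.shape[0]
        for name in ("g_yz", "g_xz", "poisson", "porosity", "permeability",
                     "tissue_density"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"material field '{name}' has wrong length")
        if np.any(self.g_xy <= 0) or np.any(self.g_yz <= 0) or np.any(self.g_xz <= 0):
            raise ValueError("all shear moduli must be > 0")
        if np.any(self.poisson <= 0) or np.any(self.poisson >= 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if np.any(self.porosity <= 0) or np.any(self.porosity >= 1):
            raise ValueError("porosity must lie in (0, 1)")
        if np.any(self.permeability <= 0):
            raise ValueError("permeability must be > 0")
        if self.air_viscosity <= 0 or self.air_compressibility <= 0:
            raise ValueError("air viscosity and compressibility must be > 0")

    @property
    def n_elements(self) -> int:
        return self.g_xy.shape[0]

    @property
    def mean_shear(self) -> np.ndarray:
        """Element-wise mean of the three plane shear moduli."""
        return (self.g_xy + self.g_yz + self.g_xz) / 3.0

    def check_against(self, mesh: ZonedMesh) -> None:
        if self.n_elements != mesh.n_elements:
            raise ValueError(
                f"material has {self.n_elements} elements, mesh has {mesh.n_elements}"
            )


@dataclass(frozen=True)
class ElasticityFieldSpec:
    """How to build the Young's-modulus field.

    ``mode`` is one of ``isotropic`` (uniform ym_mean), ``anisotropic_synthetic``
    (seeded smooth random field with the prescribed min/max/mean statistics) or
    ``anisotropic_file`` (per-element table).  ``correlation_length`` sets the
    spatial smoothness of the synthetic field; ``axis_contrast`` multiplies the
    scalar field per coordinate plane (orthotropy strength; the default triple
    averages to 1 so the plane-mean modulus keeps the prescribed field
    statistics).  An optional spherical tumor inclusion is pinned at ym_max
    (rigid).
    """

    mode: str = "isotropic"
    ym_mean: float = DEFAULT_YM_MEAN
    ym_min: float = DEFAULT_YM_MIN
    ym_max: float = DEFAULT_YM_MAX
    correlation_length: float = 0.05           # m
    axis_contrast: tuple[float, float, float] = (1.2, 1.0, 0.8)
    tumor_center: tuple[float, float, float] | None = None
    tumor_radius: float = 0.015                # m
    seed: int = 0
    file_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("isotropic", "anisotropic_synthetic", "anisotropic_file"):
            raise ValueError(f"unknown elasticity mode '{self.mode}'")
        if not (self.ym_min < self.ym_mean < self.ym_max):
            raise ValueError(
                f"need ym_min < ym_mean < ym_max, got {self.ym_min}, "
                f"{self.ym_mean}, {self.ym_max}"
            )
        if any(c <= 0 for c in self.axis_contrast):
            raise ValueError(f"axis_contrast must be positive, got {self.axis_contrast}")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        if self.mode == "anisotropic_file" and not self.file_path:
            raise ValueError("anisotropic_file mode requires file_path")


def permeability_profile(
    mesh: ZonedMesh,
    branch_radius_per_zone,
    porosity: float = DEFAULT_POROSITY,
) -> np.ndarray:
    """Per-element permeability k = phi R_z^2 / 8 from zone-wise branch radii.

    Radii must strictly decrease from the core (zone 1) outward so that
    permeability falls from the central conductive branches to the tips.
    """
    radii = np.asarray(branch_radius_per_zone, dtype=float)
    n_zones = mesh.n_zones
    if radii.shape[0] != n_zones:
        raise ValueError(f"need one branch radius per zone ({n_zones}), got {radii.shape[0]}")
    if np.any(radii <= 0):
        raise ValueError("branch radii must be > 0")
    if np.any(np.diff(radii) >= 0):
        raise ValueError(
            "branch radii must strictly decrease from core to periphery, got "
            f"{radii.tolist()}"
        )
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must lie in (0, 1), got {porosity}")
    k_zone = porosity * radii**2 / 8.0
    return k_zone[mesh.zone_label - 1]


def default_branch_radii(n_zones: int,
                         core_radius: float = DEFAULT_BRANCH_RADII[0],
                         tip_radius: float = DEFAULT_BRANCH_RADII[-1]):
    """Geometrically decreasing branch radii from ``core_radius`` to
    ``tip_radius`` across the zones (k ratio (tip/core)^2 overall)."""
    if n_zones == 1:
        return (core_radius,)
    ratio = (tip_radius / core_radius) ** (1.0 / (n_zones - 1))
    return tuple(core_radius * ratio**z for z in range(n_zones))


def airway_channel_permeability(
    mesh: ZonedMesh,
    permeability: np.ndarray,
    channel_radius: float = 0.02,
    k_channel: float | None = None,
) -> np.ndarray:
    """Carve the main-bronchus supply channel into a permeability field.

    Elements whose centroid lies within ``channel_radius`` of the segment
    from the inlet-patch centre to the mesh centroid get the core (maximum)
    permeability — the conducting airway that connects the surface inlet to
    the high-permeability core.  Without it the inlet patch would feed the
    lobe through peripheral small-airway tissue and the whole organ would lag
    the drive by the access-resistance time of that bottleneck.
    """
    inlet = mesh.boundary_tags.get("inlet")
    if inlet is None or inlet.size == 0:
        raise ValueError("mesh has no 'inlet' boundary tag for the airway channel")
    if k_channel is None:
        k_channel = float(np.max(permeability))
    a = mesh.nodes[inlet].mean(axis=0)
    b = mesh.nodes.mean(axis=0)
    c = mesh.centroids()
    ab = b - a
    t = np.clip((c - a) @ ab / (ab @ ab), 0.0, 1.0)
    d = np.linalg.norm(c - (a + t[:, None] * ab), axis=1)
    out = permeability.copy()
    out[d <= channel_radius] = k_channel
    return out


def scaled_permeability(mat: MaterialField, scale: float) -> MaterialField:
    """Material with permeability at a point of the normalized 0.01-0.1 scale.

    The default profile sits at scale ``DEFAULT_PERMEABILITY_SCALE`` (0.05);
    the returned field has k multiplied by ``scale / 0.05``.
    """
    if scale <= 0:
        raise ValueError("permeability scale must be > 0")
    return replace(mat, permeability=mat.permeability * (scale / DEFAULT_PERMEABILITY_SCALE))


# ---------------------------------------------------------------------------
# synthetic Young's-modulus field
# ---------------------------------------------------------------------------

def _smooth_random_unit_field(mesh: ZonedMesh, correlation_length: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise on elements, rank-uniformized to [0, 1].

    Smoothing is iterated face-neighbor averaging; the pass count grows with
    (correlation_length / element size)^2, the diffusion scaling, so longer
    correlation lengths give smoother fields.  correlation_length = 0 returns
    plain white noise.  The marginal distribution is mapped to uniform via
    ranks: smoothing alone concentrates values near the middle, which would
    make the field effectively homogeneous with only isolated extremes; the
    rank map keeps the spatial correlation structure while ensuring the soft
    and stiff ends of the prescribed range occupy real volume fractions.
    """
    x = rng.standard_normal(mesh.n_elements)
    if correlation_length > 0.0:
        h = float(np.cbrt(np.mean(mesh.volumes())))  # characteristic element size
        n_pass = int(np.ceil((correlation_length / h) ** 2))
        neigh = mesh.element_neighbors()
        for _ in range(n_pass):
            means = np.array([x[nb].mean() if nb else x[i] for i, nb in enumerate(neigh)])
            x = 0.5 * (x + means)
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(mesh.n_elements)
    if mesh.n_elements < 2:
        return np.full(mesh.n_elements, 0.5)
    return ranks / (mesh.n_elements - 1)


def _match_mean_power(u: np.ndarray, weights: np.ndarray, ym_min: float,
                      ym_max: float, ym_mean: float) -> np.ndarray:
    """Monotone rescale ym = ym_min + (ym_max-ym_min) u^gamma with the exponent
    solved (bisection) so the weighted mean equals ym_mean.  Preserves the
    [ym_min, ym_max] range exactly, so no clipping is needed."""
    w = weights / weights.sum()
    target = (ym_mean - ym_min) / (ym_max - ym_min)

    def mean_for(gamma: float) -> float:
        return float(np.sum(w * u**gamma))

    lo, hi = 1e-3, 1e3
    if not (mean_for(hi) <= target <= mean_for(lo)):
        raise RuntimeError("mean-matching failed: target mean outside attainable range")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mean_for(mid) > target:
            lo = mid
        else:
            hi = mid
    gamma = np.sqrt(lo * hi)
    return ym_min + (ym_max - ym_min) * u**gamma


def _read_ym_table(path: str, n_elements: int) -> np.ndarray:
    """CSV with columns element_id, ym  (or ym_xy, ym_yz, ym_xz); returns (n, 3)."""
    df = pd.read_csv(path)
    if len(df) != n_elements:
        raise ValueError(
            f"elasticity table has {len(df)} rows, mesh has {n_elements} elements"
        )
    df = df.sort_values("element_id").reset_index(drop=True)
    if not np.array_equal(df["element_id"].to_numpy(), np.arange(n_elements)):
        raise ValueError("element_id column must enumerate 0..n_elements-1")
    if "ym" in df.columns:
        ym = df["ym"].to_numpy(dtype=float)
        return np.column_stack([ym, ym, ym])
    cols = ["ym_xy", "ym_yz", "ym_xz"]
    if not all(c in df.columns for c in cols):
        raise ValueError("elasticity table needs column 'ym' or 'ym_xy','ym_yz','ym_xz'")
    return df[cols].to_numpy(dtype=float)


def generate_elasticity_field(
    mesh: ZonedMesh,
    spec: ElasticityFieldSpec,
    poisson: float = DEFAULT_POISSON,
    porosity: float = DEFAULT_POROSITY,
    branch_radii=None,
    tissue_density: float = LUNG_TISSUE_DENSITY,
    air_density: float = AIR_DENSITY,
    air_viscosity: float = AIR_VISCOSITY,
    air_compressibility: float = AIR_COMPRESSIBILITY,
    inlet_channel_radius: float | None = 0.02,
) -> MaterialField:
    """Build the full per-element MaterialField for a mesh.

    The Young's-modulus field follows ``spec`` (see ElasticityFieldSpec);
    permeability comes from the zone-wise branch-radius rule (default radii
    fall geometrically from 4 mm in the core to 0.5 mm at the tips), with the
    main-bronchus channel carved toward the inlet patch when the mesh carries
    an ``inlet`` tag (disable with ``inlet_channel_radius=None``).
    Deterministic for a fixed (mesh, spec).
    """
    if branch_radii is None:
        branch_radii = default_branch_radii(mesh.n_zones)
    k = permeability_profile(mesh, branch_radii, porosity)
    if inlet_channel_radius is not None and "inlet" in mesh.boundary_tags \
            and mesh.boundary_tags["inlet"].size:
        k = airway_channel_permeability(mesh, k, inlet_channel_radius)
    n = mesh.n_elements
    contrast = np.asarray(spec.axis_contrast, dtype=float)

    if spec.mode == "isotropic":
        ym3 = np.full((n, 3), spec.ym_mean)
    elif spec.mode == "anisotropic_synthetic":
        rng = np.random.default_rng(spec.seed)
        u = _smooth_random_unit_field(mesh, spec.correlation_length, rng)
        ym = _match_mean_power(u, mesh.volumes(), spec.ym_min, spec.ym_max, spec.ym_mean)
        if spec.tumor_center is not None:
            d = np.linalg.norm(mesh.centroids() - np.asarray(spec.tumor_center), axis=1)
            ym = np.where(d <= spec.tumor_radius, spec.ym_max, ym)
        ym3 = ym[:, None] * contrast[None, :]
    else:  # anisotropic_file
        ym3 = _read_ym_table(spec.file_path, n)

    g = shear_modulus(ym3, poisson)
    return MaterialField(
        g_xy=g[:, 0], g_yz=g[:, 1], g_xz=g[:, 2],
        poisson=np.full(n, poisson),
        porosity=np.full(n, porosity),
        permeability=k,
        tissue_density=np.full(n, tissue_density),
        air_density=air_density,
        air_viscosity=air_viscosity,
        air_compressibility=air_compressibility,
    )


def scalar_ym(mat: MaterialField) -> np.ndarray:
    """Element-wise Young's modulus back-computed from the mean plane modulus."""
    return mat.mean_shear * 2.0 * (1.0 + mat.poisson)
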