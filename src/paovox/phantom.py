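"""Randomized three-layer skin phantoms with synthetic vascular trees.

A phantom is a voxel grid (depth axis ``z``, sensor plane at ``z = 0``)
holding planar epidermis / dermis / hypodermis layers and one or more
tubular vascular bodies.  Layer thicknesses and the melanin / blood-volume
parameters are drawn uniformly from physiological ranges, every independent
vascular body is assigned one of (at most) three random sO2 values, and the
per-voxel optical coefficients at each excitation wavelength are filled in
from :mod:`paovox.optics`.

The vascular trees are parametric random-walk tubes (with optional
bifurcation) rasterized as swept spheres — a synthetic stand-in for
vessel geometries segmented from tomographic data, with radii and vessel
volume fractions chosen to look like superficial vasculature at the 0.1 mm
grid scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from paovox import optics
from paovox.optics import ChromophoreTable, DEFAULT_BLOOD_TABLE, LayerSample

__all__ = [
    "GridSpec",
    "VesselTreeParams",
    "TissueModel",
    "FULL_GRID",
    "SCALED_GRID",
    "sample_layer_thicknesses",
    "sample_layer_params",
    "generate_vessel_tree",
    "assign_vessel_so2",
    "build_tissue_model",
    "random_tissue_model",
    "LABEL_EPIDERMIS",
    "LABEL_DERMIS",
    "LABEL_HYPODERMIS",
    "LABEL_VESSEL",
]

LABEL_EPIDERMIS = 1
LABEL_DERMIS = 2
LABEL_HYPODERMIS = 3
LABEL_VESSEL = 4

PER_CM_TO_PER_MM = 0.1

# 26-connected 3D neighborhood (bwlabeln-style default).
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: ``nz`` is depth (z = 0 is the sensor plane), dx in mm."""

    nz: int
    ny: int
    nx: int
    dx_mm: float = 0.1

    def __post_init__(self) -> None:
        if min(self.nz, self.ny, self.nx) < 4:
            raise ValueError("grid must be at least 4 voxels per axis")
        if self.dx_mm <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    @property
    def depth_mm(self) -> float:
        return self.nz * self.dx_mm

    def z_centers_mm(self) -> np.ndarray:
        """Depth of each voxel-layer center below the sensor plane, mm."""
        return (np.arange(self.nz) + 0.5) * self.dx_mm


#: The full-scale simulation grid: 40 x 120 x 120 voxels at 0.1 mm (4 mm deep).
FULL_GRID = GridSpec(40, 120, 120, 0.1)
#: Reduced grid used for desk-scale datasets.
SCALED_GRID = GridSpec(24, 48, 48, 0.1)


@dataclass(frozen=True)
class VesselTreeParams:
    """Parameters of the random-walk vascular-tree generator.

    ``radius_range_mm`` is sampled per trunk; branches inherit 80% of the
    parent radius.  ``min_depth_mm`` keeps every vessel voxel below the
    deepest possible epidermis (vessels live in the dermis/hypodermis).
    """

    n_seeds: int = 3
    branch_prob: float = 0.03
    radius_range_mm: tuple[float, float] = (0.2, 0.4)
    tortuosity: float = 0.25
    min_depth_mm: float = 0.45
    max_tries: int = 8

    def validate(self, grid: GridSpec) -> None:
        r_lo, r_hi = self.radius_range_mm
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if r_lo < 2 * grid.dx_mm:
            raise ValueError("minimum vessel radius must be >= 2 voxels")
        if r_lo > r_hi:
            raise ValueError("radius range must be ordered")
        if self.min_depth_mm + 2 * r_hi >= grid.depth_mm:
            raise ValueError("grid too shallow for the requested vessel radii")


@dataclass
class TissueModel:
    """A voxel phantom plus its per-wavelength optical-property volumes.

    ``label`` holds the tissue class codes; ``body_id`` is 0 outside vessels
    and ``k >= 1`` inside the k-th independent vascular body; ``so2_true``
    is the per-voxel oxygen saturation (0 outside vessels, one constant per
    body inside).  ``mu_a`` / ``mu_s`` map wavelength (nm) to mm^-1 volumes;
    ``g`` and ``n`` are dimensionless volumes.  The photoacoustic efficiency
    ``gamma`` is 1 everywhere.
    """

    grid: GridSpec
    label: np.ndarray
    body_id: np.ndarray
    so2_true: np.ndarray
    mu_a: Mapping[float, np.ndarray]
    mu_s: Mapping[float, np.ndarray]
    g: np.ndarray
    n: np.ndarray
    gamma: float = 1.0
    layer_sample: LayerSample | None = None
    meta: dict = field(default_factory=dict)

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.mu_a))

    @property
    def segmentation_true(self) -> np.ndarray:
        """Ground-truth binary vessel map (body_id >= 1)."""
        return (self.body_id >= 1).astype(np.float64)

    @property
    def n_bodies(self) -> int:
        return int(self.body_id.max())


def sample_layer_thicknesses(
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Draw (epidermis, dermis, hypodermis) thicknesses in mm.

    Uniform over 0.1-0.3, 1.3-2.9 and 0.8-2.6 mm respectively.  The
    hypodermis additionally extends to the bottom of whatever grid the
    phantom is built on.
    """
    return (
        float(rng.uniform(0.1, 0.3)),
        float(rng.uniform(1.3, 2.9)),
        float(rng.uniform(0.8, 2.6)),
    )


def sample_layer_params(rng: np.random.Generator) -> LayerSample:
    """Draw a full per-phantom layer parameter set.

    Melanosome fraction uniform on [0.06, 0.40] (light to strongly
    pigmented skin), dermal blood volume fraction uniform on [0.002, 0.07],
    dermal blood sO2 uniform on [0.40, 1.00].
    """
    t_epi, t_derm, t_hypo = sample_layer_thicknesses(rng)
    return LayerSample(
        c_m=float(rng.uniform(0.06, 0.40)),
        c_b=float(rng.uniform(0.002, 0.07)),
        dermis_so2=float(rng.uniform(0.40, 1.00)),
        thickness_epi_mm=t_epi,
        thickness_derm_mm=t_derm,
        thickness_hypo_mm=t_hypo,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = float(np.linalg.norm(v))
    if nrm == 0.0:
        return np.array([0.0, 1.0, 0.0])
    return v / nrm


def _stamp_ball(
    mask: np.ndarray, center_mm: np.ndarray, radius_mm: float, dx: float
) -> None:
    """Mark all voxels whose centers lie within radius of center (in place)."""
    nz, ny, nx = mask.shape
    r_vox = radius_mm / dx
    c_vox = center_mm / dx - 0.5  # voxel-center coordinates
    lo = np.maximum(np.floor(c_vox - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + r_vox).astype(int) + 1, [nz, ny, nx])
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d2 = (zz - c_vox[0]) ** 2 + (yy - c_vox[1]) ** 2 + (xx - c_vox[2]) ** 2
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= r_vox**2


def _rasterize_tree(
    grid: GridSpec, params: VesselTreeParams, rng: np.random.Generator
) -> np.ndarray:
    """Rasterize one random-walk tube tree into a boolean volume."""
    dx = grid.dx_mm
    depth, height, width = (
        grid.nz * dx,
        grid.ny * dx,
        grid.nx * dx,
    )
    radius = float(rng.uniform(*params.radius_range_mm))
    z_lo = params.min_depth_mm + radius
    z_hi = depth - radius
    start = np.array(
        [
            rng.uniform(z_lo, z_hi),
            rng.uniform(0.15 * height, 0.85 * height),
            rng.uniform(0.15 * width, 0.85 * width),
        ]
    )
    # mostly-horizontal initial direction so the tube spans the field of view
    direction = _unit(
        np.array(
            [
                rng.uniform(-0.3, 0.3),
                rng.normal(),
                rng.normal(),
            ]
        )
    )
    mask = np.zeros(grid.shape, dtype=bool)
    # (position, direction, radius) stack; branches inherit a thinner radius
    branches = [(start, direction, radius)]
    max_steps = int(2.0 * max(grid.ny, grid.nx))
    while branches:
        pos, d, r = branches.pop()
        d = d.copy()
        for _ in range(max_steps):
            _stamp_ball(mask, pos, r, dx)
            d = _unit(d + params.tortuosity * rng.normal(size=3))
            pos = pos + d * dx
            # reflect off the vessel depth band
            if pos[0] < params.min_depth_mm + r or pos[0] > depth - r:
                d[0] = -d[0]
                pos[0] = np.clip(pos[0], params.min_depth_mm + r, depth - r)
            if not (0 <= pos[1] <= height and 0 <= pos[2] <= width):
                break
            if r >= 2 * (2 * dx) and rng.uniform() < params.branch_prob:
                child_dir = _unit(d + 0.8 * rng.normal(size=3))
                branches.append((pos.copy(), child_dir, 0.8 * r))
    return mask


def generate_vessel_tree(
    grid: GridSpec,
    params: VesselTreeParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``params.n_seeds`` mutually disconnected vascular bodies.

    Returns ``(mask, body_id)`` where ``mask`` is the boolean vessel volume
    and ``body_id`` labels the k-th independent body with integer ``k``.
    Bodies are pairwise disconnected under 26-connectivity: a candidate tree
    whose 1-voxel-dilated footprint touches an existing body is re-drawn (up
    to ``max_tries`` times, then dropped).  No vessel voxel can lie in the
    epidermis layer (``min_depth_mm`` exceeds the deepest epidermis).
    """
    if params is None:
        params = VesselTreeParams()
    if rng is None:
        rng = np.random.default_rng()
    params.validate(grid)

    body_id = np.zeros(grid.shape, dtype=np.int32)
    occupied_dilated = np.zeros(grid.shape, dtype=bool)
    next_id = 1
    for _seed in range(params.n_seeds):
        for _try in range(params.max_tries):
            candidate = _rasterize_tree(grid, params, rng)
            if not candidate.any():
                continue
            if not (candidate & occupied_dilated).any():
                body_id[candidate] = next_id
                occupied_dilated |= ndimage.binary_dilation(
                    candidate, structure=STRUCT_26
                )
                next_id += 1
                break
    if next_id == 1:
        raise RuntimeError("failed to place any vascular body")
    return body_id > 0, body_id


def assign_vessel_so2(
    body_id: np.ndarray,
    rng: np.random.Generator,
    n_values: int = 3,
) -> np.ndarray:
    """Assign each vascular body one of ``n_values`` random sO2 values.

    Draws ``n_values`` saturations uniformly on [0, 1] and gives every body
    one of them at random, so a phantom carries at most ``n_values``
    distinct vessel sO2 levels.  Returns the per-voxel so2_true volume
    (0 outside vessels).
    """
    n_bodies = int(body_id.max())
    if n_bodies < 1:
        raise ValueError("no vascular bodies to assign sO2 to")
    levels = rng.uniform(0.0, 1.0, size=n_values)
    choice = rng.integers(0, n_values, size=n_bodies)
    so2 = np.zeros(body_id.shape, dtype=np.float64)
    for k in range(1, n_bodies + 1):
        so2[body_id == k] = levels[choice[k - 1]]
    return so2


def build_tissue_model(
    grid: GridSpec,
    sample: LayerSample,
    vessel_mask: np.ndarray,
    body_id: np.ndarray,
    so2_true: np.ndarray,
    wavelengths: Sequence[float] = optics.WAVELENGTHS_NM,
    table: ChromophoreTable = DEFAULT_BLOOD_TABLE,
    meta: dict | None = None,
) -> TissueModel:
    """Assemble the voxel phantom and its optical-property volumes.

    Layers are planar and ordered epidermis -> dermis -> hypodermis from the
    sensor plane; the hypodermis extends to the bottom of the grid (layers
    deeper than the grid are clipped).  Vessel voxels override the layer
    label.  Coefficient volumes are stored in mm^-1.
    """
    if vessel_mask.shape != grid.shape:
        raise ValueError("vessel volume shape does not match grid")
    if sample.thickness_epi_mm >= grid.depth_mm:
        raise ValueError("epidermis thickness exceeds the grid depth")
    if vessel_mask[0].any():
        raise ValueError("vessel voxels must not touch the sensor plane")

    z = grid.z_centers_mm()
    label = np.full(grid.shape, LABEL_HYPODERMIS, dtype=np.uint8)
    epi = z < sample.thickness_epi_mm
    derm = (z >= sample.thickness_epi_mm) & (
        z < sample.thickness_epi_mm + sample.thickness_derm_mm
    )
    label[epi] = LABEL_EPIDERMIS
    label[derm] = LABEL_DERMIS
    if vessel_mask[epi].any():
        raise ValueError("vessel voxels found in the epidermis layer")
    label[vessel_mask] = LABEL_VESSEL

    so2_levels = np.unique(so2_true[vessel_mask]) if vessel_mask.any() else []
    mu_a: dict[float, np.ndarray] = {}
    mu_s: dict[float, np.ndarray] = {}
    g = np.zeros(grid.shape, dtype=np.float64)
    n = np.zeros(grid.shape, dtype=np.float64)
    for lam in wavelengths:
        mu_a_l = np.zeros(grid.shape, dtype=np.float64)
        mu_s_l = np.zeros(grid.shape, dtype=np.float64)
        for tissue, code in (
            ("epidermis", LABEL_EPIDERMIS),
            ("dermis", LABEL_DERMIS),
            ("hypodermis", LABEL_HYPODERMIS),
        ):
            props = optics.layer_optical_properties(tissue, lam, sample, table=table)
            sel = label == code
            mu_a_l[sel] = props.mu_a * PER_CM_TO_PER_MM
            mu_s_l[sel] = props.mu_s * PER_CM_TO_PER_MM
            g[sel] = props.g
            n[sel] = props.n
        for so2 in so2_levels:
            props = optics.layer_optical_properties(
                "vessel", lam, sample, vessel_so2=float(so2), table=table
            )
            sel = vessel_mask & (so2_true == so2)
            mu_a_l[sel] = props.mu_a * PER_CM_TO_PER_MM
            mu_s_l[sel] = props.mu_s * PER_CM_TO_PER_MM
            g[sel] = props.g
            n[sel] = props.n
        mu_a[float(lam)] = mu_a_l
        mu_s[float(lam)] = mu_s_l

    return TissueModel(
        grid=grid,
        label=label,
        body_id=body_id.astype(np.int32),
        so2_true=so2_true.astype(np.float64),
        mu_a=mu_a,
        mu_s=mu_s,
        g=g,
        n=n,
        gamma=1.0,
        layer_sample=sample,
        meta=dict(meta or {}),
    )


def random_tissue_model(
    grid: GridSpec,
    rng: np.random.Generator,
    params: VesselTreeParams | None = None,
    wavelengths: Sequence[float] = optics.WAVELENGTHS_NM,
    table: ChromophoreTable = DEFAULT_BLOOD_TABLE,
    meta: dict | None = None,
) -> TissueModel:
    """Draw one complete random phantom (layers + vessels + sO2)."""
    sample = sample_layer_params(rng)
    mask, body_id = generate_vessel_tree(grid, params, rng)
    so2_true = assign_vessel_so2(body_id, rng)
    return build_tissue_model(
        grid, sample, mask, body_id, so2_true, wavelengths, table, meta
    )
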