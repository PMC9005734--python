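"""Synthetic vascular geometries and simulated OCT speckle time series.

Two geometry generators provide ground truth for the downstream pipeline:

* :func:`generate_parallel_cylinders` — a Boolean model of parallel
  cylinders whose axes form a 2D Poisson point process in the plane
  perpendicular to the cylinder direction.  For this process the
  diffusion-limited fraction has the closed form
  ``DLF_Λ = exp(-ρ π (Λ + r_c)²)`` (:func:`theoretical_dlf`), which serves
  as the analytic oracle for the distance-transform metrics.
* :func:`generate_vessel_tree` — a random branching tree of tapering
  tubes, a more heterogeneous geometry without a closed form.

:func:`simulate_bscan_stack` turns a binary vessel mask into repeated
B-scan intensity series with fully developed (exponential-intensity)
speckle: vessel voxels redraw their speckle each frame while tissue
speckle is (nearly) frozen, signal decays with depth per Beer–Lambert,
and voxels below vessels carry multiplicative shadow tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import BinaryVascularMask, BScanSeries, Volume

__all__ = [
    "CylinderFieldSpec",
    "SpeckleSimSpec",
    "VesselTreeSpec",
    "CylinderField",
    "VesselTree",
    "BScanStack",
    "generate_parallel_cylinders",
    "theoretical_dlf",
    "generate_vessel_tree",
    "simulate_bscan_stack",
]

_AXIS_VECTORS = {
    "z": (1.0, 0.0, 0.0),
    "x": (0.0, 1.0, 0.0),
    "y": (0.0, 0.0, 1.0),
}


@dataclass(frozen=True)
class CylinderFieldSpec:
    """Parameters of a random parallel-cylinder vessel field.

    Parameters
    ----------
    box_size
        Physical box extent ``(z, x, y)`` in μm.
    r_c
        Cylinder radius in μm.
    line_density
        Expected number of cylinder axes per μm² of the cross-section
        perpendicular to ``axis`` (the intensity ρ of the Poisson line
        process).
    axis
        Cylinder direction: one of ``"z" | "x" | "y"`` or a 3-vector
        (normalized internally).
    seed
        Seed for the axis-position draw.
    margin
        Width (μm) of the band around the cross-section in which axes are
        also generated, so that boundary voxels see an unbiased
        environment.  Should be at least ``Λ + r_c`` for the largest
        distance threshold Λ analysed downstream.
    """

    box_size: tuple[float, float, float]
    r_c: float
    line_density: float
    axis: str | tuple[float, float, float] = "y"
    seed: int = 0
    margin: float = 165.0

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.line_density < 0:
            raise ValueError("line_density must be non-negative")
        if any(b <= 0 for b in self.box_size):
            raise ValueError("box_size must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")

    def axis_vector(self) -> np.ndarray:
        if isinstance(self.axis, str):
            try:
                v = np.array(_AXIS_VECTORS[self.axis])
            except KeyError:
                raise ValueError(f"unknown axis name {self.axis!r}") from None
        else:
            v = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError("axis vector must be nonzero")
            v = v / n
        return v


@dataclass(frozen=True)
class SpeckleSimSpec:
    """Parameters of the repeated-B-scan speckle forward model.

    ``tissue_decorrelation`` / ``vessel_decorrelation`` are the convex
    mixing weights of a per-frame speckle redraw against a frozen field:
    0 means frozen speckle (static tissue), 1 means fully refreshed each
    frame (flowing blood).
    """

    n_frames: int = 8
    tissue_decorrelation: float = 0.05
    vessel_decorrelation: float = 1.0
    attenuation_coeff: float = 0.003  # μm⁻¹, Beer–Lambert
    shadow_decay_length: float = 50.0  # μm
    shadow_strength: float = 0.5  # peak decorrelation of the sub-vessel tail
    noise_floor: float = 0.05  # mean of additive exponential noise
    frame_interval_ms: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("tissue_decorrelation", "vessel_decorrelation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff must be >= 0")
        if self.shadow_decay_length <= 0:
            raise ValueError("shadow_decay_length must be positive")
        if not 0.0 <= self.shadow_strength <= 1.0:
            raise ValueError("shadow_strength must be in [0, 1]")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")


@dataclass
class CylinderField:
    """A realized cylinder field: the voxelized mask plus ground truth."""

    mask: BinaryVascularMask
    axis_points: np.ndarray  # (n, 2) axis positions (μm) in the cross-section
    cross_axes: tuple[int, int]  # array axes spanning the cross-section
    spec: CylinderFieldSpec


@dataclass
class VesselTree:
    """A realized branching tree: mask plus centerline segments."""

    mask: BinaryVascularMask
    # each row: (z0, x0, y0, z1, x1, y1, radius) in μm
    segments: np.ndarray
    spec: "VesselTreeSpec"


def theoretical_dlf(
    r_c: float,
    line_density: float,
    threshold: float = 150.0,
    condition_on_tissue: bool = False,
) -> float:
    """Closed-form diffusion-limited fraction of a Poisson cylinder field.

    A point lies farther than ``threshold`` (Λ) from the nearest vessel
    surface iff no cylinder axis falls within ``Λ + r_c`` of it, which for
    a Poisson process of intensity ρ has probability
    ``exp(-ρ π (Λ + r_c)²)``.

    With ``condition_on_tissue=True`` the probability is conditioned on
    the point itself lying outside all cylinders (dividing by the
    non-vessel fraction ``exp(-ρ π r_c²)``), matching a DLF computed over
    tissue voxels only.  The two differ by at most the vascular volume
    density, negligible at physiological VVD of a few percent.
    """
    if r_c < 0 or line_density < 0 or threshold < 0:
        raise ValueError("arguments must be non-negative")
    out = float(np.exp(-line_density * np.pi * (threshold + r_c) ** 2))
    if condition_on_tissue:
        out /= float(np.exp(-line_density * np.pi * r_c**2))
    return out


def _cross_section_grid(
    shape: tuple[int, int, int], spacing: tuple[float, float, float], along: int
) -> tuple[tuple[int, int], np.ndarray, np.ndarray]:
    """Voxel-center coordinates of the two axes perpendicular to ``along``."""
    cross = tuple(i for i in range(3) if i != along)
    u = (np.arange(shape[cross[0]]) + 0.5) * spacing[cross[0]]
    v = (np.arange(shape[cross[1]]) + 0.5) * spacing[cross[1]]
    return cross, u, v  # type: ignore[return-value]


def generate_parallel_cylinders(
    spec: CylinderFieldSpec,
    voxel_spacing: float | tuple[float, float, float] = 2.5,
    forced_axes: np.ndarray | None = None,
) -> CylinderField:
    """Voxelize a Poisson field of parallel cylinders.

    The cylinder direction must be one of the coordinate axes (the
    voxelization exploits translational invariance along the axis).
    Axis positions are drawn in the cross-section extended by
    ``spec.margin`` on every side, so interior statistics match the
    unbounded process.

    Parameters
    ----------
    spec
        Field geometry and process intensity.
    voxel_spacing
        Scalar (isotropic) or per-axis ``(dz, dx, dy)`` spacing in μm.
    forced_axes
        Optional ``(n, 2)`` array of axis positions (μm, cross-section
        coordinates) used *instead of* the Poisson draw — handy for
        deterministic single-cylinder phantoms.

    Returns
    -------
    CylinderField
        Mask plus the realized axis coordinates (ground truth).
    """
    if np.isscalar(voxel_spacing):
        spacing = (float(voxel_spacing),) * 3
    else:
        spacing = tuple(float(s) for s in voxel_spacing)  # type: ignore[assignment]
    if min(spacing) > spec.r_c:
        warnings.warn(
            f"voxel spacing {spacing} exceeds cylinder radius {spec.r_c}; "
            "cylinders may not be resolvable",
            stacklevel=2,
        )

    axis_vec = spec.axis_vector()
    aligned = np.isclose(np.abs(axis_vec).max(), 1.0)
    if not aligned:
        raise NotImplementedError(
            "only coordinate-axis-aligned cylinder directions are supported"
        )
    along = int(np.argmax(np.abs(axis_vec)))

    shape = tuple(
        int(round(spec.box_size[i] / spacing[i])) for i in range(3)
    )
    if any(n < 2 for n in shape):
        raise ValueError(f"degenerate box: voxel shape {shape} has a dimension < 2")

    cross, u, v = _cross_section_grid(shape, spacing, along)
    extent_u = spec.box_size[cross[0]]
    extent_v = spec.box_size[cross[1]]

    if forced_axes is not None:
        pts = np.atleast_2d(np.asarray(forced_axes, dtype=float))
    else:
        rng = np.random.default_rng(spec.seed)
        m = spec.margin
        area = (extent_u + 2 * m) * (extent_v + 2 * m)
        n_cyl = rng.poisson(spec.line_density * area)
        pts = np.column_stack(
            [
                rng.uniform(-m, extent_u + m, size=n_cyl),
                rng.uniform(-m, extent_v + m, size=n_cyl),
            ]
        )

    cross_mask = np.zeros((len(u), len(v)), dtype=bool)
    r2 = spec.r_c**2
    for pu, pv in pts:
        # restrict to the bounding square of each disk
        iu = np.flatnonzero(np.abs(u - pu) <= spec.r_c)
        iv = np.flatnonzero(np.abs(v - pv) <= spec.r_c)
        if iu.size == 0 or iv.size == 0:
            continue
        du2 = (u[iu] - pu) ** 2
        dv2 = (v[iv] - pv) ** 2
        cross_mask[np.ix_(iu, iv)] |= du2[:, None] + dv2[None, :] <= r2

    data = np.broadcast_to(
        np.expand_dims(cross_mask, axis=along), shape
    ).copy()
    mask = BinaryVascularMask(
        data=data,
        spacing=spacing,  # type: ignore[arg-type]
        meta={"generator": "parallel_cylinders", "seed": spec.seed},
    )
    return CylinderField(mask=mask, axis_points=pts, cross_axes=cross, spec=spec)


@dataclass(frozen=True)
class VesselTreeSpec:
    """Parameters of the random branching-tree generator.

    Defaults produce a tumour-scale arteriole-like tree: a root tube of
    ~20 μm radius splitting over a few generations with mild tapering.
    """

    box_size: tuple[float, float, float] = (500.0, 500.0, 500.0)
    n_generations: int = 4
    root_radius: float = 20.0
    taper: float = 0.75  # child radius / parent radius
    segment_length: float = 150.0  # μm, mean parent segment length
    branch_angle_deg: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.root_radius <= 0:
            raise ValueError("root_radius must be positive")
        if not 0 < self.taper <= 1:
            raise ValueError("taper must be in (0, 1]")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")


def _rotate_towards(direction: np.ndarray, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by ``angle`` about a random perpendicular axis."""
    d = direction / np.linalg.norm(direction)
    # random vector not parallel to d
    while True:
        r = rng.normal(size=3)
        perp = r - np.dot(r, d) * d
        n = np.linalg.norm(perp)
        if n > 1e-8:
            perp /= n
            break
    return np.cos(angle) * d + np.sin(angle) * perp


def generate_vessel_tree(
    spec: VesselTreeSpec, voxel_spacing: float | tuple[float, float, float] = 2.5
) -> VesselTree:
    """Generate a connected branching tree of tapering tubes.

    The tree grows from the center of the top face downward; each segment
    splits into two children rotated by ``branch_angle_deg`` about random
    perpendicular axes, with radii reduced by ``taper``.  Segments are
    voxelized as capsules (tube plus hemispherical caps).  A
    ``n_generations`` of 0 yields a single straight tube.

    Returns the mask together with the centerline segment table
    ``(z0, x0, y0, z1, x1, y1, radius)`` as ground truth.
    """
    if np.isscalar(voxel_spacing):
        spacing = (float(voxel_spacing),) * 3
    else:
        spacing = tuple(float(s) for s in voxel_spacing)  # type: ignore[assignment]
    shape = tuple(int(round(spec.box_size[i] / spacing[i])) for i in range(3))
    if any(n < 2 for n in shape):
        raise ValueError(f"degenerate box: voxel shape {shape} has a dimension < 2")

    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box_size)
    root_start = np.array([0.0, box[1] / 2, box[2] / 2])
    root_dir = np.array([1.0, 0.0, 0.0])  # straight down in depth

    segments: list[tuple[float, ...]] = []
    frontier = [(root_start, root_dir, spec.root_radius)]
    angle = np.deg2rad(spec.branch_angle_deg)
    for gen in range(spec.n_generations + 1):
        next_frontier = []
        for start, direction, radius in frontier:
            length = spec.segment_length * (0.8 + 0.4 * rng.random())
            end = start + direction * length
            end = np.clip(end, 0.0, box)
            segments.append((*start, *end, radius))
            if gen < spec.n_generations:
                for _ in range(2):
                    child_dir = _rotate_towards(direction, angle, rng)
                    next_frontier.append((end, child_dir, radius * spec.taper))
        frontier = next_frontier

    seg_arr = np.asarray(segments)
    data = np.zeros(shape, dtype=bool)
    coords = [
        (np.arange(shape[i]) + 0.5) * spacing[i] for i in range(3)
    ]
    for z0, x0, y0, z1, x1, y1, radius in seg_arr:
        p0 = np.array([z0, x0, y0])
        p1 = np.array([z1, x1, y1])
        lo = np.minimum(p0, p1) - radius
        hi = np.maximum(p0, p1) + radius
        idx = [
            np.flatnonzero((coords[i] >= lo[i]) & (coords[i] <= hi[i]))
            for i in range(3)
        ]
        if any(ix.size == 0 for ix in idx):
            continue
        zz, xx, yy = np.meshgrid(
            coords[0][idx[0]], coords[1][idx[1]], coords[2][idx[2]], indexing="ij"
        )
        pts = np.stack([zz, xx, yy], axis=-1)
        seg = p1 - p0
        seg_len2 = float(np.dot(seg, seg))
        if seg_len2 == 0:
            d2 = np.sum((pts - p0) ** 2, axis=-1)
        else:
            t = np.clip(np.einsum("...i,i->...", pts - p0, seg) / seg_len2, 0.0, 1.0)
            proj = p0 + t[..., None] * seg
            d2 = np.sum((pts - proj) ** 2, axis=-1)
        data[np.ix_(idx[0], idx[1], idx[2])] |= d2 <= radius**2

    mask = BinaryVascularMask(
        data=data,
        spacing=spacing,  # type: ignore[arg-type]
        meta={"generator": "vessel_tree", "seed": spec.seed},
    )
    return VesselTree(mask=mask, segments=seg_arr, spec=spec)


@dataclass
class BScanStack:
    """Simulated acquisition: intensities of shape ``(z, x, y, frames)``."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    frame_interval_ms: float = 25.0
    meta: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.intensities.shape[2]

    def series(self, y: int) -> BScanSeries:
        """The repeated-B-scan series at lateral position ``y``."""
        return BScanSeries(
            intensities=self.intensities[:, :, y, :],
            axial_spacing=self.spacing[0],
            lateral_spacing=self.spacing[1],
            frame_interval_ms=self.frame_interval_ms,
        )

    def all_series(self) -> list[BScanSeries]:
        return [self.series(y) for y in range(self.n_positions)]


def _subvessel_tail(mask: np.ndarray, dz: float, decay_length: float) -> np.ndarray:
    """Exponential tail ``exp(-Δz / L)`` below vessels along each A-line.

    Δz is the physical distance to the most recent vessel voxel above in
    the same column; voxels with no vessel above (and vessel voxels
    themselves) get 0.  Only the nearest vessel run above contributes; at
    realistic vascular densities stacked vessels in one A-line are rare.
    """
    nz = mask.shape[0]
    tail = np.zeros(mask.shape, dtype=float)
    # index of most recent vessel voxel at or above each depth, else -inf
    last = np.full(mask.shape[1:], -np.inf)
    for z in range(nz):
        vessel_here = mask[z]
        below = np.isfinite(last) & ~vessel_here
        if below.any():
            delta = (z - last[below]) * dz
            tail[z][below] = np.exp(-delta / decay_length)
        last[vessel_here] = z
    return tail


def simulate_bscan_stack(mask: BinaryVascularMask, spec: SpeckleSimSpec) -> BScanStack:
    """Simulate repeated B-scan intensities from a binary vessel mask.

    The speckle model is fully developed speckle (unit-mean exponential
    intensity).  Each voxel mixes a frozen field F with per-frame redraws
    R_t: ``I_t = (1 - d) F + d R_t`` where d is the decorrelation
    fraction — ``vessel_decorrelation`` inside vessels,
    ``tissue_decorrelation`` in tissue, and below each vessel a shadow
    tail ``shadow_strength · exp(-Δz / shadow_decay_length)`` of excess
    decorrelation (moving blood scrambles the speckle of everything it
    shadows), which is what downstream shadow filtering must remove.
    Intensities are attenuated by ``exp(-μ z)`` (Beer–Lambert) and an
    additive exponential noise floor is drawn per frame.
    """
    rng = np.random.default_rng(spec.seed)
    m = mask.data
    nz, nx, ny = m.shape
    M = spec.n_frames

    frozen = rng.exponential(1.0, size=(nz, nx, ny))
    redraw = rng.exponential(1.0, size=(nz, nx, ny, M))
    d = np.where(m, spec.vessel_decorrelation, spec.tissue_decorrelation)
    if spec.shadow_strength > 0 and spec.vessel_decorrelation > 0:
        tail = _subvessel_tail(m, mask.spacing[0], spec.shadow_decay_length)
        d = np.maximum(d, spec.shadow_strength * spec.vessel_decorrelation * tail)
    d = d[..., None]
    signal = (1.0 - d) * frozen[..., None] + d * redraw

    depth = mask.depth_coords()  # μm
    atten = np.exp(-spec.attenuation_coeff * depth)[:, None, None, None]
    out = signal * atten
    if spec.noise_floor > 0:
        out = out + rng.exponential(spec.noise_floor, size=out.shape)
    return BScanStack(
        intensities=out,
        spacing=mask.spacing,
        frame_interval_ms=spec.frame_interval_ms,
        meta={"seed": spec.seed, "n_frames": M},
    )


def ground_truth_voi(mask: BinaryVascularMask) -> "Volume":
    """All-true VOI on the grid of ``mask`` (synthetic phantoms have no
    tumour boundary)."""
    from .volume import VOIMask

    return VOIMask(
        data=np.ones(mask.shape, dtype=bool),
        spacing=mask.spacing,
        meta={"provenance": "slab"},
    )
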