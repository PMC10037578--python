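"""Synthetic CT phantoms of an orbital-floor-like bone shell with a defect.

The phantom stands in for the clinical input: a thin, possibly tilted or
curved bone lamella (the orbital floor) pierced by a blowout defect whose
true surface area is known in closed form.  Coordinates follow the
anatomical convention used throughout the package:

* ``x`` — mediolateral, ``y`` — anteroposterior, ``z`` — superoinferior
  (+z = superior);
* coronal slices are constant-``y`` planes;
* world position = voxel index x spacing (no origin offset), all mm.

Floor geometries
----------------
``flat``            horizontal plane at the box mid-height.
``tilted_plane``    plane rotated by ``tilt_deg`` about the mediolateral
                    (x) axis.  The defect is an ellipse in the floor's
                    intrinsic plane, removed perpendicular to the floor, so
                    its intrinsic area is tilt-invariant (pi*a*b) while its
                    axial footprint shrinks by cos(tilt).
``spherical_cap``   lower cap of a sphere of radius ``cap_radius_mm`` whose
                    centre sits above the box mid-height; the defect is a
                    vertical cylinder of radius ``a``, so the removed
                    surface is a spherical cap of area 2*pi*R*h with
                    h = R - sqrt(R^2 - a^2).

The bone shell occupies the band of signed distance [-t, 0] below the
analytic surface, i.e. the *superior* face of the shell is exactly the
analytic surface; ground-truth rim and area therefore live on the surface
the downstream 3D measurement sees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "VoxelVolume",
    "CohortRanges",
    "true_defect_area",
    "projected_defect_area",
    "defect_boundary_polygon",
    "rasterize_phantom",
    "sample_cohort",
]

FLOOR_KINDS = ("flat", "tilted_plane", "spherical_cap")
DEFECT_SHAPES = ("circle", "ellipse")

#: maximal polar angle of the spherical floor kept in the shell; beyond it the
#: lamella would approach vertical and stop being an orbital-floor analogue.
_CAP_MAX_POLAR_DEG = 60.0
#: lateral clearance (mm) required between the defect rim and the usable floor edge.
_RIM_MARGIN_MM = 3.0


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar grid of Hounsfield units with physical voxel spacing."""

    values: np.ndarray  # (nx, ny, nz) float32, HU
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("volume values must be a 3D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth attached to a rasterized phantom.

    ``boundary_polygon`` is an ordered open loop (closure implicit) of 3D
    points on the analytic floor surface tracing the defect rim, in the same
    mm frame as the voxel volume.
    """

    true_area_3d: float  # mm^2, intrinsic area of the removed surface patch
    boundary_polygon: np.ndarray  # (m, 3) mm
    projected_area: float  # mm^2, axial (xy) footprint area of the rim
    centroid: np.ndarray  # (3,) mm, rim centroid; rim-detection hint

    def __post_init__(self) -> None:
        if self.true_area_3d < self.projected_area - 1e-9:
            raise ValueError("surface area cannot be smaller than its planar projection")
        if self.boundary_polygon.ndim != 2 or self.boundary_polygon.shape[1] != 3:
            raise ValueError("boundary polygon must be (m, 3)")
        if len(self.boundary_polygon) < 6:
            raise ValueError("boundary polygon needs at least 6 points")


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one phantom; all lengths in mm, HU for intensities."""

    floor_kind: str = "flat"
    tilt_deg: float = 0.0
    cap_radius_mm: float = 20.0
    defect_shape: str = "circle"
    semi_axis_a_mm: float = 10.0  # mediolateral semi-axis in the floor plane
    semi_axis_b_mm: float = 10.0  # anteroposterior (in-plane) semi-axis
    shell_thickness_mm: float = 1.0
    bone_hu: float = 1200.0
    tissue_hu: float = 40.0
    air_hu: float = -1000.0
    noise_sd_hu: float = 0.0
    voxel_spacing_mm: tuple[float, float, float] = (0.4, 0.75, 0.4)
    volume_extent_mm: tuple[float, float, float] = (40.0, 40.0, 32.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry helpers ---------------------------------------------------
    @property
    def tilt_rad(self) -> float:
        return math.radians(self.tilt_deg)

    def floor_center(self) -> np.ndarray:
        """Centre of the defect on the floor, snapped in y to the coronal slice grid."""
        ex, ey, ez = self.volume_extent_mm
        dy = self.voxel_spacing_mm[1]
        cy = round((ey / 2.0) / dy) * dy
        return np.array([ex / 2.0, cy, ez / 2.0])

    def sphere_center(self) -> np.ndarray:
        """Centre of the floor sphere (spherical_cap only), directly above the apex."""
        c = self.floor_center()
        return c + np.array([0.0, 0.0, self.cap_radius_mm])

    def cap_floor_radius(self) -> float:
        """Usable lateral radius of the spherical floor."""
        return self.cap_radius_mm * math.sin(math.radians(_CAP_MAX_POLAR_DEG))

    def validate(self) -> None:
        a, b = self.semi_axis_a_mm, self.semi_axis_b_mm
        if self.floor_kind not in FLOOR_KINDS:
            raise ValueError(f"unknown floor_kind {self.floor_kind!r}")
        if self.defect_shape not in DEFECT_SHAPES:
            raise ValueError(f"unknown defect_shape {self.defect_shape!r}")
        if self.defect_shape == "circle" and not math.isclose(a, b):
            raise ValueError("circle defect requires equal semi-axes")
        if min(a, b, self.shell_thickness_mm, self.cap_radius_mm) <= 0:
            raise ValueError("semi-axes, shell thickness and cap radius must be positive")
        if not 0.0 <= self.tilt_deg <= 80.0:
            raise ValueError("tilt_deg must lie in [0, 80]")
        if not self.bone_hu > self.tissue_hu > self.air_hu:
            raise ValueError("HU ordering bone > tissue > air violated")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if any(e <= 0 for e in self.volume_extent_mm):
            raise ValueError("volume extent must be positive")

        ex, ey, ez = self.volume_extent_mm
        if self.floor_kind == "spherical_cap":
            if not math.isclose(a, b):
                raise ValueError("spherical_cap supports circular defects only (a == b)")
            if a >= self.cap_radius_mm:
                raise ValueError("defect base radius must be smaller than the cap radius")
            if a + _RIM_MARGIN_MM > self.cap_floor_radius():
                raise ValueError("defect does not fit inside the spherical floor extent")
            if a + _RIM_MARGIN_MM > min(ex, ey) / 2.0:
                raise ValueError("defect does not fit inside the volume extent")
        else:
            if a + _RIM_MARGIN_MM > ex / 2.0:
                raise ValueError("defect exceeds the mediolateral floor extent")
            # in-plane extent available along v before the tilted floor leaves the box
            c, s = math.cos(self.tilt_rad), math.sin(self.tilt_rad)
            v_max = ey / 2.0 / c if c > 1e-9 else math.inf
            if s > 1e-9:
                v_max = min(v_max, ez / 2.0 / s)
            if b + _RIM_MARGIN_MM > v_max:
                raise ValueError("defect exceeds the anteroposterior floor extent at this tilt")


# ---------------------------------------------------------------------------
# analytic ground truth


def true_defect_area(spec: PhantomSpec) -> float:
    """Closed-form intrinsic area (mm^2) of the removed floor-surface patch.

    Flat or tilted planes: pi*a*b (rotation is an isometry).  Spherical cap of
    base radius a on a sphere of radius R: 2*pi*R*h, h = R - sqrt(R^2 - a^2).
    """
    a, b = spec.semi_axis_a_mm, spec.semi_axis_b_mm
    if spec.floor_kind in ("flat", "tilted_plane"):
        return math.pi * a * b
    R = spec.cap_radius_mm
    h = R - math.sqrt(R * R - a * a)
    return 2.0 * math.pi * R * h


def projected_defect_area(spec: PhantomSpec) -> float:
    """Area (mm^2) of the rim's projection onto the axial (xy) plane."""
    a, b = spec.semi_axis_a_mm, spec.semi_axis_b_mm
    if spec.floor_kind in ("flat", "tilted_plane"):
        return math.pi * a * b * math.cos(spec.tilt_rad)
    return math.pi * a * a


def defect_boundary_polygon(spec: PhantomSpec, n_points: int = 720) -> np.ndarray:
    """Ordered loop of rim points (mm) on the analytic floor surface."""
    t = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    a, b = spec.semi_axis_a_mm, spec.semi_axis_b_mm
    c = spec.floor_center()
    if spec.floor_kind in ("flat", "tilted_plane"):
        th = spec.tilt_rad
        u_axis = np.array([1.0, 0.0, 0.0])
        v_axis = np.array([0.0, math.cos(th), math.sin(th)])
        return c + np.outer(a * np.cos(t), u_axis) + np.outer(b * np.sin(t), v_axis)
    R = spec.cap_radius_mm
    cs = spec.sphere_center()
    z = cs[2] - math.sqrt(R * R - a * a)
    return np.c_[cs[0] + a * np.cos(t), cs[1] + a * np.sin(t), np.full_like(t, z)]


def _signed_distance_and_regions(
    spec: PhantomSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed distance to the floor surface (+ superior), defect membership, floor support."""
    c = spec.floor_center()
    if spec.floor_kind in ("flat", "tilted_plane"):
        th = spec.tilt_rad
        n = np.array([0.0, -math.sin(th), math.cos(th)])  # superior-facing normal
        d = (x - c[0]) * n[0] + (y - c[1]) * n[1] + (z - c[2]) * n[2]
        # in-plane coordinates; defect removed perpendicular to the floor
        u = x - c[0]
        v = (y - c[1]) * math.cos(th) + (z - c[2]) * math.sin(th)
        in_defect = (u / spec.semi_axis_a_mm) ** 2 + (v / spec.semi_axis_b_mm) ** 2 <= 1.0
        support = np.ones_like(d, dtype=bool)
        return d, in_defect, support
    cs = spec.sphere_center()
    r = np.sqrt((x - cs[0]) ** 2 + (y - cs[1]) ** 2 + (z - cs[2]) ** 2)
    d = spec.cap_radius_mm - r  # positive inside the sphere = superior side
    lat2 = (x - cs[0]) ** 2 + (y - cs[1]) ** 2
    in_defect = lat2 <= spec.semi_axis_a_mm**2
    support = (lat2 <= spec.cap_floor_radius() ** 2) & (z < cs[2])
    return d, in_defect, support


def rasterize_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Voxelize a phantom spec into an HU volume plus its analytic ground truth.

    Bone occupies the shell band of signed distance [-t, 0] below the floor
    surface, minus the defect region; the superior half-space gets tissue HU,
    the inferior (maxillary-sinus) side air HU; the defect channel is filled
    with tissue (herniated soft tissue).  Optional seeded Gaussian noise.
    """
    dx, dy, dz = spec.voxel_spacing_mm
    ex, ey, ez = spec.volume_extent_mm
    nx, ny, nz = (max(2, int(round(e / s))) for e, s in zip((ex, ey, ez), (dx, dy, dz)))
    x = (np.arange(nx) * dx)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    z = (np.arange(nz) * dz)[None, None, :]

    d, in_defect, support = _signed_distance_and_regions(spec, x, y, z)
    t = spec.shell_thickness_mm
    shell = (d >= -t) & (d <= 0.0) & support

    values = np.where(d > 0.0, spec.tissue_hu, spec.air_hu)
    values = np.where(shell, spec.bone_hu, values)
    values = np.where(shell & in_defect, spec.tissue_hu, values)
    values = np.broadcast_to(values, (nx, ny, nz)).astype(np.float32)

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd_hu, size=values.shape).astype(np.float32)

    volume = VoxelVolume(values=np.ascontiguousarray(values), spacing=(dx, dy, dz))
    polygon = defect_boundary_polygon(spec)
    truth = GroundTruth(
        true_area_3d=true_defect_area(spec),
        boundary_polygon=polygon,
        projected_area=projected_defect_area(spec),
        centroid=polygon.mean(axis=0),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# cohort sampling


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for a synthetic fracture cohort.

    Defaults emulate the observed clinical spread of defect areas (tens of
    mm^2 up to ~650 mm^2) across flat, tilted and curved floor geometries.
    """

    area_range_mm2: tuple[float, float] = (60.0, 620.0)
    tilt_range_deg: tuple[float, float] = (5.0, 45.0)
    cap_radius_range_mm: tuple[float, float] = (15.0, 30.0)
    aspect_range: tuple[float, float] = (0.8, 1.25)  # b/a for planar ellipses
    kind_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # flat, tilted, cap
    noise_sd_hu: float = 25.0

    def __post_init__(self) -> None:
        lo, hi = self.area_range_mm2
        if not 0 < lo < hi:
            raise ValueError("area range must satisfy 0 < lo < hi")
        if sum(self.kind_weights) <= 0 or min(self.kind_weights) < 0:
            raise ValueError("kind weights must be non-negative and not all zero")


def _cap_base_radius(area: float, R: float) -> float:
    """Invert 2*pi*R*h for the base radius a given cap area."""
    h = area / (2.0 * math.pi * R)
    return math.sqrt(max(2.0 * R * h - h * h, 0.0))


def sample_cohort(
    n: int, ranges: CohortRanges | None = None, seed: int = 0
) -> list[PhantomSpec]:
    """Draw ``n`` phantom specs whose analytic areas span the configured range."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    probs = np.asarray(ranges.kind_weights, dtype=float)
    probs = probs / probs.sum()

    base = PhantomSpec()
    ex = base.volume_extent_mm[0]
    specs: list[PhantomSpec] = []
    while len(specs) < n:
        kind = rng.choice(FLOOR_KINDS, p=probs)
        area = rng.uniform(*ranges.area_range_mm2)
        seed_i = int(rng.integers(0, 2**31 - 1))
        try:
            if kind == "spherical_cap":
                R = rng.uniform(*ranges.cap_radius_range_mm)
                a = _cap_base_radius(area, R)
                spec = replace(
                    base,
                    floor_kind="spherical_cap",
                    cap_radius_mm=R,
                    defect_shape="circle",
                    semi_axis_a_mm=a,
                    semi_axis_b_mm=a,
                    noise_sd_hu=ranges.noise_sd_hu,
                    seed=seed_i,
                )
            else:
                tilt = 0.0 if kind == "flat" else rng.uniform(*ranges.tilt_range_deg)
                ratio = rng.uniform(*ranges.aspect_range)
                a = math.sqrt(area / (math.pi * ratio))
                a = min(a, ex / 2.0 - _RIM_MARGIN_MM - 0.5)
                b = area / (math.pi * a)
                spec = replace(
                    base,
                    floor_kind=kind,
                    tilt_deg=tilt,
                    defect_shape="ellipse" if abs(b - a) > 1e-12 else "circle",
                    semi_axis_a_mm=a,
                    semi_axis_b_mm=b,
                    noise_sd_hu=ranges.noise_sd_hu,
                    seed=seed_i,
                )
        except ValueError:
            continue  # geometry did not fit; redraw
        specs.append(spec)
    return specs
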