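"""Synthetic voxelized head phantoms and tissue conductivity maps.

The phantom is the anatomical substrate for the volume-conductor solve: a
set of nested ellipsoidal shells (scalp, skull, CSF, brain) on a regular
voxel grid, a posterior-inferior cerebellar compartment holding a spherical
gross tumor volume (GTV) with an optional concentric necrotic core, a
brainstem cylinder, and a neck cylinder (skin over muscle over vertebral
bone) so that arrays can be placed on the lower occiput and upper neck.

Real segmented label volumes in NIfTI-1 format are read and written with
the same integer label vocabulary (:class:`Tissue`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import VoxelGrid

__all__ = [
    "Tissue",
    "LabelVolume",
    "ROIMask",
    "PhantomSpec",
    "ConductivityTable",
    "DEFAULT_CONDUCTIVITY",
    "GeometryError",
    "build_phantom",
    "assign_conductivity",
    "read_label_volume",
    "write_label_volume",
]


class Tissue(IntEnum):
    """Fixed integer label vocabulary for head segmentations."""

    AIR = 0
    SCALP = 1
    SKULL = 2
    CSF = 3
    BRAIN = 4          # supratentorial brain
    CEREBELLUM = 5
    BRAINSTEM = 6
    MUSCLE = 7         # neck / generic soft tissue
    VERTEBRA = 8
    GTV = 9
    NECROTIC_CORE = 10
    GEL = 11
    ELECTRODE = 12


class GeometryError(ValueError):
    """Raised when a phantom specification is geometrically invalid."""


@dataclass
class LabelVolume:
    """Integer tissue labels on a regular voxel grid."""

    grid: VoxelGrid
    labels: np.ndarray  # int16, shape == grid.shape

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError(
                f"label array shape {self.labels.shape} != grid shape {self.grid.shape}"
            )

    def mask(self, *tissues: Tissue) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        m = np.zeros(self.labels.shape, dtype=bool)
        for t in tissues:
            m |= self.labels == int(t)
        return m

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid, self.labels.copy())


@dataclass
class ROIMask:
    """Region-of-interest membership flags on a voxel grid."""

    grid: VoxelGrid
    name: str
    member: np.ndarray  # bool, shape == grid.shape

    def __post_init__(self) -> None:
        self.member = np.ascontiguousarray(self.member, dtype=bool)
        if self.member.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match its grid")

    @property
    def voxel_count(self) -> int:
        return int(self.member.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume


# ----------------------------------------------------------------------
# Phantom specification
# ----------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Declarative description of the synthetic head phantom.

    All lengths are millimetres in RAS world coordinates; the head-shell
    center sits at the world origin. Shell thicknesses are subtracted from
    the scalp semi-axes per axis, so nesting (scalp > skull > CSF > brain)
    holds by construction for positive thicknesses.
    """

    spacing: float = 4.0
    x_extent: tuple[float, float] = (-96.0, 96.0)
    y_extent: tuple[float, float] = (-120.0, 120.0)
    z_extent: tuple[float, float] = (-148.0, 100.0)

    # head shells; thicknesses are integer multiples of the working grid
    # spacings (4 mm default, 2 mm fine) so the thin shells rasterize
    # consistently across resolutions instead of aliasing
    scalp_axes: tuple[float, float, float] = (82.0, 102.0, 88.0)
    scalp_thickness: float = 8.0
    skull_thickness: float = 8.0
    csf_thickness: float = 4.0

    # intracranial compartments
    cerebellum_center: tuple[float, float, float] = (0.0, -35.0, -45.0)
    cerebellum_axes: tuple[float, float, float] = (45.0, 38.0, 30.0)
    brainstem_center_xy: tuple[float, float] = (0.0, -10.0)
    brainstem_radius: float = 10.0
    brainstem_z: tuple[float, float] = (-75.0, -15.0)

    # tumor: dorsal midline posterior fossa
    gtv_center: tuple[float, float, float] = (0.0, -48.0, -40.0)
    gtv_radius: float = 12.0
    necrotic_radius: float = 4.0

    # neck
    neck_top_z: float = -40.0
    neck_skin_radius: float = 55.0
    neck_muscle_radius: float = 50.0
    neck_center_xy: tuple[float, float] = (0.0, -15.0)
    vertebra_radius: float = 16.0
    vertebra_center_xy: tuple[float, float] = (0.0, -25.0)

    # optional left/right asymmetry: the head-shell center is displaced by
    # a uniform random offset in [-jitter_mm, +jitter_mm] per axis
    jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GeometryError("spacing must be > 0")
        for t in (self.scalp_thickness, self.skull_thickness, self.csf_thickness):
            if t <= 0:
                raise GeometryError("shell thicknesses must be > 0")
        if self.gtv_radius < 0 or self.necrotic_radius < 0:
            raise GeometryError("radii must be >= 0")
        if self.necrotic_radius > self.gtv_radius:
            raise GeometryError("necrotic core radius must not exceed GTV radius")
        if self.skull_thickness / self.spacing < 2.0:
            raise GeometryError(
                f"grid spacing {self.spacing} mm too coarse to resolve the "
                f"{self.skull_thickness} mm skull shell (< 2 voxels thick)"
            )
        total = self.scalp_thickness + self.skull_thickness + self.csf_thickness
        if min(self.scalp_axes) <= total:
            raise GeometryError("head semi-axes too small for the shell thicknesses")

    # derived shell semi-axes (outer surface of each shell)
    @property
    def skull_axes(self) -> tuple[float, float, float]:
        return tuple(a - self.scalp_thickness for a in self.scalp_axes)

    @property
    def csf_axes(self) -> tuple[float, float, float]:
        return tuple(a - self.skull_thickness for a in self.skull_axes)

    @property
    def brain_axes(self) -> tuple[float, float, float]:
        return tuple(a - self.csf_thickness for a in self.csf_axes)

    def make_grid(self) -> VoxelGrid:
        return VoxelGrid.from_extent(
            (self.x_extent[0], self.y_extent[0], self.z_extent[0]),
            (self.x_extent[1], self.y_extent[1], self.z_extent[1]),
            self.spacing,
        )

    def with_spacing(self, spacing: float) -> "PhantomSpec":
        return replace(self, spacing=spacing)


def mini_spec() -> PhantomSpec:
    """A reduced-size head (≈0.6 linear scale) for fast tests."""
    return PhantomSpec(
        spacing=4.0,
        x_extent=(-60.0, 60.0),
        y_extent=(-76.0, 76.0),
        z_extent=(-92.0, 64.0),
        scalp_axes=(50.0, 62.0, 54.0),
        cerebellum_center=(0.0, -21.0, -27.0),
        cerebellum_axes=(27.0, 23.0, 18.0),
        brainstem_center_xy=(0.0, -6.0),
        brainstem_radius=7.0,
        brainstem_z=(-45.0, -9.0),
        gtv_center=(0.0, -29.0, -24.0),
        gtv_radius=8.0,
        necrotic_radius=2.0,
        neck_top_z=-24.0,
        neck_skin_radius=33.0,
        neck_muscle_radius=30.0,
        neck_center_xy=(0.0, -9.0),
        vertebra_radius=10.0,
        vertebra_center_xy=(0.0, -15.0),
    )


# ----------------------------------------------------------------------
# Phantom construction
# ----------------------------------------------------------------------

def _ellipsoid_q(x, y, z, center, axes):
    """Normalized squared radius of an axis-aligned ellipsoid (<= 1 inside)."""
    return (
        ((x - center[0]) / axes[0]) ** 2
        + ((y - center[1]) / axes[1]) ** 2
        + ((z - center[2]) / axes[2]) ** 2
    )


def build_phantom(spec: PhantomSpec) -> tuple[LabelVolume, dict[str, ROIMask]]:
    """Rasterize a :class:`PhantomSpec` into a labeled head volume.

    Returns the label volume plus ROI masks for ``GTV`` (including any
    necrotic core, which clinically lies within the GTV) and
    ``CEREBELLUM``. Deterministic given the spec, including its seed.
    """
    grid = spec.make_grid()
    xs, ys, zs = grid.axes()
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]

    rng = np.random.default_rng(spec.seed)
    jitter = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3) if spec.jitter_mm > 0 else np.zeros(3)
    head_c = tuple(jitter)  # head-shell center, nominally the origin

    labels = np.zeros(grid.shape, dtype=np.int16)

    q_scalp = _ellipsoid_q(x, y, z, head_c, spec.scalp_axes)
    q_skull = _ellipsoid_q(x, y, z, head_c, spec.skull_axes)
    q_csf = _ellipsoid_q(x, y, z, head_c, spec.csf_axes)
    q_brain = _ellipsoid_q(x, y, z, head_c, spec.brain_axes)

    labels[q_scalp <= 1.0] = Tissue.SCALP
    labels[q_skull <= 1.0] = Tissue.SKULL
    labels[q_csf <= 1.0] = Tissue.CSF
    in_brain = q_brain <= 1.0
    labels[in_brain] = Tissue.BRAIN

    # posterior-inferior cerebellar compartment, clipped to the cranial cavity
    cb_c = tuple(np.asarray(spec.cerebellum_center) + jitter)
    in_cereb = (_ellipsoid_q(x, y, z, cb_c, spec.cerebellum_axes) <= 1.0) & in_brain
    labels[in_cereb] = Tissue.CEREBELLUM

    bs_cx, bs_cy = spec.brainstem_center_xy[0] + jitter[0], spec.brainstem_center_xy[1] + jitter[1]
    in_stem = (
        ((x - bs_cx) ** 2 + (y - bs_cy) ** 2 <= spec.brainstem_radius**2)
        & (z >= spec.brainstem_z[0])
        & (z <= spec.brainstem_z[1])
        & in_brain
    )
    labels[in_stem] = Tissue.BRAINSTEM

    # GTV sphere (dorsal midline posterior fossa), clipped to the cavity
    gtv_c = tuple(np.asarray(spec.gtv_center) + jitter)
    q_cavity = _ellipsoid_q(*gtv_c, head_c, spec.brain_axes)
    if q_cavity > 1.0:
        raise GeometryError(
            f"GTV center {spec.gtv_center} lies outside the cranial cavity"
        )
    if spec.gtv_radius > 0:
        r2 = (x - gtv_c[0]) ** 2 + (y - gtv_c[1]) ** 2 + (z - gtv_c[2]) ** 2
        in_gtv = (r2 <= spec.gtv_radius**2) & in_brain
        labels[in_gtv] = Tissue.GTV
        if spec.necrotic_radius > 0:
            labels[(r2 <= spec.necrotic_radius**2) & in_brain] = Tissue.NECROTIC_CORE
    else:
        in_gtv = np.zeros(grid.shape, dtype=bool)
        warnings.warn("GTV radius is 0: phantom has an empty tumor mask", stacklevel=2)

    # neck below the skull base, only where still air
    is_air = labels == Tissue.AIR
    below = np.broadcast_to(z <= spec.neck_top_z, grid.shape)
    nx_c, ny_c = spec.neck_center_xy
    vx_c, vy_c = spec.vertebra_center_xy
    r2_neck = (x - nx_c) ** 2 + (y - ny_c) ** 2
    r2_vert = (x - vx_c) ** 2 + (y - vy_c) ** 2
    neck_skin = is_air & below & np.broadcast_to(r2_neck <= spec.neck_skin_radius**2, grid.shape)
    labels[neck_skin] = Tissue.SCALP
    neck_muscle = is_air & below & np.broadcast_to(r2_neck <= spec.neck_muscle_radius**2, grid.shape)
    labels[neck_muscle] = Tissue.MUSCLE
    neck_vert = is_air & below & np.broadcast_to(r2_vert <= spec.vertebra_radius**2, grid.shape)
    labels[neck_vert & neck_muscle] = Tissue.VERTEBRA

    volume = LabelVolume(grid, labels)
    masks = {
        "GTV": ROIMask(grid, "GTV", volume.mask(Tissue.GTV, Tissue.NECROTIC_CORE)),
        "CEREBELLUM": ROIMask(grid, "CEREBELLUM", volume.mask(Tissue.CEREBELLUM)),
    }
    return volume, masks


# ----------------------------------------------------------------------
# Conductivity
# ----------------------------------------------------------------------

#: Literature-style isotropic conductivities at 200 kHz, S/m (configurable;
#: AIR is excluded from the solve domain rather than assigned a value).
DEFAULT_CONDUCTIVITY: dict[Tissue, float] = {
    Tissue.AIR: 0.0,
    Tissue.SCALP: 0.465,
    Tissue.SKULL: 0.010,
    Tissue.CSF: 1.654,
    Tissue.BRAIN: 0.276,
    Tissue.CEREBELLUM: 0.276,
    Tissue.BRAINSTEM: 0.276,
    Tissue.MUSCLE: 0.355,
    Tissue.VERTEBRA: 0.010,
    Tissue.GTV: 0.24,
    Tissue.NECROTIC_CORE: 1.0,
    Tissue.GEL: 4.0,
    Tissue.ELECTRODE: 1.0e4,
}


@dataclass
class ConductivityTable:
    """Label -> conductivity (S/m) lookup; permittivity is carried but unused
    by the conductivity-only quasi-static solver."""

    sigma: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CONDUCTIVITY))
    permittivity: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.sigma = {int(k): float(v) for k, v in self.sigma.items()}
        for label, value in self.sigma.items():
            if label == Tissue.AIR:
                continue
            if value <= 0:
                raise ValueError(
                    f"conductivity for label {Tissue(label).name if label in Tissue._value2member_map_ else label} "
                    f"must be > 0, got {value}"
                )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ConductivityTable":
        out: dict[int, float] = {}
        for key, value in mapping.items():
            if isinstance(key, str):
                key = Tissue[key.upper()]
            out[int(key)] = float(value)
        return cls(sigma=out)

    def to_mapping(self) -> dict[str, float]:
        return {Tissue(k).name: v for k, v in sorted(self.sigma.items())}


def assign_conductivity(
    volume: LabelVolume, table: ConductivityTable | None = None
) -> np.ndarray:
    """Per-voxel conductivity (S/m); AIR voxels get 0 and are excluded
    from the solve domain downstream.

    Raises ``KeyError`` naming the first label without a table entry.
    """
    if table is None:
        table = ConductivityTable()
    present = np.unique(volume.labels)
    lut = np.zeros(int(present.max()) + 1, dtype=float)
    for label in present:
        label = int(label)
        if label == Tissue.AIR:
            continue  # always excluded from the domain
        if label not in table.sigma:
            name = Tissue(label).name if label in Tissue._value2member_map_ else str(label)
            raise KeyError(f"no conductivity entry for label {name} ({label})")
        lut[label] = table.sigma[label]
    return lut[volume.labels]


# ----------------------------------------------------------------------
# NIfTI I/O
# ----------------------------------------------------------------------

def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write an integer label volume as NIfTI-1 (RAS affine, mm units)."""
    img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read an integer NIfTI-1 label volume.

    The affine must be axis-aligned RAS (diagonal up to numerical noise);
    float-typed data are rejected, since labels must be exact integers.
    """
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if not np.issubdtype(dtype, np.integer):
        raise ValueError(f"label volume must have integer data, got dtype {dtype}")
    aff = img.affine
    if aff is None:
        raise ValueError("NIfTI file carries no affine")
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise ValueError("only axis-aligned RAS affines are supported")
    spacing = tuple(np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise ValueError("affine must be RAS with positive spacings")
    data = np.asarray(img.dataobj).astype(np.int16)
    grid = VoxelGrid(shape=data.shape, spacing=spacing, origin=tuple(aff[:3, 3]))
    return LabelVolume(grid, data)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    """Export an ROI mask as a 0/1 NIfTI volume."""
    img = nib.Nifti1Image(mask.member.astype(np.uint8), mask.grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
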