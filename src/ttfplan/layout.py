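"""Transducer-array montage geometry on the scalp.

TTFields are delivered through two orthogonal channels, each a pair of
3x3 disc arrays (anterior-posterior and left-right). This module places
those arrays on the scalp of a label volume by parallel ray casting along
an outward direction, realizes the seven named montage configurations
(the conventional supratentorial layout plus six posterior-fossa
alternatives), and rasterizes each disc into a one-voxel gel layer capped
by electrode voxels for use as solver boundary conditions.

Placement model: the nine disc target points are laid out on the plane
through the array anchor perpendicular to the placement direction, then
each is projected onto the scalp along that direction. This conforms the
array to the scalp for convex head shapes; geodesic unrolling on strongly
non-convex surfaces is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import VoxelGrid
from .phantom import LabelVolume, Tissue

__all__ = [
    "ElectrodeDisc",
    "TransducerArray",
    "ArrayLayout",
    "ElectrodePatch",
    "ElectrodeModel",
    "LayoutError",
    "CONFIGURATIONS",
    "place_array",
    "named_configuration",
    "rasterize_electrodes",
    "save_layout",
    "load_layout",
]

CONFIGURATIONS = (
    "SUPRATENTORIAL",
    "PA_HORIZONTAL",
    "PA_HORIZONTAL_RIGHT",
    "PA_HORIZONTAL_LEFT",
    "PA_VERTICAL_SUPERIOR",
    "PA_VERTICAL_CENTER",
    "AP_PA_HORIZONTAL",
)

#: Tissue codes that count as "body" for surface finding.
_BODY = frozenset(int(t) for t in Tissue if t not in (Tissue.AIR, Tissue.GEL, Tissue.ELECTRODE))


class LayoutError(ValueError):
    """Raised for invalid montage geometry."""


@dataclass
class ElectrodeDisc:
    center: np.ndarray        # mm, on the scalp surface
    normal: np.ndarray        # outward unit vector
    radius: float             # mm
    channel: str              # "AP_PA" or "LEFT_RIGHT"
    polarity: int             # +1 or -1
    array_id: str             # "AP", "PA", "LEFT", "RIGHT"
    index: int = 0            # 0..8 within the 3x3 grid

    @property
    def disc_id(self) -> str:
        return f"{self.array_id}_{self.index}"


@dataclass
class TransducerArray:
    array_id: str
    channel: str
    polarity: int
    discs: list[ElectrodeDisc]
    center: np.ndarray
    long_axis: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        if len(self.discs) != 9:
            raise LayoutError(f"array {self.array_id} must have exactly 9 discs")


@dataclass
class ArrayLayout:
    """Four placed arrays realizing one named configuration."""

    name: str
    arrays: dict[str, TransducerArray]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"AP", "PA", "LEFT", "RIGHT"} - set(self.arrays)
        if missing:
            raise LayoutError(f"layout missing arrays: {sorted(missing)}")

    def channel_arrays(self, channel: str) -> tuple[TransducerArray, TransducerArray]:
        """(anode, cathode) arrays of one channel."""
        pair = [a for a in self.arrays.values() if a.channel == channel]
        if len(pair) != 2:
            raise LayoutError(f"channel {channel} does not have exactly 2 arrays")
        pair.sort(key=lambda a: -a.polarity)
        return pair[0], pair[1]


# ----------------------------------------------------------------------
# Surface ray casting
# ----------------------------------------------------------------------

def _inside(labels: np.ndarray, grid: VoxelGrid, point: np.ndarray) -> bool:
    """Whether the nearest voxel to a world point is body tissue."""
    ijk = np.rint(grid.world_to_voxel(point)).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.asarray(grid.shape)):
        return False
    return int(labels[tuple(ijk)]) in _BODY


def surface_hit(volume: LabelVolume, start: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Outermost body->air crossing along ``start + t*direction``, t >= 0.

    The ray is sampled at quarter-voxel steps; the final crossing is
    refined by bisection, giving a sub-voxel surface point.
    """
    grid = volume.grid
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise LayoutError("direction must be non-zero")
    d = d / norm
    start = np.asarray(start, dtype=float)

    step = 0.25 * min(grid.spacing)
    extent = np.asarray(grid.spacing) * np.asarray(grid.shape)
    t_max = float(np.linalg.norm(extent)) + step
    ts = np.arange(0.0, t_max, step)
    inside = np.array([_inside(volume.labels, grid, start + t * d) for t in ts])
    if not inside.any():
        raise LayoutError("ray does not intersect the head")
    i_last = int(np.max(np.nonzero(inside)))
    if i_last == len(ts) - 1:
        raise LayoutError("ray exits the grid while still inside the body")
    lo, hi = ts[i_last], ts[i_last + 1]
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if _inside(volume.labels, grid, start + mid * d):
            lo = mid
        else:
            hi = mid
    return start + 0.5 * (lo + hi) * d


def head_anchor(volume: LabelVolume) -> np.ndarray:
    """Centroid (mm) of the intracranial compartment; the default ray origin."""
    m = volume.mask(
        Tissue.BRAIN, Tissue.CEREBELLUM, Tissue.BRAINSTEM,
        Tissue.CSF, Tissue.GTV, Tissue.NECROTIC_CORE,
    )
    if not m.any():
        m = volume.labels > 0
    if not m.any():
        raise LayoutError("volume contains no body voxels")
    ijk = np.argwhere(m)
    return volume.grid.voxel_to_world(ijk.mean(axis=0))


# ----------------------------------------------------------------------
# Array placement
# ----------------------------------------------------------------------

def place_array(
    volume: LabelVolume,
    direction: np.ndarray,
    long_axis: np.ndarray,
    *,
    origin: np.ndarray | None = None,
    disc_radius: float = 10.0,
    pitch: float = 22.0,
    array_id: str = "ARRAY",
    channel: str = "AP_PA",
    polarity: int = 1,
) -> TransducerArray:
    """Place one 3x3 disc array on the scalp.

    The array anchor ray starts at ``origin`` (default: intracranial
    centroid) and runs along ``direction``; disc target points are offset
    on the perpendicular plane by ``pitch`` along the projected
    ``long_axis`` (rows) and its in-plane perpendicular (columns), then
    each is ray-cast onto the scalp along ``direction``.
    """
    if disc_radius <= 0:
        raise LayoutError("disc radius must be > 0")
    if disc_radius > pitch / 2:
        raise LayoutError(
            f"disc radius {disc_radius} mm > pitch/2 = {pitch / 2} mm: discs overlap"
        )
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    u = np.asarray(long_axis, dtype=float)
    u = u - np.dot(u, n) * n
    if np.linalg.norm(u) < 1e-9:
        raise LayoutError("long_axis is parallel to the placement direction")
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    if origin is None:
        origin = head_anchor(volume)
    origin = np.asarray(origin, dtype=float)

    discs: list[ElectrodeDisc] = []
    for idx, (row, col) in enumerate(
        (r, c) for r in (-1, 0, 1) for c in (-1, 0, 1)
    ):
        start = origin + pitch * (row * u + col * v)
        hit = surface_hit(volume, start, n)
        discs.append(
            ElectrodeDisc(
                center=hit, normal=n.copy(), radius=disc_radius,
                channel=channel, polarity=polarity, array_id=array_id, index=idx,
            )
        )
    center = discs[4].center  # row=0, col=0
    return TransducerArray(
        array_id=array_id, channel=channel, polarity=polarity,
        discs=discs, center=center, long_axis=u, pitch=pitch,
    )


def _rot_z(vec: np.ndarray, degrees: float) -> np.ndarray:
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    x, y, z = vec
    return np.array([c * x - s * y, s * x + c * y, z])


#: Default montage geometry. Directions are unnormalized outward vectors in
#: RAS; origins are offsets (mm) from the intracranial centroid. The
#: supratentorial anchors approximate the conventional layout (AP on the
#: forehead, PA high on the occiput, laterals over temporoparietal scalp);
#: the six alternatives move the laterals posteriorly with a slight
#: rotation and drop the PA array to the lower occiput / upper neck.
DEFAULT_PARAMS: dict = {
    "disc_radius": 10.0,
    "pitch": 22.0,
    "ap_dir": (0.0, 1.0, 0.35),
    "supra_pa_dir": (0.0, -1.0, 0.55),
    "supra_lateral_z": 0.25,
    "alt_lateral_dir": (1.0, -0.45, 0.15),   # mirrored in x for LEFT
    "lateral_rotation_deg": 15.0,            # posterior rotation of lateral long axes
    "pa_horizontal_origin": (0.0, -15.0, -72.0),
    "pa_lateral_shift_mm": 20.0,             # the routine 2 cm array exchange shift
    "pa_vertical_center_origin": (0.0, 0.0, -20.0),
    "pa_vertical_center_dir": (0.0, -1.0, -0.2),
    "pa_vertical_superior_origin": (0.0, 0.0, 0.0),
    "pa_vertical_superior_dir": (0.0, -1.0, 0.1),
}


def named_configuration(
    name: str, volume: LabelVolume, params: dict | None = None
) -> ArrayLayout:
    """Build one of the seven named montage configurations.

    Pure function of (name, volume, params): identical inputs give an
    identical layout.
    """
    if name not in CONFIGURATIONS:
        raise LayoutError(
            f"unknown configuration {name!r}; choose one of {list(CONFIGURATIONS)}"
        )
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    anchor = head_anchor(volume)
    r, pitch = p["disc_radius"], p["pitch"]

    def place(array_id, channel, polarity, direction, long_axis, origin_offset=(0, 0, 0)):
        return place_array(
            volume, np.asarray(direction, float), np.asarray(long_axis, float),
            origin=anchor + np.asarray(origin_offset, float),
            disc_radius=r, pitch=pitch,
            array_id=array_id, channel=channel, polarity=polarity,
        )

    x_axis, y_axis, z_axis = (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)
    supratentorial = name == "SUPRATENTORIAL"

    # --- lateral (LEFT/RIGHT) channel -------------------------------
    if supratentorial:
        lz = p["supra_lateral_z"]
        left = place("LEFT", "LEFT_RIGHT", +1, (-1.0, 0.0, lz), y_axis)
        right = place("RIGHT", "LEFT_RIGHT", -1, (1.0, 0.0, lz), y_axis)
    else:
        dx, dy, dz = p["alt_lateral_dir"]
        rot = p["lateral_rotation_deg"]
        # long axes rotated posteriorly, mirror-symmetrically
        left = place("LEFT", "LEFT_RIGHT", +1, (-dx, dy, dz), _rot_z(np.array(y_axis), -rot))
        right = place("RIGHT", "LEFT_RIGHT", -1, (dx, dy, dz), _rot_z(np.array(y_axis), rot))

    # --- AP array ----------------------------------------------------
    ap_long = z_axis if name == "AP_PA_HORIZONTAL" else x_axis
    ap = place("AP", "AP_PA", +1, p["ap_dir"], ap_long)

    # --- PA array ----------------------------------------------------
    shift = p["pa_lateral_shift_mm"]
    if supratentorial:
        pa = place("PA", "AP_PA", -1, p["supra_pa_dir"], x_axis)
    elif name in ("PA_HORIZONTAL", "AP_PA_HORIZONTAL", "PA_HORIZONTAL_RIGHT", "PA_HORIZONTAL_LEFT"):
        off = np.asarray(p["pa_horizontal_origin"], float)
        if name == "PA_HORIZONTAL_RIGHT":
            off = off + np.array([shift, 0.0, 0.0])
        elif name == "PA_HORIZONTAL_LEFT":
            off = off - np.array([shift, 0.0, 0.0])
        pa = place("PA", "AP_PA", -1, (0.0, -1.0, 0.0), x_axis, origin_offset=off)
    elif name == "PA_VERTICAL_SUPERIOR":
        pa = place("PA", "AP_PA", -1, p["pa_vertical_superior_dir"], z_axis,
                   origin_offset=p["pa_vertical_superior_origin"])
    else:  # PA_VERTICAL_CENTER
        pa = place("PA", "AP_PA", -1, p["pa_vertical_center_dir"], z_axis,
                   origin_offset=p["pa_vertical_center_origin"])

    return ArrayLayout(
        name=name,
        arrays={"AP": ap, "PA": pa, "LEFT": left, "RIGHT": right},
        params=p,
    )


# ----------------------------------------------------------------------
# Electrode rasterization
# ----------------------------------------------------------------------

@dataclass
class ElectrodePatch:
    """Voxelized realization of one disc: gel layer + electrode cap."""

    disc_id: str
    array_id: str
    channel: str
    polarity: int
    gel: np.ndarray        # (N, 3) voxel indices
    electrode: np.ndarray  # (M, 3) voxel indices


@dataclass
class ElectrodeModel:
    """Label volume with GEL/ELECTRODE voxels plus per-disc patch lists."""

    volume: LabelVolume
    patches: list[ElectrodePatch]

    def electrode_indices(self, array_id: str) -> np.ndarray:
        """All electrode voxel indices of one array, (K, 3)."""
        parts = [p.electrode for p in self.patches if p.array_id == array_id]
        return np.concatenate(parts, axis=0)


def _face_adjacent(mask: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-connected neighbor in ``mask``."""
    out = np.zeros_like(mask)
    out[1:, :, :] |= mask[:-1, :, :]
    out[:-1, :, :] |= mask[1:, :, :]
    out[:, 1:, :] |= mask[:, :-1, :]
    out[:, :-1, :] |= mask[:, 1:, :]
    out[:, :, 1:] |= mask[:, :, :-1]
    out[:, :, :-1] |= mask[:, :, 1:]
    return out


def rasterize_electrodes(layout, volume: LabelVolume) -> ElectrodeModel:
    """Rasterize every disc of a layout into GEL and ELECTRODE voxels.

    Gel is the one-voxel air layer in contact with the body inside the
    disc footprint (lateral distance from the disc axis <= radius); the
    electrode cap is the air layer in contact with that gel. Anatomy
    labels are never modified, so removing a layout recovers the input
    volume exactly. ``layout`` may be an :class:`ArrayLayout` or any
    iterable of :class:`TransducerArray`.
    """
    arrays = layout.arrays.values() if isinstance(layout, ArrayLayout) else list(layout)
    grid = volume.grid
    labels = volume.labels.copy()
    body = np.isin(volume.labels, np.fromiter(_BODY, dtype=np.int16))
    body_adj = _face_adjacent(body)
    shape = np.asarray(grid.shape)
    spacing = np.asarray(grid.spacing)

    patches: list[ElectrodePatch] = []
    for array in arrays:
        for disc in array.discs:
            n = disc.normal
            c = disc.center
            band_lo, band_hi = -1.5 * spacing.max(), 3.0 * spacing.max()
            pad = disc.radius + 2.0 * spacing.max() + band_hi
            lo = np.maximum(np.floor(grid.world_to_voxel(c - pad)).astype(int), 0)
            hi = np.minimum(np.ceil(grid.world_to_voxel(c + pad)).astype(int) + 1, shape)
            sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

            ii, jj, kk = np.meshgrid(
                np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
                indexing="ij",
            )
            pts = grid.voxel_to_world(np.stack([ii, jj, kk], axis=-1)) - c
            along = pts @ n
            lat2 = np.einsum("...i,...i", pts, pts) - along**2
            footprint = (lat2 <= disc.radius**2) & (along >= band_lo) & (along <= band_hi)

            air = labels[sl] == Tissue.AIR
            gel_local = footprint & air & body_adj[sl]
            if not gel_local.any():
                raise LayoutError(f"disc {disc.disc_id} rasterizes to zero gel voxels")
            gel_ijk = np.stack([ii[gel_local], jj[gel_local], kk[gel_local]], axis=1)
            labels[gel_ijk[:, 0], gel_ijk[:, 1], gel_ijk[:, 2]] = Tissue.GEL

            gel_full = np.zeros(tuple(hi - lo), dtype=bool)
            gel_full[gel_local] = True
            elec_local = footprint & (labels[sl] == Tissue.AIR) & _face_adjacent(gel_full)
            if not elec_local.any():
                raise LayoutError(f"disc {disc.disc_id} rasterizes to zero electrode voxels")
            elec_ijk = np.stack([ii[elec_local], jj[elec_local], kk[elec_local]], axis=1)
            labels[elec_ijk[:, 0], elec_ijk[:, 1], elec_ijk[:, 2]] = Tissue.ELECTRODE

            patches.append(
                ElectrodePatch(
                    disc_id=disc.disc_id, array_id=disc.array_id,
                    channel=disc.channel, polarity=disc.polarity,
                    gel=gel_ijk, electrode=elec_ijk,
                )
            )
    return ElectrodeModel(volume=LabelVolume(grid, labels), patches=patches)


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

def save_layout(layout: ArrayLayout, path: str | Path) -> None:
    doc = {
        "name": layout.name,
        "params": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                   for k, v in layout.params.items()},
        "arrays": {
            aid: {
                "channel": a.channel,
                "polarity": a.polarity,
                "pitch": a.pitch,
                "long_axis": a.long_axis.tolist(),
                "center": a.center.tolist(),
                "discs": [
                    {
                        "index": d.index,
                        "center": d.center.tolist(),
                        "normal": d.normal.tolist(),
                        "radius": d.radius,
                    }
                    for d in a.discs
                ],
            }
            for aid, a in layout.arrays.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_layout(path: str | Path) -> ArrayLayout:
    doc = json.loads(Path(path).read_text())
    arrays = {}
    for aid, a in doc["arrays"].items():
        discs = [
            ElectrodeDisc(
                center=np.asarray(d["center"]), normal=np.asarray(d["normal"]),
                radius=d["radius"], channel=a["channel"], polarity=a["polarity"],
                array_id=aid, index=d["index"],
            )
            for d in a["discs"]
        ]
        arrays[aid] = TransducerArray(
            array_id=aid, channel=a["channel"], polarity=a["polarity"],
            discs=discs, center=np.asarray(a["center"]),
            long_axis=np.asarray(a["long_axis"]), pitch=a["pitch"],
        )
    return ArrayLayout(name=doc["name"], arrays=arrays, params=doc.get("params", {}))
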