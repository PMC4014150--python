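"""Labelled voxel phantoms: data model, raw+CSV I/O and derived organ geometry.

Conventions
-----------
* The label grid is stored as a ``(nx, ny, nz)`` ``uint16`` array; on disk it is
  written x-fastest (Fortran ravel order) as raw little-endian unsigned 16-bit
  integers with a JSON sidecar carrying dims, voxel size and gender.
* Voxel sizes are accepted in **mm** at the boundary and held in **cm**
  internally (interaction coefficients are per cm).  Voxel centres sit at
  ``(i + 0.5) * delta`` in grid coordinates with the origin at the grid corner.
* Label 0 means "outside the body".  Every nonzero label present in the grid
  must appear in the organ table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MaterialRecord",
    "OrganRecord",
    "VoxelPhantom",
    "MATERIALS",
    "ORGAN_CATALOGUE",
    "load_phantom",
    "write_phantom",
    "generate_synthetic_phantom",
    "organ_mass",
]


@dataclass(frozen=True)
class MaterialRecord:
    """A transport material: density plus a key into the cross-section tables."""

    material_id: int
    name: str
    density: float  # g/cm^3
    cross_section_key: str

    def __post_init__(self) -> None:
        if self.density <= 0 and self.name != "outside":
            raise ValueError(f"material {self.name!r} must have positive density")


#: Four-material catalogue: the photon/electron physics of the pipeline enters
#: only through per-material interaction coefficients, so soft tissue, lung,
#: bone (homogeneous skeleton proxy) and air suffice.  Thyroid tissue is an
#: alias of soft tissue.
MATERIALS: dict[int, MaterialRecord] = {
    1: MaterialRecord(1, "soft_tissue", 1.05, "soft_tissue"),
    2: MaterialRecord(2, "lung", 0.385, "lung"),
    3: MaterialRecord(3, "bone", 1.30, "bone"),
    4: MaterialRecord(4, "air", 0.0012, "air"),
}
_MATERIAL_BY_NAME = {m.name: m for m in MATERIALS.values()}


@dataclass(frozen=True)
class OrganRecord:
    organ_id: int
    name: str
    material_id: int
    is_wall: bool = False
    is_contents: bool = False
    is_source_capable: bool = True
    is_target: bool = True

    @property
    def density(self) -> float:
        return MATERIALS[self.material_id].density

    def __post_init__(self) -> None:
        if self.organ_id <= 0:
            raise ValueError("organ_id must be a positive integer")
        if self.material_id not in MATERIALS:
            raise ValueError(f"organ {self.name!r}: unknown material {self.material_id}")


def _rec(oid, name, mat=1, **kw) -> OrganRecord:
    return OrganRecord(oid, name, mat, **kw)


#: Stable organ id assignment used by the synthetic phantoms.  Wall/contents
#: pairs (stomach, small intestine, colon, gall bladder, bladder, heart) are
#: distinct organs; air lumina are not source-capable and not dose targets.
ORGAN_CATALOGUE: dict[str, OrganRecord] = {
    r.name: r
    for r in [
        _rec(1, "residual_soft_tissue"),
        _rec(2, "skeleton", 3),
        _rec(3, "brain"),
        _rec(4, "salivary_glands"),
        _rec(5, "thyroid"),
        _rec(6, "trachea"),
        _rec(7, "trachea_lumen", 4, is_source_capable=False, is_target=False),
        _rec(8, "esophagus"),
        _rec(9, "lungs", 2),
        _rec(10, "heart_wall", is_wall=True),
        _rec(11, "heart_contents", is_contents=True),
        _rec(12, "thymus"),
        _rec(13, "stomach_wall", is_wall=True),
        _rec(14, "stomach_contents", is_contents=True),
        _rec(15, "small_intestine_wall", is_wall=True),
        _rec(16, "small_intestine_contents", is_contents=True),
        _rec(17, "colon_right_wall", is_wall=True),
        _rec(18, "colon_right_contents", is_contents=True),
        _rec(19, "colon_left_wall", is_wall=True),
        _rec(20, "colon_left_contents", is_contents=True),
        _rec(21, "liver"),
        _rec(22, "spleen"),
        _rec(23, "pancreas"),
        _rec(24, "kidneys"),
        _rec(25, "adrenals"),
        _rec(26, "gall_bladder_wall", is_wall=True),
        _rec(27, "gall_bladder_contents", is_contents=True),
        _rec(28, "bladder_wall", is_wall=True),
        _rec(29, "bladder_contents", is_contents=True),
        _rec(30, "gonads"),
    ]
}


@dataclass
class VoxelPhantom:
    """A labelled 3-D voxel grid plus its organ/material catalogue."""

    labels: np.ndarray  # (nx, ny, nz) uint16, 0 = outside body
    voxel_size_cm: tuple[float, float, float]
    organs: list[OrganRecord]
    gender: str = "male"
    name: str = "phantom"
    _by_id: dict[int, OrganRecord] = field(init=False, repr=False)
    _counts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint16)
        self.voxel_size_cm = tuple(float(v) for v in self.voxel_size_cm)
        self._by_id = {o.organ_id: o for o in self.organs}
        self._counts = np.bincount(self.labels.ravel(), minlength=self.max_label + 1)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(d) for d in self.labels.shape)

    @property
    def max_label(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_cm))

    @property
    def extent_cm(self) -> tuple[float, float, float]:
        return tuple(d * s for d, s in zip(self.dims, self.voxel_size_cm))

    def validate(self) -> None:
        if self.labels.ndim != 3 or min(self.dims) <= 0:
            raise ValueError("label grid must be a non-empty 3-D array")
        if any(v <= 0 for v in self.voxel_size_cm):
            raise ValueError("voxel size components must be positive")
        if len(self._by_id) != len(self.organs):
            raise ValueError("duplicate organ_id in organ table")
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self._by_id)
        if unknown:
            raise ValueError(f"labels absent from organ table: {sorted(unknown)}")

    # -- organ queries ---------------------------------------------------
    def organ(self, organ: int | str) -> OrganRecord:
        if isinstance(organ, str):
            for o in self.organs:
                if o.name == organ:
                    return o
            raise KeyError(f"no organ named {organ!r}")
        try:
            return self._by_id[int(organ)]
        except KeyError:
            raise KeyError(f"unknown organ id {organ}") from None

    def organ_mask(self, organ: int | str) -> np.ndarray:
        return self.labels == self.organ(organ).organ_id

    def organ_voxel_count(self, organ: int | str) -> int:
        oid = self.organ(organ).organ_id
        return int(self._counts[oid]) if oid < len(self._counts) else 0

    def organ_volume_cm3(self, organ: int | str) -> float:
        return self.organ_voxel_count(organ) * self.voxel_volume_cm3

    def organ_mass(self, organ: int | str, *, allow_empty: bool = False) -> float:
        """Mass in grams: voxel count x voxel volume x material density."""
        rec = self.organ(organ)
        n = self.organ_voxel_count(rec.organ_id)
        if n == 0 and not allow_empty:
            raise ValueError(f"organ {rec.name!r} has no voxels in the grid")
        return n * self.voxel_volume_cm3 * rec.density

    def total_mass(self) -> float:
        """Body mass from the grid (grams); equals the sum of organ masses
        (label 0, the air outside the body, is excluded)."""
        dens = self.label_density()
        dens = dens[: len(self._counts)].copy()
        dens[0] = 0.0
        return float(self._counts @ dens) * self.voxel_volume_cm3

    def body_voxel_count(self) -> int:
        return int(self.labels.size - self._counts[0])

    # -- per-label lookup arrays used by the transport kernel ------------
    def label_material(self) -> np.ndarray:
        """material_id per label (index = label); label 0 maps to air."""
        out = np.full(self.max_label + 1, _MATERIAL_BY_NAME["air"].material_id, dtype=np.int16)
        for o in self.organs:
            if o.organ_id <= self.max_label:
                out[o.organ_id] = o.material_id
        return out

    def label_density(self) -> np.ndarray:
        """density (g/cm^3) per label; label 0 maps to air density."""
        out = np.full(self.max_label + 1, _MATERIAL_BY_NAME["air"].density)
        for o in self.organs:
            if o.organ_id <= self.max_label:
                out[o.organ_id] = o.density
        return out

    def organ_names(self) -> list[str]:
        return [o.name for o in self.organs]


def organ_mass(phantom: VoxelPhantom, organ: int | str) -> float:
    """Functional alias of :meth:`VoxelPhantom.organ_mass`."""
    return phantom.organ_mass(organ)


# ---------------------------------------------------------------------------
# I/O: raw uint16 grid + JSON sidecar + CSV organ table
# ---------------------------------------------------------------------------

_ORGAN_COLUMNS = [
    "organ_id",
    "name",
    "material_id",
    "density",
    "is_wall",
    "is_contents",
    "is_source_capable",
    "is_target",
]


def write_phantom(phantom: VoxelPhantom, grid_path: str | Path, organ_table_path: str | Path | None = None) -> dict:
    """Write the grid (raw little-endian uint16, x-fastest), sidecar and organ CSV."""
    grid_path = Path(grid_path)
    if organ_table_path is None:
        organ_table_path = grid_path.with_suffix(".organs.csv")
    sidecar = {
        "dims": list(phantom.dims),
        "voxel_size_mm": [v * 10.0 for v in phantom.voxel_size_cm],
        "gender": phantom.gender,
        "name": phantom.name,
        "dtype": "uint16",
        "byte_order": "little",
        "order": "x-fastest",
    }
    phantom.labels.astype("<u2").ravel(order="F").tofile(grid_path)
    grid_path.with_suffix(grid_path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    rows = [
        {
            "organ_id": o.organ_id,
            "name": o.name,
            "material_id": o.material_id,
            "density": o.density,
            "is_wall": int(o.is_wall),
            "is_contents": int(o.is_contents),
            "is_source_capable": int(o.is_source_capable),
            "is_target": int(o.is_target),
        }
        for o in phantom.organs
    ]
    pd.DataFrame(rows, columns=_ORGAN_COLUMNS).to_csv(organ_table_path, index=False)
    return sidecar


def load_phantom(grid_path: str | Path, organ_table_path: str | Path | None = None) -> VoxelPhantom:
    """Load a phantom written by :func:`write_phantom` (or hand-built in the same format)."""
    grid_path = Path(grid_path)
    sidecar_path = grid_path.with_suffix(grid_path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    dims = tuple(int(d) for d in meta["dims"])
    voxel_mm = meta["voxel_size_mm"]
    if any(v <= 0 for v in voxel_mm):
        raise ValueError("sidecar voxel size must be positive")
    raw = np.fromfile(grid_path, dtype="<u2")
    if raw.size != math.prod(dims):
        raise ValueError(f"grid file holds {raw.size} voxels, sidecar dims imply {math.prod(dims)}")
    labels = raw.reshape(dims, order="F")
    if organ_table_path is None:
        organ_table_path = grid_path.with_suffix(".organs.csv")
    table = pd.read_csv(organ_table_path)
    organs = [
        OrganRecord(
            int(r["organ_id"]),
            str(r["name"]),
            int(r["material_id"]),
            is_wall=bool(r["is_wall"]),
            is_contents=bool(r["is_contents"]),
            is_source_capable=bool(r.get("is_source_capable", True)),
            is_target=bool(r.get("is_target", True)),
        )
        for r in table.to_dict("records")
    ]
    return VoxelPhantom(
        labels=labels,
        voxel_size_cm=tuple(v / 10.0 for v in voxel_mm),
        organs=organs,
        gender=meta.get("gender", "unknown"),
        name=meta.get("name", grid_path.stem),
    )


# ---------------------------------------------------------------------------
# Synthetic anthropomorphic phantom
# ---------------------------------------------------------------------------

#: Linear shrink factor of the female variant relative to the male: female
#: reference bodies are smaller overall (shorter, lighter, ~17 g vs ~20 g thyroid).
FEMALE_LINEAR_FACTOR = 0.94


def generate_synthetic_phantom(
    gender: str = "male",
    voxel_size_mm: tuple[float, float, float] | float = (4.0, 4.0, 4.0),
    scale: float = 1.0,
) -> VoxelPhantom:
    """Deterministic anthropomorphic voxel phantom with the reference organ set.

    The phantom is built from analytic solids (ellipsoids, cylinders, shells)
    with reference-like organ masses at ``scale=1`` (thyroid ~20 g male /
    ~17 g female), topologically sensible adjacencies (two-lobe thyroid
    flanking the trachea, esophagus behind it, bladder near the gonads) and
    wall/contents pairs for the hollow organs.  No randomness is involved:
    equal arguments always give identical grids.

    Parameters
    ----------
    gender : {"male", "female"}
    voxel_size_mm : per-axis voxel size in mm, each in [1, 10]
    scale : global linear scale factor in [0.5, 2]
    """
    if gender not in ("male", "female"):
        raise ValueError("gender must be 'male' or 'female'")
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if any(not (1.0 <= v <= 10.0) for v in voxel_size_mm):
        raise ValueError("voxel size must be within [1, 10] mm per axis")
    if not (0.5 <= scale <= 2.0):
        raise ValueError("scale must be within [0.5, 2]")

    s = scale * (1.0 if gender == "male" else FEMALE_LINEAR_FACTOR)
    dx, dy, dz = (v / 10.0 for v in voxel_size_mm)  # cm

    half_x, half_y = 17.0 * s, 11.5 * s
    height = 177.5 * s
    nx = int(math.ceil(2 * (half_x + dx) / dx))
    ny = int(math.ceil(2 * (half_y + dy) / dy))
    nz = int(math.ceil((height + 2 * dz) / dz))

    # body coordinates: x lateral (positive = anatomical left), y antero-posterior
    # (positive = posterior), z caudo-cranial with the soles at z = 0.
    X = ((np.arange(nx) + 0.5) * dx - nx * dx / 2.0)[:, None, None]
    Y = ((np.arange(ny) + 0.5) * dy - ny * dy / 2.0)[None, :, None]
    Z = ((np.arange(nz) + 0.5) * dz - dz)[None, None, :]

    labels = np.zeros((nx, ny, nz), dtype=np.uint16)

    def ell(cx, cy, cz, a, b, c):
        return (
            ((X - cx * s) / (a * s)) ** 2
            + ((Y - cy * s) / (b * s)) ** 2
            + ((Z - cz * s) / (c * s)) ** 2
            <= 1.0
        )

    def cyl(cx, cy, r, z0, z1, rx=None, ry=None):
        rx = r if rx is None else rx
        ry = r if ry is None else ry
        return (
            (((X - cx * s) / (rx * s)) ** 2 + ((Y - cy * s) / (ry * s)) ** 2 <= 1.0)
            & (Z >= z0 * s)
            & (Z < z1 * s)
        )

    def sph(cx, cy, cz, r):
        return ell(cx, cy, cz, r, r, r)

    def paint(mask, name):
        labels[mask] = ORGAN_CATALOGUE[name].organ_id

    # body envelope -> residual soft tissue
    body = (
        cyl(-8, 0, 7, 0, 84) | cyl(8, 0, 7, 0, 84)          # legs
        | cyl(0, 0, 0, 84, 90, rx=13, ry=9)                  # pelvic block
        | cyl(0, 0, 0, 90, 150, rx=16, ry=11)                # torso
        | cyl(0, 0, 5.5, 150, 157)                           # neck
        | (ell(0, 0, 166.5, 8, 10, 11) & (Z >= 157 * s))     # head
    )
    paint(body, "residual_soft_tissue")

    # skeleton proxy: femurs, pelvis ring, spine, skull shell
    skel = (
        cyl(-8, 0, 1.8, 2, 88) | cyl(8, 0, 1.8, 2, 88)
        | (cyl(0, 0, 0, 84, 94, rx=12, ry=8) & ~cyl(0, 0, 0, 84, 94, rx=10, ry=6.3))
        | cyl(0, 3.5, 1.8, 90, 152)
        | (ell(0, 0, 168, 7.0, 8.4, 8.0) & ~ell(0, 0, 168, 6.2, 7.6, 7.2))
    )
    paint(skel & body, "skeleton")

    paint(ell(0, 0, 168, 6.2, 7.6, 7.2) & body, "brain")
    paint((ell(-4.5, -2, 160.5, 1.6, 1.6, 2.2) | ell(4.5, -2, 160.5, 1.6, 1.6, 2.2)) & body, "salivary_glands")

    paint((ell(-5.8, 0.8, 132, 4.2, 6.5, 11) | ell(5.8, 0.8, 132, 4.2, 6.5, 11)) & body, "lungs")
    heart_outer = ell(2.5, -2.5, 127, 4.5, 4.0, 4.5)
    heart_inner = ell(2.5, -2.5, 127, 3.2, 2.8, 3.2)
    paint(heart_outer & ~heart_inner & body, "heart_wall")
    paint(heart_inner & body, "heart_contents")
    paint(ell(0, -5.0, 141, 1.6, 1.2, 2.2) & body, "thymus")

    paint(ell(-6, -2, 112, 9, 6.5, 7) & body, "liver")
    paint(ell(9.5, 1.5, 115, 3, 2, 5.5) & body, "spleen")

    si_outer = cyl(0, -1, 6.5, 94, 104)
    si_inner = cyl(0, -1, 4.5, 94, 104)
    paint(si_outer & ~si_inner & body, "small_intestine_wall")
    paint(si_inner & body, "small_intestine_contents")

    st_outer = ell(5, -3.5, 112, 4, 3, 5.5)
    st_inner = ell(5, -3.5, 112, 3.2, 2.2, 4.6)
    paint(st_outer & ~st_inner & body, "stomach_wall")
    paint(st_inner & body, "stomach_contents")
    paint(ell(1, -0.5, 107.5, 6, 1.8, 2.2) & body, "pancreas")

    for cx, z0, z1, side in ((-8.5, 96, 116, "right"), (8.5, 94, 114, "left")):
        outer = cyl(cx, -2.5, 2.3, z0, z1)
        inner = cyl(cx, -2.5, 1.5, z0, z1)
        paint(outer & ~inner & body, f"colon_{side}_wall")
        paint(inner & body, f"colon_{side}_contents")

    paint((ell(-5.5, 3.8, 105, 3, 2, 5.5) | ell(5.5, 3.8, 105, 3, 2, 5.5)) & body, "kidneys")
    paint((ell(-5.5, 3.8, 111.8, 1.5, 1.0, 1.3) | ell(5.5, 3.8, 111.8, 1.5, 1.0, 1.3)) & body, "adrenals")

    gb_outer = sph(-3.5, -6, 106.5, 1.8)
    gb_inner = sph(-3.5, -6, 106.5, 1.4)
    paint(gb_outer & ~gb_inner & body, "gall_bladder_wall")
    paint(gb_inner & body, "gall_bladder_contents")

    bl_outer = sph(0, -3.5, 94.5, 3.3)
    bl_inner = sph(0, -3.5, 94.5, 2.8)
    paint(bl_outer & ~bl_inner & body, "bladder_wall")
    paint(bl_inner & body, "bladder_contents")

    if gender == "male":
        gon = sph(-1.9, -6.0, 87, 1.1) | sph(1.9, -6.0, 87, 1.1)
    else:
        gon = sph(-4.0, 1.0, 96.5, 1.1) | sph(4.0, 1.0, 96.5, 1.1)
    paint(gon & body, "gonads")

    paint(cyl(0, 1.5, 0.5, 115, 152) & body, "esophagus")
    paint(cyl(0, -2.5, 0.9, 138, 154) & body, "trachea")
    paint(cyl(0, -2.5, 0.5, 138, 154) & body, "trachea_lumen")
    paint((ell(-2.0, -2.8, 151.5, 0.9, 1.0, 2.5) | ell(2.0, -2.8, 151.5, 0.9, 1.0, 2.5)) & body, "thyroid")

    counts = np.bincount(labels.ravel(), minlength=max(o.organ_id for o in ORGAN_CATALOGUE.values()) + 1)
    thyroid_id = ORGAN_CATALOGUE["thyroid"].organ_id
    if counts[thyroid_id] < 8:
        raise ValueError(
            f"voxel size too coarse to resolve the thyroid ({counts[thyroid_id]} voxels < 8)"
        )
    organs = [o for o in ORGAN_CATALOGUE.values() if counts[o.organ_id] > 0]
    return VoxelPhantom(
        labels=labels,
        voxel_size_cm=(dx, dy, dz),
        organs=organs,
        gender=gender,
        name=f"synthetic_{gender}",
    )
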