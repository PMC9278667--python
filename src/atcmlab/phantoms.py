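"""QC phantom geometries for ATCM evaluation.

Four phantoms are modelled:

* ``mercury4`` — multi-diameter polyethylene phantom: five cylinders of
  16/21/26/31/36 cm diameter joined by four tapered cone rings (51 cm
  total), each cylinder carrying five 2.5 cm material rods (solid water,
  bone, polystyrene, iodine, air) at 4.5 cm off axis.
* ``ctdi_p1`` / ``ctdi_p2`` — the 32 cm PMMA body dosimetry phantom lying
  with its cylinder axis perpendicular to the scan axis, so axial
  cross-sections are chord-by-length rectangles; P1 and P2 differ only by
  whether the chord varies along x or y (their cross-section areas, hence
  WED profiles, are identical).
* ``ctdi_t`` — three-section arrangement made by offsetting the head insert
  halfway out of the nested body ring: a 16 cm "head" cylinder, a 32 cm
  "abdomen" cylinder and a 32/16 cm "lung" annulus, 7.5 cm each.

The phantom axis z runs in mm from 0 at the Head-facing end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .wed import WEDProfile, as_table_positions

HU_AIR = -1000.0
#: PMMA at 120 kVp; the dosimetry-phantom material (configurable).
DEFAULT_PMMA_HU = 120.0
#: Air margin (mm) accepted beyond both phantom ends when rasterizing,
#: mirroring scout acquisitions that extend well past the phantom.
AIR_MARGIN_MM = 100.0

SHAPES = ("cylinder", "cone_ring", "annulus", "lying_cylinder")
PHANTOM_NAMES = ("mercury4", "ctdi_p1", "ctdi_p2", "ctdi_t")


@dataclass(frozen=True)
class MaterialHU:
    """A named material with its nominal CT number."""

    name: str
    hu: float

    def __post_init__(self) -> None:
        if self.hu < -1000.0:
            raise ValueError(f"HU below -1000 for material {self.name!r}")


POLYETHYLENE = MaterialHU("polyethylene", -90.0)
SOLID_WATER = MaterialHU("solid_water", 0.0)
BONE = MaterialHU("bone", 910.0)
POLYSTYRENE = MaterialHU("polystyrene", -40.0)
IODINE = MaterialHU("iodine_10mgml", 245.0)
AIR_ROD = MaterialHU("air", -985.0)
#: The five target rods of the multi-diameter phantom.
ROD_MATERIALS = (SOLID_WATER, BONE, POLYSTYRENE, IODINE, AIR_ROD)

ROD_DIAMETER_MM = 25.0
ROD_LENGTH_MM = 30.0
ROD_OFFSET_MM = 45.0


def _water_frac(hu: float) -> float:
    """Water-equivalent area fraction of a material, floored at zero."""
    return max(0.0, 1.0 + hu / 1000.0)


@dataclass(frozen=True)
class Rod:
    """A cylindrical insert parallel to the phantom axis."""

    material: MaterialHU
    diameter: float
    center_offset: float
    angle_deg: float
    z_start: float
    z_end: float

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.z_end <= self.z_start:
            raise ValueError("rod must have positive diameter and extent")


@dataclass(frozen=True)
class PhantomSection:
    shape: str
    start_z: float
    end_z: float
    diameter_start: float
    diameter_end: float
    material: MaterialHU
    inner_diameter: float = 0.0
    slab_length: float = 0.0   # lying_cylinder: extent along the uniform axis
    slab_axis: str = "x"       # lying_cylinder: axis along which the chord varies
    rods: tuple[Rod, ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; one of {SHAPES}")
        if self.end_z <= self.start_z:
            raise ValueError("end_z must exceed start_z")
        if self.diameter_start <= 0 or self.diameter_end <= 0:
            raise ValueError("diameters must be positive")
        if self.shape == "annulus" and self.inner_diameter <= 0:
            raise ValueError("annulus needs a positive inner diameter")
        if self.inner_diameter >= min(self.diameter_start, self.diameter_end):
            raise ValueError("inner diameter must be smaller than the outer"
                             " diameter")
        if self.shape == "lying_cylinder" and self.slab_length <= 0:
            raise ValueError("lying_cylinder needs a positive slab_length")
        rmin = 0.5 * min(self.diameter_start, self.diameter_end)
        for rod in self.rods:
            if rod.center_offset + 0.5 * rod.diameter > rmin:
                raise ValueError("rod extends outside the section")
            if rod.z_start < self.start_z or rod.z_end > self.end_z:
                raise ValueError("rod extends outside the section z range")

    @property
    def length(self) -> float:
        return self.end_z - self.start_z

    def diameter_at(self, z: float) -> float:
        """Outer diameter at z; cone-ring diameters interpolate linearly."""
        frac = (z - self.start_z) / self.length
        frac = min(max(frac, 0.0), 1.0)
        return self.diameter_start + frac * (self.diameter_end -
                                             self.diameter_start)

    def water_area_at(self, z: float) -> float:
        """Closed-form water-equivalent cross-section area (mm^2) at z."""
        g = _water_frac(self.material.hu)
        if self.shape == "lying_cylinder":
            radius = 0.5 * self.diameter_start
            zc = 0.5 * (self.start_z + self.end_z)
            chord = 2.0 * math.sqrt(max(radius ** 2 - (z - zc) ** 2, 0.0))
            return chord * self.slab_length * g
        d = self.diameter_at(z)
        area = math.pi * d ** 2 / 4.0
        if self.shape == "annulus":
            area -= math.pi * self.inner_diameter ** 2 / 4.0  # hole is air
        a_w = area * g
        for rod in self.rods:
            if rod.z_start <= z < rod.z_end:
                a_rod = math.pi * rod.diameter ** 2 / 4.0
                a_w += a_rod * (_water_frac(rod.material.hu) - g)
        return a_w


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise axial description of a phantom; z=0 at the Head end."""

    name: str
    sections: tuple[PhantomSection, ...]
    total_length: float
    head_at_z0: bool = True

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("phantom needs at least one section")
        z = 0.0
        for sec in self.sections:
            if not math.isclose(sec.start_z, z, abs_tol=1e-9):
                raise ValueError("sections must be contiguous and ordered")
            z = sec.end_z
        if not math.isclose(z, self.total_length, abs_tol=1e-9):
            raise ValueError("total_length must equal the sum of section"
                             " lengths")

    def section_at(self, z: float) -> PhantomSection | None:
        if z < 0 or z > self.total_length:
            return None
        for sec in self.sections:
            if sec.start_z <= z < sec.end_z:
                return sec
        return self.sections[-1] if z == self.total_length else None

    def water_area_at(self, z: float) -> float:
        sec = self.section_at(z)
        return sec.water_area_at(z) if sec is not None else 0.0


def _mercury_rods(start_z: float, end_z: float) -> tuple[Rod, ...]:
    zc = 0.5 * (start_z + end_z)
    return tuple(
        Rod(material=mat, diameter=ROD_DIAMETER_MM,
            center_offset=ROD_OFFSET_MM, angle_deg=90.0 + 72.0 * k,
            z_start=zc - ROD_LENGTH_MM / 2.0, z_end=zc + ROD_LENGTH_MM / 2.0)
        for k, mat in enumerate(ROD_MATERIALS))


def _build_mercury(include_handle: bool) -> PhantomSpec:
    # (shape, length mm, d_start mm, d_end mm); cylinders carry the rod set.
    plan = [
        ("cylinder", 70.0, 160.0, 160.0),
        ("cone_ring", 40.0, 160.0, 210.0),
        ("cylinder", 90.0, 210.0, 210.0),
        ("cone_ring", 40.0, 210.0, 260.0),
        ("cylinder", 60.0, 260.0, 260.0),
        ("cone_ring", 40.0, 260.0, 310.0),
        ("cylinder", 60.0, 310.0, 310.0),
        ("cone_ring", 40.0, 310.0, 360.0),
        ("cylinder", 70.0, 360.0, 360.0),
    ]
    sections: list[PhantomSection] = []
    z = 0.0
    if include_handle:
        # Handle dimensions are not part of the published geometry; modelled
        # as a polyethylene cylinder whose WED caps at 255 mm.
        d = 255.0 / math.sqrt(_water_frac(POLYETHYLENE.hu))
        sections.append(PhantomSection("cylinder", 0.0, 120.0, d, d,
                                       POLYETHYLENE))
        z = 120.0
    for shape, length, d0, d1 in plan:
        rods = _mercury_rods(z, z + length) if shape == "cylinder" else ()
        sections.append(PhantomSection(shape, z, z + length, d0, d1,
                                       POLYETHYLENE, rods=rods))
        z += length
    return PhantomSpec("mercury4", tuple(sections), z)


def _build_ctdi_p(name: str, pmma: MaterialHU) -> PhantomSpec:
    axis = "x" if name == "ctdi_p1" else "y"
    sec = PhantomSection("lying_cylinder", 0.0, 320.0, 320.0, 320.0, pmma,
                         slab_length=150.0, slab_axis=axis)
    return PhantomSpec(name, (sec,), 320.0)


def _build_ctdi_t(pmma: MaterialHU) -> PhantomSpec:
    sections = (
        PhantomSection("cylinder", 0.0, 75.0, 160.0, 160.0, pmma),
        PhantomSection("cylinder", 75.0, 150.0, 320.0, 320.0, pmma),
        PhantomSection("annulus", 150.0, 225.0, 320.0, 320.0, pmma,
                       inner_diameter=160.0),
    )
    return PhantomSpec("ctdi_t", sections, 225.0)


def build_phantom(name: str, pmma_hu: float = DEFAULT_PMMA_HU,
                  include_handle: bool = False) -> PhantomSpec:
    """Build one of the four supported phantom specifications.

    Parameters
    ----------
    name : {"mercury4", "ctdi_p1", "ctdi_p2", "ctdi_t"}
    pmma_hu : CT number used for the PMMA dosimetry phantoms.
    include_handle : add the (optional, nominally-sized) carrying handle
        ahead of the multi-diameter phantom's smallest cylinder.
    """
    if name not in PHANTOM_NAMES:
        raise ValueError(f"unknown phantom {name!r}; supported:"
                         f" {', '.join(PHANTOM_NAMES)}")
    pmma = MaterialHU("pmma", pmma_hu)
    if name == "mercury4":
        return _build_mercury(include_handle)
    if name in ("ctdi_p1", "ctdi_p2"):
        return _build_ctdi_p(name, pmma)
    return _build_ctdi_t(pmma)


def rasterize_slice(phantom: PhantomSpec, z: float, pixel_size: float = 2.0,
                    matrix: int = 256,
                    air_margin: float = AIR_MARGIN_MM) -> np.ndarray:
    """Rasterize the axial HU cross-section at phantom coordinate z (mm).

    Pixels outside the phantom are air (-1000 HU); a cone ring's diameter is
    interpolated linearly in z; rod pixels take the rod HU where z lies
    within the rod's axial extent.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if matrix < 64:
        raise ValueError("matrix must be at least 64 pixels")
    if z < -air_margin or z > phantom.total_length + air_margin:
        raise ValueError("z outside the phantom and its air margin")
    img = np.full((matrix, matrix), HU_AIR, dtype=float)
    sec = phantom.section_at(z)
    if sec is None:
        return img
    half = (matrix - 1) / 2.0
    coords = (np.arange(matrix) - half) * pixel_size
    xx, yy = np.meshgrid(coords, coords)
    if sec.shape == "lying_cylinder":
        radius = 0.5 * sec.diameter_start
        zc = 0.5 * (sec.start_z + sec.end_z)
        chord = 2.0 * math.sqrt(max(radius ** 2 - (z - zc) ** 2, 0.0))
        wx, wy = ((chord, sec.slab_length) if sec.slab_axis == "x"
                  else (sec.slab_length, chord))
        inside = (np.abs(xx) <= wx / 2.0) & (np.abs(yy) <= wy / 2.0)
        img[inside] = sec.material.hu
        return img
    rr = np.hypot(xx, yy)
    d = sec.diameter_at(z)
    inside = rr <= d / 2.0
    img[inside] = sec.material.hu
    if sec.shape == "annulus":
        img[rr <= sec.inner_diameter / 2.0] = HU_AIR
    for rod in sec.rods:
        if rod.z_start <= z < rod.z_end:
            ang = math.radians(rod.angle_deg)
            cx = rod.center_offset * math.cos(ang)
            cy = rod.center_offset * math.sin(ang)
            img[np.hypot(xx - cx, yy - cy) <= rod.diameter / 2.0] = \
                rod.material.hu
    return img


def analytic_wed_profile(phantom: PhantomSpec, dz: float = 2.0,
                         margin: float = 0.0,
                         frame: str = "table") -> WEDProfile:
    """Closed-form WED profile sampled every ``dz`` mm.

    ``frame="phantom"`` keeps the phantom axis (z=0 at the Head end,
    ascending towards the feet); ``frame="table"`` (default) maps to scanner
    table positions with the Head end at positive values and the phantom
    centred about 0. ``margin`` extends the profile into the surrounding air
    (WED = 0) at both ends.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    n = int(round((phantom.total_length + 2 * margin) / dz))
    z = -margin + dz * np.arange(n + 1)
    a_w = np.array([phantom.water_area_at(zi) for zi in z])
    wed = 2.0 * np.sqrt(a_w / math.pi)
    profile = WEDProfile(z=z, wed=wed, source="analytic", label=phantom.name)
    if frame == "phantom":
        return profile
    if frame == "table":
        return as_table_positions(profile,
                                  table_offset=phantom.total_length / 2.0)
    raise ValueError("frame must be 'table' or 'phantom'")


# ---------------------------------------------------------------------------
# Serialization (documented schema: a mapping with name/total_length/sections;
# each section mirrors PhantomSection fields, materials as {name, hu} maps).

def phantom_to_dict(phantom: PhantomSpec) -> dict:
    return asdict(phantom)


def _material_from(d: dict) -> MaterialHU:
    return MaterialHU(d["name"], float(d["hu"]))


def phantom_from_dict(data: dict) -> PhantomSpec:
    sections = []
    for s in data["sections"]:
        rods = tuple(Rod(material=_material_from(r["material"]),
                         diameter=float(r["diameter"]),
                         center_offset=float(r["center_offset"]),
                         angle_deg=float(r["angle_deg"]),
                         z_start=float(r["z_start"]),
                         z_end=float(r["z_end"]))
                     for r in s.get("rods", ()))
        sections.append(PhantomSection(
            shape=s["shape"], start_z=float(s["start_z"]),
            end_z=float(s["end_z"]),
            diameter_start=float(s["diameter_start"]),
            diameter_end=float(s["diameter_end"]),
            material=_material_from(s["material"]),
            inner_diameter=float(s.get("inner_diameter", 0.0)),
            slab_length=float(s.get("slab_length", 0.0)),
            slab_axis=s.get("slab_axis", "x"), rods=rods))
    return PhantomSpec(name=data["name"], sections=tuple(sections),
                       total_length=float(data["total_length"]),
                       head_at_z0=bool(data.get("head_at_z0", True)))


def save_phantom(phantom: PhantomSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(phantom_to_dict(phantom), fh, sort_keys=False)


def load_phantom(path) -> PhantomSpec:
    with open(path) as fh:
        return phantom_from_dict(yaml.safe_load(fh))
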