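"""Substrate geometries: phase masks, nutrient initialization, seeding.

Six parametric substrate shapes are supported: FLAT (plain slab), WALL
(a 90-degree step of glucose-bearing agar), PLATEAU (square raised
block), HOLE (square well in the slab), and CONCAVE / CONVEX
(single-axis cylinder-like curvature along x, flat along y).  The z
axis points up; agar occupies the bottom of the domain and air the
rest.  All features are rasterized by site-center membership.

Lengths in the spec are mm for features and domain, um for the seed
offset and lattice spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .cell_dynamics import GLU, CellConstants
from .rd_solver import AGAR, AIR, LatticeState, Species

MM_TO_UM = 1000.0


class GeometryKind(str, Enum):
    FLAT = "flat"
    WALL = "wall"
    PLATEAU = "plateau"
    HOLE = "hole"
    CONCAVE = "concave"
    CONVEX = "convex"


class ResolutionError(ValueError):
    """A geometric feature is not resolvable at the requested dx."""


class PlacementError(ValueError):
    """Seed position is not adjacent to the agar surface."""


@dataclass(frozen=True)
class GeometrySpec:
    """Parametric description of one substrate shape.

    ``h``/``w`` are the feature height(depth)/width in mm (plateau,
    hole; ``h`` doubles as the wall height), ``o`` the seed offset from
    the wall in um, ``radius`` the curvature radius in mm
    (kappa = 1/radius, single-axis), ``wall_thickness`` the wall block
    thickness in mm.  ``domain`` is (Lx, Ly, Lz) in mm and
    ``agar_depth`` the base slab thickness in mm.
    """

    kind: GeometryKind = GeometryKind.FLAT
    h: float = 0.2
    w: float = 0.3
    o: float = 0.0
    radius: float = 2.0
    wall_thickness: float = 0.15
    agar_depth: float = 0.5
    domain: tuple[float, float, float] = (2.0, 2.0, 1.0)

    @property
    def curvature(self) -> float:
        """kappa = 1/radius, 1/mm (concave/convex only)."""
        return 1.0 / self.radius

    def __post_init__(self) -> None:
        if self.kind in (GeometryKind.PLATEAU, GeometryKind.HOLE):
            if self.h <= 0 or self.w <= 0:
                raise ValueError("plateau/hole need h, w > 0")
        if self.kind in (GeometryKind.CONCAVE, GeometryKind.CONVEX):
            if self.radius <= 0:
                raise ValueError("curved surfaces need radius > 0")
        if self.o < 0:
            raise ValueError("wall offset o must be >= 0")


def check_resolution(spec: GeometrySpec, dx: float) -> None:
    """Reject feature sizes not resolvable at dx (< 2 sites across)."""
    def need(length_mm: float, name: str) -> None:
        n = int(round(length_mm * MM_TO_UM / dx))
        if n < 2:
            raise ResolutionError(
                f"{name} spans {n} site(s) at dx={dx} um; at least 2 "
                "required")

    need(spec.agar_depth, "agar depth")
    if spec.kind is GeometryKind.WALL:
        need(spec.wall_thickness, "wall thickness")
        need(spec.h, "wall height")
    elif spec.kind in (GeometryKind.PLATEAU, GeometryKind.HOLE):
        need(spec.h, f"{spec.kind.value} height/depth")
        need(spec.w, f"{spec.kind.value} width")
        if spec.kind is GeometryKind.HOLE and \
                round(spec.h * MM_TO_UM / dx) >= round(
                    spec.agar_depth * MM_TO_UM / dx):
            raise ResolutionError("hole deeper than the agar slab")


def _n_sites(length_mm: float, dx_um: float, odd: bool = True) -> int:
    n = max(3, int(round(length_mm * MM_TO_UM / dx_um)))
    if odd and n % 2 == 0:
        n += 1  # odd counts keep a center site for symmetric seeding
    return n


def build_substrate(spec: GeometrySpec, dx: float,
                    species: dict[str, Species]) -> LatticeState:
    """Rasterize the substrate and initialize the chemical fields.

    Agar sites get each species' ``init_agar`` concentration; air sites
    get the boundary value for gaseous species and zero otherwise.
    Features smaller than 2 dx are rejected.
    """
    check_resolution(spec, dx)
    nx = _n_sites(spec.domain[0], dx)
    ny = _n_sites(spec.domain[1], dx)
    nz = _n_sites(spec.domain[2], dx, odd=False)
    n_agar = int(round(spec.agar_depth * MM_TO_UM / dx))
    if n_agar < 2 or nz - n_agar < 2:
        raise ResolutionError("agar depth or head space < 2 sites at this dx")

    # site-center coordinates in um
    x = (np.arange(nx) + 0.5) * dx
    z = (np.arange(nz) + 0.5) * dx
    X, Z = np.meshgrid(x, z, indexing="ij")
    surface = np.full(nx, n_agar * dx)  # agar surface height, um

    kind = spec.kind
    phase = np.zeros((nx, ny, nz), dtype=np.int8)
    cx = nx * dx / 2.0

    def check_feature(n_sites_across: int, name: str) -> None:
        if n_sites_across < 2:
            raise ResolutionError(
                f"{name} spans {n_sites_across} site(s) at dx={dx} um; "
                "at least 2 required")

    if kind in (GeometryKind.FLAT,):
        pass
    elif kind is GeometryKind.WALL:
        n_wall = int(round(spec.wall_thickness * MM_TO_UM / dx))
        n_h = int(round(spec.h * MM_TO_UM / dx))
        check_feature(n_wall, "wall thickness")
        check_feature(n_h, "wall height")
        surface[:n_wall] += n_h * dx
    elif kind is GeometryKind.PLATEAU:
        n_h = int(round(spec.h * MM_TO_UM / dx))
        n_w = int(round(spec.w * MM_TO_UM / dx))
        check_feature(n_h, "plateau height")
        check_feature(n_w, "plateau width")
        half_w = n_w * dx / 2.0
        in_x = np.abs(x - cx) < half_w
        surface[in_x] += n_h * dx
    elif kind is GeometryKind.HOLE:
        n_h = int(round(spec.h * MM_TO_UM / dx))
        n_w = int(round(spec.w * MM_TO_UM / dx))
        check_feature(n_h, "hole depth")
        check_feature(n_w, "hole width")
        if n_h >= n_agar:
            raise ResolutionError("hole deeper than the agar slab")
        half_w = n_w * dx / 2.0
        in_x = np.abs(x - cx) < half_w
        surface[in_x] -= n_h * dx
    elif kind in (GeometryKind.CONCAVE, GeometryKind.CONVEX):
        R = spec.radius * MM_TO_UM
        if 2 * R < nx * dx:
            raise ResolutionError("curvature radius smaller than half the "
                                  "domain width")
        u = x - cx
        sag = R - np.sqrt(np.maximum(R * R - u * u, 0.0))
        if kind is GeometryKind.CONVEX:
            surface = surface + sag.max() - sag  # apex at the center
        else:
            surface = surface + sag - sag.max()  # trough at the center
        surface = np.maximum(surface, 2 * dx)
    else:  # pragma: no cover
        raise ValueError(f"unknown geometry kind {kind}")

    base = np.zeros((nx, nz), dtype=np.int8)
    base[Z < surface[:, None]] = AGAR
    phase[:] = base[:, None, :]

    # square footprints: plateau/hole also bounded along y
    if kind in (GeometryKind.PLATEAU, GeometryKind.HOLE):
        n_w = int(round(spec.w * MM_TO_UM / dx))
        half_w = n_w * dx / 2.0
        y = (np.arange(ny) + 0.5) * dx
        cy = ny * dx / 2.0
        out_y = np.abs(y - cy) >= half_w
        flat_col = np.zeros(nz, dtype=np.int8)
        flat_col[:n_agar] = AGAR
        phase[:, out_y, :] = flat_col[None, None, :]

    C = {}
    agar = phase == AGAR
    for name, sp in species.items():
        fld = np.zeros((nx, ny, nz))
        fld[agar] = sp.init_agar
        if sp.gaseous:
            fld[~agar] = sp.boundary_value
        C[name] = fld
    m = np.zeros((2, nx, ny, nz))
    return LatticeState(dx=dx, phase=phase, C=C, m=m,
                        meta={"geometry": spec, "n_agar": n_agar})


def surface_site(state: LatticeState, ix: int, iy: int) -> tuple[int, int,
                                                                 int]:
    """Lowest AIR site above the agar in column (ix, iy)."""
    col = state.phase[ix, iy]
    air = np.nonzero(col == AIR)[0]
    if len(air) == 0:
        raise PlacementError(f"column ({ix},{iy}) has no air")
    return ix, iy, int(air[0])


def default_seed_site(state: LatticeState,
                      spec: GeometrySpec) -> tuple[int, int, int]:
    """Where the paper seeds each geometry.

    Center of the domain surface (which for a hole is the hole floor,
    for a plateau its top); for the wall, the floor site ``o`` um from
    the wall face.
    """
    nx, ny, _ = state.dims
    if spec.kind is GeometryKind.WALL:
        n_wall = int(round(spec.wall_thickness * MM_TO_UM / state.dx))
        ix = min(n_wall + int(round(spec.o / state.dx)), nx - 1)
        return surface_site(state, ix, ny // 2)
    return surface_site(state, nx // 2, ny // 2)


def seed_colony(state: LatticeState, position: tuple[int, int, int],
                consts: CellConstants) -> LatticeState:
    """Place one cell's mass (glucose phenotype) at an AIR surface site.

    The site must be face-adjacent to agar (the slab surface or a hole
    floor/wall edge).
    """
    ix, iy, iz = position
    if state.phase[ix, iy, iz] != AIR:
        raise PlacementError("seed position is not an AIR site")
    neigh = []
    for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
              (0, 0, -1)):
        j = (ix + d[0], iy + d[1], iz + d[2])
        if all(0 <= j[a] < state.dims[a] for a in range(3)):
            neigh.append(state.phase[j])
    if AGAR not in neigh:
        raise PlacementError("seed position is not adjacent to agar")
    state.m[GLU][ix, iy, iz] += consts.m_cell
    state.meta["seed"] = (ix, iy, iz)
    return state
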