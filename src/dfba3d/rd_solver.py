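"""Explicit finite-difference diffusion on the cubic lattice.

The chemical fields obey dC/dt = div(D_eff grad C) + R(C); this module
integrates the transport part with a 7-point central stencil under
phase-restricted diffusion:

* aqueous species move only through sites containing agar or cell mass;
* gaseous species (O2) additionally see the air.  By default the air is
  treated as well mixed — every cell-free air site is held at the
  species' boundary concentration, which acts as a Dirichlet source at
  the colony surface.  An explicit ``D_air`` mode is available instead.

The local diffusivity is attenuated by the cell volume fraction via a
Maxwell-type obstruction law, and face transmissibilities are harmonic
means of the two adjacent site diffusivities, which makes the stencil
conservative across discontinuous media.  Domain-boundary sites are
reset to their boundary values after every substep (Dirichlet); with no
clamps the scheme is zero-flux (reflecting), which the tests use to
check mass conservation.

Units: lengths in um, time in s, diffusivities in um^2/s,
concentrations in mM.  Site volume in fL equals dx^3 (1 um^3 = 1 fL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

AIR = 0
AGAR = 1

#: Phenotype ordering of the biomass field axis.
PHENOTYPE_AXIS = ("glucose_utilizer", "acetate_utilizer")


class StabilityError(RuntimeError):
    """The requested time step violates the explicit stability bound."""


@dataclass(frozen=True)
class Species:
    """One diffusible chemical species.

    ``D_agar``/``D_cell_free``/``D_air`` are diffusion coefficients in
    um^2/s; aqueous species (``gaseous=False``) never diffuse through
    air regardless of ``D_air``.  ``boundary_value`` is the Dirichlet
    concentration at non-agar domain-boundary sites (and, for gaseous
    species in the well-mixed mode, throughout cell-free air) — 0 for
    nutrients that exist only in the agar.  Agar boundary sites are
    instead held at ``init_agar``, so the substrate acts as a nutrient
    reservoir.  ``Km`` is the Michaelis constant used for uptake
    saturation (mM).
    """

    name: str
    D_agar: float
    D_cell_free: float
    boundary_value: float
    init_agar: float
    D_air: float = 0.0
    gaseous: bool = False
    Km: float = 0.01

    def __post_init__(self) -> None:
        if min(self.D_agar, self.D_cell_free, self.D_air) < 0:
            raise ValueError("diffusion coefficients must be >= 0")

    @property
    def D_max(self) -> float:
        d = max(self.D_agar, self.D_cell_free)
        if self.gaseous:
            d = max(d, self.D_air)
        return d


def default_species() -> dict[str, Species]:
    """Glucose / acetate / oxygen with the package default constants.

    Glucose starts at 138.8 mM (2.5% w/v / 180.16 g/mol) in the agar;
    oxygen is air-saturated at 0.21 mM; acetate starts absent.
    """
    return {
        "glucose": Species("glucose", D_agar=600.0, D_cell_free=600.0,
                           boundary_value=0.0, init_agar=138.8, Km=0.015),
        "acetate": Species("acetate", D_agar=1100.0, D_cell_free=1100.0,
                           boundary_value=0.0, init_agar=0.0, Km=0.05),
        "oxygen": Species("oxygen", D_agar=2000.0, D_cell_free=2000.0,
                          D_air=2000.0, gaseous=True,
                          boundary_value=0.21, init_agar=0.21, Km=0.005),
    }


@dataclass
class LatticeState:
    """State of the cubic lattice.

    ``phase`` labels each site AIR or AGAR; cell mass may occupy AIR
    sites only.  ``C`` maps species name to a concentration field (mM)
    and ``m`` is the per-phenotype biomass field in fg, indexed along
    axis 0 by :data:`PHENOTYPE_AXIS`.  ``t`` is simulation time in s.
    """

    dx: float
    phase: np.ndarray
    C: dict[str, np.ndarray]
    m: np.ndarray
    t: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase.ndim != 3 or min(self.phase.shape) < 3:
            raise ValueError("lattice needs >= 3 sites per axis")
        if self.m.shape != (len(PHENOTYPE_AXIS),) + self.phase.shape:
            raise ValueError("biomass field shape mismatch")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.phase.shape

    @property
    def site_volume(self) -> float:
        """Site volume in fL (== um^3)."""
        return self.dx ** 3

    def total_mass(self) -> np.ndarray:
        """Summed biomass over phenotypes, fg."""
        return self.m.sum(axis=0)

    def copy(self) -> "LatticeState":
        return LatticeState(
            dx=self.dx, phase=self.phase.copy(),
            C={k: v.copy() for k, v in self.C.items()},
            m=self.m.copy(), t=self.t, meta=dict(self.meta))


def stable_dt(dx: float, D_max: float, safety: float = 1.0) -> float:
    """Largest stable explicit step: safety * dx^2 / (6 D_max)."""
    if dx <= 0 or D_max <= 0 or not 0 < safety <= 1:
        raise ValueError("dx > 0, D_max > 0 and 0 < safety <= 1 required")
    return safety * dx * dx / (6.0 * D_max)


def effective_diffusion(D0, phi_total):
    """Maxwell-type obstruction: D0 * 2(1 - phi) / (2 + phi)."""
    phi = np.asarray(phi_total, dtype=float)
    return D0 * 2.0 * (1.0 - phi) / (2.0 + phi)


# ---------------------------------------------------------------------------
# Field preparation
# ---------------------------------------------------------------------------

def diffusion_fields(state: LatticeState, species: Species,
                     phi_total: np.ndarray | None = None,
                     well_mixed_air: bool = True):
    """Per-site effective diffusivity and permission mask.

    Returns ``(D_eff, allowed)``.  Sites where diffusion is forbidden
    carry ``D_eff = 0`` so every face into them has zero
    transmissibility.
    """
    agar = state.phase == AGAR
    cells = state.total_mass() > 0.0
    allowed = agar | cells
    D0 = np.where(agar, species.D_agar,
                  np.where(cells, species.D_cell_free, 0.0))
    if species.gaseous:
        air_free = ~agar & ~cells
        if well_mixed_air:
            # air held at boundary value; give it the cell-free D so the
            # colony top exchanges with the (clamped) air sites
            D0 = np.where(air_free, species.D_cell_free, D0)
        else:
            D0 = np.where(air_free, species.D_air, D0)
        allowed = allowed | air_free
    if phi_total is None:
        phi_total = 0.0
    Deff = effective_diffusion(D0, phi_total)
    Deff = np.where(allowed, Deff, 0.0)
    return Deff, allowed


def boundary_clamp(state: LatticeState, species: Species,
                   allowed: np.ndarray, well_mixed_air: bool = True):
    """Dirichlet clamp mask/values for one species.

    Domain-boundary sites that participate in diffusion are held at the
    species boundary value (``init_agar`` inside agar so the nutrient
    reservoir is maintained); in the well-mixed mode every cell-free air
    site is additionally held at ``boundary_value`` for gaseous species.
    """
    nx, ny, nz = state.dims
    shell = np.zeros(state.dims, dtype=bool)
    shell[0, :, :] = shell[-1, :, :] = True
    shell[:, 0, :] = shell[:, -1, :] = True
    shell[:, :, 0] = shell[:, :, -1] = True
    agar = state.phase == AGAR
    mask = shell & allowed
    values = np.where(agar, species.init_agar, species.boundary_value)
    if species.gaseous and well_mixed_air:
        air_free = ~agar & (state.total_mass() <= 0.0)
        mask = mask | air_free
        values = np.where(air_free, species.boundary_value, values)
    return mask, values


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _diffuse_kernel(A, B, Txm, Txp, Tym, Typ, Tzm, Tzp, coef, nsub,
                    ci, cj, ck, cv):  # pragma: no cover - jitted
    nx = A.shape[0] - 2
    ny = A.shape[1] - 2
    nz = A.shape[2] - 2
    src, dst = A, B
    for _ in range(nsub):
        for i in range(1, nx + 1):
            for j in range(1, ny + 1):
                for k in range(1, nz + 1):
                    c = src[i, j, k]
                    # per-axis grouping keeps mirror images bit-identical
                    sx = (Txm[i, j, k] * (src[i - 1, j, k] - c)
                          + Txp[i, j, k] * (src[i + 1, j, k] - c))
                    sy = (Tym[i, j, k] * (src[i, j - 1, k] - c)
                          + Typ[i, j, k] * (src[i, j + 1, k] - c))
                    sz = (Tzm[i, j, k] * (src[i, j, k - 1] - c)
                          + Tzp[i, j, k] * (src[i, j, k + 1] - c))
                    dst[i, j, k] = c + coef * (sx + sy + sz)
        for n in range(ci.size):
            dst[ci[n], cj[n], ck[n]] = cv[n]
        src, dst = dst, src
    return src


def _pad(arr: np.ndarray) -> np.ndarray:
    out = np.zeros((arr.shape[0] + 2, arr.shape[1] + 2, arr.shape[2] + 2),
                   dtype=float)
    out[1:-1, 1:-1, 1:-1] = arr
    return out


def _face_transmissibilities(Deff: np.ndarray):
    """Harmonic-mean transmissibility toward each of the 6 neighbors.

    Padded arrays; ghost faces (outside the domain) get zero, making the
    unclamped boundary reflecting.
    """
    P = _pad(Deff)
    out = []
    for axis, off in ((0, -1), (0, 1), (1, -1), (1, 1), (2, -1), (2, 1)):
        Q = np.roll(P, -off, axis=axis)
        s = P + Q
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(s > 0, 2.0 * P * Q / np.where(s > 0, s, 1.0), 0.0)
        out.append(T)
    return out  # Txm, Txp, Tym, Typ, Tzm, Tzp


def diffuse(state: LatticeState, species: Species, duration: float,
            phi_total: np.ndarray | None = None, safety: float = 0.9,
            well_mixed_air: bool = True, dirichlet: bool = True,
            n_substeps: int | None = None) -> int:
    """Integrate diffusion of one species over ``duration`` seconds.

    The interval is split into equal substeps respecting the stability
    bound for the species' maximal effective diffusivity; returns the
    number of substeps taken.  With ``dirichlet=False`` no clamping is
    applied (reflecting boundaries; test harness mode).
    """
    if duration <= 0:
        return 0
    Deff, allowed = diffusion_fields(state, species, phi_total,
                                     well_mixed_air)
    Dmax = float(Deff.max())
    if Dmax == 0.0:
        return 0
    if n_substeps is None:
        dt_max = stable_dt(state.dx, Dmax, safety)
        n_substeps = max(1, int(np.ceil(duration / dt_max)))
    dt = duration / n_substeps
    if dt > stable_dt(state.dx, Dmax, 1.0) * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt:g}s exceeds stability bound "
            f"{stable_dt(state.dx, Dmax, 1.0):g}s for {species.name}")
    if dirichlet:
        mask, values = boundary_clamp(state, species, allowed,
                                      well_mixed_air)
        ci, cj, ck = np.nonzero(mask)
        cv = values[mask].astype(float)
        ci, cj, ck = ci + 1, cj + 1, ck + 1  # padded coordinates
    else:
        ci = cj = ck = np.empty(0, dtype=np.int64)
        cv = np.empty(0, dtype=float)
    T = _face_transmissibilities(Deff)
    A = _pad(state.C[species.name])
    B = A.copy()
    res = _diffuse_kernel(A, B, *T, dt / state.dx ** 2, n_substeps,
                          ci.astype(np.int64), cj.astype(np.int64),
                          ck.astype(np.int64), cv)
    state.C[species.name] = res[1:-1, 1:-1, 1:-1].copy()
    return n_substeps


def step_diffusion(state: LatticeState, species: Species, dt: float,
                   phi_total: np.ndarray | None = None,
                   well_mixed_air: bool = True,
                   dirichlet: bool = True) -> None:
    """Single explicit step; refuses dt beyond the stability bound."""
    diffuse(state, species, dt, phi_total, safety=1.0,
            well_mixed_air=well_mixed_air, dirichlet=dirichlet,
            n_substeps=1)
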