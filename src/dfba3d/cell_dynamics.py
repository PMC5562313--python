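"""Per-site biomass bookkeeping and its coupling to the chemical fields.

Cells are represented as per-phenotype volume fractions phi_i =
m_i / (V rho_i) on the lattice; they do not move by themselves but are
pushed isotropically into neighboring sites once the local packing
exceeds phi_max = 0.65.  Growth is exponential at the table-predicted
rate, dm/dt = v_bm m.  Uptake is capped by Michaelis-Menten saturation
and by the amount of chemical actually present, so concentrations never
go negative.  A regulation timer converts glucose utilizers to acetate
utilizers after sustained glucose starvation in the presence of
acetate.

Units: mass fg, volume fL, concentrations mM, fluxes mmol/gDCW/hr,
time arguments in seconds (converted internally to hours where flux
units demand it).  Biomass is interpreted as dry weight for the flux
coupling, so 1 fg of lattice mass is 1e-15 gDCW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .rd_solver import AGAR, LatticeState

S_PER_HR = 3600.0

#: phenotype indices along axis 0 of the biomass field
GLU = 0
ACE = 1


@dataclass(frozen=True)
class CellConstants:
    """Single-cell constants: m_cell = 258 fg, V_cell = 1 fL."""

    m_cell: float = 258.0
    V_cell: float = 1.0
    phi_max: float = 0.65

    def __post_init__(self) -> None:
        if not 0 < self.phi_max < 1:
            raise ValueError("phi_max must lie in (0, 1)")

    @property
    def rho(self) -> float:
        """Cell density, fg/fL."""
        return self.m_cell / self.V_cell


@dataclass
class RegulationParams:
    """Thresholds of the glucose->acetate phenotype transition.

    Conversion happens at sites where glucose < theta_glc while acetate
    > theta_ace continuously for tau seconds.  The transition is
    irreversible unless ``reversible`` is set, in which case the same
    dwell logic runs in the opposite direction when glucose returns.
    """

    theta_glc: float = 0.01   # mM
    theta_ace: float = 0.5    # mM
    tau: float = 1800.0       # s
    reversible: bool = False


@dataclass
class RegulationState:
    """Per-site dwell timers (s of continuous starvation condition)."""

    timer: np.ndarray
    reverse_timer: np.ndarray | None = None

    @classmethod
    def zeros(cls, dims, reversible: bool = False) -> "RegulationState":
        return cls(np.zeros(dims),
                   np.zeros(dims) if reversible else None)


def volume_fraction(m, V: float, consts: CellConstants):
    """phi = m / (V rho)."""
    return np.asarray(m, dtype=float) / (V * consts.rho)


def grow_biomass(m, v_bm, dt: float):
    """Exact exponential integration over the step: m exp(v_bm dt).

    ``v_bm`` in 1/hr, ``dt`` in seconds.
    """
    return np.asarray(m, dtype=float) * np.exp(
        np.asarray(v_bm, dtype=float) * dt / S_PER_HR)


def compute_uptake_bounds(C, m, V: float, dt: float, v_table_max: float,
                          Km: float):
    """Maximal uptake magnitude honoring saturation and supply.

    |v| = min(v_table_max * C/(Km + C), C V / (m dt)); the second term
    guarantees the post-reaction concentration stays >= 0.  ``m`` is the
    total cell mass at the site (fg), ``dt`` in seconds; zero cell mass
    gives a zero bound.
    """
    C = np.maximum(np.asarray(C, dtype=float), 0.0)
    m = np.asarray(m, dtype=float)
    dt_hr = dt / S_PER_HR
    sat = abs(v_table_max) * C / (Km + C)
    with np.errstate(divide="ignore", invalid="ignore"):
        supply = np.where(m > 0, C * V / (np.where(m > 0, m, 1.0) * dt_hr),
                          0.0)
    return np.minimum(sat, supply)


def apply_reaction(state: LatticeState, fluxes: dict[str, np.ndarray],
                   dt: float, tol: float = 1e-9) -> None:
    """Apply R(C) = sum_p m_p v_{C,p} / V over one interval.

    ``fluxes[species]`` has shape (2, nx, ny, nz): the applied exchange
    flux of each phenotype (mmol/gDCW/hr, uptake negative).  With m in
    fg and V in fL the fg/gDCW and fL/L conversions cancel, so
    dC [mM] = sum_p m_p v_p / V * dt_hr directly.  A resulting
    concentration below ``-tol`` mM indicates a bound violation and is
    a programming error.
    """
    V = state.site_volume
    dt_hr = dt / S_PER_HR
    for name, v in fluxes.items():
        dC = (state.m * v).sum(axis=0) / V * dt_hr
        C = state.C[name]
        C += dC
        if C.min() < -tol:
            raise AssertionError(
                f"uptake bound violated for {name}: min C = {C.min():g} mM")
        np.maximum(C, 0.0, out=C)


def update_phenotypes(state: LatticeState, reg: RegulationState,
                      params: RegulationParams, dt: float) -> None:
    """Advance dwell timers and convert starved glucose utilizers.

    At sites where glucose < theta_glc and acetate > theta_ace the timer
    accrues dt; elsewhere it resets to zero.  Once the timer reaches
    tau, all glucose-utilizer mass at the site becomes acetate-utilizer
    mass (total site mass unchanged).
    """
    cond = ((state.C["glucose"] < params.theta_glc)
            & (state.C["acetate"] > params.theta_ace))
    reg.timer[:] = np.where(cond, reg.timer + dt, 0.0)
    convert = cond & (reg.timer >= params.tau)
    if convert.any():
        moved = np.where(convert, state.m[GLU], 0.0)
        state.m[ACE] += moved
        state.m[GLU] -= moved
    if params.reversible and reg.reverse_timer is not None:
        back = state.C["glucose"] >= params.theta_glc
        reg.reverse_timer[:] = np.where(back, reg.reverse_timer + dt, 0.0)
        revert = back & (reg.reverse_timer >= params.tau)
        if revert.any():
            moved = np.where(revert, state.m[ACE], 0.0)
            state.m[GLU] += moved
            state.m[ACE] -= moved


class PushNonConvergence(RuntimeError):
    """Overflow relaxation failed to settle (fully enclosed colony)."""


def _shift_sum_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    """Sum of the two axis-neighbors' values (zero outside the domain).

    Grouped per axis so mirror-symmetric inputs give bit-identical
    mirror-symmetric outputs.
    """
    lo = np.zeros_like(arr)
    hi = np.zeros_like(arr)
    sl_from = [slice(None)] * arr.ndim
    sl_to = [slice(None)] * arr.ndim
    sl_from[axis] = slice(1, None)
    sl_to[axis] = slice(None, -1)
    lo[tuple(sl_to)] = arr[tuple(sl_from)]
    sl_from[axis] = slice(None, -1)
    sl_to[axis] = slice(1, None)
    hi[tuple(sl_to)] = arr[tuple(sl_from)]
    return lo + hi


@njit(cache=True)
def _push_kernel(m, open_site, n_open, cap_mass, tol_mass, max_sweeps,
                 blocked):  # pragma: no cover - jitted
    nph, nx, ny, nz = m.shape
    frac = np.zeros((nx, ny, nz))
    g = np.zeros((nx, ny, nz))
    for sweep in range(max_sweeps):
        any_over = False
        all_blocked = True
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    mt = m[0, i, j, k] + m[1, i, j, k]
                    ex = mt - cap_mass
                    if ex > tol_mass:
                        any_over = True
                        if n_open[i, j, k] == 0.0:
                            blocked[i, j, k] = True
                            frac[i, j, k] = 0.0
                        else:
                            all_blocked = False
                            frac[i, j, k] = ex / mt
                    else:
                        frac[i, j, k] = 0.0
        if not any_over or all_blocked:
            return sweep
        for p in range(nph):
            # per-face export (synchronous: computed before any receipt)
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        if frac[i, j, k] > 0.0:
                            g[i, j, k] = (m[p, i, j, k] * frac[i, j, k]
                                          / n_open[i, j, k])
                        else:
                            g[i, j, k] = 0.0
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        out = g[i, j, k] * n_open[i, j, k]
                        if open_site[i, j, k]:
                            # per-axis pairing keeps mirror symmetry exact
                            sx = (g[i - 1, j, k] if i > 0 else 0.0) + \
                                 (g[i + 1, j, k] if i < nx - 1 else 0.0)
                            sy = (g[i, j - 1, k] if j > 0 else 0.0) + \
                                 (g[i, j + 1, k] if j < ny - 1 else 0.0)
                            sz = (g[i, j, k - 1] if k > 0 else 0.0) + \
                                 (g[i, j, k + 1] if k < nz - 1 else 0.0)
                            m[p, i, j, k] += sx + sy + sz - out
                        else:
                            m[p, i, j, k] -= out
    return -1


def push_biomass(state: LatticeState, consts: CellConstants,
                 tol_frac: float = 1e-6, max_sweeps: int = 10_000
                 ) -> np.ndarray:
    """Relax over-packed sites by isotropic overflow.

    Every site with total phi > phi_max exports its excess mass, split
    equally among its non-agar face neighbors (phenotype proportions
    preserved); out-of-domain faces count as open and absorb the mass.
    Sweeps repeat until the worst overflow is below ``tol_frac *
    phi_max``.  Returns the boolean mask of sites that could not export
    (no open neighbors) so the engine can suppress their growth.
    """
    V = state.site_volume
    cap_mass = consts.phi_max * consts.rho * V
    open_site = state.phase != AGAR
    # number of open faces including the absorbing domain boundary
    n_open = np.full(state.dims, 6.0)
    for ax in range(3):
        n_open -= _shift_sum_axis(1.0 - open_site.astype(float), ax)
    blocked = np.zeros(state.dims, dtype=np.bool_)
    sweeps = _push_kernel(state.m, open_site, n_open, cap_mass,
                          tol_frac * cap_mass, max_sweeps, blocked)
    if sweeps < 0:
        raise PushNonConvergence(
            f"pushing did not converge after {max_sweeps} sweeps "
            f"(max phi = {state.total_mass().max() / (consts.rho * V):.3f})")
    return blocked
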