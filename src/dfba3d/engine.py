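"""Simulation orchestration: operator-split 3D dynamic FBA.

Each outer step spans one FBA refresh interval and applies, in order:

1. per-site conversion of local concentrations to uptake availabilities
   (Michaelis-Menten saturation + supply cap) and flux-table lookup;
2. reaction (exchange fluxes applied to the chemical fields) and
   exponential biomass growth at the table growth rate;
3. phenotype regulation (starvation timers);
4. isotropic pushing of over-packed biomass;
5. diffusion of every species in stability-limited substeps spanning
   the interval.

The coupling is fully deterministic: identical configurations produce
bit-identical trajectories.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import analysis as _analysis
from .cell_dynamics import (ACE, GLU, CellConstants, RegulationParams,
                            RegulationState, apply_reaction,
                            compute_uptake_bounds, grow_biomass,
                            push_biomass, update_phenotypes, volume_fraction)
from .geometry import (GeometrySpec, build_substrate, check_resolution,
                       default_seed_site, seed_colony)
from .metabolic_tables import (ACETATE, DEFAULT_AC_UPTAKE_MAX,
                               DEFAULT_AC_YIELD, DEFAULT_O2_PER_AC, GLUCOSE,
                               OXYGEN, FluxTable, Phenotype, StrainRecord,
                               STRAINS, build_surrogate_table, lookup_fluxes)
from .rd_solver import LatticeState, Species, default_species, diffuse, \
    stable_dt

logger = logging.getLogger(__name__)

S_PER_HR = 3600.0


@dataclass
class SimConfig:
    """Everything needed to run one simulation.

    ``strain`` is a packaged strain name or a :class:`StrainRecord`;
    ``fba_interval`` is the FBA refresh period in seconds of simulated
    time (decoupled from the much smaller diffusion substeps);
    ``output_interval`` the scalar-series sampling period in hours;
    ``snapshot_interval`` the full-state save period in hours (None
    saves only initial and final states).  ``clamp_concentrations``
    is a test mode: after every interval the listed species are reset
    to the given uniform values and diffusion is skipped.
    """

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    strain: str | StrainRecord = "MG1655"
    dx: float = 10.0
    duration: float = 40.0
    fba_interval: float = 36.0
    output_interval: float = 0.25
    snapshot_interval: float | None = None
    species: dict[str, Species] = field(default_factory=default_species)
    regulation: RegulationParams = field(default_factory=RegulationParams)
    constants: CellConstants = field(default_factory=CellConstants)
    safety: float = 0.9
    well_mixed_air: bool = True
    ac_uptake_max: float = DEFAULT_AC_UPTAKE_MAX
    ac_yield: float = DEFAULT_AC_YIELD
    o2_per_ac: float = DEFAULT_O2_PER_AC
    seed_site: tuple[int, int, int] | None = None
    clamp_concentrations: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.fba_interval <= 0:
            raise ValueError("fba_interval must be > 0")
        if self.duration > 0 and self.output_interval > self.duration:
            raise ValueError("output_interval must not exceed duration")
        d_max = max(sp.D_max for sp in self.species.values())
        if self.fba_interval < stable_dt(self.dx, d_max, 1.0):
            raise ValueError("fba_interval smaller than a diffusion substep")
        check_resolution(self.geometry, self.dx)

    @property
    def record(self) -> StrainRecord:
        if isinstance(self.strain, StrainRecord):
            return self.strain
        return STRAINS[self.strain]


@dataclass
class Trajectory:
    """Scalar time series plus saved lattice snapshots."""

    times: np.ndarray
    series: dict[str, np.ndarray]
    snapshots: list[tuple[float, LatticeState]]
    config: SimConfig
    metadata: dict = field(default_factory=dict)

    def series_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_hr": self.times, **self.series})

    def metric(self, key: str) -> _analysis.MetricSeries:
        units = {"ace_fraction": "1", "vol_total_fl": "fL",
                 "height_um": "um", "width_um": "um"}.get(key, "")
        return _analysis.MetricSeries(self.times, self.series[key], key,
                                      units)


def default_tables(config: SimConfig) -> dict[Phenotype, FluxTable]:
    """Surrogate flux tables for both phenotypes of the config strain."""
    kw = dict(ac_uptake_max=config.ac_uptake_max, ac_yield=config.ac_yield,
              o2_per_ac=config.o2_per_ac)
    return {p: build_surrogate_table(config.record, p, **kw)
            for p in Phenotype}


def _record_metrics(state: LatticeState, consts: CellConstants,
                    applied_ace_uptake: np.ndarray | None,
                    series: dict[str, list]) -> None:
    rho = consts.rho
    m_glu = float(state.m[GLU].sum())
    m_ace = float(state.m[ACE].sum())
    m_tot = m_glu + m_ace
    vol_glu, vol_ace = m_glu / rho, m_ace / rho
    phi = volume_fraction(state.total_mass(), state.site_volume, consts)
    dims = _analysis.colony_dimensions(state, consts)
    series["mass_glu_fg"].append(m_glu)
    series["mass_ace_fg"].append(m_ace)
    series["vol_glu_fl"].append(vol_glu)
    series["vol_ace_fl"].append(vol_ace)
    series["vol_total_fl"].append(vol_glu + vol_ace)
    series["ace_fraction"].append(m_ace / m_tot if m_tot > 0 else np.nan)
    series["max_phi"].append(float(phi.max()))
    series["height_um"].append(dims.height)
    series["width_um"].append(dims.width)
    if applied_ace_uptake is not None and m_ace > 0:
        consuming = np.abs(applied_ace_uptake) > 1e-9
        share = float(state.m[ACE][consuming].sum()) / m_ace
        turnover = float((state.m[ACE] * np.abs(applied_ace_uptake)).sum()
                         ) / max(vol_glu + vol_ace, 1e-300)
    else:
        share = np.nan if m_ace == 0 else 0.0
        turnover = 0.0 if m_tot > 0 else np.nan
    series["active_consumer_share"].append(share)
    series["ace_turnover_mM_hr"].append(turnover)


def run_simulation(config: SimConfig,
                   tables: Mapping[Phenotype, FluxTable] | None = None,
                   progress: bool = False) -> Trajectory:
    """Run one colony simulation and return its trajectory."""
    t_wall0 = _time.time()
    if tables is None:
        tables = default_tables(config)
    consts = config.constants
    species = config.species
    state = build_substrate(config.geometry, config.dx, species)
    seed = config.seed_site or default_seed_site(state, config.geometry)
    seed_colony(state, seed, consts)
    if config.clamp_concentrations is not None:
        for name, value in config.clamp_concentrations.items():
            state.C[name][:] = value
    reg = RegulationState.zeros(state.dims, config.regulation.reversible)

    dt = config.fba_interval
    n_intervals = int(round(config.duration * S_PER_HR / dt))
    rec_stride = max(1, int(round(config.output_interval * S_PER_HR / dt)))
    snap_stride = None
    if config.snapshot_interval is not None:
        snap_stride = max(1, int(round(config.snapshot_interval * S_PER_HR
                                       / dt)))
    V = state.site_volume
    tbl_glu = tables[Phenotype.GLUCOSE_UTILIZER]
    tbl_ace = tables[Phenotype.ACETATE_UTILIZER]
    glc_max = float(tbl_glu.carbon_axis[-1])
    ace_max = float(tbl_ace.carbon_axis[-1])
    o2_max = float(tbl_glu.o2_axis[-1])

    series_keys = ("mass_glu_fg", "mass_ace_fg", "vol_glu_fl", "vol_ace_fl",
                   "vol_total_fl", "ace_fraction", "max_phi", "height_um",
                   "width_um", "active_consumer_share", "ace_turnover_mM_hr")
    series: dict[str, list] = {k: [] for k in series_keys}
    times: list[float] = []
    snapshots: list[tuple[float, LatticeState]] = [(0.0, state.copy())]
    times.append(0.0)
    _record_metrics(state, consts, None, series)

    blocked = np.zeros(state.dims, dtype=bool)
    boundary_contact: float | None = None
    shell = np.zeros(state.dims, dtype=bool)
    shell[0], shell[-1] = True, True
    shell[:, 0], shell[:, -1] = True, True
    shell[:, :, 0], shell[:, :, -1] = True, True

    applied_ace = None
    for step in range(1, n_intervals + 1):
        m_tot = state.total_mass()
        phi_tot = volume_fraction(m_tot, V, consts)

        # 1) availabilities and table lookup
        avail_glc = compute_uptake_bounds(state.C[GLUCOSE], m_tot, V, dt,
                                          glc_max, species[GLUCOSE].Km)
        avail_ace = compute_uptake_bounds(state.C[ACETATE], m_tot, V, dt,
                                          ace_max, species[ACETATE].Km)
        avail_o2 = compute_uptake_bounds(state.C[OXYGEN], m_tot, V, dt,
                                         o2_max, species[OXYGEN].Km)
        flux_glu = lookup_fluxes(tbl_glu, avail_glc, avail_o2)
        flux_ace = lookup_fluxes(tbl_ace, avail_ace, avail_o2)
        # bilinear interpolation can overshoot a bound near table kinks;
        # re-clip uptakes (negative) to the availabilities
        flux_glu[GLUCOSE] = np.maximum(flux_glu[GLUCOSE], -avail_glc)
        flux_ace[ACETATE] = np.maximum(flux_ace[ACETATE], -avail_ace)
        flux_glu[OXYGEN] = np.maximum(flux_glu[OXYGEN], -avail_o2)
        flux_ace[OXYGEN] = np.maximum(flux_ace[OXYGEN], -avail_o2)
        if blocked.any():
            for f in (flux_glu, flux_ace):
                f["v_bm"] = np.where(blocked, 0.0, f["v_bm"])
        applied_ace = flux_ace[ACETATE]

        # 2) reaction + growth over the interval
        fluxes = {name: np.stack([flux_glu[name], flux_ace[name]])
                  for name in (GLUCOSE, ACETATE, OXYGEN)}
        apply_reaction(state, fluxes, dt)
        state.m[GLU] = grow_biomass(state.m[GLU], flux_glu["v_bm"], dt)
        state.m[ACE] = grow_biomass(state.m[ACE], flux_ace["v_bm"], dt)

        # 3) regulation, 4) pushing
        update_phenotypes(state, reg, config.regulation, dt)
        blocked = push_biomass(state, consts)

        # 5) transport
        if config.clamp_concentrations is not None:
            for name, value in config.clamp_concentrations.items():
                state.C[name][:] = value
        else:
            phi_now = volume_fraction(state.total_mass(), V, consts)
            for sp in species.values():
                diffuse(state, sp, dt, phi_now, safety=config.safety,
                        well_mixed_air=config.well_mixed_air)

        state.t += dt
        t_hr = state.t / S_PER_HR

        if not np.isfinite(state.total_mass().sum()) or any(
                not np.isfinite(c.sum()) for c in state.C.values()):
            raise FloatingPointError(
                f"non-finite state at t={t_hr:.3f} hr; aborting")
        if boundary_contact is None and (state.total_mass()[shell]
                                         > 0).any():
            boundary_contact = t_hr
        if step % rec_stride == 0 or step == n_intervals:
            times.append(t_hr)
            _record_metrics(state, consts, applied_ace, series)
        if snap_stride is not None and step % snap_stride == 0:
            snapshots.append((t_hr, state.copy()))
        if progress and step % max(1, int(S_PER_HR / dt)) == 0:
            logger.info("t = %.1f hr  mass = %.3g fg  ace%% = %.2f",
                        t_hr, state.total_mass().sum(),
                        100 * series["ace_fraction"][-1])

    if snapshots[-1][0] != state.t / S_PER_HR:
        snapshots.append((state.t / S_PER_HR, state.copy()))
    meta = {
        "strain": config.record.name,
        "geometry": config.geometry.kind.value,
        "dx_um": config.dx,
        "boundary_contact_hr": boundary_contact,
        "table_source": tbl_glu.meta.get("source", "unknown"),
        "wall_clock_s": _time.time() - t_wall0,
    }
    return Trajectory(np.asarray(times),
                      {k: np.asarray(v) for k, v in series.items()},
                      snapshots, config, meta)
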