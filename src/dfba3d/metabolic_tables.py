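"""Per-strain, per-phenotype flux lookup tables.

The lattice engine never solves a linear program during time stepping.
Instead it queries precomputed tables of FBA solutions indexed by
(carbon uptake, O2 uptake) availability, one table per metabolic
phenotype.  Tables can be built two ways:

* from a genome-scale metabolic model (cobrapy), after fitting the
  maximal O2 uptake and growth-associated maintenance (GAM) to measured
  chemostat growth/acetate rates, or
* from a strain record alone, via an analytic surrogate anchored to the
  measured aerobic and anaerobic operating points.

Sign convention everywhere: uptake fluxes are negative, secretion
positive, in mmol/gDCW/hr.  Growth rates are 1/hr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

GLUCOSE = "glucose"
ACETATE = "acetate"
OXYGEN = "oxygen"

#: Default maximal acetate uptake rate of the acetate-utilizing
#: phenotype, mmol/gDCW/hr.  Strain-specific acetate consumption data
#: are not available; this single value is shared by all strains and is
#: deliberately exposed as a keyword argument throughout.
DEFAULT_AC_UPTAKE_MAX = 10.0
#: Biomass yield on acetate, gDCW per mmol acetate (growth = yield * uptake).
DEFAULT_AC_YIELD = 0.025
#: O2 demand per unit acetate oxidized, mol O2 / mol acetate.
DEFAULT_O2_PER_AC = 2.0


class Phenotype(str, Enum):
    """The two metabolic phenotypes tracked on the lattice."""

    GLUCOSE_UTILIZER = "glucose_utilizer"
    ACETATE_UTILIZER = "acetate_utilizer"


@dataclass(frozen=True)
class StrainRecord:
    """Measured/fitted growth characteristics of one E. coli strain.

    Rates are magnitudes: ``v_glc_*`` are maximal glucose uptake rates,
    ``v_ac_*`` acetate efflux rates, ``v_o2_max`` the fitted maximal O2
    uptake (all mmol/gDCW/hr); ``mu_*`` growth rates (1/hr); ``gam_*``
    growth-associated maintenance (mmolATP/gDCW).  ``reported_errors``
    holds the percentage deviation of each fitted quantity from its
    experimental value.
    """

    name: str
    mu_aero: float
    mu_anaero: float
    v_glc_aero: float
    v_glc_anaero: float
    v_ac_aero: float
    v_ac_anaero: float
    v_o2_max: float
    gam_aero: float
    gam_anaero: float
    reported_errors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in ("mu_aero", "mu_anaero", "v_glc_aero", "v_glc_anaero",
                  "v_ac_aero", "v_ac_anaero", "v_o2_max", "gam_aero",
                  "gam_anaero"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be a magnitude >= 0")


#: The five packaged strains (chemostat-fitted characteristics).
STRAINS: dict[str, StrainRecord] = {
    "B21": StrainRecord(
        "B21", 0.76, 0.29, 8.0, 11.3, 0.0, 9.17, 15.5, 60.25, 50.45,
        {"mu_aero": 0.0, "mu_anaero": 0.0, "ac_aero": 0.0, "ac_anaero": 3.9}),
    "Crooks": StrainRecord(
        "Crooks", 0.96, 0.77, 12.5, 30.9, 0.0, 25.2, 33.5, 121.45, 59.75,
        {"mu_aero": 0.0, "mu_anaero": 0.0, "ac_aero": 0.0, "ac_anaero": 32.0}),
    "MG1655": StrainRecord(
        "MG1655", 0.84, 0.46, 9.5, 16.7, 3.49, 13.27, 13.9, 60.25, 50.45,
        {"mu_aero": 15.2, "mu_anaero": 0.0, "ac_aero": 0.0,
         "ac_anaero": 13.3}),
    "W": StrainRecord(
        "W", 0.97, 0.90, 9.9, 27.2, 0.0, 20.53, 17.8, 54.55, 35.65,
        {"mu_aero": 0.0, "mu_anaero": 0.0, "ac_aero": 0.0, "ac_anaero": 2.6}),
    "W3110": StrainRecord(
        "W3110", 0.61, 0.52, 6.7, 17.5, 3.03, 13.63, 7.5, 36.65, 41.65,
        {"mu_aero": 0.0, "mu_anaero": 0.0, "ac_aero": 2.7,
         "ac_anaero": 28.7}),
}


def mean_anaerobic_acetate_error(
        records: Iterable[StrainRecord] | None = None) -> float:
    """Mean absolute percentage error of fitted anaerobic acetate rates."""
    recs = list(records) if records is not None else list(STRAINS.values())
    return float(np.mean([r.reported_errors["ac_anaero"] for r in recs]))


@dataclass(frozen=True)
class FittedParams:
    """Result of fitting a genome-scale model to a strain record."""

    v_o2_max: float
    gam_aero: float
    gam_anaero: float
    residual_errors: Mapping[str, float] = field(default_factory=dict)


@dataclass
class FluxTable:
    """Precomputed dFBA solutions on a (carbon uptake, O2 uptake) grid.

    ``carbon_axis``/``o2_axis`` are evenly spaced availability
    magnitudes (mmol/gDCW/hr); ``v_bm`` is the optimal growth rate and
    ``exchanges`` maps species name to the applied exchange flux at each
    node (uptake negative, secretion positive).
    """

    phenotype: Phenotype
    carbon_axis: np.ndarray
    o2_axis: np.ndarray
    v_bm: np.ndarray
    exchanges: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nc, no = len(self.carbon_axis), len(self.o2_axis)
        if self.v_bm.shape != (nc, no):
            raise ValueError("v_bm shape does not match the axes")
        for name, arr in self.exchanges.items():
            if arr.shape != (nc, no):
                raise ValueError(f"exchange {name!r} shape mismatch")

    @property
    def carbon_species(self) -> str:
        return GLUCOSE if self.phenotype is Phenotype.GLUCOSE_UTILIZER \
            else ACETATE

    def _write_group(self, grp) -> None:
        grp.create_dataset("carbon_axis", data=self.carbon_axis)
        grp.create_dataset("o2_axis", data=self.o2_axis)
        grp.create_dataset("v_bm", data=self.v_bm)
        ex = grp.create_group("exchanges")
        for name, arr in self.exchanges.items():
            ex.create_dataset(name, data=arr)
        grp.attrs["units_axes"] = "mmol/gDCW/hr"
        grp.attrs["units_v_bm"] = "1/hr"
        grp.attrs["sign_convention"] = "uptake negative, secretion positive"
        for k, v in self.meta.items():
            grp.attrs[f"meta_{k}"] = v

    @classmethod
    def _from_group(cls, key: str, grp) -> "FluxTable":
        meta = {k[5:]: grp.attrs[k] for k in grp.attrs
                if k.startswith("meta_")}
        return cls(
            phenotype=Phenotype(key),
            carbon_axis=grp["carbon_axis"][...],
            o2_axis=grp["o2_axis"][...],
            v_bm=grp["v_bm"][...],
            exchanges={n: grp["exchanges"][n][...] for n in grp["exchanges"]},
            meta=meta,
        )

    def save_hdf5(self, path) -> None:
        save_tables({self.phenotype: self}, path)

    @classmethod
    def load_hdf5(cls, path) -> "FluxTable":
        tables = load_tables(path)
        return next(iter(tables.values()))


def save_tables(tables: Mapping[Phenotype, "FluxTable"], path) -> None:
    """Write one or more flux tables to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as h5:
        for phenotype, table in tables.items():
            table._write_group(h5.create_group(phenotype.value))


def load_tables(path) -> dict[Phenotype, "FluxTable"]:
    """Read every flux table stored in an HDF5 container."""
    import h5py

    with h5py.File(path, "r") as h5:
        return {Phenotype(key): FluxTable._from_group(key, h5[key])
                for key in h5}


# ---------------------------------------------------------------------------
# Surrogate tables anchored to the strain records
# ---------------------------------------------------------------------------

def surrogate_fluxes(
    record: StrainRecord,
    phenotype: Phenotype,
    carbon,
    o2,
    *,
    ac_uptake_max: float = DEFAULT_AC_UPTAKE_MAX,
    ac_yield: float = DEFAULT_AC_YIELD,
    o2_per_ac: float = DEFAULT_O2_PER_AC,
) -> dict[str, np.ndarray]:
    """Analytic stand-in for a genome-scale FBA solution.

    For the glucose phenotype the response interpolates between the two
    measured operating points of the strain: fully aerobic (glucose
    uptake ``v_glc_aero`` with O2 at ``v_o2_max`` yields ``mu_aero`` and
    acetate ``v_ac_aero``) and fully anaerobic (glucose ``v_glc_anaero``
    at zero O2 yields ``mu_anaero``, acetate ``v_ac_anaero``).  The O2
    sufficiency fraction is f = min(1, o2 / v_o2_max); the carbon uptake
    capacity blends linearly between the aerobic and anaerobic maxima,
    and growth/acetate are linear in the applied carbon uptake at fixed
    f.  For the acetate phenotype growth is yield * uptake, aerobic
    only: uptake is limited by the available O2 at ``o2_per_ac`` mol O2
    per mol acetate.

    Inputs are availability magnitudes (>= 0); broadcasting applies.
    Returns ``{"v_bm": ..., "glucose": ..., "acetate": ..., "oxygen": ...}``
    with the package sign convention.
    """
    carbon = np.maximum(np.asarray(carbon, dtype=float), 0.0)
    o2 = np.maximum(np.asarray(o2, dtype=float), 0.0)
    if phenotype is Phenotype.GLUCOSE_UTILIZER:
        r = record
        f = np.minimum(1.0, o2 / r.v_o2_max) if r.v_o2_max > 0 \
            else np.zeros_like(o2)
        cap = f * r.v_glc_aero + (1.0 - f) * r.v_glc_anaero
        g = np.minimum(np.minimum(carbon, r.v_glc_anaero), cap)
        mu_slope = (f * r.mu_aero / r.v_glc_aero
                    + (1.0 - f) * r.mu_anaero / r.v_glc_anaero)
        ac_slope = (f * r.v_ac_aero / r.v_glc_aero
                    + (1.0 - f) * r.v_ac_anaero / r.v_glc_anaero)
        with np.errstate(invalid="ignore", divide="ignore"):
            o2_used = np.where(cap > 0, f * r.v_o2_max * g / np.where(
                cap > 0, cap, 1.0), 0.0)
        return {
            "v_bm": g * mu_slope,
            GLUCOSE: -g,
            ACETATE: g * ac_slope,
            OXYGEN: -o2_used,
        }
    # acetate phenotype: aerobic only
    ace = np.minimum(np.minimum(carbon, ac_uptake_max), o2 / o2_per_ac)
    ace = np.minimum(ace, record.v_o2_max / o2_per_ac)
    zero = np.zeros_like(ace)
    return {
        "v_bm": ac_yield * ace,
        GLUCOSE: zero,
        ACETATE: -ace,
        OXYGEN: -o2_per_ac * ace,
    }


def build_surrogate_table(
    record: StrainRecord,
    phenotype: Phenotype,
    n_carbon: int = 50,
    n_o2: int = 160,
    **kwargs,
) -> FluxTable:
    """Sample :func:`surrogate_fluxes` on the standard table grid."""
    ac_max = kwargs.get("ac_uptake_max", DEFAULT_AC_UPTAKE_MAX)
    carbon_max = record.v_glc_anaero \
        if phenotype is Phenotype.GLUCOSE_UTILIZER else ac_max
    carbon_axis = np.linspace(0.0, carbon_max, n_carbon)
    o2_axis = np.linspace(0.0, record.v_o2_max, n_o2)
    cg, og = np.meshgrid(carbon_axis, o2_axis, indexing="ij")
    out = surrogate_fluxes(record, phenotype, cg, og, **kwargs)
    return FluxTable(
        phenotype=phenotype,
        carbon_axis=carbon_axis,
        o2_axis=o2_axis,
        v_bm=out["v_bm"],
        exchanges={k: v for k, v in out.items() if k != "v_bm"},
        meta={"source": "surrogate", "strain": record.name},
    )


# ---------------------------------------------------------------------------
# Table interpolation
# ---------------------------------------------------------------------------

def _axis_locate(axis: np.ndarray, x: np.ndarray):
    """Clamped cell index and fractional offset along one table axis."""
    x = np.clip(x, axis[0], axis[-1])
    i = np.searchsorted(axis, x, side="right") - 1
    i = np.clip(i, 0, len(axis) - 2)
    step = axis[i + 1] - axis[i]
    t = np.where(step > 0, (x - axis[i]) / np.where(step > 0, step, 1.0), 0.0)
    return i, t


def lookup_fluxes(table: FluxTable, carbon_avail, o2_avail
                  ) -> dict[str, np.ndarray]:
    """Bilinear interpolation of the table at the given availabilities.

    Availabilities (magnitudes, >= 0) are clamped to the axis maxima;
    queries exactly at a node return the node values.
    """
    carbon_avail = np.asarray(carbon_avail, dtype=float)
    o2_avail = np.asarray(o2_avail, dtype=float)
    i, tc = _axis_locate(table.carbon_axis, carbon_avail)
    j, to = _axis_locate(table.o2_axis, o2_avail)
    w00 = (1 - tc) * (1 - to)
    w10 = tc * (1 - to)
    w01 = (1 - tc) * to
    w11 = tc * to

    def interp(V: np.ndarray) -> np.ndarray:
        return (w00 * V[i, j] + w10 * V[i + 1, j]
                + w01 * V[i, j + 1] + w11 * V[i + 1, j + 1])

    out = {"v_bm": interp(table.v_bm)}
    for name, arr in table.exchanges.items():
        out[name] = interp(arr)
    return out


# ---------------------------------------------------------------------------
# Genome-scale model fitting and LP tables (cobrapy)
# ---------------------------------------------------------------------------

#: Conventional BiGG exchange identifiers.
DEFAULT_EXCHANGES = {GLUCOSE: "EX_glc__D_e", ACETATE: "EX_ac_e",
                     OXYGEN: "EX_o2_e"}
#: Metabolites whose biomass-reaction coefficients carry the GAM cost.
GAM_CONSUMED = ("atp_c", "h2o_c")
GAM_PRODUCED = ("adp_c", "pi_c", "h_c")


class ModelConfigError(ValueError):
    """The model lacks a required exchange reaction or objective."""


class InfeasibleModelError(RuntimeError):
    """FBA is infeasible at the measured uptake rates."""


def _biomass_reaction(model):
    objs = [r for r in model.reactions
            if r.objective_coefficient not in (0, 0.0)]
    if not objs:
        raise ModelConfigError("model has no objective reaction")
    return objs[0]


def _set_gam(model, gam: float) -> None:
    """Set the ATP-maintenance coefficients of the biomass reaction."""
    rxn = _biomass_reaction(model)
    new = {}
    for mid in GAM_CONSUMED:
        if mid in model.metabolites:
            new[model.metabolites.get_by_id(mid)] = -gam
    for mid in GAM_PRODUCED:
        if mid in model.metabolites:
            new[model.metabolites.get_by_id(mid)] = gam
    if not new:
        raise ModelConfigError("biomass reaction has no GAM metabolites")
    for met in new:
        if met in rxn.metabolites:
            rxn.subtract_metabolites({met: rxn.metabolites[met]})
    rxn.add_metabolites(new)


def _get_exchange(model, rxn_id: str):
    try:
        return model.reactions.get_by_id(rxn_id)
    except KeyError as exc:
        raise ModelConfigError(f"missing exchange reaction {rxn_id!r}") \
            from exc


def _solve_condition(model, glc_uptake: float, o2_uptake: float, gam: float,
                     exchanges: Mapping[str, str]):
    """Optimal (growth, acetate flux) at fixed glucose/O2 uptake bounds."""
    with model:
        _set_gam(model, gam)
        _get_exchange(model, exchanges[GLUCOSE]).lower_bound = -glc_uptake
        _get_exchange(model, exchanges[OXYGEN]).lower_bound = -o2_uptake
        mu = model.slim_optimize(error_value=np.nan)
        if np.isnan(mu):
            return np.nan, np.nan
        ac = model.reactions.get_by_id(exchanges[ACETATE]).flux
    return float(mu), float(ac)


def _pct_error(pred: float, obs: float) -> float:
    if np.isnan(pred):
        return float("inf")
    denom = abs(obs) if obs != 0 else 1.0
    return 100.0 * abs(pred - obs) / denom


def fit_strain_parameters(
    model,
    record: StrainRecord,
    exchanges: Mapping[str, str] = DEFAULT_EXCHANGES,
    v_o2_range: tuple[float, float] = (5.0, 40.0),
    gam_range: tuple[float, float] = (10.0, 130.0),
    coarse: int = 13,
    refinements: int = 3,
) -> FittedParams:
    """Fit (v_o2_max, GAM_aero, GAM_anaero) to the measured rates.

    Glucose uptake is fixed at the record's measured aerobic/anaerobic
    values; the objective is the summed absolute relative error of
    FBA-predicted growth and acetate rates against the record,
    aerobically for (v_o2_max, GAM_aero) and anaerobically (O2 closed)
    for GAM_anaero.  Search is a coarse grid followed by local
    refinement — adequate because the response is piecewise smooth in
    both parameters.
    """
    _get_exchange(model, exchanges[GLUCOSE])
    _get_exchange(model, exchanges[OXYGEN])
    _get_exchange(model, exchanges[ACETATE])

    def aero_obj(v_o2: float, gam: float) -> float:
        mu, ac = _solve_condition(model, record.v_glc_aero, v_o2, gam,
                                  exchanges)
        return _pct_error(mu, record.mu_aero) + _pct_error(ac,
                                                           record.v_ac_aero)

    def anaero_obj(gam: float) -> float:
        mu, ac = _solve_condition(model, record.v_glc_anaero, 0.0, gam,
                                  exchanges)
        return _pct_error(mu, record.mu_anaero) + _pct_error(
            ac, record.v_ac_anaero)

    # --- aerobic: 2D grid + refinement
    vo_lo, vo_hi = v_o2_range
    g_lo, g_hi = gam_range
    best = (np.inf, vo_lo, g_lo)
    for _ in range(refinements + 1):
        vos = np.linspace(vo_lo, vo_hi, coarse)
        gams = np.linspace(g_lo, g_hi, coarse)
        for vo in vos:
            for gm in gams:
                err = aero_obj(vo, gm)
                if err < best[0]:
                    best = (err, vo, gm)
        dv = (vo_hi - vo_lo) / (coarse - 1)
        dg = (g_hi - g_lo) / (coarse - 1)
        vo_lo = max(v_o2_range[0], best[1] - dv)
        vo_hi = min(v_o2_range[1], best[1] + dv)
        g_lo = max(gam_range[0], best[2] - dg)
        g_hi = min(gam_range[1], best[2] + dg)
    _, v_o2_fit, gam_aero = best

    # --- anaerobic: 1D grid + refinement (v_o2 irrelevant, O2 closed)
    g_lo, g_hi = gam_range
    best_an = (np.inf, g_lo)
    for _ in range(refinements + 1):
        for gm in np.linspace(g_lo, g_hi, coarse * 2):
            err = anaero_obj(gm)
            if err < best_an[0]:
                best_an = (err, gm)
        dg = (g_hi - g_lo) / (2 * coarse - 1)
        g_lo = max(gam_range[0], best_an[1] - dg)
        g_hi = min(gam_range[1], best_an[1] + dg)
    gam_anaero = best_an[1]

    mu_a, ac_a = _solve_condition(model, record.v_glc_aero, v_o2_fit,
                                  gam_aero, exchanges)
    mu_n, ac_n = _solve_condition(model, record.v_glc_anaero, 0.0,
                                  gam_anaero, exchanges)
    if np.isnan(mu_a) or np.isnan(mu_n):
        raise InfeasibleModelError(
            f"model infeasible at measured glucose uptake for {record.name}")
    residuals = {
        "mu_aero": _pct_error(mu_a, record.mu_aero),
        "mu_anaero": _pct_error(mu_n, record.mu_anaero),
        "ac_aero": _pct_error(ac_a, record.v_ac_aero),
        "ac_anaero": _pct_error(ac_n, record.v_ac_anaero),
    }
    return FittedParams(float(v_o2_fit), float(gam_aero), float(gam_anaero),
                        residuals)


def build_flux_table(
    model,
    phenotype: Phenotype,
    params: FittedParams,
    n_carbon: int = 50,
    n_o2: int = 160,
    carbon_max: float | None = None,
    exchanges: Mapping[str, str] = DEFAULT_EXCHANGES,
    ac_uptake_max: float = DEFAULT_AC_UPTAKE_MAX,
) -> FluxTable:
    """Solve one LP per (carbon, O2) node and tabulate the optimum.

    Axes are evenly spaced between 0 and the maximal carbon (O2) uptake
    rates.  Infeasible or failed nodes are stored as zero growth and
    zero exchange (dormancy) and counted in ``meta['failed_nodes']``.
    """
    carbon_species = GLUCOSE if phenotype is Phenotype.GLUCOSE_UTILIZER \
        else ACETATE
    if carbon_max is None:
        carbon_max = ac_uptake_max if carbon_species == ACETATE else None
    if carbon_max is None:
        raise ValueError("carbon_max required for the glucose phenotype")
    carbon_axis = np.linspace(0.0, carbon_max, n_carbon)
    o2_axis = np.linspace(0.0, params.v_o2_max, n_o2)
    shape = (n_carbon, n_o2)
    v_bm = np.zeros(shape)
    ex = {GLUCOSE: np.zeros(shape), ACETATE: np.zeros(shape),
          OXYGEN: np.zeros(shape)}
    gam = params.gam_aero
    failed = 0
    with model:
        _set_gam(model, gam)
        carbon_rxn = _get_exchange(model, exchanges[carbon_species])
        o2_rxn = _get_exchange(model, exchanges[OXYGEN])
        other = GLUCOSE if carbon_species == ACETATE else ACETATE
        other_rxn = _get_exchange(model, exchanges[other])
        if phenotype is Phenotype.ACETATE_UTILIZER:
            other_rxn.lower_bound = 0.0  # no glucose for the acetate phenotype
        for ic, c in enumerate(carbon_axis):
            for jo, o in enumerate(o2_axis):
                carbon_rxn.lower_bound = -c
                o2_rxn.lower_bound = -o
                try:
                    mu = model.slim_optimize(error_value=np.nan)
                except Exception:  # solver failure: flag, continue
                    mu = np.nan
                if np.isnan(mu) or mu < 0:
                    failed += int(np.isnan(mu))
                    continue
                v_bm[ic, jo] = mu
                for name in ex:
                    ex[name][ic, jo] = model.reactions.get_by_id(
                        exchanges[name]).flux
    if failed:
        logger.warning("build_flux_table: %d infeasible/failed nodes "
                       "stored as zero growth", failed)
    return FluxTable(phenotype, carbon_axis, o2_axis, v_bm, ex,
                     meta={"source": "fba", "failed_nodes": failed,
                           "gam": gam, "v_o2_max": params.v_o2_max})


def read_strain_table(path) -> dict[str, StrainRecord]:
    """Read strain records from delimited text (tab/comma separated).

    Expected columns: strain, mu_aero, mu_anaero, v_glc_aero,
    v_glc_anaero, v_ac_aero, v_ac_anaero, v_o2_max, gam_aero,
    gam_anaero (uptake columns may be signed; magnitudes are stored).
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    out = {}
    for _, row in df.iterrows():
        rec = StrainRecord(
            name=str(row["strain"]),
            mu_aero=float(row["mu_aero"]),
            mu_anaero=float(row["mu_anaero"]),
            v_glc_aero=abs(float(row["v_glc_aero"])),
            v_glc_anaero=abs(float(row["v_glc_anaero"])),
            v_ac_aero=float(row["v_ac_aero"]),
            v_ac_anaero=float(row["v_ac_anaero"]),
            v_o2_max=abs(float(row["v_o2_max"])),
            gam_aero=float(row["gam_aero"]),
            gam_anaero=float(row["gam_anaero"]),
        )
        out[rec.name] = rec
    return out
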