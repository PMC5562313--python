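"""Trajectory metrics: phenotype fractions, onset, dimensions, profiles,
grid-convergence errors, acetate turnover and strain correlations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_dynamics import ACE, GLU, CellConstants, volume_fraction
from .rd_solver import AGAR, LatticeState


@dataclass
class MetricSeries:
    """A labelled scalar time series (time in hours)."""

    time: np.ndarray
    value: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.time) != len(self.value):
            raise ValueError("time and value lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class PhenotypeFractions:
    glucose_utilizer: float
    acetate_utilizer: float
    active_consumer: float  # share of acetate-utilizer mass taking up acetate


def phenotype_fractions(state: LatticeState,
                        applied_ace_uptake: np.ndarray | None = None
                        ) -> PhenotypeFractions:
    """Mass fractions per phenotype (NaN sentinel for an empty lattice).

    The active-consumer share is the fraction of acetate-utilizer mass
    whose applied acetate uptake is nonzero at the evaluation step
    (requires ``applied_ace_uptake``; NaN otherwise).
    """
    m_glu = float(state.m[GLU].sum())
    m_ace = float(state.m[ACE].sum())
    total = m_glu + m_ace
    if total <= 0:
        return PhenotypeFractions(np.nan, np.nan, np.nan)
    active = np.nan
    if applied_ace_uptake is not None and m_ace > 0:
        consuming = np.abs(applied_ace_uptake) > 1e-9
        active = float(state.m[ACE][consuming].sum()) / m_ace
    return PhenotypeFractions(m_glu / total, m_ace / total, active)


def onset_time(series: MetricSeries, threshold: float = 0.01) -> float:
    """First crossing time of the threshold, linearly interpolated.

    Returns NaN if the series never reaches the threshold.  Leading NaN
    samples (empty-colony sentinels) are treated as zero.
    """
    v = np.nan_to_num(series.value, nan=0.0)
    t = series.time
    above = v >= threshold
    if not above.any():
        return np.nan
    i = int(np.argmax(above))
    if i == 0 or v[i] == v[i - 1]:
        return float(t[i])
    frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


@dataclass
class ColonyDimensions:
    height: float  # um
    width: float   # um, maximal caliper extent along either lateral axis
    aspect: float  # height / width


def _region_dimensions(mask: np.ndarray, dx: float) -> ColonyDimensions:
    if not mask.any():
        return ColonyDimensions(np.nan, np.nan, np.nan)
    ix, iy, iz = np.nonzero(mask)
    height = (iz.max() - iz.min() + 1) * dx
    width = max(ix.max() - ix.min() + 1, iy.max() - iy.min() + 1) * dx
    return ColonyDimensions(float(height), float(width),
                            float(height / width))


def colony_dimensions(state: LatticeState,
                      consts: CellConstants = CellConstants(),
                      colony_level: float = 0.64,
                      phenotype: int | None = None) -> ColonyDimensions:
    """Extent of the region where the volume fraction exceeds a contour.

    The region is where sum(phi) >= colony_level * phi_max (membership
    by site); with ``phenotype`` given, that phenotype's phi is used
    instead (e.g. the acetate-utilizing feature at contour 0.05).
    Returns NaN dimensions when the region is empty.
    """
    if not 0 < colony_level < 1:
        raise ValueError("contour level must lie in (0, 1)")
    m = state.total_mass() if phenotype is None else state.m[phenotype]
    phi = volume_fraction(m, state.site_volume, consts)
    return _region_dimensions(phi >= colony_level * consts.phi_max,
                              state.dx)


def axis_profile(state: LatticeState, species: str,
                 column: tuple[int, int] | None = None):
    """Concentration along the vertical column through the seed site.

    Returns ``(depth_um, concentration)`` with depth measured from the
    agar surface of that column (negative below the surface).
    """
    if column is None:
        seed = state.meta.get("seed")
        if seed is not None:
            column = (seed[0], seed[1])
        else:
            column = (state.dims[0] // 2, state.dims[1] // 2)
    ix, iy = column
    col_phase = state.phase[ix, iy]
    n_agar = int((col_phase == AGAR).sum())
    z_centers = (np.arange(state.dims[2]) + 0.5) * state.dx
    depth = z_centers - n_agar * state.dx
    return depth, state.C[species][ix, iy].copy()


@dataclass
class ConvergenceReport:
    """Per-resolution deviations from the finest-grid reference."""

    resolutions: list[float]
    errors: dict[float, dict[str, float]] = field(default_factory=dict)
    oscillation: dict[float, bool] = field(default_factory=dict)
    reference: float = np.nan


def _common_mask(t_a: np.ndarray, t_b: np.ndarray, t0: float, t1: float):
    sel_a = (t_a >= t0) & (t_a <= t1)
    common = np.isin(np.round(t_a, 6), np.round(t_b, 6)) & sel_a
    return common


def convergence_error(traj, ref, t0: float = 10.0, t1: float = 30.0,
                      osc_rel_amplitude: float = 0.10,
                      osc_min_changes: int = 3) -> dict:
    """Mean relative deviation of colony volumes from a reference run.

    Averages |v(t) - v_ref(t)| / v_ref(t) over the common sample times
    in [t0, t1] for total, glucose-utilizer and acetate-utilizer
    volumes (samples where the reference is zero are skipped).  The
    oscillation flag is set when the acetate-fraction series shows at
    least ``osc_min_changes`` sign changes of its discrete derivative
    with amplitude above ``osc_rel_amplitude`` of the series mean.
    """
    mask = _common_mask(traj.times, ref.times, t0, t1)
    rmask = _common_mask(ref.times, traj.times, t0, t1)
    if not mask.any():
        raise ValueError("trajectories share no sample times in [t0, t1]")
    out: dict = {}
    for key, name in (("vol_total_fl", "total"), ("vol_glu_fl", "glucose"),
                      ("vol_ace_fl", "acetate")):
        v = traj.series[key][mask]
        vr = ref.series[key][rmask]
        ok = vr > 0
        out[name] = float(np.mean(np.abs(v[ok] - vr[ok]) / vr[ok])) \
            if ok.any() else np.nan
    frac = np.nan_to_num(traj.series["ace_fraction"][mask], nan=0.0)
    d = np.diff(frac)
    scale = np.abs(frac).mean()
    signif = d[np.abs(d) > osc_rel_amplitude * scale] if scale > 0 else \
        np.empty(0)
    changes = int(np.sum(np.sign(signif[1:]) != np.sign(signif[:-1]))) \
        if signif.size > 1 else 0
    out["oscillation"] = changes >= osc_min_changes
    return out


def convergence_report(trajectories: dict[float, "object"],
                       t0: float = 10.0, t1: float = 30.0
                       ) -> ConvergenceReport:
    """Compare runs at several resolutions against the finest one."""
    res = sorted(trajectories)
    ref_dx = res[0]
    ref = trajectories[ref_dx]
    report = ConvergenceReport(resolutions=res, reference=ref_dx)
    for dx in res:
        entry = convergence_error(trajectories[dx], ref, t0, t1)
        report.oscillation[dx] = entry.pop("oscillation")
        report.errors[dx] = entry
    return report


def acetate_turnover(state: LatticeState, applied_ace_uptake: np.ndarray,
                     consts: CellConstants = CellConstants(),
                     normalize_to: float | None = None) -> float:
    """Colony-volume-normalized acetate consumption flux, mM/hr.

    sum_sites m_ace * |v_uptake| / colony volume; with ``normalize_to``
    the result is divided by that reference value (e.g. another
    strain's turnover).  NaN sentinel for an empty colony.
    """
    vol_fl = state.total_mass().sum() / consts.rho
    if vol_fl <= 0:
        return np.nan
    flux = float((state.m[ACE] * np.abs(applied_ace_uptake)).sum()) / vol_fl
    if normalize_to is not None:
        return flux / normalize_to
    return flux


def correlate_characteristics(x, y) -> tuple[float, float]:
    """Pearson r and two-tailed p (t-transform, n-2 dof).

    Returns (NaN, NaN) when either vector has zero variance.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
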