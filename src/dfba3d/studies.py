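"""Desk-scale study presets: the parametric runs behind the headline
comparisons (strain dependence, geometry dependence, grid convergence).

The original parametric studies used 10 um lattices over multi-mm
domains for 40-50 simulated hours.  These presets reproduce the same
protocols on a reduced domain (0.64 x 0.64 x 0.72 mm, 40 um lattice,
44 simulated hours), sized so a single run completes in about a minute
on one CPU core.  All physical constants (diffusivities, thresholds,
kinetics, strain tables) are identical to the full-scale defaults; only
domain, resolution and duration are scaled down.
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .engine import SimConfig, Trajectory, run_simulation
from .geometry import GeometryKind, GeometrySpec

#: Reduced-domain study conditions (mm / um / hr).
SCALED_DOMAIN = (0.64, 0.64, 0.72)
SCALED_AGAR_DEPTH = 0.2
SCALED_DX = 40.0
SCALED_DURATION = 40.0
#: Geometry runs stop shortly after the evaluation time (comparisons
#: are made before late boundary effects dominate).
GEOMETRY_EVAL_HR = 35.0
GEOMETRY_DURATION = 36.0

#: Grid-convergence study conditions.
CONV_DOMAIN = (0.4, 0.4, 0.56)
CONV_AGAR_DEPTH = 0.14
CONV_RESOLUTIONS = (28.0, 42.0, 70.0)
CONV_DURATION = 38.0
CONV_WINDOW = (28.0, 38.0)


def strain_study_config(strain: str, duration: float = SCALED_DURATION
                        ) -> SimConfig:
    """Flat-surface colony of one strain under the scaled conditions."""
    geo = GeometrySpec(kind=GeometryKind.FLAT, domain=SCALED_DOMAIN,
                       agar_depth=SCALED_AGAR_DEPTH)
    return SimConfig(geometry=geo, strain=strain, dx=SCALED_DX,
                     duration=duration, output_interval=0.25)


def geometry_study_config(kind: GeometryKind, strain: str = "MG1655",
                          duration: float = GEOMETRY_DURATION,
                          **geometry_kw) -> SimConfig:
    """MG1655 colony on one of the six substrate shapes."""
    defaults = dict(domain=SCALED_DOMAIN, agar_depth=SCALED_AGAR_DEPTH,
                    h=0.16, w=0.24, o=0.0, radius=1.0,
                    wall_thickness=0.12)
    defaults.update(geometry_kw)
    geo = GeometrySpec(kind=kind, **defaults)
    return SimConfig(geometry=geo, strain=strain, dx=SCALED_DX,
                     duration=duration, output_interval=0.25)


def convergence_config(dx: float, duration: float = CONV_DURATION
                       ) -> SimConfig:
    geo = GeometrySpec(kind=GeometryKind.FLAT, domain=CONV_DOMAIN,
                       agar_depth=CONV_AGAR_DEPTH)
    return SimConfig(geometry=geo, strain="MG1655", dx=dx,
                     duration=duration, output_interval=0.5)


# ---------------------------------------------------------------------------
# Summary metrics computed from the study trajectories
# ---------------------------------------------------------------------------

def _at(traj: Trajectory, key: str, t_hr: float) -> float:
    i = int(np.argmin(np.abs(traj.times - t_hr)))
    return float(traj.series[key][i])


def strain_summary(trajs: dict[str, Trajectory],
                   onset_threshold: float = 0.01) -> dict:
    """Cross-strain metrics of the flat-surface comparison.

    Returns onset times and final acetate-capable fractions per strain,
    their spreads, the mean active-consumer share after onset, the late
    aspect-ratio spread, and acetate turnover relative to MG1655.
    """
    onsets, fracs, shares, aspects, turnovers = {}, {}, {}, {}, {}
    for name, traj in trajs.items():
        s = traj.series
        ms = analysis.MetricSeries(traj.times, s["ace_fraction"])
        onsets[name] = analysis.onset_time(ms, onset_threshold)
        fracs[name] = float(s["ace_fraction"][-1])
        if np.isfinite(onsets[name]):
            post = s["active_consumer_share"][traj.times >= onsets[name]]
            post = post[np.isfinite(post)]
            shares[name] = float(post.mean()) if post.size else np.nan
        else:
            shares[name] = np.nan
        aspects[name] = float(s["height_um"][-1] / s["width_um"][-1])
        turnovers[name] = float(s["ace_turnover_mM_hr"][-1])
    finite = [v for v in onsets.values() if np.isfinite(v)]
    frac_vals = np.array(list(fracs.values()))
    # spread among the strains that actually fractionated: a strain with
    # no onset has fraction 0 and would make the ratio degenerate
    positive = frac_vals[frac_vals > 0]
    ref = turnovers.get("MG1655", np.nan)
    asp = np.array(list(aspects.values()))
    return {
        "onset_hr": onsets,
        "onset_spread_hr": (max(finite) - min(finite)) if len(finite) > 1
        else np.nan,
        "n_onsets_detected": len(finite),
        "ace_fraction": fracs,
        "ace_fraction_ratio": float(positive.max() / positive.min())
        if positive.size else np.nan,
        "active_consumer_share": shares,
        "mean_active_consumer_share": float(np.mean(
            [v for v in shares.values() if np.isfinite(v)]))
        if any(np.isfinite(v) for v in shares.values()) else np.nan,
        "aspect_ratio": aspects,
        "aspect_spread_rel": float((asp.max() - asp.min()) / asp.max()),
        "ace_turnover_rel_mg1655": {k: v / ref for k, v in
                                    turnovers.items()} if ref > 0 else {},
    }


def geometry_summary(flat: Trajectory, wall: Trajectory,
                     concave: Trajectory, convex: Trajectory,
                     t_eval: float = GEOMETRY_EVAL_HR) -> dict:
    """Geometry effects relative to the flat reference colony."""
    v_flat = _at(flat, "vol_total_fl", t_eval)
    f_flat = _at(flat, "ace_fraction", t_eval)
    out = {"eval_hr": t_eval}
    for name, traj in (("wall", wall), ("concave", concave),
                       ("convex", convex)):
        out[f"{name}_growth_rel"] = _at(traj, "vol_total_fl",
                                        t_eval) / v_flat - 1.0
        out[f"{name}_ace_fraction_rel"] = (
            _at(traj, "ace_fraction", t_eval) / f_flat - 1.0) \
            if f_flat > 0 else np.nan
    return out


def convergence_study(trajs: dict[float, Trajectory],
                      window: tuple[float, float] = CONV_WINDOW) -> dict:
    """Relative volume/fraction errors against the finest grid."""
    report = analysis.convergence_report(trajs, t0=window[0], t1=window[1])
    res = report.resolutions
    ref = trajs[res[0]]
    out = {"resolutions_um": res, "reference_um": report.reference,
           "errors": report.errors, "oscillation": report.oscillation}
    # phenotype-fraction deviation of the second-finest grid
    mid = trajs[res[1]]
    mask = (mid.times >= window[0]) & (mid.times <= window[1])
    rmask = (ref.times >= window[0]) & (ref.times <= window[1])
    f_mid = np.nan_to_num(mid.series["ace_fraction"][mask], nan=0.0)
    f_ref = np.nan_to_num(ref.series["ace_fraction"][rmask], nan=0.0)
    n = min(len(f_mid), len(f_ref))
    ok = f_ref[:n] > 0
    out["fraction_error_second_finest"] = float(np.mean(
        np.abs(f_mid[:n][ok] - f_ref[:n][ok]) / f_ref[:n][ok])) \
        if ok.any() else np.nan
    return out


def run_studies(strains=("B21", "Crooks", "MG1655", "W", "W3110"),
                progress: bool = False) -> dict:
    """Run the full scaled-down study battery and summarize it."""
    strain_trajs = {s: run_simulation(strain_study_config(s),
                                      progress=progress)
                    for s in strains}
    flat = strain_trajs.get("MG1655") or run_simulation(
        strain_study_config("MG1655"), progress=progress)
    wall = run_simulation(geometry_study_config(GeometryKind.WALL),
                          progress=progress)
    concave = run_simulation(geometry_study_config(GeometryKind.CONCAVE),
                             progress=progress)
    convex = run_simulation(geometry_study_config(GeometryKind.CONVEX),
                            progress=progress)
    conv = {dx: run_simulation(convergence_config(dx), progress=progress)
            for dx in CONV_RESOLUTIONS}
    return {
        "strain": strain_summary(strain_trajs),
        "geometry": geometry_summary(flat, wall, concave, convex),
        "convergence": convergence_study(conv),
    }
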