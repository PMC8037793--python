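"""Hemodynamic observables and the packing-density sweep driver.

Post-processes solved flow fields into the quantities used to judge
post-coiling aneurysm hemodynamics: wall shear stress (WSS) on the artery
and dome walls, its cycle statistics TAWSS and OSI, area-averaged dome
pressure, the mean velocity through the neck plane, and the residual flow
volume fraction RFV/AV (the share of the dome volume where blood still
moves faster than 0.01 m/s).  The sweep driver repeats the steady solve
over a list of first-coil packing densities and tabulates one summary row
per case; ``characterize_curve`` extracts the qualitative shape features
(steepest-descent interval, monotone tail, asymptotic flattening) used to
compare sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain import Domain, SIDE_OFFSETS, SIDE_YM, SIDE_YP
from .rheology import BloodModel, ergun_coefficients, viscosity
from .solver import ConvergenceError, FlowField, ProjectionSolver

RFV_SPEED_THRESHOLD = 0.01  # m/s


@dataclass(frozen=True)
class HemodynamicSummary:
    vpd_pct: float
    neck_velocity_avg: float
    wss_artery_avg: float
    wss_aneurysm_avg: float
    wss_aneurysm_max: float
    pressure_aneurysm_avg: float
    rfv_mm3: float
    av_mm3: float
    rfv_av_pct: float
    converged: bool = True


@dataclass(frozen=True)
class TransientMetrics:
    tawss_avg: float
    tawss_field: np.ndarray
    osi_avg: float
    osi_field: np.ndarray
    rfv_av_series: np.ndarray  # (time, percent) pairs
    rfv_av_cycle_avg: float


@dataclass(frozen=True)
class CurveDescriptor:
    column: str
    monotone_tail: bool
    tail_direction: str  # 'decreasing' | 'increasing' | 'none'
    steepest_interval: tuple[float, float]
    asymptote_flag: bool
    asymptote_value: Optional[float]
    vpd_of_max: float
    vpd_of_min: float


# --------------------------------------------------------------------- WSS


def _cell_center_u(f: FlowField) -> np.ndarray:
    return 0.5 * (f.u[1:, :] + f.u[:-1, :])


def _cell_center_v(f: FlowField) -> np.ndarray:
    return 0.5 * (f.v[:, 1:] + f.v[:, :-1])


def wall_shear_stress(
    field: FlowField, wall_faces: np.ndarray, domain: Domain, blood: BloodModel
):
    """Signed wall shear stress at each wall face.

    Uses a one-sided second-order gradient of the wall-tangential velocity
    (sample points at h/2 and 3h/2 from the wall, exact for quadratic
    profiles) and evaluates the viscosity at the resulting wall shear
    rate.  Returns ``(tau_vectors (n, 2), tau_magnitudes (n,))``.
    """
    h = domain.h
    active = domain.active_mask
    uc = _cell_center_u(field)
    vc = _cell_center_v(field)
    n = len(wall_faces)
    tau_vec = np.zeros((n, 2))
    tau_mag = np.zeros(n)
    for k, (ci, cj, side) in enumerate(wall_faces):
        if not active[ci, cj]:
            raise ValueError(f"wall face ({ci},{cj}) not adjacent to a flow cell")
        di, dj = SIDE_OFFSETS[int(side)]
        # inward direction, away from the wall
        ii, jj = ci - di, cj - dj
        if side in (SIDE_YM, SIDE_YP):
            tangential = uc
            t_dir = np.array([1.0, 0.0])
        else:
            tangential = vc
            t_dir = np.array([0.0, 1.0])
        u1 = tangential[ci, cj]
        if 0 <= ii < domain.nx and 0 <= jj < domain.ny and active[ii, jj]:
            u2 = tangential[ii, jj]
            grad = (9.0 * u1 - u2) / (3.0 * h)
        else:
            grad = u1 / (0.5 * h)
        eta = viscosity(abs(grad), blood)
        tau = eta * grad
        tau_vec[k] = tau * t_dir
        tau_mag[k] = abs(tau)
    return tau_vec, tau_mag


def tawss(tau_series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Time-averaged WSS magnitude over a cycle (trapezoid rule).

    ``tau_series`` has shape (nt, nfaces) of signed magnitudes or
    (nt, nfaces, 2) of vectors; requires at least 8 samples per cycle.
    """
    tau_series = np.asarray(tau_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if tau_series.shape[0] < 8:
        raise ValueError("need at least 8 samples per cycle for TAWSS")
    if tau_series.ndim == 3:
        mags = np.linalg.norm(tau_series, axis=2)
    else:
        mags = np.abs(tau_series)
    span = times[-1] - times[0]
    return np.trapezoid(mags, times, axis=0) / span


def osi(tau_vec_series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Oscillatory shear index per face.

    OSI = 0.5 (1 - |integral of tau dt| / integral of |tau| dt); 0 for a
    constant WSS direction, 0.5 when the vector time-integral cancels.
    Faces with identically zero WSS over the whole cycle return 0.
    """
    tau = np.asarray(tau_vec_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if tau.shape[0] < 8:
        raise ValueError("need at least 8 samples per cycle for OSI")
    if tau.ndim == 2:  # signed scalars on a fixed tangent
        tau = tau[:, :, None]
    vec_integral = np.trapezoid(tau, times, axis=0)
    mag_integral = np.trapezoid(np.linalg.norm(tau, axis=2), times, axis=0)
    out = np.zeros(tau.shape[1])
    ok = mag_integral > 0
    out[ok] = 0.5 * (1.0 - np.linalg.norm(vec_integral, axis=1)[ok] / mag_integral[ok])
    return np.clip(out, 0.0, 0.5)


# ------------------------------------------------------------------ volumes


def rfv_av(
    field: FlowField,
    dome_mask: np.ndarray,
    cell_volume: float,
    threshold: float = RFV_SPEED_THRESHOLD,
) -> tuple[float, float, float]:
    """Residual flow volume, aneurysm volume, and their percentage ratio.

    RFV counts dome cells whose speed exceeds ``threshold`` (default
    0.01 m/s); AV is the full dome volume.
    """
    if not np.any(dome_mask):
        raise ValueError("dome mask is empty")
    speed = np.sqrt(_cell_center_u(field) ** 2 + _cell_center_v(field) ** 2)
    above = (speed > threshold) & dome_mask
    rfv = float(above.sum()) * cell_volume
    av = float(dome_mask.sum()) * cell_volume
    return rfv, av, 100.0 * rfv / av


def area_average(values, areas=None) -> float:
    """Area-weighted mean of a per-face or per-cell quantity."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty region")
    if areas is None:
        return float(values.mean())
    areas = np.asarray(areas, dtype=float)
    return float(np.sum(values * areas) / np.sum(areas))


def neck_velocity(field: FlowField, domain: Domain) -> float:
    """Area-averaged speed on the neck plane (the dome/lumen interface).

    Both the through-plane and the in-plane component contribute: the neck
    of a side-wall sac carries a strong sweeping component parallel to the
    parent-vessel axis.
    """
    if domain.neck_face_i.size == 0:
        raise ValueError("domain has no neck plane")
    j = domain.ny_channel
    idx = domain.neck_face_i
    vn = field.v[idx, j]
    # tangential u interpolated to the v-face positions (mean of the 4
    # surrounding u faces)
    ut = 0.25 * (
        field.u[idx, j - 1] + field.u[idx + 1, j - 1] + field.u[idx, j] + field.u[idx + 1, j]
    )
    return float(np.mean(np.sqrt(vn**2 + ut**2)))


def dome_wall_pressure(field: FlowField, domain: Domain) -> float:
    """Mean pressure over dome cells adjacent to the dome wall."""
    faces = domain.wall_faces_dome
    if len(faces) == 0:
        raise ValueError("domain has no dome wall")
    vals = [field.p[ci, cj] for ci, cj, _ in faces]
    return float(np.mean(vals))


# ------------------------------------------------------------------ summary


def summarize(
    field: FlowField,
    domain: Domain,
    blood: BloodModel,
    vpd_pct: float,
    threshold: float = RFV_SPEED_THRESHOLD,
    converged: bool = True,
) -> HemodynamicSummary:
    _, tau_art = wall_shear_stress(field, domain.wall_faces_artery, domain, blood)
    _, tau_dome = wall_shear_stress(field, domain.wall_faces_dome, domain, blood)
    rfv, av, ratio = rfv_av(field, domain.porous_mask, domain.cell_volume(), threshold)
    return HemodynamicSummary(
        vpd_pct=vpd_pct,
        neck_velocity_avg=neck_velocity(field, domain),
        wss_artery_avg=area_average(tau_art),
        wss_aneurysm_avg=area_average(tau_dome),
        wss_aneurysm_max=float(tau_dome.max()) if tau_dome.size else 0.0,
        pressure_aneurysm_avg=dome_wall_pressure(field, domain),
        rfv_mm3=rfv * 1e9,
        av_mm3=av * 1e9,
        rfv_av_pct=ratio,
        converged=converged,
    )


SWEEP_COLUMNS = [
    "vpd_pct",
    "neck_velocity",
    "wss_artery",
    "wss_aneurysm",
    "pressure_aneurysm",
    "rfv_av_pct",
]


def sweep_to_frame(rows: Sequence[HemodynamicSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vpd_pct": [r.vpd_pct for r in rows],
            "neck_velocity": [r.neck_velocity_avg for r in rows],
            "wss_artery": [r.wss_artery_avg for r in rows],
            "wss_aneurysm": [r.wss_aneurysm_avg for r in rows],
            "pressure_aneurysm": [r.pressure_aneurysm_avg for r in rows],
            "rfv_av_pct": [r.rfv_av_pct for r in rows],
            "converged": [r.converged for r in rows],
        }
    )


def vpd_sweep(
    domain: Domain,
    blood: BloodModel,
    vpd_values: Sequence[float],
    inflow_velocity: float,
    tol: float = 1e-6,
    max_iter: int = 10000,
    threshold: float = RFV_SPEED_THRESHOLD,
    warm_start: bool = True,
) -> tuple[pd.DataFrame, list[HemodynamicSummary], list[FlowField]]:
    """Steady VPD sweep: one converged summary per packing density.

    Cases are warm-started from the previous converged field.  A case that
    exhausts its iteration budget is flagged (``converged=False``) and the
    sweep continues.
    """
    vpd_values = list(vpd_values)
    if any(b <= a for a, b in zip(vpd_values, vpd_values[1:])):
        raise ValueError("vpd_values must be strictly increasing")
    if vpd_values and not (0.0 <= vpd_values[0] and vpd_values[-1] <= 30.0):
        raise ValueError("vpd_values must lie within [0, 30]")
    rows: list[HemodynamicSummary] = []
    fields: list[FlowField] = []
    prev = None
    for vpd in vpd_values:
        porous = ergun_coefficients(vpd, blood)
        solver = ProjectionSolver(domain, blood, porous)
        converged = True
        try:
            f = solver.solve_steady(
                inflow_velocity, tol=tol, max_iter=max_iter,
                init=prev if warm_start else None,
            )
        except ConvergenceError as err:
            converged = False
            f = getattr(err, "last_field", None)
            if f is None:
                raise
        rows.append(summarize(f, domain, blood, vpd, threshold, converged=converged))
        fields.append(f)
        prev = f
    return sweep_to_frame(rows), rows, fields


# -------------------------------------------------------------- curve shape


def characterize_curve(
    table: pd.DataFrame,
    column: str,
    tail_start: float = 10.0,
    slope_floor_rel: float = 0.05,
) -> CurveDescriptor:
    """Finite-difference shape analysis of a sweep column vs VPD.

    Reports the VPD interval of steepest descent/ascent (max |slope|),
    whether the column is monotone beyond ``tail_start`` % VPD, whether
    the curve has flattened into an asymptote, and the VPD locations of
    the global extrema.  The asymptote flag is raised when the last three
    slope magnitudes shrink monotonically, or when they have all dropped
    below ``slope_floor_rel`` times the curve's peak slope (a curve whose
    increments have collapsed to numerical noise has flattened even if
    the noise is not itself monotone).
    """
    if len(table) < 5:
        raise ValueError("need at least 5 sweep rows to characterize a curve")
    vpd = table["vpd_pct"].to_numpy(dtype=float)
    y = table[column].to_numpy(dtype=float)
    slopes = np.diff(y) / np.diff(vpd)
    k = int(np.argmax(np.abs(slopes)))
    steepest = (float(vpd[k]), float(vpd[k + 1]))

    tail = vpd >= tail_start
    tail_y = y[tail]
    if tail_y.size >= 2:
        d = np.diff(tail_y)
        if np.all(d <= 0):
            monotone, direction = True, "decreasing"
        elif np.all(d >= 0):
            monotone, direction = True, "increasing"
        else:
            monotone, direction = False, "none"
    else:
        monotone, direction = False, "none"

    mags = np.abs(slopes)
    if mags.size >= 3:
        last3 = mags[-3:]
        floor = slope_floor_rel * mags.max()
        shrinking = bool(last3[1] < last3[0] and last3[2] < last3[1])
        collapsed = bool(np.all(last3 <= floor))
        asymptote = shrinking or collapsed
    else:
        asymptote = False
    return CurveDescriptor(
        column=column,
        monotone_tail=monotone,
        tail_direction=direction,
        steepest_interval=steepest,
        asymptote_flag=asymptote,
        asymptote_value=float(y[-1]) if asymptote else None,
        vpd_of_max=float(vpd[int(np.argmax(y))]),
        vpd_of_min=float(vpd[int(np.argmin(y))]),
    )


# --------------------------------------------------------- transient driver


def transient_metrics(
    result,
    domain: Domain,
    blood: BloodModel,
    region: str = "dome",
    threshold: float = RFV_SPEED_THRESHOLD,
) -> TransientMetrics:
    """TAWSS, OSI and the RFV/AV time series over the sampled final cycle."""
    faces = domain.wall_faces_dome if region == "dome" else domain.wall_faces_artery
    times = result.sample_times
    tau_vecs = []
    ratios = []
    for f in result.fields:
        tv, _ = wall_shear_stress(f, faces, domain, blood)
        tau_vecs.append(tv)
        if domain.porous_mask.any():
            _, _, r = rfv_av(f, domain.porous_mask, domain.cell_volume(), threshold)
        else:
            r = np.nan
        ratios.append(r)
    tau_vecs = np.array(tau_vecs)  # (nt, nfaces, 2)
    tawss_field = tawss(tau_vecs, times)
    osi_field = osi(tau_vecs, times)
    series = np.column_stack([times, ratios])
    span = times[-1] - times[0]
    cycle_avg = float(np.trapezoid(ratios, times) / span) if span > 0 else float(ratios[0])
    return TransientMetrics(
        tawss_avg=float(tawss_field.mean()),
        tawss_field=tawss_field,
        osi_avg=float(osi_field.mean()),
        osi_field=osi_field,
        rfv_av_series=series,
        rfv_av_cycle_avg=cycle_avg,
    )
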