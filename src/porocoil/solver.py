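"""Incompressible Navier–Stokes solver with a porous coiled-dome sink.

Staggered-grid (MAC) finite-volume discretization with Chorin-type
pressure projection.  Momentum uses explicit first-order upwind advection,
backward-Euler diffusion with the shear-thinning viscosity field, and an
implicit Darcy–Forchheimer sink in porous (dome) cells; continuity is
enforced to solver precision by the pressure Poisson projection.  Steady
states are reached by pseudo-time marching; pulsatile flow by time-accurate
marching over several cardiac cycles with the early cycles discarded.

The viscosity nonlinearity is resolved by Picard iteration with
under-relaxation; the momentum matrices are refactorized on a lag so each
pseudo-time step costs three triangular solves.

Walls are rigid and no-slip (mirror ghosts for tangential velocity), the
inlet carries a prescribed parabolic profile, and the outlet is a
mass-corrected zero-gradient boundary with the pressure gauge pinned near
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from .domain import Domain
from .rheology import BloodModel, PorousParams, viscosity


@dataclass
class FlowField:
    """MAC-grid flow state: u on x-faces, v on y-faces, p and viscosity at
    cell centers."""

    u: np.ndarray  # (nx+1, ny)
    v: np.ndarray  # (nx, ny+1)
    p: np.ndarray  # (nx, ny)
    mu: np.ndarray  # (nx, ny)
    time: float = 0.0

    def copy(self) -> "FlowField":
        return FlowField(self.u.copy(), self.v.copy(), self.p.copy(), self.mu.copy(), self.time)


@dataclass(frozen=True)
class InflowWaveform:
    """Periodic mean-inflow waveform as (time-fraction, velocity) samples.

    The first and last samples must agree (periodicity); velocities are
    mean-over-cross-section values in m/s and must be non-negative.
    """

    period: float
    samples: tuple[tuple[float, float], ...]
    n_cycles: int = 5

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        fr = np.array([s[0] for s in self.samples])
        vel = np.array([s[1] for s in self.samples])
        if len(self.samples) < 2 or fr[0] != 0.0 or fr[-1] != 1.0:
            raise ValueError("samples must span time fractions 0..1")
        if abs(vel[0] - vel[-1]) > 1e-12 * max(1.0, abs(vel[0])):
            raise ValueError("waveform must be periodic: first and last samples differ")
        if np.any(vel < 0):
            raise ValueError("waveform velocities must be non-negative")
        if np.any(np.diff(fr) <= 0):
            raise ValueError("sample time fractions must be strictly increasing")

    @property
    def mean_velocity(self) -> float:
        fr = np.array([s[0] for s in self.samples])
        vel = np.array([s[1] for s in self.samples])
        return float(np.trapezoid(vel, fr))

    @property
    def peak_velocity(self) -> float:
        return float(max(s[1] for s in self.samples))

    def velocity_at(self, t: float) -> float:
        frac = (t / self.period) % 1.0
        fr = np.array([s[0] for s in self.samples])
        vel = np.array([s[1] for s in self.samples])
        return float(np.interp(frac, fr, vel))


def default_waveform(
    mean_velocity: float,
    period: float = 0.8,
    t_peak_fraction: float = 0.22,
    peak_to_mean: float = 2.0,
    n_cycles: int = 5,
    n_samples: int = 64,
) -> InflowWaveform:
    """Two-harmonic pulsatile waveform with unit-mean shape.

    f(t) = 1 + a1 cos(w(t - tp)) + a2 cos(2w(t - tp)) with a1 = 3 a2 and
    a1 + a2 = peak_to_mean - 1, which keeps the waveform non-negative for
    peak-to-mean ratios up to about 2.3 and peaks early in the cycle the
    way a systolic inflow does.
    """
    amp = peak_to_mean - 1.0
    a1, a2 = 0.75 * amp, 0.25 * amp
    fr = np.linspace(0.0, 1.0, n_samples + 1)
    shape = 1.0 + a1 * np.cos(2 * np.pi * (fr - t_peak_fraction)) + a2 * np.cos(
        4 * np.pi * (fr - t_peak_fraction)
    )
    vel = mean_velocity * shape
    vel[-1] = vel[0]
    return InflowWaveform(
        period=period,
        samples=tuple(zip(fr.tolist(), vel.tolist())),
        n_cycles=n_cycles,
    )


def steady_waveform(mean_velocity: float, period: float = 0.8, n_cycles: int = 5) -> InflowWaveform:
    return InflowWaveform(
        period=period,
        samples=((0.0, mean_velocity), (1.0, mean_velocity)),
        n_cycles=n_cycles,
    )


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual_history=None, last_field=None):
        super().__init__(message)
        self.residual_history = residual_history or []
        self.last_field = last_field


@dataclass
class TransientResult:
    """Fields sampled over the final cycle plus periodicity diagnostics."""

    fields: list  # list[FlowField]
    sample_times: np.ndarray
    cycle_periodicity_rel: float
    dome_mean_speed_series: np.ndarray


class ProjectionSolver:
    """Pressure-projection solver bound to one domain + fluid model."""

    def __init__(
        self,
        domain: Domain,
        blood: BloodModel,
        porous: PorousParams,
        refactor_every: int = 20,
        picard_relax: float = 0.7,
    ):
        self.domain = domain
        self.blood = blood
        self.porous = porous
        self.refactor_every = refactor_every
        self.picard_relax = picard_relax
        self._setup_masks()
        self._setup_poisson()

    # ------------------------------------------------------------------ setup

    def _setup_masks(self) -> None:
        d = self.domain
        nx, ny = d.nx, d.ny
        active = d.active_mask
        self.active = active

        act_u = np.zeros((nx + 1, ny), dtype=bool)
        act_u[1:nx, :] = active[: nx - 1, :] & active[1:, :]
        self.act_u = act_u
        self.inlet_rows = d.inlet_rows
        self.outlet_rows = np.flatnonzero(active[nx - 1, :])

        act_v = np.zeros((nx, ny + 1), dtype=bool)
        act_v[:, 1:ny] = active[:, : ny - 1] & active[:, 1:]
        self.act_v = act_v

        self.uidx = -np.ones((nx + 1, ny), dtype=int)
        self.uidx[act_u] = np.arange(int(act_u.sum()))
        self.vidx = -np.ones((nx, ny + 1), dtype=int)
        self.vidx[act_v] = np.arange(int(act_v.sum()))
        self.pidx = -np.ones((nx, ny), dtype=int)
        self.pidx[active] = np.arange(int(active.sum()))

        # porous weight on faces: mean of adjacent-cell porous flags
        por = d.porous_mask.astype(float)
        self.por_u = np.zeros((nx + 1, ny))
        self.por_u[1:nx, :] = 0.5 * (por[: nx - 1, :] + por[1:, :])
        self.por_v = np.zeros((nx, ny + 1))
        self.por_v[:, 1:ny] = 0.5 * (por[:, : ny - 1] + por[:, 1:])

        # inlet parabolic shape, normalized so the discrete mean equals 1
        Hc = d.ny_channel * d.h
        yj = (self.inlet_rows + 0.5) * d.h
        shape = 6.0 * (yj / Hc) * (1.0 - yj / Hc)
        shape /= shape.mean()
        self.inlet_shape = shape

    def _setup_poisson(self) -> None:
        d = self.domain
        nx, ny = d.nx, d.ny
        h2 = d.h * d.h
        rows, cols, vals = [], [], []
        n_p = int(self.active.sum())
        pin = (nx - 1, int(self.outlet_rows[len(self.outlet_rows) // 2]))
        self.pin_cell = pin
        for i in range(nx):
            for j in range(ny):
                k = self.pidx[i, j]
                if k < 0:
                    continue
                if (i, j) == pin:
                    rows.append(k)
                    cols.append(k)
                    vals.append(1.0)
                    continue
                diag = 0.0
                for di, dj, facearr in (
                    (-1, 0, self.act_u[i, j]),
                    (1, 0, self.act_u[i + 1, j]),
                    (0, -1, self.act_v[i, j]),
                    (0, 1, self.act_v[i, j + 1]),
                ):
                    if not facearr:
                        continue  # closed or boundary face: Neumann
                    knb = self.pidx[i + di, j + dj]
                    diag += 1.0 / h2
                    rows.append(k)
                    cols.append(knb)
                    vals.append(-1.0 / h2)
                rows.append(k)
                cols.append(k)
                vals.append(diag if diag > 0 else 1.0)
        A = csr_matrix((vals, (rows, cols)), shape=(n_p, n_p))
        self._poisson_lu = splu(A.tocsc())

    # ------------------------------------------------------- viscosity / sink

    def shear_rate(self, f: FlowField) -> np.ndarray:
        """Cell-centered shear-rate magnitude sqrt(2 D:D)."""
        d = self.domain
        h = d.h
        ux = (f.u[1:, :] - f.u[:-1, :]) / h
        vy = (f.v[:, 1:] - f.v[:, :-1]) / h
        uc = 0.5 * (f.u[1:, :] + f.u[:-1, :])
        vc = 0.5 * (f.v[:, 1:] + f.v[:, :-1])
        uc = np.where(self.active, uc, 0.0)
        vc = np.where(self.active, vc, 0.0)
        uy = np.gradient(uc, h, axis=1)
        vx = np.gradient(vc, h, axis=0)
        return np.sqrt(2.0 * ux**2 + 2.0 * vy**2 + (uy + vx) ** 2)

    def update_viscosity(self, f: FlowField) -> None:
        target = viscosity(self.shear_rate(f), self.blood)
        w = self.picard_relax
        f.mu = w * target + (1.0 - w) * f.mu

    def _sink_coeff_u(self, f: FlowField) -> np.ndarray:
        """K = beta + alpha |U| on u-faces, weighted by porous fraction."""
        speed = self._face_speed_u(f)
        return self.por_u * (self.porous.beta + self.porous.alpha * speed)

    def _sink_coeff_v(self, f: FlowField) -> np.ndarray:
        speed = self._face_speed_v(f)
        return self.por_v * (self.porous.beta + self.porous.alpha * speed)

    def _face_speed_u(self, f: FlowField) -> np.ndarray:
        nx, ny = self.domain.nx, self.domain.ny
        s = np.zeros((nx + 1, ny))
        vbar = np.zeros((nx + 1, ny))
        vbar[1:nx, :] = 0.25 * (
            f.v[: nx - 1, :-1] + f.v[: nx - 1, 1:] + f.v[1:, :-1] + f.v[1:, 1:]
        )
        s = np.sqrt(f.u**2 + vbar**2)
        return s

    def _face_speed_v(self, f: FlowField) -> np.ndarray:
        nx, ny = self.domain.nx, self.domain.ny
        ubar = np.zeros((nx, ny + 1))
        ubar[:, 1:ny] = 0.25 * (
            f.u[:-1, : ny - 1] + f.u[:-1, 1:ny] + f.u[1:, : ny - 1] + f.u[1:, 1:ny]
        )
        return np.sqrt(f.v**2 + ubar**2)

    # ------------------------------------------------------------- assembly

    def _assemble_momentum(self, f: FlowField, dt: float):
        """Backward-Euler diffusion + implicit sink matrices for u and v."""
        d = self.domain
        nx, ny = d.nx, d.ny
        h2 = d.h * d.h
        rho = self.blood.density_rho
        c = dt / (rho * h2)

        mu_c = f.mu
        # corner viscosity: masked mean of the 4 surrounding cells
        act = self.active.astype(float)
        mu_cor = np.zeros((nx + 1, ny + 1))
        wsum = np.zeros((nx + 1, ny + 1))
        for di in (0, 1):
            for dj in (0, 1):
                mu_cor[di : nx + di, dj : ny + dj] += mu_c * act
                wsum[di : nx + di, dj : ny + dj] += act
        mu_cor = mu_cor / np.maximum(wsum, 1.0)
        mu_cor[wsum == 0] = self.blood.eta_low_plateau

        Ku = self._sink_coeff_u(f)
        Kv = self._sink_coeff_v(f)

        solid = ~self.active

        # ---- u system
        rows, cols, vals = [], [], []
        n_u = int(self.act_u.sum())
        diag = np.zeros(n_u)
        self._u_bc = []  # (row, coeff) pairs for Dirichlet rhs contributions

        ii, jj = np.nonzero(self.act_u)
        for i, j in zip(ii, jj):
            k = self.uidx[i, j]
            dval = 1.0 + dt * Ku[i, j] / rho
            # east neighbour u(i+1, j), coefficient mu at cell (i, j)
            ce = c * mu_c[i, j]
            if i + 1 <= nx - 1 and self.act_u[i + 1, j]:
                rows.append(k); cols.append(self.uidx[i + 1, j]); vals.append(-ce)
            else:
                self._u_bc.append((k, i + 1, j, ce))
            dval += ce
            # west neighbour u(i-1, j), mu at cell (i-1, j)
            cw = c * mu_c[i - 1, j]
            if i - 1 >= 1 and self.act_u[i - 1, j]:
                rows.append(k); cols.append(self.uidx[i - 1, j]); vals.append(-cw)
            else:
                self._u_bc.append((k, i - 1, j, cw))
            dval += cw
            # north neighbour u(i, j+1), mu at corner (i, j+1)
            cn = c * mu_cor[i, j + 1]
            wall_n = j + 1 >= ny or (solid[i - 1, j + 1] and solid[i, j + 1])
            south_ok = j - 1 >= 0 and self.act_u[i, j - 1]
            if wall_n:
                # quadratic wall ghost (exact for parabolic profiles):
                # ghost = (u_opp - 6 u)/3, coupling the opposite neighbour
                if south_ok:
                    dval += 3.0 * cn
                    rows.append(k); cols.append(self.uidx[i, j - 1]); vals.append(-cn / 3.0)
                else:
                    dval += 2.0 * cn  # mirror fallback
            elif self.act_u[i, j + 1]:
                rows.append(k); cols.append(self.uidx[i, j + 1]); vals.append(-cn)
                dval += cn
            else:
                dval += cn  # staircase corner, Dirichlet 0
            # south neighbour u(i, j-1), mu at corner (i, j)
            cs = c * mu_cor[i, j]
            wall_s = j - 1 < 0 or (solid[i - 1, j - 1] and solid[i, j - 1])
            north_ok = j + 1 < ny and self.act_u[i, j + 1]
            if wall_s:
                if north_ok:
                    dval += 3.0 * cs
                    rows.append(k); cols.append(self.uidx[i, j + 1]); vals.append(-cs / 3.0)
                else:
                    dval += 2.0 * cs
            elif self.act_u[i, j - 1]:
                rows.append(k); cols.append(self.uidx[i, j - 1]); vals.append(-cs)
                dval += cs
            else:
                dval += cs
            diag[k] = dval
        rows.extend(range(n_u)); cols.extend(range(n_u)); vals.extend(diag.tolist())
        Au = csr_matrix((vals, (rows, cols)), shape=(n_u, n_u))
        self._lu_u = splu(Au.tocsc())

        # ---- v system
        rows, cols, vals = [], [], []
        n_v = int(self.act_v.sum())
        diag = np.zeros(n_v)
        self._v_bc = []

        ii, jj = np.nonzero(self.act_v)
        for i, j in zip(ii, jj):
            k = self.vidx[i, j]
            dval = 1.0 + dt * Kv[i, j] / rho
            # north neighbour v(i, j+1), mu at cell (i, j)
            cn = c * mu_c[i, j]
            if j + 1 <= ny - 1 and self.act_v[i, j + 1]:
                rows.append(k); cols.append(self.vidx[i, j + 1]); vals.append(-cn)
            dval += cn
            # south neighbour v(i, j-1), mu at cell (i, j-1)
            cs = c * mu_c[i, j - 1]
            if j - 1 >= 1 and self.act_v[i, j - 1]:
                rows.append(k); cols.append(self.vidx[i, j - 1]); vals.append(-cs)
            dval += cs
            # east neighbour v(i+1, j), mu at corner (i+1, j)
            ce = c * mu_cor[i + 1, j]
            wall_e = i + 1 < nx and solid[i + 1, j - 1] and solid[i + 1, j]
            west_ok = i - 1 >= 0 and self.act_v[i - 1, j]
            if i + 1 >= nx:
                if j - 1 < self.domain.ny_channel:
                    pass  # outlet: zero-gradient ghost, no diffusive flux
                else:
                    dval += 2.0 * ce
            elif wall_e:
                if west_ok:
                    dval += 3.0 * ce  # quadratic wall ghost
                    rows.append(k); cols.append(self.vidx[i - 1, j]); vals.append(-ce / 3.0)
                else:
                    dval += 2.0 * ce
            elif self.act_v[i + 1, j]:
                rows.append(k); cols.append(self.vidx[i + 1, j]); vals.append(-ce)
                dval += ce
            else:
                dval += ce
            # west neighbour v(i-1, j), mu at corner (i, j)
            cw = c * mu_cor[i, j]
            wall_w = i - 1 >= 0 and solid[i - 1, j - 1] and solid[i - 1, j]
            east_ok = i + 1 < nx and self.act_v[i + 1, j]
            if i - 1 < 0:
                dval += 2.0 * cw  # inlet plane: v = 0 there
            elif wall_w:
                if east_ok:
                    dval += 3.0 * cw
                    rows.append(k); cols.append(self.vidx[i + 1, j]); vals.append(-cw / 3.0)
                else:
                    dval += 2.0 * cw
            elif self.act_v[i - 1, j]:
                rows.append(k); cols.append(self.vidx[i - 1, j]); vals.append(-cw)
                dval += cw
            else:
                dval += cw
            diag[k] = dval
        rows.extend(range(n_v)); cols.extend(range(n_v)); vals.extend(diag.tolist())
        Av = csr_matrix((vals, (rows, cols)), shape=(n_v, n_v))
        self._lu_v = splu(Av.tocsc())
        self._dt_assembled = dt

    # ------------------------------------------------------------- advection

    def _advection(self, f: FlowField):
        """First-order upwind advective terms on u- and v-faces."""
        d = self.domain
        nx, ny, h = d.nx, d.ny, d.h
        solid = ~self.active
        u, v = f.u, f.v

        # neighbours of u faces in x (full arrays carry Dirichlet/0 values)
        ue = np.zeros_like(u); uw = np.zeros_like(u)
        ue[:-1, :] = u[1:, :]
        ue[-1, :] = u[-1, :]  # beyond outlet: zero gradient
        uw[1:, :] = u[:-1, :]
        uw[0, :] = u[0, :]
        # neighbours in y with wall mirrors
        un = np.empty_like(u); us = np.empty_like(u)
        un[:, :-1] = u[:, 1:]
        un[:, -1] = -u[:, -1]
        us[:, 1:] = u[:, :-1]
        us[:, 0] = -u[:, 0]
        wall_n = np.zeros_like(u, dtype=bool)
        wall_s = np.zeros_like(u, dtype=bool)
        wall_n[1:nx, :-1] = solid[: nx - 1, 1:] & solid[1:, 1:]
        wall_s[1:nx, 1:] = solid[: nx - 1, :-1] & solid[1:, :-1]
        un = np.where(wall_n, -u, un)
        us = np.where(wall_s, -u, us)

        vbar = np.zeros_like(u)
        vbar[1:nx, :] = 0.25 * (
            v[: nx - 1, :-1] + v[: nx - 1, 1:] + v[1:, :-1] + v[1:, 1:]
        )
        dudx = np.where(u > 0, (u - uw), (ue - u)) / h
        dudy = np.where(vbar > 0, (u - us), (un - u)) / h
        adv_u = u * dudx + vbar * dudy

        # v faces
        vn = np.empty_like(v); vs = np.empty_like(v)
        vn[:, :-1] = v[:, 1:]
        vn[:, -1] = 0.0
        vs[:, 1:] = v[:, :-1]
        vs[:, 0] = 0.0
        vee = np.empty_like(v); vww = np.empty_like(v)
        vee[:-1, :] = v[1:, :]
        vee[-1, :] = v[-1, :]  # outlet zero gradient
        vww[1:, :] = v[:-1, :]
        vww[0, :] = -v[0, :]  # inlet plane: v = 0
        wall_e = np.zeros_like(v, dtype=bool)
        wall_w = np.zeros_like(v, dtype=bool)
        wall_e[:-1, 1:ny] = solid[1:, : ny - 1] & solid[1:, 1:]
        wall_w[1:, 1:ny] = solid[:-1, : ny - 1] & solid[:-1, 1:]
        vee = np.where(wall_e, -v, vee)
        vww = np.where(wall_w, -v, vww)

        ubar = np.zeros_like(v)
        ubar[:, 1:ny] = 0.25 * (
            u[:-1, : ny - 1] + u[:-1, 1:ny] + u[1:, : ny - 1] + u[1:, 1:ny]
        )
        dvdy = np.where(v > 0, (v - vs), (vn - v)) / h
        dvdx = np.where(ubar > 0, (v - vww), (vee - v)) / h
        adv_v = ubar * dvdx + v * dvdy
        return adv_u, adv_v

    # ----------------------------------------------------------------- step

    def _apply_inlet(self, f: FlowField, mean_velocity: float) -> None:
        f.u[0, :] = 0.0
        f.u[0, self.inlet_rows] = mean_velocity * self.inlet_shape

    def _apply_outlet(self, f: FlowField) -> None:
        """Zero-gradient outlet with exact global mass correction."""
        f.u[-1, :] = 0.0
        vals = f.u[-2, self.outlet_rows].copy()
        inflow = float(f.u[0, self.inlet_rows].sum())
        out = float(vals.sum())
        if out > 1e-14 and inflow > 1e-14:
            f.u[-1, self.outlet_rows] = vals * (inflow / out)
        elif inflow > 1e-14:
            f.u[-1, self.outlet_rows] = inflow / len(self.outlet_rows)
        else:
            f.u[-1, self.outlet_rows] = 0.0

    def divergence(self, f: FlowField) -> np.ndarray:
        d = self.domain
        div = (f.u[1:, :] - f.u[:-1, :] + f.v[:, 1:] - f.v[:, :-1]) / d.h
        return np.where(self.active, div, 0.0)

    def step(self, f: FlowField, dt: float, mean_inflow: float) -> FlowField:
        rho = self.blood.density_rho
        adv_u, adv_v = self._advection(f)

        g = f.copy()
        self._apply_inlet(g, mean_inflow)
        self._apply_outlet(g)

        nx, ny = self.domain.nx, self.domain.ny
        h = self.domain.h

        # predictor: implicit diffusion + sink, explicit advection, and the
        # lagged pressure gradient (incremental pressure-correction form,
        # needed so the converged pressure balances a stiff porous sink)
        gpx = np.zeros_like(f.u)
        gpx[1:nx, :] = (f.p[1:, :] - f.p[:-1, :]) / h
        gpy = np.zeros_like(f.v)
        gpy[:, 1:ny] = (f.p[:, 1:] - f.p[:, :-1]) / h

        rhs_u = (f.u - dt * adv_u - (dt / rho) * gpx)[self.act_u]
        for k, bi, bj, coeff in self._u_bc:
            rhs_u[k] += coeff * g.u[bi, bj]
        ustar = self._lu_u.solve(rhs_u)
        g.u[self.act_u] = ustar

        rhs_v = (f.v - dt * adv_v - (dt / rho) * gpy)[self.act_v]
        vstar = self._lu_v.solve(rhs_v)
        g.v[self.act_v] = vstar

        self._apply_outlet(g)

        # projection on the pressure increment phi = p^{n+1} - p^n
        div = self.divergence(g)
        # matrix is assembled as -laplacian (positive definite), so the
        # projection equation -lap(phi) = -(rho/dt) div u* flips the sign
        rhs_p = -(rho / dt) * div[self.active]
        rhs_p[self.pidx[self.pin_cell]] = 0.0
        phi_flat = self._poisson_lu.solve(rhs_p)
        phi = np.zeros_like(g.p)
        phi[self.active] = phi_flat

        gfx = np.zeros_like(g.u)
        gfx[1:nx, :] = (phi[1:, :] - phi[:-1, :]) / h
        g.u[self.act_u] -= (dt / rho) * gfx[self.act_u]
        gfy = np.zeros_like(g.v)
        gfy[:, 1:ny] = (phi[:, 1:] - phi[:, :-1]) / h
        g.v[self.act_v] -= (dt / rho) * gfy[self.act_v]

        self._apply_outlet(g)
        g.p = f.p + phi
        g.time = f.time + dt
        if not np.all(np.isfinite(g.u)) or not np.all(np.isfinite(g.v)):
            raise ConvergenceError("solver produced non-finite velocities (NaN field)")
        return g

    # ------------------------------------------------------------- drivers

    def initial_field(self) -> FlowField:
        d = self.domain
        f = FlowField(
            u=np.zeros((d.nx + 1, d.ny)),
            v=np.zeros((d.nx, d.ny + 1)),
            p=np.zeros((d.nx, d.ny)),
            mu=np.full((d.nx, d.ny), self.blood.eta_low_plateau),
        )
        return f

    def _suggest_dt(self, f: FlowField, u_ref: float, cfl: float = 0.35) -> float:
        umax = max(float(np.max(np.abs(f.u))), float(np.max(np.abs(f.v))), 1.5 * u_ref, 1e-9)
        return cfl * self.domain.h / umax

    def solve_steady(
        self,
        inflow_velocity: float,
        tol: float = 1e-6,
        max_iter: int = 10000,
        init: Optional[FlowField] = None,
        freeze_viscosity: bool = False,
    ) -> FlowField:
        """March in pseudo-time to a steady state.

        Convergence is declared when the largest per-step velocity change,
        relative to the mean inflow velocity, drops below ``tol``.
        Raises :class:`ConvergenceError` with the residual history if the
        iteration budget is exhausted.
        """
        if inflow_velocity < 0:
            raise ValueError("inflow_velocity must be non-negative")
        f = init.copy() if init is not None else self.initial_field()
        if inflow_velocity == 0.0:
            return f
        u_ref = inflow_velocity
        dt = self._suggest_dt(f, u_ref)
        self._apply_inlet(f, inflow_velocity)
        self._apply_outlet(f)
        if not freeze_viscosity:
            self.update_viscosity(f)
        self._assemble_momentum(f, dt)
        history = []
        for it in range(max_iter):
            if it % self.refactor_every == 0 and it > 0:
                dt_new = self._suggest_dt(f, u_ref)
                if not freeze_viscosity:
                    self.update_viscosity(f)
                if dt_new < 0.8 * dt:
                    dt = dt_new
                self._assemble_momentum(f, dt)
            g = self.step(f, dt, inflow_velocity)
            res = max(
                float(np.max(np.abs(g.u - f.u))), float(np.max(np.abs(g.v - f.v)))
            ) / u_ref
            history.append(res)
            f = g
            if res < tol:
                return f
        raise ConvergenceError(
            f"steady solve did not reach tol={tol} in {max_iter} iterations "
            f"(last residual {history[-1]:.3e})",
            residual_history=history,
            last_field=f,
        )

    def solve_transient(
        self,
        waveform: InflowWaveform,
        dt: Optional[float] = None,
        samples_per_cycle: int = 32,
        init: Optional[FlowField] = None,
    ) -> TransientResult:
        """Time-accurate pulsatile run; returns final-cycle field samples.

        Earlier cycles are discarded as start-up transient.  The advective
        CFL at the peak inflow (parabolic peak = 1.5 x mean) must stay
        below 0.5, otherwise the requested dt is rejected with a
        suggestion.
        """
        u_peak = 1.5 * waveform.peak_velocity
        dt_cfl = 0.5 * self.domain.h / max(u_peak, 1e-9)
        if dt is None:
            dt = 0.6 * dt_cfl
        if dt > dt_cfl:
            raise ValueError(
                f"dt={dt:.3e} violates the advective CFL limit for the peak inflow; "
                f"use dt <= {dt_cfl:.3e}"
            )
        n_per_cycle = max(int(np.ceil(waveform.period / dt)), samples_per_cycle)
        dt = waveform.period / n_per_cycle

        f = init.copy() if init is not None else self.initial_field()
        if waveform.peak_velocity == 0.0:
            return TransientResult(
                fields=[f],
                sample_times=np.array([0.0]),
                cycle_periodicity_rel=0.0,
                dome_mean_speed_series=np.array([0.0]),
            )
        self._apply_inlet(f, waveform.velocity_at(0.0))
        self.update_viscosity(f)
        self._assemble_momentum(f, dt)

        dome = self.domain.porous_mask
        sample_every = max(n_per_cycle // samples_per_cycle, 1)
        fields: list[FlowField] = []
        sample_times = []
        cycle_integrals = []
        speed_series = []
        total_steps = waveform.n_cycles * n_per_cycle
        acc = 0.0
        for step_i in range(total_steps):
            if step_i % self.refactor_every == 0 and step_i > 0:
                self.update_viscosity(f)
                self._assemble_momentum(f, dt)
            t_new = (step_i + 1) * dt
            f = self.step(f, dt, waveform.velocity_at(t_new))
            f.time = t_new
            if dome.any():
                uc = 0.5 * (f.u[1:, :] + f.u[:-1, :])
                vc = 0.5 * (f.v[:, 1:] + f.v[:, :-1])
                sp = float(np.sqrt(uc**2 + vc**2)[dome].mean())
            else:
                sp = float(np.abs(f.u).mean())
            acc += sp * dt
            if (step_i + 1) % n_per_cycle == 0:
                cycle_integrals.append(acc)
                acc = 0.0
            in_last_cycle = step_i >= (waveform.n_cycles - 1) * n_per_cycle
            if in_last_cycle and (step_i % sample_every == 0):
                fields.append(f.copy())
                sample_times.append(t_new)
                speed_series.append(sp)
        if len(cycle_integrals) >= 2 and cycle_integrals[-1] > 0:
            periodicity = abs(cycle_integrals[-1] - cycle_integrals[-2]) / cycle_integrals[-1]
        else:
            periodicity = 0.0
        return TransientResult(
            fields=fields,
            sample_times=np.array(sample_times),
            cycle_periodicity_rel=periodicity,
            dome_mean_speed_series=np.array(speed_series),
        )

    # --------------------------------------------------------- diagnostics

    def mass_imbalance(self, f: FlowField) -> float:
        """|inflow - outflow| / inflow across the domain boundaries."""
        h = self.domain.h
        inflow = float(f.u[0, self.inlet_rows].sum()) * h
        outflow = float(f.u[-1, self.outlet_rows].sum()) * h
        if inflow == 0.0:
            return 0.0
        return abs(inflow - outflow) / inflow
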