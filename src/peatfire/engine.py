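"""Multi-column water-balance kernel.

Columns are stand-alone, so a whole grid is advanced cell by cell with no
cross-cell terms; results are identical to stepping each column alone and
invariant under cell ordering.  The inner day/sub-step loops are compiled
with numba for throughput; :func:`peatfire.hydrology.step_day` wraps a
batch of one.

Within each internal sub-step (default 24 per day) the kernel applies, in
order: precipitation to the ponded store, infiltration (rate-limited by
the minimum saturated conductivity of the layers traversed), moisture-
limited evapotranspiration (ponded water, then litter, then root-zone
transpiration under a linear wilting-to-field-capacity stress ramp),
tipping-bucket vertical drainage of moisture above field capacity
(rate-limited by Mualem unsaturated conductivity and by acceptance of the
layer below), lateral Darcy exchange with the boundary water table, and
surface runoff of ponded water above a maximum ponding depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .hydrology import (
    FIELD_CAPACITY_HEAD,
    LITTER_FC,
    LITTER_THETA_R,
    LITTER_THETA_S,
    SAT_TOL,
    WILTING_HEAD,
    ColumnState,
    _vg_theta,
)

ROOT_DEPTH = 0.5  # m, depth over which transpiration extracts water
POND_MAX = 0.02  # m, ponded water above this runs off
_EPS = 1e-15


@dataclass
class ColumnBatch:
    """Static per-layer arrays for a set of columns with equal layer count."""

    thick: np.ndarray  # (n, L) m
    theta_r: np.ndarray
    theta_s: np.ndarray
    alpha: np.ndarray
    vg_n: np.ndarray
    ksat: np.ndarray  # m/d
    theta_fc: np.ndarray  # moisture at field-capacity suction
    theta_wp: np.ndarray  # moisture at wilting suction
    depth_bot: np.ndarray  # (n, L) cumulative depth of layer bottoms
    rootw: np.ndarray  # (n, L) thickness fraction inside the root zone, * thick
    wtdx: np.ndarray  # (n,) boundary water table depth, m
    lateral_length: np.ndarray  # (n,) m
    litter_thick: np.ndarray  # (n,) m

    @property
    def n_cells(self) -> int:
        return self.thick.shape[0]

    @property
    def n_layers(self) -> int:
        return self.thick.shape[1]

    @property
    def total_depth(self) -> np.ndarray:
        return self.depth_bot[:, -1]

    @classmethod
    def from_columns(cls, columns) -> "ColumnBatch":
        L = columns[0].n_layers
        if any(c.n_layers != L for c in columns):
            raise ValueError("all columns in a batch must share the layer count")

        def grab(attr):
            return np.array([[getattr(l, attr) for l in c.layers] for c in columns],
                            dtype=float)

        thick = grab("thickness")
        theta_r = grab("theta_r")
        theta_s = grab("theta_s")
        alpha = grab("vg_alpha")
        vg_n = grab("vg_n")
        ksat = grab("ksat")
        theta_fc = _vg_theta(FIELD_CAPACITY_HEAD, theta_r, theta_s, alpha, vg_n)
        theta_wp = _vg_theta(WILTING_HEAD, theta_r, theta_s, alpha, vg_n)
        depth_bot = np.cumsum(thick, axis=1)
        depth_top = depth_bot - thick
        overlap = np.clip(np.minimum(depth_bot, ROOT_DEPTH) - depth_top, 0.0, None)
        return cls(
            thick=thick, theta_r=theta_r, theta_s=theta_s, alpha=alpha,
            vg_n=vg_n, ksat=ksat, theta_fc=theta_fc, theta_wp=theta_wp,
            depth_bot=depth_bot, rootw=overlap,
            wtdx=np.array([c.wtdx for c in columns], dtype=float),
            lateral_length=np.array([c.lateral_length for c in columns], dtype=float),
            litter_thick=np.array([c.litter_thickness for c in columns], dtype=float),
        )

    def arrays(self) -> tuple:
        m = 1.0 - 1.0 / self.vg_n
        return (self.thick, self.theta_r, self.theta_s, m, self.ksat,
                self.theta_fc, self.theta_wp, self.depth_bot, self.rootw,
                self.wtdx, self.lateral_length, self.litter_thick)


@dataclass
class BatchState:
    theta: np.ndarray  # (n, L)
    litter: np.ndarray  # (n,)
    ponded: np.ndarray  # (n,)

    @classmethod
    def from_states(cls, batch: ColumnBatch, states) -> "BatchState":
        return cls(
            theta=np.array([s.theta for s in states], dtype=float),
            litter=np.array([s.litter_theta for s in states], dtype=float),
            ponded=np.array([s.ponded for s in states], dtype=float),
        )

    @classmethod
    def initial(cls, batch: ColumnBatch, saturate_below_wtdx: bool = True) -> "BatchState":
        """Field-capacity start, optionally pre-saturated below the boundary
        water table so spin-up begins near equilibrium."""
        theta = batch.theta_fc.copy()
        if saturate_below_wtdx:
            below = batch.depth_bot - batch.thick >= batch.wtdx[:, None]
            theta = np.where(below, batch.theta_s, theta)
        return cls(theta=theta, litter=np.full(batch.n_cells, LITTER_FC),
                   ponded=np.zeros(batch.n_cells))

    def to_states(self, batch: ColumnBatch):
        wtd = diagnose_wtd_batch(batch, self.theta, self.ponded)
        return [
            ColumnState(theta=self.theta[i].copy(), litter_theta=float(self.litter[i]),
                        ponded=float(self.ponded[i]), wtd=float(wtd[i]))
            for i in range(batch.n_cells)
        ]

    def storage(self, batch: ColumnBatch) -> np.ndarray:
        return ((self.theta * batch.thick).sum(axis=1)
                + self.litter * batch.litter_thick + self.ponded)


def diagnose_wtd_batch(batch: ColumnBatch, theta: np.ndarray,
                       ponded: np.ndarray) -> np.ndarray:
    """Water table depth per cell: top of the bottom-contiguous saturated
    zone, interpolated inside the deepest unsaturated layer between field
    capacity and saturation.  0 when fully saturated or ponded; the total
    depth when no layer at the base is saturated."""
    theta = np.asarray(theta, dtype=float)
    out = np.empty(theta.shape[0])
    for i in range(theta.shape[0]):
        out[i] = _wtd_cell(theta[i], batch.theta_s[i], batch.theta_fc[i],
                           batch.depth_bot[i], batch.thick[i], float(ponded[i]))
    return out


def near_surface_batch(batch: ColumnBatch, state: BatchState) -> np.ndarray:
    t0 = batch.litter_thick
    t1, t2 = batch.thick[:, 0], batch.thick[:, 1]
    num = t0 * state.litter + t1 * state.theta[:, 0] + t2 * state.theta[:, 1]
    return num / (t0 + t1 + t2)


# ---------------------------------------------------------------------------
# Compiled per-cell kernels
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _wtd_cell(theta, theta_s, theta_fc, depth_bot, thick, ponded):
    if ponded > 1e-12:
        return 0.0
    L = theta.shape[0]
    j = -1
    for q in range(L - 1, -1, -1):
        if theta[q] < SAT_TOL * theta_s[q]:
            j = q
            break
    if j < 0:
        return 0.0
    denom = SAT_TOL * theta_s[j] - theta_fc[j]
    if denom < 1e-9:
        denom = 1e-9
    frac = (theta[j] - theta_fc[j]) / denom
    if frac < 0.0:
        frac = 0.0
    elif frac > 1.0:
        frac = 1.0
    return depth_bot[j] - frac * thick[j]


@numba.njit(cache=True)
def _substep_cell(thick, tr, ts, m, ksat, fc, wp, depth_bot, rootw,
                  wtdx, lat_len, lit_thick, theta, litter, ponded,
                  p_sub, pet_sub, dt, desired, exp):
    """One sub-step for one column; returns updated (litter, ponded) plus
    the sub-step et, lateral and runoff totals."""
    L = theta.shape[0]
    ponded += p_sub

    # --- infiltration: litter first, then layers top-down, throttled by
    # the minimum ksat traversed so far
    if ponded > _EPS:
        lit_cap = (LITTER_THETA_S - litter) * lit_thick
        if lit_cap < 0.0:
            lit_cap = 0.0
        take = ponded if ponded < lit_cap else lit_cap
        litter += take / lit_thick
        ponded -= take
        rate = 1e30
        for j in range(L):
            if ponded <= _EPS:
                break
            rj = ksat[j] * dt
            if rj < rate:
                rate = rj
            cap = (ts[j] - theta[j]) * thick[j]
            if cap < 0.0:
                cap = 0.0
            take = ponded
            if cap < take:
                take = cap
            if rate < take:
                take = rate
            theta[j] += take / thick[j]
            ponded -= take

    # --- evapotranspiration: ponded, then litter, then stressed root zone
    e_pond = pet_sub if pet_sub < ponded else ponded
    ponded -= e_pond
    d = pet_sub - e_pond
    lit_avail = (litter - LITTER_THETA_R) * lit_thick
    if lit_avail < 0.0:
        lit_avail = 0.0
    e_lit = d if d < lit_avail else lit_avail
    litter -= e_lit / lit_thick
    d -= e_lit
    e_soil = 0.0
    if d > _EPS:
        wsum = 0.0
        tb = 0.0
        fb = 0.0
        wb = 0.0
        tot = 0.0
        for j in range(L):
            w = rootw[j]
            if w > 0.0:
                wsum += w
                tb += theta[j] * w
                fb += fc[j] * w
                wb += wp[j] * w
                a = (theta[j] - wp[j]) * w
                if a > 0.0:
                    tot += a
        stress = (tb / wsum - wb / wsum) / max(fb / wsum - wb / wsum, 1e-9)
        if stress < 0.0:
            stress = 0.0
        elif stress > 1.0:
            stress = 1.0
        e_soil = d * stress
        if e_soil > tot:
            e_soil = tot
        if tot > _EPS:
            fracd = e_soil / tot
            for j in range(L):
                w = rootw[j]
                if w > 0.0:
                    a = (theta[j] - wp[j]) * w
                    if a > 0.0:
                        theta[j] -= a * fracd / thick[j]
    et = e_pond + e_lit + e_soil

    # --- vertical drainage: litter excess into layer 1, then tipping
    # bucket with export limited by acceptance of everything below
    lit_ex = (litter - LITTER_FC) * lit_thick
    if lit_ex > 0.0:
        cap0 = (ts[0] - theta[0]) * thick[0]
        if cap0 < 0.0:
            cap0 = 0.0
        mv = lit_ex if lit_ex < cap0 else cap0
        litter -= mv / lit_thick
        theta[0] += mv / thick[0]
    for j in range(L):
        ex = (theta[j] - fc[j]) * thick[j]
        if ex < 0.0:
            ex = 0.0
        se = (theta[j] - tr[j]) / (ts[j] - tr[j])
        if se < 0.0:
            se = 0.0
        elif se > 1.0:
            se = 1.0
        ku = ksat[j] * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m[j])) ** m[j]) ** 2
        lim = ku * dt
        desired[j] = ex if ex < lim else lim
    exp[L - 1] = 0.0
    for j in range(L - 2, -1, -1):
        cap = (ts[j + 1] - theta[j + 1]) * thick[j + 1]
        if cap < 0.0:
            cap = 0.0
        room = cap + exp[j + 1]
        exp[j] = desired[j] if desired[j] < room else room
    theta[0] -= exp[0] / thick[0]
    for j in range(1, L):
        theta[j] += (exp[j - 1] - exp[j]) / thick[j]

    # --- lateral Darcy exchange with the boundary water table
    wtd = _wtd_cell(theta, ts, fc, depth_bot, thick, ponded)
    ksum = 0.0
    nsat = 0
    for j in range(L):
        if theta[j] >= SAT_TOL * ts[j]:
            ksum += ksat[j]
            nsat += 1
    kmean = ksum / nsat if nsat > 0 else ksat[L - 1]
    q = kmean * (wtdx - wtd) / lat_len * dt
    lateral = 0.0
    if q > 0.0:
        # drain the transition layer's excess first, then the saturated
        # zone top-down, leaving each tapped layer at field capacity
        j0 = -1
        for j in range(L - 1, -1, -1):
            if theta[j] < SAT_TOL * ts[j]:
                j0 = j
                break
        rem = q
        for j in range(max(j0, 0), L):
            if rem <= _EPS:
                break
            if j > j0 or theta[j] > fc[j]:
                avail = (theta[j] - fc[j]) * thick[j]
                if avail < 0.0:
                    avail = 0.0
                take = rem if rem < avail else avail
                theta[j] -= take / thick[j]
                rem -= take
        lateral = q - rem
    elif q < 0.0:
        rem = -q
        for j in range(L - 1, -1, -1):
            if rem <= _EPS:
                break
            cap = (ts[j] - theta[j]) * thick[j]
            if cap < 0.0:
                cap = 0.0
            add = rem if rem < cap else cap
            theta[j] += add / thick[j]
            rem -= add
        lateral = -((-q) - rem)

    # --- surface runoff above the ponding limit
    runoff = 0.0
    if ponded > POND_MAX:
        runoff = ponded - POND_MAX
        ponded = POND_MAX
    return litter, ponded, et, lateral, runoff


@numba.njit(cache=True)
def _run_core(thick, tr, ts, m, ksat, fc, wp, depth_bot, rootw, wtdx,
              lat_len, lit_thick, theta, litter, ponded, precip, pet,
              nsub, rec_wtd, rec_tns, rec_et, rec_lat, rec_run, rec_dst):
    n, L = thick.shape
    T = precip.shape[1]
    dt = 1.0 / nsub
    desired = np.empty(L)
    exp = np.empty(L)
    for i in range(n):
        th = theta[i]
        li = litter[i]
        po = ponded[i]
        for t in range(T):
            s0 = po + li * lit_thick[i]
            for j in range(L):
                s0 += th[j] * thick[i, j]
            et = 0.0
            lat = 0.0
            run = 0.0
            p_sub = precip[i, t] * dt
            pet_sub = pet[i, t] * dt
            for s in range(nsub):
                li, po, e1, l1, r1 = _substep_cell(
                    thick[i], tr[i], ts[i], m[i], ksat[i], fc[i], wp[i],
                    depth_bot[i], rootw[i], wtdx[i], lat_len[i], lit_thick[i],
                    th, li, po, p_sub, pet_sub, dt, desired, exp)
                et += e1
                lat += l1
                run += r1
            s1 = po + li * lit_thick[i]
            for j in range(L):
                s1 += th[j] * thick[i, j]
            rec_wtd[i, t] = _wtd_cell(th, ts[i], fc[i], depth_bot[i], thick[i], po)
            rec_tns[i, t] = ((li * lit_thick[i] + th[0] * thick[i, 0]
                              + th[1] * thick[i, 1])
                             / (lit_thick[i] + thick[i, 0] + thick[i, 1]))
            rec_et[i, t] = et
            rec_lat[i, t] = lat
            rec_run[i, t] = run
            rec_dst[i, t] = s1 - s0
        litter[i] = li
        ponded[i] = po


@numba.njit(cache=True)
def _spin_core(thick, tr, ts, m, ksat, fc, wp, depth_bot, rootw, wtdx,
               lat_len, lit_thick, theta, litter, ponded, precip, pet,
               nsub, max_years, drift_tol):
    """Repeat one forcing year per cell until its annual-mean WTD drifts
    by less than ``drift_tol`` between cycles; cells converge (and stop)
    independently.  Returns the cycles run per cell."""
    n, L = thick.shape
    T = precip.shape[1]
    dt = 1.0 / nsub
    desired = np.empty(L)
    exp = np.empty(L)
    years_run = np.zeros(n, dtype=np.int64)
    for i in range(n):
        th = theta[i]
        li = litter[i]
        po = ponded[i]
        prev = -1.0
        for year in range(max_years):
            wtd_sum = 0.0
            for t in range(T):
                p_sub = precip[i, t] * dt
                pet_sub = pet[i, t] * dt
                for s in range(nsub):
                    li, po, e1, l1, r1 = _substep_cell(
                        thick[i], tr[i], ts[i], m[i], ksat[i], fc[i], wp[i],
                        depth_bot[i], rootw[i], wtdx[i], lat_len[i], lit_thick[i],
                        th, li, po, p_sub, pet_sub, dt, desired, exp)
                wtd_sum += _wtd_cell(th, ts[i], fc[i], depth_bot[i], thick[i], po)
            mean_wtd = wtd_sum / T
            years_run[i] = year + 1
            if prev >= 0.0 and abs(mean_wtd - prev) < drift_tol:
                break
            prev = mean_wtd
        litter[i] = li
        ponded[i] = po
    return years_run


# ---------------------------------------------------------------------------
# Python-facing drivers
# ---------------------------------------------------------------------------

def step_batch_day(batch: ColumnBatch, state: BatchState, precip_m: np.ndarray,
                   pet_m: np.ndarray, sub_steps: int = 24) -> dict:
    """Advance the whole batch one day; mutates ``state`` and returns the
    per-cell daily flux ledger (all terms m of water)."""
    out = run_days(batch, state, np.asarray(precip_m, dtype=float)[:, None],
                   np.asarray(pet_m, dtype=float)[:, None], sub_steps=sub_steps)
    return {k: out[k][:, 0] for k in
            ("precip", "et", "lateral", "runoff", "delta_storage")}


def run_days(batch: ColumnBatch, state: BatchState, precip_m: np.ndarray,
             pet_m: np.ndarray, sub_steps: int = 24) -> dict:
    """Run ``T`` days given ``(n, T)`` precipitation and PET arrays,
    returning daily end-of-day WTD, near-surface moisture and the flux
    ledger as ``(n, T)`` arrays."""
    n, T = precip_m.shape
    rec = {k: np.empty((n, T)) for k in
           ("wtd", "theta_ns", "et", "lateral", "runoff", "delta_storage")}
    _run_core(*batch.arrays(), state.theta, state.litter, state.ponded,
              np.ascontiguousarray(precip_m, dtype=float),
              np.ascontiguousarray(pet_m, dtype=float), sub_steps,
              rec["wtd"], rec["theta_ns"], rec["et"], rec["lateral"],
              rec["runoff"], rec["delta_storage"])
    rec["precip"] = np.array(precip_m, dtype=float)
    return rec


def spin_up_batch(batch: ColumnBatch, state: BatchState, precip_year: np.ndarray,
                  pet_year: np.ndarray, sub_steps: int = 24, max_years: int = 56,
                  drift_tol_m: float = 1e-3) -> np.ndarray:
    """Repeat one forcing year until the annual-mean WTD drifts by less
    than ``drift_tol_m`` between cycles (or ``max_years`` is reached);
    returns the number of cycles run per cell."""
    return _spin_core(*batch.arrays(), state.theta, state.litter, state.ponded,
                      np.ascontiguousarray(precip_year, dtype=float),
                      np.ascontiguousarray(pet_year, dtype=float),
                      sub_steps, max_years, drift_tol_m)
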