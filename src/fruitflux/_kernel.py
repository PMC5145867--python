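"""Compiled core of the fruit water/carbon balance.

Everything here is numba ``@njit`` code operating on flat float64 arrays so a
full-season simulation costs microseconds; the documented public surface
lives in :mod:`fruitflux.model_core`, which wraps these functions.

Units throughout: g, h, bar, cm, degrees Celsius.

The turgor equation is solved in closed form.  Both water fluxes are linear
in the turgor pressure ``Pf`` and the solute mass-flow term is zeroed for
reverse phloem flow, which makes the volumetric balance dV/dt(Pf) a
continuous, decreasing, piecewise-linear function with a single kink at the
pressure where phloem flow changes sign.  Intersecting it with the (linear,
increasing) Lockhart growth rate therefore needs no iteration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- physical constants -----------------------------------------------------
R_BAR_L = 0.08314   # gas constant, L bar mol^-1 K^-1
R_J = 8.314         # gas constant, J mol^-1 K^-1
MW_WATER = 18.015   # g mol^-1

# -- genotype parameter slots ----------------------------------------------
IG_PHIMAX, IG_LP, IG_NUM, IG_TSTAR, IG_TAUA, IG_TAUS, IG_LP1, IG_RXP = range(8)
N_IG = 8

# -- generic-constant + plant-input slots ----------------------------------
(IC_KM, IC_PS, IC_AP, IC_AX, IC_QG, IC_QM20, IC_Q10, IC_Y, IC_TAUPHI,
 IC_HF, IC_RHOS, IC_MSUGAR, IC_GAMMAA, IC_RW, IC_CP, IC_PSI_PRE,
 IC_PSI_MID, IC_RHOSURF, IC_PIOTHER, IC_ASSRAT, IC_BSSRAT,
 IC_UPTAKE_SCALING) = range(22)
N_IC = 22

# trajectory columns (time is implicit on the uniform grid)
COL_W, COL_S, COL_PF, COL_REGIME, COL_UX, COL_UP, COL_US, COL_TF, COL_RF = range(9)
N_COL = 9

STATUS_OK = 0
STATUS_DT_UNDERFLOW = 1


@njit(cache=True)
def ssrat_at(t, assrat, bssrat):
    """Soluble-sugar fraction of dry mass: linear in days, clipped to [0, 1]."""
    v = assrat * t / 24.0 + bssrat
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=True)
def sigma_p_at(t, tau_s):
    return 1.0 - np.exp(-tau_s * t * t)


@njit(cache=True)
def active_uptake_rate(t, tstar, tau_a, nu_m):
    """Logistic decline of the maximal active-uptake rate, overflow safe."""
    z = (t - tstar) / tau_a
    if z > 500.0:
        return 0.0
    if z < -500.0:
        return nu_m
    return nu_m / (1.0 + np.exp(z))


@njit(cache=True)
def sat_vapour_pressure(t_c):
    """Magnus-type saturation vapour pressure, Pa."""
    return 610.78 * np.exp(17.27 * t_c / (t_c + 237.3))


@njit(cache=True)
def sat_vapour_density(t_c):
    """Saturated water-vapour density, g cm^-3."""
    return MW_WATER * sat_vapour_pressure(t_c) / (R_J * (t_c + 273.15)) * 1e-6


@njit(cache=True)
def osmotic_pressure_sugar(conc, t_c, m_sugar):
    """Van 't Hoff osmotic pressure (bar) of `conc` g sugar per g water."""
    return R_BAR_L * (t_c + 273.15) * conc * 1000.0 / m_sugar


@njit(cache=True)
def stem_water_potential_at(t, psi_predawn, psi_midday):
    """Diurnal stem water potential: cosine course, max 05:00, min 13:00."""
    h = t % 24.0
    if h < 5.0:
        h += 24.0
    if h < 13.0:
        f = (h - 5.0) / 8.0
        return psi_predawn + (psi_midday - psi_predawn) * 0.5 * (1.0 - np.cos(np.pi * f))
    f = (h - 13.0) / 16.0
    return psi_midday + (psi_predawn - psi_midday) * 0.5 * (1.0 - np.cos(np.pi * f))


@njit(cache=True)
def geometry(w, s, rho_s, gamma_a):
    v = w + s / rho_s
    return v, gamma_a * v ** (2.0 / 3.0)


@njit(cache=True, error_model="numpy")
def derivs(t, w, s, t_air, rh, pg, pc):
    """One right-hand-side evaluation at state (t, w, s).

    Returns (dwdt, dsdt, Pf, regime, Ux, Up, Us, Tf, Rf); regime is 1.0 for
    Lockhart growth, 0.0 for the static (no irreversible expansion) branch.
    """
    if w <= 0.0 or s <= 0.0:
        nan = np.nan
        return nan, nan, nan, nan, nan, nan, nan, nan, nan

    rho_s = pc[IC_RHOS]
    v, af = geometry(w, s, rho_s, pc[IC_GAMMAA])

    ssr = ssrat_at(t, pc[IC_ASSRAT], pc[IC_BSSRAT])
    cf = ssr * s / w
    cp = pc[IC_CP]
    m_sugar = pc[IC_MSUGAR]
    pi_f = osmotic_pressure_sugar(cf, t_air, m_sugar) + pc[IC_PIOTHER]
    pi_p = osmotic_pressure_sugar(cp, t_air, m_sugar)

    sig = sigma_p_at(t, pg[IG_TAUS])
    phi = pg[IG_PHIMAX] * np.exp(-t / pc[IC_TAUPHI])
    psi = stem_water_potential_at(t, pc[IC_PSI_PRE], pc[IC_PSI_MID])

    # series pedicel + membrane conductances; xylem scaled from phloem by rxp
    lx = pg[IG_RXP] * pg[IG_LP]
    lx1 = pg[IG_RXP] * pg[IG_LP1]
    kx = 1.0 / (1.0 / lx1 + 1.0 / (pc[IC_AX] * af * lx))
    kp = 1.0 / (1.0 / pg[IG_LP1] + 1.0 / (pc[IC_AP] * af * pg[IG_LP]))
    if not np.isfinite(kx):
        kx = 0.0
    if not np.isfinite(kp):
        kp = 0.0

    # zero-driving-force potentials: Ux = kx*(psix0 - Pf), Up = kp*(psip0 - Pf)
    psix0 = psi + pi_f
    psip0 = psi + pi_p - sig * (pi_p - pi_f)

    tf = af * pc[IC_RHOSURF] * sat_vapour_density(t_air) * (pc[IC_HF] - rh)
    if tf < 0.0:
        tf = 0.0

    nu = active_uptake_rate(t, pg[IG_TSTAR], pg[IG_TAUA], pg[IG_NUM])
    if pc[IC_UPTAKE_SCALING] > 0.5:
        nu *= s
    ua = nu * cp / (pc[IC_KM] + cp)
    ud = pc[IC_PS] * pc[IC_AP] * af * (cp - cf)
    us0 = ua + ud

    qg = pc[IC_QG]
    qm = pc[IC_QM20] * pc[IC_Q10] ** ((t_air - 20.0) / 10.0)

    # dV/dt(Pf) = C0 - C1*Pf, piecewise linear with kink at Pf = psip0:
    #   branch 1 (Pf <= psip0): forward phloem flow carries sugar (mass flow)
    #   branch 2 (Pf >= psip0): reverse flow carries none
    m1 = (1.0 - sig) * 0.5 * (cp + cf) * kp
    rw = pc[IC_RW]
    c_us = (rw * qg + 1.0 / rho_s) / (1.0 + qg)
    c_s = (rw - 1.0 / rho_s) * qm * s / (1.0 + qg)
    base = kx * psix0 + kp * psip0 - tf + c_s
    c0_1 = base + c_us * (us0 + m1 * psip0)
    c1_1 = kx + kp + c_us * m1
    c0_2 = base + c_us * us0
    c1_2 = kx + kp

    y = pc[IC_Y]
    v_phi = v * phi
    if y <= psip0:
        dv_at_y = c0_1 - c1_1 * y
    else:
        dv_at_y = c0_2 - c1_2 * y

    if dv_at_y > 0.0:
        regime = 1.0
        pf = (c0_1 + v_phi * y) / (v_phi + c1_1)
        if pf > psip0:
            pf = (c0_2 + v_phi * y) / (v_phi + c1_2)
    else:
        regime = 0.0
        if c1_1 <= 0.0:
            pf = 0.0
        else:
            pf = c0_1 / c1_1
            if pf > psip0:
                pf = c0_2 / c1_2 if c1_2 > 0.0 else 0.0
        if pf < 0.0:
            pf = 0.0

    ux = kx * (psix0 - pf)
    up = kp * (psip0 - pf)
    us = us0
    if up > 0.0:
        us += (1.0 - sig) * 0.5 * (cp + cf) * up

    dsdt = (us - qm * s) / (1.0 + qg)
    rf = us - dsdt
    dwdt = ux + up + rw * rf - tf
    return dwdt, dsdt, pf, regime, ux, up, us, tf, rf


@njit(cache=True)
def env_at(env_t, env_rh, env_t0, t):
    """Linear interpolation on the hourly climate grid, clamped at the ends."""
    x = t - env_t0
    n = env_t.shape[0]
    if x <= 0.0:
        return env_t[0], env_rh[0]
    if x >= n - 1:
        return env_t[n - 1], env_rh[n - 1]
    i = int(np.floor(x))
    f = x - i
    return (env_t[i] + f * (env_t[i + 1] - env_t[i]),
            env_rh[i] + f * (env_rh[i + 1] - env_rh[i]))


@njit(cache=True, error_model="numpy")
def rk4_step(t, w, s, h, pg, pc, env_t, env_rh, env_t0):
    t1, r1 = env_at(env_t, env_rh, env_t0, t)
    k1 = derivs(t, w, s, t1, r1, pg, pc)
    t2, r2 = env_at(env_t, env_rh, env_t0, t + 0.5 * h)
    k2 = derivs(t + 0.5 * h, w + 0.5 * h * k1[0], s + 0.5 * h * k1[1], t2, r2, pg, pc)
    k3 = derivs(t + 0.5 * h, w + 0.5 * h * k2[0], s + 0.5 * h * k2[1], t2, r2, pg, pc)
    t4, r4 = env_at(env_t, env_rh, env_t0, t + h)
    k4 = derivs(t + h, w + h * k3[0], s + h * k3[1], t4, r4, pg, pc)
    wn = w + h / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
    sn = s + h / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
    return wn, sn


@njit(cache=True, error_model="numpy")
def integrate(pg, pc, w0, s0, t0, n_steps, dt, dt_min, env_t, env_rh, env_t0):
    """Fixed-grid RK4 integration with positivity-guarded step halving.

    Returns (status, out) where out[i] holds the state and instantaneous
    diagnostic fluxes at grid time t0 + i*dt.
    """
    n = n_steps + 1
    out = np.empty((n, N_COL))
    w = w0
    s = s0
    for i in range(n):
        t = t0 + i * dt
        t_air, rh = env_at(env_t, env_rh, env_t0, t)
        d = derivs(t, w, s, t_air, rh, pg, pc)
        out[i, COL_W] = w
        out[i, COL_S] = s
        out[i, COL_PF] = d[2]
        out[i, COL_REGIME] = d[3]
        out[i, COL_UX] = d[4]
        out[i, COL_UP] = d[5]
        out[i, COL_US] = d[6]
        out[i, COL_TF] = d[7]
        out[i, COL_RF] = d[8]
        if i == n_steps:
            break
        remaining = dt
        tt = t
        h = dt
        while remaining > 1e-12:
            if h > remaining:
                h = remaining
            wn, sn = rk4_step(tt, w, s, h, pg, pc, env_t, env_rh, env_t0)
            if (not np.isfinite(wn)) or (not np.isfinite(sn)) or wn <= 0.0 or sn <= 0.0:
                h *= 0.5
                if h < dt_min:
                    return STATUS_DT_UNDERFLOW, out
                continue
            w = wn
            s = sn
            tt += h
            remaining -= h
    return STATUS_OK, out
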