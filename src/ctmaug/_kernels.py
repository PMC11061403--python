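"""Numba-compiled hot loops: time-domain integration and the MCMC objective.

Everything here is a plain-array function; the public modules wrap these in
typed containers and validation.  All randomness is drawn from numpy's legacy
global generator *inside* the jitted functions, seeded per call, which numba
supports and which makes runs bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# linearized time-domain integrator
# ---------------------------------------------------------------------------


@njit(cache=True)
def integrate_modes(n_steps, burn_steps, dt, delay_steps,
                    G_ee, G_ei, G_es, G_se, G_sr, G_re, G_rs,
                    alpha, beta, gamma, k2re2, sqrt_w, drive, seed):
    """Semi-implicit Euler integration of the linearized corticothalamic loop.

    One independent realization per spatial mode (unique squared wavenumber);
    the recorded output is the weight-summed excitatory field.  Returns
    ``(signal, ok)`` where ``ok`` is False if the state diverged.
    """
    np.random.seed(seed)
    n_modes = k2re2.shape[0]
    ab = alpha * beta
    apb = alpha + beta
    g2 = gamma * gamma
    noise_sd = drive / np.sqrt(dt)

    u = np.zeros(n_modes)
    du = np.zeros(n_modes)
    psi = np.zeros(n_modes)
    dpsi = np.zeros(n_modes)
    xr = np.zeros(n_modes)
    dxr = np.zeros(n_modes)
    xs = np.zeros(n_modes)
    dxs = np.zeros(n_modes)

    nbuf = max(delay_steps, 1)
    psi_buf = np.zeros((n_modes, nbuf))
    xs_buf = np.zeros((n_modes, nbuf))

    out = np.zeros(n_steps - burn_steps)
    idx = 0
    for t in range(n_steps):
        acc = 0.0
        for i in range(n_modes):
            if delay_steps > 0:
                psid = psi_buf[i, idx]
                xsd = xs_buf[i, idx]
            else:
                psid = psi[i]
                xsd = xs[i]
            in_u = G_ee * psi[i] + G_ei * u[i] + G_es * xsd
            in_r = G_re * psid + G_rs * xs[i]
            in_s = G_se * psid + G_sr * xr[i] + noise_sd * np.random.normal()

            du[i] += dt * (ab * (in_u - u[i]) - apb * du[i])
            u[i] += dt * du[i]
            dxr[i] += dt * (ab * (in_r - xr[i]) - apb * dxr[i])
            xr[i] += dt * dxr[i]
            dxs[i] += dt * (ab * (in_s - xs[i]) - apb * dxs[i])
            xs[i] += dt * dxs[i]
            dpsi[i] += dt * (g2 * (u[i] - (1.0 + k2re2[i]) * psi[i]) - 2.0 * gamma * dpsi[i])
            psi[i] += dt * dpsi[i]

            if delay_steps > 0:
                psi_buf[i, idx] = psi[i]
                xs_buf[i, idx] = xs[i]
            acc += sqrt_w[i] * psi[i]
        if delay_steps > 0:
            idx += 1
            if idx == delay_steps:
                idx = 0
        if t >= burn_steps:
            out[t - burn_steps] = acc
        if t % 5000 == 0:
            for i in range(n_modes):
                if not np.isfinite(psi[i]) or np.abs(psi[i]) > 1e12:
                    return out, False
    for i in range(n_modes):
        if not np.isfinite(psi[i]):
            return out, False
    return out, True


# ---------------------------------------------------------------------------
# analytic band spectrum + MCMC chain
# ---------------------------------------------------------------------------


@njit(cache=True)
def band_spectrum(params, gamma, r_e, omega, k2, kw):
    """Analytic power spectrum for the 8-parameter fit vector.

    ``params`` = (G_ee, G_ei, G_ese, G_esre, G_srs, alpha, beta, t0);
    amplitude is fixed to 1 (profiled out of the objective by the caller).
    """
    G_ee, G_ei, G_ese, G_esre, G_srs, alpha, beta, t0 = (
        params[0], params[1], params[2], params[3], params[4],
        params[5], params[6], params[7])
    nf = omega.shape[0]
    nk = k2.shape[0]
    P = np.empty(nf)
    re2 = r_e * r_e
    for j in range(nf):
        w = omega[j]
        L = 1.0 / ((1.0 - 1j * w / alpha) * (1.0 - 1j * w / beta))
        L2 = L * L
        thal = 1.0 - G_srs * L2
        cort = 1.0 - G_ei * L
        eiwt = np.cos(w * t0) + 1j * np.sin(w * t0)
        loop = (L2 * G_ese + L2 * L * G_esre) * eiwt / thal
        q2re2 = (1.0 - 1j * w / gamma) ** 2 - (L * G_ee + loop) / cort
        numer = L2 / (thal * cort)
        amp2 = numer.real * numer.real + numer.imag * numer.imag
        s = 0.0
        for i in range(nk):
            d = k2[i] * re2 + q2re2
            s += kw[i] / (d.real * d.real + d.imag * d.imag)
        P[j] = amp2 * s
    return P


@njit(cache=True)
def shape_objective(params, gamma, r_e, omega, k2, kw, log_target):
    """Log-power least squares with the multiplicative scale profiled out."""
    P = band_spectrum(params, gamma, r_e, omega, k2, kw)
    n = P.shape[0]
    for j in range(n):
        if not np.isfinite(P[j]) or P[j] <= 0.0:
            return np.inf
    r = np.log10(P) - log_target
    r -= r.sum() / n
    return (r * r).sum()


@njit(cache=True)
def spectrum_is_stable(params, gamma, r_e, omega_dense, k2, kw, ratio_ceiling):
    """Finite, positive spectrum on a dense grid with bounded peak-to-median ratio."""
    P = band_spectrum(params, gamma, r_e, omega_dense, k2, kw)
    n = P.shape[0]
    for j in range(n):
        if not np.isfinite(P[j]) or P[j] <= 0.0:
            return False
    med = np.median(P)
    return P.max() <= ratio_ceiling * med


@njit(cache=True)
def metropolis_chain(x0, lo, hi, prop_scale, n_steps, adapt_steps,
                     gamma, r_e, omega, k2, kw, log_target,
                     omega_dense, ratio_ceiling, inv_temp, seed):
    """Single-parameter-at-a-time random-walk Metropolis on the prior box.

    The proposal scales adapt multiplicatively during ``adapt_steps`` toward a
    20-40% acceptance rate, then freeze.  The posterior is
    exp(-inv_temp * objective), i.e. a Gaussian likelihood on the band's
    log-power residuals whose noise scale sets the temperature.  Returns the
    chain (n_steps, 8), objective values, best parameters/objective and the
    post-adaptation acceptance rate.
    """
    np.random.seed(seed)
    npar = x0.shape[0]
    x = x0.copy()
    fx = shape_objective(x, gamma, r_e, omega, k2, kw, log_target)
    scale = prop_scale.copy()
    chain = np.empty((n_steps, npar))
    objs = np.empty(n_steps)
    best = x.copy()
    fbest = fx
    acc_tail = 0
    ntail = 0
    acc_win = np.zeros(npar)
    try_win = np.zeros(npar)
    for t in range(n_steps):
        for p in range(npar):
            xp = x.copy()
            xp[p] = x[p] + scale[p] * np.random.normal()
            try_win[p] += 1.0
            if t >= adapt_steps:
                ntail += 1
            if xp[p] < lo[p] or xp[p] > hi[p]:
                continue
            if xp[6] < xp[5]:  # beta >= alpha
                continue
            if not spectrum_is_stable(xp, gamma, r_e, omega_dense, k2, kw,
                                      ratio_ceiling):
                continue
            fp = shape_objective(xp, gamma, r_e, omega, k2, kw, log_target)
            if fp <= fx or np.random.random() < np.exp(-inv_temp * (fp - fx)):
                x = xp
                fx = fp
                acc_win[p] += 1.0
                if t >= adapt_steps:
                    acc_tail += 1
                if fx < fbest:
                    fbest = fx
                    best = x.copy()
        if t < adapt_steps and (t + 1) % 50 == 0:
            for p in range(npar):
                rate = acc_win[p] / max(try_win[p], 1.0)
                if rate < 0.20:
                    scale[p] *= 0.7
                elif rate > 0.40:
                    scale[p] *= 1.4
                acc_win[p] = 0.0
                try_win[p] = 0.0
        chain[t] = x
        objs[t] = fx
    rate = acc_tail / max(ntail, 1)
    return chain, objs, best, fbest, rate
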