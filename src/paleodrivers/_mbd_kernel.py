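"""Numba inner loop of the multivariate birth-death sampler.

The kernel consumes pregenerated random variates (normals, uniforms,
exponentials and constant-shape gamma draws), so the whole chain is a
deterministic function of a numpy Generator seed held by the caller.

Horseshoe updates follow the inverse-gamma auxiliary-variable scheme:
with coefficients G_j ~ N(0, l_j^2 tau^2), l_j ~ half-Cauchy(0,1) and
tau ~ half-Cauchy(0,1), all four conditional updates are inverse-gamma
with constant shape, so an IG(a, b) draw is b divided by a pregenerated
Gamma(a, 1) variate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chain", "N_TRACE"]

#: columns of the trace output: log-posterior, log-prior, log-likelihood
N_TRACE = 3

LOG_2_OVER_PI = np.log(2.0 / np.pi)


@njit(cache=True)
def _exposure(N_dt: np.ndarray, w: np.ndarray) -> float:
    """sum_t N_t * dt * exp(w_t) - the rate-free part of the exposure."""
    total = 0.0
    for i in range(N_dt.shape[0]):
        total += N_dt[i] * np.exp(w[i])
    return total


@njit(cache=True)
def run_chain(
    X: np.ndarray,          # (n_cells, p) predictors per quadrature cell
    N_dt: np.ndarray,       # (n_cells,) lineage count * dt per cell
    Sb: np.ndarray,         # (p,) sum of predictor rows at birth events
    B: int,                 # number of birth events
    Sd: np.ndarray,         # (p,) sum at death events
    D: int,                 # number of death events
    a0: float,              # baseline prior Gamma shape
    b0: float,              # baseline prior Gamma rate
    n_iter: int,
    burnin: int,
    sample_every: int,
    norm: np.ndarray,       # (n_iter, 2+2p) random-walk proposal normals
    unif: np.ndarray,       # (n_iter, 2+2p) acceptance uniforms
    expo: np.ndarray,       # (n_iter, 4p+2) Exp(1) draws for IG(1, .) updates
    gam_tau: np.ndarray,    # (n_iter, 2) Gamma((p+1)/2, 1) draws for tau^2
    ind_z: np.ndarray,      # (n_iter, 2p) normals for independence proposals
    ind_u: np.ndarray,      # (n_iter, 2p) acceptance uniforms for the same
):
    p = X.shape[1]
    n_cells = X.shape[0]

    lam0 = max(B, 1) / max(N_dt.sum(), 1e-12)
    mu0 = max(D, 1) / max(N_dt.sum(), 1e-12)
    gl = np.zeros(p)
    gm = np.zeros(p)
    l2l = np.ones(p)   # lambda-side local scales squared
    l2m = np.ones(p)
    nul = np.ones(p)
    num = np.ones(p)
    tau2l = 1.0
    tau2m = 1.0
    xil = 1.0
    xim = 1.0

    wl = np.zeros(n_cells)  # X @ gl
    wm = np.zeros(n_cells)
    El = _exposure(N_dt, wl)
    Em = _exposure(N_dt, wm)

    # adaptive proposal scales
    s_lam0 = 0.3
    s_mu0 = 0.3
    s_gl = np.full(p, 0.3)
    s_gm = np.full(p, 0.3)
    acc = np.zeros(2 + 2 * p)
    tries = np.zeros(2 + 2 * p)

    n_samples = (n_iter - burnin + sample_every - 1) // sample_every
    trace = np.empty((n_samples, N_TRACE))
    params = np.empty((n_samples, 2 + 2 * p))
    omegas = np.empty((n_samples, 2 * p))
    s_idx = 0

    for it in range(n_iter):
        # --- baseline speciation rate (log-scale random walk) ---
        prop = lam0 * np.exp(s_lam0 * norm[it, 0])
        dll = B * (np.log(prop) - np.log(lam0)) - (prop - lam0) * El
        dlp = (a0 - 1.0) * (np.log(prop) - np.log(lam0)) - b0 * (prop - lam0)
        tries[0] += 1.0
        if np.log(unif[it, 0]) < dll + dlp + np.log(prop / lam0):
            lam0 = prop
            acc[0] += 1.0

        # --- baseline extinction rate ---
        prop = mu0 * np.exp(s_mu0 * norm[it, 1])
        dll = D * (np.log(prop) - np.log(mu0)) - (prop - mu0) * Em
        dlp = (a0 - 1.0) * (np.log(prop) - np.log(mu0)) - b0 * (prop - mu0)
        tries[1] += 1.0
        if np.log(unif[it, 1]) < dll + dlp + np.log(prop / mu0):
            mu0 = prop
            acc[1] += 1.0

        # --- speciation coefficients ---
        for j in range(p):
            g_new = gl[j] + s_gl[j] * norm[it, 2 + j]
            dg = g_new - gl[j]
            w_new = wl + dg * X[:, j]
            E_new = _exposure(N_dt, w_new)
            dll = Sb[j] * dg - lam0 * (E_new - El)
            dlp = -(g_new * g_new - gl[j] * gl[j]) / (2.0 * l2l[j] * tau2l)
            tries[2 + j] += 1.0
            if np.log(unif[it, 2 + j]) < dll + dlp:
                gl[j] = g_new
                wl = w_new
                El = E_new
                acc[2 + j] += 1.0

        # --- extinction coefficients ---
        for j in range(p):
            g_new = gm[j] + s_gm[j] * norm[it, 2 + p + j]
            dg = g_new - gm[j]
            w_new = wm + dg * X[:, j]
            E_new = _exposure(N_dt, w_new)
            dll = Sd[j] * dg - mu0 * (E_new - Em)
            dlp = -(g_new * g_new - gm[j] * gm[j]) / (2.0 * l2m[j] * tau2m)
            tries[2 + p + j] += 1.0
            if np.log(unif[it, 2 + p + j]) < dll + dlp:
                gm[j] = g_new
                wm = w_new
                Em = E_new
                acc[2 + p + j] += 1.0

        # --- independence refresh of coefficients (every 3rd iteration) ---
        # proposal from the conditional prior N(0, l^2 tau^2); acceptance
        # reduces to the likelihood ratio.  Keeps mixing healthy across
        # the horseshoe's collapsed and released scale regimes.
        if it % 3 == 0:
            for j in range(p):
                g_new = ind_z[it, j] * np.sqrt(l2l[j] * tau2l)
                dg = g_new - gl[j]
                w_new = wl + dg * X[:, j]
                E_new = _exposure(N_dt, w_new)
                dll = Sb[j] * dg - lam0 * (E_new - El)
                if np.log(ind_u[it, j]) < dll:
                    gl[j] = g_new
                    wl = w_new
                    El = E_new
            for j in range(p):
                g_new = ind_z[it, p + j] * np.sqrt(l2m[j] * tau2m)
                dg = g_new - gm[j]
                w_new = wm + dg * X[:, j]
                E_new = _exposure(N_dt, w_new)
                dll = Sd[j] * dg - mu0 * (E_new - Em)
                if np.log(ind_u[it, p + j]) < dll:
                    gm[j] = g_new
                    wm = w_new
                    Em = E_new

        # --- horseshoe Gibbs updates (inverse-gamma augmentation) ---
        # scales clamped to [1e-12, 1e12] against float underflow in the
        # l^2 <-> nu recursion when a coefficient sits at zero
        for j in range(p):
            l2l[j] = min(max(
                (1.0 / nul[j] + gl[j] * gl[j] / (2.0 * tau2l)) / expo[it, j],
                1e-12), 1e12)
            nul[j] = min(max(
                (1.0 + 1.0 / l2l[j]) / expo[it, p + j], 1e-12), 1e12)
            l2m[j] = min(max(
                (1.0 / num[j] + gm[j] * gm[j] / (2.0 * tau2m)) / expo[it, 2 * p + j],
                1e-12), 1e12)
            num[j] = min(max(
                (1.0 + 1.0 / l2m[j]) / expo[it, 3 * p + j], 1e-12), 1e12)
        sl = 0.0
        sm = 0.0
        for j in range(p):
            sl += gl[j] * gl[j] / (2.0 * l2l[j])
            sm += gm[j] * gm[j] / (2.0 * l2m[j])
        tau2l = min(max((1.0 / xil + sl) / gam_tau[it, 0], 1e-12), 1e12)
        xil = min(max((1.0 + 1.0 / tau2l) / expo[it, 4 * p], 1e-12), 1e12)
        tau2m = min(max((1.0 / xim + sm) / gam_tau[it, 1], 1e-12), 1e12)
        xim = min(max((1.0 + 1.0 / tau2m) / expo[it, 4 * p + 1], 1e-12), 1e12)

        # --- proposal adaptation, burn-in only ---
        if it < burnin and (it + 1) % 200 == 0:
            for idx in range(2 + 2 * p):
                if tries[idx] > 0:
                    r = acc[idx] / tries[idx]
                    f = 1.0
                    if r > 0.45:
                        f = 1.2
                    elif r < 0.2:
                        f = 1.0 / 1.2
                    if idx == 0:
                        s_lam0 *= f
                    elif idx == 1:
                        s_mu0 *= f
                    elif idx < 2 + p:
                        s_gl[idx - 2] *= f
                    else:
                        s_gm[idx - 2 - p] *= f
                acc[idx] = 0.0
                tries[idx] = 0.0

        # --- record ---
        if it >= burnin and (it - burnin) % sample_every == 0:
            ll = (
                B * np.log(lam0) + Sb @ gl - lam0 * El
                + D * np.log(mu0) + Sd @ gm - mu0 * Em
            )
            lp = (
                (a0 - 1.0) * np.log(lam0) - b0 * lam0
                + (a0 - 1.0) * np.log(mu0) - b0 * mu0
            )
            for j in range(p):
                lp += (
                    -0.5 * np.log(2.0 * np.pi * l2l[j] * tau2l)
                    - gl[j] * gl[j] / (2.0 * l2l[j] * tau2l)
                )
                lp += (
                    -0.5 * np.log(2.0 * np.pi * l2m[j] * tau2m)
                    - gm[j] * gm[j] / (2.0 * l2m[j] * tau2m)
                )
                lp += LOG_2_OVER_PI - np.log(1.0 + l2l[j])
                lp += LOG_2_OVER_PI - np.log(1.0 + l2m[j])
            lp += LOG_2_OVER_PI - np.log(1.0 + tau2l)
            lp += LOG_2_OVER_PI - np.log(1.0 + tau2m)
            trace[s_idx, 0] = ll + lp
            trace[s_idx, 1] = lp
            trace[s_idx, 2] = ll
            params[s_idx, 0] = lam0
            params[s_idx, 1] = mu0
            for j in range(p):
                params[s_idx, 2 + j] = gl[j]
                params[s_idx, 2 + p + j] = gm[j]
                omegas[s_idx, j] = l2l[j] / (1.0 + l2l[j])
                omegas[s_idx, p + j] = l2m[j] / (1.0 + l2m[j])
            s_idx += 1

    return trace[:s_idx], params[:s_idx], omegas[:s_idx]
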