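"""Numba inner loops for the per-SNP sweeps.

Both engines visit SNPs in input order, keeping an O(n) running residual
r = y - X beta - Z g - W v. For SNP i the corrected residual is
e* = r + Z_i g_i, the data projection is rhs = Z_i' E^-1 e*, and the
component log-score is

    L_k = -1/2 log(s2_k z'E^-1 z + se2)
          + 1/2 q s2_k / (se2 (s2_k z'E^-1 z + se2)) + log Pr_k,

with q = rhs^2 (+ t_i in the EM engine, where t_i is the PEV trace
correction) and the k=1 spike reducing to -1/2 log se2 + log Pr_1.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _component_scores(rhs_sq, zEz_i, comp_var, sigma_e2, logPr, out):
    lmax = -1e300
    for k in range(4):
        if comp_var[k] == 0.0:
            lk = -0.5 * np.log(sigma_e2) + logPr[k]
        else:
            d = comp_var[k] * zEz_i + sigma_e2
            lk = -0.5 * np.log(d) + 0.5 * rhs_sq * comp_var[k] / (sigma_e2 * d) + logPr[k]
        out[k] = lk
        if lk > lmax:
            lmax = lk
    s = 0.0
    for k in range(4):
        out[k] = np.exp(out[k] - lmax)
        s += out[k]
    for k in range(4):
        out[k] /= s


@njit(cache=True)
def em_sweep(Z, Einv, resid, g, zEz, t, comp_var, sigma_e2, logPr, P, pinned):
    """One full EM pass over all SNPs; updates resid, g and P in place."""
    n, m = Z.shape
    probs = np.empty(4)
    for i in range(m):
        gi = g[i]
        rhs = 0.0
        for a in range(n):
            rhs += Z[a, i] * Einv[a] * (resid[a] + Z[a, i] * gi)
        if pinned >= 0:
            for k in range(4):
                probs[k] = 0.0
            probs[pinned] = 1.0
        else:
            q = rhs * rhs + t[i]
            if q < 0.0:
                q = 0.0
            _component_scores(q, zEz[i], comp_var, sigma_e2, logPr, probs)
        for k in range(4):
            P[i, k] = probs[k]
        # slab-conditional shrinkage times the slab mass: the mixture
        # posterior mean, zero in the all-spike limit
        shrink = 0.0
        for k in range(1, 4):
            shrink += probs[k] / comp_var[k]
        denom = zEz[i] + sigma_e2 * shrink
        gnew = (1.0 - probs[0]) * rhs / denom if denom > 0.0 else 0.0
        delta = gnew - gi
        if delta != 0.0:
            for a in range(n):
                resid[a] -= Z[a, i] * delta
        g[i] = gnew


@njit(cache=True)
def mcmc_sweep(Z, Einv, resid, g, zEz, comp_var, sigma_e2, logPr, active, pinned,
               unif, norm, counts, P_iter):
    """One Gibbs pass over all SNPs (steps 5-7); updates resid and g in place.

    ``unif``/``norm`` are pre-drawn random numbers, one of each per SNP, so
    the draw order is fixed by SNP index regardless of the active mask.
    Deactivated SNPs keep g_i = 0 and count in the spike component.
    Returns nothing; per-iteration component counts go to ``counts`` and the
    per-SNP component probabilities to ``P_iter`` (-1 rows for inactive SNPs).
    """
    n, m = Z.shape
    probs = np.empty(4)
    for i in range(m):
        if not active[i]:
            counts[0] += 1
            P_iter[i, 0] = -1.0
            continue
        gi = g[i]
        rhs = 0.0
        for a in range(n):
            rhs += Z[a, i] * Einv[a] * (resid[a] + Z[a, i] * gi)
        _component_scores(rhs * rhs, zEz[i], comp_var, sigma_e2, logPr, probs)
        for k in range(4):
            P_iter[i, k] = probs[k]
        if pinned >= 0:
            k_draw = pinned
        else:
            u = unif[i]
            acc = 0.0
            k_draw = 3
            for k in range(4):
                acc += probs[k]
                if u < acc:
                    k_draw = k
                    break
        counts[k_draw] += 1
        if k_draw == 0 or comp_var[k_draw] == 0.0:
            gnew = 0.0
        else:
            denom = zEz[i] + sigma_e2 / comp_var[k_draw]
            if denom <= 0.0:
                gnew = 0.0
            else:
                mu = rhs / denom
                sd = np.sqrt(sigma_e2 / denom)
                gnew = mu + sd * norm[i]
        delta = gnew - gi
        if delta != 0.0:
            for a in range(n):
                resid[a] -= Z[a, i] * delta
        g[i] = gnew
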