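"""No-burn-in Gibbs sampler seeded by the EM output.

Each iteration runs the full conditional cycle: error variance (scaled
inverse-chi-square), fixed effects (multivariate normal), polygenic variance
and effects, then a per-SNP pass sampling the mixture indicator from the
softmax of the component log-likelihoods and the effect from its conjugate
normal, and finally the mixing proportions from Dirichlet(counts + 1).

A speed-up scheme averages each SNP's spike probability P(i,1) over the
first ``speedup_window`` iterations; SNPs whose average is at least the
threshold ``a`` are permanently deactivated (effect fixed at zero, still
counted in the spike component of the Dirichlet update). Posterior means
average over all iterations - the EM start replaces burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import mcmc_sweep
from .datamodel import MixturePrior, ModelState, TraitData
from .em import PR_FLOOR, em_update_beta
from .gblup import VarianceComponents

__all__ = [
    "McmcConfig",
    "McmcTrace",
    "PosteriorSummary",
    "sample_sigma_e",
    "sample_beta",
    "sample_sigma_a",
    "sample_v",
    "mcmc_component_loglik",
    "sample_snp",
    "apply_speedup",
    "sample_pr",
    "run_mcmc",
]


@dataclass
class McmcConfig:
    n_iter: int = 4000
    burn_in: int = 0  # iterations excluded from posterior averages (pure-MCMC mode)
    speedup_enabled: bool = True
    speedup_window: int = 500
    speedup_threshold: float = 0.9
    speedup_use_indicator: bool = False  # deactivate on sampled-spike frequency
    seed: int = 0
    record_samples: bool = False
    sigma_a_df_n: bool = False  # use df n-2 instead of q-2 for the polygenic variance
    pin_component: int | None = None
    update_sigma_e: bool = True
    update_pr: bool = True

    def __post_init__(self) -> None:
        if not (0.5 <= self.speedup_threshold <= 1.0):
            raise ValueError("speedup threshold must be in [0.5, 1]")
        if self.speedup_enabled and self.n_iter > 0 and self.speedup_window >= self.n_iter:
            raise ValueError("speedup_window must be smaller than n_iter")
        if self.burn_in < 0 or (self.n_iter > 0 and self.burn_in >= self.n_iter):
            raise ValueError("burn_in must be in [0, n_iter)")


@dataclass
class McmcTrace:
    sigma_e2: np.ndarray
    sigma_a2: np.ndarray
    Pr: np.ndarray          # n_iter x 4
    counts: np.ndarray      # n_iter x 4, sums to m each iteration
    g_samples: np.ndarray | None = None
    # final chain state, for residual-cache audits
    final_residual: np.ndarray | None = None
    final_g: np.ndarray | None = None
    final_beta: np.ndarray | None = None
    final_v: np.ndarray | None = None


@dataclass
class PosteriorSummary:
    g_mean: np.ndarray
    g_sd: np.ndarray
    beta_mean: np.ndarray
    v_mean: np.ndarray
    Pr_mean: np.ndarray
    P_mean: np.ndarray       # m x 4 averaged responsibilities (pre-deactivation for inactive SNPs)
    pip: np.ndarray          # 1 - P_mean[:, 0]
    component_counts: np.ndarray  # posterior mean per-iteration counts, sums to m
    active: np.ndarray
    sigma_e2_mean: float
    sigma_a2_mean: float
    n_iter: int


def sample_sigma_e(residual, E_diag, rng):
    """Scaled Inv-chi2(n-2, y*'E^-1 y*/(n-2)) drawn as SS / chi2_{n-2}."""
    n = len(residual)
    ss = float(residual @ (residual / E_diag))
    if ss <= 0:
        raise ValueError("degenerate zero residual sum of squares")
    return ss / rng.chisquare(n - 2)


def sample_beta(y_adj, X, E_diag, sigma_e2, rng):
    """Draw beta ~ N((X'E^-1X)^-1 X'E^-1 y_adj, (X'E^-1X)^-1 se2)."""
    XtEi = X.T / E_diag[None, :]
    XtEiX = XtEi @ X
    try:
        L = np.linalg.cholesky(np.linalg.inv(XtEiX) * sigma_e2)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("X'E^-1X singular: X rank deficient") from exc
    mu = np.linalg.solve(XtEiX, XtEi @ y_adj)
    return mu + L @ rng.standard_normal(X.shape[1])


def sample_sigma_a(v, Ainv, sigma_a2_old, rng, df=None):
    """Scaled Inv-chi2 for the polygenic variance; df defaults to q-2."""
    q = len(v)
    ss = float(v @ Ainv @ v)
    if ss <= 0:
        import warnings

        warnings.warn("polygenic effects all zero; keeping previous sigma_a2",
                      UserWarning, stacklevel=2)
        return sigma_a2_old
    df = (q - 2) if df is None else df
    return ss / rng.chisquare(df)


def sample_v(y_adj, W, Ainv, E_diag, sigma_a2, sigma_e2, rng):
    """Draw v ~ N(mu, se2 (W'E^-1W + A^-1 se2/sa2)^-1)."""
    WtEi = W.T / E_diag[None, :]
    prec = WtEi @ W + Ainv * (sigma_e2 / sigma_a2)
    cov = sigma_e2 * np.linalg.inv(prec)
    mu = np.linalg.solve(prec, WtEi @ y_adj)
    L = np.linalg.cholesky(0.5 * (cov + cov.T))
    return mu + L @ rng.standard_normal(len(mu))


def mcmc_component_loglik(rhs, zEz_i, sigma_e2, prior: MixturePrior, Pr=None):
    """4-vector L(g_i | s2_k); ``rhs`` is Z_i'E^-1 e* for the corrected residual."""
    Pr = prior.Pr if Pr is None else np.asarray(Pr, dtype=float)
    logPr = np.log(np.maximum(Pr, PR_FLOOR))
    s2 = prior.component_variances
    L = np.empty(4)
    L[0] = -0.5 * np.log(sigma_e2) + logPr[0]
    for k in range(1, 4):
        d = s2[k] * zEz_i + sigma_e2
        L[k] = -0.5 * np.log(d) + 0.5 * rhs * rhs * s2[k] / (sigma_e2 * d) + logPr[k]
    if not np.all(np.isfinite(L)):
        raise FloatingPointError(f"non-finite component log-likelihoods: {L}")
    return L


def sample_snp(rhs, zEz_i, loglik, sigma_e2, prior: MixturePrior, rng):
    """Draw the mixture indicator and, for slab components, the effect."""
    p = np.exp(loglik - loglik.max())
    p /= p.sum()
    k = int(rng.choice(4, p=p))
    if k == 0:
        return k, 0.0
    denom = zEz_i + sigma_e2 / prior.component_variances[k]
    mu = rhs / denom
    s = sigma_e2 / denom
    return k, mu + np.sqrt(s) * rng.standard_normal()


def apply_speedup(p1_mean, threshold):
    """Mask of SNPs to deactivate: average spike probability >= threshold."""
    return p1_mean >= threshold


def sample_pr(counts, rng):
    """Pr ~ Dirichlet(counts + 1)."""
    return rng.dirichlet(np.asarray(counts, dtype=float) + 1.0)


def run_mcmc(trait: TraitData, Z, prior: MixturePrior, state0: ModelState,
             config: McmcConfig = None, A=None):
    """Run the Gibbs cycle for config.n_iter iterations with no burn-in."""
    config = config or McmcConfig()
    rng = np.random.default_rng(config.seed)
    Z = np.asfortranarray(Z, dtype=np.float64)
    n, m = Z.shape
    y, X, E = trait.y, trait.X, trait.E_diag
    Einv = 1.0 / E
    W = trait.W
    comp_var = prior.component_variances
    zEz = np.einsum("ij,ij->j", Z, Einv[:, None] * Z)
    pinned = -1 if config.pin_component is None else int(config.pin_component)

    g = state0.g.astype(np.float64).copy()
    beta = state0.beta.copy()
    sigma_e2 = float(state0.sigma_e2)
    sigma_a2 = float(state0.sigma_a2)
    Pr = state0.Pr.copy()
    active = state0.active.copy()
    g[~active] = 0.0
    poly = sigma_a2 > 0 and A is not None and W is not None
    v = state0.v.copy() if poly else np.zeros(0)
    Ainv = np.linalg.inv(A) if poly else None
    residual = y - X @ beta - Z @ g - (W @ v if poly else 0.0)

    n_iter = config.n_iter
    if n_iter == 0:
        return _summary_from_state(g, beta, v, Pr, state0.P, active, sigma_e2,
                                   sigma_a2, m), McmcTrace(
            sigma_e2=np.zeros(0), sigma_a2=np.zeros(0),
            Pr=np.zeros((0, 4)), counts=np.zeros((0, 4), dtype=np.int64))

    g_sum = np.zeros(m)
    g_sumsq = np.zeros(m)
    beta_sum = np.zeros_like(beta)
    v_sum = np.zeros_like(v)
    Pr_sum = np.zeros(4)
    P_accum = np.zeros((m, 4))
    P_count = np.zeros(m)
    p1_window = np.zeros(m)
    tr_se = np.zeros(n_iter)
    tr_sa = np.zeros(n_iter)
    tr_Pr = np.zeros((n_iter, 4))
    tr_counts = np.zeros((n_iter, 4), dtype=np.int64)
    g_samples = np.zeros((n_iter, m)) if config.record_samples else None
    P_iter = np.zeros((m, 4))

    for it in range(n_iter):
        if config.update_sigma_e:
            sigma_e2 = sample_sigma_e(residual, E, rng)
        # fixed effects
        y_adj = y - Z @ g - (W @ v if poly else 0.0)
        beta_new = sample_beta(y_adj, X, E, sigma_e2, rng)
        residual += X @ (beta - beta_new)
        beta = beta_new
        if poly:
            sigma_a2 = sample_sigma_a(v, Ainv, sigma_a2, rng,
                                      df=(n - 2) if config.sigma_a_df_n else None)
            v_new = sample_v(y - Z @ g - X @ beta, W, Ainv, E, sigma_a2, sigma_e2, rng)
            residual += W @ (v - v_new)
            v = v_new
        # per-SNP Gibbs pass
        unif = rng.random(m)
        norm = rng.standard_normal(m)
        counts = np.zeros(4, dtype=np.int64)
        logPr = np.log(np.maximum(Pr, PR_FLOOR))
        mcmc_sweep(Z, Einv, residual, g, zEz, comp_var, sigma_e2, logPr,
                   active, pinned, unif, norm, counts, P_iter)
        if config.update_pr and pinned < 0:
            Pr = sample_pr(counts, rng)
        # accumulate (post burn-in only; the hybrid uses burn_in = 0)
        live = P_iter[:, 0] >= 0
        if it >= config.burn_in:
            g_sum += g
            g_sumsq += g * g
            beta_sum += beta
            if poly:
                v_sum += v
            Pr_sum += Pr
            P_accum[live] += P_iter[live]
            P_count[live] += 1
        if it < config.speedup_window:
            if config.speedup_use_indicator:
                p1_window[live] += (g[live] == 0.0)
                p1_window[~live] += 1.0
            else:
                p1_window[live] += P_iter[live, 0]
                p1_window[~live] += 1.0
        tr_se[it] = sigma_e2
        tr_sa[it] = sigma_a2
        tr_Pr[it] = Pr
        tr_counts[it] = counts
        if g_samples is not None:
            g_samples[it] = g
        # speed-up decision, once, at the end of the window
        if config.speedup_enabled and it + 1 == config.speedup_window:
            drop = active & apply_speedup(p1_window / config.speedup_window,
                                          config.speedup_threshold)
            if np.any(drop):
                residual += Z[:, drop] @ g[drop]
                g[drop] = 0.0
                active[drop] = False

    n_kept = n_iter - config.burn_in
    P_mean = np.where(P_count[:, None] > 0, P_accum / np.maximum(P_count, 1)[:, None], 0.0)
    g_mean = g_sum / n_kept
    g_var = np.maximum(g_sumsq / n_kept - g_mean**2, 0.0)
    summary = PosteriorSummary(
        g_mean=g_mean,
        g_sd=np.sqrt(g_var),
        beta_mean=beta_sum / n_kept,
        v_mean=v_sum / n_kept if poly else np.zeros(0),
        Pr_mean=Pr_sum / n_kept,
        P_mean=P_mean,
        pip=1.0 - P_mean[:, 0],
        component_counts=tr_counts[config.burn_in:].mean(axis=0),
        active=active,
        sigma_e2_mean=float(tr_se[config.burn_in:].mean()),
        sigma_a2_mean=float(tr_sa[config.burn_in:].mean()),
        n_iter=n_iter,
    )
    trace = McmcTrace(sigma_e2=tr_se, sigma_a2=tr_sa, Pr=tr_Pr,
                      counts=tr_counts, g_samples=g_samples,
                      final_residual=residual, final_g=g, final_beta=beta,
                      final_v=v)
    return summary, trace


def _summary_from_state(g, beta, v, Pr, P, active, sigma_e2, sigma_a2, m):
    return PosteriorSummary(
        g_mean=g.copy(), g_sd=np.zeros(m), beta_mean=beta.copy(),
        v_mean=v.copy(), Pr_mean=Pr.copy(), P_mean=P.copy(),
        pip=1.0 - P[:, 0], component_counts=P.sum(axis=0),
        active=active.copy(), sigma_e2_mean=sigma_e2,
        sigma_a2_mean=sigma_a2, n_iter=0,
    )
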