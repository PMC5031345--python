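"""Expectation-maximisation engine with PEV correction.

Iterates, until convergence of the SNP-effect vector, full sweeps of

  * per-SNP responsibilities P(i,k), with the fixed PEV trace t_i added to
    the squared data projection to account for the error in all other SNP
    effects,
  * MAP SNP-effect updates
    g_i = (Z_i'E^-1 Z_i + se2 sum_{k>=2} P(i,k)/s2_k)^-1 Z_i'E^-1 e*,

followed by global updates of the mixing proportions
Pr_k = (sum_i P(i,k) + 1)/(m + 4), the error variance
se2 = (e'E^-1 e + tr(E^-1 PEV))/n, the fixed effects (GLS given g, v) and
the polygenic effects. The genetic and polygenic variances stay fixed at
their input (GBLUP) values. The run is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import em_sweep
from .datamodel import MixturePrior, ModelState, TraitData
from .gblup import PevCache, VarianceComponents

__all__ = [
    "EmConfig",
    "EmResult",
    "residual_correct",
    "em_responsibilities",
    "em_update_snp",
    "em_update_pr",
    "em_update_sigma_e",
    "em_update_beta",
    "em_update_v",
    "em_check_convergence",
    "run_em",
]

PR_FLOOR = 1e-12


@dataclass
class EmConfig:
    g_init: float = 0.01
    Pr_init: tuple = (0.5, 0.487, 0.01, 0.003)
    tol: float = 1e-10
    max_iter: int = 1000
    update_polygenic: bool = True
    update_sigma_e: bool = True
    update_pr: bool = True
    pin_component: int | None = None  # force all responsibilities to one component
    # How the PEV trace t_i enters the responsibility scores:
    #   "minus": use max(rhs^2 - t_i, 0), discounting the estimation-error
    #            energy of all other SNP effects from the observed projection
    #            (default; reproduces the over-shrinkage of the EM-only variant),
    #   "plus":  use rhs^2 + t_i (expectation over the missing corrected
    #            residual around its posterior mean),
    #   "off":   ignore t_i.
    pev_mode: str = "minus"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        pr = np.asarray(self.Pr_init, dtype=float)
        if abs(pr.sum() - 1) > 1e-8 or np.any(pr < 0):
            raise ValueError("Pr_init must lie on the simplex")
        if self.pev_mode not in ("minus", "plus", "off"):
            raise ValueError("pev_mode must be 'minus', 'plus' or 'off'")


@dataclass
class EmResult:
    state: ModelState
    n_iterations: int
    converged: bool
    trajectory: np.ndarray  # convergence statistic per sweep


def residual_correct(residual, Z, g, i):
    """e* for SNP i: add the SNP's own contribution back to the residual."""
    return residual + Z[:, i] * g[i]

def em_responsibilities(rhs, zEz_i, t_i, sigma_e2, prior: MixturePrior, Pr=None):
    """P(i, .) from the expected log scores; ``rhs`` is Z_i'E^-1 e*."""
    Pr = prior.Pr if Pr is None else np.asarray(Pr, dtype=float)
    logPr = np.log(np.maximum(Pr, PR_FLOOR))
    s2 = prior.component_variances
    q = max(rhs * rhs + t_i, 0.0)  # t_i may arrive signed (pev_mode "minus")
    l = np.empty(4)
    l[0] = -0.5 * np.log(sigma_e2) + logPr[0]
    for k in range(1, 4):
        d = s2[k] * zEz_i + sigma_e2
        l[k] = -0.5 * np.log(d) + 0.5 * q * s2[k] / (sigma_e2 * d) + logPr[k]
    if not np.all(np.isfinite(l)):
        raise FloatingPointError(f"non-finite component scores: {l}")
    p = np.exp(l - l.max())
    return p / p.sum()

def em_update_snp(rhs, zEz_i, P_row, sigma_e2, prior: MixturePrior):
    """Posterior-mean update for one SNP effect.

    Slab-conditional shrinkage (Z_i'E^-1 Z_i + se2 sum_{k>=2} P(i,k)/s2_k)^-1
    scaled by the slab mass 1 - P(i,1), so the estimate goes to zero as the
    spike responsibility goes to one; returns 0 for a zero-precision system.
    """
    s2 = prior.component_variances
    shrink = sum(P_row[k] / s2[k] for k in range(1, 4))
    denom = zEz_i + sigma_e2 * shrink
    return (1.0 - P_row[0]) * rhs / denom if denom > 0 else 0.0

def em_update_pr(P):
    """Lagrange-multiplier update: Pr_k = (sum_i P(i,k) + 1)/(m + 4)."""
    col = P.sum(axis=0)
    return (col + 1.0) / (P.shape[0] + 4.0)

def em_update_sigma_e(residual, E_diag, trace_resid, n=None):
    """se2 = (e'E^-1 e + tr(E^-1 PEV))/n."""
    n = len(residual) if n is None else n
    val = (residual @ (residual / E_diag) + trace_resid) / n
    if val <= 0:
        raise FloatingPointError("non-positive error variance update")
    return float(val)

def em_update_beta(y_adj, X, E_diag):
    """GLS fixed effects: (X'E^-1X)^-1 X'E^-1 (y - Zg - Wv)."""
    XtEi = X.T / E_diag[None, :]
    return np.linalg.solve(XtEi @ X, XtEi @ y_adj)

def em_update_v(y_adj, W, A, E_diag, sigma_a2, sigma_e2):
    """Polygenic BLUP given the current g, beta:
    v = (W'E^-1W sa2 + se2 A^-1)^-1 sa2 W'E^-1 (y - Zg - X beta)."""
    Ainv = np.linalg.inv(A)
    WtEi = W.T / E_diag[None, :]
    lhs = sigma_a2 * (WtEi @ W) + sigma_e2 * Ainv
    return np.linalg.solve(lhs, sigma_a2 * (WtEi @ y_adj))

def em_check_convergence(g_new, g_old, tol):
    """Relative squared change (dg'dg)/(g'g); converged iff <= tol."""
    num = float((g_new - g_old) @ (g_new - g_old))
    den = float(g_new @ g_new)
    if den == 0.0:
        return (num == 0.0), np.inf if num > 0 else 0.0
    stat = num / den
    return stat <= tol, stat


def run_em(trait: TraitData, Z, prior: MixturePrior, pev: PevCache,
           vc: VarianceComponents, A=None, config: EmConfig = None,
           verbose: bool = False) -> EmResult:
    """Run the EM module to convergence (steps: sweep SNPs, then globals)."""
    config = config or EmConfig()
    Z = np.asfortranarray(Z, dtype=np.float64)
    n, m = Z.shape
    y, X, E = trait.y, trait.X, trait.E_diag
    Einv = 1.0 / E
    W = trait.W
    comp_var = prior.component_variances
    zEz = np.einsum("ij,ij->j", Z, Einv[:, None] * Z)

    g = np.full(m, config.g_init, dtype=np.float64)
    Pr = np.asarray(config.Pr_init, dtype=float).copy()
    sigma_e2 = float(vc.sigma_e2)
    sigma_a2 = float(vc.sigma_a2)
    poly = config.update_polygenic and sigma_a2 > 0 and A is not None and W is not None
    v = np.zeros(A.shape[0]) if poly else np.zeros(0)
    beta = em_update_beta(y - Z @ g, X, E)
    residual = y - X @ beta - Z @ g
    if poly:
        residual -= W @ v
    P = np.full((m, 4), 0.25)
    pinned = -1 if config.pin_component is None else int(config.pin_component)
    t = np.ascontiguousarray(pev.trace_terms, dtype=np.float64)
    if config.pev_mode == "minus":
        t = -t
    elif config.pev_mode == "off":
        t = np.zeros_like(t)

    traj = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        g_old = g.copy()
        logPr = np.log(np.maximum(Pr, PR_FLOOR))
        em_sweep(Z, Einv, residual, g, zEz, t, comp_var, sigma_e2, logPr, P, pinned)
        # global updates once per sweep
        if config.update_pr and pinned < 0:
            Pr = em_update_pr(P)
        if config.update_sigma_e:
            sigma_e2 = em_update_sigma_e(residual, E, pev.trace_resid)
        y_adj = y - Z @ g - (W @ v if poly else 0.0)
        beta = em_update_beta(y_adj, X, E)
        if poly:
            v = em_update_v(y - Z @ g - X @ beta, W, A, E, sigma_a2, sigma_e2)
        residual = y - X @ beta - Z @ g - (W @ v if poly else 0.0)
        converged, stat = em_check_convergence(g, g_old, config.tol)
        traj.append(stat)
        if verbose:
            print(f"sweep {it}: stat={stat:.3e} se2={sigma_e2:.6g} Pr={np.round(Pr, 4)}")
        if converged:
            break
    state = ModelState(
        g=g, beta=beta, v=v, sigma_e2=sigma_e2, sigma_a2=sigma_a2,
        P=P, Pr=Pr, active=np.ones(m, dtype=bool), residual=residual,
    )
    return EmResult(state=state, n_iterations=it, converged=converged,
                    trajectory=np.asarray(traj))
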