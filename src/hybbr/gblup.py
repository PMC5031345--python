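"""GBLUP baseline, EM-REML variance estimation, and the PEV cache.

GBLUP treats the total genomic value u ~ N(0, G sigma_g^2) with optional
pedigree polygenic term v ~ N(0, A sigma_a^2), so the phenotypic covariance
is V = G sg2 + W A W' sa2 + E se2. Fixed effects are estimated by GLS and
random effects by BLUP.

The prediction-error variance (PEV) of the genomic value,

    PEV = G sg2 - G sg2 P_V G sg2,
    P_V = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1,

feeds the EM module: its per-SNP trace corrections
t_i = Z_i' E^-1 PEV E^-1 Z_i account for the uncertainty in all other SNP
effects when the responsibility of SNP i is evaluated, and tr(E^-1 PEV)
enters the error-variance update. The cache is computed once, before the EM
iterations, and held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "VarianceComponents",
    "PevCache",
    "GblupResult",
    "gblup_fit",
    "estimate_variances_emreml",
    "compute_pev",
]


@dataclass
class VarianceComponents:
    sigma_e2: float
    sigma_g2: float
    sigma_a2: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma_e2 <= 0 or self.sigma_g2 <= 0 or self.sigma_a2 < 0:
            raise ValueError("require sigma_e2 > 0, sigma_g2 > 0, sigma_a2 >= 0")

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass
class PevCache:
    PEV: np.ndarray
    trace_terms: np.ndarray  # t_i = Z_i' E^-1 PEV E^-1 Z_i
    trace_resid: float  # tr(E^-1 PEV)


@dataclass
class GblupResult:
    beta: np.ndarray
    u: np.ndarray  # genomic values, n-vector
    v: np.ndarray  # polygenic values, q-vector (empty if disabled)
    residuals: np.ndarray
    gebv: np.ndarray
    vinv_resid: np.ndarray = None  # V^-1 (y - X beta); SNP-effect backsolve

    def snp_effects(self, Z, sigma_g2, divisor=None):
        """Equivalent SNP-BLUP effects g = (sg2/m) Z' V^-1 (y - X beta),
        for G = ZZ'/m; lets GEBV be scored on out-of-sample genotypes."""
        Z = np.asarray(Z)
        d = Z.shape[1] if divisor is None else divisor
        return (sigma_g2 / d) * (Z.T @ self.vinv_resid)


def _build_v(trait, G, A, vc):
    n = trait.n
    V = vc.sigma_g2 * G + np.diag(vc.sigma_e2 * trait.E_diag)
    if vc.sigma_a2 > 0 and A is not None:
        W = trait.W if trait.W is not None else np.eye(n)
        V = V + vc.sigma_a2 * (W @ A @ W.T)
    return 0.5 * (V + V.T)


def _solve_gls(V, X, y):
    try:
        cf = linalg.cho_factor(V)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"phenotypic covariance V is not positive definite "
            f"(cond ~ {np.linalg.cond(V):.3e})"
        ) from exc
    ViX = linalg.cho_solve(cf, X)
    Viy = linalg.cho_solve(cf, y)
    XtViX = X.T @ ViX
    try:
        beta = np.linalg.solve(XtViX, X.T @ Viy)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("X'V^-1X singular: X rank deficient") from exc
    return beta, cf


def gblup_fit(trait, G, A=None, vc: VarianceComponents = None) -> GblupResult:
    """Fit the GBLUP mixed model and return BLUP genomic values.

    beta_hat = (X'V^-1X)^-1 X'V^-1 y, u_hat = G sg2 V^-1 (y - X beta_hat),
    v_hat = sa2 A W' V^-1 (y - X beta_hat). GEBV = u_hat (+ W v_hat when the
    polygenic term is enabled).
    """
    y, X = trait.y, trait.X
    V = _build_v(trait, G, A, vc)
    beta, cf = _solve_gls(V, X, y)
    r = y - X @ beta
    Vir = linalg.cho_solve(cf, r)
    u = vc.sigma_g2 * (G @ Vir)
    gebv = u.copy()
    if vc.sigma_a2 > 0 and A is not None:
        W = trait.W if trait.W is not None else np.eye(trait.n)
        v = vc.sigma_a2 * (A @ (W.T @ Vir))
        gebv = gebv + W @ v
    else:
        v = np.zeros(0)
    residuals = y - X @ beta - gebv
    return GblupResult(beta=beta, u=u, v=v, residuals=residuals, gebv=gebv,
                       vinv_resid=Vir)


def compute_pev(trait, Z, G, A=None, vc: VarianceComponents = None) -> PevCache:
    """Prediction-error covariance of the GBLUP genomic value plus traces.

    With fixed effects absorbed through the projection
    P_V = V^-1 - V^-1 X (X'V^-1 X)^-1 X' V^-1:

        PEV = Cov(u - u_hat) = G sg2 - (G sg2) P_V (G sg2).

    The per-SNP corrections t_i = Z_i' E^-1 PEV E^-1 Z_i are computed via
    M = E^-1 PEV E^-1 and held constant over the EM iterations.
    """
    V = _build_v(trait, G, A, vc)
    X = trait.X
    cf = linalg.cho_factor(V)
    Vi = linalg.cho_solve(cf, np.eye(trait.n))
    ViX = Vi @ X
    P_V = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
    Gs = vc.sigma_g2 * G
    PEV = Gs - Gs @ P_V @ Gs
    PEV = 0.5 * (PEV + PEV.T)
    Einv = 1.0 / trait.E_diag
    M = (Einv[:, None] * PEV) * Einv[None, :]
    Z = np.asarray(Z)
    trace_terms = np.einsum("ij,ij->j", Z, M @ Z)
    trace_terms = np.maximum(trace_terms, 0.0)
    trace_resid = float(np.sum(Einv * np.diag(PEV)))
    return PevCache(PEV=PEV, trace_terms=trace_terms, trace_resid=trace_resid)


def reml_loglik(trait, G, vc) -> float:
    """Restricted log-likelihood of (sigma_g2, sigma_e2) under V = G sg2 + E se2."""
    V = _build_v(trait, G, None, vc)
    X, y = trait.X, trait.y
    sign, logdetV = np.linalg.slogdet(V)
    beta, cf = _solve_gls(V, X, y)
    r = y - X @ beta
    Vir = linalg.cho_solve(cf, r)
    ViX = linalg.cho_solve(cf, X)
    sign2, logdetX = np.linalg.slogdet(X.T @ ViX)
    return -0.5 * (logdetV + logdetX + r @ Vir)


def estimate_variances_emreml(trait, G, A=None, tol=1e-6, max_iter=500,
                              return_trajectory=False):
    """EM-REML for (sigma_g2, sigma_e2) under y = X beta + u + e, u ~ N(0, G sg2).

    Works on error contrasts: with K an orthonormal basis of the complement
    of col(X) and E^-1/2-weighted data, z = K'y has independent rotated
    coordinates z_j ~ N(0, sg2 d_j + se2) after a one-off eigendecomposition
    of K'GK. EM then alternates the closed-form conditional moments of the
    rotated genetic values, so each iteration is O(n) and the restricted
    log-likelihood never decreases. Non-convergence returns the last iterate
    with ``converged = False``.
    """
    y, X = trait.y, trait.X
    n, p = trait.n, X.shape[1]
    if n < p + 2:
        raise ValueError("need n >= p + 2 records for REML")
    Eirt = 1.0 / np.sqrt(trait.E_diag)
    yw = Eirt * y
    Xw = Eirt[:, None] * X
    Gw = (Eirt[:, None] * G) * Eirt[None, :]
    # orthonormal error contrasts: last n-p columns of the full Q of Xw
    Q, _ = np.linalg.qr(Xw, mode="complete")
    K = Q[:, p:]
    d, U = np.linalg.eigh(K.T @ Gw @ K)
    d = np.maximum(d, 0.0)
    z = U.T @ (K.T @ yw)
    n_c = len(z)

    vary = float(np.var(yw))
    se2, sg2 = 0.5 * vary, 0.5 * vary
    traj = []
    converged = False
    for _ in range(max_iter):
        V = sg2 * d + se2
        traj.append(float(-0.5 * np.sum(np.log(V) + z * z / V)))
        u_mean = sg2 * d * z / V
        u_var = sg2 * d * se2 / V
        with np.errstate(divide="ignore", invalid="ignore"):
            gq = np.where(d > 0, (u_mean**2 + u_var) / np.maximum(d, 1e-300), 0.0)
        sg2_new = float(np.sum(gq)) / max(int((d > 0).sum()), 1)
        se2_new = float(np.sum((z - u_mean) ** 2 + u_var)) / n_c
        se2_new = max(se2_new, 1e-12 * vary)
        sg2_new = max(sg2_new, 1e-12 * vary)
        rel = max(abs(se2_new - se2) / se2, abs(sg2_new - sg2) / sg2)
        se2, sg2 = se2_new, sg2_new
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM-REML did not converge; returning last iterate",
                      UserWarning, stacklevel=2)
    vc = VarianceComponents(sigma_e2=se2, sigma_g2=sg2, sigma_a2=0.0,
                            converged=converged)
    if return_trajectory:
        return vc, np.asarray(traj)
    return vc
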