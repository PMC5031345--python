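"""Orchestration (GBLUP -> EM -> MCMC) and evaluation surfaces.

Prediction accuracy is the Pearson correlation between GEBV and the
validation phenotype, bias is the slope of the regression of phenotype on
GEBV (1 = unbiased), binary traits are scored by the area under the ROC
curve, and QTL mapping uses the posterior inclusion probability
PIP_i = sum_{k=2..4} P_bar(i,k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .datamodel import MixturePrior, TraitData, build_grm
from .em import EmConfig, run_em
from .gblup import VarianceComponents, compute_pev, estimate_variances_emreml, gblup_fit
from .mcmc import McmcConfig, PosteriorSummary, run_mcmc

__all__ = [
    "EvaluationReport",
    "HybbrResult",
    "run_hybbr",
    "predict_gebv",
    "accuracy_and_bias",
    "compute_auc",
    "qtl_report",
]


@dataclass
class EvaluationReport:
    accuracy: float | None
    bias: float | None
    auc: float | None
    component_counts: np.ndarray | None = None
    qtl_hits: pd.DataFrame | None = None


@dataclass
class HybbrResult:
    summary: PosteriorSummary
    em_result: object
    trace: object
    pev: object
    vc: VarianceComponents
    prior: MixturePrior


def run_hybbr(trait: TraitData, Z, vc: VarianceComponents = None, A=None,
              em_config: EmConfig = None, mcmc_config: McmcConfig = None,
              prior: MixturePrior = None, G=None, skip_em: bool = False,
              verbose: bool = False) -> HybbrResult:
    """Full hybrid pipeline: PEV from GBLUP, EM to convergence, then MCMC.

    ``mcmc_config.n_iter = 0`` gives an EM-only (emBayesR-style) run;
    ``skip_em = True`` gives a pure-MCMC run from the default start, which
    then needs its own burn-in.
    """
    Z = np.asfortranarray(Z, dtype=np.float64)
    if vc is None:
        G = build_grm(Z) if G is None else G
        vc = estimate_variances_emreml(trait, G)
    if prior is None:
        prior = MixturePrior(sigma_g2=vc.sigma_g2)
    em_config = em_config or EmConfig()
    mcmc_config = mcmc_config or McmcConfig()
    if G is None:
        G = build_grm(Z)
    pev = compute_pev(trait, Z, G, A=A, vc=vc)
    if skip_em:
        from .datamodel import ModelState

        m = Z.shape[1]
        q = A.shape[0] if (A is not None and vc.sigma_a2 > 0) else 0
        state0 = ModelState(
            g=np.zeros(m), beta=np.zeros(trait.X.shape[1]), v=np.zeros(q),
            sigma_e2=vc.sigma_e2, sigma_a2=vc.sigma_a2,
            P=np.full((m, 4), 0.25), Pr=np.asarray(em_config.Pr_init, dtype=float),
            active=np.ones(m, dtype=bool),
            residual=trait.y - trait.X @ np.zeros(trait.X.shape[1]),
        )
        em_result = None
    else:
        em_result = run_em(trait, Z, prior, pev, vc, A=A, config=em_config,
                           verbose=verbose)
        state0 = em_result.state
    summary, trace = run_mcmc(trait, Z, prior, state0, config=mcmc_config, A=A)
    if mcmc_config.n_iter == 0 and em_result is not None:
        summary = _em_only_summary(em_result)
    return HybbrResult(summary=summary, em_result=em_result, trace=trace,
                       pev=pev, vc=vc, prior=prior)


def _em_only_summary(em_result) -> PosteriorSummary:
    st = em_result.state
    m = len(st.g)
    return PosteriorSummary(
        g_mean=st.g.copy(), g_sd=np.zeros(m), beta_mean=st.beta.copy(),
        v_mean=st.v.copy(), Pr_mean=st.Pr.copy(), P_mean=st.P.copy(),
        pip=1.0 - st.P[:, 0], component_counts=st.P.sum(axis=0),
        active=st.active.copy(), sigma_e2_mean=st.sigma_e2,
        sigma_a2_mean=st.sigma_a2, n_iter=0,
    )


def predict_gebv(Z_val, summary: PosteriorSummary, include_polygenic: bool = False,
                 A_cross=None, A_ref=None, W_ref=None):
    """GEBV for validation individuals: Z_val g_bar (+ pedigree projection).

    Validation genotypes must be standardized with the reference allele
    frequencies. With ``include_polygenic`` the polygenic contribution is
    projected through the pedigree as A_cross A_ref^-1 v_bar.
    """
    Z_val = np.asarray(Z_val)
    if Z_val.shape[1] != len(summary.g_mean):
        raise ValueError(
            f"SNP-set mismatch: validation has {Z_val.shape[1]} SNPs, "
            f"model has {len(summary.g_mean)}")
    gebv = Z_val @ summary.g_mean
    if include_polygenic and len(summary.v_mean):
        if A_cross is None or A_ref is None:
            raise ValueError("A_cross and A_ref required for the polygenic projection")
        gebv = gebv + A_cross @ np.linalg.solve(A_ref, summary.v_mean)
    return gebv


def accuracy_and_bias(gebv, pheno):
    """(Pearson r, slope of phenotype regressed on GEBV)."""
    gebv = np.asarray(gebv, dtype=float)
    pheno = np.asarray(pheno, dtype=float)
    if len(gebv) < 3:
        raise ValueError("need at least 3 paired records")
    if np.var(gebv) == 0 or np.var(pheno) == 0:
        return None, None
    r = float(np.corrcoef(gebv, pheno)[0, 1])
    cov = np.cov(pheno, gebv, ddof=1)
    slope = float(cov[0, 1] / cov[1, 1])
    return r, slope


def compute_auc(scores, labels):
    """Rank-based (Mann-Whitney) AUC; None when only one class is present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def qtl_report(summary: PosteriorSummary, snp_ids=None, positions=None,
               threshold: float = None, top_n: int = None) -> pd.DataFrame:
    """Ranked SNP table by PIP = sum_{k>=2} P_bar(i,k).

    Default top-set size is m * Pr_bar_4 (the expected number of SNPs in the
    largest-variance component), at least 1. Ties keep input order. SNPs
    deactivated by the speed-up carry PIPs computed over their
    pre-deactivation samples and are flagged.
    """
    m = len(summary.pip)
    pip = summary.pip
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(m)])
    if positions is None:
        positions = np.arange(m)
    df = pd.DataFrame({
        "snp_id": np.asarray(snp_ids),
        "position": np.asarray(positions),
        "pip": pip,
        "mean_effect": summary.g_mean,
        "active": summary.active,
    })
    df = df.sort_values("pip", ascending=False, kind="stable")
    if threshold is not None:
        return df[df["pip"] >= threshold].reset_index(drop=True)
    if top_n is None:
        top_n = max(1, int(round(m * summary.Pr_mean[3])))
    return df.head(top_n).reset_index(drop=True)


def evaluate(summary, Z_val, pheno_val, is_binary=False, snp_ids=None,
             positions=None, **gebv_kwargs) -> EvaluationReport:
    """Accuracy/bias (or AUC) plus component counts and the QTL table."""
    gebv = predict_gebv(Z_val, summary, **gebv_kwargs)
    if is_binary:
        auc = compute_auc(gebv, pheno_val)
        acc = bias = None
    else:
        auc = None
        acc, bias = accuracy_and_bias(gebv, pheno_val)
    return EvaluationReport(
        accuracy=acc, bias=bias, auc=auc,
        component_counts=summary.component_counts,
        qtl_hits=qtl_report(summary, snp_ids=snp_ids, positions=positions),
    )
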