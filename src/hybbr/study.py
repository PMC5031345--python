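"""Desk-scale validation studies of the hybrid sampler.

Each function simulates data under a fixed study condition (see
``hybbr.scenarios``), runs the package end to end, and returns plain
measurements: accuracies against a held-out 20 % validation split, speed-up
deactivation fractions, architecture recovery, QTL PIPs, and conjugate- and
distributional-oracle deviations. Problem sizes are chosen so the whole
study runs on one CPU in minutes; docs/methods.md discusses the choices and
what they do and do not show.
"""

from __future__ import annotations

import numpy as np

from .datamodel import MixturePrior, TraitData, build_grm
from .em import EmConfig, run_em
from .gblup import VarianceComponents, compute_pev, gblup_fit
from .mcmc import McmcConfig, run_mcmc
from .pipeline import accuracy_and_bias, compute_auc, run_hybbr
from .scenarios import (architecture_scenario, null_scenario, parity_scenario,
                        qtl_scenario, speedup_scenario, split_dataset)
from .simulate import SimScenario

EM_CFG = dict(max_iter=400)
HYBRID_ITERS = 1500
LONG_ITERS = 6000
LONG_BURNIN = 3000


def _true_vc(sc: SimScenario) -> VarianceComponents:
    return VarianceComponents(sigma_e2=sc.sigma_e2, sigma_g2=sc.sigma_g2,
                              sigma_a2=sc.sigma_a2)


def _acc(summary, d) -> float:
    r, _ = accuracy_and_bias(d["Z_val"] @ summary.g_mean, d["y_val"])
    return r


def ridge_oracle(trait: TraitData, Z, lam: float):
    """Joint (beta, g) mode of the single-component Gaussian model:
    [[X'X, X'Z], [Z'X, Z'Z + lam I]] [beta; g] = [X'y; Z'y]."""
    X, y = trait.X, trait.y
    p, m = X.shape[1], Z.shape[1]
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(m)]])
    sol = np.linalg.solve(C, np.concatenate([X.T @ y, Z.T @ y]))
    return sol[:p], sol[p:]


def conjugate_check(seed: int, n: int = 200, m: int = 50,
                    mcmc_iters: int = 2000) -> dict:
    """EM and MCMC pinned to the largest Gaussian component vs closed-form ridge.

    With responsibilities pinned to component 4, no polygenic term, E = I and
    sigma_e2 fixed, the converged EM effects must equal the ridge solution
    with lam = sigma_e2 / (0.01 sigma_g2), and the MCMC posterior means must
    agree within Monte-Carlo error (batch-means SE, 20 batches).
    """
    sc = SimScenario(n=n, m=m, true_Pr=(0.0, 0.0, 0.0, 1.0), h2=0.5, seed=seed)
    d = split_dataset(sc, val_frac=0.0)
    trait, Z = d["trait_ref"], d["Z_ref"]
    vc = _true_vc(sc)
    prior = MixturePrior(sigma_g2=vc.sigma_g2)
    lam = vc.sigma_e2 / prior.component_variances[3]
    _, g_ridge = ridge_oracle(trait, Z, lam)

    G = build_grm(Z)
    pev = compute_pev(trait, Z, G, vc=vc)
    em = run_em(trait, Z, prior, pev, vc,
                config=EmConfig(pin_component=3, update_sigma_e=False,
                                update_pr=False, tol=1e-16, max_iter=5000))
    em_rel_err = float(np.linalg.norm(em.state.g - g_ridge)
                       / np.linalg.norm(g_ridge))

    mc_cfg = McmcConfig(n_iter=mcmc_iters, seed=seed, pin_component=3,
                        update_sigma_e=False, speedup_enabled=False,
                        record_samples=True)
    summ, trace = run_mcmc(trait, Z, prior, em.state, config=mc_cfg)
    # batch-means Monte-Carlo SE per SNP
    n_batch = 20
    batches = trace.g_samples.reshape(n_batch, mcmc_iters // n_batch, m).mean(axis=1)
    se = batches.std(axis=0, ddof=1) / np.sqrt(n_batch)
    z = np.abs(summ.g_mean - g_ridge) / np.maximum(se, 1e-300)
    return {
        "em_ridge_rel_err": em_rel_err,
        "mcmc_max_z": float(z.max()),
        "mcmc_mean_z": float(z.mean()),
        "mcmc_frac_within_3se": float((z <= 3.0).mean()),
    }


def _hybrid_run(d, sc, seed, speedup=True, mcmc_iters=HYBRID_ITERS):
    vc = _true_vc(sc)
    return run_hybbr(d["trait_ref"], d["Z_ref"], vc=vc,
                     em_config=EmConfig(**EM_CFG),
                     mcmc_config=McmcConfig(n_iter=mcmc_iters, seed=seed,
                                            speedup_enabled=speedup))


def hybrid_vs_long_study(n_seeds: int = 8, base_seed: int = 0) -> dict:
    """Hybrid (EM start, short chain) vs long chain from a cold start.

    The long chain runs 4x the hybrid's iterations from the default start
    and discards the first half as burn-in; the hybrid discards nothing.
    """
    acc_h, acc_l = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        sc = null_scenario(seed)
        d = split_dataset(sc)
        res_h = _hybrid_run(d, sc, seed)
        res_l = run_hybbr(d["trait_ref"], d["Z_ref"], vc=_true_vc(sc),
                          skip_em=True,
                          mcmc_config=McmcConfig(n_iter=LONG_ITERS,
                                                 burn_in=LONG_BURNIN,
                                                 seed=seed + 10000,
                                                 speedup_enabled=False))
        acc_h.append(_acc(res_h.summary, d))
        acc_l.append(_acc(res_l.summary, d))
    acc_h, acc_l = np.array(acc_h), np.array(acc_l)
    return {
        "acc_hybrid": acc_h.tolist(),
        "acc_long": acc_l.tolist(),
        "mean_acc_hybrid": float(acc_h.mean()),
        "mean_acc_long": float(acc_l.mean()),
        "mean_abs_diff": float(abs(acc_h.mean() - acc_l.mean())),
    }


def speedup_study(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """Prediction accuracy and SNP deactivation with the speed-up on vs off."""
    acc_on, acc_off, frac_deact = [], [], []
    for s in range(n_seeds):
        seed = base_seed + s
        sc = speedup_scenario(seed)
        d = split_dataset(sc)
        res_on = _hybrid_run(d, sc, seed, speedup=True)
        res_off = _hybrid_run(d, sc, seed, speedup=False)
        acc_on.append(_acc(res_on.summary, d))
        acc_off.append(_acc(res_off.summary, d))
        frac_deact.append(1.0 - res_on.summary.active.mean())
    return {
        "acc_speedup": acc_on,
        "acc_no_speedup": acc_off,
        "mean_abs_diff": float(abs(np.mean(acc_on) - np.mean(acc_off))),
        "frac_deactivated": frac_deact,
        "median_frac_deactivated": float(np.median(frac_deact)),
    }


def qtl_gblup_study(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """Major-gene architecture: mixture model vs GBLUP, plus QTL mapping.

    20 QTL are planted, each explaining 4.5 % of the genetic variance.
    Returns per-seed accuracies for both methods, the planted-QTL PIPs and
    the median PIP of null SNPs.
    """
    acc_h, acc_g, qtl_pips, null_medians = [], [], [], []
    for s in range(n_seeds):
        seed = base_seed + s
        sc = qtl_scenario(seed)
        d = split_dataset(sc)
        vc = _true_vc(sc)
        res = _hybrid_run(d, sc, seed)
        acc_h.append(_acc(res.summary, d))
        G = build_grm(d["Z_ref"])
        fit = gblup_fit(d["trait_ref"], G, vc=vc)
        g_blup = fit.snp_effects(d["Z_ref"], vc.sigma_g2)
        r, _ = accuracy_and_bias(d["Z_val"] @ g_blup, d["y_val"])
        acc_g.append(r)
        qtl = d["truth"].qtl_idx
        nulls = np.setdiff1d(np.arange(sc.m), np.where(d["truth"].g != 0)[0])
        qtl_pips.append(res.summary.pip[qtl].tolist())
        null_medians.append(float(np.median(res.summary.pip[nulls])))
    acc_h, acc_g = np.array(acc_h), np.array(acc_g)
    all_pips = np.concatenate(qtl_pips)
    return {
        "acc_hybbr": acc_h.tolist(),
        "acc_gblup": acc_g.tolist(),
        "n_seeds_hybbr_wins_or_ties": int((acc_h >= acc_g).sum()),
        "n_seeds": n_seeds,
        "qtl_pip_min": float(all_pips.min()),
        "qtl_pip_frac_above_0.9": float((all_pips > 0.9).mean()),
        "null_pip_median": float(np.median(null_medians)),
    }


def parity_study(n_seeds: int = 6, base_seed: int = 0) -> dict:
    """Small-effects-only architecture: mixture model should match GBLUP."""
    acc_h, acc_g = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        sc = parity_scenario(seed)
        d = split_dataset(sc)
        vc = _true_vc(sc)
        res = _hybrid_run(d, sc, seed)
        acc_h.append(_acc(res.summary, d))
        G = build_grm(d["Z_ref"])
        fit = gblup_fit(d["trait_ref"], G, vc=vc)
        g_blup = fit.snp_effects(d["Z_ref"], vc.sigma_g2)
        r, _ = accuracy_and_bias(d["Z_val"] @ g_blup, d["y_val"])
        acc_g.append(r)
    return {
        "acc_hybbr": acc_h,
        "acc_gblup": acc_g,
        "mean_diff": float(np.mean(acc_h) - np.mean(acc_g)),
    }


def architecture_study(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """Recovery of the mixture architecture on a wide panel (m=5000).

    Effects are drawn from the prior without rescaling so the generative and
    analysis variance grids coincide; the GBLUP stage receives the realized
    genetic variance while the mixture prior keeps the generative scale.
    """
    post_c4, planted_c4, pr1 = [], [], []
    for s in range(n_seeds):
        seed = base_seed + s
        sc = architecture_scenario(seed)
        d = split_dataset(sc, val_frac=0.0)
        var_g = float(np.var(d["geno"].Z @ d["truth"].g))
        vc = VarianceComponents(sigma_e2=sc.sigma_e2,
                                sigma_g2=max(var_g, 1e-3 * sc.sigma_g2))
        prior = MixturePrior(sigma_g2=sc.sigma_g2)
        res = run_hybbr(d["trait_ref"], d["Z_ref"], vc=vc, prior=prior,
                        em_config=EmConfig(**EM_CFG),
                        mcmc_config=McmcConfig(n_iter=HYBRID_ITERS, seed=seed))
        post_c4.append(float(res.summary.component_counts[3]))
        planted_c4.append(int((d["truth"].labels == 3).sum()))
        pr1.append(float(res.summary.Pr_mean[0]))
    return {
        "posterior_c4_counts": post_c4,
        "planted_c4_counts": planted_c4,
        "mean_posterior_c4": float(np.mean(post_c4)),
        "mean_planted_c4": float(np.mean(planted_c4)),
        "count_ratio": float(np.mean(post_c4) / max(np.mean(planted_c4), 1e-9)),
        "Pr1_estimates": pr1,
        "median_Pr1": float(np.median(pr1)),
    }


def sampler_moment_checks(seed: int, n_draws: int = 100_000) -> dict:
    """Closed-form first moments vs empirical means of the component samplers."""
    rng = np.random.default_rng(seed)
    out = {}
    # scaled inverse-chi-square: SS/chi2_df has mean SS/(df-2)
    n, ss = 30, 57.0
    resid = np.zeros(n)
    resid[0] = np.sqrt(ss)
    from .mcmc import sample_pr, sample_sigma_e

    draws = np.array([sample_sigma_e(resid, np.ones(n), rng) for _ in range(n_draws)])
    expect = ss / (n - 4)  # df = n-2, mean SS/(df-2)
    se = draws.std(ddof=1) / np.sqrt(n_draws)
    out["invchi2_z"] = float(abs(draws.mean() - expect) / se)
    # Dirichlet(counts+1) mean
    counts = np.array([7, 1, 1, 1])
    dirs = np.array([sample_pr(counts, rng) for _ in range(n_draws // 10)])
    expect_pr = (counts + 1) / (counts + 1).sum()
    se_pr = dirs.std(axis=0, ddof=1) / np.sqrt(len(dirs))
    out["dirichlet_max_z"] = float(np.max(np.abs(dirs.mean(axis=0) - expect_pr) / se_pr))
    # categorical indicator frequencies vs softmax probabilities
    from .mcmc import mcmc_component_loglik, sample_snp

    prior = MixturePrior(sigma_g2=1.0, Pr=np.array([0.4, 0.3, 0.2, 0.1]))
    L = mcmc_component_loglik(rhs=3.0, zEz_i=10.0, sigma_e2=1.0, prior=prior)
    p = np.exp(L - L.max())
    p /= p.sum()
    ks = np.array([sample_snp(3.0, 10.0, L, 1.0, prior, rng)[0]
                   for _ in range(n_draws)])
    freqs = np.bincount(ks, minlength=4) / n_draws
    se_k = np.sqrt(p * (1 - p) / n_draws)
    out["categorical_max_z"] = float(np.max(np.abs(freqs - p) / np.maximum(se_k, 1e-12)))
    return out
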