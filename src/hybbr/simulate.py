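"""Synthetic-data generator with full ground truth.

Genotypes are binomial dosages at uniform MAF (optionally with first-order
Markov LD between adjacent SNPs), SNP effects come from the four-component
spike + Gaussian mixture, an optional pedigree contributes polygenic
effects v ~ N(0, A sigma_a^2), and phenotypes follow
y = X beta + Z g + W v + e with heterogeneous residual weights. Heritability
is defined as h2 = sigma_g2 / (sigma_g2 + sigma_e2) on the SNP genetic
variance; binary traits threshold the liability at the prevalence quantile.

By default the drawn effects are rescaled so the realized var(Zg) equals
sigma_g2 exactly, which makes parameter-recovery tests sharp at small n;
set ``rescale_effects=False`` to draw from the prior without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (GenotypeMatrix, Pedigree, TraitData, build_a_matrix,
                        standardize_genotypes)

__all__ = [
    "SimScenario",
    "SimTruth",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_pedigree_polygenic",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass
class SimScenario:
    n: int = 2000
    m: int = 5000
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.0
    true_Pr: tuple = (0.99, 0.007, 0.002, 0.001)
    sigma_g2: float = 1.0
    h2: float = 0.5
    sigma_a2_fraction: float = 0.0  # polygenic variance as a fraction of sigma_g2
    n_founders: int = 0             # pedigree founders; 0 disables the pedigree
    n_generations: int = 2
    weight_pattern: str = "homogeneous"  # or "two-class"
    binary: bool = False
    prevalence: float = 0.5
    n_qtl: int = 0                  # planted large-effect QTL (overrides mixture draw for these)
    qtl_var_frac: float = 0.05      # genetic-variance share of each planted QTL
    rescale_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0,1)")
        pr = np.asarray(self.true_Pr, dtype=float)
        if abs(pr.sum() - 1) > 1e-8 or np.any(pr < 0):
            raise ValueError("true_Pr must lie on the simplex")
        if self.binary and not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0,1)")

    @property
    def sigma_e2(self) -> float:
        return self.sigma_g2 * (1.0 - self.h2) / self.h2

    @property
    def sigma_a2(self) -> float:
        return self.sigma_a2_fraction * self.sigma_g2


@dataclass
class SimTruth:
    g: np.ndarray
    labels: np.ndarray      # component index 0..3 per SNP (one-hot b(i,k) equivalent)
    v: np.ndarray
    beta: np.ndarray
    breeding_values: np.ndarray  # Zg + Wv per record
    qtl_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def simulate_genotypes(scenario: SimScenario, rng=None) -> GenotypeMatrix:
    """Binomial(2, p) dosages; optional adjacent-SNP Markov correlation."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    n, m = scenario.n, scenario.m
    p = rng.uniform(*scenario.maf_range, size=m)
    rho = scenario.ld_rho
    if rho == 0.0:
        raw = rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    else:
        # two haplotypes per individual, each a first-order Markov chain of alleles
        raw = np.zeros((n, m))
        for _ in range(2):
            hap = np.zeros((n, m), dtype=np.int8)
            hap[:, 0] = rng.random(n) < p[0]
            for j in range(1, m):
                stay = rng.random(n) < rho
                fresh = (rng.random(n) < p[j]).astype(np.int8)
                hap[:, j] = np.where(stay, hap[:, j - 1], fresh)
            raw += hap
    return standardize_genotypes(raw)


def simulate_effects(scenario: SimScenario, Z, rng=None):
    """Mixture-architecture SNP effects and their component labels.

    Planted QTL (``n_qtl`` > 0) are assigned to the largest-variance
    component at evenly spaced positions and rescaled so each explains
    ``qtl_var_frac`` of the genetic variance; the remaining SNPs share the
    rest under the mixture draw.
    """
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    m = scenario.m
    pr = np.asarray(scenario.true_Pr, dtype=float)
    scales = np.array([0.0, 1e-4, 1e-3, 1e-2]) * scenario.sigma_g2
    labels = rng.choice(4, size=m, p=pr)
    qtl_idx = np.zeros(0, dtype=int)
    if scenario.n_qtl > 0:
        qtl_idx = np.linspace(0, m - 1, scenario.n_qtl).round().astype(int)
        labels[qtl_idx] = 3
    if scenario.h2 > 0 and not np.any(labels > 0):
        raise ValueError("all SNPs landed in the spike; cannot realize h2 > 0")
    g = np.where(labels == 0, 0.0, rng.standard_normal(m) * np.sqrt(scales[labels]))
    if scenario.n_qtl > 0:
        g[qtl_idx] = np.sqrt(scales[3]) * rng.standard_normal(scenario.n_qtl)
        g[qtl_idx] = np.where(g[qtl_idx] == 0, np.sqrt(scales[3]), g[qtl_idx])
    if scenario.rescale_effects:
        Z = np.asarray(Z)
        if scenario.n_qtl > 0:
            bg = np.setdiff1d(np.where(labels > 0)[0], qtl_idx)
            share_qtl = scenario.n_qtl * scenario.qtl_var_frac
            if share_qtl > 1 + 1e-9:
                raise ValueError("planted QTL variance shares exceed sigma_g2")
            # each QTL explains exactly qtl_var_frac of sigma_g2
            for j in qtl_idx:
                var_j = np.var(Z[:, j] * g[j])
                g[j] *= np.sqrt(scenario.qtl_var_frac * scenario.sigma_g2 / var_j)
            if len(bg) and share_qtl < 1:
                var_bg = np.var(Z[:, bg] @ g[bg])
                if var_bg > 0:
                    g[bg] *= np.sqrt((1 - share_qtl) * scenario.sigma_g2 / var_bg)
            else:
                g[bg] = 0.0
        else:
            var_g = np.var(Z @ g)
            if var_g > 0:
                g *= np.sqrt(scenario.sigma_g2 / var_g)
    return g, labels, qtl_idx


def simulate_pedigree_polygenic(scenario: SimScenario, rng=None, ped=None):
    """Founder population plus random-mating generations; v via chol(A sa2).

    Pass an existing ``ped`` to redraw polygenic effects on a fixed
    pedigree structure.
    """
    rng = np.random.default_rng(scenario.seed + 2) if rng is None else rng
    nf = scenario.n_founders
    if nf <= 0:
        return None, np.zeros(0)
    if ped is None:
        ids = [f"F{j}" for j in range(nf)]
        sire = [None] * nf
        dam = [None] * nf
        per_gen = nf
        for gen in range(scenario.n_generations):
            pool = list(range(len(ids)))
            for j in range(per_gen):
                s, d = rng.choice(pool, size=2, replace=False)
                ids.append(f"G{gen}_{j}")
                sire.append(ids[s])
                dam.append(ids[d])
        ped = build_a_matrix(ids, sire, dam)
    sa2 = scenario.sigma_a2
    if sa2 == 0:
        return ped, np.zeros(ped.q)
    L = np.linalg.cholesky(ped.A + 1e-10 * np.eye(ped.q))
    v = np.sqrt(sa2) * (L @ rng.standard_normal(ped.q))
    return ped, v


def simulate_phenotypes(Z, g, scenario: SimScenario, v=None, W=None,
                        beta=None, X=None, rng=None) -> tuple[TraitData, np.ndarray]:
    """y = X beta + Zg + Wv + e with e ~ N(0, E sigma_e2); returns (trait, tbv)."""
    rng = np.random.default_rng(scenario.seed + 3) if rng is None else rng
    Z = np.asarray(Z)
    n = Z.shape[0]
    tbv = Z @ g
    if v is not None and W is not None and len(v):
        tbv = tbv + W @ v
    if X is None:
        X = np.ones((n, 1))
        beta = np.zeros(1) if beta is None else np.asarray(beta, dtype=float)
    if scenario.weight_pattern == "two-class" and not scenario.binary:
        E_diag = np.where(np.arange(n) < n // 2, 1.0, 4.0)
    else:
        E_diag = np.ones(n)
    e = rng.standard_normal(n) * np.sqrt(scenario.sigma_e2 * E_diag)
    y = X @ beta + tbv + e
    if scenario.binary:
        thresh = np.quantile(y, 1.0 - scenario.prevalence)
        y = (y > thresh).astype(float)
        E_diag = np.ones(n)
    trait = TraitData(y=y, E_diag=E_diag, X=X, W=W, is_binary=scenario.binary)
    return trait, tbv


def simulate_dataset(scenario: SimScenario):
    """Full generative pass: genotypes, pedigree, effects, phenotypes, truth."""
    rng = np.random.default_rng(scenario.seed)
    geno = simulate_genotypes(scenario, rng)
    g, labels, qtl_idx = simulate_effects(scenario, geno.Z, rng)
    ped, v = simulate_pedigree_polygenic(scenario, rng)
    W = None
    if ped is not None:
        if ped.q < scenario.n:
            raise ValueError("pedigree smaller than the number of records")
        W = np.zeros((scenario.n, ped.q))
        W[np.arange(scenario.n), np.arange(scenario.n)] = 1.0
    beta = np.zeros(1)
    trait, tbv = simulate_phenotypes(geno.Z, g, scenario, v=v, W=W, beta=beta, rng=rng)
    truth = SimTruth(g=g, labels=labels, v=v, beta=beta,
                     breeding_values=tbv, qtl_idx=qtl_idx)
    return geno, trait, ped, truth
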