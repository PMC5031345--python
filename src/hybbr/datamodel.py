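"""Domain types and construction of the linear-model matrices.

The data model is

    y = X beta + Z g + W v + e,

with ``y`` the n phenotypic records, ``X`` the fixed-effect design, ``Z`` the
standardized genotype matrix (allele dosages centred at 2p and scaled by
sqrt(2p(1-p))), ``g`` the m SNP effects, ``W`` the incidence matrix mapping
records to pedigree individuals, ``v ~ N(0, A sigma_a^2)`` the polygenic
effects, and ``e ~ N(0, E sigma_e^2)`` residuals whose diagonal weight matrix
``E`` allows records of differing precision (e.g. bull daughter-trait
deviations vs. cow trait deviations).

Each SNP effect is given a four-component mixture prior: a point mass at zero
and three normals with variances (1e-4, 1e-3, 1e-2) times the genetic variance
sigma_g^2, with mixing proportions Pr ~ Dirichlet(1,1,1,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MixturePrior",
    "TraitData",
    "Pedigree",
    "ModelState",
    "standardize_genotypes",
    "build_grm",
    "build_a_matrix",
    "build_weight_matrix",
    "build_design",
]

MIXTURE_SCALES = np.array([0.0, 1e-4, 1e-3, 1e-2])


@dataclass
class GenotypeMatrix:
    """Raw dosages plus the standardized design matrix Z.

    ``raw`` holds allele dosages in {0,1,2} (NaN for missing), ``p`` the
    per-SNP allele frequency and ``Z`` the column-standardized dosages.
    Monomorphic SNPs are retained with an all-zero Z column so that SNP
    indices stay aligned with the input file.
    """

    raw: np.ndarray
    p: np.ndarray
    Z: np.ndarray
    snp_ids: np.ndarray
    individual_ids: np.ndarray
    monomorphic: np.ndarray = field(default=None)

    @property
    def n_individuals(self) -> int:
        return self.raw.shape[0]

    @property
    def n_snps(self) -> int:
        return self.raw.shape[1]


@dataclass
class MixturePrior:
    """Four-component spike + Gaussian mixture prior on SNP effects."""

    sigma_g2: float
    Pr: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.487, 0.01, 0.003]))
    dirichlet_alpha: np.ndarray = field(default_factory=lambda: np.ones(4))
    scales: np.ndarray = field(default_factory=lambda: MIXTURE_SCALES.copy())

    def __post_init__(self) -> None:
        self.Pr = np.asarray(self.Pr, dtype=float)
        if self.sigma_g2 <= 0:
            raise ValueError("sigma_g2 must be positive")
        if self.Pr.shape != (4,) or np.any(self.Pr < 0) or abs(self.Pr.sum() - 1) > 1e-8:
            raise ValueError("Pr must be a 4-vector on the simplex")

    @property
    def component_variances(self) -> np.ndarray:
        return self.scales * self.sigma_g2


@dataclass
class TraitData:
    """Phenotypes, residual weights and design matrices for one trait."""

    y: np.ndarray
    E_diag: np.ndarray
    X: np.ndarray
    W: np.ndarray = None  # n x q incidence; None when no polygenic term
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = self.y.shape[0]
        if self.E_diag is None:
            self.E_diag = np.ones(n)
        self.E_diag = np.asarray(self.E_diag, dtype=float)
        if np.any(self.E_diag <= 0):
            raise ValueError("residual weights must be positive")
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=float)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class Pedigree:
    """Pedigree records and the numerator relationship matrix A."""

    ids: np.ndarray
    sire: np.ndarray  # index into ids, -1 for unknown
    dam: np.ndarray
    A: np.ndarray

    @property
    def q(self) -> int:
        return len(self.ids)


@dataclass
class ModelState:
    """Current values of all model unknowns plus the running residual."""

    g: np.ndarray
    beta: np.ndarray
    v: np.ndarray
    sigma_e2: float
    sigma_a2: float
    P: np.ndarray  # m x 4 responsibilities
    Pr: np.ndarray
    active: np.ndarray
    residual: np.ndarray

    def recompute_residual(self, y, Z, X, W=None) -> np.ndarray:
        r = y - X @ self.beta - Z @ self.g
        if W is not None and self.v is not None and len(self.v):
            r = r - W @ self.v
        return r


def standardize_genotypes(raw, freq=None, snp_ids=None, individual_ids=None) -> GenotypeMatrix:
    """Centre and scale allele dosages: z = (s - 2p) / sqrt(2p(1-p)).

    Missing dosages are mean-imputed to 2p (z = 0) before standardization.
    When ``freq`` is absent, p is estimated as the column mean over
    non-missing entries divided by 2. Monomorphic SNPs (p outside (0,1))
    keep an all-zero Z column and are flagged with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw dosage matrix must be 2-D")
    n, m = raw.shape
    missing = np.isnan(raw)
    if np.any(missing.all(axis=0)):
        bad = np.where(missing.all(axis=0))[0]
        raise ValueError(f"all-missing genotype columns: {bad.tolist()}")
    valid = ~missing
    vals = np.where(missing, 0.0, raw)
    if np.any((vals[valid.nonzero()] % 1 != 0) | (vals < -1e-9).any() | (vals > 2 + 1e-9).any()):
        raise ValueError("dosages must be in {0, 1, 2} or missing")
    if freq is None:
        p = vals.sum(axis=0) / (2.0 * valid.sum(axis=0))
    else:
        p = np.asarray(freq, dtype=float)
        if p.shape != (m,):
            raise ValueError("freq must have one entry per SNP")
    mono = (p <= 0.0) | (p >= 1.0)
    if np.any(mono):
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNP(s); Z columns set to zero",
            UserWarning,
            stacklevel=2,
        )
    denom = np.where(mono, 1.0, np.sqrt(2.0 * p * (1.0 - p)))
    imputed = np.where(missing, 2.0 * p, raw)
    Z = (imputed - 2.0 * p) / denom
    Z[:, mono] = 0.0
    Z = np.asfortranarray(Z)
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(m)])
    if individual_ids is None:
        individual_ids = np.array([f"id{j}" for j in range(n)])
    return GenotypeMatrix(
        raw=raw,
        p=p,
        Z=Z,
        snp_ids=np.asarray(snp_ids),
        individual_ids=np.asarray(individual_ids),
        monomorphic=mono,
    )


def build_grm(Z, divisor="m") -> np.ndarray:
    """Genomic relationship matrix G = Z Z' / m from standardized genotypes.

    ``divisor`` is the number of SNPs by default; pass ``"n"`` to divide by
    the number of individuals instead.
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if m == 0:
        raise ValueError("cannot build a GRM with zero SNPs")
    d = m if divisor == "m" else n
    G = (Z @ Z.T) / d
    return 0.5 * (G + G.T)


def build_a_matrix(ids, sire, dam) -> Pedigree:
    """Numerator relationship matrix by Henderson's tabular method.

    ``sire``/``dam`` give parent identifiers, with None/''/0/NaN for
    unknown parents. Records are topologically sorted so parents precede
    offspring; an individual appearing in its own ancestry raises.

    Tabular rules: a_jj = 1 + a_sd/2 and a_jk = (a_ks + a_kd)/2, with
    unknown parents contributing zero.
    """
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")
    idx = {x: i for i, x in enumerate(ids)}

    def _parent(x):
        if x is None:
            return -1
        if isinstance(x, float) and np.isnan(x):
            return -1
        s = str(x)
        if s in ("", "0", "0.0", ".", "NA", "nan"):
            return -1
        if s not in idx:
            raise ValueError(f"parent {s!r} not listed as an individual")
        return idx[s]

    si = np.array([_parent(x) for x in sire], dtype=int)
    di = np.array([_parent(x) for x in dam], dtype=int)

    # topological order (Kahn); a cycle means someone is their own ancestor
    q = len(ids)
    children = [[] for _ in range(q)]
    indeg = np.zeros(q, dtype=int)
    for j in range(q):
        for par in (si[j], di[j]):
            if par >= 0:
                children[par].append(j)
                indeg[j] += 1
    order = [j for j in range(q) if indeg[j] == 0]
    head = 0
    while head < len(order):
        j = order[head]
        head += 1
        for c in children[j]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
    if len(order) != q:
        raise ValueError("pedigree contains a cycle (individual is its own ancestor)")

    A = np.zeros((q, q))
    for j in order:
        s, d = si[j], di[j]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[j, j] = 1.0 + 0.5 * asd
        for k in order:
            if k == j:
                continue
            aks = A[k, s] if s >= 0 else 0.0
            akd = A[k, d] if d >= 0 else 0.0
            val = 0.5 * (aks + akd)
            A[j, k] = A[k, j] = val
    return Pedigree(ids=np.array(ids), sire=si, dam=di, A=A)


def build_weight_matrix(weights, is_binary: bool = False) -> np.ndarray:
    """Diagonal of the residual weight matrix E.

    Equal-information records yield E = I. Binary (case/control) traits
    force E = I regardless of supplied weights, since all records carry
    the same error magnitude.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("residual weights must be positive")
    if is_binary:
        if not np.allclose(w, w[0]):
            warnings.warn("binary trait: residual weights replaced by identity", UserWarning, stacklevel=2)
        return np.ones_like(w)
    return w


def build_design(covariates: pd.DataFrame | None, n: int, ped_ids=None, record_ids=None):
    """Fixed-effect design X (with intercept) and polygenic incidence W.

    Categorical covariate columns are dummy-coded dropping the first level;
    numeric columns enter as-is. ``W`` places a 1 in column j for a record
    belonging to pedigree individual j, and is None when no pedigree is
    supplied.
    """
    cols = [np.ones(n)]
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate table length mismatch")
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, drop_first=True)
                for c in dummies.columns:
                    cols.append(dummies[c].to_numpy(dtype=float))
            else:
                cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    W = None
    if ped_ids is not None:
        ped_ids = [str(x) for x in ped_ids]
        pos = {x: j for j, x in enumerate(ped_ids)}
        if record_ids is None:
            raise ValueError("record_ids required to build W")
        W = np.zeros((n, len(ped_ids)))
        for i, rid in enumerate(record_ids):
            j = pos.get(str(rid))
            if j is None:
                raise ValueError(f"record {rid!r} has no pedigree match")
            W[i, j] = 1.0
    return X, W
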