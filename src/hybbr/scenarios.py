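"""Standard simulated study conditions and split helpers.

These scenarios fix the generative conditions used by the validation study
that ships with the package (tests and scripts/acceptance.py): a null-like
polygenic architecture with mixing proportions (0.99, 0.007, 0.002, 0.001)
and h2 = 0.5, a major-gene architecture with 20 planted QTL, a small-effect
parity architecture, and a wide-panel architecture-recovery setting.
Problem sizes are desk-scale so a full study runs on one CPU in minutes;
docs/methods.md records the choices.
"""

from __future__ import annotations

import numpy as np

from .datamodel import TraitData
from .simulate import SimScenario, simulate_dataset

STANDARD_PR = (0.99, 0.007, 0.002, 0.001)


def null_scenario(seed: int) -> SimScenario:
    """Sparse mixture architecture, n=1250 records x m=1000 SNPs."""
    return SimScenario(n=1250, m=1000, true_Pr=STANDARD_PR, h2=0.5, seed=seed)


def speedup_scenario(seed: int) -> SimScenario:
    """Sparse mixture architecture at panel width m=5000, n=2500 records.

    The SNP-deactivation scheme needs the wide-panel regime: the posterior
    of the mixing proportions concentrates only when many null SNPs
    contribute evidence, so spike probabilities sustain the 0.9 threshold.
    """
    return SimScenario(n=2500, m=5000, true_Pr=STANDARD_PR, h2=0.5, seed=seed)


def qtl_scenario(seed: int) -> SimScenario:
    """20 planted QTL, each 4.5 % of the genetic variance, n=1875 x m=5000."""
    return SimScenario(n=1875, m=5000, true_Pr=(0.99, 0.01, 0.0, 0.0), h2=0.5,
                       n_qtl=20, qtl_var_frac=0.045, seed=seed)


def parity_scenario(seed: int) -> SimScenario:
    """Every SNP carries a tiny effect (component 2 only), n=1250 x m=1000;
    the infinitesimal regime where the mixture model should match GBLUP."""
    return SimScenario(n=1250, m=1000, true_Pr=(0.0, 1.0, 0.0, 0.0), h2=0.5,
                       seed=seed)


def architecture_scenario(seed: int) -> SimScenario:
    """Wide panel for proportion recovery: m=5000 SNPs, n=2500 records,
    effects drawn from the prior without rescaling so the generative and
    analysis variance grids coincide."""
    return SimScenario(n=2500, m=5000, true_Pr=STANDARD_PR, h2=0.5,
                       rescale_effects=False, seed=seed)


def split_dataset(scenario: SimScenario, val_frac: float = 0.2):
    """Simulate and split into reference/validation, leakage-free.

    Both splits are standardized with allele frequencies estimated from the
    reference rows only, mirroring how a validation cohort is scored with
    reference-panel frequencies.
    """
    geno, trait, ped, truth = simulate_dataset(scenario)
    n = scenario.n
    rng = np.random.default_rng(scenario.seed + 1000)
    perm = rng.permutation(n)
    n_val = int(round(val_frac * n))
    val_idx, ref_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])

    raw_ref = geno.raw[ref_idx]
    p_ref = np.nanmean(raw_ref, axis=0) / 2.0
    p_ref = np.clip(p_ref, 1e-6, 1 - 1e-6)
    denom = np.sqrt(2.0 * p_ref * (1.0 - p_ref))
    Z_ref = np.asfortranarray((np.nan_to_num(raw_ref, nan=0.0) - 2.0 * p_ref) / denom)
    Z_val = (np.nan_to_num(geno.raw[val_idx], nan=0.0) - 2.0 * p_ref) / denom

    trait_ref = TraitData(y=trait.y[ref_idx], E_diag=trait.E_diag[ref_idx],
                          X=trait.X[ref_idx], W=None, is_binary=trait.is_binary)
    return {
        "geno": geno,
        "truth": truth,
        "trait_ref": trait_ref,
        "Z_ref": Z_ref,
        "Z_val": Z_val,
        "y_val": trait.y[val_idx],
        "tbv_val": truth.breeding_values[val_idx],
        "ref_idx": ref_idx,
        "val_idx": val_idx,
    }
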