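import numpy as np
import pytest

from hybbr.datamodel import MixturePrior, TraitData
from hybbr.gblup import VarianceComponents
from hybbr.simulate import SimScenario, simulate_dataset


@pytest.fixture(scope="session")
def small_data():
    """Small simulated dataset without a pedigree (n=120, m=40)."""
    sc = SimScenario(n=120, m=40, h2=0.5, true_Pr=(0.8, 0.1, 0.06, 0.04), seed=7)
    geno, trait, ped, truth = simulate_dataset(sc)
    vc = VarianceComponents(sigma_e2=sc.sigma_e2, sigma_g2=sc.sigma_g2)
    prior = MixturePrior(sigma_g2=vc.sigma_g2)
    return {"scenario": sc, "geno": geno, "trait": trait, "truth": truth,
            "vc": vc, "prior": prior}


@pytest.fixture(scope="session")
def pedigree_data():
    """Simulated dataset with pedigree polygenic effects (n=60 records)."""
    sc = SimScenario(n=60, m=30, h2=0.4, true_Pr=(0.7, 0.15, 0.1, 0.05),
                     sigma_a2_fraction=0.5, n_founders=20, n_generations=2,
                     seed=13)
    geno, trait, ped, truth = simulate_dataset(sc)
    vc = VarianceComponents(sigma_e2=sc.sigma_e2, sigma_g2=sc.sigma_g2,
                            sigma_a2=sc.sigma_a2)
    prior = MixturePrior(sigma_g2=vc.sigma_g2)
    return {"scenario": sc, "geno": geno, "trait": trait, "ped": ped,
            "truth": truth, "vc": vc, "prior": prior}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
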