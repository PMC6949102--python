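import numpy as np
import pytest

from smlnet.diffexpr import DrugLncRNAAssociation
from smlnet.network import build_smln
from smlnet.synthetic import SynthConfig, generate_instances


@pytest.fixture(scope="session")
def small_noiseless():
    """Tiny zero-noise synthetic study with its planted truth."""
    cfg = SynthConfig(n_drugs=12, n_lncrnas=10, n_mrnas=50, noise_sd=0.0, seed=7)
    expr, manifest, truth = generate_instances(cfg)
    return cfg, expr, manifest, truth


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions (60 drugs, 40 lncRNAs, noise 0.3)."""
    cfg = SynthConfig(seed=11)
    expr, manifest, truth = generate_instances(cfg)
    return cfg, expr, manifest, truth


def random_associations(rng, n_drugs=8, n_lncs=6, density=0.4):
    """Random deduplicated association table for construction oracles."""
    assoc = []
    for i in range(n_drugs):
        for j in range(n_lncs):
            if rng.random() < density:
                assoc.append(
                    DrugLncRNAAssociation(
                        drug_id=f"d{i}",
                        lncrna_id=f"l{j}",
                        sign="up" if rng.random() < 0.5 else "down",
                        mean_log2fc=float(rng.normal()),
                        n_supporting_instances=1,
                    )
                )
    return assoc


@pytest.fixture
def random_smln():
    rng = np.random.default_rng(5)
    assoc = random_associations(rng)
    return build_smln(assoc), assoc
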