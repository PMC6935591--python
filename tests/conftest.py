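import numpy as np
import pandas as pd
import pytest

from clinekit.config import ClineGroup, TraitSpec, TruthConfig
from clinekit.simulate import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact labelled dataset shared by read-only tests."""
    cfg = TruthConfig(
        n_pops=40, n_per_pop=8, n_control_loci=300,
        n_neutral_candidate_loci=200,
        cline_groups=[
            ClineGroup("rw1", 12, "rangewide", center=0.0, width=2.5,
                       p_lo=0.02, p_hi=0.98),
            ClineGroup("loc1", 12, "localized", center=2.0, width=0.4,
                       p_lo=0.02, p_hi=0.98),
        ],
        traits=[TraitSpec("cold_injury", ["rw1", "loc1"], effect_size=0.3),
                TraitSpec("shoot_mass", ["rw1"], effect_size=0.3)],
        n_blocks=4, n_locs_per_block=3, seed=42)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_genotypes():
    """3 individuals x 2 loci with known codes, for hand-check tests."""
    from clinekit.io import GenotypeMatrix

    codes = np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8)
    loci = pd.DataFrame({"locus": ["l1", "l2"], "contig": ["c1", "c2"],
                         "klass": "candidate", "ref": "A", "alt": "G"})
    return GenotypeMatrix(codes, ["i1", "i2", "i3"], loci)
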