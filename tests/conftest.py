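import numpy as np
import pytest

from orgkit import core_model as cm
from orgkit import synthetic_data as sd


@pytest.fixture(scope="session")
def donor_plastome() -> cm.GenomeRecord:
    rng = np.random.default_rng(990)
    seq = sd.screen_duplicates(sd.random_dna(rng, 20000, 0.38), 30, rng, 0.38)
    return cm.GenomeRecord("donor_plastome", seq, cm.Topology.circular)


@pytest.fixture(scope="session")
def small_genome() -> tuple:
    cfg = sd.SimConfig(seed=21, genome_length=40000, n_genes=5, n_trans_introns=1)
    return sd.generate_genome(cfg)


@pytest.fixture(scope="session")
def plastome_model():
    from orgkit import isoform as iso

    genome, ir_pair, form_b = sd.make_synthetic_plastome(10000, 1000, 4000, 41)
    model = iso.build_alternative_form(genome, ir_pair)
    return genome, ir_pair, form_b, model
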