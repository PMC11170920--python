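import numpy as np
import pytest

from ocgi.caller import call_genome
from ocgi.orthology import build_orthologous_sites
from ocgi.simulate import SyntheticSpec, make_species_pair


@pytest.fixture(scope="session")
def turnover_study():
    """A mid-sized simulated species pair with recovered orthologous sites,
    shared by the orthology and turnover tests."""
    spec = SyntheticSpec(
        seed=17,
        n_chroms=2,
        chrom_length_bp=1_000_000,
        n_islands=250,
        turnover_fractions=(0.4, 0.3, 0.3),
    )
    pair = make_species_pair(spec)
    calls_A = call_genome(pair.seq_A)
    calls_B = call_genome(pair.seq_B)
    sites = build_orthologous_sites(
        calls_A,
        calls_B,
        pair.map_A_to_human,
        pair.map_B_to_human,
        seqs_A=pair.seq_A,
        seqs_B=pair.seq_B,
    )
    return {
        "spec": spec,
        "pair": pair,
        "calls_A": calls_A,
        "calls_B": calls_B,
        "sites": sites,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
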