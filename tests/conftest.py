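import numpy as np
import pytest

from wreconserve import DegenerateMotif, PromoterRecord


@pytest.fixture(scope="session")
def wre() -> DegenerateMotif:
    return DegenerateMotif()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_record(seq: str, species: str = "human", upstream: int | None = None,
                downstream: int = 0, isoform: str = "iso1",
                gene: str = "WNT3A") -> PromoterRecord:
    if upstream is None:
        upstream = len(seq) - downstream
    return PromoterRecord(species=species, gene=gene, isoform_id=isoform,
                          upstream=upstream, downstream=downstream, sequence=seq)


@pytest.fixture(scope="session")
def five_species_tree_newick() -> str:
    # unrooted (trifurcating) version of the default simulation topology
    return ("((human:0.08,(mouse:0.06,rat:0.06):0.04):0.12,"
            "chicken:0.35,zebrafish:0.65);")
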