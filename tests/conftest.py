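import numpy as np
import pytest

from difmod import Replicon, load_dif1_reference, load_reference_sites
from difmod._seq import revcomp
from difmod.synthetic_data import mutate_site, random_background


@pytest.fixture(scope="session")
def refs():
    return load_reference_sites()


@pytest.fixture(scope="session")
def cd_ref(refs):
    return refs[0].sequence


@pytest.fixture(scope="session")
def dc_ref(refs):
    return refs[1].sequence


@pytest.fixture(scope="session")
def dif1_ref():
    return load_dif1_reference()


@pytest.fixture
def rng():
    return np.random.default_rng(20190329)


def make_background(length, rng, gc=0.40, scrub=True, circular=True):
    """Random background, by default scrubbed of chance dif-like windows."""
    from difmod.synthetic_data import scrub_chance_sites

    seq = random_background(length, gc, rng)
    if scrub:
        seq = scrub_chance_sites(seq, rng, circular=circular)
    return seq


def plant(background: str, insert: str, position1: int) -> str:
    """Replace background bases with `insert` at a 1-based position (no wrap)."""
    i = position1 - 1
    assert i + len(insert) <= len(background)
    return background[:i] + insert + background[i + len(insert):]


@pytest.fixture
def replicon_with_cd_site(cd_ref, rng):
    """1-kb linear replicon with an exact CD site at positions 101-128."""
    seq = plant(make_background(1000, rng, circular=False), cd_ref, 101)
    return Replicon(id="planted", sequence=seq, topology="linear", category="plasmid")


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default-condition dataset shared by recovery tests."""
    from difmod.synthetic_data import SimulationSpec, generate_dataset

    return generate_dataset(SimulationSpec(seed=11))


# map generator template names to the labels the catalog-joining rule produces
TEMPLATE_LABELS = {
    "chrAB_dif": "chrA-chrB_dif",
    "terC_dif": "terC_dif",
    "kup_dif": "kup-orfY_dif",
    "ohr1_dif": "ohr-ohrR_dif",
    "sulP_dif": "sulP-orfX_dif",
    "sulP_uspA_dif": "sulP-uspA_dif",
    "add_dif": "add_toxin-add_antitoxin_dif",
}
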