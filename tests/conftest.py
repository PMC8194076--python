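import numpy as np
import pytest

from haplomite.haplogroups import ReferencePanel
from haplomite.seq_core import AlignedMatrix, SequenceRecord
from haplomite.synthetic_data import (
    SynthConfig,
    simulate_farm_sample,
    simulate_haplogroup_panel,
)


@pytest.fixture(scope="session")
def config():
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def panel(config):
    return simulate_haplogroup_panel(config)


@pytest.fixture(scope="session")
def reference_panel(panel):
    return ReferencePanel.from_synth(panel)


@pytest.fixture(scope="session")
def star_farm(config, panel):
    """A single-haplogroup farm with the star-expansion pattern."""
    return simulate_farm_sample(
        config, panel, "single_group", farm_id="star", rng=np.random.default_rng(7)
    )


@pytest.fixture(scope="session")
def numt_farm(config, panel):
    return simulate_farm_sample(
        config, panel, "with_numt", farm_id="numtfarm",
        rng=np.random.default_rng(13),
    )


def sk_like_matrix():
    """17 copies of a hub plus three distinct single-mutation variants, the
    laboratory-population star pattern."""
    hub = "ACGTACGTACGTACGTACGT"
    variants = [
        hub[:3] + "A" + hub[4:],   # T->A at 3
        hub[:7] + "C" + hub[8:],   # T->C at 7
        hub[:11] + "G" + hub[12:],  # T->G at 11
    ]
    records = [
        SequenceRecord(f"sk{i:02d}", hub, farm="SK") for i in range(17)
    ] + [
        SequenceRecord(f"skv{i}", v, farm="SK") for i, v in enumerate(variants)
    ]
    return AlignedMatrix(records)


@pytest.fixture()
def sk_matrix():
    return sk_like_matrix()
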