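import numpy as np
import pytest

from mitoedit.simulate import make_planted_dataset
from mitoedit.sites import EditingSite


@pytest.fixture(scope="session")
def planted_small():
    """A small planted four-library design: 12 sites (5 down, 3 up), depth 150."""
    config, expected = make_planted_dataset(
        n_sites=12, n_decreased=5, n_increased=3, depth=150, seed=11
    )
    return config, expected


@pytest.fixture(scope="session")
def duplicated_references():
    """Two references sharing a verbatim 160 bp block (ambiguity trap)."""
    rng = np.random.default_rng(42)
    block = "".join(rng.choice(list("ACGT"), size=160))
    ref_a = "".join(rng.choice(list("ACGT"), size=120)) + block + "".join(
        rng.choice(list("ACGT"), size=120)
    )
    ref_b = "".join(rng.choice(list("ACGT"), size=80)) + block + "".join(
        rng.choice(list("ACGT"), size=140)
    )
    return {"gene_a": ref_a, "gene_b": ref_b}


@pytest.fixture()
def toy_reference():
    """One 200 bp transcript with two annotated C sites inside the shared window."""
    rng = np.random.default_rng(7)
    seq = rng.choice(list("ACGT"), size=200)
    seq[79] = "C"
    seq[119] = "C"
    references = {"tx": "".join(seq)}
    sites = [
        EditingSite("tx-80", "tx", 80),
        EditingSite("tx-120", "tx", 120),
    ]
    return references, sites
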