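import numpy as np
import pytest
from hypothesis import settings

from condensekit import synthgen
from condensekit.xlmap import CrosslinkRecord, PeptideInterval

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_record(
    res_a,
    res_b,
    pep_a,
    pep_b,
    aa_a="K",
    aa_b="K",
    condition="125mM",
    n_xsm=1,
    protein="TOY",
):
    """Shorthand record constructor for tests."""
    return CrosslinkRecord(
        protein_id=protein,
        res_a=res_a,
        res_b=res_b,
        aa_a=aa_a,
        aa_b=aa_b,
        pep_a=PeptideInterval(*pep_a),
        pep_b=PeptideInterval(*pep_b),
        condition=condition,
        n_xsm=n_xsm,
    )


@pytest.fixture
def toy_monomer():
    return synthgen.make_toy_structure(64, n_chains=1, spacing=3.8)


@pytest.fixture
def toy_dimer():
    return synthgen.make_toy_structure(64, n_chains=2, spacing=3.8, offset=20.0)
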