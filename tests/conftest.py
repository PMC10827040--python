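import numpy as np
import pytest

from srnatail.refio import ReferenceRecord


@pytest.fixture(scope="session")
def mir_guga():
    """miR-125a-5p-like reference: mature ends ...CCUGUG, genomic A downstream."""
    return ReferenceRecord(
        ref_id="mir-guga",
        ref_class="miRNA",
        mature_seq="UCCCUGAGACCCUUUAACCUGUG",
        downstream_seq="AUUUCGGC",
    )


@pytest.fixture(scope="session")
def u6_like():
    """Toy U6-like snRNA: canonical end at the Lsm-adjacent +1U, U tract downstream."""
    return ReferenceRecord(
        ref_id="u6-like",
        ref_class="snRNA",
        mature_seq="GAUUAGCAUGGCCCCUGCGCAAGGAUU",
        downstream_seq="UUUUCGCA",
        boundary_offset=0,
    )


@pytest.fixture(scope="session")
def clean_pair():
    """Guide/passenger miRNA pair with non-colliding downstream contexts.

    Downstream starts with C/G so A- and U-tails are never templated-
    absorbable at the boundary.
    """
    guide = ReferenceRecord(
        ref_id="mir-g", ref_class="miRNA",
        mature_seq="ACGUACGUACGUACGUACGG",
        downstream_seq="CGCGCGCG",
        partner_id="mir-p", arm_role="guide",
    )
    passenger = ReferenceRecord(
        ref_id="mir-p", ref_class="miRNA",
        mature_seq="GGCAUUCAGGCAUUCAGGCA",
        downstream_seq="GCGCGCGC",
        partner_id="mir-g", arm_role="passenger",
    )
    return {guide.ref_id: guide, passenger.ref_id: passenger}


@pytest.fixture(scope="session")
def refset(mir_guga, u6_like, clean_pair):
    refs = {mir_guga.ref_id: mir_guga, u6_like.ref_id: u6_like}
    refs.update(clean_pair)
    return refs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
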