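import numpy as np
import pytest

from rupestre.data_core import (
    HabitatClass,
    IncidenceMatrix,
    Physiognomy,
    SiteRecord,
    Substrate,
)
from rupestre.megatree import read_dated

# six-tip ultrametric fixture, root age 100 My
SIX_TIP_NEWICK = (
    "(((a:10,b:10)ab:20,c:30)abc:70,((d:25,e:25)de:50,f:75)def:25)root;"
)


@pytest.fixture(scope="session")
def six_tip_tree():
    return read_dated(SIX_TIP_NEWICK, is_string=True)


@pytest.fixture(scope="session")
def six_tip_distances():
    """Hand-computed patristic distances for the six-tip fixture."""
    labels = ["a", "b", "c", "d", "e", "f"]
    mrca_age = {
        ("a", "b"): 10, ("a", "c"): 30, ("b", "c"): 30,
        ("d", "e"): 25, ("d", "f"): 75, ("e", "f"): 75,
    }
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            age = mrca_age.get((labels[i], labels[j]), 100)
            D[i, j] = D[j, i] = 2 * age
    return labels, D


@pytest.fixture
def small_matrix():
    #        sp1 sp2 sp3 sp4 sp5
    # s1      1   1   0   1   0
    # s2      0   1   1   1   0
    # s3      1   0   0   1   1
    return IncidenceMatrix(
        ["s1", "s2", "s3"],
        ["sp1", "sp2", "sp3", "sp4", "sp5"],
        np.array([[1, 1, 0, 1, 0], [0, 1, 1, 1, 0], [1, 0, 0, 1, 1]]),
    )


def make_record(site_id, substrate="quartzite", physiognomy="open", disturbed=False):
    return SiteRecord(
        site_id=site_id,
        substrate=Substrate(substrate),
        physiognomy=Physiognomy(physiognomy),
        disturbed=disturbed,
    )


@pytest.fixture
def small_meta():
    return [
        make_record("s1", "canga", "forest"),
        make_record("s2", "quartzite", "open"),
        make_record("s3", "quartzite", "open"),
    ]
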