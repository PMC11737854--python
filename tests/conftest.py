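import numpy as np
import pytest

from tcrhla.types import Clonotype, Cohort, Donor, HlaAllele

A0201 = HlaAllele.parse("A*02:01")
B0702 = HlaAllele.parse("B*07:02")


def beta(cdr3, v="TRBV19"):
    return Clonotype(chain="beta", cdr3_aa=cdr3, v_family=v)


def alpha(cdr3, v="TRAV12"):
    return Clonotype(chain="alpha", cdr3_aa=cdr3, v_family=v)


def make_donor(donor_id, clonotypes, hla=None, has_alpha=None, cohort="test"):
    return Donor(
        donor_id=donor_id,
        cohort=cohort,
        clonotypes=frozenset(clonotypes),
        has_alpha=has_alpha,
        hla=frozenset(hla) if hla is not None else None,
    )


@pytest.fixture
def tiny_typed_cohort():
    """10 donors; clonotype X tracks A*02:01 carriage perfectly, Y is noise."""
    x, y = beta("CASSLGETQYF"), beta("CASSNOISEQYF", v="TRBV7")
    donors = []
    rng = np.random.default_rng(0)
    for i in range(10):
        positive = i < 5
        clonos = {x} if positive else set()
        if rng.random() < 0.5:
            clonos.add(y)
        donors.append(
            make_donor(f"d{i}", clonos, hla={A0201} if positive else {B0702})
        )
    return Cohort(donors=donors, name="tiny")
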