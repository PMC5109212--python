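import numpy as np
import pytest

from corrmr import fixtures
from corrmr.records import AssociationSet, LdMatrix, SnpAssociation


def snp(
    rsid,
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    eaf=0.3,
    p=1e-10,
    n=100_000,
    **kw,
):
    return SnpAssociation(
        rsid=rsid,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        eaf=eaf,
        p=p,
        n=n,
        **kw,
    )


def association_set(records, trait_name="trait", trait_type="continuous"):
    return AssociationSet(trait_name, trait_type, records)


def identity_ld(rsids):
    return LdMatrix(list(rsids), np.eye(len(rsids)))


@pytest.fixture(scope="session")
def coffee_exposure():
    return fixtures.coffee_instruments()


@pytest.fixture(scope="session")
def coffee_ld():
    return fixtures.coffee_ld()


@pytest.fixture(scope="session")
def coffee_annotations():
    return fixtures.coffee_annotations()
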