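import pytest

from srmiso import isoform_db as idb
from srmiso import simulate as sim


@pytest.fixture(scope="session")
def family():
    """Default neurexin-like generated family (3 genes, 26 isoforms)."""
    return sim.generate_family(sim.neurexin_like_config(seed=42))


@pytest.fixture(scope="session")
def groups(family):
    return idb.build_detection_groups(family)


@pytest.fixture(scope="session")
def index(family):
    return idb.PeptideIndex(family, max_missed=2, il_equivalent=True)


@pytest.fixture(scope="session")
def panel(family):
    return sim.design_default_panel(family)


@pytest.fixture(scope="session")
def toy_family():
    """Hand-built two-gene family with shared and unique peptides.

    geneA alpha/beta share the C-terminal suffix 'CCCRDDDK'; geneB has
    one isoform whose second peptide matches geneA's shared peptide
    region only in part.
    """
    return [
        idb.IsoformRecord("A-alpha", "geneA", "alpha", {}, "MAAAKWWWRCCCRDDDK"),
        idb.IsoformRecord("A-beta", "geneA", "beta", {}, "MEEEKCCCRDDDK"),
        idb.IsoformRecord("B-alpha", "geneB", "alpha", {}, "MFFFKCCCRGGGK"),
    ]
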