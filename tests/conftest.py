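import pytest

import phylometab as pm
from phylometab import phenospace as ps
from phylometab import profiles as pr


@pytest.fixture(scope="session")
def bundle():
    return pm.load_knowledge_base()


@pytest.fixture(scope="session")
def space(bundle):
    """Shared phenotype-space viability cache (LP results are reused)."""
    return ps.PhenoSpace(bundle)


@pytest.fixture(scope="session")
def clade_profiles(bundle):
    return pr.synthesize_clade_profiles(bundle)


@pytest.fixture(scope="session")
def pathway_defs(bundle):
    return [bundle.pathways[p] for p in pr.PATHWAY_ORDER]
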