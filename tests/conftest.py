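import pytest

import allelescope as a
from allelescope.structure_caller import CompositeReference


@pytest.fixture(scope="session")
def lib():
    return a.make_library(1)


@pytest.fixture(scope="session")
def blueprints(lib):
    return a.builtin_blueprints(lib)


@pytest.fixture(scope="session")
def ref(lib):
    return CompositeReference.from_library(lib)


@pytest.fixture(scope="session")
def alleles(lib, blueprints):
    """Ground-truth AlleleTruth objects for every built-in blueprint."""
    return {name: a.build_allele(lib, bp) for name, bp in blueprints.items()}
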