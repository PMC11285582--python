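import warnings

import pytest

from hcase import (
    FixtureSpec,
    build_reference_space,
    embed_library,
    generate_compounds,
    generate_scaffolds,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(n_scaffolds=30, n_compounds=40, seed=7)


@pytest.fixture(scope="session")
def scaffold_set(spec):
    return generate_scaffolds(spec)


@pytest.fixture(scope="session")
def compound_library(spec, scaffold_set):
    return generate_compounds(scaffold_set, spec)


@pytest.fixture(scope="session")
def space(scaffold_set):
    return build_reference_space(scaffold_set, source="test-fixture")


@pytest.fixture(scope="session")
def embedded(space, compound_library):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return embed_library(compound_library, space, z=4)
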