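import pytest

import metalscreen as ms
from metalscreen import registry


@pytest.fixture(scope="session")
def amines():
    return registry.default_amines()


@pytest.fixture(scope="session")
def pyridyl_alkynes():
    return registry.default_pyridyl_alkynes()


@pytest.fixture(scope="session")
def picolylamines():
    return registry.default_picolylamines()


@pytest.fixture(scope="session")
def aryl_alkynes():
    return registry.default_aryl_alkynes()


@pytest.fixture(scope="session")
def scaffolds():
    return registry.default_scaffolds()


@pytest.fixture(scope="session")
def scaffold_map(scaffolds):
    return {s.id: s for s in scaffolds}


@pytest.fixture(scope="session")
def t4p_ligands(amines, pyridyl_alkynes):
    return ms.enumerate_ligands(amines, pyridyl_alkynes)


@pytest.fixture(scope="session")
def t1mp_ligands(picolylamines, aryl_alkynes):
    return ms.enumerate_ligands(picolylamines, aryl_alkynes)


@pytest.fixture(scope="session")
def all_complexes(t4p_ligands, t1mp_ligands, scaffolds):
    return ms.assemble_complexes(t4p_ligands + t1mp_ligands, scaffolds)
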