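import pytest

from mtphylogeo import load_haplogroup_tree, load_reference


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def tree(reference):
    return load_haplogroup_tree(reference=reference)
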