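import pytest

from ergolabel import TracerSpec, load_atlas
from ergolabel.fragments import packaged_annotations_path, read_annotations


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def ergosterol(atlas):
    return atlas.molecule("ergosterol")


@pytest.fixture(scope="session")
def tracer():
    return TracerSpec()


@pytest.fixture(scope="session")
def annotations(atlas, ergosterol):
    return read_annotations(packaged_annotations_path(), ergosterol)
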