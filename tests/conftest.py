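import pytest

from therapylines import EngineConfig, assign_lines, datasets


@pytest.fixture(scope="session")
def reference_history():
    """The packaged ten-segment breast-cancer worked example."""
    return datasets.breast_cancer_history()


@pytest.fixture(scope="session")
def reference_annotated(reference_history):
    return assign_lines(reference_history)


@pytest.fixture()
def default_config():
    return EngineConfig()
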