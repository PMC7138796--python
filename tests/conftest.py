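import pytest

from stwintron import SplicingParams, builtin_templates, realize_template


@pytest.fixture(scope="session")
def params():
    return SplicingParams()


@pytest.fixture(scope="session")
def templates():
    return builtin_templates()


@pytest.fixture(scope="session")
def realized(templates):
    """One realization per built-in template at a fixed seed."""
    return {name: realize_template(t, seed=1) for name, t in templates.items()}
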