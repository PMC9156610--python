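import json
from pathlib import Path

import pytest

from cpmsize import load_registry

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def by_id(registry):
    return {sc.id: sc for sc in registry}


@pytest.fixture(scope="session")
def survival_reference():
    """Pinned final sizes from the independent numerical oracle (synthetic
    stand-in for an external reference run; see the fixture's comment)."""
    with open(FIXTURES / "survival_reference_synthetic.json") as fh:
        return json.load(fh)
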