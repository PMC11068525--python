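import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make `oracles` importable

from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tiny_chain():
    """A -> B activating, C -| B inhibiting."""
    from squadflow import build_topology
    return build_topology(["A", "B", "C"], [("A", "B", "+"), ("C", "B", "-")])


@pytest.fixture
def recovery_fixture():
    from squadflow.synthetic import three_gene_recovery
    return three_gene_recovery()
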