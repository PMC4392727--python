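from __future__ import annotations

import pytest

from epcaudit import enrich, worked_examples


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


@pytest.fixture(scope="session")
def albuterol_enriched(examples):
    """The beta2-agonist example KB after role harmonization and folding."""
    return enrich(examples["albuterol"].kb)
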