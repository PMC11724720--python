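"""Shared fixtures: one synthetic study bundle, featurized once per session."""

from __future__ import annotations

import pytest

from nrpcm import assemble, default_manifest, generate_all
from nrpcm.fixtures import FixtureConfig


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study (seed 42)."""
    return generate_all(FixtureConfig())


@pytest.fixture(scope="session")
def manifest():
    return default_manifest()


@pytest.fixture(scope="session")
def examples(bundle, manifest):
    """Featurized modeling examples (5 training targets x 300 compounds)."""
    ex, problems = assemble(bundle.train_records, bundle.panel, bundle.compounds, manifest)
    assert not problems
    return ex


@pytest.fixture(scope="session")
def external_examples(bundle, manifest):
    """Featurized held-out-target examples (external-style validation)."""
    ex, problems = assemble(
        bundle.external_records, bundle.panel, bundle.compounds, manifest
    )
    assert not problems
    return ex
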