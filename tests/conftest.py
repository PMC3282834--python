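"""Shared fixtures: small seeded synthetic scenarios."""

from __future__ import annotations

import pytest

from transqc.simulate import TruthSpec, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A compact all-features scenario: motifs, SL reads, singletons, decoys."""
    spec = TruthSpec(
        n_genes=60,
        seed=7,
        motif_fraction=0.1,
        sl_fraction=0.1,
        singleton_fraction=0.15,
        decoy_rate=0.2,
        depth_per_transcript=3,
    )
    return simulate_bundle(spec)


@pytest.fixture(scope="session")
def clean_bundle():
    """No paralogues, no flags, all isotigs: exact-recovery scenario."""
    spec = TruthSpec(
        n_genes=80,
        seed=11,
        motif_fraction=0.0,
        sl_fraction=0.0,
        singleton_fraction=0.0,
        decoy_rate=0.0,
        depth_per_transcript=2,
    )
    return simulate_bundle(spec)
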