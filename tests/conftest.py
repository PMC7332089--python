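"""Shared fixtures: small hand-made inputs plus one session-scoped default
synthetic benchmark (generation + similarity + clustering is the expensive
step, so it is built exactly once and shared read-only)."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

from hypbench.assembly import AssemblyConfig
from hypbench.io import ProteinRecord
from hypbench.pipeline import ClusteredBenchmark, cluster_and_assemble
from hypbench.synth import SyntheticBenchmark, SyntheticConfig, generate_proteome

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord(id="toy", sequence="AAAAAAPAAAAAA")


@dataclass
class BenchmarkBundle:
    data: SyntheticBenchmark
    clustered: ClusteredBenchmark


def _build(config: SyntheticConfig) -> BenchmarkBundle:
    data = generate_proteome(config)
    clustered = cluster_and_assemble(data.proteins, data.annotations,
                                     assembly=AssemblyConfig())
    return BenchmarkBundle(data=data, clustered=clustered)


@pytest.fixture(scope="session")
def default_benchmark() -> BenchmarkBundle:
    """The standard benchmark: default generator config, default pipeline."""
    return _build(SyntheticConfig())


@pytest.fixture(scope="session")
def small_benchmark() -> BenchmarkBundle:
    """A fast, reduced benchmark for tests that only need plumbing."""
    return _build(SyntheticConfig(n_collagen=3, n_other=30, seed=42))
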