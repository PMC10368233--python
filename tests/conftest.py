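"""Shared fixtures.

The session-scoped ``e2e`` fixture runs the full desk-scale protocol once —
simulation, leave-one-chromosome-out training of all three channel
configurations, tiled prediction of the held-out chromosome, shuffle
controls, and the ChIP-seq inner-product baseline — and is shared by every
test that asserts on end-to-end behavior.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pytest

from chromaloop.data_io import GenomeGrid
from chromaloop.evaluation import EvalSpec, MetricsReport
from chromaloop.synthetic import SyntheticConfig, simulate_trio
from chromaloop.workflow import (
    ExperimentResult,
    baseline_metrics,
    run_experiment,
    shuffle_metrics,
)

E2E_SEED = 1
E2E_TEST_CHROM = "chrA"


@pytest.fixture
def grid10() -> GenomeGrid:
    return GenomeGrid("chr1", 10_000, 500)


@pytest.fixture
def tiny_grid() -> GenomeGrid:
    return GenomeGrid("chrT", 10_000, 3)


@dataclass
class E2EBundle:
    results: Dict[str, ExperimentResult]
    baseline: Dict[str, MetricsReport]
    shuffle_hic: Dict[str, MetricsReport]
    shuffle_chip: Dict[str, MetricsReport]
    config: SyntheticConfig


@pytest.fixture(scope="session")
def e2e() -> E2EBundle:
    cfg = SyntheticConfig(seed=E2E_SEED)
    trio = simulate_trio(cfg)
    results = {
        mode: run_experiment(cfg, E2E_TEST_CHROM, mode=mode, trio=trio)
        for mode in ("both", "hic_only", "chip_only")
    }
    both = results["both"]
    spec = EvalSpec(band=both.band, seed=E2E_SEED)
    return E2EBundle(
        results=results,
        baseline=baseline_metrics(trio, both.labels, E2E_TEST_CHROM, both.band, spec),
        shuffle_hic=shuffle_metrics(both, "shuffleHiC", seed=E2E_SEED),
        shuffle_chip=shuffle_metrics(both, "shuffleChIPseq", seed=E2E_SEED),
        config=cfg,
    )
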