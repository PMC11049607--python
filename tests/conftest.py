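import numpy as np
import pytest

from panelcna import (PanelRegion, PlantedEvent, SimulationConfig,
                      simulate_dataset)


@pytest.fixture(scope="session")
def tiny_panel():
    """Three regions on three chromosomes; MYC is short (~10 bins)."""
    return [
        PanelRegion("MYC", "chr8", 128_600_000, 128_734_000),
        PanelRegion("TP53", "chr17", 7_400_000, 7_700_000),
        PanelRegion("EGFR", "chr7", 55_000_000, 55_400_000),
    ]


def make_events(panel, sample_ids, gene, total_copies):
    region = {r.gene: r for r in panel}[gene]
    return [
        PlantedEvent(s, gene, total_copies, region.chrom, region.start,
                     region.end)
        for s in sample_ids
    ]


@pytest.fixture(scope="session")
def small_dataset(tiny_panel):
    """Six-tumor cohort: CN=4 on MYC in three samples, purity 0.6-1.0."""
    samples = [f"BR{i:02d}" for i in range(1, 7)]
    cfg = SimulationConfig(
        seed=42,
        tumor_type_mix={"breast": 6},
        purity_range=(0.6, 1.0),
        event_table=make_events(tiny_panel, samples[:3], "MYC", 4),
    )
    return simulate_dataset(cfg, panel=tiny_panel)


@pytest.fixture(scope="session")
def neutral_dataset(tiny_panel):
    """Event-free cohort for null-case checks."""
    cfg = SimulationConfig(
        seed=7, tumor_type_mix={"breast": 4}, event_table=[]
    )
    return simulate_dataset(cfg, panel=tiny_panel)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
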