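import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from sweepscan.panel import GeneticMap, HaplotypePanel
from sweepscan.simulate import SimulationConfig, SweepSpec, simulate_panel


def make_panel(alleles, positions=None, pops=("A", "B"), chrom="chr1"):
    """Handmade panel: rows split evenly between the given populations."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap = alleles.shape[0]
    assert n_hap % (2 * len(pops)) == 0
    per_pop = n_hap // len(pops)
    samples, pop_of = [], {}
    for pi, pop in enumerate(pops):
        for d in range(per_pop // 2):
            s = f"{pop}{d}"
            samples.extend([s, s])
            pop_of[s] = pop
    if positions is None:
        positions = np.arange(alleles.shape[1]) * 30
    return HaplotypePanel(chrom, np.asarray(positions), alleles, samples, pop_of)


@pytest.fixture(scope="session")
def uniform_map():
    return GeneticMap.uniform("chr1", 1_000_000, 25.0)


@pytest.fixture(scope="session")
def neutral_sim():
    """Small neutral three-population panel reused across tests."""
    cfg = SimulationConfig(seed=11, chrom_length=150_000)
    panel, gmap, truth = simulate_panel(cfg)
    return panel, gmap, cfg


@pytest.fixture(scope="session")
def sweep_sim():
    """Panel with one planted hard sweep at high frequency."""
    cfg = SimulationConfig(
        seed=7, chrom_length=300_000,
        sweeps=[SweepSpec(core_position=150_000, selected_freq_focal=0.95,
                          founder_haplotypes=1, footprint_cm=0.1)])
    panel, gmap, truth = simulate_panel(cfg)
    return panel, gmap, truth, cfg
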