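import pytest

from lrstitch.io_formats import Contig
from lrstitch.pipeline import scaffold_assembly
from lrstitch.simulator import (SimConfig, evaluate, fragment_contigs,
                                simulate_genome, simulate_placements)


@pytest.fixture
def tiny_contigs():
    return {
        "c1": Contig("c1", 8, "ACGTACGT"),
        "c2": Contig("c2", 8, "ACGTTTTT"),
        "c3": Contig("c3", 4, "GGCC"),
    }


def run_simulation(config: SimConfig):
    """Full synthetic round: genome -> contigs -> placements -> scaffolds -> score."""
    genome, annotation = simulate_genome(config)
    contigs, layout = fragment_contigs(genome, annotation, config)
    contig_map = {c.id: c for c in contigs}
    placements = simulate_placements(layout, config)
    run = scaffold_assembly(contig_map, placements=placements)
    report = evaluate(run.scaffolds, layout, contig_map)
    return contig_map, layout, run, report


@pytest.fixture
def run_sim():
    return run_simulation
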