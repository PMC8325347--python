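import numpy as np
import pytest

from sigmaswitch.genome_io import GeneFeature, GenomeRecord
from sigmaswitch.simulate import PromoterDesign, SimulationSpec, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20210721)


@pytest.fixture
def small_genome():
    """500-bp replicon with two genes and three intergenic regions."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    genome = GenomeRecord("chr1", seq)
    genes = [
        GeneFeature("g1", "chr1", 101, 200, "+"),
        GeneFeature("g2", "chr1", 301, 400, "-"),
    ]
    return genome, genes


@pytest.fixture
def planted_simulation():
    """Simulated replicon with a mix of recoverable and filtered designs."""
    designs = (
        PromoterDesign(mm35=0, mm10=0, spacer=15, dist=50, strand="+"),
        PromoterDesign(mm35=1, mm10=1, spacer=13, dist=150, strand="-"),
        PromoterDesign(mm35=0, mm10=2, spacer=17, dist=199, strand="+"),
        PromoterDesign(mm35=0, mm10=0, spacer=15, dist=201, strand="+"),  # too far
        PromoterDesign(mm35=2, mm10=2, spacer=15, dist=60, strand="-", kind="decoy"),
    )
    spec = SimulationSpec(seed=11, promoters=designs, n_genes=6, gap_length=500)
    genome, genes, truth = generate_genome(spec)
    return spec, genome, genes, truth
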