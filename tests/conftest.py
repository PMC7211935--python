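import pytest

from tailstriage import (
    PipelineConfig,
    ProteinRecord,
    SyntheticDesign,
    synthesize_study,
)
from tailstriage.records import Domain


@pytest.fixture(scope="session")
def noiseless_study():
    """Noiseless, dropout-free study: the exact-recovery fixture (seed 13)."""
    design = SyntheticDesign(seed=13, noise_sd_log2=0.0, dropout_rate=0.0)
    proteins, truth, tables = synthesize_study(design)
    return design, proteins, truth, tables


@pytest.fixture(scope="session")
def noisy_study():
    """Default study conditions: effect 2, noise 0.5, 10% dropout."""
    design = SyntheticDesign(seed=7)
    proteins, truth, tables = synthesize_study(design)
    return design, proteins, truth, tables


def config_for(design: SyntheticDesign) -> PipelineConfig:
    return PipelineConfig(
        orientation=design.orientation_map,
        species_by_replicate={r.replicate_id: r.species for r in design.replicates},
        seed=design.seed,
    )


@pytest.fixture
def dkk3_like():
    """A DKK3-shaped record: cysteine-rich domains and hydrophobic sites."""
    seq = list("A" * 300)
    seq[125] = "M"  # P1 of the first cleavage (1-based 126)
    seq[251] = "I"  # P1 of the second (1-based 252)
    return ProteinRecord(
        accession="RAB-DKK3",
        gene_symbol="DKK3",
        species="rabbit",
        sequence="".join(seq),
        domains=(Domain("CRD1", 147, 203), Domain("CRD2", 213, 282)),
    )
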