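import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from fusionloci.synth import (  # noqa: E402
    ComplementPlantConfig,
    FusionPlantConfig,
    GenomeConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort: genome bundle, fusions and planted truth."""
    gcfg = GenomeConfig(n_chromosomes=3, genes_per_chrom=40)
    fcfg = FusionPlantConfig(
        n_read_through=20, n_intrachromosomal_non_adjacent=6, n_interchromosomal=4,
        n_sense_antisense=2,
        splice_class_counts={"GT-AG": 18, "GC-AG": 3, "AT-AC": 2, "CT-AC": 2,
                             "CT-GC": 2, "other": 3},
        boundary_counts={"both": 14, "gene1_only": 6, "gene2_only": 5, "neither": 5},
        frame_counts={"in_frame": 18, "frameshift": 7, "not_applicable": 5},
    )
    return generate_cohort(gcfg, fcfg, seed=11)


@pytest.fixture(scope="session")
def complement_cohort():
    """A cohort where every fusion has a planted reverse-complementary
    flank run at offsets -30..-11 of the up1/up2 combination."""
    gcfg = GenomeConfig(n_chromosomes=3, genes_per_chrom=60)
    fcfg = FusionPlantConfig(
        n_read_through=40, n_intrachromosomal_non_adjacent=6, n_interchromosomal=4,
        n_sense_antisense=1,
        splice_class_counts={"GT-AG": 50},
        boundary_counts={"both": 30, "gene1_only": 8, "gene2_only": 7, "neither": 5},
        frame_counts={"in_frame": 40, "frameshift": 6, "not_applicable": 4},
        complement=ComplementPlantConfig(n_fusions=50),
    )
    return generate_cohort(gcfg, fcfg, seed=3)
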