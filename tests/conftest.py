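import numpy as np
import pytest
from hypothesis import settings

from altstart.simulate import PlantedGeneSpec, SimulationConfig, generate_cohort
from altstart.startcall import train_start_model

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_training_cohort(seed: int = 11, n_genes: int = 80):
    """One undiverged genome with many annotated genes: E. coli-like start
    codon usage (~80/15/5 ATG/GTG/TTG) and SD motifs at spacers 5-9."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        genes.append(
            PlantedGeneSpec(
                f"tg{i:03d}",
                orf_length=120,
                start_codon=str(rng.choice(["ATG", "GTG", "TTG"], p=[0.8, 0.15, 0.05])),
                sd_spacer=int(rng.integers(5, 10)),
            )
        )
    cfg = SimulationConfig(
        seed=seed, n_genomes=1, contig_length=n_genes * 300 + 5000, genes=genes
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_model():
    cohort = make_training_cohort()
    gid = sorted(cohort.genomes)[0]
    return train_start_model(cohort.genomes[gid], cohort.annotations[gid])


@pytest.fixture(scope="session")
def small_cohort():
    """Five diverged genomes carrying one GTG regulator with a planted SD."""
    spec = PlantedGeneSpec("lacI", orf_length=300, start_codon="GTG", sd_spacer=7)
    cfg = SimulationConfig(
        seed=2, n_genomes=5, contig_length=6000, genes=[spec], divergence_rate=0.04
    )
    return generate_cohort(cfg)
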