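import numpy as np
import pandas as pd
import pytest

from admixpanel.ancestry import ReferencePanelFreqs
from admixpanel.freqs import population_allele_frequencies
from admixpanel.io import (
    MISSING,
    GenotypeMatrix,
    concat_samples,
    make_sample_table,
    make_variant_table,
)
from admixpanel.simulate import (
    AFT,
    BI,
    EUT,
    SimulationConfig,
    simulate_ancestral_frequencies,
    simulate_crossbreds,
    simulate_genotypes_from_freqs,
)


@pytest.fixture
def tiny_g() -> GenotypeMatrix:
    """3 samples x 4 SNPs, one missing call, two chromosomes."""
    variants = make_variant_table(
        ["s1", "s2", "s3", "s4"],
        ["1", "1", "2", "2"],
        [100, 5_000_000, 200, 900_000],
        ["A", "C", "G", "A"],
        ["B", "T", "T", "C"],
    )
    samples = make_sample_table(
        ["i1", "i2", "i3"], ["popA", "popA", "popB"], roles="reference"
    )
    dosage = np.array(
        [
            [0, 1, 2, 2],
            [1, MISSING, 2, 0],
            [2, 2, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(dosage=dosage, samples=samples, variants=variants)


def random_genotypes(
    rng: np.random.Generator,
    n_samples: int = 20,
    n_snps: int = 30,
    missing_rate: float = 0.1,
    population: str = "pop",
) -> GenotypeMatrix:
    dosage = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    positions = np.sort(
        rng.choice(10_000_000, size=n_snps, replace=False) + 1
    )
    variants = make_variant_table(
        [f"s{j}" for j in range(n_snps)],
        ["1"] * n_snps,
        positions,
    )
    samples = make_sample_table(
        [f"i{i}" for i in range(n_samples)], population, roles="crossbred"
    )
    return GenotypeMatrix(dosage=dosage, samples=samples, variants=variants)


@pytest.fixture(scope="session")
def sim_bundle():
    """Mid-size simulated world reused across module tests: ancestral
    frequencies, reference individuals, estimated reference frequencies and
    a crossbred cohort with truth."""
    cfg = SimulationConfig(seed=42, n_snps=800, n_reference=60, n_crossbred=150)
    anc = simulate_ancestral_frequencies(cfg)
    refs_g = concat_samples(
        simulate_genotypes_from_freqs(anc, pop, cfg.n_reference, seed=900 + i)
        for i, pop in enumerate((EUT, AFT, BI))
    )
    ref_freqs = population_allele_frequencies(refs_g)
    crossbreds, truth = simulate_crossbreds(
        anc, cfg.admixture_law, cfg.n_crossbred, seed=901
    )
    refs = ReferencePanelFreqs.from_table(
        ref_freqs, populations=[EUT, AFT, BI], dairy_populations=[EUT]
    )
    return {
        "config": cfg,
        "ancestral": anc,
        "ref_genotypes": refs_g,
        "ref_freqs": ref_freqs,
        "refs": refs,
        "crossbreds": crossbreds,
        "q_true": truth.q_true,
    }
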