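"""Shared fixtures: small synthetic datasets reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from retroquant.align import AlignParams, ReferenceIndex, assign_reads
from retroquant.simulate import (
    ConsensusLibrary,
    FamilySpec,
    GroupSpec,
    SimConfig,
    plant_genome,
    simulate_sample,
)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, n))


def mutate_at(seq: str, positions, shift: int = 1) -> str:
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[("ACGT".index(out[p]) + shift) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Zero-divergence, zero-error simulation: every read is an exact
    substring of a transcribed locus (or its reverse complement)."""
    cfg = SimConfig(
        seed=101,
        n_chromosomes=2,
        chromosome_length=40_000,
        families=(
            FamilySpec("FAMA", 600, 3, 0.0, 0.0, 0.3),
            FamilySpec("FAMB", 500, 3, 0.0, 0.0, 0.3),
        ),
        fraction_transcribed=1.0,
        expression_log_sd=0.5,
        expression_sample_sd=0.0,
        reads_per_sample=600,
        read_length=100,
        sequencing_error_rate=0.0,
        gdna_contamination=0.0,
        background_gene_fraction=0.0,
        n_background_genes=4,
        groups=(GroupSpec("g1", 1), GroupSpec("g2", 1)),
    )
    cfg.validate()
    library = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
    planted = plant_genome(cfg, library)
    reads, truth = simulate_sample(planted, cfg.groups[0], "g101")
    return cfg, library, planted, reads, truth


@pytest.fixture(scope="session")
def zero_noise_assignments(zero_noise_sim):
    cfg, library, planted, reads, truth = zero_noise_sim
    cons_index = ReferenceIndex(library.records)
    genome_index = ReferenceIndex(planted.chroms)
    ca = assign_reads(reads, cons_index, AlignParams(mode="unique_only"))
    ga = assign_reads(
        reads, genome_index, AlignParams(mode="multi_random", seed=7)
    )
    return ca, ga
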