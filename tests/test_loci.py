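"""Locus extraction, unique-mapping fractions, midpoint counting, scoring."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from retroquant.align import AlignmentHit, AlignParams, ReadAssignment, ReferenceIndex, assign_reads
from retroquant.loci import (
    chromosome_distribution,
    classify_locus_context,
    count_per_locus,
    extract_family_reads,
    score_locus,
    score_table,
    unique_mapping_fraction,
)
from retroquant.models import Gene, RepeatLocus
from retroquant.simulate import (
    ConsensusLibrary,
    FamilySpec,
    GroupSpec,
    SimConfig,
    plant_genome,
    simulate_sample,
)


def _hit(ref_id, start, length=100):
    return AlignmentHit(
        "r", ref_id, start, "+", (("=", length),), length, 0, 0, 0, 0, 0, 1.0, 1.0
    )


def _unique(read_id, chrom, start, length=100):
    return ReadAssignment(read_id, "unique", _hit(chrom, start, length), 1)


class TestExtractFamilyReads:
    FAMILY_OF = {"W-int": "W", "W-ltr": "W", "H-int": "H"}

    def _assign(self, read_id, status, ref):
        return ReadAssignment(
            read_id, status, _hit(ref, 0) if status == "unique" else None,
            1 if status == "unique" else 2,
        )

    def test_union_over_family_consensuses_no_duplicates(self):
        assignments = [
            self._assign("a", "unique", "W-int"),
            self._assign("b", "unique", "W-ltr"),
            self._assign("c", "unique", "H-int"),
            self._assign("d", "multi", "W-int"),
        ]
        ids = extract_family_reads(assignments, self.FAMILY_OF, "W")
        assert ids == {"a", "b"}

    def test_empty_when_no_reads_match(self):
        assert extract_family_reads([], self.FAMILY_OF, "H") == set()

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError, match="unknown family"):
            extract_family_reads([], self.FAMILY_OF, "K")


class TestUniqueMappingFraction:
    def test_empty_extracted_set_is_nan(self):
        assert math.isnan(unique_mapping_fraction(set(), []))

    def test_fraction_counts_unique_statuses(self):
        ga = [
            _unique("a", "chr1", 0),
            ReadAssignment("b", "multi", None, 2),
            ReadAssignment("c", "unassigned", None, 0),
        ]
        assert unique_mapping_fraction({"a", "b", "c"}, ga) == pytest.approx(1 / 3)

    def test_two_identical_planted_copies_give_zero(self):
        cfg = SimConfig(
            seed=91,
            n_chromosomes=1,
            chromosome_length=30_000,
            families=(FamilySpec("DUP", 600, 2, 0.0, 0.0, 0.0),),
            fraction_transcribed=1.0,
            expression_sample_sd=0.0,
            reads_per_sample=200,
            sequencing_error_rate=0.0,
            gdna_contamination=0.0,
            background_gene_fraction=0.0,
            n_background_genes=2,
            groups=(GroupSpec("a", 1), GroupSpec("b", 1)),
        )
        cfg.validate()
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        reads, _ = simulate_sample(planted, cfg.groups[0], "dup1")
        ga = assign_reads(reads, ReferenceIndex(planted.chroms), AlignParams())
        ids = {r for r, _ in reads}
        assert unique_mapping_fraction(ids, ga) == 0.0

    def test_single_copy_gives_one(self):
        cfg = SimConfig(
            seed=92,
            n_chromosomes=1,
            chromosome_length=20_000,
            families=(FamilySpec("ONE", 600, 1, 0.0, 0.0, 0.0),),
            fraction_transcribed=1.0,
            expression_sample_sd=0.0,
            reads_per_sample=100,
            sequencing_error_rate=0.0,
            gdna_contamination=0.0,
            background_gene_fraction=0.0,
            n_background_genes=2,
            groups=(GroupSpec("a", 1), GroupSpec("b", 1)),
        )
        cfg.validate()
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        reads, _ = simulate_sample(planted, cfg.groups[0], "one1")
        ga = assign_reads(reads, ReferenceIndex(planted.chroms), AlignParams())
        assert unique_mapping_fraction({r for r, _ in reads}, ga) == 1.0


class TestCountPerLocus:
    LOCI = [
        RepeatLocus("L1", "chr1", 1000, 1600, "+", "FAM"),
        RepeatLocus("L2", "chr1", 3000, 3500, "+", "FAM"),
    ]

    def test_midpoint_rule_at_boundaries(self):
        reads = [
            _unique("in1", "chr1", 1200),       # midpoint 1250, inside L1
            _unique("edge_in", "chr1", 960),    # midpoint 1010, inside L1
            _unique("edge_out", "chr1", 940),   # midpoint 990, outside
            _unique("in2", "chr1", 3100),       # inside L2
        ]
        counts, off = count_per_locus(reads, self.LOCI)
        assert counts["L1"] == 2 and counts["L2"] == 1
        assert off == 1

    def test_conservation_counts_plus_off_equals_unique(self):
        rng = np.random.default_rng(4)
        reads = [
            _unique(f"r{i}", "chr1", int(rng.integers(0, 4000))) for i in range(60)
        ] + [ReadAssignment("m", "multi", None, 2)]
        counts, off = count_per_locus(reads, self.LOCI)
        assert counts.sum() + off == 60

    def test_overlapping_annotation_raises_naming_pair(self):
        bad = self.LOCI + [RepeatLocus("L3", "chr1", 1500, 1700, "+", "FAM")]
        with pytest.raises(ValueError, match="L1.*L3|L3.*L1"):
            count_per_locus([], bad)


class TestScoreLocus:
    @pytest.mark.parametrize(
        "count,score",
        [(0, 0), (2, 0), (3, 1), (29, 1), (30, 2), (299, 2), (300, 3),
         (2999, 3), (3000, 4), (29999, 4), (30000, 5), (10**6, 5)],
    )
    def test_detection_floor_and_log_decade_bins(self, count, score):
        assert score_locus(count) == score

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            score_locus(-1)

    def test_custom_edges(self):
        assert score_locus(5, edges=(5, 10)) == 1
        assert score_locus(10, edges=(5, 10)) == 2

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10**5), min_size=1, max_size=20))
    def test_scores_nondecreasing_when_counts_doubled(self, counts):
        before = [score_locus(c) for c in counts]
        after = [score_locus(2 * c) for c in counts]
        assert all(b <= a for b, a in zip(before, after))


class TestChromosomeDistribution:
    def test_single_chromosome_both_fractions_one(self):
        loci = [RepeatLocus("L1", "chr1", 100, 700, "+", "F")]
        reads = [_unique("a", "chr1", 200)]
        df = chromosome_distribution(loci, reads)
        assert df.loc["chr1", "content_fraction"] == 1.0
        assert df.loc["chr1", "read_fraction"] == 1.0

    def test_content_fractions_from_annotated_bases(self):
        loci = [
            RepeatLocus("L1", "chr1", 0, 600, "+", "F"),
            RepeatLocus("L2", "chr2", 0, 400, "+", "F"),
        ]
        df = chromosome_distribution(loci, [])
        assert df.loc["chr1", "content_fraction"] == pytest.approx(0.6)
        assert df.loc["chr2", "content_fraction"] == pytest.approx(0.4)

    def test_reads_without_content_reported(self):
        loci = [RepeatLocus("L1", "chr1", 0, 600, "+", "F")]
        reads = [_unique("a", "chr2", 100)]
        df = chromosome_distribution(loci, reads)
        assert df.loc["chr2", "content_fraction"] == 0.0
        assert df.loc["chr2", "read_fraction"] == 1.0

    def test_fraction_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        loci = [
            RepeatLocus(f"L{i}", f"chr{1 + i % 3}", i * 1000, i * 1000 + 300, "+", "F")
            for i in range(9)
        ]
        reads = [
            _unique(f"r{i}", f"chr{1 + int(rng.integers(3))}", int(rng.integers(5000)))
            for i in range(40)
        ]
        df = chromosome_distribution(loci, reads)
        assert df["content_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert df["read_fraction"].sum() == pytest.approx(1.0, abs=1e-9)


class TestLocusContext:
    GENES = [Gene("G1", "chr1", 1000, 4000, "+", ((1000, 1300), (3700, 4000)))]

    def test_intronic_with_host_gene(self):
        loci = [RepeatLocus("L1", "chr1", 2000, 2500, "+", "F")]
        ctx = classify_locus_context(loci, self.GENES)
        assert ctx.loc["L1", "context"] == "intronic"
        assert ctx.loc["L1", "host_gene"] == "G1"

    def test_intergenic(self):
        loci = [RepeatLocus("L1", "chr1", 8000, 8500, "+", "F")]
        ctx = classify_locus_context(loci, self.GENES)
        assert ctx.loc["L1", "context"] == "intergenic"

    def test_exon_overlapping_flagged(self):
        loci = [RepeatLocus("L1", "chr1", 1200, 1600, "+", "F")]
        ctx = classify_locus_context(loci, self.GENES)
        assert ctx.loc["L1", "context"] == "exon_overlapping"

    def test_simulated_intronic_fraction_recovered(self):
        cfg = SimConfig(
            seed=17,
            n_chromosomes=2,
            chromosome_length=120_000,
            families=(FamilySpec("FAM", 400, 40, 0.02, 0.0, 0.5),),
            n_background_genes=0,
            groups=(GroupSpec("a", 1), GroupSpec("b", 1)),
        )
        cfg.validate()
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        ctx = classify_locus_context(planted.repeat_annotation, planted.genes)
        frac = (ctx["context"] == "intronic").mean()
        assert 0.3 < frac < 0.7  # binomial check around the configured 0.5
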