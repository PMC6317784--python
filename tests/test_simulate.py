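"""Synthetic-data generator: determinism, ground-truth accounting, planting."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from retroquant.align import align_read
from retroquant.simulate import (
    CapacityError,
    ConfigurationError,
    ConsensusLibrary,
    FamilySpec,
    GroupSpec,
    SimConfig,
    _revcomp,
    generate_consensus_library,
    plant_genome,
    simulate_cohort,
    simulate_cohort_counts,
    simulate_sample,
)


class TestConsensusLibrary:
    def test_generate_counts_lengths_names(self):
        lib = generate_consensus_library(3, (200, 1000), seed=7)
        assert len(lib.records) == 3
        assert len(set(lib.records)) == 3
        for seq in lib.records.values():
            assert 200 <= len(seq) <= 1000
            assert set(seq) <= set("ACGT")

    def test_deterministic_for_fixed_seed(self, tmp_path):
        a = generate_consensus_library(3, (200, 1000), seed=7)
        b = generate_consensus_library(3, (200, 1000), seed=7)
        assert a.records == b.records
        a.write_fasta(tmp_path / "a.fa")
        b.write_fasta(tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_zero_families_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            generate_consensus_library(0, (200, 1000), seed=7)

    def test_invalid_length_range_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            generate_consensus_library(2, (1000, 200), seed=7)


class TestPlantGenome:
    def _config(self, **kw):
        base = dict(
            seed=5,
            n_chromosomes=2,
            chromosome_length=50_000,
            families=(FamilySpec("FAM", 500, 5, 0.0, 0.0, 0.0),),
            n_background_genes=5,
            groups=(GroupSpec("a", 1), GroupSpec("b", 1)),
        )
        base.update(kw)
        return SimConfig(**base)

    def test_full_length_untruncated_copies(self):
        cfg = self._config()
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        assert len(planted.loci) == 5
        assert all(
            lt.locus.has_5prime_end and lt.locus.has_3prime_end
            for lt in planted.loci
        )

    def test_zero_divergence_copies_match_consensus_strand_adjusted(self):
        cfg = self._config()
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        cons = lib.records["FAM"]
        for lt in planted.loci:
            l = lt.locus
            seq = planted.chroms[l.chrom][l.start : l.end]
            if l.strand == "-":
                seq = _revcomp(seq)
            assert seq == cons

    def test_full_truncation_probability_drops_one_end(self):
        cfg = self._config(
            families=(FamilySpec("FAM", 500, 8, 0.0, 1.0, 0.0),),
        )
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        for lt in planted.loci:
            assert lt.locus.is_pseudoelement
            assert lt.locus.length >= cfg.read_length
            # the surviving segment still matches the consensus terminus
            cons = lib.records["FAM"]
            seq = planted.chroms[lt.locus.chrom][lt.locus.start : lt.locus.end]
            if lt.locus.strand == "-":
                seq = _revcomp(seq)
            if lt.locus.has_5prime_end:
                assert cons.startswith(seq)
            else:
                assert cons.endswith(seq)

    def test_copies_do_not_overlap(self):
        cfg = self._config(
            families=(
                FamilySpec("A", 400, 10, 0.05, 0.3, 0.4),
                FamilySpec("B", 300, 10, 0.05, 0.3, 0.4),
            )
        )
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        by_chrom: dict[str, list] = {}
        for lt in planted.loci:
            by_chrom.setdefault(lt.locus.chrom, []).append(lt.locus)
        for ls in by_chrom.values():
            ls.sort(key=lambda l: l.start)
            for a, b in zip(ls, ls[1:]):
                assert a.end <= b.start

    def test_intronic_copies_lie_within_host_gene_intron(self):
        cfg = self._config(families=(FamilySpec("FAM", 400, 10, 0.0, 0.0, 1.0),))
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        hosts = {g.gene_id: g for g in planted.genes if g.gene_id.startswith("HOST")}
        assert len(hosts) == 10
        for lt in planted.loci:
            host = [
                g
                for g in hosts.values()
                if g.chrom == lt.locus.chrom
                and g.start < lt.locus.start
                and lt.locus.end < g.end
            ]
            assert len(host) == 1
            intron = host[0].introns[0]
            assert intron[0] < lt.locus.start and lt.locus.end < intron[1]

    def test_capacity_error_when_genome_too_small(self):
        cfg = self._config(
            chromosome_length=2000,
            families=(FamilySpec("FAM", 500, 10, 0.0, 0.0, 0.0),),
        )
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        with pytest.raises(CapacityError):
            plant_genome(cfg, lib)


class TestSimulateSample:
    def test_read_count_and_origin_accounting(self, zero_noise_sim):
        cfg, library, planted, reads, truth = zero_noise_sim
        assert len(reads) == cfg.reads_per_sample
        assert len(truth) == cfg.reads_per_sample
        # every read id has exactly one truth record
        assert truth["read_id"].is_unique
        assert set(truth["origin_class"]) <= {"locus", "gene", "gdna"}

    def test_zero_noise_reads_are_exact_locus_substrings(self, zero_noise_sim):
        cfg, library, planted, reads, truth = zero_noise_sim
        truth_by_id = truth.set_index("read_id")
        for read_id, seq in reads[:100]:
            row = truth_by_id.loc[read_id]
            assert row["origin_class"] == "locus"
            chrom_seq = planted.chroms[row["chrom"]]
            frag = chrom_seq[row["start"] : row["end"]]
            assert seq in (frag, _revcomp(frag))

    def test_paired_mode_emits_synchronized_mates(self):
        cfg = SimConfig(
            seed=9,
            n_chromosomes=1,
            chromosome_length=50_000,
            families=(FamilySpec("FAM", 600, 4, 0.0, 0.0, 0.0),),
            fraction_transcribed=1.0,
            reads_per_sample=200,
            paired=True,
            n_background_genes=5,
            groups=(GroupSpec("a", 1), GroupSpec("b", 1)),
        )
        cfg.validate()
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        reads, truth = simulate_sample(planted, cfg.groups[0], "p1")
        assert len(reads) == 2 * cfg.reads_per_sample
        ids = [r for r, _ in reads]
        assert all(
            ids[i].endswith("/1") and ids[i + 1].endswith("/2")
            and ids[i][:-2] == ids[i + 1][:-2]
            for i in range(0, len(ids), 2)
        )
        assert all(len(s) == cfg.read_length for _, s in reads)

    def test_background_only_mixture_has_no_repeat_reads(self):
        cfg = SimConfig(
            seed=13,
            n_chromosomes=1,
            chromosome_length=50_000,
            families=(FamilySpec("FAM", 600, 4, 0.0, 0.0, 0.0),),
            fraction_transcribed=0.0,
            reads_per_sample=300,
            gdna_contamination=0.0,
            background_gene_fraction=1.0,
            n_background_genes=5,
            groups=(GroupSpec("a", 1), GroupSpec("b", 1)),
        )
        cfg.validate()
        lib = ConsensusLibrary.from_family_specs(cfg.families, cfg.seed)
        planted = plant_genome(cfg, lib)
        _, truth = simulate_sample(planted, cfg.groups[0], "b1")
        assert (truth["origin_class"] == "gene").all()

    def test_zero_divergence_reads_align_to_source_consensus_with_identity(
        self, zero_noise_sim
    ):
        cfg, library, planted, reads, truth = zero_noise_sim
        fam_of_locus = {lt.locus.locus_id: lt.locus.family for lt in planted.loci}
        truth_by_id = truth.set_index("read_id")
        for read_id, seq in reads[:40]:
            fam = fam_of_locus[truth_by_id.loc[read_id, "origin_id"]]
            hits = align_read(seq, library.records, read_id=read_id)
            assert any(h.ref_id == fam and h.similarity == 1.0 for h in hits)


class TestCohort:
    def test_single_group_is_configuration_error(self):
        cfg = SimConfig(groups=(GroupSpec("only", 3),))
        with pytest.raises(ConfigurationError):
            simulate_cohort(cfg)

    def test_empty_group_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SimConfig(
                groups=(GroupSpec("a", 0), GroupSpec("b", 3))
            ).validate()

    def test_cohort_outputs_are_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(
            seed=21,
            n_chromosomes=1,
            chromosome_length=40_000,
            families=(FamilySpec("FAM", 500, 4, 0.05, 0.2, 0.3),),
            reads_per_sample=150,
            n_background_genes=5,
            groups=(GroupSpec("x", 2), GroupSpec("y", 2)),
        )
        simulate_cohort(cfg, tmp_path / "run1")
        simulate_cohort(cfg, tmp_path / "run2")
        files1 = sorted(p.relative_to(tmp_path / "run1") for p in (tmp_path / "run1").rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(tmp_path / "run2") for p in (tmp_path / "run2").rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (tmp_path / "run1" / rel).read_bytes() == (
                tmp_path / "run2" / rel
            ).read_bytes(), rel

    def test_group_multiplier_scales_family_read_share(self):
        cfg = SimConfig(
            seed=33,
            n_chromosomes=2,
            chromosome_length=80_000,
            families=(
                FamilySpec("UP", 500, 6, 0.05, 0.0, 0.0),
                FamilySpec("FLAT", 500, 6, 0.05, 0.0, 0.0),
            ),
            fraction_transcribed=1.0,
            expression_log_sd=0.5,
            expression_sample_sd=0.0,
            reads_per_sample=20_000,
            background_gene_fraction=0.7,
            gdna_contamination=0.05,
            n_background_genes=10,
            groups=(
                GroupSpec("ctrl", 10),
                GroupSpec("case", 10, {"UP": 2.0}),
            ),
        )
        df = simulate_cohort_counts(cfg)
        frac = df.set_index(["group"]).eval("UP / total_reads")
        ratio = frac.loc["case"].mean() / frac.loc["ctrl"].mean()
        # case/ctrl UP-origin share ~2x ctrl (slightly shrunk by renormalization)
        assert 1.6 < ratio < 2.1
        flat = df.set_index(["group"]).eval("FLAT / total_reads")
        assert 0.85 < flat.loc["case"].mean() / flat.loc["ctrl"].mean() < 1.15

    def test_null_multiplier_groups_are_exchangeable(self):
        cfg = SimConfig(
            seed=44,
            families=(FamilySpec("FAM", 500, 6, 0.05, 0.0, 0.0),),
            fraction_transcribed=1.0,
            reads_per_sample=5_000,
            n_background_genes=8,
            groups=(GroupSpec("g1", 12), GroupSpec("g2", 12)),
        )
        df = simulate_cohort_counts(cfg)
        g = df.groupby("group")["FAM"].mean()
        assert abs(g["g1"] - g["g2"]) / g.mean() < 0.25

    def test_counts_mode_origin_totals(self):
        cfg = SimConfig(
            seed=55,
            families=(FamilySpec("FAM", 500, 5, 0.05, 0.2, 0.3),),
            reads_per_sample=1000,
            groups=(GroupSpec("a", 2), GroupSpec("b", 2)),
        )
        df = simulate_cohort_counts(cfg)
        sums = df[["gdna", "background", "FAM"]].sum(axis=1)
        assert (sums == cfg.reads_per_sample).all()
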