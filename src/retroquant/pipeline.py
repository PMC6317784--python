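"""End-to-end pipeline: align -> quantify -> locus-map -> score -> compare.

Stages run per sample against the consensus library (unique matches only)
and the genome (multi-hits randomly assigned, which supplies the
mappable-read denominator); family reads are then remapped per region to
annotated loci, scored, and group contrasts are tested.  All result tables
carry a header comment with version, seed and a parameter digest, and a
rerun with an identical configuration is byte-identical.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .align import AlignParams, ReferenceIndex, assign_reads, mappable_read_count
from .loci import (
    DEFAULT_SCORE_EDGES,
    chromosome_distribution,
    classify_locus_context,
    count_per_locus,
    extract_family_reads,
    score_table,
    unique_mapping_fraction,
)
from .quantify import SampleQuant, classify_genomic_context, count_per_consensus, region_average, spearman_pairwise
from .stats import compare_groups

log = logging.getLogger("retroquant")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    consensus: Path
    genome: Path
    repeats: Path
    genes: Path
    sample_sheet: Path
    outdir: Path
    seed: int = 0
    align: AlignParams = field(default_factory=AlignParams)
    families_of_interest: list[str] = field(default_factory=list)
    family_map: dict[str, str] = field(default_factory=dict)
    score_edges: tuple[int, ...] = DEFAULT_SCORE_EDGES
    contrasts: list[tuple[str, str]] = field(default_factory=list)

    @staticmethod
    def from_yaml(path: str | Path, outdir: str | Path | None = None) -> "PipelineConfig":
        path = Path(path)
        data = rio.load_yaml(path)
        base = path.parent

        def _p(key: str) -> Path:
            if key not in data:
                raise ValueError(f"configuration is missing required path {key!r}")
            p = Path(data[key])
            return p if p.is_absolute() else base / p

        align_kwargs = data.get("align", {})
        contrasts = []
        for c in data.get("contrasts", []):
            if isinstance(c, str):
                a, _, b = c.partition(":")
                contrasts.append((a, b))
            else:
                contrasts.append((c[0], c[1]))
        return PipelineConfig(
            consensus=_p("consensus"),
            genome=_p("genome"),
            repeats=_p("repeats"),
            genes=_p("genes"),
            sample_sheet=_p("sample_sheet"),
            outdir=Path(outdir) if outdir else _p("outdir"),
            seed=int(data.get("seed", 0)),
            align=AlignParams(mode="multi_random", **align_kwargs),
            families_of_interest=list(data.get("families_of_interest", [])),
            family_map=dict(data.get("family_map", {})),
            score_edges=tuple(data.get("score_edges", DEFAULT_SCORE_EDGES)),
            contrasts=contrasts,
        )

    def validate(self) -> None:
        for key in ("consensus", "genome", "repeats", "genes", "sample_sheet"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")


def _sample_seed(seed: int, sample_id: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(sample_id.encode())) % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with the stage name and input context.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": config.seed,
        "params": rio.params_digest(
            {
                "align": vars(config.align) if not hasattr(config.align, "__dataclass_fields__") else str(config.align),
                "score_edges": list(config.score_edges),
                "seed": config.seed,
            }
        ),
    }

    stage = "load-inputs"
    try:
        consensus = rio.read_fasta(config.consensus)
        genome = rio.read_fasta(config.genome)
        loci = rio.read_bed_repeats(config.repeats)
        genes = rio.read_genes(config.genes)
        sheet = rio.read_sample_sheet(config.sample_sheet)
        family_of = dict(config.family_map) or {
            l.family: l.family for l in loci
        } | {name: name for name in consensus}
        families = config.families_of_interest or sorted({l.family for l in loci})

        cons_index = ReferenceIndex(consensus)
        genome_index = ReferenceIndex(genome)
        cons_params = AlignParams(
            similarity_min=config.align.similarity_min,
            length_fraction_min=config.align.length_fraction_min,
            mismatch_cost=config.align.mismatch_cost,
            insertion_cost=config.align.insertion_cost,
            deletion_cost=config.align.deletion_cost,
            mode="unique_only",
        )

        stage = "align"
        squants: list[SampleQuant] = []
        context_rows = {}
        cons_assign = {}
        genome_assign = {}
        base = Path(config.sample_sheet).parent
        for _, row in sheet.iterrows():
            sample_id = row["sample_id"]
            log.info("stage=align sample=%s", sample_id)
            fq1 = base / row["fastq_1"]
            if row.get("fastq_2"):
                reads = list(rio.read_fastq((fq1, base / row["fastq_2"])))
            else:
                reads = list(rio.read_fastq(fq1))
            ca = assign_reads(reads, cons_index, cons_params)
            gparams = AlignParams(
                similarity_min=config.align.similarity_min,
                length_fraction_min=config.align.length_fraction_min,
                mismatch_cost=config.align.mismatch_cost,
                insertion_cost=config.align.insertion_cost,
                deletion_cost=config.align.deletion_cost,
                mode="multi_random",
                seed=_sample_seed(config.seed, sample_id),
            )
            ga = assign_reads(reads, genome_index, gparams)
            cons_assign[sample_id] = ca
            genome_assign[sample_id] = ga
            total = mappable_read_count(ga)
            counts = count_per_consensus(ca, list(consensus))
            squants.append(
                SampleQuant(
                    sample_id=sample_id,
                    region=row.get("region", ""),
                    group=row.get("group", ""),
                    total_mappable=total,
                    counts=counts,
                )
            )
            context_rows[sample_id] = classify_genomic_context(ga, genes).as_dict()

        stage = "quantify"
        log.info("stage=quantify")
        counts_df = pd.DataFrame({s.sample_id: s.counts for s in squants}).rename_axis("consensus")
        rpm_df = pd.DataFrame({s.sample_id: s.normalized for s in squants}).rename_axis("consensus")
        totals = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in squants],
                "region": [s.region for s in squants],
                "group": [s.group for s in squants],
                "total_mappable": [s.total_mappable for s in squants],
                "repeat_unique_reads": [sum(s.counts.values()) for s in squants],
            }
        ).set_index("sample_id")
        context_df = pd.DataFrame(context_rows).T.rename_axis("sample_id")

        quant_dir = out / "quant"
        quant_dir.mkdir(exist_ok=True)
        rio.write_tsv(quant_dir / "counts.tsv", counts_df, meta)
        rio.write_tsv(quant_dir / "rpm.tsv", rpm_df, meta)
        rio.write_tsv(quant_dir / "totals.tsv", totals, meta)
        rio.write_tsv(quant_dir / "context.tsv", context_df, meta)

        regions = sorted({s.region for s in squants})
        prof_dir = out / "profiles"
        prof_dir.mkdir(exist_ok=True)
        means = {
            r: region_average([s for s in squants if s.region == r]) for r in regions
        }
        means_df = pd.DataFrame(means).rename_axis("consensus")
        rio.write_tsv(prof_dir / "region_means.tsv", means_df, meta)
        if len(regions) >= 2 and means_df.shape[0] >= 3:
            rio.write_tsv(prof_dir / "spearman.tsv", spearman_pairwise(means_df), meta)

        stage = "locus-map"
        locus_dir = out / "locus"
        locus_dir.mkdir(exist_ok=True)
        sheet_regions = {row["sample_id"]: row.get("region", "") for _, row in sheet.iterrows()}
        score_rows = []
        uf_rows = []
        chrom_rows = []
        ctx = classify_locus_context(loci, genes)
        for family in families:
            fam_loci = [l for l in loci if l.family == family]
            if not fam_loci:
                continue
            for region in regions:
                rsamples = [s for s, r in sheet_regions.items() if r == region]
                pooled_ids: set[str] = set()
                pooled_ga = []
                for s in rsamples:
                    # read ids are globally unique (sample id embedded)
                    ids = extract_family_reads(cons_assign[s], family_of, family)
                    pooled_ids |= ids
                    pooled_ga.extend(
                        a for a in genome_assign[s] if a.read_id in ids
                    )
                log.info(
                    "stage=locus-map family=%s region=%s reads=%d",
                    family,
                    region,
                    len(pooled_ids),
                )
                uf = unique_mapping_fraction(pooled_ids, pooled_ga)
                uf_rows.append(
                    {
                        "family": family,
                        "region": region,
                        "extracted_reads": len(pooled_ids),
                        "unique_fraction": uf,
                    }
                )
                counts, off = count_per_locus(pooled_ga, fam_loci)
                st = score_table(counts, config.score_edges)
                for locus_id, r in st.iterrows():
                    score_rows.append(
                        {
                            "family": family,
                            "region": region,
                            "locus_id": locus_id,
                            "read_count": int(r["read_count"]),
                            "score": int(r["score"]),
                            "context": ctx.loc[locus_id, "context"],
                            "host_gene": ctx.loc[locus_id, "host_gene"],
                            "off_annotation_reads": off,
                        }
                    )
                cd = chromosome_distribution(fam_loci, pooled_ga, chromosomes=list(genome))
                for chrom, r in cd.iterrows():
                    chrom_rows.append(
                        {
                            "family": family,
                            "region": region,
                            "chrom": chrom,
                            "content_fraction": r["content_fraction"],
                            "read_fraction": r["read_fraction"],
                        }
                    )
        rio.write_tsv(locus_dir / "scores.tsv", pd.DataFrame(score_rows), meta, index=False)
        rio.write_tsv(locus_dir / "unique_fraction.tsv", pd.DataFrame(uf_rows), meta, index=False)
        rio.write_tsv(
            locus_dir / "chrom_distribution.tsv", pd.DataFrame(chrom_rows), meta, index=False
        )

        stage = "compare"
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        if config.contrasts:
            log.info("stage=compare contrasts=%s", config.contrasts)
            var_df = totals.reset_index()[["sample_id", "group"]].copy()
            var_df["total_repeat_fraction"] = (
                totals["repeat_unique_reads"] / totals["total_mappable"]
            ).to_numpy()
            for family in families:
                members = [c for c in rpm_df.index if family_of.get(c) == family]
                var_df[f"rpm_{family}"] = rpm_df.loc[members].sum(axis=0).reindex(
                    var_df["sample_id"]
                ).to_numpy()
            variables = ["total_repeat_fraction"] + [f"rpm_{f}" for f in families]
            comparisons = compare_groups(var_df, variables, config.contrasts)
            cmp_meta = dict(meta)
            cmp_meta["note"] = comparisons.attrs["note"]
            rio.write_tsv(stats_dir / "comparisons.tsv", comparisons, cmp_meta, index=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
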