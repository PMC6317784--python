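"""Synthetic genomes, repeat annotations and cohort read sets with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a toy genome carrying planted, diverged, optionally truncated copies
of several repeat families; transcription of a known subset of loci with
log-normally distributed levels; background gene transcription; optional
genomic-DNA contamination; and cohorts of samples in two or more diagnostic
groups whose family expression is scaled by group multipliers.

Reads are drawn from transcribed loci proportionally to expression x length,
strands are unstranded (either orientation with probability 0.5), and all
outputs are byte-identical for a fixed configuration: per-sample generators
are derived from the root seed by stable hashing of the sample id, so adding
samples does not perturb existing ones.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .models import Gene, RepeatLocus

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class CapacityError(RuntimeError):
    """Genome too small to host the requested repeat copies and genes."""


def _child_rng(seed: int, *tokens: str | int) -> np.random.Generator:
    """Stable child generator: root seed plus CRC32-hashed string tokens."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            entropy.append(zlib.crc32(t.encode()))
        else:
            entropy.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(entropy)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution at ``rate``; substitutions never produce N."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # shift each hit base by 1-3 positions in the ACGT alphabet
        code = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(code + rng.integers(1, 4, hit.size)) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class FamilySpec:
    """Shape of one synthetic repeat family."""

    family_name: str
    consensus_length: int = 800
    copy_number: int = 12
    divergence_rate: float = 0.05
    truncation_prob: float = 0.2
    intronic_fraction: float = 0.3

    def validate(self, read_length: int) -> None:
        if self.consensus_length < max(50, read_length):
            raise ConfigurationError(
                f"{self.family_name}: consensus_length must be >= read length"
            )
        if self.copy_number < 1:
            raise ConfigurationError(f"{self.family_name}: copy_number must be >= 1")
        if not (0.0 <= self.divergence_rate <= 0.2):
            raise ConfigurationError(
                f"{self.family_name}: divergence_rate must be in [0, 0.2]"
            )
        for name in ("truncation_prob", "intronic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{self.family_name}: {name} must be in [0,1]")


@dataclass(frozen=True)
class GroupSpec:
    """A diagnostic group: label, size, per-family expression multipliers.

    ``multipliers`` maps family name -> factor; a bare float applies to every
    family; missing families default to 1.0.
    """

    label: str
    n_samples: int
    multipliers: dict[str, float] | float = field(default_factory=dict)

    def factor(self, family: str) -> float:
        if isinstance(self.multipliers, (int, float)):
            return float(self.multipliers)
        return float(self.multipliers.get(family, 1.0))


def default_families() -> list[FamilySpec]:
    return [
        FamilySpec("ERVF1", 900, 12, 0.05, 0.2, 0.3),
        FamilySpec("ERVF2", 700, 12, 0.08, 0.2, 0.3),
        FamilySpec("ERVF3", 800, 20, 0.03, 0.2, 0.3),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration (defaults are the package's reference
    study conditions; see the methods note)."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 120_000
    families: tuple[FamilySpec, ...] = field(
        default_factory=lambda: tuple(default_families())
    )
    fraction_transcribed: float = 0.5
    expression_log_mean: float = 0.0
    expression_log_sd: float = 2.0
    reads_per_sample: int = 20_000
    read_length: int = 100
    paired: bool = False
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    sequencing_error_rate: float = 0.002
    gdna_contamination: float = 0.05
    background_gene_fraction: float = 0.75
    groups: tuple[GroupSpec, ...] = field(
        default_factory=lambda: (GroupSpec("control", 8), GroupSpec("case", 8))
    )
    region: str = "regionA"
    n_background_genes: int = 25
    gene_exon_length: int = 300
    gene_intron_length: int = 1200
    intron_pad: int = 150
    expression_sample_sd: float = 0.3
    gene_exonic_only: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", tuple(self.families))
        object.__setattr__(self, "groups", tuple(self.groups))

    def validate(self) -> None:
        for name in (
            "fraction_transcribed",
            "sequencing_error_rate",
            "gdna_contamination",
            "background_gene_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.gdna_contamination + self.background_gene_fraction > 1.0 + 1e-12:
            raise ConfigurationError(
                "gdna_contamination + background_gene_fraction must be <= 1"
            )
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "reads_per_sample",
            "read_length",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.read_length < 20:
            raise ConfigurationError("read_length must be >= 20")
        if not self.families:
            raise ConfigurationError("at least one repeat family is required")
        names = [f.family_name for f in self.families]
        if len(set(names)) != len(names):
            raise ConfigurationError("family names must be unique")
        for f in self.families:
            f.validate(self.read_length)
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("group labels must be unique")
        for g in self.groups:
            if g.n_samples < 1:
                raise ConfigurationError(f"group {g.label!r} must have >= 1 sample")
        if self.expression_log_sd < 0 or self.expression_sample_sd < 0:
            raise ConfigurationError("expression spreads must be non-negative")

    @staticmethod
    def from_dict(data: dict) -> "SimConfig":
        data = dict(data)
        fams = tuple(FamilySpec(**f) for f in data.pop("families", []))
        groups = tuple(GroupSpec(**g) for g in data.pop("groups", []))
        cfg = SimConfig(
            **data,
            **({"families": fams} if fams else {}),
            **({"groups": groups} if groups else {}),
        )
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Consensus library


@dataclass
class ConsensusLibrary:
    """Named consensus sequences grouped into repeat families."""

    records: dict[str, str]
    family_of: dict[str, str]

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, fam in self.family_of.items():
            out.setdefault(fam, []).append(name)
        return out

    def write_fasta(self, path: str | Path) -> None:
        rio.write_fasta(path, self.records)

    @staticmethod
    def from_family_specs(
        families: Sequence[FamilySpec], seed: int
    ) -> "ConsensusLibrary":
        records: dict[str, str] = {}
        family_of: dict[str, str] = {}
        for spec in families:
            rng = _child_rng(seed, "consensus", spec.family_name)
            records[spec.family_name] = _random_bases(rng, spec.consensus_length)
            family_of[spec.family_name] = spec.family_name
        return ConsensusLibrary(records, family_of)


def generate_consensus_library(
    n_families: int,
    length_range: tuple[int, int] = (600, 1200),
    seed: int = 0,
    prefix: str = "FAM",
) -> ConsensusLibrary:
    """Random consensus library: one sequence per family, unique names."""
    if n_families < 1:
        raise ConfigurationError("n_families must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 50 or hi < lo:
        raise ConfigurationError(f"invalid length range ({lo}, {hi})")
    records: dict[str, str] = {}
    family_of: dict[str, str] = {}
    for i in range(n_families):
        name = f"{prefix}{i + 1:02d}"
        rng = _child_rng(seed, "consensus", name)
        length = int(rng.integers(lo, hi + 1))
        records[name] = _random_bases(rng, length)
        family_of[name] = name
    return ConsensusLibrary(records, family_of)


# ---------------------------------------------------------------------------
# Genome planting


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth for one planted locus."""

    locus: RepeatLocus
    consensus: str  # consensus name the copy derives from
    transcribed: bool
    expression: float  # relative level; 0 when not transcribed


@dataclass
class PlantedGenome:
    chroms: dict[str, str]
    loci: list[LocusTruth]
    genes: list[Gene]
    config: SimConfig

    @property
    def repeat_annotation(self) -> list[RepeatLocus]:
        return [lt.locus for lt in self.loci]

    def locus_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": lt.locus.locus_id,
                "chrom": lt.locus.chrom,
                "start": lt.locus.start,
                "end": lt.locus.end,
                "strand": lt.locus.strand,
                "family": lt.locus.family,
                "has_5prime_end": lt.locus.has_5prime_end,
                "has_3prime_end": lt.locus.has_3prime_end,
                "transcribed": lt.transcribed,
                "expression": lt.expression,
            }
            for lt in self.loci
        ]
        return pd.DataFrame(rows).set_index("locus_id")

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "repeats": outdir / "repeats.bed",
            "genes": outdir / "genes.bed",
            "locus_truth": outdir / "locus_truth.tsv",
        }
        rio.write_fasta(paths["genome"], self.chroms)
        rio.write_bed_repeats(paths["repeats"], self.repeat_annotation)
        rio.write_genes_bed12(paths["genes"], self.genes)
        rio.write_tsv(paths["locus_truth"], self.locus_table(), {"seed": self.config.seed})
        return paths


def plant_genome(config: SimConfig, library: ConsensusLibrary) -> PlantedGenome:
    """Plant diverged, optionally truncated repeat copies and gene models on a
    random genome.  Copies never overlap each other or genes; intronic copies
    lie strictly within a host gene's intron."""
    config.validate()
    rng = _child_rng(config.seed, "plant")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_len = config.chromosome_length
    chrom_arrays = {
        name: np.frombuffer(
            _random_bases(rng, chrom_len).encode(), dtype=np.uint8
        ).copy()
        for name in chrom_names
    }

    fam_consensuses = library.families()
    min_len = max(50, config.read_length)

    # build the list of objects to place: (kind, payload, length)
    objects: list[tuple] = []
    for spec in config.families:
        if spec.family_name not in fam_consensuses:
            raise ConfigurationError(
                f"family {spec.family_name!r} missing from consensus library"
            )
        cons_names = fam_consensuses[spec.family_name]
        for i in range(spec.copy_number):
            cname = cons_names[int(rng.integers(len(cons_names)))]
            cons = library.records[cname]
            has5 = has3 = True
            seq = cons
            if rng.random() < spec.truncation_prob:
                frac = rng.uniform(0.1, 0.5)
                cut = int(frac * len(cons))
                cut = min(cut, len(cons) - min_len)
                if cut > 0:
                    if rng.random() < 0.5:
                        seq = cons[cut:]
                        has5 = False
                    else:
                        seq = cons[:-cut]
                        has3 = False
            seq = _mutate(seq, spec.divergence_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            intronic = rng.random() < spec.intronic_fraction
            locus_id = f"{spec.family_name}_L{i + 1:03d}"
            objects.append(
                ("copy", (locus_id, spec.family_name, cname, seq, strand, has5, has3), intronic)
            )
    for i in range(config.n_background_genes):
        objects.append(("bg_gene", f"BG{i + 1:03d}", False))

    def obj_span(obj) -> int:
        kind, payload, intronic = obj
        if kind == "bg_gene":
            return 2 * config.gene_exon_length + config.gene_intron_length
        seq = payload[3]
        if intronic:
            return 2 * config.gene_exon_length + 2 * config.intron_pad + len(seq)
        return len(seq)

    total_bases = sum(obj_span(o) for o in objects)
    genome_bases = config.n_chromosomes * chrom_len
    if total_bases >= 0.8 * genome_bases:
        raise CapacityError(
            f"planted objects need {total_bases} bases but the genome has "
            f"{genome_bases} (limit 80%)"
        )

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def try_place(span: int) -> tuple[str, int]:
        for _ in range(2000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            if span + 2 > chrom_len:
                continue
            start = int(rng.integers(1, chrom_len - span - 1))
            if all(e2 <= start or s2 >= start + span for s2, e2 in occupied[chrom]):
                occupied[chrom].append((start, start + span))
                return chrom, start
        raise CapacityError("could not place all objects without overlap")

    loci: list[LocusTruth] = []
    genes: list[Gene] = []
    gene_counter = 0
    for kind, payload, intronic in objects:
        if kind == "bg_gene":
            span = 2 * config.gene_exon_length + config.gene_intron_length
            chrom, start = try_place(span)
            e1 = (start, start + config.gene_exon_length)
            e2 = (start + config.gene_exon_length + config.gene_intron_length, start + span)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(payload, chrom, start, start + span, strand, (e1, e2)))
            continue
        locus_id, family, cname, seq, strand, has5, has3 = payload
        if intronic:
            ex = config.gene_exon_length
            pad = config.intron_pad
            span = 2 * ex + 2 * pad + len(seq)
            chrom, start = try_place(span)
            gene_counter += 1
            gid = f"HOST{gene_counter:03d}"
            gstrand = "+" if rng.random() < 0.5 else "-"
            e1 = (start, start + ex)
            e2 = (start + span - ex, start + span)
            genes.append(Gene(gid, chrom, start, start + span, gstrand, (e1, e2)))
            lstart = start + ex + pad
        else:
            chrom, lstart = try_place(len(seq))
        lend = lstart + len(seq)
        placed = seq if strand == "+" else _revcomp(seq)
        chrom_arrays[chrom][lstart:lend] = np.frombuffer(placed.encode(), dtype=np.uint8)
        locus = RepeatLocus(locus_id, chrom, lstart, lend, strand, family, has5, has3)
        transcribed = bool(rng.random() < config.fraction_transcribed)
        expression = (
            float(rng.lognormal(config.expression_log_mean, config.expression_log_sd))
            if transcribed
            else 0.0
        )
        loci.append(LocusTruth(locus, cname, transcribed, expression))

    chroms = {name: arr.tobytes().decode() for name, arr in chrom_arrays.items()}
    loci.sort(key=lambda lt: (lt.locus.chrom, lt.locus.start))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return PlantedGenome(chroms, loci, genes, config)


_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_RC)[::-1].decode()


# ---------------------------------------------------------------------------
# Read sampling


def _origin_categories(
    planted: PlantedGenome, group: GroupSpec, rng: np.random.Generator
):
    """Origin categories and probabilities for one sample.

    Returns (labels, probs): labels are ('gdna', '.'), ('gene', gene_id) and
    ('locus', locus_id) tuples.  Family expression is scaled by the group
    multiplier and a per-sample log-normal jitter; the repeat share of the
    transcript pool scales accordingly relative to the fixed background gene
    weight, so at multiplier 1 the expected mixture equals the configured
    gdna / background / repeat proportions.
    """
    cfg = planted.config
    g = cfg.gdna_contamination
    b = cfg.background_gene_fraction
    r0 = max(0.0, 1.0 - g - b)

    eligible = [
        lt
        for lt in planted.loci
        if lt.transcribed and lt.locus.length >= cfg.read_length
    ]
    base_w = np.array([lt.expression * lt.locus.length for lt in eligible])
    s0 = float(base_w.sum())
    jitter: dict[str, float] = {}
    for spec in cfg.families:
        jitter[spec.family_name] = (
            float(rng.lognormal(0.0, cfg.expression_sample_sd))
            if cfg.expression_sample_sd > 0
            else 1.0
        )
    mult = np.array(
        [group.factor(lt.locus.family) * jitter[lt.locus.family] for lt in eligible]
    )
    w = base_w * mult
    s = float(w.sum())

    rep_raw = r0 * (s / s0) if s0 > 0 else 0.0
    denom = rep_raw + b
    if denom > 0:
        p_rep = (1.0 - g) * rep_raw / denom
        p_bg = (1.0 - g) - p_rep
    else:
        p_rep = p_bg = 0.0
    if g + p_rep + p_bg <= 0:
        raise ConfigurationError("read mixture has zero total probability")

    labels: list[tuple[str, str]] = [("gdna", ".")]
    probs: list[float] = [g]
    if p_bg > 0 and planted.genes:
        glens = np.array([gene.end - gene.start for gene in planted.genes], float)
        gp = p_bg * glens / glens.sum()
        for gene, p in zip(planted.genes, gp):
            labels.append(("gene", gene.gene_id))
            probs.append(float(p))
    if p_rep > 0 and s > 0:
        lp = p_rep * w / s
        for lt, p in zip(eligible, lp):
            labels.append(("locus", lt.locus.locus_id))
            probs.append(float(p))
    probs_arr = np.array(probs)
    probs_arr /= probs_arr.sum()
    return labels, probs_arr


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    return _mutate(seq, rate, rng)


def simulate_sample(
    planted: PlantedGenome,
    group: GroupSpec,
    sample_id: str,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one sample's reads and per-read ground truth.

    Returns (reads, truth): reads are (read_id, sequence) in emission order
    (mates interleaved ``/1``, ``/2`` in paired mode); truth has one row per
    FASTQ record with the read's origin class, origin id and coordinates.
    """
    cfg = planted.config
    rng = _child_rng(cfg.seed, "sample", sample_id)
    labels, probs = _origin_categories(planted, group, rng)
    counts = rng.multinomial(cfg.reads_per_sample, probs)

    genes_by_id = {g.gene_id: g for g in planted.genes}
    loci_by_id = {lt.locus.locus_id: lt.locus for lt in planted.loci}
    chrom_names = list(planted.chroms)
    chrom_lens = np.array([len(planted.chroms[c]) for c in chrom_names], float)
    chrom_p = chrom_lens / chrom_lens.sum()

    # assemble (origin_class, origin_id, chrom, interval) per fragment, then
    # shuffle so origins are interleaved in the output
    frags: list[tuple[str, str, str, int, int]] = []
    L = cfg.read_length
    for (kind, oid), n in zip(labels, counts):
        for _ in range(int(n)):
            if cfg.paired:
                flen = int(round(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd)))
                flen = max(L, flen)
            else:
                flen = L
            if kind == "gdna":
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                limit = len(planted.chroms[chrom])
            elif kind == "gene":
                gene = genes_by_id[oid]
                if cfg.gene_exonic_only:
                    exons = [e for e in gene.exons if e[1] - e[0] >= L]
                    s_, e_ = exons[int(rng.integers(len(exons)))]
                    flen_eff = min(flen, e_ - s_)
                    pos = int(rng.integers(s_, e_ - flen_eff + 1))
                    frags.append((kind, oid, gene.chrom, pos, pos + flen_eff))
                    continue
                chrom, lo, hi = gene.chrom, gene.start, gene.end
                flen_eff = min(flen, hi - lo)
                pos = int(rng.integers(lo, hi - flen_eff + 1))
                frags.append((kind, oid, chrom, pos, pos + flen_eff))
                continue
            else:
                locus = loci_by_id[oid]
                chrom, lo, hi = locus.chrom, locus.start, locus.end
                flen_eff = min(flen, hi - lo)
                pos = int(rng.integers(lo, hi - flen_eff + 1))
                frags.append((kind, oid, chrom, pos, pos + flen_eff))
                continue
            flen_eff = min(flen, limit)
            pos = int(rng.integers(0, limit - flen_eff + 1))
            frags.append((kind, oid, chrom, pos, pos + flen_eff))

    order = rng.permutation(len(frags))
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    err = cfg.sequencing_error_rate
    for out_i, idx in enumerate(order):
        kind, oid, chrom, fs, fe = frags[idx]
        frag = planted.chroms[chrom][fs:fe]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = _revcomp(frag)
        base_id = f"{sample_id}:r{out_i + 1:07d}"
        if cfg.paired:
            r1 = _apply_errors(frag[:L], err, rng)
            r2 = _apply_errors(_revcomp(frag[-L:]), err, rng)
            for mate, seq in (("1", r1), ("2", r2)):
                reads.append((f"{base_id}/{mate}", seq))
                truth_rows.append(
                    {
                        "read_id": f"{base_id}/{mate}",
                        "origin_class": kind,
                        "origin_id": oid,
                        "chrom": chrom,
                        "start": fs,
                        "end": fe,
                        "strand": strand,
                    }
                )
        else:
            seq = _apply_errors(frag, err, rng)
            reads.append((base_id, seq))
            truth_rows.append(
                {
                    "read_id": base_id,
                    "origin_class": kind,
                    "origin_id": oid,
                    "chrom": chrom,
                    "start": fs,
                    "end": fe,
                    "strand": strand,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "origin_class", "origin_id", "chrom", "start", "end", "strand"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSim:
    """In-memory result of a cohort simulation."""

    config: SimConfig
    library: ConsensusLibrary
    planted: PlantedGenome
    sample_sheet: pd.DataFrame
    reads: dict[str, list[tuple[str, str]]]
    truth: pd.DataFrame  # per-read truth with a sample_id column


def simulate_cohort(config: SimConfig, outdir: str | Path | None = None) -> CohortSim:
    """Simulate a full cohort; optionally write all artifacts under ``outdir``.

    Requires at least two diagnostic groups (single-group comparisons are a
    configuration error).
    """
    config.validate()
    if len(config.groups) < 2:
        raise ConfigurationError("a cohort needs at least two groups")
    library = ConsensusLibrary.from_family_specs(config.families, config.seed)
    planted = plant_genome(config, library)

    sheet_rows = []
    reads: dict[str, list[tuple[str, str]]] = {}
    truth_parts = []
    for group in config.groups:
        for i in range(group.n_samples):
            sample_id = f"{group.label}{i + 1:02d}"
            r, t = simulate_sample(planted, group, sample_id)
            reads[sample_id] = r
            t.insert(0, "sample_id", sample_id)
            truth_parts.append(t)
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "region": config.region,
                    "group": group.label,
                    "fastq_1": f"reads/{sample_id}_1.fastq" if config.paired else f"reads/{sample_id}.fastq",
                    "fastq_2": f"reads/{sample_id}_2.fastq" if config.paired else "",
                }
            )
    sheet = pd.DataFrame(sheet_rows, columns=rio.SAMPLE_SHEET_COLUMNS)
    truth = pd.concat(truth_parts, ignore_index=True)
    sim = CohortSim(config, library, planted, sheet, reads, truth)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "reads").mkdir(parents=True, exist_ok=True)
        planted.write(outdir)
        library.write_fasta(outdir / "consensus.fa")
        rio.write_sample_sheet(outdir / "samples.tsv", sheet)
        rio.write_tsv(outdir / "read_truth.tsv", truth, {"seed": config.seed}, index=False)
        for sample_id, rs in reads.items():
            if config.paired:
                r1 = [(rid, s) for rid, s in rs if rid.endswith("/1")]
                r2 = [(rid, s) for rid, s in rs if rid.endswith("/2")]
                rio.write_fastq(outdir / "reads" / f"{sample_id}_1.fastq", r1)
                rio.write_fastq(outdir / "reads" / f"{sample_id}_2.fastq", r2)
            else:
                rio.write_fastq(outdir / "reads" / f"{sample_id}.fastq", rs)
    return sim


def simulate_cohort_counts(
    config: SimConfig,
    planted: PlantedGenome | None = None,
    cohort: int | str = 0,
) -> pd.DataFrame:
    """Counts-only cohort: per-sample true origin counts without sequences.

    Draws each sample's reads from the same origin-category distribution the
    read simulator uses, aggregated to family level.  Used for statistical
    calibration at cohort scales where emitting sequence is unnecessary.
    Returns a tidy frame: sample_id, group, total_reads, gdna, background and
    one column per family.
    """
    config.validate()
    if len(config.groups) < 2:
        raise ConfigurationError("a cohort needs at least two groups")
    if planted is None:
        library = ConsensusLibrary.from_family_specs(config.families, config.seed)
        planted = plant_genome(config, library)
    fam_of_locus = {lt.locus.locus_id: lt.locus.family for lt in planted.loci}
    fams = [f.family_name for f in config.families]
    rows = []
    for group in config.groups:
        for i in range(group.n_samples):
            sample_id = f"{group.label}{i + 1:02d}"
            rng = _child_rng(config.seed, "counts", str(cohort), sample_id)
            labels, probs = _origin_categories(planted, group, rng)
            counts = rng.multinomial(config.reads_per_sample, probs)
            row = {
                "sample_id": sample_id,
                "group": group.label,
                "total_reads": config.reads_per_sample,
                "gdna": 0,
                "background": 0,
            }
            for f in fams:
                row[f] = 0
            for (kind, oid), n in zip(labels, counts):
                if kind == "gdna":
                    row["gdna"] += int(n)
                elif kind == "gene":
                    row["background"] += int(n)
                else:
                    row[fam_of_locus[oid]] += int(n)
            rows.append(row)
    return pd.DataFrame(rows)
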