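"""Readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open everywhere; conversions happen
only at format boundaries (BED is native, GTF is shifted on ingest).
FASTQ/FASTA input may be gzip-compressed (detected by suffix).
"""
from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import Gene, RepeatLocus

FASTQ_QUALITY_CHAR = "I"  # constant Phred+33 quality; qualities are unused


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name->sequence dict.

    Sequences are upper-cased and U is normalised to T.  Duplicate names and
    empty sequences are format errors.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA record name {rec.id!r}")
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
            out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def _strip_mate(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def read_fastq(
    path: str | Path | Sequence[str | Path],
) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file or a synchronized pair.

    For a pair, mates are yielded alternately with ``/1`` / ``/2`` suffixes
    normalised onto the ids; desynchronised pairs raise at the first
    mismatching record.
    """
    if isinstance(path, (str, Path)):
        with _open_text(path) as fh:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                if len(seq) != len(qual):
                    raise ValueError(f"FASTQ record {i}: sequence/quality length mismatch")
                yield title.split()[0], seq.upper().replace("U", "T")
        return
    p1, p2 = path
    with _open_text(p1) as fh1, _open_text(p2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for i, ((t1, s1, q1), (t2, s2, q2)) in enumerate(zip(it1, it2)):
            id1 = _strip_mate(t1.split()[0])
            id2 = _strip_mate(t2.split()[0])
            if id1 != id2:
                raise ValueError(
                    f"desynchronised FASTQ pair at record {i}: {id1!r} != {id2!r}"
                )
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise ValueError(f"FASTQ record {i}: sequence/quality length mismatch")
            yield id1 + "/1", s1.upper().replace("U", "T")
            yield id2 + "/2", s2.upper().replace("U", "T")


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{FASTQ_QUALITY_CHAR * len(seq)}\n")


# ---------------------------------------------------------------------------
# Repeat annotation (BED6 + family, has_5prime_end, has_3prime_end)

def read_bed_repeats(path: str | Path) -> list[RepeatLocus]:
    loci: list[RepeatLocus] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: expected 9 BED columns, got {len(f)}")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            loci.append(
                RepeatLocus(
                    locus_id=f[3],
                    chrom=f[0],
                    start=start,
                    end=end,
                    strand=f[5],
                    family=f[6],
                    has_5prime_end=f[7] == "1",
                    has_3prime_end=f[8] == "1",
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.locus_id))
    return loci


def write_bed_repeats(path: str | Path, loci: Iterable[RepeatLocus]) -> None:
    loci = sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.locus_id))
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                "\t".join(
                    [
                        l.chrom,
                        str(l.start),
                        str(l.end),
                        l.locus_id,
                        "0",
                        l.strand,
                        l.family,
                        "1" if l.has_5prime_end else "0",
                        "1" if l.has_3prime_end else "0",
                    ]
                )
                + "\n"
            )


def convert_repeatmasker_out(
    path: str | Path, family_map: dict[str, str] | None = None
) -> list[RepeatLocus]:
    """Convert a RepeatMasker .out table to repeat loci.

    ``family_map`` optionally maps repeat names to family labels (defaults to
    the repeat name itself).  Completeness flags are set from the repeat-end
    columns: a copy is taken to have its 5' (3') end when the match reaches
    within 20 bases of the consensus start (end).
    """
    loci: list[RepeatLocus] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if not f or not f[0].isdigit():
                continue  # header / blank lines
            chrom, start, end = f[4], int(f[5]) - 1, int(f[6])
            strand = "+" if f[8] == "+" else "-"
            name = f[9]
            if strand == "+":
                rep_begin, rep_left = int(f[11]), f[13]
            else:
                rep_begin, rep_left = int(f[13].strip("()") or 0), f[11]
            rep_left = int(str(rep_left).strip("()") or 0)
            family = (family_map or {}).get(name, name)
            loci.append(
                RepeatLocus(
                    locus_id=f"{name}_{chrom}_{start}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    family=family,
                    has_5prime_end=rep_begin <= 20,
                    has_3prime_end=rep_left <= 20,
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.locus_id))
    return loci


# ---------------------------------------------------------------------------
# Gene annotation: BED12 (native) or GTF-lite

def read_genes(path: str | Path) -> list[Gene]:
    """Read gene models from BED12 or GTF (detected by suffix)."""
    path = Path(path)
    suffixes = {s.lstrip(".") for s in path.suffixes}
    if "gtf" in suffixes or "gff" in suffixes:
        return _read_genes_gtf(path)
    return _read_genes_bed12(path)


def _read_genes_bed12(path: Path) -> list[Gene]:
    genes: list[Gene] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected BED12, got {len(f)} columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(Gene(f[3], chrom, start, end, f[5], exons))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def _read_genes_gtf(path: Path) -> list[Gene]:
    """Minimal GTF reader: collects exon features grouped by gene_id
    (1-based closed coordinates shifted to 0-based half-open on ingest)."""
    exons: dict[str, list[tuple[str, int, int, str]]] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: malformed GTF line")
            if f[2] != "exon":
                continue
            start, end = int(f[3]) - 1, int(f[4])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end after conversion")
            gene_id = None
            for attr in f[8].split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('" ')
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{ln}: exon without gene_id attribute")
            exons.setdefault(gene_id, []).append((f[0], start, end, f[6]))
    genes = []
    for gene_id, exs in exons.items():
        chrom = exs[0][0]
        strand = exs[0][3]
        coords = sorted((s, e) for _, s, e, _ in exs)
        genes.append(
            Gene(gene_id, chrom, coords[0][0], max(e for _, e in coords), strand, tuple(coords))
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def write_genes_bed12(path: str | Path, genes: Iterable[Gene]) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    with open(path, "w") as fh:
        for g in genes:
            exs = sorted(g.exons)
            sizes = ",".join(str(e - s) for s, e in exs)
            offsets = ",".join(str(s - g.start) for s, e in exs)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0,0,0",
                        str(len(exs)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet

SAMPLE_SHEET_COLUMNS = ["sample_id", "region", "group", "fastq_1", "fastq_2"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in sample sheet")
    return df


def write_sample_sheet(path: str | Path, df: pd.DataFrame) -> None:
    cols = [c for c in SAMPLE_SHEET_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in SAMPLE_SHEET_COLUMNS
    ]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables with a reproducibility header

def params_digest(params: object) -> str:
    """Stable 12-hex digest of a parameter mapping/dataclass for TSV headers."""
    try:
        from dataclasses import asdict, is_dataclass

        if is_dataclass(params):
            params = asdict(params)
    except TypeError:
        pass
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(
    path: str | Path,
    df: pd.DataFrame,
    meta: dict | None = None,
    index: bool = True,
) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# retroquant {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# SAM export

def write_sam(
    path: str | Path,
    assignments: Iterable,
    references: dict[str, str],
    reads: dict[str, str] | None = None,
) -> None:
    """Write chosen alignments as SAM 1.6 (clips as soft clips, NM tag =
    mismatches + gap bases).  Unassigned reads are emitted as unmapped when
    their sequence is available in ``reads``."""
    from .align import revcomp

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:retroquant\tPN:retroquant\n")
        for a in assignments:
            hit = a.chosen_hit
            if hit is None:
                if reads and a.read_id in reads:
                    seq = reads[a.read_id]
                    fh.write(
                        f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t"
                        f"{FASTQ_QUALITY_CHAR * len(seq)}\n"
                    )
                continue
            flag = 16 if hit.strand == "-" else 0
            cigar = "".join(
                f"{n}{'M' if op in '=X' else op}" for op, n in _merge_cigar(hit.ops)
            )
            nm = hit.n_mismatch + hit.n_ins_bases + hit.n_del_bases
            mapq = 60 if a.status == "unique" else 0
            if reads and a.read_id in reads:
                seq = reads[a.read_id]
                if hit.strand == "-":
                    seq = revcomp(seq)
                qual = FASTQ_QUALITY_CHAR * len(seq)
            else:
                seq, qual = "*", "*"
            fh.write(
                f"{a.read_id}\t{flag}\t{hit.ref_id}\t{hit.ref_start + 1}\t{mapq}\t"
                f"{cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{nm}\n"
            )


def _merge_cigar(ops: tuple[tuple[str, int], ...]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        op = "M" if op in "=X" else op
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


# ---------------------------------------------------------------------------
# Assignment tables (TSV serialisation of ReadAssignment lists)


def ops_to_string(ops: tuple[tuple[str, int], ...]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def string_to_ops(s: str) -> tuple[tuple[str, int], ...]:
    import re

    return tuple((m.group(2), int(m.group(1))) for m in re.finditer(r"(\d+)([=XIDS])", s))


def write_assignments(path: str | Path, assignments: Iterable) -> None:
    cols = [
        "read_id",
        "status",
        "n_best_hits",
        "ref_id",
        "ref_start",
        "strand",
        "ops",
        "n_match",
        "n_mismatch",
        "n_ins_bases",
        "n_del_bases",
        "n_clip_bases",
        "cost",
        "similarity",
        "length_fraction",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in assignments:
            h = a.chosen_hit
            if h is None:
                fh.write(f"{a.read_id}\t{a.status}\t{a.n_best_hits}" + "\t." * 12 + "\n")
            else:
                fh.write(
                    "\t".join(
                        [
                            a.read_id,
                            a.status,
                            str(a.n_best_hits),
                            h.ref_id,
                            str(h.ref_start),
                            h.strand,
                            ops_to_string(h.ops),
                            str(h.n_match),
                            str(h.n_mismatch),
                            str(h.n_ins_bases),
                            str(h.n_del_bases),
                            str(h.n_clip_bases),
                            str(h.cost),
                            f"{h.similarity:.8f}",
                            f"{h.length_fraction:.8f}",
                        ]
                    )
                    + "\n"
                )


def read_assignments(path: str | Path) -> list:
    from .align import AlignmentHit, ReadAssignment

    out = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hit = None
            if f[idx["ref_id"]] != ".":
                hit = AlignmentHit(
                    read_id=f[idx["read_id"]],
                    ref_id=f[idx["ref_id"]],
                    ref_start=int(f[idx["ref_start"]]),
                    strand=f[idx["strand"]],
                    ops=string_to_ops(f[idx["ops"]]),
                    n_match=int(f[idx["n_match"]]),
                    n_mismatch=int(f[idx["n_mismatch"]]),
                    n_ins_bases=int(f[idx["n_ins_bases"]]),
                    n_del_bases=int(f[idx["n_del_bases"]]),
                    n_clip_bases=int(f[idx["n_clip_bases"]]),
                    cost=int(f[idx["cost"]]),
                    similarity=float(f[idx["similarity"]]),
                    length_fraction=float(f[idx["length_fraction"]]),
                )
            out.append(
                ReadAssignment(
                    f[idx["read_id"]], f[idx["status"]], hit, int(f[idx["n_best_hits"]])
                )
            )
    return out


# ---------------------------------------------------------------------------
# YAML configuration

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return data


def dump_yaml(path: str | Path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
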