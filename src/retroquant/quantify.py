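"""Per-consensus counting, normalization and profile comparison.

Family-level expression is quantified as the number of reads uniquely
assigned to each consensus sequence, normalised to reads per million
genome-mappable reads:

    normalized[c] = unique_count[c] / total_mappable * 1e6

where ``total_mappable`` is the sample's read count against the genome with
multi-hits randomly assigned.  Region profiles are arithmetic means of the
per-sample normalised vectors (mean of ratios, not ratio of sums), and
profiles are compared by Spearman rank correlation with average ranks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .align import ReadAssignment
from .models import Gene


@dataclass
class SampleQuant:
    """Per-sample consensus quantification."""

    sample_id: str
    region: str
    group: str
    total_mappable: int
    counts: dict[str, int]
    normalized: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.normalized = normalize(self.counts, self.total_mappable)


@dataclass(frozen=True)
class ContextFractions:
    """Fractions of uniquely genome-mapped reads by genomic context."""

    exonic: float
    intronic: float
    intergenic: float

    def as_dict(self) -> dict[str, float]:
        return {
            "exonic": self.exonic,
            "intronic": self.intronic,
            "intergenic": self.intergenic,
        }


def count_per_consensus(
    assignments: Iterable[ReadAssignment],
    consensus_names: Sequence[str],
) -> dict[str, int]:
    """Unique-read counts per consensus.

    Reads ambiguous across (or within) consensuses are multi and excluded;
    consensuses with zero counts are retained in the vector.
    """
    counts = {name: 0 for name in consensus_names}
    for a in assignments:
        if a.status == "unique":
            counts[a.chosen_hit.ref_id] += 1
    return counts


def normalize(counts: Mapping[str, int], total_mappable: int) -> dict[str, float]:
    """Reads-per-million-mappable normalization: count / total * 1e6."""
    if total_mappable <= 0:
        raise ZeroDivisionError(
            "total_mappable must be positive to normalise counts"
        )
    return {c: n / total_mappable * 1e6 for c, n in counts.items()}


def region_average(samples: Sequence[SampleQuant]) -> pd.Series:
    """Per-consensus arithmetic mean of normalised values across samples."""
    if not samples:
        raise ValueError("region_average requires at least one sample")
    df = pd.DataFrame([s.normalized for s in samples])
    return df.mean(axis=0)


def spearman_pairwise(vectors: Mapping[str, pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of per-consensus profile vectors.

    Vectors must share the consensus index and have length >= 3.  A constant
    vector has undefined rank correlation; the corresponding entries are NaN
    and a warning is issued.
    """
    if not isinstance(vectors, pd.DataFrame):
        vectors = pd.DataFrame(vectors)
    if vectors.shape[1] < 2:
        raise ValueError("need at least two profile vectors")
    if vectors.shape[0] < 3:
        raise ValueError("profile vectors must have length >= 3")
    if vectors.isna().any().any():
        raise ValueError("profile vectors contain missing values")
    names = list(vectors.columns)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            if vectors[a].nunique() == 1 or vectors[b].nunique() == 1:
                warnings.warn(
                    f"constant profile vector in pair ({a}, {b}); rho undefined",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rho = np.nan
            else:
                rho = float(sps.spearmanr(vectors[a], vectors[b]).statistic)
            out.loc[a, b] = rho
            out.loc[b, a] = rho
    return out


def _gene_trees(genes: Sequence[Gene]):
    exon_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for g in genes:
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
        for s, e in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
    return exon_trees, body_trees


def classify_genomic_context(
    assignments: Iterable[ReadAssignment],
    genes: Sequence[Gene],
    chrom_of: Mapping[str, str] | None = None,
) -> ContextFractions:
    """Classify uniquely genome-mapped reads as exonic / intronic / intergenic.

    A read is exonic when its alignment overlaps any exon by at least one
    base, else intronic when it lies within a gene body, else intergenic
    (priority exonic > intronic > intergenic).
    """
    exon_trees, body_trees = _gene_trees(genes)
    n_ex = n_in = n_ig = 0
    for a in assignments:
        if a.status != "unique":
            continue
        hit = a.chosen_hit
        chrom = hit.ref_id if chrom_of is None else chrom_of[hit.ref_id]
        s, e = hit.ref_start, hit.ref_end
        if chrom in exon_trees and exon_trees[chrom].overlap(s, e):
            n_ex += 1
        elif chrom in body_trees and body_trees[chrom].overlap(s, e):
            n_in += 1
        else:
            n_ig += 1
    total = n_ex + n_in + n_ig
    if total == 0:
        raise ValueError("no uniquely mapped reads to classify")
    return ContextFractions(n_ex / total, n_in / total, n_ig / total)
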