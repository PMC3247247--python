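"""Conserved miRNA assignment and expression quantification.

Tags passing the >2-read threshold are matched against a mature miRNA
reference at 100% identity / >=85% coverage; tags landing on the arm
of the hairpin opposite the annotated mature species are counted as
miRNA* (star). Expression is summarised as log2 relative abundance per
sample, with zero-read genes recorded as missing rather than -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .annotate import SeedIndex, align_ungapped
from .io_formats import ReferenceSet, Tag

__all__ = [
    "GeneCounts",
    "MirnaProfile",
    "ReferenceConsistencyError",
    "assign_conserved",
    "relative_abundance",
]


class ReferenceConsistencyError(ValueError):
    """Mature sequence absent from its own hairpin record."""


@dataclass
class GeneCounts:
    mature_count: int = 0
    star_count: int = 0
    tag_ids: list[str] = field(default_factory=list)

    @property
    def star_exceeds_mature(self) -> bool:
        return self.star_count > self.mature_count


@dataclass
class MirnaProfile:
    """Per-sample miRNA read counts (mature and star, by gene)."""

    sample_id: str
    genes: dict[str, GeneCounts] = field(default_factory=dict)

    @property
    def totals(self) -> int:
        """Total miRNA-mapped reads (mature + star)."""
        return sum(g.mature_count + g.star_count for g in self.genes.values())

    @property
    def total_mature(self) -> int:
        return sum(g.mature_count for g in self.genes.values())

    def expressed_genes(self) -> list[str]:
        return [g for g, c in self.genes.items() if c.mature_count > 0]

    def gene_read_stats(self) -> dict[str, float]:
        """Mean/median reads per expressed gene (mature counts)."""
        counts = [c.mature_count for c in self.genes.values() if c.mature_count > 0]
        if not counts:
            return {"n_genes": 0, "mean": 0.0, "median": 0.0}
        return {
            "n_genes": len(counts),
            "mean": float(np.mean(counts)),
            "median": float(np.median(counts)),
        }


def _mature_span_in_hairpin(mature: str, hairpin: str, gene: str) -> tuple[int, int]:
    pos = hairpin.find(mature)
    if pos < 0:
        raise ReferenceConsistencyError(
            f"gene {gene!r}: mature sequence not found in its hairpin"
        )
    return pos, pos + len(mature)


def assign_conserved(
    tags: Iterable[Tag],
    mature_db: ReferenceSet,
    hairpin_db: ReferenceSet | None = None,
    min_reads: int = 2,
    sample_id: str = "sample",
) -> MirnaProfile:
    """Assign tags to conserved miRNA genes and count mature/star reads.

    Only tags with count strictly greater than ``min_reads`` participate.
    A tag matching a mature reference (100% identity, >=85% coverage)
    increments that gene's mature count; a tag matching the hairpin on
    the arm opposite the mature annotation (same thresholds) increments
    the star count. Each tag maps to at most one gene: the best hit by
    E-value, ties broken by gene name. Genes without a hairpin record
    cannot receive star counts; such tags stay unassigned.
    """
    mature_index = SeedIndex(mature_db, word_size=8)
    hairpin_index = None
    mature_span: dict[str, tuple[int, int]] = {}
    hairpin_len: dict[str, int] = {}
    if hairpin_db is not None and len(hairpin_db):
        hairpin_index = SeedIndex(hairpin_db, word_size=8)
        hairpin_by_id = dict(hairpin_db.records)
        for gene, mat in mature_db.records:
            if gene in hairpin_by_id:
                mature_span[gene] = _mature_span_in_hairpin(mat, hairpin_by_id[gene], gene)
                hairpin_len[gene] = len(hairpin_by_id[gene])

    profile = MirnaProfile(sample_id=sample_id)
    for gene, _ in mature_db.records:
        profile.genes[gene] = GeneCounts()

    for tag in tags:
        if tag.count <= min_reads:
            continue
        hits = align_ungapped(
            tag.seq, mature_index, min_identity=1.0, max_evalue=0.01,
            min_coverage=0.85, query_id=tag.tag_id,
        )
        # small-RNA reads are stranded: only sense-strand matches count,
        # otherwise a miRNA* (reverse complement of the mature) would be
        # mistaken for a minus-strand mature hit
        hits = [h for h in hits if h.strand == "+"]
        if hits:
            gene = hits[0].subject_id  # sort order: E-value, score, subject id
            profile.genes[gene].mature_count += tag.count
            profile.genes[gene].tag_ids.append(tag.tag_id)
            continue
        if hairpin_index is None:
            continue
        hp_hits = align_ungapped(
            tag.seq, hairpin_index, min_identity=1.0, max_evalue=0.01,
            min_coverage=0.85, query_id=tag.tag_id,
        )
        hp_hits = [h for h in hp_hits if h.strand == "+"]
        for hit in hp_hits:
            gene = hit.subject_id
            span = mature_span.get(gene)
            if span is None:
                continue
            m_start, m_end = span
            if hit.s_end <= m_start or hit.s_start >= m_end:
                # disjoint from the mature arm; require the opposite half
                mid = hairpin_len[gene] / 2
                mature_on_5p = (m_start + m_end) / 2 < mid
                hit_on_3p = (hit.s_start + hit.s_end) / 2 >= mid
                if mature_on_5p == hit_on_3p:
                    if gene not in profile.genes:
                        profile.genes[gene] = GeneCounts()
                    profile.genes[gene].star_count += tag.count
                    profile.genes[gene].tag_ids.append(tag.tag_id)
                    break
    return profile


def relative_abundance(profiles: list[MirnaProfile]) -> pd.DataFrame:
    """log2 relative abundance matrix, genes x samples.

    Each cell is log2(mature reads of the gene / total mature miRNA
    reads of the sample). Genes with zero reads in a sample are missing
    (NaN), never -inf; no pseudocount is added. The heat map excludes
    miRNA* species, so star counts do not enter the matrix.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    genes: list[str] = []
    for p in profiles:
        for g in p.genes:
            if g not in genes:
                genes.append(g)
    data: dict[str, list[float]] = {}
    for p in profiles:
        total = p.total_mature
        if total == 0:
            raise ValueError(f"sample {p.sample_id!r} has no miRNA-mapped reads")
        col = []
        for g in genes:
            c = p.genes.get(g, GeneCounts()).mature_count
            col.append(np.log2(c / total) if c > 0 else np.nan)
        data[p.sample_id] = col
    return pd.DataFrame(data, index=genes)
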