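"""Ungapped seed-and-extend similarity search and RNA-class annotation.

A BLAST-like search specialised for 17-26 nt queries: exact word seeds
are extended without gaps under a +1/-2 scoring scheme, hits are scored
with ungapped Karlin-Altschul statistics, and each tag is classified
into an RNA class (tRNA -> rRNA -> snRNA/snoRNA -> miRNA -> mRNA ->
genome) by precedence. Conserved-miRNA matching demands 100% identity
at word size 8 and E <= 0.01; genome and long-reference matching uses
word size 12 at >= 80% identity. Hits covering less than 85% of the
query are ignored throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.optimize import brentq

from .io_formats import ReferenceSet, Tag, reverse_complement

__all__ = [
    "AlignmentHit",
    "Annotation",
    "ClassParams",
    "SeedIndex",
    "build_seed_index",
    "align_ungapped",
    "karlin_lambda",
    "evalue",
    "classify_tags",
    "DEFAULT_CLASS_PARAMS",
    "CLASS_PRECEDENCE",
]

MATCH_SCORE = 1
MISMATCH_SCORE = -2
XDROP = 6
KA_K = 0.3  # fixed prefactor; lambda is computed exactly


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped hit in 0-based half-open coordinates.

    Subject coordinates are always on the forward strand of the subject;
    ``strand`` records whether the query matched the reverse complement.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    matches: int
    mismatches: int
    identity: float
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.s_end - self.s_start:
            raise ValueError("ungapped hit must have equal query/subject spans")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class Annotation:
    tag_id: str
    assigned_class: str
    best_hit: Optional[AlignmentHit] = None


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics for the ungapped +1/-2 scheme


def karlin_lambda(
    match_score: int = MATCH_SCORE,
    mismatch_score: int = MISMATCH_SCORE,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s(i,j)) = 1 for lambda > 0.

    For a 4-letter alphabet with score ``match_score`` on the diagonal and
    ``mismatch_score`` off it, the equation reduces to
    p_match * e^(lambda*match) + p_mismatch * e^(lambda*mismatch) = 1 with
    p_match = sum_i p_i^2. The expected per-pair score must be negative.
    """
    p = list(background)
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValueError("background composition must sum to 1")
    p_match = sum(x * x for x in p)
    p_mis = 1.0 - p_match
    expected = p_match * match_score + p_mis * mismatch_score
    if expected >= 0:
        raise ValueError("expected per-pair score must be negative")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match_score) + p_mis * math.exp(lam * mismatch_score) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-15))


_LAMBDA_CACHE: dict[tuple, float] = {}


def evalue(
    score: float,
    m: int,
    n: int,
    match_score: int = MATCH_SCORE,
    mismatch_score: int = MISMATCH_SCORE,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """E = K * m * n * exp(-lambda * score) with K fixed at 0.3.

    ``m`` and ``n`` are the query length and the total searched subject
    length. E-values here serve as a fixed-threshold filter, so only
    lambda is computed exactly.
    """
    key = (match_score, mismatch_score, tuple(background))
    lam = _LAMBDA_CACHE.get(key)
    if lam is None:
        lam = karlin_lambda(match_score, mismatch_score, background)
        _LAMBDA_CACHE[key] = lam
    return KA_K * m * n * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# Seed index


class SeedIndex:
    """Exact k-mer postings over both strands of a reference set.

    Minus-strand sequences are indexed as full reverse complements; hit
    coordinates are mapped back to the forward strand at reporting time.
    k-mers containing N are not indexed.
    """

    def __init__(self, refset: ReferenceSet, word_size: int) -> None:
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        if all(len(seq) < word_size for _, seq in refset):
            raise ValueError("word_size exceeds every reference sequence")
        self.refset = refset
        self.word_size = word_size
        # (record index, strand) -> oriented sequence
        self.oriented: dict[tuple[int, str], str] = {}
        self.postings: dict[str, list[tuple[int, str, int]]] = {}
        for ridx, (_, seq) in enumerate(refset):
            for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
                self.oriented[(ridx, strand)] = oriented
                for pos in range(len(oriented) - word_size + 1):
                    kmer = oriented[pos : pos + word_size]
                    if "N" in kmer:
                        continue
                    self.postings.setdefault(kmer, []).append((ridx, strand, pos))
        # total searched length, counting both strands
        self.search_length = 2 * refset.total_length

    def lookup(self, kmer: str) -> list[tuple[int, str, int]]:
        return self.postings.get(kmer, [])


def build_seed_index(refset: ReferenceSet, word_size: int) -> SeedIndex:
    """Build an exact-word lookup over both strands of ``refset``."""
    return SeedIndex(refset, word_size)


# ---------------------------------------------------------------------------
# Seed-and-extend alignment


def _extend_on_diagonal(
    query: str, subject: str, diag: int, seed_pos: int, word_size: int
) -> tuple[int, int, int]:
    """Maximal-scoring ungapped extension of a seed along one diagonal.

    ``diag`` = subject_pos - query_pos. Extends the exact seed left and
    right, tracking the best cumulative score and stopping once the
    running score falls ``XDROP`` below it. Returns (q_start, q_end,
    score) of the best extension.
    """
    lo = max(0, -diag)
    hi = min(len(query), len(subject) - diag)  # query positions [lo, hi)
    seed_end = seed_pos + word_size
    score = word_size * MATCH_SCORE

    best_right = seed_end
    running = score
    best = score
    q = seed_end
    while q < hi:
        running += MATCH_SCORE if query[q] == subject[q + diag] else MISMATCH_SCORE
        q += 1
        if running > best:
            best = running
            best_right = q
        elif best - running > XDROP:
            break
    right_gain = best - score

    best_left = seed_pos
    running = score
    best = score
    q = seed_pos
    while q > lo:
        q -= 1
        running += MATCH_SCORE if query[q] == subject[q + diag] else MISMATCH_SCORE
        if running > best:
            best = running
            best_left = q
        elif best - running > XDROP:
            break
    left_gain = best - score

    total = score + left_gain + right_gain
    return best_left, best_right, total


def align_ungapped(
    query: str,
    index: SeedIndex,
    min_identity: float = 0.8,
    max_evalue: float | None = 1e-3,
    min_coverage: float = 0.85,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Seed-and-extend ungapped search of ``query`` against an index.

    Every exact word seed nucleates a bidirectional extension under
    +1/-2 scoring with an X-drop of 6; per diagonal only the best
    extension is kept. Hits are filtered by identity, E-value and the
    85% query-coverage rule, then sorted by E-value ascending with ties
    broken by score descending and subject id.
    """
    w = index.word_size
    if len(query) < w:
        raise ValueError("query shorter than word size")
    seeds: dict[tuple[int, str, int], list[int]] = {}
    for qpos in range(len(query) - w + 1):
        kmer = query[qpos : qpos + w]
        if "N" in kmer:
            continue
        for ridx, strand, spos in index.lookup(kmer):
            seeds.setdefault((ridx, strand, spos - qpos), []).append(qpos)

    hits: list[AlignmentHit] = []
    for (ridx, strand, diag), qpositions in seeds.items():
        subject = index.oriented[(ridx, strand)]
        best: tuple[int, int, int] | None = None
        covered_until = -1
        for qpos in sorted(qpositions):
            if qpos + w <= covered_until:
                continue  # seed inside the previous extension
            ext = _extend_on_diagonal(query, subject, diag, qpos, w)
            covered_until = ext[1]
            if best is None or ext[2] > best[2]:
                best = ext
        q_start, q_end, score = best
        length = q_end - q_start
        matches = sum(
            1 for k in range(q_start, q_end) if query[k] == subject[k + diag]
        )
        mismatches = length - matches
        identity = matches / length
        e = evalue(score, len(query), index.search_length)
        if identity < min_identity:
            continue
        if max_evalue is not None and e > max_evalue:
            continue
        if length < min_coverage * len(query):
            continue
        s_start, s_end = q_start + diag, q_end + diag
        if strand == "-":
            slen = len(subject)
            s_start, s_end = slen - s_end, slen - s_start
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=index.refset.records[ridx][0],
                q_start=q_start,
                q_end=q_end,
                s_start=s_start,
                s_end=s_end,
                strand=strand,
                matches=matches,
                mismatches=mismatches,
                identity=identity,
                score=float(score),
                evalue=e,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id, h.strand, h.s_start))
    return hits


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class ClassParams:
    """Per-class search parameters."""

    word_size: int
    min_identity: float
    max_evalue: Optional[float]
    min_coverage: float = 0.85


# miRNA mapping: word 8, 100% identity, E <= 0.01; everything else
# (tRNA/rRNA/sn(o)RNA/hairpin/mRNA/genome): word 12, >= 80% identity.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "tRNA": ClassParams(12, 0.80, 1e-3),
    "rRNA": ClassParams(12, 0.80, 1e-3),
    "snRNA_snoRNA": ClassParams(12, 0.80, 1e-3),
    "miRNA_mature": ClassParams(8, 1.00, 0.01),
    "miRNA_hairpin": ClassParams(12, 0.80, 1e-3),
    "mRNA": ClassParams(12, 0.80, 1e-3),
    "genome": ClassParams(12, 0.80, 1e-3),
}

# reference label -> reported annotation class
CLASS_OF_REFSET = {
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "snRNA_snoRNA": "snRNA_snoRNA",
    "miRNA_mature": "miRNA",
    "miRNA_hairpin": "miRNA",
    "mRNA": "mRNA",
    "genome": "genome_unannotated",
}

CLASS_PRECEDENCE = (
    "tRNA",
    "rRNA",
    "snRNA_snoRNA",
    "miRNA",
    "mRNA",
    "genome_unannotated",
    "unknown",
)


def classify_tags(
    tags: Iterable[Tag],
    refsets: Sequence[ReferenceSet],
    params_per_class: Mapping[str, ClassParams] | None = None,
) -> tuple[list[Annotation], pd.DataFrame]:
    """Assign each tag to the first RNA class with a passing hit.

    ``refsets`` must be ordered by precedence (tRNA first, genome last);
    a genome hit with no prior class reports as ``genome_unannotated``
    and a tag with no passing hit anywhere as ``unknown``. The summary
    table counts reads (tag counts), not tags, per class.
    """
    tags = list(tags)
    params = dict(DEFAULT_CLASS_PARAMS)
    if params_per_class:
        params.update(params_per_class)
    indexes: list[tuple[str, SeedIndex, ClassParams]] = []
    for refset in refsets:
        p = params[refset.class_label]
        indexes.append((refset.class_label, SeedIndex(refset, p.word_size), p))

    annotations: list[Annotation] = []
    for tag in tags:
        assigned = "unknown"
        best_hit: Optional[AlignmentHit] = None
        for label, index, p in indexes:
            if len(tag.seq) < p.word_size:
                continue
            hits = align_ungapped(
                tag.seq,
                index,
                min_identity=p.min_identity,
                max_evalue=p.max_evalue,
                min_coverage=p.min_coverage,
                query_id=tag.tag_id,
            )
            if hits:
                assigned = CLASS_OF_REFSET[label]
                best_hit = hits[0]
                break
        annotations.append(Annotation(tag.tag_id, assigned, best_hit))

    counts = {cls: {"tags": 0, "reads": 0} for cls in CLASS_PRECEDENCE}
    by_id = {t.tag_id: t for t in tags}
    for ann in annotations:
        counts[ann.assigned_class]["tags"] += 1
        counts[ann.assigned_class]["reads"] += by_id[ann.tag_id].count
    summary = pd.DataFrame(
        [
            {"class": cls, "tags": v["tags"], "reads": v["reads"]}
            for cls, v in counts.items()
        ]
    )
    return annotations, summary
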