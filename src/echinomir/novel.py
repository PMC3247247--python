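"""Novel miRNA discovery from genomic hairpins and read signatures.

Tags with more than 5 reads that escape annotation are mapped exactly
to the genome, candidate precursors are excised around each locus,
folded by maximum base pairing (Watson-Crick + GU wobble, pseudoknot
free), and accepted when they show the hallmarks of Dicer processing:
the putative mature species sits entirely on one stem arm with at
least 60% of its bases paired, and the implied star species (pairing
partner with the canonical 2-nt 3' overhang) stays clear of the
terminal loop. This deterministic structure/signature test is a
simplified stand-in for probabilistic discovery tools of the miRDeep
family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Optional, Sequence

from .io_formats import ReferenceSet, Tag, reverse_complement

__all__ = [
    "GenomeLocus",
    "HairpinCandidate",
    "map_to_genome_exact",
    "excise_precursor",
    "fold_nussinov",
    "score_hairpin_candidate",
    "seed_match",
    "cross_species_presence",
    "discover_novel",
]

CAN_PAIR = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)


@dataclass(frozen=True)
class GenomeLocus:
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("locus must satisfy 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass
class HairpinCandidate:
    """An excised precursor with fold, arm assignment and read signature."""

    locus: GenomeLocus
    precursor_seq: str
    mature_span: tuple[int, int]  # on the precursor, 5'->3'
    structure: str = ""
    n_pairs: int = 0
    star_span: Optional[tuple[int, int]] = None
    loop_span: Optional[tuple[int, int]] = None
    signature: tuple[int, int, int] = (0, 0, 0)  # mature, star, loop reads
    paired_mature_bases: int = 0
    score: float = 0.0
    score_components: dict[str, float] = field(default_factory=dict)
    passed: bool = False
    fail_reason: str = ""

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_span[0] : self.mature_span[1]]


def map_to_genome_exact(
    tags: Iterable[Tag], genome: ReferenceSet, min_reads: int = 5
) -> list[tuple[Tag, GenomeLocus]]:
    """All exact full-length genome matches of tags with count > min_reads.

    Forward matches report strand '+'; matches of the reverse complement
    report strand '-' with coordinates on the forward strand.
    """
    if not len(genome):
        raise ValueError("empty genome")
    out: list[tuple[Tag, GenomeLocus]] = []
    for tag in tags:
        if tag.count <= min_reads:
            continue
        rc = reverse_complement(tag.seq)
        for contig, seq in genome:
            for probe, strand in ((tag.seq, "+"), (rc, "-")):
                if strand == "-" and rc == tag.seq:
                    continue  # palindromic: already reported on '+'
                start = seq.find(probe)
                while start >= 0:
                    out.append(
                        (tag, GenomeLocus(contig, start, start + len(probe), strand))
                    )
                    start = seq.find(probe, start + 1)
    return out


def excise_precursor(
    genome: ReferenceSet, locus: GenomeLocus, flank: int = 70
) -> list[HairpinCandidate]:
    """Two candidate precursors around a mapped tag.

    Candidate A extends ``flank`` nt downstream of the tag (mature on the
    5' arm), candidate B ``flank`` nt upstream (mature on the 3' arm);
    both are clipped at contig edges. Minus-strand loci are reverse
    complemented so the tag always reads 5'->3' within the precursor.
    """
    if flank < 20:
        raise ValueError("flank must be >= 20")
    contig_seq = genome.get(locus.contig)
    length = len(contig_seq)
    tag_len = locus.end - locus.start
    candidates: list[HairpinCandidate] = []
    if locus.strand == "+":
        spans = [
            (locus.start, min(locus.end + flank, length), "A"),
            (max(0, locus.start - flank), locus.end, "B"),
        ]
    else:
        # downstream in read orientation = upstream in genome coordinates
        spans = [
            (max(0, locus.start - flank), locus.end, "A"),
            (locus.start, min(locus.end + flank, length), "B"),
        ]
    for start, end, kind in spans:
        seq = contig_seq[start:end]
        if locus.strand == "-":
            seq = reverse_complement(seq)
        if kind == "A":
            mature_span = (0, tag_len)
        else:
            mature_span = (len(seq) - tag_len, len(seq))
        candidates.append(
            HairpinCandidate(
                locus=GenomeLocus(locus.contig, start, end, locus.strand),
                precursor_seq=seq,
                mature_span=mature_span,
            )
        )
    return candidates


def fold_nussinov(seq: str, min_loop: int = 3) -> tuple[str, int]:
    """Maximum base pairing fold, returned as (dot-bracket, n_pairs).

    Watson-Crick and GU pairs are allowed, hairpin loops must span at
    least ``min_loop`` unpaired bases (|i - j| > min_loop), and the
    traceback is pseudoknot-free and deterministic: at each subproblem,
    position i pairs with the largest admissible j, and pairing is
    preferred over leaving i unpaired when scores tie.
    """
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError("sequence too short to fold")
    pairable = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (seq[i], seq[j]) in CAN_PAIR:
                pairable[i][j] = True

    # dp[i][j] = max pairs in seq[i..j]; filled by increasing span
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            row = pairable[i]
            for k in range(i + min_loop + 1, j + 1):
                if row[k]:
                    inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                    rest = dp[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            dp[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = dp[i][j]
        chosen = -1
        for k in range(j, i + min_loop, -1):  # largest admissible j first
            if pairable[i][k]:
                inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                rest = dp[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + rest == target:
                    chosen = k
                    break
        if chosen < 0:
            stack.append((i + 1, j))
        else:
            structure[i] = "("
            structure[chosen] = ")"
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
    return "".join(structure), dp[0][n - 1]


def _pair_table(structure: str) -> list[int]:
    """partner index per position, -1 when unpaired."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            table[i], table[j] = j, i
    return table


def score_hairpin_candidate(
    candidate: HairpinCandidate,
    mature_tag: Tag,
    nearby_tags: Sequence[Tag] = (),
    min_paired_fraction: float = 0.6,
    min_loop: int = 3,
) -> HairpinCandidate:
    """Fold a candidate precursor and test it for a Dicer-like signature.

    Pass criteria: (a) the mature span lies entirely on one arm (none of
    its bases pair with other mature bases, and all partners sit on one
    side); (b) at least ``min_paired_fraction`` of mature bases are
    paired; (c) the star span, the pairing partner of the mature span
    extended by the canonical 2-nt 3' overhang, does not overlap the
    terminal loop. The additive score combines read support and
    structure: log2(mature reads + 1) + 2*[star reads observed] +
    paired fraction - log2(loop reads + 1).
    """
    if not candidate.structure:
        candidate.structure, candidate.n_pairs = fold_nussinov(
            candidate.precursor_seq, min_loop=min_loop
        )
    table = _pair_table(candidate.structure)
    m0, m1 = candidate.mature_span
    mlen = m1 - m0
    partners = [table[i] for i in range(m0, m1) if table[i] >= 0]
    candidate.paired_mature_bases = len(partners)
    paired_fraction = len(partners) / mlen

    def fail(reason: str) -> HairpinCandidate:
        candidate.passed = False
        candidate.fail_reason = reason
        _apply_score(candidate, mature_tag, nearby_tags, paired_fraction)
        return candidate

    if any(m0 <= p < m1 for p in partners):
        return fail("loop overlap")  # mature folds back on itself
    if partners and not (
        all(p >= m1 for p in partners) or all(p < m0 for p in partners)
    ):
        return fail("partners on both sides")
    if paired_fraction < min_paired_fraction:
        return fail("insufficient pairing")
    if not partners:
        return fail("insufficient pairing")

    p_min, p_max = min(partners), max(partners)
    length = len(candidate.precursor_seq)
    # the star's 3' end extends 2 nt past the partner of the mature 5' end
    if partners[0] >= m1:  # mature on the 5' arm, star on the 3' arm
        star_span = (p_min, min(p_max + 3, length))
        loop_span = (m1, p_min)  # apex between mature 3' end and star
        if loop_span[1] < loop_span[0]:
            candidate.star_span, candidate.loop_span = star_span, None
            return fail("no terminal loop")
    else:  # mature on the 3' arm, star on the 5' arm
        star_span = (p_min, min(p_max + 3, length))
        # the 2-nt overhang eats into the apex; what remains is the loop
        loop_span = (p_max + 3, m0)
        if loop_span[1] < loop_span[0]:
            candidate.star_span, candidate.loop_span = star_span, None
            return fail("star overlaps loop")
    candidate.star_span = star_span
    candidate.loop_span = loop_span
    if _overlap(star_span, (m0, m1)):
        return fail("star overlaps mature")

    candidate.passed = True
    _apply_score(candidate, mature_tag, nearby_tags, paired_fraction)
    return candidate


def _locate(span_seq: str, tag_seq: str) -> Optional[tuple[int, int]]:
    pos = span_seq.find(tag_seq)
    return (pos, pos + len(tag_seq)) if pos >= 0 else None


def _apply_score(
    candidate: HairpinCandidate,
    mature_tag: Tag,
    nearby_tags: Sequence[Tag],
    paired_fraction: float,
) -> None:
    mature_reads = mature_tag.count
    star_reads = 0
    loop_reads = 0
    for tag in nearby_tags:
        if tag.tag_id == mature_tag.tag_id:
            continue
        span = _locate(candidate.precursor_seq, tag.seq)
        if span is None:
            continue
        if candidate.star_span and _overlap(span, candidate.star_span):
            star_reads += tag.count
        elif candidate.loop_span and _overlap(span, candidate.loop_span):
            loop_reads += tag.count
    candidate.signature = (mature_reads, star_reads, loop_reads)
    components = {
        "mature_read_score": log2(mature_reads + 1),
        "star_bonus": 2.0 if star_reads > 0 else 0.0,
        "paired_fraction": paired_fraction,
        "loop_read_penalty": log2(loop_reads + 1),
    }
    candidate.score_components = components
    candidate.score = (
        components["mature_read_score"]
        + components["star_bonus"]
        + components["paired_fraction"]
        - components["loop_read_penalty"]
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def seed_match(candidate_mature: str, known_matures: ReferenceSet) -> list[str]:
    """Known miRNAs sharing the seed (positions 2-8, 1-based) of a candidate."""
    if len(candidate_mature) < 8:
        raise ValueError("candidate mature must be at least 8 nt")
    seed = candidate_mature[1:8]
    out = []
    for rid, seq in known_matures:
        if len(seq) >= 8 and seq[1:8] == seed:
            out.append(rid)
    return out


def cross_species_presence(
    candidates: Sequence[HairpinCandidate],
    other_species_tags: Sequence[Tag],
    min_coverage: float = 0.85,
) -> list[tuple[bool, int]]:
    """Is each candidate's mature species present in another library?

    Present means some other-species tag matches the candidate mature at
    100% identity over at least ``min_coverage`` of the tag. Returns a
    (present, supporting read count) pair per candidate.
    """
    results: list[tuple[bool, int]] = []
    for cand in candidates:
        mature = cand.mature_seq
        reads = 0
        for tag in other_species_tags:
            if _matches_full_identity(tag.seq, mature, min_coverage):
                reads += tag.count
        results.append((reads > 0, reads))
    return results


def _matches_full_identity(tag_seq: str, mature: str, min_coverage: float) -> bool:
    """Exact ungapped overlap of >= min_coverage of the tag against mature."""
    need = max(1, math.ceil(min_coverage * len(tag_seq)))
    if tag_seq in mature:
        return True
    # allow a short unmatched 3' tail on the tag (isoform-style variation)
    for length in range(min(len(tag_seq), len(mature)), need - 1, -1):
        if tag_seq[:length] in mature:
            return True
    return False


def discover_novel(
    tags: Sequence[Tag],
    genome: ReferenceSet,
    known_matures: ReferenceSet | None = None,
    other_species_tags: Sequence[Tag] = (),
    min_reads: int = 5,
    flank: int = 70,
) -> list[HairpinCandidate]:
    """End-to-end novel discovery for unannotated tags.

    Maps tags exactly to the genome, excises and scores both candidate
    precursors per locus, and keeps the best passing candidate per
    locus. Seed matches to known miRNAs and cross-species presence are
    recorded on the returned candidates (as ``seed_matches`` /
    ``present_in_other`` attributes).
    """
    mapped = map_to_genome_exact(tags, genome, min_reads=min_reads)
    scored_all: list[HairpinCandidate] = []
    for tag, locus in mapped:
        best: HairpinCandidate | None = None
        for cand in excise_precursor(genome, locus, flank=flank):
            cand.source_tag_id = tag.tag_id
            scored = score_hairpin_candidate(cand, tag, nearby_tags=tags)
            if scored.passed and (best is None or scored.score > best.score):
                best = scored
        if best is not None:
            scored_all.append(best)
    # one candidate per hairpin: greedy by score over overlapping loci;
    # strand is ignored because the two strands of a stem-loop region
    # describe the same genomic hairpin
    scored_all.sort(key=lambda c: (-c.score, c.locus.contig, c.locus.start))
    passed: list[HairpinCandidate] = []
    for cand in scored_all:
        clash = any(
            kept.locus.contig == cand.locus.contig
            and _overlap(
                (kept.locus.start, kept.locus.end), (cand.locus.start, cand.locus.end)
            )
            for kept in passed
        )
        if not clash:
            passed.append(cand)
    for cand in passed:
        cand.seed_matches = (
            seed_match(cand.mature_seq, known_matures) if known_matures else []
        )
    presence = cross_species_presence(passed, other_species_tags)
    for cand, (present, reads) in zip(passed, presence):
        cand.present_in_other = present
        cand.other_species_reads = reads
    return passed
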