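"""Genome mapping, precursor excision, folding and hairpin scoring."""

import itertools
import random

import pytest

from echinomir.io_formats import ReferenceSet, Tag, reverse_complement
from echinomir.novel import (
    CAN_PAIR,
    GenomeLocus,
    HairpinCandidate,
    cross_species_presence,
    excise_precursor,
    fold_nussinov,
    map_to_genome_exact,
    score_hairpin_candidate,
    seed_match,
)

# ---------------------------------------------------------------------------
# exact genome mapping


def _genome(seq):
    return ReferenceSet("genome", [("c1", seq)])


def test_minus_strand_locus():
    tag_seq = "ACGGTTCAGACCGGTTAAGCCG"
    genome = _genome("TTTT" + reverse_complement(tag_seq) + "AAAA")
    out = map_to_genome_exact([Tag("t1", tag_seq, 10)], genome)
    assert len(out) == 1
    _, locus = out[0]
    assert (locus.start, locus.end, locus.strand) == (4, 4 + len(tag_seq), "-")


def test_multi_mapping_reports_all_loci():
    tag_seq = "ACGGTTCAGACCGGTTAAGCCG"
    genome = _genome(tag_seq + "TTTT" + tag_seq + "AAAA" + tag_seq)
    out = map_to_genome_exact([Tag("t1", tag_seq, 10)], genome)
    assert len(out) == 3


def test_count_threshold_is_strict():
    tag_seq = "ACGGTTCAGACCGGTTAAGCCG"
    genome = _genome(tag_seq)
    assert map_to_genome_exact([Tag("t1", tag_seq, 5)], genome) == []
    assert len(map_to_genome_exact([Tag("t1", tag_seq, 6)], genome)) == 1


# ---------------------------------------------------------------------------
# precursor excision


def test_excision_spans():
    genome = _genome("A" * 300)
    a, b = excise_precursor(genome, GenomeLocus("c1", 100, 122, "+"), flank=70)
    assert (a.locus.start, a.locus.end) == (100, 192)
    assert a.mature_span == (0, 22)
    assert (b.locus.start, b.locus.end) == (30, 122)
    assert b.mature_span == (70, 92)


def test_excision_clipped_at_contig_edge():
    genome = _genome("A" * 50)
    a, b = excise_precursor(genome, GenomeLocus("c1", 23, 45, "+"), flank=70)
    assert a.locus.end == 50  # clipped downstream
    assert b.locus.start == 0  # clipped upstream


def test_minus_strand_excision_is_reverse_complement():
    rng = random.Random(1)
    seq = "".join(rng.choice("ACGT") for _ in range(300))
    genome = _genome(seq)
    locus = GenomeLocus("c1", 100, 122, "-")
    a, _ = excise_precursor(genome, locus, flank=70)
    # candidate A: tag + 70 nt downstream in read orientation = upstream
    # genomic, reverse complemented
    assert a.precursor_seq == reverse_complement(seq[30:122])
    assert a.precursor_seq.startswith(reverse_complement(seq[100:122]))


# ---------------------------------------------------------------------------
# folding


def test_fold_perfect_stem():
    structure, n_pairs = fold_nussinov("GGGAAACCC")
    assert n_pairs == 3
    assert structure == "(((...)))"


def test_fold_unpairable_sequence():
    structure, n_pairs = fold_nussinov("AAAAAA")
    assert n_pairs == 0
    assert structure == "......"


def _enumerate_structures(seq, min_loop=3):
    """Exhaustively enumerate every pseudoknot-free pairing (oracle)."""
    n = len(seq)

    def rec(i, j):
        if j - i < 0:
            yield frozenset()
            return
        yield from rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in CAN_PAIR:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield inner | outer | {(i, k)}

    yield from rec(0, n - 1)


def _check_structure_valid(seq, structure, min_loop=3):
    stack = []
    pairs = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs.append((j, i))
    assert not stack
    for i, j in pairs:
        assert (seq[i], seq[j]) in CAN_PAIR
        assert j - i > min_loop
    return len(pairs)


@pytest.mark.parametrize("seed", range(40))
def test_fold_matches_exhaustive_enumeration(seed):
    rng = random.Random(seed)
    n = rng.randint(6, 13)
    seq = "".join(rng.choice("ACGT") for _ in range(n))
    best = max(len(s) for s in _enumerate_structures(seq))
    structure, n_pairs = fold_nussinov(seq)
    assert n_pairs == best
    assert _check_structure_valid(seq, structure) == n_pairs


def test_fold_too_short_sequence_errors():
    with pytest.raises(ValueError):
        fold_nussinov("ACG")


# ---------------------------------------------------------------------------
# hairpin scoring


def _perfect_candidate(mature=None, loop="ATAACGGTCA", arm="5p"):
    rng = random.Random(9)
    mature = mature or "".join(rng.choice("ACGT") for _ in range(22))
    if arm == "5p":
        precursor = mature + loop + reverse_complement(mature)
        span = (0, 22)
    else:
        precursor = reverse_complement(mature) + loop + mature
        span = (len(precursor) - 22, len(precursor))
    return HairpinCandidate(
        locus=GenomeLocus("c1", 0, len(precursor), "+"),
        precursor_seq=precursor,
        mature_span=span,
    )


@pytest.mark.parametrize("arm", ["5p", "3p"])
def test_perfect_stem_hairpin_passes(arm):
    cand = _perfect_candidate(arm=arm)
    mature_tag = Tag("t1", cand.mature_seq, 50)
    scored = score_hairpin_candidate(cand, mature_tag)
    assert scored.passed, scored.fail_reason
    assert scored.paired_mature_bases >= 0.6 * 22
    assert scored.score > 0


def test_star_reads_raise_the_score():
    cand1 = _perfect_candidate()
    cand2 = _perfect_candidate()
    mature_tag = Tag("t1", cand1.mature_seq, 50)
    star_tag = Tag("t2", reverse_complement(cand1.mature_seq), 8)
    alone = score_hairpin_candidate(cand1, mature_tag)
    with_star = score_hairpin_candidate(cand2, mature_tag, [star_tag])
    assert with_star.signature[1] == 8
    assert with_star.score == pytest.approx(alone.score + 2.0)


def test_mature_straddling_loop_fails():
    rng = random.Random(4)
    stem = "".join(rng.choice("ACGT") for _ in range(20))
    precursor = stem + "AATCG" + reverse_complement(stem)
    cand = HairpinCandidate(
        locus=GenomeLocus("c1", 0, len(precursor), "+"),
        precursor_seq=precursor,
        mature_span=(10, 32),  # spans the loop
    )
    scored = score_hairpin_candidate(cand, Tag("t1", cand.mature_seq, 20))
    assert not scored.passed


def test_insufficient_pairing_fails():
    # A/C-only mature: pairs only with T/G, and the precursor provides at
    # most 10 such bases, so < 60% of the mature can ever pair
    mature = "ACCAACCAAACCCAAACCAACC"
    precursor = mature + "AACCAAACCA" + reverse_complement(mature[:10])
    cand = HairpinCandidate(
        locus=GenomeLocus("c1", 0, len(precursor), "+"),
        precursor_seq=precursor,
        mature_span=(0, 22),
    )
    scored = score_hairpin_candidate(cand, Tag("t1", mature, 20))
    assert not scored.passed
    assert scored.fail_reason in ("insufficient pairing", "partners on both sides")


def test_unfolded_candidate_gets_folded_on_demand():
    cand = _perfect_candidate()
    assert cand.structure == ""
    scored = score_hairpin_candidate(cand, Tag("t1", cand.mature_seq, 5))
    assert scored.structure  # fold performed inside the scorer


# ---------------------------------------------------------------------------
# seed matching and cross-species presence


def test_seed_match_positions_2_to_8():
    cand = "TGAGGTAGTAGGTTGTATAGTT"
    same_seed = "A" + cand[1:8] + "CCCCCCCCCCCCCC"
    known = ReferenceSet(
        "miRNA_mature",
        [("match", same_seed), ("nomatch", "TGAGCTAGTAGGTTGTATAGTT")],
    )
    assert seed_match(cand, known) == ["match"]


def test_seed_match_requires_minimum_length():
    known = ReferenceSet("miRNA_mature", [("x", "ACGTACGTACGT")])
    with pytest.raises(ValueError):
        seed_match("ACGTACG", known)


def test_cross_species_presence_thresholds():
    cand = _perfect_candidate()
    mature = cand.mature_seq
    exact = Tag("o1", mature, 12)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    tail = "".join(flip[b] for b in mature[16:20])
    partial80 = Tag("o2", mature[:16] + tail, 5)  # only 16/20 of tag matches
    [(p1, r1)] = cross_species_presence([cand], [exact])
    assert p1 and r1 == 12
    [(p2, _)] = cross_species_presence([cand], [partial80])
    assert not p2
    [(p3, _)] = cross_species_presence([cand], [])
    assert not p3
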