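"""Seed index, ungapped alignment, E-values and class assignment."""

import math
import random

import numpy as np
import pytest

from echinomir.annotate import (
    ClassParams,
    SeedIndex,
    align_ungapped,
    build_seed_index,
    classify_tags,
    evalue,
    karlin_lambda,
)
from echinomir.io_formats import ReferenceSet, Tag, reverse_complement

# ---------------------------------------------------------------------------
# seed index


def test_seed_index_postings_both_strands():
    refset = ReferenceSet("genome", [("c1", "AACCGGTTACGTACGT")])
    index = build_seed_index(refset, 8)
    kmer = "AACCGGTT"
    assert (0, "+", 0) in index.lookup(kmer)
    rc_hit = index.lookup(reverse_complement(kmer))
    assert any(strand == "-" for _, strand, _ in rc_hit)


def test_seed_index_skips_ambiguous_kmers():
    refset = ReferenceSet("genome", [("c1", "ACGTNACGTACGT")])
    index = build_seed_index(refset, 8)
    assert all("N" not in k for k in index.postings)


def test_seed_index_word_size_too_long():
    refset = ReferenceSet("tRNA", [("t1", "ACGTA")])
    with pytest.raises(ValueError):
        build_seed_index(refset, 8)


# ---------------------------------------------------------------------------
# alignment


def _mkindex(subject, word=8, label="mRNA"):
    return SeedIndex(ReferenceSet(label, [("s1", subject)]), word)


def test_exact_substring_alignment():
    query = "ACGTTGCAACGGTCAAGGCTA"
    subject = "TTTT" + query + "GGGG"
    hits = align_ungapped(query, _mkindex(subject), min_identity=1.0, max_evalue=10)
    assert hits
    top = hits[0]
    assert top.identity == 1.0
    assert top.length == len(query)
    assert (top.s_start, top.s_end) == (4, 4 + len(query))
    assert top.strand == "+"


def test_reverse_strand_alignment_reports_forward_coordinates():
    query = "ACGTTGCAACGGTCAAGGCTA"
    subject = "TT" + reverse_complement(query) + "AA"
    hits = align_ungapped(query, _mkindex(subject), min_identity=1.0, max_evalue=10)
    assert hits and hits[0].strand == "-"
    assert (hits[0].s_start, hits[0].s_end) == (2, 2 + len(query))


def test_full_identity_required_rejects_mismatched_hit():
    # 22-nt query matching 18/22 positions fails at 100% identity
    rng = random.Random(5)
    query = "".join(rng.choice("ACGT") for _ in range(22))
    mutated = list(query)
    for pos in (3, 9, 15, 20):
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
    subject = "AAAA" + "".join(mutated) + "TTTT"
    hits = align_ungapped(query, _mkindex(subject), min_identity=1.0, max_evalue=10)
    assert hits == []


def test_coverage_rule_85_percent():
    # 20-nt query: a 16-nt hit (80%) is rejected, a 17-nt hit (85%) kept
    rng = random.Random(11)
    query = "".join(rng.choice("ACGT") for _ in range(20))
    subject16 = "CCCC" + query[:16]  # only 80% of the query present
    hits16 = align_ungapped(
        query, _mkindex(subject16), min_identity=1.0, max_evalue=1e6
    )
    assert hits16 == []
    subject17 = "CCCC" + query[:17]
    hits17 = align_ungapped(
        query, _mkindex(subject17), min_identity=1.0, max_evalue=1e6
    )
    assert hits17 and hits17[0].length == 17


def test_hit_monotonicity_under_stricter_filters():
    rng = random.Random(3)
    query = "".join(rng.choice("ACGT") for _ in range(22))
    noisy = list(query)
    noisy[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[10]]
    subject = "GG" + "".join(noisy) + "CC" + query
    index = _mkindex(subject)
    loose = align_ungapped(query, index, min_identity=0.8, max_evalue=1e6)
    tight_id = align_ungapped(query, index, min_identity=1.0, max_evalue=1e6)
    tight_e = align_ungapped(query, index, min_identity=0.8, max_evalue=1e-30)

    def keyset(hits):
        return {(h.subject_id, h.strand, h.s_start, h.s_end) for h in hits}

    assert keyset(tight_id) <= keyset(loose)
    assert keyset(tight_e) <= keyset(loose)


# ---------------------------------------------------------------------------
# E-value statistics


def _lambda_by_bisection():
    """Independent bisection on (1/4) e^L + (3/4) e^(-2L) = 1."""
    lo, hi = 1e-9, 10.0
    f = lambda lam: 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def test_lambda_matches_independent_bisection():
    lam = karlin_lambda()
    assert lam == pytest.approx(_lambda_by_bisection(), abs=1e-9)
    assert lam == pytest.approx(1.33, abs=0.01)


def test_evalue_score_ratio_is_exp_minus_lambda():
    lam = karlin_lambda()
    assert evalue(11, 20, 1000) / evalue(10, 20, 1000) == pytest.approx(
        math.exp(-lam)
    )


def test_evalue_linear_in_search_space():
    assert evalue(10, 20, 2000) == pytest.approx(2 * evalue(10, 20, 1000))


def test_evalue_rejects_nonnegative_expected_score():
    with pytest.raises(ValueError):
        karlin_lambda(match_score=1, mismatch_score=1)


# ---------------------------------------------------------------------------
# brute-force equivalence (small version; the large suite runs in the
# acceptance tests)


@pytest.mark.parametrize("seed", range(30))
def test_align_matches_brute_force_on_planted_pairs(seed):
    from oracles import brute_force_scan, hits_by_diagonal

    rng = random.Random(seed)
    query = "".join(rng.choice("ACGT") for _ in range(rng.randint(17, 26)))
    subject = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 40)))
    if rng.random() < 0.7:  # plant a (possibly mutated) copy of the query
        frag = query[: rng.randint(int(0.8 * len(query)), len(query))]
        frag = list(frag)
        if rng.random() < 0.4 and len(frag) > 4:
            pos = rng.randrange(len(frag))
            frag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[pos]]
        ins = rng.randint(0, len(subject))
        subject = subject[:ins] + "".join(frag) + subject[ins:]
    refset = ReferenceSet("mRNA", [("s1", subject)])
    index = SeedIndex(refset, 8)
    hits = align_ungapped(query, index, min_identity=1.0, max_evalue=0.01)
    got = hits_by_diagonal(hits, {"s1": len(subject)})
    expected = brute_force_scan(query, refset, 1.0, 0.01, 0.85)
    assert got == expected


# ---------------------------------------------------------------------------
# classification


def _tag(seq, count=10, tid="t1"):
    return Tag(tid, seq, count)


def test_precedence_rrna_before_mrna():
    seq = "ACGGTTCAGACCGGTTAAGCCG"
    rrna = ReferenceSet("rRNA", [("rr1", "TTTT" + seq + "AAAA")])
    mrna = ReferenceSet("mRNA", [("m1", "GGGG" + seq + "CCCC")])
    anns, summary = classify_tags([_tag(seq)], [rrna, mrna])
    assert anns[0].assigned_class == "rRNA"


def test_exact_mature_match_is_mirna():
    mature = "TGAGGTAGTAGGTTGTATAGTT"
    refset = ReferenceSet("miRNA_mature", [("let-7", mature)])
    anns, _ = classify_tags([_tag(mature)], [refset])
    assert anns[0].assigned_class == "miRNA"
    assert anns[0].best_hit.subject_id == "let-7"


def test_no_hit_is_unknown_and_partition_holds():
    mature = "TGAGGTAGTAGGTTGTATAGTT"
    refset = ReferenceSet("miRNA_mature", [("let-7", mature)])
    tags = [
        _tag(mature, 7, "t1"),
        _tag("CCCCCCCCCCCCCCCCCCCCCC", 3, "t2"),
    ]
    anns, summary = classify_tags(tags, [refset])
    assert {a.tag_id: a.assigned_class for a in anns} == {
        "t1": "miRNA",
        "t2": "unknown",
    }
    assert summary["reads"].sum() == 10  # partition over reads
    assert len(anns) == len(tags)  # exactly one class per tag


def test_genome_hit_without_other_class_is_genome_unannotated():
    seq = "ACGGTTCAGACCGGTTAAGCCGAT"
    genome = ReferenceSet("genome", [("c1", "T" * 20 + seq + "A" * 20)])
    anns, _ = classify_tags([_tag(seq)], [genome])
    assert anns[0].assigned_class == "genome_unannotated"
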