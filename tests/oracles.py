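"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the code paths they check: the alignment
oracle scans every diagonal with a Kadane best-segment pass instead of
seeding and extending; the folding oracle enumerates every
pseudoknot-free structure; the clustering oracle recomputes every
inter-cluster average from the base distance matrix at each step.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from echinomir.annotate import evalue
from echinomir.io_formats import reverse_complement
from echinomir.novel import CAN_PAIR


def brute_force_scan(query, refset, min_identity, max_evalue, min_coverage):
    """All-offset ungapped scan. Returns {(subject, strand, diagonal):
    best passing score}. Ties on score prefer the shorter segment."""
    search_length = 2 * refset.total_length
    passing = {}
    for rid, subject in refset.records:
        for strand in "+-":
            sseq = subject if strand == "+" else reverse_complement(subject)
            for diag in range(-(len(query) - 1), len(sseq)):
                lo = max(0, -diag)
                hi = min(len(query), len(sseq) - diag)
                if hi - lo <= 0:
                    continue
                scores = [
                    1 if query[q] == sseq[q + diag] else -2 for q in range(lo, hi)
                ]
                best = (-math.inf, 0, 0)
                run = 0.0
                start = 0
                for k, s in enumerate(scores):
                    if run <= 0:
                        run, start = s, k
                    else:
                        run += s
                    if run > best[0]:
                        best = (run, start, k + 1)
                score, b0, b1 = best
                if score <= 0:
                    continue
                seg = scores[b0:b1]
                matches = sum(1 for s in seg if s == 1)
                identity = matches / len(seg)
                e = evalue(score, len(query), search_length)
                if (
                    identity >= min_identity
                    and e <= max_evalue
                    and len(seg) >= min_coverage * len(query)
                ):
                    key = (rid, strand, diag)
                    if key not in passing or score > passing[key]:
                        passing[key] = score
    return passing


def hits_by_diagonal(hits, subject_lengths):
    """Project implementation hits onto the oracle's key space."""
    out = {}
    for h in hits:
        if h.strand == "+":
            diag = h.s_start - h.q_start
        else:
            diag = (subject_lengths[h.subject_id] - h.s_end) - h.q_start
        out[(h.subject_id, h.strand, diag)] = h.score
    return out


def enumerate_max_pairs(seq, min_loop=3):
    """Maximum pairs over the exhaustive enumeration of all structures."""
    n = len(seq)

    def rec(i, j):
        if j - i < 0:
            yield 0
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in CAN_PAIR:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield 1 + inner + outer

    return max(rec(0, n - 1))


def brute_force_average_linkage(matrix):
    """Step-by-step average-linkage heights from the base distances."""
    base = np.sqrt(((matrix[:, None, :] - matrix[None, :, :]) ** 2).sum(axis=2))
    n = matrix.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(sorted(clusters), 2):
            d = np.mean([base[i, j] for i in clusters[x] for j in clusters[y]])
            key = tuple(sorted((min(clusters[x]), min(clusters[y]))))
            if best is None or d < best[0] - 1e-12 or (
                abs(d - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (d, key, x, y)
        d, _, x, y = best
        heights.append(d)
        clusters[next_id] = clusters.pop(x) + clusters.pop(y)
        next_id += 1
    return heights
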