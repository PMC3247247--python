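"""Collapse reads into count-bearing expression tags.

Reads with identical sequence, or whose sequences are 5'-anchored
(one a prefix of the other) with a length difference of at most 2 nt,
are merged into a single tag whose read count is the expression
estimate. The 5' anchoring reflects miRNA biogenesis: Drosha/Dicer fix
the 5' end while the 3' end varies between isoforms.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from .io_formats import Read, Tag

__all__ = ["collapse_reads", "filter_tags"]


def _compatible_lengths(length: int, max_diff: int) -> range:
    return range(max(1, length - max_diff), length + max_diff + 1)


def collapse_reads(
    reads: Iterable[Read | str],
    max_length_diff: int = 2,
    anchor: str = "five_prime",
    tag_prefix: str = "tag",
) -> list[Tag]:
    """Collapse reads into tags.

    Exact-sequence groups are formed first, then visited in a canonical
    order (count descending, length descending, lexicographic) and each
    group joins the earliest-founded existing tag whose representative is
    5'-prefix-compatible within ``max_length_diff`` nt, or founds a new
    tag. The representative of a tag is its founding (highest-count)
    member. The result is invariant under permutation of the input.

    ``anchor="both_ends"`` additionally allows a shorter sequence to join
    when it is a suffix of the representative.
    """
    if anchor not in ("five_prime", "both_ends"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    counts: Counter = Counter()
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        if not seq:
            raise ValueError("cannot collapse an empty sequence")
        counts[seq] += 1

    groups = sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))

    tags: list[Tag] = []
    # representative sequence -> founding order index, for prefix lookups
    by_prefix: dict[str, list[int]] = {}
    by_exact: dict[str, int] = {}

    def register(rep: str, idx: int) -> None:
        by_exact[rep] = idx
        for cut in _compatible_lengths(len(rep), max_length_diff):
            if cut <= len(rep):
                by_prefix.setdefault(rep[:cut], []).append(idx)

    for seq, count in groups:
        candidates: set[int] = set()
        # longer-or-equal representatives that start with this sequence
        candidates.update(by_prefix.get(seq, []))
        # shorter representatives that are a prefix of this sequence
        for cut in range(max(1, len(seq) - max_length_diff), len(seq)):
            idx = by_exact.get(seq[:cut])
            if idx is not None:
                candidates.add(idx)
        if anchor == "both_ends":
            for cut in range(max(1, len(seq) - max_length_diff), len(seq)):
                idx = by_exact.get(seq[-cut:])
                if idx is not None:
                    candidates.add(idx)
        valid = [
            i for i in candidates if abs(len(tags[i].seq) - len(seq)) <= max_length_diff
        ]
        if valid:
            tag = tags[min(valid)]  # earliest-founded = highest-count chain head
            tag.members[seq] = tag.members.get(seq, 0) + count
            tag.count += count
        else:
            idx = len(tags)
            tags.append(Tag(f"{tag_prefix}{idx + 1}", seq, count, {seq: count}))
            register(seq, idx)
    return tags


def filter_tags(tags: list[Tag], min_reads: int) -> list[Tag]:
    """Keep tags with count strictly greater than ``min_reads``.

    The ">2 reads" (conserved discovery) and ">5 reads" (novel-candidate
    input) thresholds are both strict inequalities.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return [t for t in tags if t.count > min_reads]
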