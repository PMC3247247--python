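"""Read preprocessing: 3' quality trimming, adapter removal, length filter.

The stages run in fixed order — quality trim, 3' adapter, 5' adapter,
17-26 nt length filter — mirroring the top of the analysis pipeline.
All trimming operations return a prefix (3' operations) or suffix
(5' operation) of the input read; nothing is ever inserted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .io_formats import Read

__all__ = [
    "TrimResult",
    "AdapterAlignment",
    "trim_quality_3prime",
    "trim_adapter_3prime",
    "trim_adapter_5prime",
    "best_adapter_alignment",
    "filter_by_length",
    "preprocess_read",
    "preprocess_library",
    "PreprocessStats",
]

UNCHANGED = "unchanged"
QUALITY_TRIMMED = "quality_trimmed"
ADAPTER_TRIMMED = "adapter_trimmed"
DISCARDED = "discarded"


@dataclass(frozen=True)
class TrimResult:
    """Outcome of one trimming stage. ``read`` is None when discarded."""

    read: Optional[Read]
    action: str
    trim_start: Optional[int] = None


@dataclass(frozen=True)
class AdapterAlignment:
    """Ungapped semi-global placement of the adapter on a read suffix."""

    read_offset: int
    score: float
    matches: int
    aligned_length: int


def trim_quality_3prime(read: Read, cutoff: int = 20) -> TrimResult:
    """Remove the maximal 3' suffix in which every base is below ``cutoff``.

    Scanning stops at the 3'-most base with quality >= cutoff (a Phred 20
    cutoff keeps bases with <=1% error probability). A read with no such
    base is discarded.
    """
    keep = len(read)
    while keep > 0 and read.qual[keep - 1] < cutoff:
        keep -= 1
    if keep == 0:
        return TrimResult(None, DISCARDED, trim_start=0)
    if keep == len(read):
        return TrimResult(read, UNCHANGED)
    return TrimResult(read.prefix(keep), QUALITY_TRIMMED, trim_start=keep)


def _base_weight(q: int) -> float:
    # probability the base call is correct
    return 1.0 - 10.0 ** (-q / 10.0)


# w(q) lookup for the 0..62 Phred range, avoids pow() in the hot path
_WEIGHT_TABLE = np.array([1.0 - 10.0 ** (-q / 10.0) for q in range(63)])


def best_adapter_alignment(read: Read, adapter: str) -> Optional[AdapterAlignment]:
    """Best quality-weighted ungapped placement of ``adapter`` on the read.

    Semi-global: the adapter may overhang the read's 3' end, so at offset
    ``o`` only the first ``len(read) - o`` adapter bases participate.
    Per-base score is +w(q) for a match and -w(q) for a mismatch with
    w(q) = 1 - 10^(-q/10), so low-quality bases carry little evidence
    either way. Ties go to the smallest offset (the longest trim).
    """
    n = len(read)
    la = len(adapter)
    seq = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    adp = np.frombuffer(adapter.encode(), dtype=np.uint8)
    w = _WEIGHT_TABLE[np.asarray(read.qual, dtype=np.intp)]
    # pad so every offset sees a full-width window; padded cells score 0
    pad_seq = np.zeros(n + la, dtype=np.uint8)
    pad_seq[:n] = seq
    pad_w = np.zeros(n + la)
    pad_w[:n] = w
    windows = np.lib.stride_tricks.sliding_window_view(pad_seq, la)[:n]
    w_windows = np.lib.stride_tricks.sliding_window_view(pad_w, la)[:n]
    match = windows == adp
    scores = np.where(match, w_windows, -w_windows).sum(axis=1)
    offset = int(np.argmax(scores))  # argmax takes the first = smallest offset
    aligned = min(la, n - offset)
    matches = int(match[offset, :aligned].sum())
    return AdapterAlignment(offset, float(scores[offset]), matches, aligned)


def trim_adapter_3prime(
    read: Read,
    adapter: str,
    min_score: float = 5.0,
    min_matches: int = 6,
) -> TrimResult:
    """Locate the 3' adapter by quality-weighted ungapped alignment and
    truncate the read at the start of the optimum placement.

    The placement must score at least ``min_score`` and contain at least
    ``min_matches`` matching bases; otherwise the read is unchanged. An
    accepted placement at offset 0 (adapter dimer, empty insert) discards
    the read.
    """
    if len(adapter) < min_matches:
        raise ValueError("adapter shorter than min_matches")
    hit = best_adapter_alignment(read, adapter)
    if hit is None or hit.score < min_score or hit.matches < min_matches:
        return TrimResult(read, UNCHANGED)
    if hit.read_offset == 0:
        return TrimResult(None, DISCARDED, trim_start=0)
    return TrimResult(read.prefix(hit.read_offset), ADAPTER_TRIMMED, trim_start=hit.read_offset)


def trim_adapter_5prime(read: Read, adapter: str, min_match: int = 10) -> TrimResult:
    """Strip a 5' adapter remnant matched exactly at the read's 5' end.

    The longest adapter suffix of length >= ``min_match`` that equals the
    read's prefix is removed; shorter coincidental matches are ignored.
    """
    limit = min(len(adapter), len(read))
    for length in range(limit, min_match - 1, -1):
        if adapter[-length:] == read.seq[:length]:
            if length == len(read):
                return TrimResult(None, DISCARDED, trim_start=0)
            return TrimResult(read.suffix_from(length), ADAPTER_TRIMMED, trim_start=length)
    return TrimResult(read, UNCHANGED)


def filter_by_length(
    reads: Iterable[Read], min_len: int = 17, max_len: int = 26
) -> tuple[list[Read], Counter]:
    """Keep reads with min_len <= length <= max_len.

    Returns the kept reads and a length histogram over ALL input reads
    (computed before filtering), the raw material for a read-length
    distribution plot.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    histogram: Counter = Counter()
    kept: list[Read] = []
    for read in reads:
        histogram[len(read)] += 1
        if min_len <= len(read) <= max_len:
            kept.append(read)
    return kept, histogram


@dataclass
class PreprocessStats:
    """Per-stage read accounting for one library."""

    n_input: int = 0
    n_discarded_quality: int = 0
    n_discarded_adapter_dimer: int = 0
    n_discarded_length: int = 0
    n_kept: int = 0
    length_histogram: Counter = None  # over trimmed reads, before length filter

    def __post_init__(self) -> None:
        if self.length_histogram is None:
            self.length_histogram = Counter()

    def check(self) -> None:
        assert (
            self.n_input
            == self.n_discarded_quality
            + self.n_discarded_adapter_dimer
            + self.n_discarded_length
            + self.n_kept
        )


def preprocess_read(
    read: Read,
    adapter3: str,
    adapter5: str | None = None,
    quality_cutoff: int = 20,
    min_score: float = 5.0,
    min_matches: int = 6,
) -> tuple[Optional[Read], str]:
    """Quality trim, then 3' adapter, then 5' adapter, for a single read.

    Returns (trimmed read or None, reason) where reason is "ok",
    "quality" or "adapter_dimer".
    """
    res = trim_quality_3prime(read, quality_cutoff)
    if res.read is None:
        return None, "quality"
    res = trim_adapter_3prime(res.read, adapter3, min_score, min_matches)
    if res.read is None:
        return None, "adapter_dimer"
    if adapter5:
        res = trim_adapter_5prime(res.read, adapter5)
        if res.read is None:
            return None, "adapter_dimer"
    return res.read, "ok"


def preprocess_library(
    reads: Iterable[Read],
    adapter3: str,
    adapter5: str | None = None,
    quality_cutoff: int = 20,
    min_len: int = 17,
    max_len: int = 26,
    min_score: float = 5.0,
    min_matches: int = 6,
) -> Iterator[Read]:
    """Full preprocessing of a library; yields surviving reads.

    Attach a :class:`PreprocessStats` via :func:`preprocess_library_stats`
    when accounting is needed.
    """
    kept, _ = preprocess_library_stats(
        reads, adapter3, adapter5, quality_cutoff, min_len, max_len, min_score, min_matches
    )
    yield from kept


def preprocess_library_stats(
    reads: Iterable[Read],
    adapter3: str,
    adapter5: str | None = None,
    quality_cutoff: int = 20,
    min_len: int = 17,
    max_len: int = 26,
    min_score: float = 5.0,
    min_matches: int = 6,
) -> tuple[list[Read], PreprocessStats]:
    """Preprocess a library and return (kept reads, per-stage accounting)."""
    stats = PreprocessStats()
    trimmed: list[Read] = []
    for read in reads:
        stats.n_input += 1
        out, reason = preprocess_read(
            read, adapter3, adapter5, quality_cutoff, min_score, min_matches
        )
        if out is None:
            if reason == "quality":
                stats.n_discarded_quality += 1
            else:
                stats.n_discarded_adapter_dimer += 1
            continue
        trimmed.append(out)
    kept, histogram = filter_by_length(trimmed, min_len, max_len)
    stats.length_histogram = histogram
    stats.n_kept = len(kept)
    stats.n_discarded_length = len(trimmed) - len(kept)
    stats.check()
    return kept, stats
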