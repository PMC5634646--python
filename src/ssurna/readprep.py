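"""Quality trimming, paired-end merging, and ambiguity/homopolymer/length screens.

Trimming keeps the longest 5'-anchored prefix in which every sliding window
(window = max(20 bp, 10% of the read)) has mean phred quality at or above the
floor (Q20 by default).  Merging reverse-complements R2, scans every ungapped
3' overlap, and resolves conflicting columns by the higher-quality base.
Screens drop merged reads with ambiguous bases or a mononucleotide run longer
than eight; reads at or below the length floor are set aside (counted, not
classified).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy.signal import fftconvolve

from .seqio import PipelineConfig, SeqRecord

__all__ = [
    "MergeParams",
    "RejectionTally",
    "quality_trim",
    "merge_pairs",
    "screen_sequences",
]

MIN_TRIMMED_LENGTH = 20


class MissingQualityError(ValueError):
    pass


@dataclass(frozen=True)
class MergeParams:
    min_overlap: int = 10
    max_mismatch_frac: float = 0.08

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0.0 <= self.max_mismatch_frac < 0.5):
            raise ValueError("max_mismatch_frac must be in [0, 0.5)")


def _window_size(n: int) -> int:
    return max(20, n // 10)


def _trim_length_once(qual: list[int], n: int, floor: int) -> int:
    """Longest prefix of the first ``n`` scores whose every full window
    (size from ``n``) has mean >= floor."""
    w = _window_size(n)
    if n < w:
        mean = sum(qual[:n]) / n if n else 0.0
        return n if mean >= floor else 0
    running = sum(qual[:w])
    if running / w < floor:
        return w - 1
    for i in range(1, n - w + 1):
        running += qual[i + w - 1] - qual[i - 1]
        if running / w < floor:
            return i + w - 1
    return n


def quality_trim(rec: SeqRecord, floor: int) -> SeqRecord | None:
    """3'-trim ``rec`` to the longest prefix whose every full sliding window
    has mean quality >= ``floor``; ``None`` if the result is shorter than
    20 bp.

    The window size tracks the current length (max of 20 bp and 10%), so the
    cut is iterated to a fixed point; trimming is therefore idempotent.
    """
    if rec.qual is None:
        raise MissingQualityError(f"record {rec.id!r} has no qualities")
    keep = len(rec)
    while True:
        new = _trim_length_once(rec.qual, keep, floor)
        if new == keep:
            break
        keep = new
    if keep < MIN_TRIMMED_LENGTH:
        return None
    if keep == len(rec):
        return rec
    return SeqRecord(rec.id, rec.seq[:keep], rec.qual[:keep])


def _overlap_stats(s1: str, s2: str, o: int) -> tuple[int, int]:
    mism = sum(1 for a, b in zip(s1[-o:], s2[:o]) if a != b)
    return o - mism, mism


def _best_overlap(s1: str, s2: str, params: MergeParams) -> tuple[int, int] | None:
    """Best ungapped 3' overlap of s1 with s2: (overlap, mismatches) of the
    candidate maximising matches - mismatches (ties to the longer overlap),
    among overlaps passing the mismatch limit; ``None`` if none pass.

    Match counts for every overlap are computed at once by FFT correlation
    of one-hot base encodings.
    """
    n1, n2 = len(s1), len(s2)
    max_o = min(n1, n2)
    if max_o < params.min_overlap:
        return None
    a = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)
    conv = np.zeros(n1 + n2 - 1)
    for base in (65, 67, 71, 84):  # A C G T
        conv += fftconvolve((a == base).astype(np.float64), (b == base)[::-1])
    o = np.arange(params.min_overlap, max_o + 1)
    matches = np.rint(conv[n1 + n2 - 1 - o]).astype(np.int64)
    mism = o - matches
    valid = mism <= params.max_mismatch_frac * o
    if not valid.any():
        return None
    score = 2 * matches - o
    # lexicographic (score, overlap) maximum
    key = score * (max_o + 1) + o
    key[~valid] = np.iinfo(np.int64).min
    i = int(np.argmax(key))
    return int(o[i]), int(mism[i])


def merge_pairs(
    r1: SeqRecord, r2: SeqRecord, params: MergeParams = MergeParams()
) -> SeqRecord | None:
    """Merge a pair on its best ungapped 3' overlap, or ``None`` if no overlap
    of at least ``min_overlap`` bases passes the mismatch limit.

    R2 is reverse-complemented first.  The candidate maximising
    matches - mismatches wins (ties to the longer overlap); conflicting
    columns take the higher-quality base.
    """
    rc2 = r2.reverse_complement()
    s1, s2 = r1.seq, rc2.seq
    best = _best_overlap(s1, s2, params)
    if best is None:
        return None
    o, _ = best
    q1 = r1.qual if r1.qual is not None else [40] * len(s1)
    q2 = rc2.qual if rc2.qual is not None else [40] * len(s2)
    mid_seq, mid_qual = [], []
    for i in range(o):
        a, qa = s1[len(s1) - o + i], q1[len(s1) - o + i]
        b, qb = s2[i], q2[i]
        if a == b:
            mid_seq.append(a)
            mid_qual.append(max(qa, qb))
        elif qa >= qb:
            mid_seq.append(a)
            mid_qual.append(qa)
        else:
            mid_seq.append(b)
            mid_qual.append(qb)
    seq = s1[: len(s1) - o] + "".join(mid_seq) + s2[o:]
    qual = q1[: len(s1) - o] + mid_qual + q2[o:]
    return SeqRecord(_strip_mate_suffix(r1.id), seq, qual)


def _strip_mate_suffix(rec_id: str) -> str:
    if len(rec_id) > 2 and rec_id[-2] == "/" and rec_id[-1] in "12":
        return rec_id[:-2]
    return rec_id


@dataclass
class RejectionTally:
    """Per-reason screen counts; kept + rejected + short == input."""

    kept: int = 0
    ambiguous: int = 0
    homopolymer: int = 0
    short: int = 0

    @property
    def input_count(self) -> int:
        return self.kept + self.ambiguous + self.homopolymer + self.short

    def as_rows(self) -> list[dict[str, object]]:
        return [
            {"reason": "kept", "count": self.kept},
            {"reason": "ambiguous", "count": self.ambiguous},
            {"reason": "homopolymer", "count": self.homopolymer},
            {"reason": "below_min_length", "count": self.short},
        ]


def _max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best if seq else 0


def screen_sequences(
    records: Iterable[SeqRecord],
    cfg: PipelineConfig,
    short_sink: list[SeqRecord] | None = None,
) -> tuple[Iterator[SeqRecord], RejectionTally]:
    """Apply the ambiguity / homopolymer / length screens.

    Returns a fully-materialised kept stream plus the rejection tally.
    Reads containing N or any non-ACGT code are dropped; reads with a
    mononucleotide run longer than ``cfg.max_homopolymer`` are dropped;
    clean reads not longer than ``cfg.min_length`` are excluded from the
    classification set (optionally collected in ``short_sink``) but counted.
    """
    tally = RejectionTally()
    kept: list[SeqRecord] = []
    acgt = set("ACGT")
    for rec in records:
        if set(rec.seq) - acgt:
            tally.ambiguous += 1
        elif _max_homopolymer_run(rec.seq) > cfg.max_homopolymer:
            tally.homopolymer += 1
        elif len(rec) <= cfg.min_length:
            tally.short += 1
            if short_sink is not None:
                short_sink.append(rec)
        else:
            tally.kept += 1
            kept.append(rec)
    return iter(kept), tally
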