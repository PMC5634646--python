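"""Mapping SSU reads onto the *E. coli*-numbered 16S template and trimming
to the 8F-V1-V2 window (positions 8-242).

Reads are placed with an infix alignment (the whole read aligned inside the
template, end gaps on the template free), strand auto-detected; a read is
unmapped when identity over the aligned span falls below 60% (tolerant
enough for archaeal divergence from the bacterial template, and configurable).
Coordinates are 1-based inclusive on the ungapped template.  Only reads whose
alignment fully spans the window enter OTU analysis; the trimmed product
keeps read insertions (they are read bases) and records deletions as gap
columns so downstream distances can be computed column-wise without a fresh
alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import edlib
import numpy as np

from .seqio import PipelineConfig, SeqRecord, reverse_complement

__all__ = [
    "CoordinateMap",
    "TrimmedRead",
    "map_to_template",
    "position_distribution",
    "trim_to_region",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class CoordinateMap:
    """Alignment of one read onto the template.

    ``pairs`` lists (read offset, template position) for every aligned
    column, both 0-based read offsets and 1-based template positions,
    strictly increasing on both axes.  Offsets refer to the read in the
    mapped orientation; ``strand`` records whether that is the reverse
    complement of the input.
    """

    read_id: str
    start: int  # 1-based inclusive template position
    end: int
    pairs: list[tuple[int, int]]
    identity: float
    strand: str = "+"

    def contains(self, region_start: int, region_end: int) -> bool:
        return self.start <= region_start and self.end >= region_end


@dataclass
class TrimmedRead:
    """Read content over the 8F-V1-V2 window.

    ``seq`` is the read's bases across the window (insertions retained);
    ``aligned`` has exactly one character per template column of the window,
    with '-' where the read has a deletion, so trimmed reads from the same
    window are directly comparable column by column.
    """

    id: str
    seq: str
    aligned: str


class TemplateError(ValueError):
    pass


def _align_one_strand(seq: str, template: str) -> tuple[int, list[tuple[int, int]], float] | None:
    res = edlib.align(seq, template, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start = res["locations"][0][0]  # 0-based on template
    pairs: list[tuple[int, int]] = []
    q, t = 0, t_start
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        if op in "=XM":
            for _ in range(n):
                pairs.append((q, t + 1))  # template positions 1-based
                q += 1
                t += 1
            columns += n
            if op == "=":
                matches += n
        elif op == "I":  # read-only bases
            q += n
            columns += n
        else:  # 'D': template-only positions
            t += n
            columns += n
    identity = matches / columns if columns else 0.0
    return res["editDistance"], pairs, identity


def map_to_template(
    rec: SeqRecord, template: str, min_identity: float = 0.60
) -> CoordinateMap | None:
    """Place ``rec`` on the template; ``None`` when identity < ``min_identity``.

    Both strands are tried and the lower edit distance kept (ties to the
    forward strand).
    """
    if not template:
        raise TemplateError("empty 16S coordinate template")
    best = None
    for strand, s in (("+", rec.seq), ("-", reverse_complement(rec.seq))):
        res = _align_one_strand(s, template)
        if res is None:
            continue
        dist, pairs, identity = res
        if best is None or dist < best[0]:
            best = (dist, pairs, identity, strand)
    if best is None:
        return None
    _, pairs, identity, strand = best
    if identity < min_identity or not pairs:
        return None
    return CoordinateMap(
        read_id=rec.id,
        start=pairs[0][1],
        end=pairs[-1][1],
        pairs=pairs,
        identity=identity,
        strand=strand,
    )


def position_distribution(
    maps: Iterable[CoordinateMap],
    template_length: int,
    region_start: int = 8,
    region_end: int = 242,
) -> tuple[np.ndarray, float]:
    """Per-position read coverage plus the fraction of reads whose span fully
    contains [region_start, region_end].

    The coverage array is indexed by 1-based template position (index 0
    unused)."""
    coverage = np.zeros(template_length + 1, dtype=np.int64)
    n = contained = 0
    for m in maps:
        coverage[m.start : m.end + 1] += 1
        n += 1
        if m.contains(region_start, region_end):
            contained += 1
    if n == 0:
        raise ValueError("no mapped reads")
    return coverage, contained / n


def trim_to_region(
    cmap: CoordinateMap, rec: SeqRecord, cfg: PipelineConfig
) -> TrimmedRead | None:
    """Cut the read to template positions [region_start, region_end].

    Rejects (returns ``None``) any read whose alignment does not fully span
    the window: only complete-region reads enter OTU analysis.  The read is
    first put in mapped orientation, so trimming is orientation-independent.
    """
    lo, hi = cfg.region_start, cfg.region_end
    if not cmap.contains(lo, hi):
        return None
    seq = rec.seq if cmap.strand == "+" else reverse_complement(rec.seq)
    in_window = [(q, t) for q, t in cmap.pairs if lo <= t <= hi]
    if not in_window:
        return None
    q_first, q_last = in_window[0][0], in_window[-1][0]
    trimmed_seq = seq[q_first : q_last + 1]
    aligned_chars = []
    by_template = dict((t, q) for q, t in in_window)
    for t in range(lo, hi + 1):
        q = by_template.get(t)
        aligned_chars.append(seq[q] if q is not None else "-")
    return TrimmedRead(id=cmap.read_id, seq=trimmed_seq, aligned="".join(aligned_chars))
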