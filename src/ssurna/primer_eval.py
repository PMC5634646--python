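"""In-silico coverage evaluation of the degenerate forward primer 8F.

8F (5'-AGAGTTTGAT(C/T)(A/C)TGGCTCAG-3', i.e. AGAGTTTGATYMTGGCTCAG) anneals
at *E. coli* 16S positions 8-27.  A read counts toward the evaluation only
when its template alignment fully spans that window; it is "non-covered"
when at least one window position disagrees with every expansion of the
primer.  A mismatch is a window position whose read base is not in the IUPAC
set of the primer base; unpaired positions inside the window (indels) also
count — a primer cannot anneal across an indel.  Read Ns fail every primer
base (conservative).

Non-coverage rates are tabulated per taxon at each requested rank as
non_covered / covering reads; the count of all classified reads of the taxon
is carried alongside since published tables have used either denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .refmap import CoordinateMap
from .seqio import SeqRecord, reverse_complement
from .taxclass import Classification

__all__ = [
    "DegeneratePrimer",
    "PrimerMatchResult",
    "PRIMER_8F",
    "expand_iupac",
    "match_primer",
    "noncoverage_rates",
    "mismatch_catalogue",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    pattern: str  # IUPAC string, 5'->3' on the template plus strand
    template_window: tuple[int, int]  # 1-based inclusive template positions

    def __post_init__(self) -> None:
        for i, c in enumerate(self.pattern):
            if c not in IUPAC:
                raise AlphabetError(f"invalid IUPAC character {c!r} at position {i}")
        lo, hi = self.template_window
        if hi - lo + 1 != len(self.pattern):
            raise ValueError("template window length must equal pattern length")


PRIMER_8F = DegeneratePrimer("8F", "AGAGTTTGATYMTGGCTCAG", (8, 27))


@dataclass
class PrimerMatchResult:
    read_id: str
    covers_window: bool
    n_mismatches: int | None = None
    mismatch_positions: list[int] = field(default_factory=list)
    observed_window: str | None = None

    @property
    def non_covered(self) -> bool:
        return bool(self.covers_window and self.n_mismatches)


def expand_iupac(pattern: str) -> list[str]:
    """All exact sequences matching an IUPAC pattern (cartesian expansion)."""
    sets = []
    for i, c in enumerate(pattern):
        if c not in IUPAC:
            raise AlphabetError(f"invalid IUPAC character {c!r} at position {i}")
        sets.append(IUPAC[c])
    return ["".join(p) for p in itertools.product(*sets)]


def match_primer(
    cmap: CoordinateMap, rec: SeqRecord, primer: DegeneratePrimer = PRIMER_8F
) -> PrimerMatchResult:
    """Evaluate one mapped read against the primer window.

    ``covers_window`` is true iff the alignment fully spans the window.
    Mismatches: window positions whose read base is outside the primer
    base's IUPAC set, plus unpaired template positions (deletions) and
    read insertions inside the window.
    """
    lo, hi = primer.template_window
    if not cmap.contains(lo, hi):
        return PrimerMatchResult(read_id=cmap.read_id, covers_window=False)
    seq = rec.seq if cmap.strand == "+" else reverse_complement(rec.seq)
    by_template = {t: q for q, t in cmap.pairs}
    mism_positions: list[int] = []
    window_chars: list[str] = []
    for t in range(lo, hi + 1):
        q = by_template.get(t)
        base = primer.pattern[t - lo]
        if q is None:  # deletion in the read
            window_chars.append("-")
            mism_positions.append(t)
        else:
            c = seq[q]
            window_chars.append(c)
            if c not in IUPAC[base]:
                mism_positions.append(t)
    # read insertions strictly inside the window
    in_window = [(q, t) for q, t in cmap.pairs if lo <= t <= hi]
    if in_window:
        q_span = in_window[-1][0] - in_window[0][0] + 1
        insertions = q_span - len(in_window)
        for _ in range(insertions):
            mism_positions.append(lo)  # annotate at window start
    mism_positions.sort()
    return PrimerMatchResult(
        read_id=cmap.read_id,
        covers_window=True,
        n_mismatches=len(mism_positions),
        mismatch_positions=mism_positions,
        observed_window="".join(window_chars),
    )


def noncoverage_rates(
    results: Sequence[PrimerMatchResult],
    classifications: Sequence[Classification],
    rank_depths: Sequence[int] = (0, 1),
    suppress_below: int | None = None,
) -> list[dict[str, object]]:
    """Per-taxon non-coverage table at each requested rank depth
    (0 = domain, 1 = phylum, ...).

    rate = non_covered / covering reads of the taxon; ``classified_total``
    additionally counts the taxon's reads that do not cover the window.
    Taxa with no covering reads report an undefined (None) rate.  With
    ``suppress_below`` set, taxa with fewer non-covered reads are flagged
    (``suppressed`` column) rather than dropped.
    """
    if len(results) != len(classifications):
        raise ValueError("results and classifications must be parallel")
    rows: list[dict[str, object]] = []
    for depth in rank_depths:
        per_taxon: dict[str, list[int]] = {}
        for res, cls in zip(results, classifications):
            taxon = cls.taxon_at(depth)
            counts = per_taxon.setdefault(taxon, [0, 0, 0])  # covering, noncov, total
            counts[2] += 1
            if res.covers_window:
                counts[0] += 1
                if res.n_mismatches:
                    counts[1] += 1
        for taxon in sorted(per_taxon):
            covering, noncov, total = per_taxon[taxon]
            rate = noncov / covering if covering else None
            rows.append(
                {
                    "rank_depth": depth,
                    "taxon": taxon,
                    "non_covered": noncov,
                    "covering": covering,
                    "classified_total": total,
                    "rate": rate,
                    "suppressed": (
                        suppress_below is not None and noncov < suppress_below
                    ),
                }
            )
    return rows


def mismatch_catalogue(
    results: Iterable[PrimerMatchResult], primer: DegeneratePrimer = PRIMER_8F
) -> list[dict[str, object]]:
    """Distinct observed primer-window variants with counts and per-position
    differences against the nearest primer expansion (minimum Hamming
    distance, ties to the lexicographically first expansion)."""
    expansions = expand_iupac(primer.pattern)
    counts: dict[str, int] = {}
    for res in results:
        if res.covers_window and res.observed_window is not None:
            counts[res.observed_window] = counts.get(res.observed_window, 0) + 1
    rows = []
    for window in sorted(counts, key=lambda w: (-counts[w], w)):
        best_exp, best_d = None, None
        for exp in expansions:
            if len(exp) != len(window):
                d = max(len(exp), len(window))
            else:
                d = sum(1 for a, b in zip(window, exp) if a != b)
            if best_d is None or d < best_d:
                best_exp, best_d = exp, d
        diffs = (
            ";".join(
                f"{primer.template_window[0] + i}{best_exp[i]}>{window[i]}"
                for i in range(len(window))
                if i < len(best_exp) and window[i] != best_exp[i]
            )
            if len(window) == len(best_exp)
            else "length_change"
        )
        rows.append(
            {
                "observed_window": window,
                "count": counts[window],
                "nearest_expansion": best_exp,
                "hamming": best_d,
                "differences": diffs or ".",
            }
        )
    return rows
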