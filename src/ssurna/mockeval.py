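"""Mock-community accuracy machinery.

Composition tables at a chosen rank and length floor, ordinary
least-squares comparison of two compositions (slope, intercept, r²),
observed/expected fold-error tables across length cut-offs (the menu
200/250/360 bp), per-taxon read-length histograms with peak calling,
5'-ligation start-point histograms for LSU reads, and the two-tailed
Fisher's exact test used to compare sequence-type fractions between
datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .refmap import CoordinateMap
from .taxclass import Classification

__all__ = [
    "CompositionTable",
    "RegressionSummary",
    "composition",
    "compare_compositions",
    "length_cutoff_sensitivity",
    "length_distribution",
    "start_point_distribution",
    "fisher_exact_2x2",
]


class EmptyCompositionError(ValueError):
    pass


class InsufficientPointsError(ValueError):
    pass


class UndefinedTestError(ValueError):
    pass


@dataclass
class CompositionTable:
    rank_depth: int
    proportions: dict[str, float]
    total: int

    def __post_init__(self) -> None:
        if self.proportions:
            s = sum(self.proportions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {s}, not 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("negative proportion")


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def composition(
    classifications: Sequence[Classification],
    lengths: Sequence[int],
    rank_depth: int = 5,
    min_length: int = 250,
    include_unclassified: bool = True,
) -> CompositionTable:
    """Taxon proportions at ``rank_depth`` among reads longer than
    ``min_length``.  Reads not accepted at that depth count as
    'unclassified' (droppable via ``include_unclassified=False``)."""
    if len(classifications) != len(lengths):
        raise ValueError("classifications and lengths must be parallel")
    counts: dict[str, int] = {}
    for cls, n in zip(classifications, lengths):
        if n <= min_length:
            continue
        taxon = cls.taxon_at(rank_depth)
        if taxon == "unclassified" and not include_unclassified:
            continue
        counts[taxon] = counts.get(taxon, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise EmptyCompositionError(
            f"no reads longer than {min_length} classified at depth {rank_depth}"
        )
    props = {t: c / total for t, c in sorted(counts.items())}
    return CompositionTable(rank_depth=rank_depth, proportions=props, total=total)


def compare_compositions(
    x: CompositionTable | Mapping[str, float],
    y: CompositionTable | Mapping[str, float],
) -> RegressionSummary:
    """OLS of y-proportions on x-proportions over the taxon union
    (absent taxa contribute 0)."""
    px = x.proportions if isinstance(x, CompositionTable) else dict(x)
    py = y.proportions if isinstance(y, CompositionTable) else dict(y)
    taxa = sorted(set(px) | set(py))
    if len(taxa) < 2:
        raise InsufficientPointsError("need at least 2 taxa for regression")
    xv = np.array([px.get(t, 0.0) for t in taxa])
    yv = np.array([py.get(t, 0.0) for t in taxa])
    if np.ptp(xv) == 0.0:
        raise InsufficientPointsError(
            "x-composition is uniform; the regression is degenerate"
        )
    res = stats.linregress(xv, yv)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(taxa),
    )


def length_cutoff_sensitivity(
    classifications: Sequence[Classification],
    lengths: Sequence[int],
    expected: Mapping[str, float],
    cutoffs: Sequence[int] = (200, 250, 360),
    rank_depth: int = 5,
) -> list[dict[str, object]]:
    """Observed/expected fold ratio per taxon per length cut-off.

    Folds outside [0.5, 2.0] are flagged; an expected proportion of 0 with
    observed reads reports an infinite fold (flagged)."""
    rows: list[dict[str, object]] = []
    for cutoff in cutoffs:
        table = composition(
            classifications,
            lengths,
            rank_depth=rank_depth,
            min_length=cutoff,
            include_unclassified=False,
        )
        for taxon in sorted(set(expected) | set(table.proportions)):
            obs = table.proportions.get(taxon, 0.0)
            exp = expected.get(taxon, 0.0)
            if exp == 0.0:
                fold = math.inf if obs > 0 else 1.0
            else:
                fold = obs / exp
            rows.append(
                {
                    "cutoff": cutoff,
                    "taxon": taxon,
                    "observed": obs,
                    "expected": exp,
                    "fold": fold,
                    "flagged": not (0.5 <= fold <= 2.0),
                }
            )
    return rows


def length_distribution(
    lengths: Sequence[int],
    taxa: Sequence[str],
    peak_prominence_frac: float = 0.01,
) -> dict[str, dict[str, object]]:
    """Per-taxon read-length histogram (1-bp bins) plus called peaks.

    Peaks are local maxima with prominence at least
    ``peak_prominence_frac`` of the taxon's read count."""
    if len(lengths) != len(taxa):
        raise ValueError("lengths and taxa must be parallel")
    out: dict[str, dict[str, object]] = {}
    by_taxon: dict[str, list[int]] = {}
    for n, t in zip(lengths, taxa):
        by_taxon.setdefault(t, []).append(n)
    for taxon in sorted(by_taxon):
        vals = np.asarray(by_taxon[taxon])
        hist = np.bincount(vals)
        prominence = max(1.0, peak_prominence_frac * vals.size)
        # pad so a maximum at either end of the support is still a peak
        padded = np.concatenate([[0], hist, [0]])
        peaks, _ = find_peaks(padded, prominence=prominence)
        out[taxon] = {"histogram": hist, "peaks": [int(p) - 1 for p in peaks]}
    return out


def start_point_distribution(maps: Iterable[CoordinateMap]) -> np.ndarray:
    """Histogram of aligned 5' start positions (1-based; index 0 unused),
    the in-silico analogue of the adaptor-ligation start-point profile."""
    starts = [m.start for m in maps]
    if not starts:
        return np.zeros(1, dtype=np.int64)
    return np.bincount(np.asarray(starts))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p for the table [[a, b], [c, d]]
    (method of small p-values: sum of hypergeometric probabilities not
    exceeding the observed table's)."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n < 1:
        raise UndefinedTestError("empty table")
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        raise UndefinedTestError("a margin of the 2x2 table is zero")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
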