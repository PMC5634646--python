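"""k-mer naive-Bayes taxonomic classification with bootstrap confidence.

This is the RDP/Wang scheme: references are grouped at the genus level (here,
by full lineage); each genus g gets per-word log conditional probabilities

    log P(w | g) = log((m_g(w) + p_w) / (M_g + 1)),   p_w = (n_w + 0.5) / (N + 1)

where m_g(w) counts genus members containing word w, M_g is the genus size,
n_w the number of references containing w, and N the reference count.  A
query is scored by summing log P(w|g) over its distinct k-mers (k = 8); the
argmax genus wins, ties broken by lexicographic lineage.  Confidence comes
from 100 bootstrap resamples, each drawing ceil(m/8) of the m query words
with replacement; per-rank confidence is the fraction of resamples whose
winner agrees with the full-data lineage down to that rank, so confidences
are non-increasing from domain to genus.  The lineage is truncated at the
deepest rank meeting the cut-off (80% for reads, 50% for OTU
representatives); deeper ranks report as unclassified.

Both strands are scored and the better one kept: merged 5'-adaptor inserts
can be antisense relative to the reference set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .seqio import TaxonomyLineage, reverse_complement

__all__ = ["KmerIndex", "Classification", "build_index", "classify"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TABLE = bytes(
    {65: 0, 67: 1, 71: 2, 84: 3}.get(i, 255) for i in range(256)
)


class TooShortError(ValueError):
    pass


class EmptyReferenceError(ValueError):
    pass


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Distinct k-mer integer codes of ``seq`` (k-mers with non-ACGT bases
    are skipped)."""
    raw = np.frombuffer(seq.encode("ascii").translate(_CODE_TABLE), dtype=np.uint8)
    codes = raw.astype(np.int64)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes != 255
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        out = out * 4 + np.where(valid[j : j + n], codes[j : j + n], 0)
        ok &= valid[j : j + n]
    return np.unique(out[ok])


@dataclass
class KmerIndex:
    """Per-genus log-posterior word table (genera ordered lexicographically)."""

    k: int
    genera: list[TaxonomyLineage]
    log_cond: np.ndarray  # shape (n_genera, 4**k), float32

    @property
    def n_genera(self) -> int:
        return len(self.genera)


def build_index(
    references: Mapping[str, tuple[str, TaxonomyLineage]], k: int = 8
) -> KmerIndex:
    """Build the classifier index from id -> (sequence, lineage).

    Duplicate sequences within a genus only count once per distinct
    sequence set entry; word statistics use presence, not multiplicity, so a
    duplicated reference record leaves the index unchanged.
    """
    if not references:
        raise EmptyReferenceError("reference set is empty")
    if not (4 <= k <= 12):
        raise ValueError("k must be in 4..12")
    # de-duplicate identical (sequence, lineage) entries
    seen: dict[tuple[str, TaxonomyLineage], None] = {}
    for seq, lineage in references.values():
        seen.setdefault((seq, lineage), None)
    by_genus: dict[TaxonomyLineage, list[str]] = {}
    for seq, lineage in seen:
        by_genus.setdefault(lineage, []).append(seq)
    genera = sorted(by_genus, key=lambda lin: lin.taxa)
    n_words = 4**k
    presence = np.zeros(n_words, dtype=np.float64)  # n_w over all references
    genus_counts = []
    n_refs = 0
    for lineage in genera:
        counts = np.zeros(n_words, dtype=np.float64)
        for seq in sorted(by_genus[lineage]):
            words = _kmer_codes(seq, k)
            counts[words] += 1.0
            presence[words] += 1.0
            n_refs += 1
        genus_counts.append(counts)
    prior = (presence + 0.5) / (n_refs + 1.0)
    log_cond = np.empty((len(genera), n_words), dtype=np.float32)
    for gi, (lineage, counts) in enumerate(zip(genera, genus_counts)):
        m_g = len(by_genus[lineage])
        log_cond[gi] = np.log((counts + prior) / (m_g + 1.0))
    return KmerIndex(k=k, genera=genera, log_cond=log_cond)


@dataclass
class Classification:
    """Winning lineage with per-rank bootstrap confidences (percent)."""

    lineage: TaxonomyLineage
    bootstrap: list[float]  # one per rank, root to leaf, non-increasing
    cutoff: float
    strand: str = "+"
    score: float = 0.0

    @property
    def accepted_depth(self) -> int:
        """Number of accepted ranks (0 = nothing met the cut-off)."""
        depth = 0
        for b in self.bootstrap:
            if b >= self.cutoff:
                depth += 1
            else:
                break
        return depth

    @property
    def accepted_rank(self) -> str | None:
        if self.accepted_depth == 0:
            return None
        return self.lineage.ranks[self.accepted_depth - 1][0]

    def accepted_lineage(self) -> tuple[str, ...]:
        return self.lineage.taxa[: self.accepted_depth]

    def taxon_at(self, depth: int) -> str:
        """Accepted taxon at rank ``depth`` (0 = domain), or 'unclassified'."""
        if depth < self.accepted_depth:
            return self.lineage.taxa[depth]
        return "unclassified"

    @property
    def domain(self) -> str:
        return self.taxon_at(0)

    @property
    def domain_bootstrap(self) -> float:
        return self.bootstrap[0]

    def to_mothur_string(self) -> str:
        parts = [
            f"{taxon}({int(round(b))})"
            for taxon, b in zip(self.lineage.taxa, self.bootstrap)
        ]
        return ";".join(parts) + ";"


def classify(
    seq: str,
    idx: KmerIndex,
    bootstrap_cutoff: float = 80.0,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
) -> Classification:
    """Classify one sequence against the index.

    Deterministic given (seq, idx, seed).  Raises :class:`TooShortError` if
    the sequence is shorter than k.
    """
    if len(seq) < idx.k:
        raise TooShortError(f"sequence length {len(seq)} < k={idx.k}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    best_words, best_scores, strand = None, None, "+"
    for strand_label, s in (("+", seq), ("-", reverse_complement(seq))):
        words = _kmer_codes(s, idx.k)
        if words.size == 0:
            continue
        scores = idx.log_cond[:, words].sum(axis=1)
        if best_scores is None or scores.max() > best_scores.max():
            best_words, best_scores, strand = words, scores, strand_label
    if best_words is None:
        raise TooShortError("no valid ACGT k-mers in query")
    winner = int(np.argmax(best_scores))  # first max = lexicographic tie-break
    lineage = idx.genera[winner]
    m = best_words.size
    sub = math.ceil(m / 8)
    draws = rng.integers(0, m, size=(n_boot, sub))
    # (G, n_boot, sub) -> summed scores per genus per resample
    boot_scores = idx.log_cond[:, best_words[draws]].sum(axis=2)
    boot_winners = np.argmax(boot_scores, axis=0)
    depth = len(lineage)
    agree = np.zeros(depth, dtype=np.float64)
    winner_taxa = lineage.taxa
    for g in np.unique(boot_winners):
        g_taxa = idx.genera[int(g)].taxa
        count = int((boot_winners == g).sum())
        d = 0
        for a, b in zip(g_taxa, winner_taxa):
            if a != b:
                break
            d += 1
        agree[:d] += count
    bootstrap = list(100.0 * agree / n_boot)
    return Classification(
        lineage=lineage,
        bootstrap=bootstrap,
        cutoff=float(bootstrap_cutoff),
        strand=strand,
        score=float(best_scores[winner]),
    )
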