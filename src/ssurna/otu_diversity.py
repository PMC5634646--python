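"""OTU clustering of window-trimmed reads and alpha-diversity estimation.

Distances are proportions of mismatched template columns between two trimmed
reads (both already aligned to the same window by the reference mapping
step, so no fresh pairwise alignment is needed): a column where exactly one
read has a gap is a mismatch, both-gap and terminal-gap columns are skipped.
Clustering is average-neighbor (UPGMA) hierarchical clustering cut at the
distance threshold, 0.03 for the main analysis, via
``scipy.cluster.hierarchy``; the representative of an OTU is the member with
the smallest summed distance to its co-members (ties to the smallest id).

Richness/diversity estimators (observed OTUs, bias-corrected Chao1, ACE with
rare cut-off 10, Shannon with natural log) come from scikit-bio; estimates
are means over 100 fixed-depth subsamples drawn without replacement
(multivariate hypergeometric), 500 reads for archaea and 5000 for bacteria
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from skbio.diversity.alpha import ace as _ace
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import shannon as _shannon

from .refmap import TrimmedRead
from .seqio import PipelineConfig
from .taxclass import Classification, KmerIndex, classify
from .triage import is_contaminant

__all__ = [
    "DistanceMatrix",
    "OTU",
    "OTUTable",
    "DiversityEstimates",
    "pairwise_distances",
    "cluster_otus",
    "cluster_reads",
    "classify_representatives",
    "alpha_diversity",
]


class WindowMismatchError(ValueError):
    pass


class SubsampleError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    condensed: np.ndarray  # scipy condensed order

    def as_square(self) -> np.ndarray:
        n = len(self.ids)
        sq = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                sq[i, j] = sq[j, i] = self.condensed[k]
                k += 1
        return sq


@dataclass
class OTU:
    members: list[str]
    representative: str
    lineage: Classification | None = None

    @property
    def abundance(self) -> int:
        return len(self.members)


@dataclass
class OTUTable:
    otus: dict[str, OTU] = field(default_factory=dict)
    representative_seqs: dict[str, str] = field(default_factory=dict)

    @property
    def abundances(self) -> list[int]:
        return [self.otus[o].abundance for o in sorted(self.otus)]

    @property
    def total_reads(self) -> int:
        return sum(o.abundance for o in self.otus.values())

    def as_rows(self) -> list[dict[str, object]]:
        rows = []
        for otu_id in sorted(self.otus):
            otu = self.otus[otu_id]
            rows.append(
                {
                    "otu": otu_id,
                    "abundance": otu.abundance,
                    "representative": otu.representative,
                    "lineage": (
                        ";".join(otu.lineage.accepted_lineage()) + ";"
                        if otu.lineage is not None
                        else ""
                    ),
                }
            )
        return rows


def _encode(aligned_seqs: Sequence[str]) -> np.ndarray:
    length = len(aligned_seqs[0])
    if any(len(s) != length for s in aligned_seqs):
        raise WindowMismatchError("trimmed reads come from different windows")
    mat = np.frombuffer(
        "".join(aligned_seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(aligned_seqs), length)
    return mat


def pairwise_distances(trimmed: Sequence[TrimmedRead]) -> DistanceMatrix:
    """Column-wise distances between window-trimmed reads.

    distance = mismatched columns / compared columns; terminal-gap and
    both-gap columns are not compared, one-sided gaps mismatch.
    """
    ids = [t.id for t in trimmed]
    if len(trimmed) < 1:
        return DistanceMatrix(ids=ids, condensed=np.empty(0))
    mat = _encode([t.aligned for t in trimmed])
    gap = ord("-")
    n, L = mat.shape
    is_gap = mat == gap
    # terminal-gap spans per sequence
    first = np.argmax(~is_gap, axis=1)
    last = L - 1 - np.argmax(~is_gap[:, ::-1], axis=1)
    cols = np.arange(L)
    interior = (cols >= first[:, None]) & (cols <= last[:, None])
    condensed = np.empty(n * (n - 1) // 2, dtype=np.float64)
    k = 0
    for i in range(n):
        comp = interior[i] & interior[i + 1 :]
        both_gap = is_gap[i] & is_gap[i + 1 :]
        compared = comp & ~both_gap
        mism = compared & (mat[i] != mat[i + 1 :])
        ncomp = compared.sum(axis=1)
        nmism = mism.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(ncomp > 0, nmism / np.maximum(ncomp, 1), 1.0)
        condensed[k : k + n - i - 1] = d
        k += n - i - 1
    return DistanceMatrix(ids=ids, condensed=condensed)


def cluster_otus(
    dm: DistanceMatrix,
    cutoff: float = 0.03,
    method: str = "average",
    groups: Mapping[str, Sequence[str]] | None = None,
) -> OTUTable:
    """Average-neighbor clustering of a distance matrix cut at ``cutoff``.

    ``groups`` optionally maps each matrix id to the full list of read ids
    it stands for (de-replicated input); OTU members are expanded through
    it.  Deterministic under permutation of the input order (clusters and
    representatives depend only on the distances and ids).
    """
    table = OTUTable()
    n = len(dm.ids)
    if n == 0:
        return table
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(dm.condensed, method=method)
        labels = fcluster(Z, t=cutoff, criterion="distance")
    sq = dm.as_square() if n > 1 else np.zeros((1, 1))
    # canonical OTU order: by smallest member id for permutation invariance
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    ordered = sorted(clusters.values(), key=lambda idxs: min(dm.ids[i] for i in idxs))
    for num, idxs in enumerate(ordered, start=1):
        member_ids = sorted(dm.ids[i] for i in idxs)
        rep_idx = min(
            idxs, key=lambda i: (sq[i, idxs].sum(), dm.ids[i])
        )
        rep = dm.ids[rep_idx]
        if groups is not None:
            expanded: list[str] = []
            for mid in member_ids:
                expanded.extend(groups[mid])
            member_ids = sorted(expanded)
        table.otus[f"OTU{num:04d}"] = OTU(members=member_ids, representative=rep)
    return table


def cluster_reads(
    trimmed: Sequence[TrimmedRead], cutoff: float = 0.03
) -> OTUTable:
    """De-replicate, compute distances, cluster, and expand members back to
    reads.  Representative sequences are attached to the table."""
    if not trimmed:
        return OTUTable()
    uniques: dict[str, list[TrimmedRead]] = {}
    for t in trimmed:
        uniques.setdefault(t.aligned, []).append(t)
    reps: list[TrimmedRead] = []
    groups: dict[str, list[str]] = {}
    for aligned, members in uniques.items():
        members.sort(key=lambda t: t.id)
        lead = members[0]
        reps.append(lead)
        groups[lead.id] = [m.id for m in members]
    reps.sort(key=lambda t: t.id)
    dm = pairwise_distances(reps)
    table = cluster_otus(dm, cutoff=cutoff, groups=groups)
    seq_by_id = {t.id: t.seq for t in reps}
    for otu in table.otus.values():
        table.representative_seqs[otu.representative] = seq_by_id[otu.representative]
    return table


def classify_representatives(
    table: OTUTable,
    idx: KmerIndex,
    cfg: PipelineConfig,
    seed: int = 0,
) -> tuple[OTUTable, dict[str, int]]:
    """Classify OTU representatives (bootstrap cut-off 50% by default) and
    drop chloroplast/mitochondria OTUs; returns the table plus a tally."""
    kept = OTUTable()
    tally = {"kept": 0, "organelle_removed": 0}
    for otu_id in sorted(table.otus):
        otu = table.otus[otu_id]
        seq = table.representative_seqs.get(otu.representative)
        if seq is None:
            raise KeyError(f"no representative sequence for {otu_id}")
        cls = classify(seq, idx, cfg.bootstrap_otu_cutoff, seed=seed)
        if is_contaminant(cls):
            tally["organelle_removed"] += 1
            continue
        tally["kept"] += 1
        kept.otus[otu_id] = OTU(
            members=otu.members, representative=otu.representative, lineage=cls
        )
        kept.representative_seqs[otu.representative] = seq
    return kept, tally


@dataclass
class DiversityEstimates:
    sobs: float
    chao: float
    ace: float
    shannon: float
    subsample_depth: int
    n_resamples: int


def _single_sample_estimates(counts: np.ndarray) -> tuple[float, float, float, float]:
    counts = counts[counts > 0]
    sobs = float(counts.size)
    if counts.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    chao = float(_chao1(counts, bias_corrected=True))
    try:
        ace = float(_ace(counts, rare_threshold=10))
    except (ZeroDivisionError, ValueError):
        ace = sobs  # no rare classes or degenerate input: fall back to sobs
    shannon = float(_shannon(counts, base=np.e))
    return sobs, chao, ace, shannon


def alpha_diversity(
    abundances: Sequence[int] | OTUTable,
    depth: int | None = None,
    n_resamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> DiversityEstimates:
    """Mean sobs / Chao1 / ACE / Shannon over fixed-depth subsamples.

    ``depth=None`` (or the full total) computes the estimators once on the
    full abundance vector.  Subsampling is without replacement and
    deterministic given the seed.
    """
    if isinstance(abundances, OTUTable):
        counts = np.asarray(abundances.abundances, dtype=np.int64)
    else:
        counts = np.asarray(list(abundances), dtype=np.int64)
    total = int(counts.sum())
    if depth is None or depth == total:
        sobs, chao, ace, shannon = _single_sample_estimates(counts)
        return DiversityEstimates(sobs, chao, ace, shannon, total, 1)
    if depth > total:
        raise SubsampleError(f"subsample depth {depth} > total reads {total}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    acc = np.zeros(4)
    for _ in range(n_resamples):
        sub = rng.multivariate_hypergeometric(counts, depth)
        acc += np.array(_single_sample_estimates(np.asarray(sub)))
    sobs, chao, ace, shannon = acc / n_resamples
    return DiversityEstimates(sobs, chao, ace, shannon, depth, n_resamples)
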