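"""Sequence-type cascade: SSU rRNA / LSU rRNA / candidate-mRNA / other.

Every merged read is first classified against the SSU reference partition;
a domain-level bootstrap of at least 80% calls it SSU rRNA.  Failing that,
the read is aligned against the per-domain LSU partitions: the maximum
semi-global alignment score fixes the winning partition, and the read is LSU
if that score reaches the floor (10 by default) and the LSU classifier also
reaches 80% at the domain rank.  Everything else is non-rRNA and is routed
to a pluggable mRNA-annotation hook (the default hook annotates nothing, so
such reads land in "other"); the protein-database search the hook stands for
is intentionally not part of this package.

Alignment scores are computed from an infix (free end gaps on the reference)
edit-distance alignment, scored match +1 / mismatch -1 / gap -2 per column.
The floor is in these arbitrary score units and is exposed in config.

Chloroplast, mitochondrial and human reads are removed after typing and
tallied under "Others", mirroring the contaminant screen of the published
workflow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import edlib

from .seqio import PipelineConfig, SeqRecord, reverse_complement
from .taxclass import Classification, KmerIndex, classify

__all__ = [
    "AlignmentScore",
    "SequenceTypeVerdict",
    "alignment_score",
    "lsu_partition_scores",
    "assign_type",
    "triage_read",
    "remove_contaminants",
    "summarize_types",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

MRNAHook = Callable[[SeqRecord], str | None]


class IncompleteEvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentScore:
    score: float
    reference_partition: str  # e.g. "LSU/Bacteria"

    @property
    def domain(self) -> str:
        return self.reference_partition.split("/")[-1]


@dataclass
class SequenceTypeVerdict:
    read_id: str
    type: str  # SSU | LSU | mRNA_candidate | other
    domain: str  # Archaea | Bacteria | Eukaryota | none
    score: float = float("nan")
    bootstrap: float = float("nan")
    annotation: str | None = None

    def __post_init__(self) -> None:
        if (self.domain != "none") != (self.type in ("SSU", "LSU")):
            raise ValueError("domain must be set exactly for rRNA verdicts")


def _cigar_column_counts(cigar: str) -> tuple[int, int, int]:
    eq = mism = gaps = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            eq += n
        elif op in "XM":
            mism += n
        else:
            gaps += n
    return eq, mism, gaps


def alignment_score(seq: str, reference: str) -> float:
    """Best-strand infix alignment score (match +1, mismatch -1, gap -2,
    free end gaps on the reference)."""
    best = float("-inf")
    for s in (seq, reverse_complement(seq)):
        res = edlib.align(s, reference, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        eq, mism, gaps = _cigar_column_counts(res["cigar"])
        best = max(best, float(eq - mism - 2 * gaps))
    return best


def lsu_partition_scores(
    seq: str, lsu_partitions: Mapping[str, Mapping[str, tuple[str, object]]]
) -> list[AlignmentScore]:
    """Max alignment score of ``seq`` against each LSU domain partition."""
    out = []
    for domain in sorted(lsu_partitions):
        refs = lsu_partitions[domain]
        best = max(
            (alignment_score(seq, ref_seq) for ref_seq, _ in refs.values()),
            default=float("-inf"),
        )
        out.append(AlignmentScore(score=best, reference_partition=f"LSU/{domain}"))
    return out


def assign_type(
    rec: SeqRecord,
    ssu_cls: Classification,
    lsu_scores: Sequence[AlignmentScore] | None,
    lsu_cls: Classification | None,
    cfg: PipelineConfig,
    mrna_hook: MRNAHook | None = None,
) -> SequenceTypeVerdict:
    """Apply the SSU -> LSU -> mRNA-hook -> other cascade to one read."""
    cutoff = cfg.bootstrap_read_cutoff
    if ssu_cls.domain_bootstrap >= cutoff:
        return SequenceTypeVerdict(
            read_id=rec.id,
            type="SSU",
            domain=ssu_cls.lineage.domain,
            score=ssu_cls.score,
            bootstrap=ssu_cls.domain_bootstrap,
        )
    if lsu_scores is None:
        raise IncompleteEvidenceError(
            f"read {rec.id!r}: SSU classification below cut-off and no LSU scores"
        )
    best = max(lsu_scores, key=lambda a: (a.score, a.reference_partition))
    if (
        best.score >= cfg.lsu_score_floor
        and lsu_cls is not None
        and lsu_cls.domain_bootstrap >= cutoff
    ):
        return SequenceTypeVerdict(
            read_id=rec.id,
            type="LSU",
            domain=best.domain,
            score=best.score,
            bootstrap=lsu_cls.domain_bootstrap,
        )
    annotation = mrna_hook(rec) if mrna_hook is not None else None
    if annotation is not None:
        return SequenceTypeVerdict(
            rec.id, "mRNA_candidate", "none", annotation=annotation
        )
    return SequenceTypeVerdict(rec.id, "other", "none")


def triage_read(
    rec: SeqRecord,
    ssu_idx: KmerIndex,
    lsu_idx: KmerIndex,
    lsu_partitions: Mapping[str, Mapping[str, tuple[str, object]]],
    cfg: PipelineConfig,
    seed: int = 0,
    mrna_hook: MRNAHook | None = None,
) -> tuple[SequenceTypeVerdict, Classification]:
    """Classify one read against SSU, lazily against LSU, and type it.

    Returns the verdict plus the classification matching the verdict's
    molecule (SSU classification for SSU/non-rRNA reads, LSU for LSU reads).
    """
    ssu_cls = classify(rec.seq, ssu_idx, cfg.bootstrap_read_cutoff, seed=seed)
    if ssu_cls.domain_bootstrap >= cfg.bootstrap_read_cutoff:
        verdict = assign_type(rec, ssu_cls, None, None, cfg, mrna_hook)
        return verdict, ssu_cls
    lsu_scores = lsu_partition_scores(rec.seq, lsu_partitions)
    lsu_cls = classify(rec.seq, lsu_idx, cfg.bootstrap_read_cutoff, seed=seed)
    verdict = assign_type(rec, ssu_cls, lsu_scores, lsu_cls, cfg, mrna_hook)
    cls = lsu_cls if verdict.type == "LSU" else ssu_cls
    return verdict, cls


_CONTAMINANT_TAXA = {"chloroplast", "mitochondria", "mitochondrion"}
_HUMAN_TAXA = {"homo", "homo sapiens", "human"}


def is_contaminant(cls: Classification) -> bool:
    taxa = [t.lower() for t in cls.accepted_lineage()]
    if any(t in _CONTAMINANT_TAXA for t in taxa):
        return True
    return any(t in _HUMAN_TAXA for t in taxa)


def remove_contaminants(
    items: Iterable[tuple[SequenceTypeVerdict, Classification]],
) -> tuple[list[tuple[SequenceTypeVerdict, Classification]], dict[str, int]]:
    """Drop rRNA reads whose lineage is chloroplast/mitochondria/human.

    Dropped reads are re-typed as "other" in the returned tally, matching
    the published accounting where they fall under "Others".
    """
    kept: list[tuple[SequenceTypeVerdict, Classification]] = []
    tally = {"kept": 0, "contaminant": 0}
    for verdict, cls in items:
        if verdict.type in ("SSU", "LSU") and is_contaminant(cls):
            tally["contaminant"] += 1
        else:
            tally["kept"] += 1
            kept.append((verdict, cls))
    return kept, tally


def summarize_types(
    verdicts: Iterable[SequenceTypeVerdict],
) -> list[dict[str, object]]:
    """Count and percentage table by sequence type and (for rRNA) domain.

    Rows follow the All / LSU / SSU / mRNA / Others block layout; domain
    percentages are within their rRNA type.
    """
    verdicts = list(verdicts)
    total = len(verdicts)
    by_type: dict[str, int] = {"SSU": 0, "LSU": 0, "mRNA_candidate": 0, "other": 0}
    by_domain: dict[tuple[str, str], int] = {}
    for v in verdicts:
        by_type[v.type] = by_type.get(v.type, 0) + 1
        if v.type in ("SSU", "LSU"):
            key = (v.type, v.domain)
            by_domain[key] = by_domain.get(key, 0) + 1
    rows: list[dict[str, object]] = [
        {"block": "All", "group": "", "count": total, "percent": 100.0 if total else 0.0}
    ]
    for block, label in (("LSU", "LSU rRNA"), ("SSU", "SSU rRNA")):
        n = by_type.get(block, 0)
        rows.append(
            {
                "block": label,
                "group": "",
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
            }
        )
        for domain in ("Archaea", "Bacteria", "Eukaryota"):
            dn = by_domain.get((block, domain), 0)
            rows.append(
                {
                    "block": label,
                    "group": domain,
                    "count": dn,
                    "percent": 100.0 * dn / n if n else 0.0,
                }
            )
    for block, label in (("mRNA_candidate", "mRNA"), ("other", "Others")):
        n = by_type.get(block, 0)
        rows.append(
            {
                "block": label,
                "group": "",
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
            }
        )
    return rows
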