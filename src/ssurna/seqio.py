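"""Readers and writers for the formats the pipeline touches, plus run configuration.

Sequence data moves through the pipeline as lightweight :class:`SeqRecord`
objects (id, DNA string, optional phred qualities).  RNA input is normalised
to the DNA alphabet at ingest (U -> T) so every downstream stage reasons over
{A, C, G, T, N, IUPAC}.  Only phred+33 FASTQ is accepted: the library this
pipeline models is MiSeq 2x300 chemistry, which has been phred+33 since
Casava 1.8, and silently mis-decoding phred+64 would shift every quality by
31.
"""

from __future__ import annotations

import dataclasses
import io
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "SeqRecord",
    "TaxonomyLineage",
    "PipelineConfig",
    "MalformedRecordError",
    "PairingError",
    "MissingLineageError",
    "ReferenceDB",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_reference",
    "write_table",
    "reverse_complement",
]

# Canonical rank names used when a lineage is deep enough; deeper levels keep
# positional names ("rank7", ...).
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


class MalformedRecordError(ValueError):
    """A FASTQ/FASTA record violates the format (e.g. seq/qual length mismatch)."""


class PairingError(ValueError):
    """R1/R2 mates could not be matched by id."""


class MissingLineageError(KeyError):
    """Reference FASTA ids without a taxonomy entry."""

    def __init__(self, ids: Sequence[str]):
        self.ids = list(ids)
        super().__init__(f"reference ids missing from taxonomy: {', '.join(self.ids)}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """One sequence: identifier, nucleotides, optional per-base phred scores."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise MalformedRecordError("record with empty id")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise MalformedRecordError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        qual = None if self.qual is None else self.qual[::-1]
        return SeqRecord(self.id, reverse_complement(self.seq), qual)


@dataclass(frozen=True)
class TaxonomyLineage:
    """Root-to-leaf taxon names (domain first), e.g. Bacteria;Firmicutes;...;Bacillus."""

    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("empty lineage")
        for i, t in enumerate(self.taxa):
            if not t:
                raise ValueError(f"empty taxon name at rank index {i}")

    @classmethod
    def from_string(cls, s: str) -> "TaxonomyLineage":
        parts = s.strip().rstrip(";").split(";")
        return cls(tuple(p.strip() for p in parts))

    @property
    def ranks(self) -> list[tuple[str, str]]:
        names = [
            RANK_NAMES[i] if i < len(RANK_NAMES) else f"rank{i + 1}"
            for i in range(len(self.taxa))
        ]
        return list(zip(names, self.taxa))

    @property
    def domain(self) -> str:
        return self.taxa[0]

    def at_rank(self, depth: int) -> tuple[str, ...]:
        """Lineage truncated to ``depth + 1`` levels (depth 0 = domain)."""
        return self.taxa[: depth + 1]

    def __len__(self) -> int:
        return len(self.taxa)

    def __str__(self) -> str:
        return ";".join(self.taxa) + ";"


@dataclass
class PipelineConfig:
    """Tunable constants of the analysis pipeline.

    Defaults are the published operating point: Q20 quality floor,
    homopolymer limit 8, 250 bp length floor for read classification,
    80%/50% bootstrap cut-offs for reads/OTU representatives, LSU alignment
    score floor 10, the 8F-V1-V2 window at *E. coli* positions 8-242, OTU
    distance 0.03, and diversity subsampling depths of 500 (archaea) /
    5000 (bacteria).
    """

    quality_floor: int = 20
    max_homopolymer: int = 8
    min_length: int = 250
    bootstrap_read_cutoff: int = 80
    bootstrap_otu_cutoff: int = 50
    lsu_score_floor: float = 10.0
    region_start: int = 8
    region_end: int = 242
    otu_distance: float = 0.03
    subsample_archaea: int = 500
    subsample_bacteria: int = 5000
    rng_seed: int = 1
    # merge parameters (the joiner's documented defaults; not stated by the
    # protocol, exposed here)
    merge_min_overlap: int = 10
    merge_max_mismatch_frac: float = 0.08
    min_identity: float = 0.60

    def __post_init__(self) -> None:
        if not (0.0 < self.otu_distance < 1.0):
            raise ValueError("otu_distance must be in (0, 1)")
        if not (1 <= self.region_start < self.region_end):
            raise ValueError("need 1 <= region_start < region_end")
        if not (0 <= self.bootstrap_read_cutoff <= 100):
            raise ValueError("bootstrap_read_cutoff must be a percentage")
        if not (0 <= self.bootstrap_otu_cutoff <= 100):
            raise ValueError("bootstrap_otu_cutoff must be a percentage")
        if self.quality_floor < 0 or self.max_homopolymer < 1:
            raise ValueError("bad quality_floor/max_homopolymer")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file."""
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kind = types[key]
            kwargs[key] = float(value) if "float" in str(kind) else int(value)
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

_PHRED_OFFSET = 33
_MAX_PHRED = 60  # phred+33 MiSeq tops out around Q41; above 60 smells of phred+64


def _decode_qual(line: str, rec_id: str) -> list[int]:
    qual = [ord(c) - _PHRED_OFFSET for c in line]
    for q in qual:
        if q < 0:
            raise MalformedRecordError(
                f"record {rec_id!r}: quality character below '!' (not phred+33)"
            )
        if q > _MAX_PHRED:
            raise MalformedRecordError(
                f"record {rec_id!r}: quality {q} > {_MAX_PHRED}; "
                "input looks phred+64-encoded, only phred+33 is supported"
            )
    return qual


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream phred+33 FASTQ records in file order.

    Raises :class:`MalformedRecordError` on truncated records, seq/qual
    length mismatches, or quality strings outside the phred+33 range.
    """
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise MalformedRecordError(f"expected '@' header, got {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual_line = fh.readline().rstrip("\n")
            if not plus.startswith("+") or not qual_line and seq:
                raise MalformedRecordError(f"truncated FASTQ record at {header!r}")
            rec_id = header[1:].split()[0]
            seq = seq.upper().replace("U", "T")
            if len(qual_line) != len(seq):
                raise MalformedRecordError(
                    f"record {rec_id!r}: sequence length {len(seq)} != "
                    f"quality length {len(qual_line)}"
                )
            yield SeqRecord(rec_id, seq, _decode_qual(qual_line, rec_id))


def _pair_key(rec_id: str) -> str:
    # Illumina pre-1.8 "name/1" "name/2"; Casava 1.8+ mates share the id.
    if len(rec_id) > 2 and rec_id[-2] == "/" and rec_id[-1] in "12":
        return rec_id[:-2]
    return rec_id


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[SeqRecord, SeqRecord]]:
    """Stream matched (R1, R2) pairs; mates are matched positionally and their
    ids checked (``/1``-``/2`` suffixes or identical Casava-1.8 ids)."""
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise PairingError(f"R1 record {r1.id!r} has no R2 mate")
        if _pair_key(r1.id) != _pair_key(r2.id):
            raise PairingError(f"mate ids do not match: {r1.id!r} vs {r2.id!r}")
        yield r1, r2
    leftover = next(it2, None)
    if leftover is not None:
        raise PairingError(f"R2 record {leftover.id!r} has no R1 mate")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise MalformedRecordError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + _PHRED_OFFSET) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    rec_id, chunks = None, []
    with open(path) as fh:
        for line in itertools.chain(fh, [">"]):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rec_id is not None:
                    seq = "".join(chunks).upper().replace("U", "T")
                    yield SeqRecord(rec_id, seq)
                rec_id, chunks = line[1:].split()[0] if line[1:] else None, []
            elif rec_id is not None:
                chunks.append(line.strip())


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Reference database (FASTA + mothur-style taxonomy TSV)
# ---------------------------------------------------------------------------


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLineage]:
    lineages: dict[str, TaxonomyLineage] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec_id, lineage_str = line.split("\t", 1)
        except ValueError as exc:
            raise MalformedRecordError(
                f"{path}:{ln}: expected 'id<TAB>lineage'"
            ) from exc
        try:
            lineages[rec_id.strip()] = TaxonomyLineage.from_string(lineage_str)
        except ValueError as exc:
            raise MalformedRecordError(f"{path}:{ln}: {exc}") from exc
    return lineages


def read_reference(
    fasta: str | Path, taxonomy: str | Path
) -> dict[str, tuple[str, TaxonomyLineage]]:
    """Load a reference set: id -> (DNA sequence, lineage).

    Every FASTA id must appear in the taxonomy file; U is normalised to T.
    """
    lineages = read_taxonomy(taxonomy)
    out: dict[str, tuple[str, TaxonomyLineage]] = {}
    missing = []
    for rec in read_fasta(fasta):
        if rec.id not in lineages:
            missing.append(rec.id)
        else:
            out[rec.id] = (rec.seq, lineages[rec.id])
    if missing:
        raise MissingLineageError(missing)
    return out


@dataclass
class ReferenceDB:
    """Reference sequences partitioned by molecule (SSU/LSU) and, for LSU,
    by domain.

    ``ssu`` maps id -> (sequence, lineage); ``lsu`` maps domain ->
    {id -> (sequence, lineage)}.  ``template_id`` names the SSU record whose
    ungapped coordinates define the *E. coli*-style numbering axis.
    """

    ssu: dict[str, tuple[str, TaxonomyLineage]]
    lsu: dict[str, dict[str, tuple[str, TaxonomyLineage]]]
    template_id: str

    @property
    def template(self) -> str:
        return self.ssu[self.template_id][0]

    @property
    def lsu_all(self) -> dict[str, tuple[str, TaxonomyLineage]]:
        merged: dict[str, tuple[str, TaxonomyLineage]] = {}
        for refs in self.lsu.values():
            merged.update(refs)
        return merged

    def molecule_of(self, ref_id: str) -> str:
        if ref_id in self.ssu:
            return "SSU"
        if ref_id in self.lsu_all:
            return "LSU"
        raise KeyError(ref_id)

    def sequence_of(self, ref_id: str) -> str:
        if ref_id in self.ssu:
            return self.ssu[ref_id][0]
        return self.lsu_all[ref_id][0]

    def lineage_of(self, ref_id: str) -> TaxonomyLineage:
        if ref_id in self.ssu:
            return self.ssu[ref_id][1]
        return self.lsu_all[ref_id][1]

    @classmethod
    def from_files(
        cls,
        ssu_fasta: str | Path,
        ssu_taxonomy: str | Path,
        lsu_sources: Mapping[str, tuple[str | Path, str | Path]],
        template_id: str,
    ) -> "ReferenceDB":
        """Load from FASTA + taxonomy TSV files; ``lsu_sources`` maps domain
        name -> (fasta, taxonomy)."""
        ssu = read_reference(ssu_fasta, ssu_taxonomy)
        if template_id not in ssu:
            raise KeyError(f"template id {template_id!r} not in SSU reference")
        lsu = {
            domain: read_reference(fasta, tax)
            for domain, (fasta, tax) in lsu_sources.items()
        }
        return cls(ssu=ssu, lsu=lsu, template_id=template_id)


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------


def _format_cell(value: object) -> str:
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV with a header row, in input order.

    Floats are written with four decimal places so proportion tables are
    stable across runs.  ``columns`` supplies the header when ``rows`` is
    empty (a header-only file is still written).
    """
    header = list(columns) if columns is not None else (list(rows[0]) if rows else [])
    buf = io.StringIO()
    buf.write("\t".join(header) + "\n")
    for row in rows:
        if list(row.keys()) != header:
            raise ValueError("rows do not share a schema")
        buf.write("\t".join(_format_cell(v) for v in row.values()) + "\n")
    Path(path).write_text(buf.getvalue())
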