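"""Generative simulator of the 5'-adaptor-ligation library chemistry.

The simulator produces paired 2x300 FASTQ plus a ground-truth table from a
mock-community specification, emulating each step of the wet protocol:

* 5'-anchored inserts — the adaptor ligates to the RNA 5' terminus, so SSU
  inserts start at molecule position 1 with high probability (default 0.8,
  the remainder modelling degraded molecules); LSU molecules additionally
  break mid-molecule (default half the inserts start near the middle),
  which is how SSU-sized LSU fragments end up in the library;
* random-hexamer priming — the insert 3' end follows a mixture of Gaussian
  length peaks over a uniform background (per-member peak overrides model
  the non-random priming that gives each isolate its own length signature);
* PCR — 15 cycles with a log-linear efficiency bias in insert length and
  GC deviation from 0.5, realised as rejection sampling; the zero-bias
  default is the clean instrument, :meth:`LibraryModel.with_pcr_bias` is
  calibrated so that an AT/GC-extreme, short-peaked member distorts by the
  published-order two-to-threefold;
* size selection of the 400-600 bp PCR products, expressed on insert
  coordinates as a soft 205-465 bp window after the ~180 bp of adaptor/tag
  sequence (gel cuts are fuzzy at the edges);
* sequencing — 2x300 paired reads with uniform substitution errors and a
  logistic phred profile decaying from ~Q38 to ~Q22.

Everything is synthetic and desk-scale: :func:`build_toy_reference`
deterministically fabricates a five-isolate reference set (three bacteria,
one archaeon, one fungal 18S) mirroring the mock design, with the archaeal
and low-GC bacterial members hitting the 68% / 34% 16S GC contents that
drive the GC-bias story, plus per-domain LSU partitions and a chloroplast
contaminant, all on an *E. coli*-style coordinate template.  No network
access, no real accessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .seqio import ReferenceDB, SeqRecord, TaxonomyLineage

__all__ = [
    "MockSpec",
    "MockMember",
    "LibraryModel",
    "TruthRecord",
    "PlantedVariant",
    "build_toy_reference",
    "simulate_library",
    "plant_primer_variants",
    "mock2_spec",
    "unequal_mock_spec",
    "analytic_region_fraction",
    "TEMPLATE_LENGTH",
]

TEMPLATE_LENGTH = 1542
LSU_LENGTH = 2400

# E. coli-style hypervariable windows (1-based, inclusive) on the template.
VARIABLE_REGIONS = [
    (69, 99), (137, 242), (433, 497), (576, 682), (822, 879),
    (986, 1043), (1117, 1173), (1243, 1294), (1435, 1465),
]

PRIMER_WINDOW = (8, 27)

_BASES = "ACGT"


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Toy reference generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))


def _break_homopolymers(seq: list[str], rng: np.random.Generator, max_run: int = 6) -> None:
    run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > max_run:
            choices = [b for b in _BASES if b != seq[i]]
            seq[i] = choices[int(rng.integers(len(choices)))]
            run = 1


def _variable_mask(length: int) -> np.ndarray:
    mask = np.zeros(length + 1, dtype=bool)  # 1-based
    for lo, hi in VARIABLE_REGIONS:
        if lo <= length:
            mask[lo : min(hi, length) + 1] = True
    return mask


def _mutate(
    template: str,
    rng: np.random.Generator,
    p_conserved: float,
    p_variable: float,
    gc_bias: float = 0.5,
    protect: tuple[int, int] | None = PRIMER_WINDOW,
) -> list[str]:
    mask = _variable_mask(len(template))
    out = list(template)
    for pos in range(1, len(template) + 1):
        if protect is not None and protect[0] <= pos <= protect[1]:
            continue
        rate = p_variable if mask[pos] else p_conserved
        if rng.random() < rate:
            old = out[pos - 1]
            weights = np.array(
                [1 - gc_bias, gc_bias, gc_bias, 1 - gc_bias], dtype=np.float64
            )
            weights[_BASES.index(old)] = 0.0
            weights /= weights.sum()
            out[pos - 1] = _BASES[int(rng.choice(4, p=weights))]
    return out


def _gc_fraction(seq: Sequence[str]) -> float:
    gc = sum(1 for c in seq if c in "GC")
    return gc / len(seq)


def _adjust_gc(
    seq: list[str],
    target_gc: float,
    rng: np.random.Generator,
    protect: tuple[int, int] | None = PRIMER_WINDOW,
) -> None:
    """Flip AT<->GC at random unprotected sites until the overall GC fraction
    rounds to the target at integer-percent precision."""
    positions = [
        i
        for i in range(len(seq))
        if protect is None or not (protect[0] <= i + 1 <= protect[1])
    ]
    rng.shuffle(positions)
    tol = 0.0015
    idx = 0

    def run_at(i: int) -> int:
        b = seq[i]
        run = 1
        j = i - 1
        while j >= 0 and seq[j] == b:
            run += 1
            j -= 1
        j = i + 1
        while j < len(seq) and seq[j] == b:
            run += 1
            j += 1
        return run

    while abs(_gc_fraction(seq) - target_gc) > tol and idx < len(positions):
        i = positions[idx]
        idx += 1
        need_gc = _gc_fraction(seq) < target_gc
        old = seq[i]
        if need_gc and old in "AT":
            seq[i] = "G" if rng.random() < 0.5 else "C"
        elif not need_gc and old in "GC":
            seq[i] = "A" if rng.random() < 0.5 else "T"
        else:
            continue
        if run_at(i) > 6:  # never re-introduce long homopolymers
            seq[i] = old


_SSU_LINEAGES = {
    "Eco_16S_syn": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacteriales;Enterobacteriaceae;Escherichia;",
    "Bsu_16S_syn": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;",
    "Cca_16S_syn": "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Chryseobacterium;",
    "Hha_16S_syn": "Archaea;Euryarchaeota;Halobacteria;Halobacteriales;Halobacteriaceae;Halobacterium;",
    "Ppa_18S_syn": "Eukaryota;Opisthokonta;Nucletmycea;Fungi;Ascomycota;Pichia;",
    "Chl_16S_syn": "Bacteria;Cyanobacteria;Chloroplast;Chloroplast;Chloroplast;Chloroplast;",
}

_LSU_LINEAGES = {
    "Eco_23S_syn": ("Bacteria", "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacteriales;Enterobacteriaceae;Escherichia;"),
    "Bsu_23S_syn": ("Bacteria", "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;"),
    "Cca_23S_syn": ("Bacteria", "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Chryseobacterium;"),
    "Hha_23S_syn": ("Archaea", "Archaea;Euryarchaeota;Halobacteria;Halobacteriales;Halobacteriaceae;Halobacterium;"),
    "Ppa_25S_syn": ("Eukaryota", "Eukaryota;Opisthokonta;Nucletmycea;Fungi;Ascomycota;Pichia;"),
}

# GC targets mirror the published 16S GC contents of the extreme members.
_GC_TARGETS = {"Hha_16S_syn": 0.68, "Cca_16S_syn": 0.34}

# Divergence bands (conserved, variable substitution rates) per member.
_DIVERGENCE = {
    "Bsu_16S_syn": (0.02, 0.30, 0.50),
    "Cca_16S_syn": (0.03, 0.35, 0.25),
    "Hha_16S_syn": (0.06, 0.40, 0.75),
    "Chl_16S_syn": (0.03, 0.25, 0.50),
}


def build_toy_reference(
    seed: int = 0, include_contaminants: bool = True
) -> ReferenceDB:
    """Deterministically fabricate the five-isolate synthetic reference set.

    Returns a :class:`~ssurna.seqio.ReferenceDB` whose template is the
    *Escherichia* 16S analogue (1542 bp, primer window at positions 8-27 set
    to an exact 8F expansion).  All records are synthetic stand-ins, not the
    deposited accessions.
    """
    rng = np.random.default_rng(seed)
    template = list(_random_seq(rng, TEMPLATE_LENGTH, gc=0.54))
    lo, hi = PRIMER_WINDOW
    template[lo - 1 : hi] = list("AGAGTTTGATCCTGGCTCAG")
    _break_homopolymers(template, rng)
    template_str = "".join(template)

    ssu: dict[str, tuple[str, TaxonomyLineage]] = {
        "Eco_16S_syn": (
            template_str,
            TaxonomyLineage.from_string(_SSU_LINEAGES["Eco_16S_syn"]),
        )
    }
    for ref_id, (p_cons, p_var, gc_bias) in _DIVERGENCE.items():
        if ref_id == "Chl_16S_syn" and not include_contaminants:
            continue
        seq = _mutate(template_str, rng, p_cons, p_var, gc_bias)
        if ref_id == "Bsu_16S_syn":
            # a different legal expansion of the degenerate positions
            seq[lo - 1 : hi] = list("AGAGTTTGATTATGGCTCAG")
        _break_homopolymers(seq, rng)
        if ref_id in _GC_TARGETS:
            _adjust_gc(seq, _GC_TARGETS[ref_id], rng)
        ssu[ref_id] = (
            "".join(seq),
            TaxonomyLineage.from_string(_SSU_LINEAGES[ref_id]),
        )
    # fungal 18S analogue: heavier divergence plus expansion segments
    seq18 = _mutate(template_str, rng, 0.12, 0.50, 0.5, protect=None)
    insert_points = sorted(rng.choice(TEMPLATE_LENGTH, size=4, replace=False))
    for offset, point in enumerate(insert_points):
        extra = list(_random_seq(rng, 52, gc=0.45))
        seq18[point + offset * 52 : point + offset * 52] = extra
    _break_homopolymers(seq18, rng)
    ssu["Ppa_18S_syn"] = (
        "".join(seq18),
        TaxonomyLineage.from_string(_SSU_LINEAGES["Ppa_18S_syn"]),
    )

    # Decoy taxa: a classification database is always far larger than the
    # mock membership, and a genus-starved index lets chance k-mer hits pile
    # up confidence at the domain rank.  Sixteen extra synthetic genera,
    # balanced across the three domains, restore realistic bootstrap scatter
    # for non-SSU queries.
    decoy_base = {"Bacteria": template_str, "Archaea": ssu["Hha_16S_syn"][0],
                  "Eukaryota": "".join(seq18)}
    decoy_plan = [("Bacteria", 6), ("Archaea", 5), ("Eukaryota", 5)]
    for domain, n_decoys in decoy_plan:
        for i in range(1, n_decoys + 1):
            seq_list = list(
                _mutate_uniform(decoy_base[domain], rng, 0.30 + 0.04 * (i % 3))
            )
            seq_list[lo - 1 : hi] = list(decoy_base[domain][lo - 1 : hi])
            _break_homopolymers(seq_list, rng)
            short = domain[:4]
            lineage = (
                f"{domain};{short}Phylum{i}syn;{short}Class{i}syn;"
                f"{short}Order{i}syn;{short}Family{i}syn;{short}Genus{i}syn;"
            )
            ssu[f"{short}_decoy{i}_syn"] = (
                "".join(seq_list),
                TaxonomyLineage.from_string(lineage),
            )

    bact_lsu_backbone = _random_seq(rng, LSU_LENGTH, gc=0.52)
    lsu: dict[str, dict[str, tuple[str, TaxonomyLineage]]] = {
        "Archaea": {},
        "Bacteria": {},
        "Eukaryota": {},
    }
    for ref_id, (domain, lineage_str) in _LSU_LINEAGES.items():
        if domain == "Bacteria":
            seq = _mutate_uniform(bact_lsu_backbone, rng, 0.0 if ref_id == "Eco_23S_syn" else 0.15)
        elif domain == "Archaea":
            seq = _random_seq(rng, LSU_LENGTH, gc=0.60)
        else:
            seq = _random_seq(rng, LSU_LENGTH + 300, gc=0.46)
        seq_list = list(seq)
        _break_homopolymers(seq_list, rng)
        lsu[domain][ref_id] = (
            "".join(seq_list),
            TaxonomyLineage.from_string(lineage_str),
        )
    return ReferenceDB(ssu=ssu, lsu=lsu, template_id="Eco_16S_syn")


def _mutate_uniform(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Mock specification and library model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockMember:
    ref_id: str
    molecule: str  # "SSU" | "LSU"
    proportion: float


@dataclass
class MockSpec:
    members: list[MockMember]
    total_reads: int
    seed: int = 0

    def __post_init__(self) -> None:
        s = sum(m.proportion for m in self.members)
        if abs(s - 1.0) > 1e-9:
            raise ConfigurationError(f"member proportions sum to {s}, not 1")


def mock2_spec(
    total_reads: int = 20_000, seed: int = 0, lsu_fraction: float = 0.0
) -> MockSpec:
    """The equal-abundance five-member mock (the Mock-2 analogue), optionally
    diluted with LSU molecules of the same five isolates."""
    ssu_ids = ["Eco_16S_syn", "Bsu_16S_syn", "Cca_16S_syn", "Hha_16S_syn", "Ppa_18S_syn"]
    lsu_ids = ["Eco_23S_syn", "Bsu_23S_syn", "Cca_23S_syn", "Hha_23S_syn", "Ppa_25S_syn"]
    members = [
        MockMember(r, "SSU", (1 - lsu_fraction) / len(ssu_ids)) for r in ssu_ids
    ]
    if lsu_fraction > 0:
        members += [
            MockMember(r, "LSU", lsu_fraction / len(lsu_ids)) for r in lsu_ids
        ]
    return MockSpec(members=members, total_reads=total_reads, seed=seed)


def isolate_length_peaks() -> dict[str, list[tuple[float, float, float]]]:
    """Per-isolate insert-length signatures for the extreme members: the
    AT-rich bacterium peaks at 219 and 355 bp, the GC-rich archaeon at 294
    and 449 bp (non-random hexamer priming gives each isolate its own
    peaks); the remaining 5% of draws fall on the uniform background."""
    return {
        "Cca_16S_syn": [(219.0, 8.0, 0.50), (355.0, 8.0, 0.45)],
        "Hha_16S_syn": [(294.0, 8.0, 0.50), (449.0, 8.0, 0.45)],
    }


def unequal_mock_spec(total_reads: int = 20_000, seed: int = 0) -> MockSpec:
    """A mock with member abundances spanning tenfold (0.05-0.50), the
    regime over which quantitative recovery is evaluated; equal-abundance
    mocks leave a composition regression degenerate."""
    ssu_ids = ["Eco_16S_syn", "Bsu_16S_syn", "Cca_16S_syn", "Hha_16S_syn", "Ppa_18S_syn"]
    props = [0.50, 0.25, 0.125, 0.075, 0.05]
    members = [MockMember(r, "SSU", p) for r, p in zip(ssu_ids, props)]
    return MockSpec(members=members, total_reads=total_reads, seed=seed)


@dataclass
class LibraryModel:
    """Parameters of the library-chemistry model; defaults are the clean
    (bias-free) instrument."""

    ssu_anchor_prob: float = 0.8
    lsu_anchor_prob: float = 0.5
    lsu_mid_frac_mean: float = 0.5
    lsu_mid_frac_sd: float = 0.10
    length_peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(300.0, 30.0, 0.6)]
    )  # (mean, sd, weight); remaining weight is the uniform background
    member_peaks: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=dict
    )
    pcr_cycles: int = 15
    pcr_length_coef: float = 0.0
    pcr_gc_coef: float = 0.0
    pcr_length_ref: float = 300.0
    pcr_length_scale: float = 100.0
    size_selection: tuple[int, int] = (205, 465)
    read_length: int = 300
    substitution_rate: float = 0.001
    qual_high: float = 38.0
    qual_low: float = 22.0

    def __post_init__(self) -> None:
        if self.size_selection[0] >= self.size_selection[1]:
            raise ConfigurationError("size_selection min must be < max")
        w = sum(w for _, _, w in self.length_peaks)
        if w > 1.0 + 1e-9:
            raise ConfigurationError("length peak weights exceed 1")
        for p in (self.ssu_anchor_prob, self.lsu_anchor_prob, self.substitution_rate):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("probabilities must be in [0, 1]")

    @classmethod
    def with_pcr_bias(cls, **overrides) -> "LibraryModel":
        """Bias preset: shorter inserts amplify better and GC-extreme inserts
        amplify worse.  Coefficients are calibrated (analytically, from the
        resampling weights) so that with the isolate length signatures of
        :func:`isolate_length_peaks` the short-peaked AT-rich member
        overestimates about twofold and the GC-rich member underestimates
        two-to-threefold over 15 cycles."""
        params = dict(pcr_length_coef=0.18, pcr_gc_coef=0.2)
        params.update(overrides)
        return cls(**params)

    def pcr_weight(self, insert_len: int, gc: float) -> float:
        if self.pcr_length_coef == 0.0 and self.pcr_gc_coef == 0.0:
            return 1.0
        exponent = -self.pcr_cycles * (
            self.pcr_length_coef
            * (insert_len - self.pcr_length_ref)
            / self.pcr_length_scale
            + self.pcr_gc_coef * abs(gc - 0.5)
        )
        return math.exp(exponent)

    @property
    def max_pcr_weight(self) -> float:
        return self.pcr_weight(self.size_selection[0], 0.5)


@dataclass
class TruthRecord:
    read_id: str
    source: str
    molecule: str
    insert_start: int  # 1-based on the source molecule
    insert_end: int
    planted_variant: bool = False

    def as_row(self) -> dict[str, object]:
        return {
            "read_id": self.read_id,
            "source": self.source,
            "molecule": self.molecule,
            "insert_start": self.insert_start,
            "insert_end": self.insert_end,
            "planted_variant": int(self.planted_variant),
        }


@dataclass(frozen=True)
class PlantedVariant:
    genus: str
    ref_id: str
    variant_seq: str
    fraction: float
    edit_position: int


def plant_primer_variants(
    refdb: ReferenceDB,
    genus: str,
    edit: tuple[int, str],
    fraction: float,
) -> tuple[ReferenceDB, PlantedVariant]:
    """Create a primer-window variant of a genus' SSU reference.

    ``edit`` is (template position inside the 8F window, replacement base).
    The returned :class:`PlantedVariant` is handed to
    :func:`simulate_library`, which draws the stated fraction of that genus'
    reads from the variant sequence and flags them in the truth table.  The
    reference database itself is unchanged (the variant models an unobserved
    allele, not a new reference taxon).
    """
    pos, base = edit
    if not (PRIMER_WINDOW[0] <= pos <= PRIMER_WINDOW[1]):
        raise ConfigurationError(
            f"edit position {pos} outside the primer window {PRIMER_WINDOW}"
        )
    if base not in _BASES:
        raise ConfigurationError(f"replacement base {base!r} not in ACGT")
    if not (0.0 <= fraction <= 1.0):
        raise ConfigurationError("fraction must be in [0, 1]")
    candidates = [
        rid
        for rid, (_, lineage) in refdb.ssu.items()
        if lineage.taxa[-1] == genus
    ]
    if not candidates:
        raise ConfigurationError(f"no SSU reference for genus {genus!r}")
    ref_id = sorted(candidates)[0]
    seq = refdb.ssu[ref_id][0]
    if seq[pos - 1] == base:
        raise ConfigurationError(
            f"reference already carries {base!r} at position {pos}"
        )
    variant_seq = seq[: pos - 1] + base + seq[pos:]
    return refdb, PlantedVariant(
        genus=genus,
        ref_id=ref_id,
        variant_seq=variant_seq,
        fraction=fraction,
        edit_position=pos,
    )


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------


def _draw_insert_length(
    model: LibraryModel, member_id: str, rng: np.random.Generator
) -> int:
    peaks = model.member_peaks.get(member_id, model.length_peaks)
    total_w = sum(w for _, _, w in peaks)
    u = rng.random()
    acc = 0.0
    for mean, sd, w in peaks:
        acc += w
        if u < acc:
            return int(round(rng.normal(mean, sd)))
    lo, hi = model.size_selection
    return int(rng.integers(lo, hi + 1))


def _draw_start(
    model: LibraryModel, molecule: str, length: int, rng: np.random.Generator
) -> int:
    lo = model.size_selection[0]
    max_start = max(2, length - lo + 1)
    anchor = model.ssu_anchor_prob if molecule == "SSU" else model.lsu_anchor_prob
    if rng.random() < anchor:
        return 1
    if molecule == "SSU":
        return int(rng.integers(2, max_start + 1))
    mid = rng.normal(length * model.lsu_mid_frac_mean, length * model.lsu_mid_frac_sd)
    return int(np.clip(round(mid), 2, max_start))


def _quality_profile(
    n: int, model: LibraryModel, rng: np.random.Generator
) -> list[int]:
    i = np.arange(n)
    x0, s = 0.7 * model.read_length, 0.08 * model.read_length
    mean = model.qual_low + (model.qual_high - model.qual_low) / (
        1.0 + np.exp((i - x0) / s)
    )
    qual = np.rint(mean + rng.integers(-2, 3, size=n)).astype(int)
    return list(np.clip(qual, 2, 40))


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


_RC = str.maketrans("ACGTN", "TGCAN")


def simulate_library(
    spec: MockSpec,
    model: LibraryModel,
    refdb: ReferenceDB,
    planted: Sequence[PlantedVariant] = (),
) -> tuple[list[tuple[SeqRecord, SeqRecord]], list[TruthRecord], dict[str, int]]:
    """Simulate the library: returns (read pairs, truth records, stats).

    Candidate inserts are drawn until ``spec.total_reads`` pass size
    selection and the PCR-bias acceptance step; rejected draws are counted
    in the stats (``size_rejected``, ``pcr_rejected``).
    """
    rng = np.random.default_rng(spec.seed)
    proportions = np.array([m.proportion for m in spec.members])
    planted_by_ref = {p.ref_id: p for p in planted}
    seqs = {}
    for m in spec.members:
        seq = refdb.sequence_of(m.ref_id)
        if refdb.molecule_of(m.ref_id) != m.molecule:
            raise ConfigurationError(
                f"member {m.ref_id} is not a {m.molecule} reference"
            )
        seqs[m.ref_id] = seq
    gc_prefix = {
        rid: np.concatenate(
            [[0], np.cumsum([c in "GC" for c in seq])]
        )
        for rid, seq in seqs.items()
    }
    variant_gc_prefix = {
        p.ref_id: np.concatenate(
            [[0], np.cumsum([c in "GC" for c in p.variant_seq])]
        )
        for p in planted
    }
    w_max = model.max_pcr_weight
    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    truth: list[TruthRecord] = []
    stats = {"emitted": 0, "size_rejected": 0, "pcr_rejected": 0}
    lo, hi = model.size_selection
    max_attempts = 200 * spec.total_reads + 10_000
    attempts = 0
    while len(pairs) < spec.total_reads:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                "simulation rejection rate too high; check the library model"
            )
        mi = int(rng.choice(len(spec.members), p=proportions))
        member = spec.members[mi]
        use_variant = False
        pv = planted_by_ref.get(member.ref_id)
        if pv is not None and member.molecule == "SSU" and rng.random() < pv.fraction:
            use_variant = True
        mol_seq = pv.variant_seq if use_variant else seqs[member.ref_id]
        mol_len = len(mol_seq)
        start = _draw_start(model, member.molecule, mol_len, rng)
        raw_len = _draw_insert_length(model, member.ref_id, rng)
        ins_len = min(raw_len, mol_len - start + 1)
        if not (lo <= ins_len <= hi):
            stats["size_rejected"] += 1
            continue
        if w_max > 0 and (model.pcr_length_coef or model.pcr_gc_coef):
            prefix = (
                variant_gc_prefix[member.ref_id] if use_variant else gc_prefix[member.ref_id]
            )
            gc = (prefix[start - 1 + ins_len] - prefix[start - 1]) / ins_len
            if rng.random() >= model.pcr_weight(ins_len, gc) / w_max:
                stats["pcr_rejected"] += 1
                continue
        insert = mol_seq[start - 1 : start - 1 + ins_len]
        idx = len(pairs)
        read_id = f"read{idx:06d}"
        r1_seq = _apply_errors(insert[: model.read_length], model.substitution_rate, rng)
        rc = insert.translate(_RC)[::-1]
        r2_seq = _apply_errors(rc[: model.read_length], model.substitution_rate, rng)
        r1 = SeqRecord(
            f"{read_id}/1", r1_seq, _quality_profile(len(r1_seq), model, rng)
        )
        r2 = SeqRecord(
            f"{read_id}/2", r2_seq, _quality_profile(len(r2_seq), model, rng)
        )
        pairs.append((r1, r2))
        truth.append(
            TruthRecord(
                read_id=read_id,
                source=member.ref_id,
                molecule=member.molecule,
                insert_start=start,
                insert_end=start + ins_len - 1,
                planted_variant=use_variant,
            )
        )
    stats["emitted"] = len(pairs)
    return pairs, truth, stats


# ---------------------------------------------------------------------------
# Analytic accounting
# ---------------------------------------------------------------------------


def _length_pmf(model: LibraryModel, member_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Discrete pmf of the raw insert-length draw over its support."""
    peaks = model.member_peaks.get(member_id, model.length_peaks)
    lo, hi = model.size_selection
    lows = [lo] + [int(math.floor(m - 8 * s)) for m, s, _ in peaks]
    highs = [hi] + [int(math.ceil(m + 8 * s)) for m, s, _ in peaks]
    support = np.arange(max(1, min(lows)), max(highs) + 1)
    pmf = np.zeros_like(support, dtype=np.float64)
    total_w = 0.0
    for mean, sd, w in peaks:
        total_w += w
        pmf += w * (
            norm.cdf(support + 0.5, mean, sd) - norm.cdf(support - 0.5, mean, sd)
        )
    bg = 1.0 - total_w
    if bg > 0:
        in_bg = (support >= lo) & (support <= hi)
        pmf[in_bg] += bg / (hi - lo + 1)
    return support, pmf


def analytic_region_fraction(
    spec: MockSpec,
    model: LibraryModel,
    refdb: ReferenceDB,
    region: tuple[int, int] = (8, 242),
    domains: tuple[str, ...] = ("Archaea", "Bacteria"),
) -> float:
    """Exact probability, under the configured breakpoint/length/PCR models,
    that an emitted prokaryotic SSU read fully contains the template window.

    Mirrors the simulator's draw-then-reject semantics: numerator and
    denominator are both restricted to accepted SSU draws from the listed
    domains.
    """
    r_lo, r_hi = region
    lo, hi = model.size_selection
    num = den = 0.0
    for member in spec.members:
        if member.molecule != "SSU":
            continue
        seq, lineage = refdb.ssu[member.ref_id]
        if lineage.domain not in domains:
            continue
        mol_len = len(seq)
        gc_prefix = np.concatenate([[0], np.cumsum([c in "GC" for c in seq])])
        support, pmf = _length_pmf(model, member.ref_id)
        max_start = max(2, mol_len - lo + 1)
        starts = np.arange(1, max_start + 1)
        p_start = np.full(starts.shape, (1 - model.ssu_anchor_prob) / (max_start - 1))
        p_start[0] = model.ssu_anchor_prob
        # ins_len = min(raw, mol_len - start + 1), truncation negligible for
        # SSU at these scales but handled exactly:
        for s, ps in zip(starts, p_start):
            cap = mol_len - s + 1
            ins = np.minimum(support, cap)
            ok = (ins >= lo) & (ins <= hi)
            if not ok.any():
                continue
            ins_ok = ins[ok]
            p_ok = pmf[ok]
            if model.pcr_length_coef or model.pcr_gc_coef:
                gc = (gc_prefix[s - 1 + ins_ok] - gc_prefix[s - 1]) / ins_ok
                w = np.exp(
                    -model.pcr_cycles
                    * (
                        model.pcr_length_coef
                        * (ins_ok - model.pcr_length_ref)
                        / model.pcr_length_scale
                        + model.pcr_gc_coef * np.abs(gc - 0.5)
                    )
                )
            else:
                w = np.ones_like(p_ok)
            mass = member.proportion * ps * p_ok * w
            den += mass.sum()
            if s <= r_lo:
                contains = s + ins_ok - 1 >= r_hi
                num += mass[contains].sum()
    if den == 0:
        raise ConfigurationError("no accepted SSU mass under this model")
    return num / den
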