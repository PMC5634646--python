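import numpy as np
import pytest

from ssurna import primer_eval
from ssurna.primer_eval import (
    PRIMER_8F,
    AlphabetError,
    expand_iupac,
    match_primer,
    mismatch_catalogue,
    noncoverage_rates,
)
from ssurna.refmap import map_to_template
from ssurna.seqio import SeqRecord, TaxonomyLineage
from ssurna.taxclass import Classification


def test_8f_expands_to_four_sequences():
    exps = expand_iupac(PRIMER_8F.pattern)
    assert len(exps) == 4
    assert "AGAGTTTGATCATGGCTCAG" in exps
    assert "AGAGTTTGATCCTGGCTCAG" in exps
    assert "AGAGTTTGATTATGGCTCAG" in exps
    assert "AGAGTTTGATTCTGGCTCAG" in exps


def test_expand_no_degeneracy_and_nn():
    assert expand_iupac("ACGT") == ["ACGT"]
    assert len(expand_iupac("NN")) == 16


def test_expand_invalid_character_names_position():
    with pytest.raises(AlphabetError, match="position 2"):
        expand_iupac("ACXGT")


def _window_read(refdb, window):
    """A read covering positions 1-120 whose primer window reads ``window``."""
    template = refdb.template
    seq = template[:7] + window + template[27:120]
    rec = SeqRecord("w", seq)
    m = map_to_template(rec, template)
    assert m is not None and m.start == 1
    return m, rec


def test_exact_expansion_zero_mismatches(refdb):
    m, rec = _window_read(refdb, "AGAGTTTGATCATGGCTCAG")
    res = match_primer(m, rec)
    assert res.covers_window and res.n_mismatches == 0
    assert res.observed_window == "AGAGTTTGATCATGGCTCAG"


def test_single_substitution_counts_once(refdb):
    # window position 13 (template position 20): T -> G
    window = list("AGAGTTTGATCATGGCTCAG")
    window[12] = "G"
    m, rec = _window_read(refdb, "".join(window))
    res = match_primer(m, rec)
    assert res.n_mismatches == 1
    assert res.mismatch_positions == [20]
    assert res.non_covered


def test_degenerate_positions_accept_both_bases(refdb):
    for w in ("AGAGTTTGATCATGGCTCAG", "AGAGTTTGATTCTGGCTCAG"):
        m, rec = _window_read(refdb, w)
        assert match_primer(m, rec).n_mismatches == 0


def test_read_starting_past_window_does_not_cover(refdb):
    template = refdb.template
    rec = SeqRecord("x", template[49:300])
    m = map_to_template(rec, template)
    res = match_primer(m, rec)
    assert not res.covers_window and res.n_mismatches is None


def test_read_n_fails_every_primer_base(refdb):
    window = "N" + "GAGTTTGATCATGGCTCAG"
    m, rec = _window_read(refdb, window)
    assert match_primer(m, rec).n_mismatches == 1


def test_deletion_inside_window_counts_as_mismatch(refdb):
    template = refdb.template
    seq = template[:14] + template[15:300]  # delete template position 15
    rec = SeqRecord("d", seq)
    m = map_to_template(rec, template)
    res = match_primer(m, rec)
    assert res.covers_window and res.n_mismatches >= 1
    assert 15 in res.mismatch_positions


def _fake_results_and_cls(spec):
    """spec: list of (taxon, covers, mism) -> parallel results/classifications."""
    results, cls = [], []
    for i, (taxon, covers, mism) in enumerate(spec):
        results.append(
            primer_eval.PrimerMatchResult(
                read_id=f"r{i}",
                covers_window=covers,
                n_mismatches=mism if covers else None,
                observed_window="AGAGTTTGATCATGGCTCAG" if covers else None,
            )
        )
        lineage = TaxonomyLineage.from_string(f"Bacteria;{taxon}ph;x;y;z;{taxon};")
        cls.append(
            Classification(lineage=lineage, bootstrap=[100.0] * 6, cutoff=80.0)
        )
    return results, cls


def test_rate_is_ratio_of_noncovered_to_covering():
    spec = [("A", True, 1)] * 5 + [("A", True, 0)] * 95
    results, cls = _fake_results_and_cls(spec)
    rows = noncoverage_rates(results, cls, rank_depths=(5,))
    (row,) = rows
    assert row["rate"] == 0.05 and row["covering"] == 100


def test_rate_undefined_without_covering_reads():
    results, cls = _fake_results_and_cls([("A", False, None)] * 3)
    (row,) = noncoverage_rates(results, cls, rank_depths=(5,))
    assert row["rate"] is None and row["classified_total"] == 3


def test_suppression_flag_below_ten():
    spec = [("A", True, 1)] * 5 + [("A", True, 0)] * 5 + [("B", True, 1)] * 12
    results, cls = _fake_results_and_cls(spec)
    rows = noncoverage_rates(results, cls, rank_depths=(5,), suppress_below=10)
    by_taxon = {r["taxon"]: r for r in rows}
    assert by_taxon["A"]["suppressed"] and not by_taxon["B"]["suppressed"]


def test_taxon_counts_partition_covering_reads():
    spec = [("A", True, 0)] * 7 + [("B", True, 1)] * 4 + [("C", False, None)] * 2
    results, cls = _fake_results_and_cls(spec)
    rows = noncoverage_rates(results, cls, rank_depths=(5,))
    assert sum(r["covering"] for r in rows) == 11
    assert sum(r["classified_total"] for r in rows) == 13


def test_mismatches_outside_window_do_not_change_rates(refdb):
    template = refdb.template
    reads = []
    for i in range(20):
        seq = list(template[:300])
        if i % 2:
            seq[100] = "ACGT".replace(seq[100], "")[0]  # outside the window
        reads.append(SeqRecord(f"r{i}", "".join(seq)))
    results = [match_primer(map_to_template(r, template), r) for r in reads]
    assert all(res.n_mismatches == 0 for res in results)


def test_match_agrees_with_hamming_oracle(refdb, rng):
    """match_primer equals minimum Hamming distance over the four primer
    expansions on indel-free reads (gapless identity maps)."""
    from ssurna.refmap import CoordinateMap

    template = refdb.template
    expansions = expand_iupac(PRIMER_8F.pattern)
    for _ in range(300):
        window = "".join(rng.choice(list("ACGT"), 20))
        seq = template[:7] + window + template[27:150]
        rec = SeqRecord("x", seq)
        m = CoordinateMap(
            read_id="x",
            start=1,
            end=len(seq),
            pairs=[(i, i + 1) for i in range(len(seq))],
            identity=1.0,
        )
        res = match_primer(m, rec)
        oracle = min(
            sum(a != b for a, b in zip(window, exp)) for exp in expansions
        )
        assert res.n_mismatches == oracle


def test_catalogue_counts_and_nearest_expansion():
    results, _ = _fake_results_and_cls([("A", True, 0)] * 3)
    variant = primer_eval.PrimerMatchResult(
        read_id="v",
        covers_window=True,
        n_mismatches=1,
        observed_window="AGAGTTTGATCAGGGCTCAG",
    )
    rows = mismatch_catalogue(list(results) + [variant] * 10)
    by_window = {r["observed_window"]: r for r in rows}
    assert by_window["AGAGTTTGATCATGGCTCAG"]["count"] == 3
    v = by_window["AGAGTTTGATCAGGGCTCAG"]
    assert v["count"] == 10 and v["hamming"] == 1
    assert v["nearest_expansion"] == "AGAGTTTGATCATGGCTCAG"
    assert v["differences"] == "20T>G"
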