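import re

import numpy as np
import pytest
from scipy.stats import chisquare

from ssurna import simdata
from ssurna.simdata import (
    ConfigurationError,
    LibraryModel,
    MockMember,
    MockSpec,
    analytic_region_fraction,
    build_toy_reference,
    isolate_length_peaks,
    mock2_spec,
    plant_primer_variants,
    simulate_library,
    unequal_mock_spec,
)

MEMBERS = ["Eco_16S_syn", "Bsu_16S_syn", "Cca_16S_syn", "Hha_16S_syn", "Ppa_18S_syn"]


def test_toy_reference_deterministic():
    a, b = build_toy_reference(3), build_toy_reference(3)
    assert a.ssu == b.ssu and a.lsu == b.lsu


def test_toy_reference_gc_targets(refdb):
    def gc(seq):
        return 100.0 * sum(c in "GC" for c in seq) / len(seq)

    assert round(gc(refdb.ssu["Hha_16S_syn"][0])) == 68
    assert round(gc(refdb.ssu["Cca_16S_syn"][0])) == 34


def test_toy_reference_no_long_homopolymers(refdb):
    for rid, (seq, _) in {**refdb.ssu, **refdb.lsu_all}.items():
        longest = max(len(m.group()) for m in re.finditer(r"(.)\1*", seq))
        assert longest <= 8, rid


def test_member_divergence_within_bands(refdb):
    """Prokaryotic members stay homologous enough to map (>= 60% identity to
    the template) yet distinct (<= 98%)."""
    template = refdb.template
    for rid in ("Bsu_16S_syn", "Cca_16S_syn", "Hha_16S_syn", "Chl_16S_syn"):
        seq = refdb.ssu[rid][0]
        ident = sum(a == b for a, b in zip(seq, template)) / len(template)
        assert 0.60 <= ident <= 0.98, (rid, ident)


def test_primer_window_conserved_in_bacteria(refdb):
    from ssurna.primer_eval import PRIMER_8F, expand_iupac

    expansions = expand_iupac(PRIMER_8F.pattern)
    for rid in ("Eco_16S_syn", "Bsu_16S_syn", "Cca_16S_syn"):
        window = refdb.ssu[rid][0][7:27]
        assert window in expansions, rid


def test_spec_proportions_must_sum_to_one():
    with pytest.raises(ConfigurationError):
        MockSpec(members=[MockMember("Eco_16S_syn", "SSU", 0.5)], total_reads=10)


def test_truth_conservation_and_size_selection(refdb):
    spec = mock2_spec(500, seed=21)
    model = LibraryModel()
    pairs, truth, stats = simulate_library(spec, model, refdb)
    assert len(pairs) == len(truth) == spec.total_reads == stats["emitted"]
    lo, hi = model.size_selection
    for t in truth:
        length = t.insert_end - t.insert_start + 1
        assert lo <= length <= hi
        assert 1 <= t.insert_start <= t.insert_end <= len(
            refdb.sequence_of(t.source)
        )


def test_simulation_deterministic(refdb):
    spec = mock2_spec(200, seed=9)
    p1, t1, _ = simulate_library(spec, LibraryModel(), refdb)
    p2, t2, _ = simulate_library(spec, LibraryModel(), refdb)
    assert p1 == p2 and t1 == t2


def test_zero_bias_proportions_chi_square(refdb):
    spec = mock2_spec(6000, seed=31)
    _, truth, _ = simulate_library(spec, LibraryModel(), refdb)
    counts = {m: 0 for m in MEMBERS}
    for t in truth:
        counts[t.source] += 1
    stat, p = chisquare(list(counts.values()))
    assert p > 0.001


def test_ssu_anchoring_fraction(refdb):
    spec = mock2_spec(4000, seed=41)
    _, truth, _ = simulate_library(spec, LibraryModel(), refdb)
    anchored = np.mean([t.insert_start == 1 for t in truth])
    se = np.sqrt(0.8 * 0.2 / len(truth))
    assert abs(anchored - 0.8) < 4 * se


def test_lsu_breakpoints_mixture(refdb):
    members = [MockMember("Eco_23S_syn", "LSU", 1.0)]
    spec = MockSpec(members=members, total_reads=2000, seed=51)
    _, truth, _ = simulate_library(spec, LibraryModel(), refdb)
    starts = np.array([t.insert_start for t in truth])
    frac_anchor = np.mean(starts == 1)
    se = np.sqrt(0.5 * 0.5 / len(starts))
    assert abs(frac_anchor - 0.5) < 4 * se
    mid = starts[starts > 1]
    L = len(refdb.lsu["Bacteria"]["Eco_23S_syn"][0])
    assert abs(np.median(mid) - L / 2) < 0.15 * L


def test_reads_are_mates_of_the_insert(refdb):
    from ssurna.seqio import reverse_complement

    spec = mock2_spec(50, seed=61)
    model = LibraryModel(substitution_rate=0.0)
    pairs, truth, _ = simulate_library(spec, model, refdb)
    for (r1, r2), t in zip(pairs, truth):
        insert = refdb.sequence_of(t.source)[t.insert_start - 1 : t.insert_end]
        assert r1.seq == insert[: len(r1.seq)]
        assert r2.seq == reverse_complement(insert)[: len(r2.seq)]


def test_planted_variant_validation(refdb):
    with pytest.raises(ConfigurationError):
        plant_primer_variants(refdb, "Bacillus", (100, "C"), 0.4)
    with pytest.raises(ConfigurationError):
        plant_primer_variants(refdb, "NoSuchGenus", (20, "C"), 0.4)


def test_planted_fraction_zero_and_one(refdb):
    spec = mock2_spec(300, seed=71)
    _, pv = plant_primer_variants(refdb, "Bacillus", (20, "C"), 0.0)
    _, truth, _ = simulate_library(spec, LibraryModel(), refdb, planted=[pv])
    assert not any(t.planted_variant for t in truth)
    _, pv1 = plant_primer_variants(refdb, "Bacillus", (20, "C"), 1.0)
    pairs, truth, _ = simulate_library(
        spec, LibraryModel(substitution_rate=0.0), refdb, planted=[pv1]
    )
    bsu = [t for t in truth if t.source == "Bsu_16S_syn"]
    assert bsu and all(t.planted_variant for t in bsu)
    # anchored reads carry the edited base at position 20
    for (r1, _), t in zip(pairs, truth):
        if t.source == "Bsu_16S_syn" and t.insert_start == 1:
            assert r1.seq[19] == "C"


def test_analytic_fraction_matches_truth(refdb):
    spec = mock2_spec(10_000, seed=81)
    model = LibraryModel()
    pred = analytic_region_fraction(spec, model, refdb)
    _, truth, _ = simulate_library(spec, model, refdb)
    prok = {"Eco_16S_syn", "Bsu_16S_syn", "Cca_16S_syn", "Hha_16S_syn"}
    obs = np.mean(
        [t.insert_start <= 8 and t.insert_end >= 242 for t in truth if t.source in prok]
    )
    assert abs(pred - obs) < 0.02


def test_analytic_fraction_increases_with_anchoring(refdb):
    spec = mock2_spec(100, seed=0)
    fr = [
        analytic_region_fraction(spec, LibraryModel(ssu_anchor_prob=p), refdb)
        for p in (0.2, 0.5, 0.8, 0.95)
    ]
    assert fr == sorted(fr)
    assert all(0.0 <= f <= 1.0 for f in fr)


def test_biased_model_prefers_short_inserts(refdb):
    model = simdata.LibraryModel.with_pcr_bias(
        member_peaks=isolate_length_peaks()
    )
    spec = mock2_spec(3000, seed=91)
    _, truth, _ = simulate_library(spec, model, refdb)
    by_member = {}
    for t in truth:
        by_member.setdefault(t.source, []).append(
            t.insert_end - t.insert_start + 1
        )
    # the 219-peaked member is drawn mostly from its short peak under bias
    cca = np.asarray(by_member["Cca_16S_syn"])
    assert np.mean(cca < 280) > 0.7


def test_quality_profile_in_range(refdb):
    pairs, _, _ = simulate_library(mock2_spec(30, seed=3), LibraryModel(), refdb)
    for r1, r2 in pairs:
        for rec in (r1, r2):
            assert all(2 <= q <= 40 for q in rec.qual)
            assert len(rec.qual) == len(rec.seq)


def test_unequal_mock_spans_tenfold():
    spec = unequal_mock_spec(100, seed=0)
    props = [m.proportion for m in spec.members]
    assert max(props) / min(props) == pytest.approx(10.0)
    assert sum(props) == pytest.approx(1.0)
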