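import itertools
import math

import numpy as np
import pytest

from ssurna import otu_diversity
from ssurna.otu_diversity import (
    DistanceMatrix,
    SubsampleError,
    alpha_diversity,
    cluster_otus,
    cluster_reads,
    pairwise_distances,
)
from ssurna.refmap import TrimmedRead


def _tr(read_id, aligned):
    return TrimmedRead(id=read_id, seq=aligned.replace("-", ""), aligned=aligned)


def test_identical_reads_distance_zero():
    dm = pairwise_distances([_tr("a", "ACGT" * 25), _tr("b", "ACGT" * 25)])
    assert dm.condensed[0] == 0.0


def test_single_substitution_over_100_columns():
    a = "ACGT" * 25
    b = "T" + a[1:]
    dm = pairwise_distances([_tr("a", a), _tr("b", b)])
    assert dm.condensed[0] == pytest.approx(0.01)


def test_one_sided_gap_is_mismatch_both_gap_skipped():
    a = "ACGTACGTAC"
    b = "ACGT-CGTAC"  # one internal gap
    c = "ACGT-CGTAC"
    dm = pairwise_distances([_tr("a", a), _tr("b", b), _tr("c", c)])
    # a-b: 1 mismatch / 10 compared; b-c: both-gap column skipped -> 0/9
    assert dm.condensed[0] == pytest.approx(0.1)
    assert dm.condensed[1] == pytest.approx(0.1)
    assert dm.condensed[2] == 0.0


def test_terminal_gaps_excluded():
    a = "--GTACGTAC"
    b = "ACGTACGTAC"
    dm = pairwise_distances([_tr("a", a), _tr("b", b)])
    assert dm.condensed[0] == 0.0


def test_window_mismatch_rejected():
    with pytest.raises(otu_diversity.WindowMismatchError):
        pairwise_distances([_tr("a", "ACGT"), _tr("b", "ACGTA")])


def _dm(ids, dists):
    return DistanceMatrix(ids=list(ids), condensed=np.asarray(dists, dtype=float))


def test_cluster_pair_and_singleton():
    dm = _dm("ABC", [0.01, 0.50, 0.50])  # AB, AC, BC
    table = cluster_otus(dm, 0.03)
    parts = sorted(sorted(o.members) for o in table.otus.values())
    assert parts == [["A", "B"], ["C"]]


def test_all_identical_single_otu():
    reads = [_tr(f"r{i}", "ACGT" * 30) for i in range(8)]
    table = cluster_reads(reads, 0.03)
    assert len(table.otus) == 1
    (otu,) = table.otus.values()
    assert otu.abundance == 8


def _average_linkage_oracle(n, sq, cutoff):
    """O(n^3) agglomerative average-neighbor clustering, merging the closest
    pair while its average inter-cluster distance <= cutoff."""
    clusters = [{i} for i in range(n)]
    while len(clusters) > 1:
        best, bd = None, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([sq[i, j] for i in clusters[a] for j in clusters[b]])
            if bd is None or d < bd:
                best, bd = (a, b), d
        if bd > cutoff:
            break
        a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return sorted(sorted(c) for c in clusters)


@pytest.mark.parametrize("trial", range(25))
def test_cluster_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(4, 13))
    sq = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(0.0, 0.12, size=len(iu[0]))
    sq[iu] = vals
    sq += sq.T
    dm = _dm([f"s{i:02d}" for i in range(n)], vals)
    table = cluster_otus(dm, 0.03)
    got = sorted(
        sorted(int(m[1:]) for m in o.members) for o in table.otus.values()
    )
    assert got == _average_linkage_oracle(n, sq, 0.03)


def test_cluster_permutation_invariant():
    rng = np.random.default_rng(77)
    n = 10
    sq = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    sq[iu] = rng.uniform(0, 0.1, size=len(iu[0]))
    sq += sq.T
    ids = [f"s{i}" for i in range(n)]

    def parts(order):
        vals = [sq[order[i], order[j]] for i in range(n) for j in range(i + 1, n)]
        dm = _dm([ids[k] for k in order], vals)
        t = cluster_otus(dm, 0.03)
        return sorted(sorted(o.members) for o in t.otus.values())

    base = parts(list(range(n)))
    for _ in range(5):
        order = list(rng.permutation(n))
        assert parts(order) == base


def test_representative_minimises_summed_distance():
    # B is the medoid: distances AB=0.01, BC=0.01, AC=0.02
    dm = _dm("ABC", [0.01, 0.02, 0.01])
    table = cluster_otus(dm, 0.05)
    (otu,) = table.otus.values()
    assert otu.representative == "B"


def test_abundances_conserve_reads():
    rng = np.random.default_rng(5)
    reads = [
        _tr(f"r{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(30)
    ]
    table = cluster_reads(reads, 0.03)
    assert table.total_reads == 30
    all_members = sorted(m for o in table.otus.values() for m in o.members)
    assert all_members == sorted(r.id for r in reads)


def test_organelle_otus_removed(refdb, cfg):
    from ssurna.refmap import map_to_template, trim_to_region
    from ssurna.seqio import SeqRecord
    from ssurna.taxclass import build_index

    idx = build_index(refdb.ssu)
    trimmed = []
    for src in ("Eco_16S_syn", "Chl_16S_syn"):
        seq = refdb.ssu[src][0]
        for i in range(3):
            rec = SeqRecord(f"{src}_{i}", seq[:300])
            m = map_to_template(rec, refdb.template, 0.5)
            trimmed.append(trim_to_region(m, rec, cfg))
    table = cluster_reads(trimmed, 0.03)
    assert len(table.otus) == 2
    kept, tally = otu_diversity.classify_representatives(table, idx, cfg, seed=3)
    assert tally["organelle_removed"] == 1 and len(kept.otus) == 1
    (otu,) = kept.otus.values()
    assert otu.lineage.lineage.taxa[-1] == "Escherichia"


def test_diversity_closed_forms():
    est = alpha_diversity([5, 3, 2, 1, 1])
    assert est.sobs == 5
    assert est.chao == pytest.approx(5.5)  # 5 + 2*1/(2*(1+1))
    est4 = alpha_diversity([10, 10, 10, 10])
    assert est4.shannon == pytest.approx(math.log(4))
    est1 = alpha_diversity([17])
    assert (est1.sobs, est1.shannon, est1.chao) == (1, 0.0, 1.0)


def test_diversity_estimator_inequalities(rng):
    for _ in range(20):
        counts = rng.integers(1, 50, size=int(rng.integers(2, 30)))
        est = alpha_diversity(list(counts))
        assert est.chao >= est.sobs
        assert est.ace >= est.sobs or est.ace == pytest.approx(est.sobs)
        assert 0.0 <= est.shannon <= math.log(est.sobs) + 1e-9


def test_subsampling_deterministic_and_depth_checked():
    counts = [40, 30, 20, 10, 5, 1]
    a = alpha_diversity(counts, depth=50, seed=11)
    b = alpha_diversity(counts, depth=50, seed=11)
    assert a == b
    c = alpha_diversity(counts, depth=50, seed=12)
    assert c != a
    with pytest.raises(SubsampleError):
        alpha_diversity(counts, depth=1000)


def test_subsampled_richness_monotone_in_depth():
    rng = np.random.default_rng(2)
    counts = list(rng.integers(1, 60, size=40))
    means = [
        alpha_diversity(counts, depth=d, n_resamples=50, seed=4).sobs
        for d in (50, 150, 400)
    ]
    assert means == sorted(means)
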