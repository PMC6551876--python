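"""Consensus majority calls, interval queries, and nearest genes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from monometh.annotate import (
    DonorTrackSet, IntervalSet, annotate_cpgs, majority_call, nearest_gene,
    nearest_genes_bulk,
)
from monometh.io import GenomicInterval


def test_majority_call_examples():
    assert majority_call(["E", "E", "E", "Q", "Q"], 3) == "E"
    assert majority_call(["E", "E", "Q", "Q", "Q"], 3) == "Q"
    assert majority_call(["E", "E", "Q", "Q", None], 3) is None
    # two labels reaching a low threshold is ambiguous -> no call
    assert majority_call(["E", "E", "Q", "Q"], 2) is None
    # absent donors carry no vote
    assert majority_call(["E", "E", None, None, None], 2) == "E"
    with pytest.raises(ValueError):
        majority_call([], 3)


def test_majority_call_dnase_thresholds():
    votes = ["1"] * 13 + [None] * 13
    assert majority_call(votes, 13) == "1"
    assert majority_call(["1"] * 12 + [None] * 14, 13) is None


@given(st.lists(st.sampled_from(["E", "Q", "T", None]), min_size=1, max_size=8),
       st.integers(1, 8), st.randoms(use_true_random=False))
def test_majority_call_permutation_invariant(labels, min_votes, rnd):
    shuffled = list(labels)
    rnd.shuffle(shuffled)
    assert majority_call(labels, min_votes) == majority_call(shuffled, min_votes)


def _tracks():
    per_donor = {
        "d1": [GenomicInterval("chr1", 0, 100, "E"), GenomicInterval("chr1", 100, 200, "Q")],
        "d2": [GenomicInterval("chr1", 0, 150, "E")],
        "d3": [GenomicInterval("chr1", 50, 200, "E")],
        "d4": [GenomicInterval("chr1", 0, 200, "Q")],
        "d5": [],
    }
    return DonorTrackSet(per_donor)


def test_labels_at_and_consensus():
    ts = _tracks()
    assert ts.labels_at("chr1", 60) == ["E", "E", "E", "Q", None]
    assert ts.consensus_at("chr1", 60, 3) == "E"
    assert ts.consensus_at("chr1", 10, 3) is None  # E:2, Q:1
    assert ts.labels_at("chr2", 60) == [None] * 5
    # half-open: position 200 is outside every interval
    assert ts.labels_at("chr1", 200) == [None] * 5


def test_consensus_segments_match_pointwise_oracle():
    ts = _tracks()
    segments, votes = ts.consensus_segments(min_votes=3)
    called = {}
    for iv in segments:
        for p in range(iv.start, iv.end):
            called[p] = iv.label
    for p in range(0, 250):
        expected = ts.consensus_at("chr1", p, 3)
        assert called.get(p) == expected, p
    assert (votes["votes"] >= 3).all()


def test_interval_set_halfopen():
    s = IntervalSet([GenomicInterval("chr1", 10, 20, "m1")])
    assert not s.contains("chr1", 9)
    assert s.contains("chr1", 10)
    assert s.contains("chr1", 19)
    assert not s.contains("chr1", 20)
    assert s.labels_overlapping("chr1", 0, 10) == set()
    assert s.labels_overlapping("chr1", 0, 11) == {"m1"}
    assert s.labels_overlapping("chr2", 0, 100) == set()


# ---------------------------------------------------------------------------
# nearest gene
# ---------------------------------------------------------------------------

def _genes():
    return pd.DataFrame({
        "gene": ["A", "B", "C"],
        "chrom": ["chr1", "chr1", "chr2"],
        "tss": [100, 300, 50],
        "tes": [200, 400, 90],
        "strand": ["+", "-", "+"],
    })


def test_nearest_gene_examples():
    genes = _genes()
    assert nearest_gene("chr1", 110, genes) == ("A", 10.0)
    # pos 250 is 50 from A's TES and 50 from B's TSS; tie broken by
    # smaller TSS distance (B: 50 < A: 150)
    assert nearest_gene("chr1", 250, genes) == ("B", 50.0)
    assert nearest_gene("chr2", 90, genes) == ("C", 0.0)
    g, d = nearest_gene("chrX", 5, genes)
    assert g is None and np.isnan(d)


def test_nearest_gene_lexicographic_tiebreak():
    genes = pd.DataFrame({
        "gene": ["zeta", "alpha"],
        "chrom": ["chr1", "chr1"],
        "tss": [100, 140],
        "tes": [400, 440],
        "strand": ["+", "+"],
    })
    # pos 120: 20 from both TSSs -> lexicographic
    assert nearest_gene("chr1", 120, genes)[0] == "alpha"


def test_bulk_matches_scalar_oracle():
    rng = np.random.default_rng(10)
    genes = pd.DataFrame({
        "gene": [f"g{i}" for i in range(12)],
        "chrom": rng.choice(["chr1", "chr2"], 12),
        "tss": rng.integers(1, 5000, 12),
        "tes": rng.integers(5001, 10000, 12),
        "strand": rng.choice(["+", "-"], 12),
    })
    cpg_map = pd.DataFrame({
        "chrom": rng.choice(["chr1", "chr2", "chr3"], 200),
        "pos": rng.integers(1, 11000, 200),
    }, index=[f"cg{i}" for i in range(200)])
    bulk = nearest_genes_bulk(cpg_map, genes)
    for pid, rec in cpg_map.iterrows():
        g, d = nearest_gene(rec["chrom"], int(rec["pos"]), genes)
        assert bulk.loc[pid, "nearest_gene"] == g, pid
        if np.isnan(d):
            assert np.isnan(bulk.loc[pid, "gene_distance"])
        else:
            assert bulk.loc[pid, "gene_distance"] == d, pid


# ---------------------------------------------------------------------------
# per-CpG annotation
# ---------------------------------------------------------------------------

def test_annotate_cpgs_against_direct_overlap():
    rng = np.random.default_rng(12)
    n_cpg = 60
    cpg_map = pd.DataFrame({
        "chrom": "chr1",
        "pos": sorted(rng.choice(np.arange(1, 3000), n_cpg, replace=False)),
    }, index=[f"cg{i}" for i in range(n_cpg)])
    cpg_map["pos0"] = cpg_map["pos"] - 1

    def random_track(n_donors, label_pool):
        per = {}
        for d in range(n_donors):
            ivs, cur = [], 0
            while cur < 3000:
                ln = int(rng.integers(50, 400))
                if rng.random() < 0.7:
                    ivs.append(GenomicInterval(
                        "chr1", cur, cur + ln, str(rng.choice(label_pool))))
                cur += ln
            per[f"d{d}"] = ivs
        return per

    states = {ct: random_track(5, ["E", "Q", "T"]) for ct in ("monocyte", "macrophage")}
    dnase = {"monocyte": random_track(26, ["1"]), "macrophage": random_track(4, ["1"])}
    hic = {ct: [GenomicInterval("chr1", 500, 900, "enh")] for ct in ("monocyte", "macrophage")}
    motif = IntervalSet([GenomicInterval("chr1", 1000, 1008, "CEBP_like")])
    genes = _genes()

    ann = annotate_cpgs(
        cpg_map,
        {ct: DonorTrackSet(t) for ct, t in states.items()},
        {ct: DonorTrackSet(t) for ct, t in dnase.items()},
        {ct: IntervalSet(v) for ct, v in hic.items()},
        genes, motif_sites=motif,
        state_min_votes=3,
        dnase_min_votes={"monocyte": 13, "macrophage": 2})

    def direct_labels(per_donor, pos0):
        out = []
        for d in sorted(per_donor):
            lab = None
            for iv in per_donor[d]:
                if iv.start <= pos0 < iv.end:
                    lab = iv.label
                    break
            out.append(lab)
        return out

    for pid, rec in cpg_map.iterrows():
        p = int(rec["pos0"])
        exp_state = majority_call(direct_labels(states["monocyte"], p), 3)
        assert ann.loc[pid, "state_mono"] == exp_state, pid
        dn = direct_labels(dnase["macrophage"], p)
        assert ann.loc[pid, "dhs_mac"] == (sum(l is not None for l in dn) >= 2)
        assert ann.loc[pid, "hic_mono"] == (500 <= p < 900)
        expected_hits = "CEBP_like" if (p + 26 > 1000 and p - 25 < 1008) else ""
        assert ann.loc[pid, "motif_hits"] == expected_hits, pid
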