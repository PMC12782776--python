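import itertools
import math
import random

import pytest
from hypothesis import given, strategies as st

from mitocomp import (Alignment, filter_blocks, mean_ng86, ng86,
                      nucleotide_diversity, pairwise_distance,
                      sliding_diversity)
from mitocomp.divergence import SaturationError, syn_sites
from mitocomp.simulate import simulate_coding_alignment

from .oracles import gblocks_like_reference


def _random_alignment(rng, nrow=6, ncol=120, gap_frac=0.08):
    rows = []
    for _ in range(nrow):
        row = "".join(rng.choice("ACGT") if rng.random() > gap_frac else "-"
                      for _ in range(ncol))
        rows.append(row)
    return Alignment([f"t{i}" for i in range(nrow)], rows)


def test_filter_keeps_identical_alignment_unchanged():
    aln = Alignment(["a", "b"], ["ACGTACGTACGTACGT", "ACGTACGTACGTACGT"])
    out = filter_blocks(aln, 0.5, 8, 10, False)
    assert out.rows == aln.rows


def test_filter_removes_gap_column_when_gaps_disallowed():
    base = "ACGTACGTACGTACG"
    aln = Alignment(["a", "b"], [base[:7] + "-" + base[7:], base[:7] + "A" + base[7:]])
    out = filter_blocks(aln, 0.5, 8, 10, allow_gaps=False)
    assert 7 not in out.kept_columns
    assert "-" not in out.rows[0]


def test_filter_matches_straight_line_reference():
    rng = random.Random(5)
    for _ in range(10):
        aln = _random_alignment(rng)
        out = filter_blocks(aln, 0.5, 8, 10, False)
        expected = gblocks_like_reference(aln.rows, 0.5, 8, 10, False)
        assert out.kept_columns == expected


def test_pi_forced_by_definition():
    aln = Alignment(["a", "b"], ["AAAAAAAAAA", "AACCAAAAAA"])
    assert nucleotide_diversity(aln) == pytest.approx(0.2)
    same = Alignment(["a", "b"], ["ACGTACGTAC"] * 2)
    assert nucleotide_diversity(same) == 0.0


def test_pi_equals_mean_pairwise_p_distance(panel):
    aln = panel.alignments["ND3"]
    pi = nucleotide_diversity(aln)
    ps = [pairwise_distance(a, b, "p")
          for a, b in itertools.combinations(aln.rows, 2)]
    assert pi == pytest.approx(sum(ps) / len(ps), abs=1e-12)


def test_sliding_window_arithmetic_and_gap_handling():
    rows = ["ACGT" * 50, "ACGT" * 50]
    wd = sliding_diversity(Alignment(["a", "b"], rows), window=50, step=25)
    assert len(wd.midpoints) == len(wd.pi)
    assert all(p == 0.0 for p in wd.pi)
    gap = Alignment(["a", "b"], ["----", "ACGT"])
    assert math.isnan(sliding_diversity(gap, window=4, step=4).pi[0])


def test_distances_zero_for_identical_pair():
    for model in ("p", "JC", "K2P"):
        assert pairwise_distance("ACGTACGT", "ACGTACGT", model) == 0.0


def test_jc_closed_form_at_p_03():
    a = "A" * 70 + "C" * 30
    b = "A" * 70 + "G" * 30
    expected = -0.75 * math.log(1 - 4 * 0.3 / 3)  # independent closed form
    assert pairwise_distance(a, b, "JC") == pytest.approx(expected, abs=1e-12)
    assert round(pairwise_distance(a, b, "JC"), 5) == 0.38312


def test_k2p_separates_transitions_and_transversions():
    # 2 transitions (A<->G) and 1 transversion (A<->C) over 100 sites
    a = "A" * 100
    b = "G" * 2 + "C" * 1 + "A" * 97
    P, Q = 0.02, 0.01
    expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
    assert pairwise_distance(a, b, "K2P") == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("model", ["JC", "K2P"])
def test_corrected_distances_reduce_to_p_at_low_divergence(model):
    a = "ACGT" * 250
    b = "CCGT" + "ACGT" * 249          # p = 0.001
    p = pairwise_distance(a, b, "p")
    d = pairwise_distance(a, b, model)
    assert abs(d - p) / p < 0.01


def test_saturated_distance_raises():
    with pytest.raises(SaturationError):
        pairwise_distance("A" * 10, "G" * 10, "JC")


def test_ng86_identical_and_synonymous_pairs():
    rp = ng86("ATGTTATTC", "ATGTTATTC")
    assert rp.Ka == 0.0 and rp.Ks == 0.0 and math.isnan(rp.ratio)
    rp2 = ng86("TTT", "TTC")           # Phe→Phe, purely synonymous
    assert rp2.Nd == 0.0 and rp2.Sd == 1.0
    # in context the synonymous change yields Ks > 0 and Ka = 0
    rp3 = ng86("ATGGCA" * 5 + "TTT", "ATGGCA" * 5 + "TTC")
    assert rp3.Ka == 0.0 and rp3.Ks > 0.0 and math.isnan(rp3.ratio) is False


codon = st.sampled_from([c for c in
                         ("".join(t) for t in itertools.product("ACGT", repeat=3))
                         if c not in ("TAA", "TAG")])


@given(st.lists(st.tuples(codon, codon), min_size=1, max_size=40))
def test_ng86_symmetry_and_site_count_identity(pairs):
    a = "".join(p[0] for p in pairs)
    b = "".join(p[1] for p in pairs)
    ab, ba = ng86(a, b), ng86(b, a)
    assert ab.S == pytest.approx(ba.S, abs=1e-9)
    assert ab.Sd == pytest.approx(ba.Sd, abs=1e-9)
    assert ab.Nd == pytest.approx(ba.Nd, abs=1e-9)
    assert ab.S + ab.N == pytest.approx(3 * ab.n_codons, abs=1e-9)


def test_syn_sites_bounds():
    assert 0.0 <= syn_sites("TTT") <= 3.0
    assert syn_sites("TTA") > syn_sites("TGG")  # Leu codon vs lone Trp codon


def test_omega_recovery_is_monotone():
    """Mean NG86 ω across replicate genes increases with simulated ω."""
    tree = "(A:0.15,B:0.15);"
    means = []
    for k, omega in enumerate((0.05, 0.2, 0.5)):
        vals = []
        for rep in range(12):
            aln = simulate_coding_alignment(tree, n_codons=150, omega=omega,
                                            seed=1000 * k + rep)
            rp = ng86(aln.rows[0], aln.rows[1])
            if not math.isnan(rp.ratio):
                vals.append(rp.ratio)
        means.append(sum(vals) / len(vals))
    assert means[0] < means[1] < means[2]


def test_mean_ng86_over_panel_reflects_gene_constraint(panel):
    cox1 = mean_ng86(panel.alignments["COX1"], "COX1")
    atp8 = mean_ng86(panel.alignments["ATP8"], "ATP8")
    assert cox1.ratio < atp8.ratio
    assert cox1.ratio < 1.0 and atp8.ratio < 1.0
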