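import pytest

from mitocomp import (
    account, extract_gene, locate_control_region, read_genbank,
    reverse_complement, write_genbank,
)
from mitocomp.records import (EmptyAccountError, Feature, GeneLookupError,
                              MitoRecord)
from mitocomp.simulate import SimConfig, simulate_panel

TOY_GENBANK = """\
LOCUS       TOY00001                 100 bp    DNA     circular INV 01-JAN-2000
DEFINITION  toy record.
ACCESSION   TOY00001
VERSION     TOY00001
KEYWORDS    .
SOURCE      toy organism
  ORGANISM  toy organism
FEATURES             Location/Qualifiers
     source          1..100
                     /organism="toy organism"
     CDS             10..18
                     /gene="COI"
     tRNA            complement(20..85)
                     /product="tRNA-Val"
ORIGIN
        1 aaaaaaaaaa cccccccccc gggggggggg tttttttttt aaaaaaaaaa cccccccccc
       61 gggggggggg tttttttttt aaaaaaaaaa cccccccccc
//
"""

WRAP_GENBANK = """\
LOCUS       WRAP0001                 200 bp    DNA     circular INV 01-JAN-2000
DEFINITION  wrap record.
ACCESSION   WRAP0001
VERSION     WRAP0001
KEYWORDS    .
SOURCE      toy organism
  ORGANISM  toy organism
FEATURES             Location/Qualifiers
     source          1..200
                     /organism="toy organism"
     rRNA            join(190..200,1..10)
                     /gene="16S"
ORIGIN
        1 aaaaaaaaaa cccccccccc gggggggggg tttttttttt aaaaaaaaaa cccccccccc
       61 gggggggggg tttttttttt aaaaaaaaaa cccccccccc ggggggggga aaaaaaaaaa
      121 cccccccccc ggggggggga aaaaaaaaaa cccccccccc ggggggggga aaaaaaaaaa
      181 ccccccccga aaaaaaaaaa
//
"""


def test_genbank_coordinates_convert_one_based_inclusive(tmp_path):
    p = tmp_path / "toy.gb"
    p.write_text(TOY_GENBANK)
    rec = read_genbank(p)
    assert rec.length == 100
    cds = rec.get_feature("COX1")          # "COI" mapped via synonym table
    assert (cds.start, cds.end, cds.strand) == (9, 18, 1)
    trna = rec.get_feature("trnV")
    assert (trna.start, trna.end, trna.strand) == (19, 85, -1)


def test_join_across_origin_becomes_wrapping_feature(tmp_path):
    p = tmp_path / "wrap.gb"
    p.write_text(WRAP_GENBANK)
    rec = read_genbank(p)
    f = rec.get_feature("rrnL")            # "16S" synonym
    assert f.wraps_origin
    assert (f.start, f.end) == (189, 10)
    assert f.span(rec.length) == 21


def test_roundtrip_preserves_all_fields(tmp_path, small_panel):
    for rec in small_panel.records[:2]:
        p = tmp_path / f"{rec.accession}.gb"
        write_genbank(rec, p)
        back = read_genbank(p)
        assert back.sequence == rec.sequence
        assert back.accession == rec.accession
        assert back.circular == rec.circular
        a = [(f.label, f.ftype, f.start, f.end, f.strand, f.wraps_origin,
              f.copy_index) for f in rec.features_sorted()]
        b = [(f.label, f.ftype, f.start, f.end, f.strand, f.wraps_origin,
              f.copy_index) for f in back.features_sorted()]
        assert a == b


def test_extract_gene_slice_and_reverse_complement():
    rec = MitoRecord(
        accession="X", organism="toy", sequence="AAAAAAAAAATTTGGGATGCCC",
        features=[Feature("COX1", "PCG", 10, 16, 1),
                  Feature("ND1", "PCG", 16, 22, -1)])
    assert extract_gene(rec, "COX1") == "TTTGGG"
    assert extract_gene(rec, "ND1") == "GGGCAT"
    # involution: reverse complement twice restores the forward slice
    assert reverse_complement(reverse_complement("GGGCAT")) == "GGGCAT"
    with pytest.raises(GeneLookupError):
        extract_gene(rec, "CYTB")


def test_duplicated_trni_requires_copy_index(panel_trni5):
    rec = panel_trni5.records[0]
    with pytest.raises(GeneLookupError):
        extract_gene(rec, "trnI")
    second = extract_gene(rec, "trnI", copy_index=2)
    assert second == extract_gene(rec, "trnI", copy_index=1)  # tandem copies
    f1 = rec.get_feature("trnI", 1)
    f2 = rec.get_feature("trnI", 2)
    assert f1.start != f2.start


def test_account_abutting_and_overlapping_features():
    seq = "A" * 20
    rec = MitoRecord("X", "toy", seq, features=[
        Feature("COX1", "PCG", 0, 10, 1), Feature("COX2", "PCG", 10, 20, 1)])
    acc = account(rec)
    assert acc.igs_list == [] and acc.overlap_list == []
    rec2 = MitoRecord("Y", "toy", seq, features=[
        Feature("ATP8", "PCG", 0, 10, 1), Feature("ATP6", "PCG", 6, 20, 1)])
    acc2 = account(rec2)
    assert acc2.overlap_list == [("ATP8", "ATP6", 4)]


def test_account_empty_record_errors():
    rec = MitoRecord("X", "toy", "ACGT" * 10)
    with pytest.raises(EmptyAccountError):
        account(rec)


def test_planted_long_igs_recovered():
    cfg = SimConfig(seed=3, tree="(A:0.01,B:0.01);",
                    igs_plan={("ND4L", "trnT"): 1212})
    res = simulate_panel(cfg)
    acc = account(res.records[0])
    assert ("ND4L", "trnT", 1212) in acc.igs_list


def test_conserved_overlaps_present_in_panel(panel):
    for rec in panel.records:
        acc = account(rec)
        assert ("ATP8", "ATP6", 4) in acc.overlap_list
        assert ("ND4", "ND4L", 7) in acc.overlap_list


def test_coverage_conservation(panel, panel_trni5):
    """Feature spans minus overlaps plus spacers plus CR tile the circle."""
    for rec in panel.records + panel_trni5.records:
        acc = account(rec)
        L = rec.length
        span = sum(f.span(L) for f in rec.features if f.ftype != "CR")
        total = (span - sum(o[2] for o in acc.overlap_list)
                 + sum(g[2] for g in acc.igs_list) + acc.cr_len)
        assert total == L


def test_genome_counts_and_pcg_fraction(panel):
    for rec in panel.records:
        acc = account(rec)
        assert (acc.n_pcg, acc.n_trna, acc.n_rrna) == (13, 22, 2)
        assert 0.70 < acc.pcg_fraction < 0.74


def test_control_region_located_when_unannotated(panel):
    rec = panel.records[0]
    cr = rec.get_feature("CR")
    stripped = MitoRecord(rec.accession, rec.organism, rec.sequence,
                          features=[f for f in rec.features if f.ftype != "CR"])
    start, end = locate_control_region(stripped)
    assert (start, end) == (cr.start, cr.end)
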