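"""Base composition, A+T content, and AT/GC strand skews.

Skews follow the standard strand-asymmetry definitions
AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed on the
sense (coding) strand for gene-level profiles and on the deposited forward
strand for whole-genome profiles.  IUPAC ambiguity codes are retained in
sequences but excluded from every numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import MitoRecord, extract_gene, feature_sequence, reverse_complement


class UndefinedCompositionError(ValueError):
    """Raised for a sequence with no unambiguous A/C/G/T bases."""


@dataclass
class CompositionProfile:
    region: str
    counts: dict[str, int]
    n_ambiguous: int
    at_content: float      # percent of unambiguous bases
    gc_content: float
    at_skew: float
    gc_skew: float
    at_skew_defined: bool = True
    gc_skew_defined: bool = True

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def composition(seq: str, region: str = "whole") -> CompositionProfile:
    """Composition profile of one sequence.

    A skew whose denominator is zero (e.g. GC-skew of an A/T-only sequence)
    is reported as 0.0 with the corresponding ``*_defined`` flag cleared,
    so degenerate toy inputs do not abort batch runs.
    """
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    n_ambig = sum(1 for c in s if c not in "ACGT-")
    if total == 0:
        raise UndefinedCompositionError(f"no unambiguous bases in region {region!r}")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at, gc = a + t, g + c
    at_skew = (a - t) / at if at else 0.0
    gc_skew = (g - c) / gc if gc else 0.0
    return CompositionProfile(
        region=region, counts=counts, n_ambiguous=n_ambig,
        at_content=100.0 * at / total, gc_content=100.0 * gc / total,
        at_skew=at_skew, gc_skew=gc_skew,
        at_skew_defined=at > 0, gc_skew_defined=gc > 0,
    )


def _codon_positions(sense: str, codon_start: int) -> tuple[str, str, str]:
    body = sense[codon_start - 1:]
    return body[0::3], body[1::3], body[2::3]


def region_compositions(record: MitoRecord, include_cr_in_whole: bool = True
                        ) -> dict[str, CompositionProfile]:
    """Per-region composition profiles for one annotated genome.

    Regions: whole genome (forward strand), all-PCG concatenation on the
    coding strand in genome order, its three codon-position subsets (frame
    anchored at each gene's annotated start, honouring ``codon_start``),
    PCG12, pooled tRNA and rRNA sense strands, CR, and every single gene.
    """
    L = record.length
    profiles: dict[str, CompositionProfile] = {}
    whole_seq = record.sequence
    if not include_cr_in_whole:
        crs = [f for f in record.features if f.ftype == "CR"]
        if crs:
            masked = set()
            for f in crs:
                span = f.span(L)
                for i in range(span):
                    masked.add((f.start + i) % L)
            whole_seq = "".join(b for i, b in enumerate(record.sequence) if i not in masked)
    profiles["whole"] = composition(whole_seq, "whole")

    pcg_parts, pos = [], [[], [], []]
    trna_parts, rrna_parts, cr_parts = [], [], []
    for f in record.features_sorted():
        fwd = feature_sequence(record, f)
        sense = reverse_complement(fwd) if f.strand == -1 else fwd
        key = f.label if f.copy_index == 1 else f"{f.label}.{f.copy_index}"
        if f.ftype in ("PCG", "tRNA", "rRNA", "CR"):
            profiles[key] = composition(sense, key)
        if f.ftype == "PCG":
            pcg_parts.append(sense)
            p1, p2, p3 = _codon_positions(sense, f.codon_start)
            pos[0].append(p1)
            pos[1].append(p2)
            pos[2].append(p3)
        elif f.ftype == "tRNA":
            trna_parts.append(sense)
        elif f.ftype == "rRNA":
            rrna_parts.append(sense)
        elif f.ftype == "CR":
            cr_parts.append(sense)
    if pcg_parts:
        profiles["PCG"] = composition("".join(pcg_parts), "PCG")
        for i, name in enumerate(("PCG-pos1", "PCG-pos2", "PCG-pos3")):
            profiles[name] = composition("".join(pos[i]), name)
        profiles["PCG12"] = composition("".join(pos[0]) + "".join(pos[1]), "PCG12")
    if trna_parts:
        profiles["tRNA"] = composition("".join(trna_parts), "tRNA")
    if rrna_parts:
        profiles["rRNA"] = composition("".join(rrna_parts), "rRNA")
    if cr_parts:
        profiles["CR"] = composition("".join(cr_parts), "CR")
    return profiles


_MATRIX_REGIONS = ("whole", "PCG", "PCG-pos1", "PCG-pos2", "PCG-pos3",
                   "PCG12", "tRNA", "rRNA", "CR")


def panel_matrix(records: list[MitoRecord], include_cr_in_whole: bool = True
                 ) -> pd.DataFrame:
    """Species × (region × statistic) matrix of A+T%, GC%, AT-skew, GC-skew."""
    rows = {}
    for rec in records:
        prof = region_compositions(rec, include_cr_in_whole)
        row = {}
        for region in _MATRIX_REGIONS:
            if region not in prof:
                continue
            p = prof[region]
            row[f"{region}.AT%"] = p.at_content
            row[f"{region}.GC%"] = p.gc_content
            row[f"{region}.AT-skew"] = p.at_skew
            row[f"{region}.GC-skew"] = p.gc_skew
        rows[rec.organism or rec.accession] = row
    return pd.DataFrame.from_dict(rows, orient="index")
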