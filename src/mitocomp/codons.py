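"""Codon usage under the invertebrate mitochondrial genetic code.

Uses NCBI translation table 5 (AGA/AGG → Ser, ATA → Met, TGA → Trp; stops
TAA/TAG).  Handles the non-canonical starts of insect mitogenomes (ATN, GTG,
TTG, and the CGA start of COX1) and incomplete stop codons (a trailing T or
TA completed to TAA by polyadenylation of the mRNA).

RSCU (relative synonymous codon usage) of codon c in a synonymous family F is
``count_c * |F| / sum(count_f for f in F)``; a uniformly used family has RSCU
1.0 everywhere, and the family sums to |F| whenever usage is nonzero.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

TABLE_ID = 5
_TABLE = CodonTable.unambiguous_dna_by_id[TABLE_ID]
STOP_CODONS = frozenset(_TABLE.stop_codons)          # {TAA, TAG}
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)  # 62 sense codons
START_CODONS = frozenset({"ATT", "ATC", "ATA", "ATG", "GTG", "TTG", "CGA"})

FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)


class FrameError(ValueError):
    pass


class InternalStopWarning(UserWarning):
    pass


def translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon; None for stops or ambiguous codons."""
    return CODON_TO_AA.get(codon.upper())


def detect_start_stop(cds: str, downstream_base: str | None = None
                      ) -> tuple[str, str]:
    """Start codon and stop-codon tag of a sense-strand CDS.

    Returns ``(start, stop_tag)`` with ``stop_tag`` one of the complete stops
    ``TAA``/``TAG``, the incomplete ``TA``/``T`` (polyadenylation-completed),
    or ``absent`` when the CDS is a whole number of codons but ends on a sense
    codon.  A CDS whose trailing partial codon is not T/TA is a frame error.
    """
    s = cds.upper()
    if len(s) < 4:
        raise FrameError(f"CDS too short ({len(s)} nt)")
    start = s[:3]
    r = len(s) % 3
    if r == 0:
        last = s[-3:]
        return start, (last if last in STOP_CODONS else "absent")
    tail = s[-r:]
    if tail in ("T", "TA"):
        return start, tail
    raise FrameError(
        f"length ≡ {r} (mod 3) but trailing {tail!r} is not an incomplete stop")


def trim_cds(cds: str) -> tuple[str, str, str]:
    """Split a sense CDS into (start codon, in-frame body, stop tag).

    The body excludes the start codon and any complete or incomplete stop.
    """
    start, stop = detect_start_stop(cds)
    s = cds.upper()
    if stop in ("T", "TA"):
        body = s[3:len(s) - len(stop)]
    elif stop in STOP_CODONS:
        body = s[3:-3]
    else:
        body = s[3:]
    return start, body, stop


@dataclass
class CodonProfile:
    starts: dict[str, str] = field(default_factory=dict)   # gene → start codon
    stops: dict[str, str] = field(default_factory=dict)    # gene → stop tag
    codon_counts: Counter = field(default_factory=Counter)
    aa_counts: Counter = field(default_factory=Counter)
    total_aa: int = 0
    n_ambiguous_codons: int = 0
    internal_stops: list[tuple[str, int, str]] = field(default_factory=list)
    rscu: dict[str, float] = field(default_factory=dict)
    empty_families: list[str] = field(default_factory=list)


def codon_counts(cds_map: dict[str, str], include_start: bool = False,
                 include_stop: bool = False) -> CodonProfile:
    """Pooled codon usage over a set of sense-strand CDSs (gene → sequence).

    Start codons and complete stop codons are excluded from usage counts by
    default (non-ATN starts such as CGA or TTG would otherwise distort
    rare-codon counts); both can be included for sensitivity analysis.
    Codons containing ambiguity codes are dropped and tallied separately;
    in-frame internal stops are reported as warnings, not errors.
    """
    prof = CodonProfile()
    for gene, cds in cds_map.items():
        start, body, stop = trim_cds(cds)
        prof.starts[gene] = start
        prof.stops[gene] = stop
        usable = (start if include_start else "") + body \
            + (stop if include_stop and stop in STOP_CODONS else "")
        for i in range(0, len(usable) - len(usable) % 3, 3):
            codon = usable[i:i + 3]
            if any(b not in "ACGT" for b in codon):
                prof.n_ambiguous_codons += 1
                continue
            if codon in STOP_CODONS:
                prof.internal_stops.append((gene, i, codon))
                warnings.warn(f"in-frame stop {codon} at {gene}:{i} "
                              "(possible misannotation)", InternalStopWarning,
                              stacklevel=2)
                continue
            prof.codon_counts[codon] += 1
            prof.aa_counts[CODON_TO_AA[codon]] += 1
    prof.total_aa = sum(prof.aa_counts.values())
    prof.rscu = rscu(prof.codon_counts)
    prof.empty_families = [aa for aa, fam in FAMILIES.items()
                           if sum(prof.codon_counts[c] for c in fam) == 0]
    return prof


def rscu(counts: Counter | dict[str, int]) -> dict[str, float]:
    """RSCU for every sense codon; families with zero usage get all-zero RSCU."""
    out: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in fam)
        k = len(fam)
        for c in fam:
            out[c] = (counts.get(c, 0) * k / total) if total else 0.0
    return out


def profile_frame(prof: CodonProfile) -> pd.DataFrame:
    """64-row table of codon, amino acid, count and RSCU (stops count-only)."""
    rows = []
    bases = "TCAG"
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                aa = CODON_TO_AA.get(codon, "*")
                rows.append({
                    "codon": codon,
                    "amino_acid": aa,
                    "count": prof.codon_counts.get(codon, 0),
                    "rscu": prof.rscu.get(codon, float("nan")),
                })
    return pd.DataFrame(rows)
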