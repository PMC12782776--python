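"""Annotated circular mitogenomes: GenBank I/O, feature extraction, structural accounting.

A mitogenome is modelled as a circular DNA sequence plus an ordered feature
table over a controlled 38-label vocabulary (13 protein-coding genes, 22
tRNAs, 2 rRNAs, and the control region).  Internal coordinates are 0-based
half-open on the deposited forward (J, majority) strand; GenBank I/O converts
exactly to and from 1-based inclusive coordinates.  Features may wrap the
circular origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

PCG_LABELS = (
    "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)
TRNA_LABELS = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)
RRNA_LABELS = ("rrnL", "rrnS")
CONTROLLED_LABELS = frozenset(PCG_LABELS) | frozenset(TRNA_LABELS) | frozenset(RRNA_LABELS) | {"CR"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenBankParseError(ValueError):
    pass


class FeatureBoundsError(ValueError):
    pass


class GeneLookupError(KeyError):
    pass


class EmptyAccountError(ValueError):
    pass


def _load_synonyms() -> dict[str, str]:
    table = {}
    text = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        syn, canon = line.split("\t")
        table[syn.strip().lower()] = canon.strip()
    for label in CONTROLLED_LABELS:
        table.setdefault(label.lower(), label)
    return table


SYNONYMS = _load_synonyms()


def canonical_label(name: str) -> str:
    """Map an annotation name to the controlled vocabulary; unknown → 'other'."""
    key = " ".join(name.strip().lower().replace("_", " ").split())
    return SYNONYMS.get(key, SYNONYMS.get(key.replace("-", " "), "other"))


def ftype_of(label: str) -> str:
    if label in PCG_LABELS:
        return "PCG"
    if label in TRNA_LABELS:
        return "tRNA"
    if label in RRNA_LABELS:
        return "rRNA"
    if label == "CR":
        return "CR"
    return "other"


@dataclass
class Feature:
    """One annotated span.  ``start``/``end`` are 0-based half-open on the
    forward strand; a feature wrapping the circular origin has ``wraps_origin``
    set, with ``start`` near the end of the sequence and ``end`` the length of
    the prefix it covers."""

    label: str
    ftype: str
    start: int
    end: int
    strand: int = 1
    wraps_origin: bool = False
    copy_index: int = 1
    codon_start: int = 1
    incomplete_stop: bool = False

    def span(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start

    def linear_start(self) -> int:
        return self.start


@dataclass
class MitoRecord:
    accession: str
    organism: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        L = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < L) or not (0 < f.end <= L):
                raise FeatureBoundsError(
                    f"{f.label}: [{f.start},{f.end}) outside sequence of length {L}")
            if f.wraps_origin and not self.circular:
                raise FeatureBoundsError(f"{f.label} wraps origin of a linear record")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_sorted(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: (f.start, -f.span(self.length)))

    def get_feature(self, label: str, copy_index: int | None = None) -> Feature:
        hits = [f for f in self.features if f.label == label]
        if not hits:
            available = sorted({f.label for f in self.features})
            raise GeneLookupError(f"{label!r} not annotated; available: {available}")
        if len(hits) > 1:
            if copy_index is None:
                raise GeneLookupError(
                    f"{label!r} has {len(hits)} copies; copy_index required")
            hits = [f for f in hits if f.copy_index == copy_index]
            if not hits:
                raise GeneLookupError(f"{label!r} copy {copy_index} absent")
        return hits[0]


def feature_sequence(record: MitoRecord, feature: Feature) -> str:
    """Forward-strand bases under a feature, honouring origin wrap."""
    if feature.wraps_origin:
        fwd = record.sequence[feature.start:] + record.sequence[:feature.end]
    else:
        fwd = record.sequence[feature.start:feature.end]
    return fwd


def extract_gene(record: MitoRecord, label: str, copy_index: int | None = None) -> str:
    """Coding/sense-strand sequence of a gene (reverse-complemented for −)."""
    f = record.get_feature(label, copy_index)
    fwd = feature_sequence(record, f)
    return reverse_complement(fwd) if f.strand == -1 else fwd


# ---------------------------------------------------------------------------
# GenBank I/O

_BIO_TYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
              "D-loop": "CR", "misc_feature": "other"}


def _name_of(bf: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in bf.qualifiers:
            return str(bf.qualifiers[key][0])
    return ""


def read_genbank(path) -> MitoRecord:
    """Read a single-entry GenBank flat file into a :class:`MitoRecord`.

    GenBank's 1-based inclusive coordinates become 0-based half-open; a
    ``join`` across the origin of a circular sequence becomes one feature
    with ``wraps_origin=True``.  Names are mapped through the synonym table;
    unmappable features become ``other``.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise GenBankParseError(f"cannot parse {path}: {exc}") from exc
    L = len(rec.seq)
    circular = rec.annotations.get("topology", "circular") == "circular"
    feats: list[Feature] = []
    for bf in rec.features:
        if bf.type not in _BIO_TYPES:
            continue
        label = canonical_label(_name_of(bf))
        if bf.type == "D-loop":
            label = "CR"
        ftype = ftype_of(label)
        if ftype == "other" and bf.type in ("CDS", "tRNA", "rRNA"):
            ftype = _BIO_TYPES[bf.type]
        loc = bf.location
        strand = -1 if (loc.strand == -1) else 1
        wraps = False
        if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
            p1, p2 = loc.parts
            if int(p1.end) == L and int(p2.start) == 0:
                start, end, wraps = int(p1.start), int(p2.end), True
            else:
                start, end = int(loc.start), int(loc.end)
        else:
            start, end = int(loc.start), int(loc.end)
        if end > L or start < 0:
            raise FeatureBoundsError(
                f"{label}: GenBank location {loc} outside sequence length {L}")
        codon_start = int(bf.qualifiers.get("codon_start", ["1"])[0])
        incomplete = any("incomplete" in str(v).lower()
                         for v in bf.qualifiers.get("note", []))
        feats.append(Feature(label=label, ftype=ftype, start=start, end=end,
                             strand=strand, wraps_origin=wraps,
                             codon_start=codon_start, incomplete_stop=incomplete))
    _assign_copy_indices(feats)
    organism = rec.annotations.get("organism", rec.description or "")
    return MitoRecord(accession=rec.id or rec.name, organism=organism,
                      sequence=str(rec.seq).upper(), circular=circular,
                      features=feats)


def _assign_copy_indices(feats: list[Feature]) -> None:
    seen: dict[str, int] = {}
    for f in feats:
        seen[f.label] = seen.get(f.label, 0) + 1
        f.copy_index = seen[f.label]


def write_genbank(record: MitoRecord, path) -> None:
    """Write a MitoRecord as a single GenBank flat file (round-trip exact)."""
    seq_rec = SeqRecord(Seq(record.sequence), id=record.accession,
                        name=record.accession.split(".")[0][:16],
                        description=f"{record.organism} mitochondrion, complete genome")
    seq_rec.annotations["molecule_type"] = "DNA"
    seq_rec.annotations["topology"] = "circular" if record.circular else "linear"
    seq_rec.annotations["organism"] = record.organism
    seq_rec.annotations["date"] = "01-JAN-2000"  # fixed for byte-identical output
    L = record.length
    src = SeqFeature(SimpleLocation(0, L, strand=1), type="source",
                     qualifiers={"organism": [record.organism]})
    seq_rec.features.append(src)
    for f in record.features:
        if f.wraps_origin:
            loc = CompoundLocation([SimpleLocation(f.start, L, strand=f.strand),
                                    SimpleLocation(0, f.end, strand=f.strand)])
        else:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        if f.ftype == "PCG":
            btype = "CDS"
        elif f.ftype in ("tRNA", "rRNA"):
            btype = f.ftype
        elif f.ftype == "CR":
            btype = "D-loop"
        else:
            btype = "misc_feature"
        quals = {"gene": [f.label]}
        if f.ftype == "PCG":
            quals["codon_start"] = [str(f.codon_start)]
            if f.incomplete_stop:
                quals["note"] = ["incomplete stop codon"]
        seq_rec.features.append(SeqFeature(loc, type=btype, qualifiers=quals))
    SeqIO.write([seq_rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Structural accounting

@dataclass
class GenomeAccount:
    accession: str
    genome_length: int
    n_pcg: int
    n_trna: int
    n_rrna: int
    total_pcg_len: int
    pcg_fraction: float
    cr_len: int
    igs_list: list[tuple[str, str, int]]
    overlap_list: list[tuple[str, str, int]]
    per_gene_lengths: dict[str, int]

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["igs_list"] = [list(t) for t in self.igs_list]
        d["overlap_list"] = [list(t) for t in self.overlap_list]
        return json.dumps(d, indent=2)


def account(record: MitoRecord) -> GenomeAccount:
    """Structural accounting: gene counts and lengths, PCG fraction, control
    region length, intergenic spacers (IGS) and overlaps between consecutive
    features on the circle.

    IGS are maximal unannotated gaps between consecutive annotated features;
    overlaps are positive intersections of consecutive features.  The identity
    Σ(non-CR spans) − Σ(overlaps) + Σ(IGS) + CR = genome length holds whenever
    the annotation tiles the circle.
    """
    feats = [f for f in record.features if f.ftype in ("PCG", "tRNA", "rRNA", "CR")]
    if not feats:
        raise EmptyAccountError(f"{record.accession}: no annotated features")
    L = record.length
    feats = sorted(feats, key=lambda f: f.start)
    igs: list[tuple[str, str, int]] = []
    overlaps: list[tuple[str, str, int]] = []
    n = len(feats)
    for i in range(n):
        cur, nxt = feats[i], feats[(i + 1) % n]
        cur_end = cur.start + cur.span(L)
        nxt_start = nxt.start + (L if i == n - 1 else 0)
        gap = nxt_start - cur_end
        if gap >= 1:
            igs.append((cur.label, nxt.label, gap))
        elif gap <= -1:
            overlaps.append((cur.label, nxt.label, -gap))
    per_gene: dict[str, int] = {}
    for f in feats:
        key = f.label if f.copy_index == 1 else f"{f.label}.{f.copy_index}"
        per_gene[key] = f.span(L)
    total_pcg = sum(f.span(L) for f in feats if f.ftype == "PCG")
    cr_len = sum(f.span(L) for f in feats if f.ftype == "CR")
    return GenomeAccount(
        accession=record.accession,
        genome_length=L,
        n_pcg=sum(1 for f in feats if f.ftype == "PCG"),
        n_trna=sum(1 for f in feats if f.ftype == "tRNA"),
        n_rrna=sum(1 for f in feats if f.ftype == "rRNA"),
        total_pcg_len=total_pcg,
        pcg_fraction=total_pcg / L,
        cr_len=cr_len,
        igs_list=igs,
        overlap_list=overlaps,
        per_gene_lengths=per_gene,
    )


def locate_control_region(record: MitoRecord, strategy: str = "auto") -> tuple[int, int]:
    """Locate the CR as forward-strand ``(start, end)`` (end may exceed length
    for a wrap).  ``flanked``: region between rrnS and trnI (ephemerellid
    arrangement); ``longest``: longest unannotated stretch; ``auto`` tries
    ``flanked`` first."""
    if strategy not in ("auto", "flanked", "longest"):
        raise ValueError(f"unknown strategy {strategy!r}")
    L = record.length
    feats = [f for f in record.features_sorted() if f.ftype != "CR"]
    if not feats:
        raise EmptyAccountError("no annotated features to locate the CR against")
    gaps = []  # (left feature, right feature, start, end)
    n = len(feats)
    for i in range(n):
        cur, nxt = feats[i], feats[(i + 1) % n]
        cur_end = cur.start + cur.span(L)
        gap = (nxt.start + (L if i == n - 1 else 0)) - cur_end
        if gap >= 1:
            gaps.append((cur, nxt, cur_end % L, cur_end % L + gap))
    if not gaps:
        raise EmptyAccountError("annotation leaves no unannotated region")
    flanked = [g for g in gaps if {g[0].label, g[1].label} & {"trnI", "rrnS"}]
    if strategy == "flanked" and not flanked:
        raise GeneLookupError("no unannotated region flanked by rrnS/trnI")
    pool = flanked if (flanked and strategy in ("auto", "flanked")) else gaps
    best = max(pool, key=lambda g: g[3] - g[2])
    return best[2], best[3]


def write_gene_fasta(records: Iterable[MitoRecord], label: str, path) -> None:
    """FASTA export of one gene across records, header accession|label|strand."""
    with open(path, "w") as fh:
        for rec in records:
            f = rec.get_feature(label)
            strand = "+" if f.strand == 1 else "-"
            fh.write(f">{rec.accession}|{label}|{strand}\n")
            fh.write(extract_gene(rec, label) + "\n")
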