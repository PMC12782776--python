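"""Synthetic annotated mitogenomes with controllable evolutionary structure.

Generates 37-gene circular mitogenomes (13 PCGs, 22 tRNAs, 2 rRNAs, one
control region) along a known tree so that every downstream analysis is
testable without downloads.  Coding sequences evolve by a site-wise
accept/reject process: nucleotide changes are proposed with kappa-weighted
transition/transversion rates and position-specific base-composition bias,
changes creating stop codons are rejected, and nonsynonymous changes are
accepted with probability ω.  This is a deliberately simple,
non-time-reversible approximation of a codon model — adequate for
parameter-ordering and recovery tests, not for likelihood work.  tRNAs,
rRNAs and the CR evolve neutrally.

Genomes are assembled on either the ancestral insect gene order or the
ephemerellid order (trnI inverted and translocated between rrnS and the CR,
optionally in multiple tandem copies), with planted CR tandem repeats,
intergenic spacers, and the conserved ATP8–ATP6 (4 bp) and ND4–ND4L (7 bp)
overlaps.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .codons import CODON_TO_AA, STOP_CODONS
from .divergence import Alignment
from .gene_order import ANCESTRAL_INSECT_ORDER, EPHEMERELLID_ORDER
from .records import (Feature, MitoRecord, ftype_of, reverse_complement,
                      write_genbank)

PCGS = ("ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
        "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1")

# typical insect mitochondrial PCG lengths (codons, excluding start and stop)
DEFAULT_GENE_CODONS = {
    "ND2": 341, "COX1": 512, "COX2": 227, "ATP8": 52, "ATP6": 224,
    "COX3": 263, "ND3": 117, "ND5": 578, "ND4": 447, "ND4L": 96,
    "ND6": 174, "CYTB": 380, "ND1": 314,
}

# per-gene ω defaults mirroring the strong purifying selection of mitogenomes,
# with COX1/COX2 most constrained and ATP8/ND6/ND2 most relaxed
DEFAULT_OMEGA = {
    "ND2": 0.20, "COX1": 0.02, "COX2": 0.04, "ATP8": 0.33, "ATP6": 0.12,
    "COX3": 0.06, "ND3": 0.15, "ND5": 0.18, "ND4": 0.16, "ND4L": 0.20,
    "ND6": 0.28, "CYTB": 0.08, "ND1": 0.10,
}

DEFAULT_STARTS = {
    "COX1": "CGA", "ND6": "TTG", "ND3": "GTG", "ND5": "GTG", "ATP6": "ATA",
}

# frozen body codons engineering the conserved inter-gene overlaps:
# ATP8(+) last 4 nt "ATAA" == ATP6(+) first 4 nt; ND4(−) first 7 sense nt
# "ATGTTAT" == ND4L(−) last 7 sense nt (incomplete stop T).
_FROZEN_BODY = {
    "ATP8": {-1: "ATA"},
    "ATP6": {0: "ATT"},
    "ND4": {0: "TTA", 1: "TAT"},
    "ND4L": {-2: "ATG", -1: "TTA"},
}
INCOMPLETE_STOP_GENES = {"ND4L": "T", "COX2": "T"}

DEFAULT_OVERLAPS = {("ATP8", "ATP6"): 4, ("ND4", "ND4L"): 7}

# moderately A+T-biased defaults in the ephemerellid range (~65% A+T overall)
DEFAULT_COMP = (
    {"A": 0.28, "C": 0.20, "G": 0.25, "T": 0.27},   # codon position 1
    {"A": 0.20, "C": 0.25, "G": 0.15, "T": 0.40},   # codon position 2
    {"A": 0.40, "C": 0.12, "G": 0.08, "T": 0.40},   # codon position 3
)
DEFAULT_RNA_COMP = {"A": 0.34, "C": 0.17, "G": 0.17, "T": 0.32}

DEFAULT_TREE = (
    "(((Drunella_ishiyamana:0.10,((Torleya_nepalica:0.04,Torleya_tumiforceps:0.04)"
    ":0.02,(Torleya_grandiforceps:0.04,Torleya_mikhaili:0.04):0.02):0.04):0.02,"
    "(Cincticostella_femorata:0.05,(Cincticostella_gosei:0.04,"
    "Cincticostella_fusca:0.04):0.02):0.05):0.02,((Serratella_ignita:0.05,"
    "Serratella_zapekinae:0.05):0.03,(Teloganopsis_jinghongensis:0.06,"
    "Uracanthella_punctisetae:0.06):0.03):0.03);"
)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    tree: str = DEFAULT_TREE
    tree_scale: float = 1.0
    gene_codons: dict = field(default_factory=lambda: dict(DEFAULT_GENE_CODONS))
    omega: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    kappa: float = 4.0
    comp_targets: tuple = DEFAULT_COMP
    rna_comp: dict = field(default_factory=lambda: dict(DEFAULT_RNA_COMP))
    order_template: str = "ephemerellid"   # or "ancestral"
    trni_copies: int = 1
    trna_length: int = 66
    rrnl_length: int = 1250
    rrns_length: int = 800
    cr_length: int = 780
    cr_repeat_motif: str = "TTATAAATA"
    cr_repeat_copies: int = 4
    igs_plan: dict = field(default_factory=lambda: {
        ("ND4L", "trnT"): 30, ("trnS2", "ND1"): 17,
        ("trnE", "trnF"): 4, ("COX3", "trnG"): 1, ("trnY", "COX1"): 3,
    })

    def validate(self) -> None:
        if any(w <= 0 for w in self.omega.values()):
            raise SimConfigError("ω must be positive")
        for row in self.comp_targets:
            if abs(sum(row.values()) - 1.0) > 1e-6:
                raise SimConfigError("composition targets must sum to 1 per position")
        if self.order_template not in ("ancestral", "ephemerellid"):
            raise SimConfigError(f"unknown order template {self.order_template!r}")
        if self.trni_copies < 1:
            raise SimConfigError("trni_copies must be ≥ 1")
        # third position must leave a non-stop completion for a TA prefix
        p3 = self.comp_targets[2]
        if (self.comp_targets[0].get("T", 0) > 0 and self.comp_targets[1].get("A", 0) > 0
                and p3.get("C", 0) + p3.get("T", 0) <= 0):
            raise SimConfigError("unreachable composition: TA_ codons would all be stops")


# ---------------------------------------------------------------------------
# Elementary sequence processes

def _sample_bases(rng: np.random.Generator, comp: dict, n: int) -> str:
    probs = np.array([comp.get(b, 0.0) for b in BASES])
    probs = probs / probs.sum()
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=probs))


def _sample_codon(rng: np.random.Generator, comp_targets) -> str:
    b1 = _sample_bases(rng, comp_targets[0], 1)
    b2 = _sample_bases(rng, comp_targets[1], 1)
    p3 = dict(comp_targets[2])
    if b1 + b2 == "TA":   # exclude stop-completing third bases, renormalize
        p3.pop("A", None)
        p3.pop("G", None)
    b3 = _sample_bases(rng, p3, 1)
    return b1 + b2 + b3


def _mutate_neutral(seq: str, t: float, comp: dict, kappa: float,
                    rng: np.random.Generator) -> str:
    s = list(seq)
    L = len(s)
    for _ in range(rng.poisson(t * L)):
        i = int(rng.integers(L))
        cur = s[i]
        weights = np.array([
            0.0 if b == cur else comp.get(b, 0.0) * (kappa if (cur, b) in _TRANSITION else 1.0)
            for b in BASES])
        if weights.sum() <= 0:
            continue
        s[i] = BASES[int(rng.choice(4, p=weights / weights.sum()))]
    return "".join(s)


def _mutate_coding(body: str, t: float, omega: float, kappa: float,
                   comp_targets, frozen_codons: set[int],
                   rng: np.random.Generator) -> str:
    s = list(body)
    L = len(s)
    for _ in range(rng.poisson(t * L)):
        site = int(rng.integers(L))
        ci = site // 3
        if ci in frozen_codons:
            continue
        pos = site % 3
        cur = s[site]
        comp = comp_targets[pos]
        weights = np.array([
            0.0 if b == cur else comp.get(b, 0.0) * (kappa if (cur, b) in _TRANSITION else 1.0)
            for b in BASES])
        if weights.sum() <= 0:
            continue
        new = BASES[int(rng.choice(4, p=weights / weights.sum()))]
        codon = "".join(s[3 * ci:3 * ci + 3])
        new_codon = codon[:pos] + new + codon[pos + 1:]
        if new_codon in STOP_CODONS:
            continue
        if CODON_TO_AA[new_codon] != CODON_TO_AA[codon]:
            if rng.random() >= omega:
                continue
        s[site] = new
    return "".join(s)


# ---------------------------------------------------------------------------
# Tandem repeats

def plant_tandem_repeat(cr: str, motif: str, copies: int,
                        position: int | None = None) -> str:
    """Insert ``copies`` tandem copies of ``motif`` into a sequence (at its
    midpoint by default)."""
    if not motif:
        raise ValueError("empty motif")
    if copies < 2:
        raise ValueError("copies must be ≥ 2")
    pos = len(cr) // 2 if position is None else position
    return cr[:pos] + motif * copies + cr[pos:]


def detect_tandem_repeats(seq: str, max_period: int = 12,
                          min_copies: float = 2.0, min_len: int = 24
                          ) -> list[tuple[str, int, float, tuple[int, int]]]:
    """Period-scan tandem repeat detector.

    For each period p ≤ ``max_period`` it finds maximal runs of positions
    with ``seq[i] == seq[i-p]`` and reports runs reaching ``min_copies``
    copies and ``min_len`` total span as ``(motif, period, copies, (start,
    end))``.  A planted ``motif × copies`` block is always re-detected when
    the thresholds admit it (plant → detect round trip).
    """
    n = len(seq)
    if max_period > n // 2:
        warnings.warn(f"max_period {max_period} clamped to {n // 2}")
        max_period = n // 2
    hits = []
    for p in range(1, max_period + 1):
        i = p
        while i < n:
            if seq[i] == seq[i - p]:
                j = i
                while j < n and seq[j] == seq[j - p]:
                    j += 1
                span = (j - i) + p
                copies = span / p
                start = i - p
                if copies >= min_copies and span >= min_len:
                    hits.append((seq[start:start + p], p, copies, (start, start + span)))
                i = j + 1
            else:
                i += 1
    return hits


# ---------------------------------------------------------------------------
# Panel simulation

@dataclass
class PanelResult:
    records: list[MitoRecord]
    alignments: dict[str, Alignment]   # gene → ungapped true alignment
    tree: dendropy.Tree
    manifest: dict


def _frozen_codon_indices(gene: str, n_codons: int) -> set[int]:
    out = set()
    for rel in _FROZEN_BODY.get(gene, {}):
        out.add(rel % n_codons)
    return out


def _root_body(gene: str, n_codons: int, cfg: SimConfig,
               rng: np.random.Generator) -> str:
    codons = [_sample_codon(rng, cfg.comp_targets) for _ in range(n_codons)]
    for rel, codon in _FROZEN_BODY.get(gene, {}).items():
        codons[rel % n_codons] = codon
    return "".join(codons)


def _evolve_along_tree(tree: dendropy.Tree, root_seq: str, mutate, seed_key) -> dict[str, str]:
    """Generic DFS evolution; ``mutate(seq, t, rng)``; returns taxon → sequence."""
    out: dict[str, str] = {}
    counter = [0]

    def walk(node, seq):
        for child in node.child_nodes():
            counter[0] += 1
            t = child.edge.length or 0.0
            rng = np.random.default_rng([*seed_key, counter[0]])
            child_seq = mutate(seq, t, rng)
            if child.is_leaf():
                out[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.seed_node, root_seq)
    return out


def template_items(cfg: SimConfig) -> list[tuple[str, int]]:
    base = (ANCESTRAL_INSECT_ORDER if cfg.order_template == "ancestral"
            else EPHEMERELLID_ORDER).items
    items = list(base)
    if cfg.order_template == "ephemerellid" and cfg.trni_copies > 1:
        # tandem trnI copies between rrnS and the CR
        items = items + [("trnI", -1)] * (cfg.trni_copies - 1)
    return items


def simulate_panel(cfg: SimConfig) -> PanelResult:
    """Simulate a panel of annotated mitogenomes along ``cfg.tree``.

    Returns assembled records, the true (ungapped) per-gene alignments on the
    sense strand, the generating tree, and a manifest of true parameters.
    """
    cfg.validate()
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= cfg.tree_scale
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]

    gene_list = list(PCGS) + [lab for lab, _ in ANCESTRAL_INSECT_ORDER.items
                              if ftype_of(lab) == "tRNA"] + ["rrnL", "rrnS", "CR"]
    rna_lengths = {"rrnL": cfg.rrnl_length, "rrnS": cfg.rrns_length, "CR": cfg.cr_length}

    sequences: dict[str, dict[str, str]] = {}   # gene → taxon → sense sequence
    for gi, gene in enumerate(gene_list):
        root_rng = np.random.default_rng([cfg.seed, gi, 999_983])
        if gene in PCGS:
            n_cod = cfg.gene_codons[gene]
            frozen = _frozen_codon_indices(gene, n_cod)
            root = _root_body(gene, n_cod, cfg, root_rng)
            omega = cfg.omega[gene]
            mut = lambda s, t, rng, om=omega, fr=frozen: _mutate_coding(
                s, t, om, cfg.kappa, cfg.comp_targets, fr, rng)
        else:
            L = rna_lengths.get(gene, cfg.trna_length)
            root = _sample_bases(root_rng, cfg.rna_comp, L)
            mut = lambda s, t, rng: _mutate_neutral(s, t, cfg.rna_comp, cfg.kappa, rng)
        sequences[gene] = _evolve_along_tree(tree, root, mut, (cfg.seed, gi))

    # assemble sense sequences with start/stop codons and planted CR repeats
    full_sense: dict[str, dict[str, str]] = {g: {} for g in gene_list}
    for gene in gene_list:
        for taxon in taxa:
            body = sequences[gene][taxon]
            if gene in PCGS:
                start = DEFAULT_STARTS.get(gene, "ATG")
                stop = INCOMPLETE_STOP_GENES.get(gene, "TAA")
                full_sense[gene][taxon] = start + body + stop
            elif gene == "CR":
                full_sense[gene][taxon] = plant_tandem_repeat(
                    body, cfg.cr_repeat_motif, cfg.cr_repeat_copies)
            else:
                full_sense[gene][taxon] = body

    items = template_items(cfg)
    records = []
    for ti, taxon in enumerate(taxa):
        igs_rng = np.random.default_rng([cfg.seed, 777_001, ti])
        seq_parts: list[str] = []
        pos = 0
        feats: list[Feature] = []
        prev_label = items[-1][0]
        for label, sign in items:
            igs_len = cfg.igs_plan.get((prev_label, label), 0)
            if igs_len:
                seq_parts.append(_sample_bases(igs_rng, cfg.rna_comp, igs_len))
                pos += igs_len
            sense = full_sense[label][taxon]
            fwd = reverse_complement(sense) if sign == -1 else sense
            o = DEFAULT_OVERLAPS.get((prev_label, label), 0) if seq_parts else 0
            if o:
                tail = "".join(seq_parts)[-o:]
                assert tail == fwd[:o], f"inconsistent {prev_label}–{label} overlap"
                start = pos - o
                seq_parts.append(fwd[o:])
            else:
                start = pos
                seq_parts.append(fwd)
            pos = start + len(fwd)
            feats.append(Feature(
                label=label, ftype=ftype_of(label), start=start, end=pos,
                strand=sign, incomplete_stop=label in INCOMPLETE_STOP_GENES))
            prev_label = label
        seen: dict[str, int] = {}
        for f in feats:
            seen[f.label] = seen.get(f.label, 0) + 1
            f.copy_index = seen[f.label]
        rec = MitoRecord(accession=f"SIM{ti + 1:03d}",
                         organism=taxon.replace("_", " "),
                         sequence="".join(seq_parts), circular=True,
                         features=feats)
        records.append(rec)

    alignments = {}
    for gene in gene_list:
        if gene == "CR":
            continue
        is_codon = gene in PCGS
        if is_codon:
            # start codon + body; stop codons stripped so rows are sense codons
            start = DEFAULT_STARTS.get(gene, "ATG")
            rows = [start + sequences[gene][t] for t in taxa]
        else:
            rows = [full_sense[gene][t] for t in taxa]
        alignments[gene] = Alignment(list(taxa), rows, is_codon=is_codon)

    manifest = {
        "config": _config_dict(cfg),
        "taxa": taxa,
        "genome_lengths": {r.accession: r.length for r in records},
        "gene_order": [("-" if s < 0 else "") + lab for lab, s in items],
    }
    return PanelResult(records=records, alignments=alignments, tree=tree,
                       manifest=manifest)


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["igs_plan"] = {f"{a}-{b}": v for (a, b), v in cfg.igs_plan.items()}
    return d


def simulate_coding_alignment(tree_newick: str, n_codons: int, omega: float,
                              kappa: float = 4.0, comp_targets=DEFAULT_COMP,
                              seed: int = 0) -> Alignment:
    """Evolve a single coding gene along a tree; returns the true codon
    alignment (no start/stop codons).  Used for rate-recovery experiments."""
    tree = dendropy.Tree.get(data=tree_newick, schema="newick",
                             preserve_underscores=True)
    rng = np.random.default_rng([seed, 424_243])
    root = "".join(_sample_codon(rng, comp_targets) for _ in range(n_codons))
    mut = lambda s, t, r: _mutate_coding(s, t, omega, kappa, comp_targets, set(), r)
    leaf_seqs = _evolve_along_tree(tree, root, mut, (seed, 31_337))
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    return Alignment(taxa, [leaf_seqs[t] for t in taxa], is_codon=True)


def write_panel(result: PanelResult, outdir) -> None:
    """Write GenBank records, per-gene FASTA alignments, the true tree, and
    the parameter manifest under ``outdir``."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in result.records:
        write_genbank(rec, out / f"{rec.accession}.gb")
    for gene, aln in result.alignments.items():
        with open(out / f"{gene}.aln.fasta", "w") as fh:
            for name, row in zip(aln.names, aln.rows):
                fh.write(f">{name}\n{row}\n")
    with open(out / "true_tree.nwk", "w") as fh:
        fh.write(result.tree.as_string(schema="newick"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
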