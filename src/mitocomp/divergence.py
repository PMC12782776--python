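"""Alignment filtering, nucleotide diversity, genetic distances, and NG86 Ka/Ks.

Nucleotide diversity is the average pairwise proportion of differing sites
(π = Σ_{i<j} p_ij / C(n,2)), computed after complete deletion of columns
containing gaps or ambiguity — the DnaSP convention, without the n/(n−1)
correction.  Pairwise distances offer p, Jukes–Cantor, and Kimura 2-parameter
corrections.  Ka/Ks follows Nei & Gojobori's counting method: per-codon
synonymous site fractions averaged over the two sequences, multi-hit codons
averaged over all shortest mutational pathways that avoid stop codons, and a
Jukes–Cantor correction of the proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import SeqIO

from .codons import CODON_TO_AA, STOP_CODONS

GAP_CHARS = set("-.")
UNAMBIGUOUS = set("ACGT")
PURINES = set("AG")


class SaturationError(ValueError):
    pass


@dataclass
class Alignment:
    names: list[str]
    rows: list[str]
    is_codon: bool = False
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows of unequal length")
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]
        if self.is_codon and self.n_cols % 3 != 0:
            raise ValueError("codon alignment length not a multiple of 3")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def columns(self):
        return zip(*self.rows)

    def take_columns(self, cols: list[int]) -> "Alignment":
        rows = ["".join(r[i] for i in cols) for r in self.rows]
        return Alignment(list(self.names), rows, is_codon=False)

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


def read_fasta_alignment(path, is_codon: bool = False) -> Alignment:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(names, rows, is_codon=is_codon)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Conserved-block filtering (Gblocks-like)

def filter_blocks(aln: Alignment, min_conserved_frac: float = 0.5,
                  max_nonconserved_run: int = 8, min_block_len: int = 10,
                  allow_gaps: bool = False) -> Alignment:
    """Keep conserved column blocks, in the spirit of Gblocks.

    A column is conserved when (with ``allow_gaps=False``) it contains no gap
    characters and its most frequent unambiguous residue reaches
    ``min_conserved_frac`` of the rows.  Runs of non-conserved columns longer
    than ``max_nonconserved_run`` separate blocks; shorter internal runs are
    retained.  Blocks are trimmed to conserved ends and dropped when shorter
    than ``min_block_len``.  The selected columns are recorded on the result
    as ``kept_columns``; an empty selection returns an empty alignment rather
    than raising.
    """
    ncol = aln.n_cols
    conserved = []
    gapped = []
    for col in aln.columns():
        has_gap = any(c in GAP_CHARS for c in col)
        gapped.append(has_gap)
        if not allow_gaps and has_gap:
            conserved.append(False)
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c in UNAMBIGUOUS:
                counts[c] = counts.get(c, 0) + 1
        top = max(counts.values()) if counts else 0
        conserved.append(top / aln.n_rows >= min_conserved_frac)

    kept: list[int] = []
    segment: list[int] = []
    run = 0

    def flush(seg: list[int]) -> None:
        while seg and not conserved[seg[0]]:
            seg.pop(0)
        while seg and not conserved[seg[-1]]:
            seg.pop()
        if len(seg) >= min_block_len:
            kept.extend(seg)

    for i in range(ncol):
        if conserved[i]:
            run = 0
            segment.append(i)
        else:
            run += 1
            segment.append(i)
            if run > max_nonconserved_run:
                del segment[-run:]
                flush(segment)
                segment = []
    flush(segment)
    if not allow_gaps:   # gap columns are removed even inside tolerated runs
        kept = [i for i in kept if not gapped[i]]
    out = aln.take_columns(kept)
    out.kept_columns = kept  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Nucleotide diversity

def _comparable_columns(aln: Alignment) -> list[int]:
    return [i for i, col in enumerate(aln.columns())
            if all(c in UNAMBIGUOUS for c in col)]


def _p_distance_strings(a: str, b: str) -> tuple[int, int]:
    diffs = sum(1 for x, y in zip(a, b) if x != y)
    return diffs, len(a)


def nucleotide_diversity(aln: Alignment) -> float:
    """π over the whole alignment (complete deletion); NaN when no
    comparable sites remain."""
    if aln.n_rows < 2:
        raise ValueError("π needs at least two sequences")
    cols = _comparable_columns(aln)
    if not cols:
        return float("nan")
    sub = aln.take_columns(cols)
    total, npairs = 0.0, 0
    for a, b in itertools.combinations(sub.rows, 2):
        d, n = _p_distance_strings(a, b)
        total += d / n
        npairs += 1
    return total / npairs


@dataclass
class WindowDiversity:
    window: int
    step: int
    midpoints: list[float]
    pi: list[float]
    per_gene: dict[str, float] = field(default_factory=dict)


def sliding_diversity(aln: Alignment, window: int = 200, step: int = 20
                      ) -> WindowDiversity:
    """Sliding-window π across alignment columns (complete deletion within
    each window; NaN for windows with no comparable sites)."""
    mids, pis = [], []
    ncol = aln.n_cols
    start = 0
    while start < ncol:
        end = min(start + window, ncol)
        sub = aln.take_columns(list(range(start, end)))
        try:
            pi = nucleotide_diversity(sub)
        except ValueError:
            pi = float("nan")
        mids.append((start + end) / 2)
        pis.append(pi)
        if end == ncol:
            break
        start += step
    per_gene = {}
    for gene, (s, e) in aln.partitions.items():
        per_gene[gene] = nucleotide_diversity(aln.take_columns(list(range(s, e))))
    return WindowDiversity(window, step, mids, pis, per_gene)


# ---------------------------------------------------------------------------
# Pairwise distances

def _pairwise_deletion(a: str, b: str) -> tuple[str, str]:
    keep = [(x, y) for x, y in zip(a, b)
            if x in UNAMBIGUOUS and y in UNAMBIGUOUS]
    if not keep:
        raise ValueError("no comparable sites after deletion")
    return "".join(x for x, _ in keep), "".join(y for _, y in keep)


def pairwise_distance(a: str, b: str, model: str = "K2P") -> float:
    """p, JC69, or K2P distance between two aligned sequences (columns with
    gaps/ambiguity in either sequence are deleted first)."""
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    a, b = _pairwise_deletion(a.upper(), b.upper())
    n = len(a)
    if model == "p":
        return sum(x != y for x, y in zip(a, b)) / n
    if model == "JC":
        p = sum(x != y for x, y in zip(a, b)) / n
        arg = 1 - 4 * p / 3
        if arg <= 0:
            raise SaturationError(f"JC undefined at p = {p:.4f}")
        return -0.75 * math.log(arg)
    if model == "K2P":
        ts = sum(1 for x, y in zip(a, b)
                 if x != y and (x in PURINES) == (y in PURINES))
        tv = sum(1 for x, y in zip(a, b)
                 if x != y and (x in PURINES) != (y in PURINES))
        P, Q = ts / n, tv / n
        arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
        if arg1 <= 0 or arg2 <= 0:
            raise SaturationError(f"K2P undefined at P = {P:.4f}, Q = {Q:.4f}")
        return -0.5 * math.log(arg1 * math.sqrt(arg2))
    raise ValueError(f"unknown model {model!r}")


def mean_pairwise_distance(aln: Alignment, model: str = "K2P") -> float:
    vals = [pairwise_distance(a, b, model)
            for a, b in itertools.combinations(aln.rows, 2)]
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks

@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> tuple[float, float, float]:
    """Per-position synonymous fractions of a sense codon.  Changes creating
    stop codons are excluded from the denominator at each position."""
    aa = CODON_TO_AA[codon]
    fracs = []
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            syn += CODON_TO_AA[alt] == aa
        fracs.append(syn / valid if valid else 0.0)
    return tuple(fracs)


def syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0–3); 3 − this is nonsynonymous."""
    return sum(_syn_fraction(codon))


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """(syn, nonsyn) differences between two sense codons, averaged over all
    shortest mutational pathways that avoid stop codons; None when every
    pathway crosses a stop."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    return (sum(t[0] for t in totals) / len(totals),
            sum(t[1] for t in totals) / len(totals))


@dataclass
class RatePair:
    Ka: float
    Ks: float
    ratio: float            # NaN when undefined
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    n_skipped: int = 0
    gene: str | None = None


def _jc_rate(p: float) -> float:
    arg = 1 - 4 * p / 3
    if arg <= 0:
        raise SaturationError(f"proportion {p:.4f} beyond JC correction")
    return -0.75 * math.log(arg)


def ng86(a: str, b: str, gene: str | None = None) -> RatePair:
    """Nei–Gojobori Ka/Ks for two frame-aligned coding sequences.

    Codons containing gaps or ambiguity in either sequence are removed
    pairwise; codon pairs whose every mutational pathway crosses a stop are
    skipped and counted in ``n_skipped``.  The ratio is NaN when Ks = 0.
    """
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    if len(a) % 3:
        raise ValueError("length not a multiple of 3")
    a, b = a.upper(), b.upper()
    S = Sd = Nd = 0.0
    n_codons = n_skipped = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i:i + 3], b[i:i + 3]
        if (any(ch not in UNAMBIGUOUS for ch in c1 + c2)
                or c1 in STOP_CODONS or c2 in STOP_CODONS):
            continue
        diffs = _pathway_diffs(c1, c2)
        if diffs is None:
            n_skipped += 1
            continue
        sd, nd = diffs
        S += (syn_sites(c1) + syn_sites(c2)) / 2
        Sd += sd
        Nd += nd
        n_codons += 1
    N = 3 * n_codons - S
    if n_codons == 0:
        return RatePair(float("nan"), float("nan"), float("nan"),
                        0.0, 0.0, 0.0, 0.0, 0, n_skipped, gene)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    if pS >= 0.75 or pN >= 0.75:
        return RatePair(float("nan"), float("nan"), float("nan"),
                        S, N, Sd, Nd, n_codons, n_skipped, gene)
    Ks = _jc_rate(pS)
    Ka = _jc_rate(pN)
    ratio = Ka / Ks if Ks > 0 else float("nan")
    return RatePair(Ka, Ks, ratio, S, N, Sd, Nd, n_codons, n_skipped, gene)


def mean_ng86(aln: Alignment, gene: str | None = None) -> RatePair:
    """Mean pairwise NG86 over all sequence pairs of a codon alignment.

    Pairs with undefined Ka or Ks (saturation) are dropped from the means;
    the ratio reported is mean(Ka)/mean(Ks) over the retained pairs.
    """
    pairs = [ng86(x, y, gene) for x, y in itertools.combinations(aln.rows, 2)]
    ok = [p for p in pairs if not math.isnan(p.Ka) and not math.isnan(p.Ks)]
    if not ok:
        return RatePair(float("nan"), float("nan"), float("nan"),
                        0, 0, 0, 0, 0, len(pairs), gene)
    ka = sum(p.Ka for p in ok) / len(ok)
    ks = sum(p.Ks for p in ok) / len(ok)
    ratio = ka / ks if ks > 0 else float("nan")
    first = ok[0]
    return RatePair(ka, ks, ratio, first.S, first.N,
                    sum(p.Sd for p in ok) / len(ok),
                    sum(p.Nd for p in ok) / len(ok),
                    first.n_codons, sum(p.n_skipped for p in ok), gene)
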