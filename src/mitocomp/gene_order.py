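"""Signed circular gene orders: normalization, rearrangement classification,
breakpoint distance, and single-event tandem-duplication–random-loss (TDRL)
explainability.

A gene order is a circular sequence of signed labels (duplicates allowed).
Normalization anchors the circle at COX1 on the + strand — COX1 is never
rearranged in mayfly mitogenomes, which makes comparisons deterministic —
falling back to the lexicographically minimal rotation when COX1 is absent.
The ancestral insect arrangement (Clary–Wolstenholme order) ships as data,
as does the ephemerellid arrangement with its inverted/translocated trnI
between rrnS and the control region.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

from .records import MitoRecord

Signed = tuple[str, int]


class LabelUniverseError(ValueError):
    def __init__(self, only_a: set, only_b: set):
        self.only_a, self.only_b = only_a, only_b
        super().__init__(f"label universes differ: only in first {sorted(only_a)}, "
                         f"only in second {sorted(only_b)}")


@dataclass(frozen=True)
class GeneOrder:
    items: tuple[Signed, ...]
    reference: str | None = None

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.items)

    def n_copies(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab, _ in self.items:
            out[lab] = out.get(lab, 0) + 1
        return out

    def serialize(self) -> str:
        return ",".join(("-" if s < 0 else "") + lab for lab, s in self.items)

    @staticmethod
    def parse(text: str, reference: str | None = None) -> "GeneOrder":
        items = []
        for tok in text.strip().split(","):
            tok = tok.strip()
            if not tok:
                continue
            if tok.startswith("-"):
                items.append((tok[1:], -1))
            else:
                items.append((tok.lstrip("+"), 1))
        return GeneOrder(tuple(items), reference)


def _load_order(name: str, ref: str) -> GeneOrder:
    text = resources.files("mitocomp.data").joinpath(name).read_text()
    return GeneOrder.parse(text, ref)


ANCESTRAL_INSECT_ORDER = _load_order("ancestral_insect_order.txt", "ancestral-insect")
EPHEMERELLID_ORDER = _load_order("ephemerellid_order.txt", "ephemerellid")


def _reflect(items: tuple[Signed, ...]) -> tuple[Signed, ...]:
    return tuple((lab, -s) for lab, s in reversed(items))


def _rotations(items: tuple[Signed, ...]):
    n = len(items)
    for i in range(n):
        yield items[i:] + items[:i]


def _min_rotation(items: tuple[Signed, ...]) -> tuple[Signed, ...]:
    return min(_rotations(items))


def normalize(order: GeneOrder) -> GeneOrder:
    """Unique rotation/reflection-normalized form, anchored at COX1(+)."""
    candidates = []
    for variant in (order.items, _reflect(order.items)):
        anchors = [i for i, (lab, s) in enumerate(variant) if lab == "COX1" and s == 1]
        if anchors:
            i = anchors[0]
            candidates.append(variant[i:] + variant[:i])
    if candidates:
        return GeneOrder(min(candidates), order.reference)
    return GeneOrder(min(_min_rotation(order.items),
                         _min_rotation(_reflect(order.items))), order.reference)


def order_of(record: MitoRecord) -> GeneOrder:
    """Signed circular gene order of an annotated genome (features sorted by
    start on the circle; CR kept as a positional marker; duplicates kept)."""
    feats = [f for f in record.features_sorted()
             if f.ftype in ("PCG", "tRNA", "rRNA", "CR")]
    items = tuple((f.label, f.strand) for f in feats)
    return normalize(GeneOrder(items, record.accession))


# ---------------------------------------------------------------------------
# Adjacencies and breakpoint distance

def _adjacency(a: Signed, b: Signed) -> tuple:
    """Canonical signed adjacency: (a→b) equals (−b→−a)."""
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def adjacency_set(items: tuple[Signed, ...]) -> set:
    n = len(items)
    return {_adjacency(items[i], items[(i + 1) % n]) for i in range(n)}


def _collapse_duplicates(order: GeneOrder, reference: GeneOrder) -> GeneOrder:
    """Collapse duplicate labels to one copy each, preferring the copy that
    retains a reference-context adjacency (makes breakpoint distance
    well-defined under duplication)."""
    dup_labels = {lab for lab, k in order.n_copies().items() if k > 1}
    if not dup_labels:
        return order
    ref_adj = adjacency_set(reference.items)
    items = list(order.items)
    for lab in sorted(dup_labels):
        idxs = [i for i, (l, _) in enumerate(items) if l == lab]
        keep = idxs[0]
        for i in idxs:
            n = len(items)
            prev_, next_ = items[(i - 1) % n], items[(i + 1) % n]
            if (_adjacency(prev_, items[i]) in ref_adj
                    or _adjacency(items[i], next_) in ref_adj):
                keep = i
                break
        items = [it for j, it in enumerate(items) if j == keep or it[0] != lab]
    return GeneOrder(tuple(items), order.reference)


def breakpoint_distance(order: GeneOrder, reference: GeneOrder) -> int:
    """Signed circular breakpoint distance: reference adjacencies absent from
    the (duplicate-collapsed) order."""
    a = _collapse_duplicates(order, reference)
    b = _collapse_duplicates(reference, order)
    return len(adjacency_set(b.items) - adjacency_set(a.items))


# ---------------------------------------------------------------------------
# Rearrangement report

@dataclass
class RearrangementEvent:
    gene: str
    type: str                       # inversion | translocation | inverse-translocation | duplication
    from_context: tuple[str, str]
    to_context: tuple[str, str]


@dataclass
class RearrangementReport:
    identical: bool
    events: list[RearrangementEvent]
    n_copies: dict[str, int]
    breakpoint_distance: int

    def to_json(self) -> str:
        return json.dumps({
            "identical": self.identical,
            "breakpoint_distance": self.breakpoint_distance,
            "n_copies": self.n_copies,
            "events": [e.__dict__ for e in self.events],
        }, default=list, indent=2)


def _context(items: tuple[Signed, ...], i: int) -> tuple[str, str]:
    n = len(items)
    return items[(i - 1) % n][0], items[(i + 1) % n][0]


def compare(order: GeneOrder, reference: GeneOrder) -> RearrangementReport:
    """Classify single-gene rearrangements of ``order`` against ``reference``.

    A gene whose strand flips in the same inter-gene context is an inversion;
    a changed context with the same strand is a translocation; both together
    an inverse-translocation.  Extra copies are duplication events.
    """
    if set(order.labels) != set(reference.labels):
        raise LabelUniverseError(set(order.labels) - set(reference.labels),
                                 set(reference.labels) - set(order.labels))
    n_copies = order.n_copies()
    collapsed = normalize(_collapse_duplicates(order, reference))
    ref = normalize(reference)
    bd = breakpoint_distance(order, reference)
    events: list[RearrangementEvent] = []
    pos = {lab: i for i, (lab, _) in enumerate(collapsed.items)}
    # first pass: every gene whose strand or inter-gene context changed
    candidates: dict[str, tuple[bool, tuple[str, str], tuple[str, str]]] = {}
    for i, (lab, sign) in enumerate(ref.items):
        j = pos[lab]
        o_sign = collapsed.items[j][1]
        ref_ctx = _context(ref.items, i)
        ord_ctx = _context(collapsed.items, j)
        if o_sign != sign or ord_ctx != ref_ctx:
            candidates[lab] = (o_sign != sign, ref_ctx, ord_ctx)
    # second pass: drop bystanders — genes without a strand flip whose context
    # difference vanishes once the other candidate genes are deleted from both
    # orders (their neighbours moved, they did not)
    def _pruned_moved(lab: str, removed: set[str]) -> bool:
        ref_p = tuple(it for it in ref.items if it[0] == lab or it[0] not in removed)
        ord_p = tuple(it for it in collapsed.items
                      if it[0] == lab or it[0] not in removed)
        i_r = next(i for i, it in enumerate(ref_p) if it[0] == lab)
        i_o = next(i for i, it in enumerate(ord_p) if it[0] == lab)
        return _context(ref_p, i_r) != _context(ord_p, i_o)

    bystanders = {lab for lab, (flip, _, _) in candidates.items()
                  if not flip and not _pruned_moved(lab, set(candidates) - {lab})}
    movers = set(candidates) - bystanders
    # movers are classified with bystanders retained as static landmarks
    for lab in movers:
        sign_flip, ref_ctx, ord_ctx = candidates[lab]
        moved = _pruned_moved(lab, movers - {lab})
        if sign_flip and moved:
            etype = "inverse-translocation"
        elif sign_flip:
            etype = "inversion"
        else:
            etype = "translocation"
        events.append(RearrangementEvent(lab, etype, ref_ctx, ord_ctx))
    for lab, k in sorted(n_copies.items()):
        if k > 1:
            i = pos[lab]
            events.append(RearrangementEvent(lab, "duplication",
                                             _context(ref.items, [x for x, (l, _) in enumerate(ref.items) if l == lab][0]),
                                             _context(collapsed.items, i)))
    identical = bd == 0 and not events
    return RearrangementReport(identical=identical, events=events,
                               n_copies=n_copies, breakpoint_distance=bd)


# ---------------------------------------------------------------------------
# Single-event TDRL

@dataclass
class TdrlScenario:
    block: tuple[str, ...]          # duplicated block, in source order
    keep_new: tuple[bool, ...]      # per block gene: True = keep the new copy


@dataclass
class TdrlResult:
    applicable: bool
    scenarios: list[TdrlScenario]
    needs_inversion: set[str] = field(default_factory=set)

    @property
    def explainable(self) -> bool:
        return self.applicable and bool(self.scenarios)


def _circular_key(labels: tuple[str, ...]) -> tuple[str, ...]:
    n = len(labels)
    return min(labels[i:] + labels[:i] for i in range(n))


def tdrl_explainable(source: GeneOrder, target: GeneOrder,
                     max_block: int = 10) -> TdrlResult:
    """Enumerate all single TDRL events turning ``source`` into ``target``.

    A TDRL event duplicates a contiguous circular block of ≤ ``max_block``
    genes in tandem, then deletes exactly one copy of each duplicated gene.
    TDRL preserves strands, so any per-gene sign difference makes the result
    not-applicable and lists the genes needing a prior inversion.
    """
    if max_block > 10:
        raise ValueError("max_block capped at 10 (exponential loss patterns)")
    if set(source.labels) != set(target.labels):
        raise LabelUniverseError(set(source.labels) - set(target.labels),
                                 set(target.labels) - set(source.labels))
    src_sign = dict(source.items)
    tgt_sign = dict(target.items)
    mismatched = {lab for lab in src_sign if src_sign[lab] != tgt_sign[lab]}
    if mismatched:
        return TdrlResult(False, [], mismatched)
    src = source.labels
    tgt_key = _circular_key(target.labels)
    n = len(src)
    scenarios: list[TdrlScenario] = []
    for start in range(n):
        rotated = src[start:] + src[:start]
        for blen in range(1, min(max_block, n) + 1):
            block, rest = rotated[:blen], rotated[blen:]
            for keep_new in itertools.product((False, True), repeat=blen):
                first = tuple(g for g, kn in zip(block, keep_new) if not kn)
                second = tuple(g for g, kn in zip(block, keep_new) if kn)
                result = first + second + rest
                if _circular_key(result) == tgt_key:
                    scenarios.append(TdrlScenario(block, keep_new))
    return TdrlResult(True, scenarios)
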