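"""Independent brute-force oracles used by several test modules.

These are deliberately written as plain, straight-line enumerations that do
not share code with the library implementations they check.
"""

from __future__ import annotations

import itertools


def brute_adjacencies(items):
    """All signed circular adjacencies of a signed order, canonicalized by
    explicit double listing of each adjacency and its strand-complement."""
    out = set()
    n = len(items)
    for i in range(n):
        a = items[i]
        b = items[(i + 1) % n]
        fwd = (a, b)
        rev = ((b[0], -b[1]), (a[0], -a[1]))
        out.add(fwd if fwd <= rev else rev)
    return out


def brute_breakpoints(order_items, ref_items):
    return len(brute_adjacencies(ref_items) - brute_adjacencies(order_items))


def brute_tdrl_outcomes(labels, max_block):
    """Every arrangement reachable from circular ``labels`` by one tandem
    duplication (block length ≤ max_block) followed by random loss, as a set
    of rotation-canonical tuples."""
    n = len(labels)
    outcomes = set()
    for start in range(n):
        rot = labels[start:] + labels[:start]
        for blen in range(1, min(max_block, n) + 1):
            block = rot[:blen]
            rest = rot[blen:]
            duplicated = block + block + rest
            # delete one copy of each duplicated gene: copy positions are
            # i (first) and blen + i (second)
            for choice in itertools.product((0, 1), repeat=blen):
                delete = {i if c else blen + i for i, c in enumerate(choice)}
                result = tuple(g for i, g in enumerate(duplicated) if i not in delete)
                outcomes.add(rotation_canonical(result))
    return outcomes


def rotation_canonical(labels):
    n = len(labels)
    return min(tuple(labels[i:] + labels[:i]) for i in range(n))


def gblocks_like_reference(rows, min_frac, max_run, min_len, allow_gaps):
    """Column-by-column reimplementation of the conserved-block filter."""
    nrow = len(rows)
    ncol = len(rows[0])
    passing = []
    for j in range(ncol):
        col = [r[j] for r in rows]
        if not allow_gaps and any(c in "-." for c in col):
            passing.append(False)
            continue
        freq = {}
        for c in col:
            if c in "ACGT":
                freq[c] = freq.get(c, 0) + 1
        best = max(freq.values()) if freq else 0
        passing.append(best / nrow >= min_frac)
    # split on failing runs longer than max_run, trim, enforce min length
    kept = []
    seg = []
    i = 0
    while i < ncol:
        if passing[i]:
            seg.append(i)
            i += 1
            continue
        j = i
        while j < ncol and not passing[j]:
            j += 1
        run = j - i
        if run > max_run or j == ncol:
            if len(seg) >= min_len:
                kept.extend(seg)
            seg = []
        else:
            if seg:  # tolerate a short internal failing run
                seg.extend(range(i, j))
        i = j
    if len(seg) >= min_len:
        kept.extend(seg)
    if not allow_gaps:
        kept = [j for j in kept if not any(r[j] in "-." for r in rows)]
    return kept
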