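"""Independent oracles used by the test suite.

These recompute expected results from first principles (raw intervals,
textbook formulas, exhaustive enumeration) without calling the code paths
they check.
"""

from __future__ import annotations

import math
from typing import Dict, List, Set, Tuple

import numpy as np
from scipy import stats as _st

MAX_LOSS = 0.10


def coding_length_raw(t, exon_index: int) -> int:
    """Exon coding length recomputed directly from raw intervals."""
    s, e = t.exons[exon_index - 1]
    return max(0, min(e, t.cds_end) - max(s, t.cds_start))


def cds_length_raw(t) -> int:
    return sum(coding_length_raw(t, i) for i in range(1, len(t.exons) + 1))


def loss_raw(t, removed: Set[int], extra: int = 0) -> float:
    return (sum(coding_length_raw(t, i) for i in removed) + extra) / cds_length_raw(t)


def brute_force_es_rf(t, block: List[int]) -> Set[int]:
    """All single-neighbor skips that restore the frame of a removed block.

    Enumerates both immediate neighbors and re-derives every condition from
    raw intervals: neighbor coding length not a multiple of three, combined
    removed length a multiple of three, no first/last exon touched, total
    loss at most 10%.
    """
    n = len(t.exons)
    accepted: Set[int] = set()
    if any(b in (1, n) for b in block):
        return accepted
    block_sum = sum(coding_length_raw(t, b) for b in block)
    if block_sum % 3 == 0:
        return accepted
    for nb in (min(block) - 1, max(block) + 1):
        if not (1 < nb < n):
            continue
        clen = coding_length_raw(t, nb)
        if clen % 3 == 0:
            continue
        if (block_sum + clen) % 3 != 0:
            continue
        if loss_raw(t, set(block) | {nb}) > MAX_LOSS:
            continue
        accepted.add(nb)
    return accepted


def brute_force_es_ve(t, exon: int) -> bool:
    """Single in-frame internal exon skip, rechecked from raw intervals."""
    n = len(t.exons)
    clen = coding_length_raw(t, exon)
    return (
        1 < exon < n
        and clen > 0
        and clen % 3 == 0
        and loss_raw(t, {exon}) <= MAX_LOSS
    )


def pearson_textbook(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Pearson r and two-sided p from the textbook formulas.

    r from centered sums of products; p from the exact t transform
    t = r * sqrt((n-2) / (1-r^2)) against a t distribution with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(_st.t.sf(abs(tstat), df=n - 2))
    return r, p


def bh_textbook(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, step-up, from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def reachable_descendants(parents: Dict[str, Set[str]], terms: Set[str],
                          root: str) -> Set[str]:
    """Reflexive descendant closure by exhaustive path checking."""
    children: Dict[str, Set[str]] = {t: set() for t in terms}
    for child, ps in parents.items():
        for p in ps:
            children[p].add(child)
    out = {root}
    changed = True
    while changed:
        changed = False
        for t in list(out):
            for c in children.get(t, ()):
                if c not in out:
                    out.add(c)
                    changed = True
    return out
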