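"""Independent brute-force registration oracle.

Enumerates every monotone registration of a 5'-arm window against a 3'-arm
window that is consistent with a pair table (paired positions must appear
with their partner; unpaired positions may face each other as a mismatch or
a gap as a bulge), then selects the canonical one: maximal number of
mismatch rows, ties broken by the lexicographically smallest row-key
sequence.  Written independently of the package's two-pointer walk.
"""

from __future__ import annotations

from functools import lru_cache

BIG = 10**9


def enumerate_registrations(pairs: dict[int, int],
                            i_lo: int, i_hi: int,
                            j_lo: int, j_hi: int):
    """All consistent monotone registrations as lists of (src5, src3, paired).

    The 5' window is walked ascending from ``i_lo``; the 3' window descending
    from ``j_hi``.  Registrations that would strand a paired position (its
    partner consumed in another row) are pruned.
    """

    def in_j(p):
        return p is not None and j_lo <= p <= j_hi

    def in_i(p):
        return p is not None and i_lo <= p <= i_hi

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        i_active = i <= i_hi
        j_active = j >= j_lo
        if not i_active and not j_active:
            return [()]
        pi = pairs.get(i) if i_active else None
        pj = pairs.get(j) if j_active else None
        # stranded partner -> dead branch
        if i_active and in_j(pi) and pi > j:
            return []
        if j_active and in_i(pj) and pj < i:
            return []
        if i_active and j_active and pi == j:
            return [((i, j, True),) + rest for rest in rec(i + 1, j - 1)]
        out = []
        if i_active and j_active and not in_j(pi) and not in_i(pj):
            out += [((i, j, False),) + rest for rest in rec(i + 1, j - 1)]
        if i_active and not in_j(pi):
            out += [((i, None, False),) + rest for rest in rec(i + 1, j)]
        if j_active and not in_i(pj):
            out += [((None, j, False),) + rest for rest in rec(i, j - 1)]
        return out

    return [list(r) for r in rec(i_lo, j_hi)]


def _row_key(row):
    src5, src3, _ = row
    return (src5 if src5 is not None else BIG,
            -src3 if src3 is not None else BIG)


def canonical_registration(pairs, i_lo, i_hi, j_lo, j_hi):
    """The oracle's pick: max mismatch rows, then smallest row-key sequence."""
    candidates = enumerate_registrations(pairs, i_lo, i_hi, j_lo, j_hi)
    assert candidates, "no consistent registration exists"

    def n_mismatch(reg):
        return sum(1 for s5, s3, p in reg
                   if s5 is not None and s3 is not None and not p)

    best_mm = max(n_mismatch(r) for r in candidates)
    pool = [r for r in candidates if n_mismatch(r) == best_mm]
    return min(pool, key=lambda reg: [_row_key(r) for r in reg])
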