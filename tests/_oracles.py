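"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles (exhaustive
enumeration, transitive closure, per-base bitmaps, pathway enumeration)
without reusing the package's optimised code paths.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from trimscape.structural_scanner import ScanParams


def oracle_scan_tuples(seq: str, params: ScanParams) -> list[tuple[int, int, int, float]]:
    """Exhaustive direct-repeat enumeration under the documented definition.

    Returns resolved candidate tuples ``(start, d, ltr_len, identity)``.
    Every step (seed runs, per-run window choice, nesting filter, overlap
    resolution) is re-implemented with plain loops.
    """
    seq = seq.upper()
    n = len(seq)
    k, a = params.seed_k, params.end_anchor
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    raw: dict[tuple[int, int, int], float] = {}
    for d in range(params.d_min, min(params.d_max, n - 1) + 1):
        m = (arr[: n - d] == arr[d:]) & acgt[: n - d] & acgt[d:]
        m = [bool(x) for x in m]
        # maximal runs of matches of length >= k
        runs = []
        i = 0
        while i < len(m):
            if m[i]:
                j = i
                while j < len(m) and m[j]:
                    j += 1
                if j - i >= k:
                    runs.append((i, j))
                i = j
            else:
                i += 1
        l_lo = max(params.min_ltr, d - params.max_spacing, k)
        l_hi = min(params.max_ltr, d - params.min_spacing)
        if l_lo > l_hi:
            continue
        for rs, re in runs:
            best = None
            for i0 in range(max(0, rs + k - l_hi), re - k + 1):
                if i0 + a > len(m) or not all(m[i0 : i0 + a]):
                    continue
                for j0 in range(max(rs + k, i0 + l_lo), min(len(m), i0 + l_hi) + 1):
                    if j0 - a < 0 or not all(m[j0 - a : j0]):
                        continue
                    L = j0 - i0
                    if not l_lo <= L <= l_hi:
                        continue
                    if min(j0, re) - max(i0, rs) < k:
                        continue
                    matches = sum(m[i0:j0])
                    ident = matches / L
                    if ident < params.min_ltr_identity:
                        continue
                    key = (2 * matches - L, ident, L, -i0, -j0)
                    if best is None or key > best[0]:
                        best = (key, i0, L, ident)
            if best is not None:
                _, i0, L, ident = best
                raw[(i0, d, L)] = ident
    cands = [(s, d, L, ident) for (s, d, L), ident in raw.items()]
    cands = _oracle_drop_nested(cands)
    return _oracle_resolve(cands)


def _oracle_drop_nested(cands, eps=8):
    def dropped_by(A, alive_cands):
        s, d, L, _ = A
        e = s + d + L
        ltr5 = (s, s + L)
        ltr3 = (s + d, e)
        borrowed5 = borrowed3 = False
        for B in alive_cands:
            if B is A:
                continue
            bs, bd, bL, _ = B
            be = bs + bd + bL
            if (bs, be) == (s, e):
                continue
            if (bs >= s - eps and be <= s + d + eps) or (
                bs >= s + L - eps and be <= e + eps
            ):
                return True
            for w in (ltr5, ltr3):
                if bs < w[0] - eps and be > w[1] + eps:
                    return True
            b5 = (bs, bs + bL)
            b3 = (bs + bd, be)
            if abs(ltr5[0] - b3[0]) <= eps and abs(ltr5[1] - b3[1]) <= eps:
                borrowed5 = True
            if abs(ltr3[0] - b5[0]) <= eps and abs(ltr3[1] - b5[1]) <= eps:
                borrowed3 = True
            if borrowed5 and borrowed3:
                return True
        return False

    accepted = []
    for A in sorted(cands, key=lambda c: (c[1] + c[2], c[0], c[2])):
        if not dropped_by(A, accepted):
            accepted.append(A)
    final = [A for A in accepted if not dropped_by(A, accepted)]
    return sorted(final)


def _oracle_resolve(cands):
    order = sorted(cands, key=lambda c: (-c[3], -(c[1] + c[2]), c[0], c[2]))
    kept = []
    for c in order:
        s, d, L, _ = c
        e = s + d + L
        if any(s < ks + kd + kL and ks < e for ks, kd, kL, _ in kept):
            continue
        kept.append(c)
    return sorted(kept)


# ---------------------------------------------------------------------------
# clustering oracle
# ---------------------------------------------------------------------------


def oracle_transitive_clusters(ids, link) -> list[frozenset]:
    """Transitive closure by repeated sweeps over an explicit link matrix."""
    groups = [{i} for i in ids]
    changed = True
    while changed:
        changed = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(link(x, y) for x in groups[gi] for y in groups[gj]):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break
    return sorted((frozenset(g) for g in groups), key=lambda g: sorted(g))


# ---------------------------------------------------------------------------
# masked-bp oracle
# ---------------------------------------------------------------------------


def oracle_masked_bp(intervals: list[tuple[int, int]], length: int) -> int:
    bitmap = np.zeros(length, dtype=bool)
    for s, e in intervals:
        bitmap[max(0, s) : min(length, e)] = True
    return int(bitmap.sum())


# ---------------------------------------------------------------------------
# Ka/Ks oracle (single or multi codon, independent pathway enumeration)
# ---------------------------------------------------------------------------

_ORACLE_TABLE = {}


def _aa(codon: str) -> str:
    if not _ORACLE_TABLE:
        from Bio.Data.CodonTable import standard_dna_table as t

        _ORACLE_TABLE.update(t.forward_table)
        for s in t.stop_codons:
            _ORACLE_TABLE[s] = "*"
    return _ORACLE_TABLE[codon]


def oracle_codon_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        syn = cons = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _aa(alt) == "*":
                continue
            cons += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if cons:
            total += syn / cons
    return total


def oracle_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in permutations(pos):
        cur, sd, nd, blocked = c1, 0, 0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _aa(nxt) == "*":
                blocked = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    use = [r for r in results if not r[2]] or results
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


def oracle_kaks_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) by direct enumeration."""
    S = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if _aa(ca) == "*" and _aa(cb) == "*" and i == len(cds_a) - 3:
            break
        n_codons += 1
        S += (oracle_codon_sites(ca) + oracle_codon_sites(cb)) / 2
        sd, nd = oracle_codon_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return S, 3 * n_codons - S, Sd, Nd
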