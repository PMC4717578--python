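"""De novo detection of miniature LTR-element candidates.

A candidate is a pair of nearby direct repeats (the putative LTRs)
separated by an internal spacer and usually flanked by a 4-6 bp
target-site duplication (TSD).  Detection uses exact k-mer seeding plus
score-maximising ungapped extension, under a crisp enumerable definition
so that a brute-force oracle can reproduce the output exactly:

For an offset ``d`` (distance between the 5' and 3' LTR starts) let
``m[i] = (s[i] == s[i+d])`` over unambiguous bases.  A *seed run* is a
maximal run of matches of length >= ``seed_k``.  Each seed run proposes
one LTR window ``[i, i+L)`` -- the window that

* overlaps the run by at least ``seed_k`` columns,
* starts and ends on ``end_anchor`` consecutive matching columns,
* satisfies ``min_ltr <= L <= max_ltr`` and
  ``min_spacing <= d - L <= max_spacing``,
* has column identity >= ``min_ltr_identity``,

and maximises the ungapped score ``matches - mismatches``; ties prefer
higher identity, then the longer window, then the leftmost.  Candidates
from all offsets are then overlap-resolved genome-wide keeping the
higher-identity, then longer, then leftmost element.

Boundary refinement (:func:`refine_boundaries`) shifts the LTR windows to
maximise LTR-pair alignment identity with 5'-TG...CA-3' terminal
preference; :func:`polish_boundaries_tsd` additionally snaps boundaries
onto an exact flanking TSD when one exists within a small identity
tolerance, automating the boundary inspection step of a manual survey.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, replace

import numpy as np

from ._align import global_identity
from .errors import FlankError, FormatError

IUPAC = set("ACGTRYSWKMBDHVN")
_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ScanParams:
    """Structural bounds of the search (miniature-element limits)."""

    min_ltr: int = 30
    max_ltr: int = 500
    min_spacing: int = 30
    max_spacing: int = 2000
    seed_k: int = 12
    min_ltr_identity: float = 0.80
    tsd_min: int = 4
    tsd_max: int = 6
    end_anchor: int = 4

    def validate(self) -> None:
        if self.min_ltr > self.max_ltr or self.min_spacing > self.max_spacing:
            raise FormatError("scan parameter ranges are inverted")
        if not 0 < self.min_ltr_identity <= 1:
            raise FormatError("min_ltr_identity must be in (0, 1]")
        if not 1 <= self.end_anchor <= self.seed_k:
            raise FormatError("end_anchor must be in [1, seed_k]")

    @property
    def d_min(self) -> int:
        return self.min_ltr + self.min_spacing

    @property
    def d_max(self) -> int:
        return self.max_ltr + self.max_spacing


@dataclass(frozen=True)
class CandidateElement:
    """A located candidate element (all intervals 0-based half-open)."""

    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    internal: tuple[int, int]
    ltr_identity: float
    tsd: tuple[str, tuple[int, int], tuple[int, int]] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tsd_seq(self) -> str | None:
        return self.tsd[0] if self.tsd else None

    def sequence(self, genome: dict[str, str]) -> str:
        return genome[self.chrom][self.start : self.end]


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC
    if bad:
        raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def _seed_pair_regions(seq: str, params: ScanParams) -> dict[int, list[tuple[int, int]]]:
    """For each offset d with exact seed-k-mer pairs: merged search regions
    (in 5'-LTR start coordinates) padded by the maximum window length."""
    k = params.seed_k
    index: dict[str, list[int]] = {}
    valid = set("ACGT")
    run_ok = 0
    for i, c in enumerate(seq):
        run_ok = run_ok + 1 if c in valid else 0
        if run_ok >= k:
            index.setdefault(seq[i - k + 1 : i + 1], []).append(i - k + 1)
    by_offset: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai, p1 in enumerate(positions):
            for p2 in positions[ai + 1 :]:
                d = p2 - p1
                if d < params.d_min:
                    continue
                if d > params.d_max:
                    break
                by_offset.setdefault(d, []).append(p1)
    pad = params.max_ltr + k
    regions: dict[int, list[tuple[int, int]]] = {}
    for d, starts in by_offset.items():
        starts.sort()
        merged: list[tuple[int, int]] = []
        for p in starts:
            lo, hi = p - pad, p + k + pad
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        regions[d] = [(max(0, lo), min(len(seq) - d, hi)) for lo, hi in merged]
    return regions


# ---------------------------------------------------------------------------
# per-run window selection
# ---------------------------------------------------------------------------


def match_vector(s_bytes: np.ndarray, d: int, lo: int, hi: int) -> np.ndarray:
    """m[i] for i in [lo, hi): bases at i and i+d equal and unambiguous."""
    a = s_bytes[lo:hi]
    b = s_bytes[lo + d : hi + d]
    return (a == b) & np.isin(a, _ACGT_BYTES)


def _anchored_starts(m: np.ndarray, a: int) -> np.ndarray:
    """boolean: position i starts >= a consecutive matches."""
    if len(m) < a:
        return np.zeros(0, dtype=bool)
    cs = np.concatenate(([0], np.cumsum(m)))
    return (cs[a:] - cs[:-a]) == a


def best_window_for_run(
    m: np.ndarray, cs: np.ndarray, rs: int, re: int, d: int, params: ScanParams
) -> tuple[int, int, float] | None:
    """The score-optimal anchored window for one seed run.

    Returns ``(start, ltr_len, identity)`` in the coordinates of *m*, or
    ``None`` when no window satisfies the constraints.  Maximises
    ``matches - mismatches``; ties: higher identity, longer, leftmost
    start, leftmost end.
    """
    k, a = params.seed_k, params.end_anchor
    l_lo = max(params.min_ltr, d - params.max_spacing, k)
    l_hi = min(params.max_ltr, d - params.min_spacing)
    if l_lo > l_hi:
        return None
    anchored = _anchored_starts(m, a)
    i_lo, i_hi = max(0, rs + k - l_hi), re - k  # inclusive start positions
    ii = np.arange(i_lo, i_hi + 1)
    ii = ii[(ii >= 0) & (ii < len(anchored)) & anchored[np.clip(ii, 0, len(anchored) - 1)]]
    j_lo, j_hi = rs + k, min(len(m), re - k + l_hi)  # exclusive ends, inclusive range
    jj = np.arange(j_lo, j_hi + 1)
    jj = jj[jj - a >= 0]
    jj = jj[anchored[jj - a]]
    if len(ii) == 0 or len(jj) == 0:
        return None
    L = jj[None, :] - ii[:, None]
    matches = cs[jj][None, :] - cs[ii][:, None]
    overlap = np.minimum(jj[None, :], re) - np.maximum(ii[:, None], rs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ident = np.where(L > 0, matches / np.maximum(L, 1), 0.0)
    valid = (
        (L >= l_lo) & (L <= l_hi) & (overlap >= k)
        & (ident >= params.min_ltr_identity)
    )
    if not valid.any():
        return None
    score = np.where(valid, 2 * matches - L, np.iinfo(np.int64).min)
    smax = score.max()
    tie = valid & (score == smax)
    ident_masked = np.where(tie, ident, -1.0)
    imax = ident_masked.max()
    tie &= np.isclose(ident_masked, imax, rtol=0, atol=1e-12)
    l_masked = np.where(tie, L, -1)
    lmax = l_masked.max()
    tie &= l_masked == lmax
    rows, cols = np.nonzero(tie)
    order = np.lexsort((jj[cols], ii[rows]))
    r, c = rows[order[0]], cols[order[0]]
    return int(ii[r]), int(L[r, c]), float(ident[r, c])


def _runs(m: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= k."""
    if len(m) == 0:
        return []
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= k]


# ---------------------------------------------------------------------------
# structural filtering and overlap resolution
# ---------------------------------------------------------------------------


def drop_nested_pairs(
    cands: list[tuple[int, int, int, float]], eps: int = 8
) -> list[tuple[int, int, int, float]]:
    """Remove repeat-pair artefacts that contain a whole smaller candidate.

    Two nearby copies of the same element pair up as artefactual "LTR
    pairs" whose repeat units are really whole elements or pieces of
    them.  A candidate A is dropped (within *eps* bp of slack) when
    another candidate B witnesses one of three artefact signatures:

    * B lies entirely within A minus one of A's LTRs (A's repeat unit
      contains a complete element);
    * one of A's LTR windows lies strictly in B's interior, B reaching
      past it on both sides (A's "LTR" is just part of B's element);
    * A's 5' LTR coincides with some candidate's 3' LTR *and* A's 3' LTR
      coincides with some candidate's 5' LTR (A is the spacer between
      two genuine elements, borrowing one LTR from each).

    A witness must itself be credible: candidates are examined shortest
    first, each judged only against already-accepted (shorter) ones, and
    the survivors are then swept once more against each other -- so an
    artefact cannot take a genuine element down with it, and remaining
    short artefacts fall to either the sweep or overlap resolution.
    """
    if len(cands) < 2:
        return list(cands)

    def windows(c: tuple[int, int, int, float]) -> tuple[tuple[int, int], tuple[int, int]]:
        s, d, length, _ = c
        return (s, s + length), (s + d, s + d + length)

    def same_window(w1: tuple[int, int], w2: tuple[int, int]) -> bool:
        return abs(w1[0] - w2[0]) <= eps and abs(w1[1] - w2[1]) <= eps

    def witnessed(cand, others) -> bool:
        s, d, length, _ = cand
        e = s + d + length
        zones = ((s - eps, s + d + eps), (s + length - eps, e + eps))
        ltr5, ltr3 = windows(cand)
        borrowed5 = borrowed3 = False
        for other in others:
            if other is cand:
                continue
            bs, bd, bL, _ = other
            be = bs + bd + bL
            if be < s - eps or bs > e + eps or (bs, be) == (s, e):
                continue
            if any(bs >= z_lo and be <= z_hi for z_lo, z_hi in zones):
                return True
            for w in (ltr5, ltr3):
                if bs < w[0] - eps and be > w[1] + eps:
                    return True
            b5, b3 = windows(other)
            if same_window(ltr5, b3):
                borrowed5 = True
            if same_window(ltr3, b5):
                borrowed3 = True
            if borrowed5 and borrowed3:
                return True
        return False

    accepted: list[tuple[int, int, int, float]] = []
    for cand in sorted(cands, key=lambda c: (c[1] + c[2], c[0], c[2])):
        if not witnessed(cand, accepted):
            accepted.append(cand)
    final = [c for c in accepted if not witnessed(c, accepted)]
    final.sort(key=lambda c: c[0])
    return final


def resolve_overlaps(
    cands: list[tuple[int, int, int, float]],
) -> list[tuple[int, int, int, float]]:
    """Greedy selection of non-overlapping candidates.

    Input/output tuples are ``(start, d, ltr_len, identity)``; priority is
    identity desc, element length desc, leftmost start, shortest LTR.
    """
    order = sorted(cands, key=lambda c: (-c[3], -(c[1] + c[2]), c[0], c[2]))
    kept: list[tuple[int, int, int, float]] = []
    kept_sorted: list[tuple[int, int]] = []  # (start, end) sorted by start
    starts: list[int] = []
    for c in order:
        start, d, length, _ = c
        end = start + d + length
        jlo = bisect_left(starts, start - 3001)
        clash = False
        for j in range(jlo, len(kept_sorted)):
            s2, e2 = kept_sorted[j]
            if s2 >= end:
                break
            if start < e2:
                clash = True
                break
        if clash:
            continue
        pos = bisect_left(starts, start)
        starts.insert(pos, start)
        kept_sorted.insert(pos, (start, end))
        kept.append(c)
    kept.sort(key=lambda c: c[0])
    return kept


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def detect_tsd(
    candidate: CandidateElement,
    genome: dict[str, str],
    tsd_min: int = 4,
    tsd_max: int = 6,
) -> tuple[str, tuple[int, int], tuple[int, int]] | None:
    """Longest exact 4-6 bp duplication anchored at the element boundaries."""
    seq = genome[candidate.chrom]
    if candidate.start < tsd_max or candidate.end + tsd_max > len(seq):
        raise FlankError(
            f"candidate {candidate.chrom}:{candidate.start}-{candidate.end} "
            f"has less than {tsd_max} bp of flank"
        )
    for length in range(tsd_max, tsd_min - 1, -1):
        left = seq[candidate.start - length : candidate.start].upper()
        right = seq[candidate.end : candidate.end + length].upper()
        if left == right and "N" not in left:
            return (
                left,
                (candidate.start - length, candidate.start),
                (candidate.end, candidate.end + length),
            )
    return None


def scan(genome: dict[str, str], params: ScanParams | None = None) -> list[CandidateElement]:
    """Scan a genome for direct-repeat pairs satisfying *params*.

    Returns candidates sorted by (chrom, start); overlapping candidates
    are resolved keeping the higher-identity, then longer, then leftmost.
    """
    params = params or ScanParams()
    params.validate()
    out: list[CandidateElement] = []
    for chrom in genome:
        seq = _validate_sequence(genome[chrom])
        if not seq:
            raise FormatError(f"empty sequence for {chrom}")
        s_bytes = np.frombuffer(seq.encode(), dtype=np.uint8)
        raw: dict[tuple[int, int, int], float] = {}
        for d, regions in _seed_pair_regions(seq, params).items():
            for lo, hi in regions:
                if hi <= lo:
                    continue
                m = match_vector(s_bytes, d, lo, hi)
                cs = np.concatenate(([0], np.cumsum(m)))
                for rs, re in _runs(m, params.seed_k):
                    best = best_window_for_run(m, cs, rs, re, d, params)
                    if best is None:
                        continue
                    i, length, ident = best
                    raw[(lo + i, d, length)] = ident
        cands = [(s, d, length, ident) for (s, d, length), ident in raw.items()]
        cands = drop_nested_pairs(cands)
        for start, d, length, ident in resolve_overlaps(cands):
            cand = CandidateElement(
                chrom=chrom,
                start=start,
                end=start + d + length,
                ltr5=(start, start + length),
                ltr3=(start + d, start + d + length),
                internal=(start + length, start + d),
                ltr_identity=ident,
            )
            try:
                tsd = detect_tsd(cand, genome, params.tsd_min, params.tsd_max)
            except FlankError:
                tsd = None
            out.append(replace(cand, tsd=tsd))
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def _tg_ca_score(ltr5: str, ltr3: str) -> int:
    score = 0
    for ltr in (ltr5, ltr3):
        if ltr.startswith("TG"):
            score += 1
        if ltr.endswith("CA"):
            score += 1
    return score


def _rebuild(candidate: CandidateElement, genome: dict[str, str],
             ltr5: tuple[int, int], ltr3: tuple[int, int]) -> CandidateElement:
    seq = genome[candidate.chrom]
    ident, _ = global_identity(seq[ltr5[0] : ltr5[1]], seq[ltr3[0] : ltr3[1]])
    cand = CandidateElement(
        chrom=candidate.chrom,
        start=ltr5[0],
        end=ltr3[1],
        ltr5=ltr5,
        ltr3=ltr3,
        internal=(ltr5[1], ltr3[0]),
        ltr_identity=ident,
    )
    try:
        tsd = detect_tsd(cand, genome)
    except FlankError:
        tsd = None
    return replace(cand, tsd=tsd)


def refine_boundaries(
    candidate: CandidateElement, genome: dict[str, str], max_shift: int = 15, rounds: int = 2
) -> CandidateElement:
    """Adjust boundaries within +/-*max_shift* bp to maximise LTR-pair identity.

    Three move families are searched in turn: shifting both windows
    together (start/end offsets applied to both LTRs), then each LTR
    window rigidly on its own.  Ties prefer terminal 5'-TG...CA-3' LTR
    ends, then the longer LTR pair, then the leftmost placement.  The
    input is returned unchanged when no strictly better placement exists.
    """
    seq = genome[candidate.chrom]

    def key(l5: tuple[int, int], l3: tuple[int, int]) -> tuple:
        a = seq[l5[0] : l5[1]]
        b = seq[l3[0] : l3[1]]
        ident, _ = global_identity(a, b)
        return (round(ident, 9), _tg_ca_score(a, b), len(a) + len(b), -l5[0], -l3[0])

    cur5 = candidate.ltr5
    cur3 = candidate.ltr3
    cur_key = key(cur5, cur3)
    shifts = range(-max_shift, max_shift + 1)
    for _ in range(rounds):
        improved = False
        for family in ("both", "ltr5", "ltr3"):
            best_key, best5, best3 = cur_key, cur5, cur3
            for ds in shifts:
                for de in shifts:
                    if family == "both":
                        l5 = (cur5[0] + ds, cur5[1] + de)
                        l3 = (cur3[0] + ds, cur3[1] + de)
                    elif family == "ltr5":
                        l5 = (cur5[0] + ds, cur5[1] + de)
                        l3 = cur3
                    else:
                        l5 = cur5
                        l3 = (cur3[0] + ds, cur3[1] + de)
                    if l5[0] < 0 or l3[1] > len(seq):
                        continue
                    if l5[1] - l5[0] < 10 or l3[1] - l3[0] < 10 or l3[0] - l5[1] < 1:
                        continue
                    k = key(l5, l3)
                    if k > best_key:
                        best_key, best5, best3 = k, l5, l3
            if best_key > cur_key:
                cur_key, cur5, cur3 = best_key, best5, best3
                improved = True
        if not improved:
            break
    if (cur5, cur3) == (candidate.ltr5, candidate.ltr3):
        return candidate
    return _rebuild(candidate, genome, cur5, cur3)


def polish_boundaries_tsd(
    candidate: CandidateElement,
    genome: dict[str, str],
    max_shift: int = 25,
    identity_tol: float = 0.06,
) -> CandidateElement:
    """Snap element boundaries onto an exact flanking TSD.

    Searches element start/end shifts within +/-*max_shift* bp for a
    placement with an exact 4-6 bp TSD whose LTR-pair identity is within
    *identity_tol* of the current one.  Placements are ranked by identity
    quantised into 0.02-wide bins first -- so losing a genuinely matching
    terminal column outranks a substitution-noise tie -- then by TSD
    length, then by the smallest shift.  Mirrors how a curator uses the
    TSD to fix boundaries that substitution noise has nudged inward.
    """
    seq = genome[candidate.chrom]
    base_ident = candidate.ltr_identity

    def rank(
        ident: float, tg_ca: int, tsd_len: int, ds: int, de: int
    ) -> tuple:
        # any TSD first, then intact 5'-TG...CA-3' termini (the strongest
        # positional signal; chance placements essentially never show all
        # four), then coarse identity, then the smallest shift, then the
        # longer TSD
        return (
            1 if tsd_len else 0,
            tg_ca,
            int(ident * 50 + 1e-9),
            -(abs(ds) + abs(de)),
            tsd_len,
            -ds,
            -de,
        )

    cur_tsd_len = len(candidate.tsd[0]) if candidate.tsd else 0
    cur_tg_ca = _tg_ca_score(
        seq[candidate.ltr5[0] : candidate.ltr5[1]],
        seq[candidate.ltr3[0] : candidate.ltr3[1]],
    )
    best_key = rank(base_ident, cur_tg_ca, cur_tsd_len, 0, 0)
    best: tuple[tuple[int, int], tuple[int, int]] | None = None
    for ds in range(-max_shift, max_shift + 1):
        for de in range(-max_shift, max_shift + 1):
            if ds == 0 and de == 0:
                continue
            # symmetric move: both LTR windows keep their mutual offset
            l5 = (candidate.ltr5[0] + ds, candidate.ltr5[1] + de)
            l3 = (candidate.ltr3[0] + ds, candidate.ltr3[1] + de)
            if l5[0] < 0 or l3[1] > len(seq):
                continue
            if l5[1] - l5[0] < 10 or l3[0] - l5[1] < 1:
                continue
            probe = CandidateElement(
                candidate.chrom, l5[0], l3[1], l5, l3, (l5[1], l3[0]), 0.0
            )
            try:
                tsd = detect_tsd(probe, genome)
            except FlankError:
                tsd = None
            if tsd is None:
                continue
            a = seq[l5[0] : l5[1]]
            b = seq[l3[0] : l3[1]]
            ident, _ = global_identity(a, b)
            if ident < base_ident - identity_tol:
                continue
            k = rank(ident, _tg_ca_score(a, b), len(tsd[0]), ds, de)
            if k > best_key:
                best_key, best = k, (l5, l3)
    if best is None:
        return candidate
    return _rebuild(candidate, genome, best[0], best[1])


def scan_and_refine(
    genome: dict[str, str], params: ScanParams | None = None
) -> list[CandidateElement]:
    """Full detection pipeline: scan, refine boundaries, snap onto TSDs."""
    params = params or ScanParams()
    out = []
    for cand in scan(genome, params):
        cand = polish_boundaries_tsd(cand, genome)
        out.append(cand)
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def ltr_lengths_ok(candidate: CandidateElement, params: ScanParams) -> bool:
    for s, e in (candidate.ltr5, candidate.ltr3):
        if not params.min_ltr <= e - s <= params.max_ltr:
            return False
    s, e = candidate.internal
    return params.min_spacing <= e - s <= params.max_spacing
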