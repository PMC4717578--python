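"""Shared pairwise-alignment primitives.

Thin wrappers around :mod:`edlib` (fast edit-distance alignment with an
alignment path) and :class:`Bio.Align.PairwiseAligner` (local affine-gap
alignment).  Every module of the pipeline expresses its sequence
comparisons through these three primitives:

* :func:`global_identity` -- end-to-end identity of two sequences
  (matches / alignment columns).
* :func:`local_align` -- best local alignment with the masking score
  convention (match +1, mismatch -1, gap open -5, gap extend -1).
* :func:`find_local_matches` -- seeded search for local occurrences of a
  query inside a chromosome-scale subject.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
from Bio import Align

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: default masking-style scores used throughout the pipeline
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -5
GAP_EXTEND = -1


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Identity of the end-to-end (Needleman-Wunsch) alignment of *a* and *b*.

    Returns ``(matches / columns, columns)``.  Two empty sequences have
    identity 0 over 0 columns.
    """
    if not a or not b:
        return 0.0, 0
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in parse_cigar(res["cigar"]):
        columns += n
        if op == "=":
            matches += n
    return (matches / columns if columns else 0.0), columns


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of ``query`` against ``target``."""

    score: float
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_LOCAL_ALIGNER = _make_aligner()


def local_align(target: str, query: str) -> LocalHit | None:
    """Best Smith-Waterman alignment of *query* within *target*.

    Scores: match +1, mismatch -1, gap open -5, extend -1.  Returns ``None``
    when no positive-scoring alignment exists.
    """
    target = target.upper()
    query = query.upper()
    if not target or not query:
        return None
    alignments = _LOCAL_ALIGNER.align(target, query)
    try:
        aln = alignments[0]
    except (IndexError, ValueError):
        return None
    if aln.score <= 0:
        return None
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return None
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        seg_t = target[ts:te]
        seg_q = query[qs:qe]
        matches += sum(x == y for x, y in zip(seg_t, seg_q))
        columns += te - ts
        prev_t, prev_q = te, qe
    return LocalHit(
        score=float(aln.score),
        target_start=int(tblocks[0][0]),
        target_end=int(tblocks[-1][1]),
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
        matches=matches,
        columns=columns,
    )


_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every ACGT-only k-mer in *seq*."""
    index: dict[str, list[int]] = {}
    valid = set("ACGT")
    seq = seq.upper()
    bad_until = -1
    for i in range(len(seq) - k + 1):
        if i == 0 or bad_until < i:
            window = seq[i : i + k]
            for j, c in enumerate(window):
                if c not in valid:
                    bad_until = i + j
        if bad_until >= i:
            continue
        if seq[i + k - 1] not in valid:
            bad_until = i + k - 1
            continue
        index.setdefault(seq[i : i + k], []).append(i)
    return index


class SubjectIndex:
    """k-mer index over one subject sequence, reused across queries."""

    def __init__(self, seq: str, k: int = 12):
        self.seq = seq.upper()
        self.k = k
        self._index = kmer_positions(self.seq, k)

    def seed_diagonal_clusters(self, query: str, band: int = 60) -> list[tuple[int, int]]:
        """Subject windows likely to contain a local match of *query*.

        Seeds are exact shared k-mers; seeds are grouped by alignment
        diagonal (subject pos - query pos) into bands, and each band is
        widened to cover a full query placement.
        """
        k = self.k
        query = query.upper()
        diag_hits: list[tuple[int, int]] = []  # (diagonal, subject pos)
        for qpos in range(0, len(query) - k + 1):
            kmer = query[qpos : qpos + k]
            for spos in self._index.get(kmer, ()):  # noqa: B905
                diag_hits.append((spos - qpos, spos))
        if not diag_hits:
            return []
        diag_hits.sort()
        windows: list[tuple[int, int]] = []
        cur_diag = None
        lo = hi = 0
        for diag, _spos in diag_hits:
            if cur_diag is None or diag - cur_diag > band:
                if cur_diag is not None:
                    windows.append((lo, hi))
                lo, hi = diag, diag
            else:
                hi = diag
            cur_diag = diag
        windows.append((lo, hi))
        pad = band
        merged: list[tuple[int, int]] = []
        for lo, hi in windows:
            start = max(0, lo - pad)
            end = min(len(self.seq), hi + len(query) + pad)
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return merged


@dataclass(frozen=True)
class GenomeHit:
    """A local occurrence of a query sequence on a subject."""

    start: int  # subject coordinates, 0-based half-open
    end: int
    strand: str  # '+' or '-'
    score: float
    identity: float
    query_start: int  # coordinates on the forward-strand query
    query_end: int
    columns: int

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def find_local_matches(
    query: str,
    subject: str | SubjectIndex,
    min_identity: float = 0.7,
    min_len: int = 30,
    k: int = 12,
    both_strands: bool = False,
) -> list[GenomeHit]:
    """Seeded local search of *query* against a large *subject*.

    Exact shared k-mers seed candidate windows; each window is aligned
    with the local aligner.  Overlapping hits on the same strand are
    reduced to the best-scoring one.
    """
    index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(subject, k)
    hits: list[GenomeHit] = []
    strands = [("+", query)]
    if both_strands:
        strands.append(("-", revcomp(query)))

    def emit(wstart: int, wend: int, strand: str, q: str, depth: int) -> None:
        """Align q in the window; recurse left/right of each accepted hit
        so that several copies inside one seeded window are all found."""
        if wend - wstart < min_len or depth > 50:
            return
        window = index.seq[wstart:wend]
        hit = local_align(window, q)
        if hit is None or hit.target_span < min_len:
            return
        if hit.identity >= min_identity:
            if strand == "+":
                qs, qe = hit.query_start, hit.query_end
            else:
                qs, qe = len(q) - hit.query_end, len(q) - hit.query_start
            hits.append(
                GenomeHit(
                    start=wstart + hit.target_start,
                    end=wstart + hit.target_end,
                    strand=strand,
                    score=hit.score,
                    identity=hit.identity,
                    query_start=qs,
                    query_end=qe,
                    columns=hit.columns,
                )
            )
        emit(wstart, wstart + hit.target_start, strand, q, depth + 1)
        emit(wstart + hit.target_end, wend, strand, q, depth + 1)

    for strand, q in strands:
        for wstart, wend in index.seed_diagonal_clusters(q):
            emit(wstart, wend, strand, q, 0)
    return _dedupe_hits(hits)


def _dedupe_hits(hits: list[GenomeHit]) -> list[GenomeHit]:
    """Keep the best hit among mutually overlapping ones (score, length, leftmost)."""
    order = sorted(hits, key=lambda h: (-h.score, -(h.end - h.start), h.start))
    kept: list[GenomeHit] = []
    for h in order:
        if any(h.start < kh.end and kh.start < h.end for kh in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def interval_union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total
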