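"""Autonomous partners, deletion breakpoints and insertion polymorphisms.

A miniature element's *partner* is a larger LTR retrotransposon whose
LTRs match the element's LTR and whose internal region shares sequence
with the element's internal region -- the putative progenitor that could
mobilise it in trans.  The element typically derives from the partner by
an internal deletion; a short *duplicated internal sequence* flanks the
deleted segment at the breakpoint.  Partners with a long intact
retrotransposase frame are classified putatively autonomous.

Polymorphic insertions between two assemblies are called by mapping an
annotated element's flanks onto the other genome: a polymorphic site
shows both flanks contiguous with a single TSD copy at the junction.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import SubjectIndex, find_local_matches, local_align
from .trim_filter import coding_capacity, six_frame_peptides


@dataclass(frozen=True)
class PartnerElement:
    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity_to_trim: float
    internal_shared_bp: int
    longest_orf_aa: int = 0
    autonomy: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BreakpointReport:
    breakpoint: int  # position on the partner (and the TRIM 5' block end)
    dup_seq: str | None
    dup_copy_5prime: tuple[int, int] | None
    dup_copy_3prime: tuple[int, int] | None
    dup_identity: float
    deleted_span: tuple[int, int]
    block5_identity: float
    block3_identity: float


@dataclass(frozen=True)
class PolymorphicInsertion:
    carrier: str  # genome id carrying the insertion
    chrom: str
    start: int
    end: int
    tsd: str
    empty_site: tuple[str, int, int]  # orthologous junction on the other genome
    left_flank_identity: float
    right_flank_identity: float


def find_partners(
    trim_seq: str,
    trim_ltr_len: int,
    genome: dict[str, str],
    min_ltr_identity: float = 0.79,
    min_partner_len: int = 3000,
    max_partner_len: int = 25_000,
    min_internal_segment: int = 100,
    proteins: dict[str, str] | None = None,
) -> list[PartnerElement]:
    """Larger elements whose LTR pair matches the query element's LTR.

    Candidate partners are pairs of genomic LTR matches spanning at least
    *min_partner_len* whose intervening region also shares an aligned
    segment of >= *min_internal_segment* bp with the query's internal
    region.  Autonomy is classified when *proteins* are supplied.
    """
    ltr = trim_seq[:trim_ltr_len]
    internal = trim_seq[trim_ltr_len : len(trim_seq) - trim_ltr_len]
    out = []
    for chrom, seq in genome.items():
        hits = [
            h
            for h in find_local_matches(ltr, seq, min_identity=min_ltr_identity, min_len=20)
            if h.query_span >= 0.8 * len(ltr)
        ]
        hits.sort(key=lambda h: h.start)
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                a, b = hits[i], hits[j]
                span = b.end - a.start
                if span < min_partner_len:
                    continue
                if span > max_partner_len:
                    break
                inner = seq[a.end : b.start]
                ih = local_align(inner, internal)
                if ih is None or ih.target_span < min_internal_segment:
                    continue
                if ih.identity < 0.70:
                    continue
                ident = (a.identity + b.identity) / 2
                partner_seq = seq[a.start : b.end]
                orf_aa, autonomy = 0, ""
                if proteins is not None:
                    autonomy, orf_aa = classify_autonomy(partner_seq, proteins)
                out.append(
                    PartnerElement(
                        chrom=chrom,
                        start=a.start,
                        end=b.end,
                        ltr5=(a.start, a.end),
                        ltr3=(b.start, b.end),
                        ltr_identity_to_trim=ident,
                        internal_shared_bp=ih.target_span,
                        longest_orf_aa=orf_aa,
                        autonomy=autonomy,
                    )
                )
    return sorted(out, key=lambda p: (p.chrom, p.start))


def locate_breakpoint(
    trim_seq: str,
    partner_seq: str,
    min_block_identity: float = 0.85,
    min_dup_len: int = 8,
    max_dup_len: int = 60,
    min_dup_identity: float = 0.90,
    min_deletion: int = 20,
) -> BreakpointReport | None:
    """Decompose the element into 5'/3' blocks on the partner.

    The element's 5' block is colinear with the partner's 5' region and
    its 3' block with the partner's 3' region; the junction between them
    is the breakpoint and the partner segment in between is the deletion
    that produced the element.  Both blocks must match at >=
    *min_block_identity*, else ``None`` ("no breakpoint").  Where a
    sequence repeat makes the junction ambiguous, the 3'-most placement
    is reported, so a duplicated internal sequence sits immediately 5' of
    the breakpoint.  A duplicated internal sequence is reported when
    near-identical copies (>= *min_dup_identity*, >= *min_dup_len* bp)
    flank the deleted segment.
    """
    n_t, n_p = len(trim_seq), len(partner_seq)
    gap_len = n_p - n_t
    if gap_len < min_deletion:
        return None
    pre = [x == y for x, y in zip(trim_seq, partner_seq)]
    suf = [
        trim_seq[n_t - 1 - i] == partner_seq[n_p - 1 - i] for i in range(n_t)
    ]
    pre_cum = [0]
    for v in pre:
        pre_cum.append(pre_cum[-1] + v)
    suf_cum = [0]
    for v in suf:
        suf_cum.append(suf_cum[-1] + v)
    min_block = 15
    best = None
    for c in range(min_block, n_t - min_block + 1):
        total = pre_cum[c] + suf_cum[n_t - c]
        # ties (repeats at the junction) resolve to the 3'-most placement
        if best is None or total >= best[0]:
            best = (total, c)
    if best is None:
        return None
    t_break = best[1]
    block5_ident = pre_cum[t_break] / t_break
    block3_ident = suf_cum[n_t - t_break] / (n_t - t_break)
    if block5_ident < min_block_identity or block3_ident < min_block_identity:
        return None
    p_gap_start = t_break
    p_gap_end = t_break + gap_len
    # duplicated internal sequence: the junction canonicalisation above
    # puts one copy immediately 5' of the breakpoint and the other at the
    # tail of the deleted segment; extend leftward from the junction to
    # the score-maximal length (matches - mismatches)
    best_dup = None
    best_score = 0
    matches = 0
    for length in range(1, min(max_dup_len, gap_len, p_gap_start) + 1):
        x = partner_seq[p_gap_start - length]
        y = partner_seq[p_gap_end - length]
        matches += x == y
        score = 2 * matches - length
        ident = matches / length
        if length >= min_dup_len and ident >= min_dup_identity and score > best_score:
            best_score = score
            best_dup = (
                partner_seq[p_gap_start - length : p_gap_start],
                (p_gap_start - length, p_gap_start),
                (p_gap_end - length, p_gap_end),
                ident,
            )
    if best_dup:
        dup_seq, c5, c3, dup_ident = best_dup
    else:
        dup_seq, c5, c3, dup_ident = None, None, None, 0.0
    return BreakpointReport(
        breakpoint=t_break,
        dup_seq=dup_seq,
        dup_copy_5prime=c5,
        dup_copy_3prime=c3,
        dup_identity=dup_ident,
        deleted_span=(p_gap_start, p_gap_end),
        block5_identity=block5_ident,
        block3_identity=block3_ident,
    )


def classify_autonomy(
    partner_seq: str,
    proteins: dict[str, str],
    min_orf_aa: int = 900,
) -> tuple[str, int]:
    """putative_autonomous iff a >= *min_orf_aa* translated frame exists
    and the sequence has retroelement coding capacity; returns the label
    and the longest frame length in residues."""
    peptides = six_frame_peptides(partner_seq, min_aa=1)
    longest = max((len(p) for p in peptides), default=0)
    if longest >= min_orf_aa:
        has_coding, _ = coding_capacity(partner_seq, proteins)
        if has_coding:
            return "putative_autonomous", longest
    return "non_autonomous", longest


def _map_flank(
    flank: str, index: SubjectIndex, min_identity: float
) -> tuple[int, int, float] | None | str:
    """Best unique placement of a flank on the other genome.

    Returns (start, end, identity), None when unmapped, or "ambiguous"
    when several well-separated placements tie.
    """
    hits = find_local_matches(flank, index, min_identity=min_identity, min_len=50)
    strong = [
        h
        for h in hits
        if h.identity >= min_identity and h.query_span >= 0.9 * len(flank)
    ]
    if not strong:
        return None
    if len(strong) > 1:
        return "ambiguous"
    h = strong[0]
    # extend the placement to cover the full flank coordinates
    start = h.start - h.query_start
    end = h.end + (len(flank) - h.query_end)
    return start, end, h.identity


def call_polymorphic_insertions(
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    annotations: list[tuple[str, str, int, int]],
    flank_bp: int = 500,
    min_flank_identity: float = 0.90,
    tsd_range: tuple[int, int] = (4, 6),
    carrier: str = "a",
) -> tuple[list[PolymorphicInsertion], list[str]]:
    """Insertions present in genome A but absent at the orthologous site in B.

    For each annotated element ``(id, chrom, start, end)`` in A, both
    *flank_bp* flanks are mapped onto B.  The element is polymorphic when
    the flanks land contiguously (overlapping by a single 4-6 bp TSD
    copy, with no element-sized gap between them).  Elements whose flanks
    map to several loci are skipped and returned as ambiguous ids.
    """
    indexes = {chrom: SubjectIndex(seq) for chrom, seq in genome_b.items()}
    calls: list[PolymorphicInsertion] = []
    ambiguous: list[str] = []
    tsd_min, tsd_max = tsd_range
    for el_id, chrom, start, end in annotations:
        seq_a = genome_a[chrom]
        if start < flank_bp or end + flank_bp > len(seq_a):
            continue
        results = []
        for side in ("left", "right"):
            placed = None
            # fall back to a half-length flank when the full flank does not
            # map (e.g. another polymorphic element sits inside it)
            for fb in (flank_bp, flank_bp // 2):
                flank = (
                    seq_a[start - fb : start] if side == "left" else seq_a[end : end + fb]
                )
                placed = None
                for bchrom, index in indexes.items():
                    r = _map_flank(flank, index, min_flank_identity)
                    if r == "ambiguous":
                        placed = "ambiguous"
                        break
                    if r is not None:
                        if placed is not None:
                            placed = "ambiguous"
                            break
                        placed = (bchrom, *r)
                if placed is not None:
                    break
            results.append(placed)
        if "ambiguous" in results:
            ambiguous.append(el_id)
            continue
        if None in results:
            continue
        (lchrom, lstart, lend, lident), (rchrom, rstart, rend, rident) = results
        if lchrom != rchrom:
            continue
        overlap = lend - rstart
        if not tsd_min <= overlap <= tsd_max:
            continue
        tsd = genome_b[lchrom][rstart:lend]
        calls.append(
            PolymorphicInsertion(
                carrier=carrier,
                chrom=chrom,
                start=start,
                end=end,
                tsd=tsd,
                empty_site=(lchrom, rstart, lend),
                left_flank_identity=lident,
                right_flank_identity=rident,
            )
        )
    return calls, ambiguous
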