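"""Library-based annotation of all element copies in a genome.

Each subfamily consensus is aligned locally against both strands of the
genome; hits are scored with the masking convention (match +1, mismatch
-1, gap open -5, extend -1, scaled x10) and kept above a score cutoff
(default 250) and length floor (50 bp).  Overlapping hits from different
subfamilies are resolved by score, then length, then position.  Each hit
is classified as complete, fragmented, or solo LTR from its footprint on
the consensus, and per-genome summaries report copy numbers, masked base
pairs and the masked genome fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import SubjectIndex, find_local_matches, interval_union_length
from .errors import ConfigurationError

SCORE_SCALE = 10


@dataclass(frozen=True)
class LibraryConsensus:
    """One subfamily consensus with its LTR coordinates.

    The consensus is laid out LTR + internal + LTR; *ltr_length* delimits
    both terminal repeats.
    """

    subfamily_id: str
    sequence: str
    ltr_length: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationHit:
    """A library-masking match on the genome."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily_id: str
    score: float  # masking-convention score (raw alignment score x 10)
    identity: float
    query_start: int  # footprint on the consensus (forward orientation)
    query_end: int
    completeness: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSummary:
    """Table-style per-subfamily and total annotation summary."""

    genome_bp: int
    per_subfamily: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def copy_number_total(self) -> int:
        return int(sum(v["copy_number_total"] for v in self.per_subfamily.values()))

    @property
    def copy_number_complete(self) -> int:
        return int(sum(v["copy_number_complete"] for v in self.per_subfamily.values()))

    @property
    def masked_bp(self) -> int:
        return int(sum(v["masked_bp"] for v in self.per_subfamily.values()))

    @property
    def fraction_percent(self) -> float:
        return 100.0 * self.masked_bp / self.genome_bp if self.genome_bp else 0.0


def classify_completeness(
    hit: AnnotationHit,
    consensus: LibraryConsensus,
    min_complete_cov: float = 0.80,
    end_window: int = 20,
    min_ltr_cov: float = 0.80,
) -> str:
    """complete / solo_ltr / fragmented from the hit's consensus footprint.

    Complete: covers >= *min_complete_cov* of the consensus and reaches
    into both terminal *end_window*-bp LTR ends.  Solo LTR: confined to
    one LTR's coordinates, covering >= *min_ltr_cov* of it.  Otherwise
    fragmented.
    """
    qs, qe = hit.query_start, hit.query_end
    L = consensus.length
    ltr = consensus.ltr_length
    covered = qe - qs
    if (
        covered >= min_complete_cov * L
        and qs < end_window
        and qe > L - end_window
    ):
        return "complete"
    for lo, hi in ((0, ltr), (L - ltr, L)):
        if qs >= lo - 5 and qe <= hi + 5 and covered >= min_ltr_cov * ltr:
            return "solo_ltr"
    return "fragmented"


def _resolve(hits: list[AnnotationHit]) -> list[AnnotationHit]:
    """Keep the best hit among overlapping ones: score, length, leftmost."""
    order = sorted(hits, key=lambda h: (-h.score, -h.length, h.start, h.subfamily_id))
    kept: list[AnnotationHit] = []
    for h in order:
        if any(
            h.chrom == k.chrom and h.start < k.end and k.start < h.end for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start))
    return kept


def mask(
    genome: dict[str, str],
    library: list[LibraryConsensus],
    min_score: float = 250.0,
    min_len: int = 50,
    min_identity: float = 0.60,
) -> list[AnnotationHit]:
    """Annotate all copies (complete and fragmented) of library consensuses.

    Aligns every consensus to both strands of every chromosome and keeps
    hits with masking score >= *min_score* and length >= *min_len*;
    overlapping hits are resolved by score, then length, then position.
    """
    if not library:
        raise ConfigurationError("empty consensus library")
    all_hits: list[AnnotationHit] = []
    for chrom, seq in genome.items():
        index = SubjectIndex(seq)
        for cons in library:
            for gh in find_local_matches(
                cons.sequence,
                index,
                min_identity=min_identity,
                min_len=min_len,
                both_strands=True,
            ):
                score = gh.score * SCORE_SCALE
                if score < min_score or gh.end - gh.start < min_len:
                    continue
                hit = AnnotationHit(
                    chrom=chrom,
                    start=gh.start,
                    end=gh.end,
                    strand=gh.strand,
                    subfamily_id=cons.subfamily_id,
                    score=score,
                    identity=gh.identity,
                    query_start=gh.query_start,
                    query_end=gh.query_end,
                )
                hit = AnnotationHit(
                    **{**hit.__dict__, "completeness": classify_completeness(hit, cons)}
                )
                all_hits.append(hit)
    return _resolve(all_hits)


def summarize(hits: list[AnnotationHit], genome_bp: int) -> GenomeSummary:
    """Copy numbers, masked bp (interval union) and masked fraction."""
    summary = GenomeSummary(genome_bp=genome_bp)
    by_sf: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        by_sf.setdefault(h.subfamily_id, []).append(h)
    for sf, sf_hits in sorted(by_sf.items()):
        masked = sum(
            interval_union_length(
                [(h.start, h.end) for h in sf_hits if h.chrom == chrom]
            )
            for chrom in {h.chrom for h in sf_hits}
        )
        summary.per_subfamily[sf] = {
            "copy_number_total": len(sf_hits),
            "copy_number_complete": sum(
                1 for h in sf_hits if h.completeness == "complete"
            ),
            "copy_number_solo": sum(
                1 for h in sf_hits if h.completeness == "solo_ltr"
            ),
            "masked_bp": masked,
            "fraction_percent": 100.0 * masked / genome_bp if genome_bp else 0.0,
        }
    return summary


# ---------------------------------------------------------------------------
# segment-level annotation (input to tandem-array detection)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """An LTR (kind 'L') or internal (kind 'I') segment on the genome."""

    chrom: str
    start: int
    end: int
    kind: str
    strand: str
    subfamily_id: str
    identity: float


def annotate_segments(
    genome: dict[str, str],
    library: list[LibraryConsensus],
    min_identity: float = 0.70,
    min_cov: float = 0.60,
) -> list[Segment]:
    """Genome-wide LTR and internal-region segments per subfamily.

    The LTR and the internal part of each consensus are searched
    separately on both strands; a match must cover >= *min_cov* of the
    query part.  Output is sorted by position.
    """
    out: list[Segment] = []
    for chrom, seq in genome.items():
        index = SubjectIndex(seq)
        for cons in library:
            parts = {
                "L": cons.sequence[: cons.ltr_length],
                "I": cons.sequence[cons.ltr_length : len(cons.sequence) - cons.ltr_length],
            }
            for kind, part in parts.items():
                if not part:
                    continue
                for gh in find_local_matches(
                    part, index, min_identity=min_identity, min_len=20, both_strands=True
                ):
                    if gh.query_span < min_cov * len(part):
                        continue
                    out.append(
                        Segment(
                            chrom=chrom,
                            start=gh.start,
                            end=gh.end,
                            kind=kind,
                            strand=gh.strand,
                            subfamily_id=cons.subfamily_id,
                            identity=gh.identity,
                        )
                    )
    # resolve overlapping segments of the same kind (different subfamilies)
    out.sort(key=lambda s: (s.chrom, s.start, s.kind))
    resolved: list[Segment] = []
    for seg in sorted(out, key=lambda s: (-(s.end - s.start) * s.identity, s.start)):
        if any(
            seg.chrom == r.chrom
            and seg.start < r.end
            and r.start < seg.end
            and min(seg.end, r.end) - max(seg.start, r.start)
            > 0.5 * min(seg.end - seg.start, r.end - r.start)
            for r in resolved
        ):
            continue
        resolved.append(seg)
    resolved.sort(key=lambda s: (s.chrom, s.start))
    return resolved
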