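"""Detection and classification of tandemly arrayed elements (TA-TRIMs).

A tandem array is a run of LTR (L) and internal (I) segments -- at least
three LTRs -- with only small gaps between consecutive segments.  Arrays
are written as structure strings ``LnIm`` (e.g. ``L3I2``: two elements
sharing the middle LTR) and flagged as *inverted* when segment strands
change within the run, the arrangement of two head-to-head elements.
Whole-array target-site duplications are reported but never used as a
filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .library_masker import Segment


@dataclass
class TandemArray:
    """A run of >= 3 LTR segments with their internal spacers."""

    chrom: str
    start: int
    end: int
    segments: list[Segment]
    structure: str
    inverted: bool
    non_canonical: bool = False
    tsd: str | None = None

    @property
    def n_ltr(self) -> int:
        return sum(1 for s in self.segments if s.kind == "L")

    @property
    def n_internal(self) -> int:
        return sum(1 for s in self.segments if s.kind == "I")


def structure_string(segments: list[Segment]) -> tuple[str, bool, bool]:
    """``("LnIm", inverted, non_canonical)`` for ordered segments.

    inverted is True when strand changes within the run; non_canonical
    flags runs that do not start and end with an LTR.
    """
    n_l = sum(1 for s in segments if s.kind == "L")
    n_i = len(segments) - n_l
    strands = {s.strand for s in segments}
    inverted = len(strands) > 1
    non_canonical = not segments or segments[0].kind != "L" or segments[-1].kind != "L"
    return f"L{n_l}I{n_i}", inverted, non_canonical


def detect_arrays(
    segments: list[Segment],
    genome: dict[str, str] | None = None,
    gap_tol: int = 10,
    min_ltrs: int = 3,
) -> list[TandemArray]:
    """Merge adjacent segments (gap <= *gap_tol*) into arrays of >= 3 LTRs.

    Ordinary two-LTR elements (``L2I1``) are not arrays.  When *genome*
    is given, a whole-array TSD (exact 4-6 bp duplication flanking the
    full array span) is reported when present.
    """
    arrays: list[TandemArray] = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in sorted(by_chrom.items()):
        segs = sorted(segs, key=lambda s: s.start)
        run: list[Segment] = []
        for seg in segs + [None]:  # type: ignore[list-item]
            if run and (
                seg is None or seg.start - run[-1].end > gap_tol
            ):
                if sum(1 for s in run if s.kind == "L") >= min_ltrs:
                    structure, inverted, non_canonical = structure_string(run)
                    arr = TandemArray(
                        chrom=chrom,
                        start=run[0].start,
                        end=run[-1].end,
                        segments=list(run),
                        structure=structure,
                        inverted=inverted,
                        non_canonical=non_canonical,
                    )
                    if genome is not None:
                        arr.tsd = validate_array_tsd(arr, genome)
                    arrays.append(arr)
                run = []
            if seg is not None:
                run.append(seg)
    return arrays


def validate_array_tsd(
    array: TandemArray, genome: dict[str, str], tsd_min: int = 4, tsd_max: int = 6
) -> str | None:
    """Exact 4-6 bp duplication flanking the whole array span, if any."""
    seq = genome[array.chrom]
    if array.start < tsd_max or array.end + tsd_max > len(seq):
        return None
    for length in range(tsd_max, tsd_min - 1, -1):
        left = seq[array.start - length : array.start].upper()
        right = seq[array.end : array.end + length].upper()
        if left == right and "N" not in left:
            return left
    return None


def array_summary(arrays: list[TandemArray]) -> pd.DataFrame:
    """Frequency table of structure strings with percentages of all arrays."""
    if not arrays:
        return pd.DataFrame(columns=["structure", "count", "percent"])
    counts: dict[str, int] = {}
    for a in arrays:
        counts[a.structure] = counts.get(a.structure, 0) + 1
    total = len(arrays)
    rows = [
        {"structure": s, "count": n, "percent": 100.0 * n / total}
        for s, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)
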