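"""The three defining criteria of a miniature LTR element (TRIM).

A candidate from the structural scan is retained as a TRIM only when

1. it is shorter than 1,500 bp and contains no gaps (no ``N``), with a
   target-site duplication delimiting its boundaries;
2. its subfamily has copy-number support: at least two complete copies
   flanked by *different* TSD sequences, or one complete copy plus one
   solo LTR (the TSD requirement guards against segmental duplications
   and tandem repeats masquerading as elements);
3. it has no retrotransposase coding capacity (no long translated frame
   matching a retroelement protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

from ._align import find_local_matches
from .clustering import UnionFind, pairwise_coverage_identity, _shared_kmers
from .structural_scanner import CandidateElement

MAX_TRIM_LENGTH = 1500


@dataclass(frozen=True)
class TRIMElement:
    """A candidate that passed all three TRIM criteria."""

    candidate: CandidateElement
    subfamily_index: int
    copy_support: str  # 'multi_complete' | 'complete_plus_solo'

    @property
    def start(self) -> int:
        return self.candidate.start

    @property
    def end(self) -> int:
        return self.candidate.end


@dataclass
class FilterReport:
    """Accounting of retained and rejected candidates."""

    retained: list[TRIMElement] = field(default_factory=list)
    rejected: list[tuple[CandidateElement, str]] = field(default_factory=list)

    def rejection_reasons(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.rejected:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


def find_solo_ltrs(
    genome: dict[str, str] | str,
    ltr_consensus: str,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    exclude: list[CandidateElement] | None = None,
) -> list[tuple[str, int, int]]:
    """Genomic matches of a single LTR that are not part of an LTR pair.

    A solo LTR is a local match of the LTR consensus at >= *min_identity*
    identity over >= *min_coverage* of the consensus length, outside every
    excluded candidate's span.  Returns ``(chrom, start, end)`` tuples.
    """
    genomes = {"seq": genome} if isinstance(genome, str) else genome
    exclude = exclude or []
    out: list[tuple[str, int, int]] = []
    for chrom, seq in genomes.items():
        for hit in find_local_matches(
            ltr_consensus, seq, min_identity=min_identity, min_len=10
        ):
            if hit.query_span < min_coverage * len(ltr_consensus):
                continue
            if any(
                c.chrom == chrom and hit.start < c.end and c.start < hit.end
                for c in exclude
            ):
                continue
            out.append((chrom, hit.start, hit.end))
    return sorted(out)


_PROTEIN_ALIGNER = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        _PROTEIN_ALIGNER = aligner
    return _PROTEIN_ALIGNER


def six_frame_peptides(seq: str, min_aa: int = 100) -> list[str]:
    """Stop-to-stop peptides of >= *min_aa* residues in all six frames."""
    peptides = []
    for frame_seq in (seq, str(Seq(seq).reverse_complement())):
        for offset in range(3):
            sub = frame_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            translated = str(Seq(sub).translate())
            peptides.extend(p for p in translated.split("*") if len(p) >= min_aa)
    return peptides


def coding_capacity(
    element_seq: str,
    proteins: dict[str, str],
    min_identity: float = 0.50,
    min_aln_aa: int = 80,
    min_peptide_aa: int = 100,
) -> tuple[bool, tuple[str, float, int] | None]:
    """Does the element translate into a retroelement-like protein?

    True iff any six-frame stop-free peptide of >= *min_peptide_aa*
    residues aligns locally to any protein at >= *min_identity* identity
    over >= *min_aln_aa* aligned columns.  Elements shorter than 300 bp
    cannot host a 100-aa frame and return False.  Also returns the best
    hit as ``(protein_id, identity, aligned_columns)``.
    """
    if len(element_seq) < 3 * min_peptide_aa or not proteins:
        return False, None
    peptides = six_frame_peptides(element_seq, min_peptide_aa)
    best: tuple[str, float, int] | None = None
    for pep in peptides:
        for pid, prot in proteins.items():
            aligner = _protein_aligner()
            try:
                aln = aligner.align(prot, pep)[0]
            except (IndexError, ValueError):
                continue
            tb, qb = aln.aligned
            if len(tb) == 0:
                continue
            matches = sum(
                sum(x == y for x, y in zip(prot[ts:te], pep[qs:qe]))
                for (ts, te), (qs, qe) in zip(tb, qb)
            )
            columns = 0
            prev_t = prev_q = None
            for (ts, te), (qs, qe) in zip(tb, qb):
                if prev_t is not None:
                    columns += (ts - prev_t) + (qs - prev_q)
                columns += te - ts
                prev_t, prev_q = te, qe
            if columns == 0:
                continue
            ident = matches / columns
            if columns >= min_aln_aa and ident >= min_identity:
                if best is None or (ident, columns) > (best[1], best[2]):
                    best = (pid, ident, columns)
    return best is not None, best


def provisional_clusters(
    candidates: list[CandidateElement],
    genome: dict[str, str],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
) -> list[int]:
    """Single-linkage 80/80 cluster index per candidate."""
    seqs = [c.sequence(genome) for c in candidates]
    uf = UnionFind(len(candidates))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if not _shared_kmers(seqs[i], seqs[j]):
                continue
            ident, cov = pairwise_coverage_identity(seqs[i], seqs[j])
            if ident >= min_identity and cov >= min_coverage:
                uf.union(i, j)
    roots = [uf.find(i) for i in range(len(candidates))]
    index_of_root: dict[int, int] = {}
    out = []
    for r in roots:
        if r not in index_of_root:
            index_of_root[r] = len(index_of_root)
        out.append(index_of_root[r])
    return out


def apply_trim_criteria(
    candidates: list[CandidateElement],
    genome: dict[str, str],
    proteins: dict[str, str] | None = None,
    max_length: int = MAX_TRIM_LENGTH,
) -> FilterReport:
    """Retain candidates that satisfy all three TRIM criteria.

    The retained and rejected sets partition the input; every rejected
    candidate carries the first criterion it failed
    (``too_long`` / ``contains_n`` / ``no_tsd`` / ``insufficient_copies``
    / ``coding_capacity``).
    """
    proteins = proteins or {}
    report = FilterReport()
    if not candidates:
        return report
    clusters = provisional_clusters(candidates, genome)

    structural_fail: dict[int, str] = {}
    for i, cand in enumerate(candidates):
        seq = cand.sequence(genome).upper()
        if cand.length >= max_length:
            structural_fail[i] = "too_long"
        elif "N" in seq:
            structural_fail[i] = "contains_n"
        elif cand.tsd is None:
            structural_fail[i] = "no_tsd"

    # copy-number support per provisional cluster, counting only
    # structurally sound complete copies
    solo_cache: dict[int, bool] = {}
    support: dict[int, str | None] = {}
    for ci in sorted(set(clusters)):
        members = [
            i for i in range(len(candidates)) if clusters[i] == ci and i not in structural_fail
        ]
        tsds = {candidates[i].tsd[0] for i in members if candidates[i].tsd}
        if len(tsds) >= 2:
            support[ci] = "multi_complete"
            continue
        if members:
            rep = candidates[members[0]]
            ltr_seq = rep.sequence(genome)[: rep.ltr5[1] - rep.ltr5[0]]
            if ci not in solo_cache:
                solos = find_solo_ltrs(genome, ltr_seq, exclude=candidates)
                solo_cache[ci] = len(solos) >= 1
            support[ci] = "complete_plus_solo" if solo_cache[ci] else None
        else:
            support[ci] = None

    for i, cand in enumerate(candidates):
        if i in structural_fail:
            report.rejected.append((cand, structural_fail[i]))
            continue
        sup = support[clusters[i]]
        if sup is None:
            report.rejected.append((cand, "insufficient_copies"))
            continue
        has_coding, _ = coding_capacity(cand.sequence(genome), proteins)
        if has_coding:
            report.rejected.append((cand, "coding_capacity"))
            continue
        report.retained.append(TRIMElement(cand, clusters[i], sup))
    return report
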