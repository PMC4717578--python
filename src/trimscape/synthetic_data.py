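"""Synthetic genomes with implanted miniature LTR retrotransposons.

Every downstream stage of the pipeline is exercised against genomes built
here, where the exact coordinates, sequences, target-site duplications
(TSDs) and subfamily labels of all implanted features are known.

The generator emulates the study inputs of a TRIM survey:

* complete elements -- ``TSD + LTR + internal + LTR' + TSD`` where the two
  TSD copies are identical host-derived sequence and the 3' LTR has
  diverged from the 5' LTR by at most the configured substitution rate;
* solo LTRs -- a single LTR with its own TSD pair;
* tandem arrays -- alternating LTR/internal segments (``L3I2`` etc.),
  optionally followed by their reverse complement (inverted arrays);
* an autonomous "partner" retroelement carrying a duplicated internal
  sequence at the deletion breakpoint that relates it to a derived TRIM;
* multi-exon gene models;
* per-cytosine bisulfite count tables and small-RNA alignments realising
  the Type I / II / III methylation archetypes of TRIM families.

Insertion mechanics: an insertion at background position ``p`` with TSD
length ``t`` duplicates the host bases ``bg[p-t:p]`` so the final genome
reads ``bg[:p] + element + bg[p-t:p] + bg[p:]``.  Deleting every element
plus its 3' TSD copy therefore restores the background byte-for-byte,
which is the generator's central testable invariant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._align import revcomp
from .errors import FormatError, SizingError

#: margin kept element-free at both chromosome ends
EDGE_MARGIN = 150
#: minimum separation between insertion points on the background
MIN_SEPARATION = 60

BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartnerSpec:
    """Geometry of an autonomous partner and its derived TRIM.

    ``breakpoint_offset`` is the coordinate on the derived TRIM (and,
    identically, on the partner) where the 5' block ends: the internal
    deletion that produced the TRIM starts there.  ``orf_aa`` > 0 embeds a
    retrotransposase-like open reading frame of that many residues in the
    deleted (partner-only) region.
    """

    partner_length: int = 5000
    dup_seq_length: int = 25
    breakpoint_offset: int = 130
    trim_length: int = 408
    ltr_length: int = 115
    ltr_divergence: float = 0.03
    dup_divergence: float = 0.04
    orf_aa: int = 0


@dataclass(frozen=True)
class SimulationSpec:
    """All knobs of one simulated genome."""

    genome_length: int = 200_000
    gc_content: float = 0.40
    n_trims: int = 20
    ltr_len_range: tuple[int, int] = (80, 200)
    internal_len_range: tuple[int, int] = (100, 600)
    divergence: float = 0.02
    tsd_len_range: tuple[int, int] = (4, 6)
    n_solo_ltrs: int = 0
    array_specs: tuple[str, ...] = ()
    n_genes: int = 0
    n_subfamilies: int = 3
    n_decoy_tandem_repeats: int = 0
    intron_bias: float = 0.0
    partner_spec: PartnerSpec | None = None
    seed: int = 0
    chrom: str = "chr1"

    def validate(self) -> None:
        lo, hi = self.ltr_len_range
        if not (30 <= lo <= hi <= 500):
            raise SizingError(f"ltr_len_range {self.ltr_len_range} outside [30, 500]")
        ilo, ihi = self.internal_len_range
        if not (30 <= ilo <= ihi <= 2000):
            raise SizingError(f"internal_len_range {self.internal_len_range} outside [30, 2000]")
        tlo, thi = self.tsd_len_range
        if not (4 <= tlo <= thi <= 6):
            raise SizingError(f"tsd_len_range {self.tsd_len_range} outside [4, 6]")
        if not (0.0 <= self.divergence <= 0.3):
            raise SizingError(f"divergence {self.divergence} outside [0, 0.3]")
        if not (0.0 < self.gc_content < 1.0):
            raise SizingError("gc_content must be in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth for one implanted feature (0-based half-open interval)."""

    element_id: str
    chrom: str
    start: int
    end: int
    kind: str  # complete | solo_ltr | array | partner | decoy
    tsd: str
    subfamily_id: str
    structure: str = ""
    ltr_len: int = 0
    bg_pos: int = -1  # insertion point on the background sequence

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class GeneModel:
    """A gene with one (implied) mRNA and ordered exons; 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class PartnerSim:
    """Output of :func:`simulate_partner`."""

    partner_seq: str
    trim_seq: str
    dup_seq: str
    breakpoint: int  # junction coordinate on the TRIM / partner 5' block
    deleted_len: int
    ltr_len: int
    orf_protein: str | None = None


# ---------------------------------------------------------------------------
# low-level sequence helpers
# ---------------------------------------------------------------------------


def random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p)) if n else ""


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at per-site probability *rate*."""
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


_CODONS_BY_AA: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODONS_BY_AA:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS_BY_AA.setdefault(aa, codon)
    return _CODONS_BY_AA


def back_translate(protein: str) -> str:
    """A deterministic coding sequence for *protein* (first codon per residue)."""
    table = _codon_table()
    return "".join(table[aa] for aa in protein)


def random_protein(n_aa: int, rng: np.random.Generator) -> str:
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(aas, size=n_aa))


# ---------------------------------------------------------------------------
# subfamily construction
# ---------------------------------------------------------------------------


@dataclass
class _Subfamily:
    sf_id: str
    ltr: str
    internal: str


def _make_subfamilies(spec: SimulationSpec, rng: np.random.Generator) -> list[_Subfamily]:
    subs = []
    for i in range(max(1, spec.n_subfamilies)):
        ltr_len = int(rng.integers(spec.ltr_len_range[0], spec.ltr_len_range[1] + 1))
        int_len = int(rng.integers(spec.internal_len_range[0], spec.internal_len_range[1] + 1))
        ltr = "TG" + random_seq(max(0, ltr_len - 4), spec.gc_content, rng) + "CA"
        internal = random_seq(int_len, spec.gc_content, rng)
        subs.append(_Subfamily(f"sf{i + 1}", ltr, internal))
    return subs


def _trim_copy(sf: _Subfamily, divergence: float, rng: np.random.Generator) -> tuple[str, str, str]:
    """(ltr5, internal, ltr3) for one copy; the 3' LTR diverges from the 5'."""
    d_copy = float(rng.uniform(0, divergence)) if divergence > 0 else 0.0
    ltr5 = mutate(sf.ltr, d_copy / 2, rng)
    internal = mutate(sf.internal, d_copy / 2, rng)
    ltr3 = mutate(ltr5, float(rng.uniform(0, divergence)) if divergence > 0 else 0.0, rng)
    return ltr5, internal, ltr3


_ARRAY_RE = re.compile(r"^L(\d+)I(\d+)(!?)$")


def _array_segments(
    sf: _Subfamily, structure: str, divergence: float, rng: np.random.Generator
) -> tuple[list[tuple[str, str, str]], str]:
    """Segments ``(kind, seq, strand)`` for a structure string.

    ``"LnIm"`` builds the canonical alternation L,I,L,...,L (requires
    n == m + 1).  A trailing ``"!"`` appends the reverse complement of the
    forward unit, modelling the two-inverted-elements arrangement; the
    returned canonical structure string counts all segments.
    """
    m = _ARRAY_RE.match(structure)
    if not m:
        raise FormatError(f"unparseable array structure {structure!r}")
    n_l, n_i, inv = int(m.group(1)), int(m.group(2)), bool(m.group(3))
    if n_l != n_i + 1:
        raise FormatError(f"array {structure!r} is not a canonical L(m+1)Im alternation")
    segs: list[tuple[str, str, str]] = []
    for j in range(n_l + n_i):
        kind = "L" if j % 2 == 0 else "I"
        master = sf.ltr if kind == "L" else sf.internal
        segs.append((kind, mutate(master, divergence / 2, rng), "+"))
    if inv:
        rev = [(kind, revcomp(seq), "-") for kind, seq, _ in reversed(segs)]
        segs = segs + rev
    total_l = sum(1 for k, _, _ in segs if k == "L")
    total_i = len(segs) - total_l
    return segs, f"L{total_l}I{total_i}"


# ---------------------------------------------------------------------------
# partner / derived-TRIM construction
# ---------------------------------------------------------------------------


def simulate_partner(spec: SimulationSpec, rng: np.random.Generator | None = None) -> PartnerSim:
    """Build an autonomous partner and its internally deleted TRIM derivative.

    The partner reads ``LTR + A + D + M + D' + B + LTR'`` and the derived
    TRIM is the partner with ``M + D'`` deleted, i.e. ``LTR + A + D + B +
    LTR'``: the near-identical copies ``D`` and ``D'`` (the *duplicated
    internal sequence*) flank the deleted segment at the breakpoint.
    """
    if spec.partner_spec is None:
        raise SizingError("partner_spec missing from SimulationSpec")
    ps = spec.partner_spec
    rng = np.random.default_rng(spec.seed + 7) if rng is None else rng
    ltr_len = ps.ltr_length
    trim_internal_len = ps.trim_length - 2 * ltr_len
    if trim_internal_len <= 0:
        raise SizingError("trim_length too small for two LTRs")
    if ps.dup_seq_length >= trim_internal_len:
        raise SizingError(
            f"dup_seq length {ps.dup_seq_length} >= internal length {trim_internal_len}"
        )
    deleted_len = ps.partner_length - ps.trim_length
    if deleted_len < 0:
        raise SizingError("partner_length smaller than trim_length")
    if deleted_len == 0 and ps.dup_seq_length > 0:
        raise SizingError("zero deletion requires dup_seq_length == 0")
    bp = ps.breakpoint_offset
    if bp < ps.dup_seq_length:
        raise SizingError("breakpoint_offset before the end of the dup_seq")
    if bp > ps.trim_length - ltr_len:
        raise SizingError("breakpoint_offset inside the 3' LTR")
    len_m = deleted_len - ps.dup_seq_length
    if deleted_len > 0 and len_m < 0:
        raise SizingError("deletion shorter than the duplicated internal sequence")

    gc = spec.gc_content
    ltr5 = "TG" + random_seq(ltr_len - 4, gc, rng) + "CA"
    ltr3 = mutate(ltr5, ps.ltr_divergence, rng)
    internal = random_seq(trim_internal_len, gc, rng)
    trim = ltr5 + internal + ltr3
    d = trim[bp - ps.dup_seq_length : bp]
    orf_protein: str | None = None
    if deleted_len == 0:
        m_seg = ""
        d2 = ""
    else:
        d2 = mutate(d, ps.dup_divergence, rng)
        if ps.orf_aa > 0:
            orf_protein = random_protein(ps.orf_aa, rng)
            cds = "ATG" + back_translate(orf_protein) + "TAA"
            pad = len_m - len(cds)
            if pad < 0:
                raise SizingError(
                    f"deleted segment ({len_m} bp) cannot host a {ps.orf_aa}-aa ORF"
                )
            left = pad // 2
            m_seg = random_seq(left, gc, rng) + cds + random_seq(pad - left, gc, rng)
        else:
            m_seg = random_seq(len_m, gc, rng)
        if len_m >= 2 and ps.dup_seq_length > 0:
            # keep the planted duplication exactly dup_seq_length long:
            # the columns flanking the two copies must mismatch, which
            # the deleted segment's edge bases control (left of D' is
            # M's tail; right of D is M's head, while right of D' is the
            # TRIM's 3' block)
            def _differ(base: str) -> str:
                return "ACGT"[("ACGT".index(base) + 1) % 4]

            tail = list(m_seg)
            for k in range(1, min(8, len_m - 1) + 1):
                tail[-k] = _differ(trim[bp - ps.dup_seq_length - k])
            tail[0] = _differ(trim[bp])
            m_seg = "".join(tail)
    # partner = TRIM 5' block + deleted segment (M + D') + TRIM 3' block;
    # the two dup copies (D in the 5' block, D' ending the deleted
    # segment) flank the deleted segment
    partner = trim[:bp] + m_seg + d2 + trim[bp:]
    assert len(partner) == ps.partner_length and len(trim) == ps.trim_length
    return PartnerSim(
        partner_seq=partner,
        trim_seq=trim,
        dup_seq=d,
        breakpoint=bp,
        deleted_len=deleted_len,
        ltr_len=ltr_len,
        orf_protein=orf_protein,
    )


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


@dataclass
class _Insertion:
    bg_pos: int
    element_seq: str
    tsd_len: int
    kind: str
    subfamily_id: str
    structure: str = ""
    ltr_len: int = 0


def _make_genes(spec: SimulationSpec, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    if spec.n_genes == 0:
        return genes
    structures = []
    for _ in range(spec.n_genes):
        n_exons = int(rng.integers(2, 7))
        exon_lens = rng.integers(150, 401, size=n_exons)
        intron_lens = rng.integers(200, 801, size=n_exons - 1)
        structures.append((exon_lens, intron_lens))
    total = sum(int(e.sum() + i.sum()) for e, i in structures)
    avail = spec.genome_length - 2 * EDGE_MARGIN - 200 * spec.n_genes
    if total > avail:
        raise SizingError(
            f"genome of {spec.genome_length} bp cannot host {spec.n_genes} genes "
            f"({total} bp needed, {avail} bp available)"
        )
    # lay genes left-to-right with random gaps
    slack = avail - total
    gaps = rng.multinomial(slack, np.ones(spec.n_genes) / spec.n_genes)
    pos = EDGE_MARGIN
    for gi, (exon_lens, intron_lens) in enumerate(structures):
        pos += int(gaps[gi]) + 200
        start = pos
        exons = []
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{gi + 1}", spec.chrom, strand, start, pos, exons))
    return genes


def _sample_positions(
    n: int,
    spec: SimulationSpec,
    rng: np.random.Generator,
    taken: list[int],
    genes: list[GeneModel],
) -> list[int]:
    lo, hi = EDGE_MARGIN, spec.genome_length - EDGE_MARGIN
    if hi <= lo or (n + len(taken)) * MIN_SEPARATION > (hi - lo):
        raise SizingError(
            f"genome of {spec.genome_length} bp cannot host {n + len(taken)} insertions "
            f"at {MIN_SEPARATION}-bp separation"
        )
    introns = [iv for g in genes for iv in g.introns]
    out: list[int] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise SizingError("could not place all insertions; genome too crowded")
        p = int(rng.integers(lo, hi))
        if spec.intron_bias > 0 and not any(s <= p < e for s, e in introns):
            if rng.random() < spec.intron_bias / (1 + spec.intron_bias):
                continue
        if all(abs(p - q) >= MIN_SEPARATION for q in taken + out):
            out.append(p)
    return out


def _materialize(
    background: str, insertions: list[_Insertion], chrom: str
) -> tuple[str, list[TruthRecord]]:
    """Apply insertions left-to-right, duplicating the host TSD."""
    insertions = sorted(insertions, key=lambda ins: ins.bg_pos)
    parts: list[str] = []
    truths: list[TruthRecord] = []
    prev = 0
    offset = 0
    for idx, ins in enumerate(insertions):
        p, t = ins.bg_pos, ins.tsd_len
        parts.append(background[prev:p])
        tsd = background[p - t : p] if t else ""
        start = p + offset
        parts.append(ins.element_seq)
        parts.append(tsd)
        truths.append(
            TruthRecord(
                element_id=f"{ins.kind}_{idx + 1}",
                chrom=chrom,
                start=start,
                end=start + len(ins.element_seq),
                kind=ins.kind,
                tsd=tsd,
                subfamily_id=ins.subfamily_id,
                structure=ins.structure,
                ltr_len=ins.ltr_len,
                bg_pos=p,
            )
        )
        offset += len(ins.element_seq) + t
        prev = p
    parts.append(background[prev:])
    return "".join(parts), truths


def _map_coord(insertions: list[_Insertion], x: int) -> int:
    """Final-genome coordinate of background coordinate *x*."""
    shift = sum(
        len(ins.element_seq) + ins.tsd_len for ins in insertions if ins.bg_pos <= x
    )
    return x + shift


def _lift_genes(genes: list[GeneModel], insertions: list[_Insertion]) -> list[GeneModel]:
    ins_sorted = sorted(insertions, key=lambda i: i.bg_pos)
    lifted = []
    for g in genes:
        exons = [
            (_map_coord(ins_sorted, s), _map_coord(ins_sorted, e)) for s, e in g.exons
        ]
        lifted.append(
            GeneModel(
                g.gene_id,
                g.chrom,
                g.strand,
                _map_coord(ins_sorted, g.start),
                _map_coord(ins_sorted, g.end),
                exons,
            )
        )
    return lifted


def _plan_insertions(
    spec: SimulationSpec,
    rng: np.random.Generator,
    subfamilies: list[_Subfamily],
    genes: list[GeneModel],
    taken: list[int] | None = None,
    tsd_len_override: int | None = None,
) -> tuple[list[_Insertion], PartnerSim | None]:
    plans: list[_Insertion] = []
    taken = list(taken or [])

    def tsd_len() -> int:
        if tsd_len_override is not None:
            return tsd_len_override
        lo, hi = spec.tsd_len_range
        return int(rng.integers(lo, hi + 1))

    n_partner = 1 if spec.partner_spec is not None else 0
    total = (
        spec.n_trims
        + spec.n_solo_ltrs
        + len(spec.array_specs)
        + spec.n_decoy_tandem_repeats
        + n_partner
    )
    positions = _sample_positions(total, spec, rng, taken, genes)
    pos_iter = iter(positions)

    for i in range(spec.n_trims):
        sf = subfamilies[i % len(subfamilies)]
        ltr5, internal, ltr3 = _trim_copy(sf, spec.divergence, rng)
        plans.append(
            _Insertion(
                next(pos_iter), ltr5 + internal + ltr3, tsd_len(), "complete", sf.sf_id,
                ltr_len=len(ltr5),
            )
        )
    for i in range(spec.n_solo_ltrs):
        sf = subfamilies[i % len(subfamilies)]
        solo = mutate(sf.ltr, spec.divergence / 2, rng)
        plans.append(
            _Insertion(next(pos_iter), solo, tsd_len(), "solo_ltr", sf.sf_id, ltr_len=len(solo))
        )
    for i, structure in enumerate(spec.array_specs):
        sf = subfamilies[i % len(subfamilies)]
        segs, canonical = _array_segments(sf, structure, spec.divergence, rng)
        seq = "".join(s for _, s, _ in segs)
        plans.append(
            _Insertion(
                next(pos_iter), seq, tsd_len(), "array", sf.sf_id,
                structure=canonical, ltr_len=len(sf.ltr),
            )
        )
    for _ in range(spec.n_decoy_tandem_repeats):
        unit = random_seq(int(rng.integers(120, 260)), spec.gc_content, rng)
        plans.append(
            _Insertion(next(pos_iter), unit * int(rng.integers(3, 6)), 0, "decoy", "")
        )
    partner_sim: PartnerSim | None = None
    if spec.partner_spec is not None:
        partner_sim = simulate_partner(spec, rng)
        plans.append(
            _Insertion(
                next(pos_iter), partner_sim.partner_seq, tsd_len(), "partner",
                "sf_partner", ltr_len=partner_sim.ltr_len,
            )
        )
    return plans, partner_sim


@dataclass
class SimulatedGenome:
    """One simulated genome with full ground truth."""

    genome: dict[str, str]
    truth: list[TruthRecord]
    genes: list[GeneModel]
    background: str
    subfamily_ltrs: dict[str, str]
    subfamily_internals: dict[str, str]
    partner: PartnerSim | None = None

    @property
    def seq(self) -> str:
        return next(iter(self.genome.values()))


def simulate_genome(spec: SimulationSpec) -> SimulatedGenome:
    """Generate one chromosome with implanted elements, genes and truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    background = random_seq(spec.genome_length, spec.gc_content, rng)
    genes_bg = _make_genes(spec, rng)
    subfamilies = _make_subfamilies(spec, rng)
    plans, partner_sim = _plan_insertions(spec, rng, subfamilies, genes_bg)
    seq, truth = _materialize(background, plans, spec.chrom)
    genes = _lift_genes(genes_bg, plans)
    return SimulatedGenome(
        genome={spec.chrom: seq},
        truth=truth,
        genes=genes,
        background=background,
        subfamily_ltrs={sf.sf_id: sf.ltr for sf in subfamilies},
        subfamily_internals={sf.sf_id: sf.internal for sf in subfamilies},
        partner=partner_sim,
    )


def reconstruct_background(seq: str, truth: list[TruthRecord]) -> str:
    """Delete every implanted element plus its 3' TSD copy from *seq*."""
    out = seq
    for rec in sorted(truth, key=lambda r: r.start, reverse=True):
        out = out[: rec.start] + out[rec.end + len(rec.tsd) :]
    return out


# ---------------------------------------------------------------------------
# two-genome comparisons
# ---------------------------------------------------------------------------


@dataclass
class GenomePair:
    """Two genomes sharing a background, with per-genome truth."""

    genome_a: dict[str, str]
    genome_b: dict[str, str]
    truth_a: list[TruthRecord]
    truth_b: list[TruthRecord]
    background: str
    shared_ids: set[str]

    def specific_records(self, which: str) -> list[TruthRecord]:
        truth = self.truth_a if which == "a" else self.truth_b
        return [r for r in truth if r.element_id not in self.shared_ids]


def make_genome_pair(spec: SimulationSpec, shared_fraction: float) -> GenomePair:
    """Two genomes over one background: shared insertions at homologous
    coordinates, genome-specific insertions (5-bp TSD) absent in the partner."""
    if not 0.0 <= shared_fraction <= 1.0:
        raise SizingError("shared_fraction must lie in [0, 1]")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    background = random_seq(spec.genome_length, spec.gc_content, rng)
    subfamilies = _make_subfamilies(spec, rng)
    n_shared = int(round(shared_fraction * spec.n_trims))
    n_specific = spec.n_trims - n_shared

    base = replace(spec, n_solo_ltrs=0, array_specs=(), n_decoy_tandem_repeats=0,
                   partner_spec=None, n_genes=0)
    shared_plans, _ = _plan_insertions(
        replace(base, n_trims=n_shared), rng, subfamilies, [], tsd_len_override=5
    )
    taken = [p.bg_pos for p in shared_plans]
    a_plans, _ = _plan_insertions(
        replace(base, n_trims=n_specific), rng, subfamilies, [], taken=taken,
        tsd_len_override=5,
    )
    taken += [p.bg_pos for p in a_plans]
    b_plans, _ = _plan_insertions(
        replace(base, n_trims=n_specific), rng, subfamilies, [], taken=taken,
        tsd_len_override=5,
    )

    def build(extra: list[_Insertion], tag: str) -> tuple[dict[str, str], list[TruthRecord]]:
        plans = sorted(shared_plans + extra, key=lambda i: i.bg_pos)
        seq, truth = _materialize(background, plans, spec.chrom)
        # element ids must identify the planned insertion across genomes
        by_pos = {p.bg_pos: p for p in plans}
        for rec in truth:
            src = by_pos[rec.bg_pos]
            owner = "sh" if src in shared_plans else tag
            rec.element_id = f"{owner}_{rec.bg_pos}"
        return {spec.chrom: seq}, truth

    genome_a, truth_a = build(a_plans, "a")
    genome_b, truth_b = build(b_plans, "b")
    shared_ids = {f"sh_{p.bg_pos}" for p in shared_plans}
    return GenomePair(genome_a, genome_b, truth_a, truth_b, background, shared_ids)


def orthologous_position(pair: GenomePair, bg_pos: int, which: str) -> int:
    """Coordinate in genome *which* ('a'/'b') homologous to a background position."""
    truth = pair.truth_a if which == "a" else pair.truth_b
    shift = sum(
        (r.end - r.start) + len(r.tsd) for r in truth if r.bg_pos <= bg_pos
    )
    return bg_pos + shift


# ---------------------------------------------------------------------------
# methylome emission
# ---------------------------------------------------------------------------

#: per-(type, region) methylation rates by context (CG, CHG, CHH)
_TYPE_RATES: dict[tuple[str, str], tuple[str, ...]] = {
    ("I", "body"): ("high", "high", "high"),
    ("I", "flank"): ("low", "low", "low"),
    ("II", "body"): ("high", "high", "low"),
    ("II", "flank"): ("high", "high", "low"),
    ("III", "body"): ("high", "low", "low"),
    ("III", "flank"): ("low", "low", "low"),
}

_CONTEXTS = ("CG", "CHG", "CHH")


def cytosine_contexts(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand cytosine positions and context codes (0=CG, 1=CHG, 2=CHH)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(arr)
    is_c = arr == ord("C")
    is_c[max(0, n - 2) :] = False  # need two downstream bases for the context
    pos = np.flatnonzero(is_c)
    nxt1 = arr[pos + 1]
    nxt2 = arr[pos + 2]
    ctx = np.full(len(pos), 2, dtype=np.int8)  # CHH
    ctx[nxt1 == ord("G")] = 0  # CG
    ctx[(nxt1 != ord("G")) & (nxt2 == ord("G"))] = 1  # CHG
    return pos, ctx


def emit_methylome(
    genome: dict[str, str],
    truth: list[TruthRecord],
    type_by_subfamily: dict[str, str],
    seed: int,
    high_rate: float = 0.85,
    low_rate: float = 0.05,
    coverage_mean: float = 20.0,
    flank: int = 2000,
) -> pd.DataFrame:
    """Per-cytosine bisulfite counts realising Type I/II/III profiles.

    Counts are binomial draws at the configured per-context rate with
    Poisson coverage; columns: chrom, pos, context, mc, total.
    """
    for label in type_by_subfamily.values():
        if label not in {"I", "II", "III"}:
            raise FormatError(f"unknown methylation type label {label!r}")
    rng = np.random.default_rng(seed)
    level = {"high": high_rate, "low": low_rate}
    frames = []
    for chrom, seq in genome.items():
        pos, ctx = cytosine_contexts(seq)
        if len(pos) == 0:
            continue
        rates = np.full((len(pos), 3), low_rate)
        recs = [
            r for r in truth
            if r.chrom == chrom and r.subfamily_id in type_by_subfamily
            and r.kind in {"complete", "array", "solo_ltr"}
        ]
        for region, lo_off in (("flank", flank), ("body", 0)):
            for r in recs:
                t = type_by_subfamily[r.subfamily_id]
                if region == "flank":
                    sel = ((pos >= r.start - flank) & (pos < r.start)) | (
                        (pos >= r.end) & (pos < r.end + flank)
                    )
                else:
                    sel = (pos >= r.start) & (pos < r.end)
                for ci in range(3):
                    rates[sel, ci] = level[_TYPE_RATES[(t, region)][ci]]
        total = rng.poisson(coverage_mean, size=len(pos))
        keep = total > 0
        if not keep.any():
            continue
        rate_at = rates[np.arange(len(pos)), ctx]
        mc = rng.binomial(total[keep], rate_at[keep])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "context": np.array(_CONTEXTS)[ctx[keep]],
                    "mc": mc,
                    "total": total[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "context", "mc", "total"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# small-RNA emission
# ---------------------------------------------------------------------------


def emit_srna(
    genome: dict[str, str],
    truth: list[TruthRecord],
    type_by_subfamily: dict[str, str],
    seed: int,
    type1_mean_24nt: float = 40.0,
    type1_mean_21nt: float = 3.0,
    stray_mean: float = 0.3,
    background_per_kb: float = 0.5,
    total_mapped_reads: int = 2_000_000,
) -> tuple[pd.DataFrame, int]:
    """Small-RNA alignments (BED-like) with abundant 24-nt reads on Type I bodies.

    Returns the alignment table (chrom, start, end, read_id, length, strand)
    and the library's total mapped read count used for TPM normalisation
    (the table lists only reads falling in the simulated region).
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0

    def add_reads(chrom: str, lo: int, hi: int, n: int, length: int) -> None:
        nonlocal counter
        hi = max(lo + 1, hi - length)
        for _ in range(n):
            s = int(rng.integers(lo, hi))
            counter += 1
            rows.append((chrom, s, s + length, f"r{counter:07d}", length,
                         "+" if rng.random() < 0.5 else "-"))

    for r in truth:
        if r.subfamily_id not in type_by_subfamily or r.kind not in {"complete", "array"}:
            continue
        t = type_by_subfamily[r.subfamily_id]
        if t == "I":
            add_reads(r.chrom, r.start, r.end, int(rng.poisson(type1_mean_24nt)), 24)
            add_reads(r.chrom, r.start, r.end, int(rng.poisson(type1_mean_21nt)), 21)
        else:
            add_reads(r.chrom, r.start, r.end, int(rng.poisson(stray_mean)), 24)
    for chrom, seq in genome.items():
        n_bg = int(rng.poisson(background_per_kb * len(seq) / 1000))
        for _ in range(n_bg):
            length = int(rng.choice([20, 21, 22, 23, 24]))
            s = int(rng.integers(0, max(1, len(seq) - length)))
            counter += 1
            rows.append((chrom, s, s + length, f"r{counter:07d}", length,
                         "+" if rng.random() < 0.5 else "-"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "read_id", "length", "strand"])
    return df, total_mapped_reads
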