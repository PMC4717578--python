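"""Relating element annotations to gene models.

Positional classification of insertions (exon > intron > 1.5-kb upstream
> intergenic, each hit counted once), TRIM-related-gene (TRG) versus
other-gene (NTRG) structure statistics, insertion densities across gene
size classes, gene-capture detection in element internal regions, and a
Nei-Gojobori (1986) Ka/Ks estimator with Jukes-Cantor correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._align import local_align
from .errors import AnnotationError, FormatError
from .synthetic_data import GeneModel

UPSTREAM_BP = 1500


@dataclass(frozen=True)
class InsertionContext:
    hit_id: str
    gene_id: str | None
    category: str  # exon | intron | upstream_1500 | intergenic


def classify_insertions(
    hits: list[tuple[str, str, int, int]],
    genes: list[GeneModel],
    upstream_bp: int = UPSTREAM_BP,
) -> list[InsertionContext]:
    """Assign each hit ``(hit_id, chrom, start, end)`` one positional class.

    Precedence: exon > intron > upstream (within *upstream_bp* of the
    TSS, outside any gene) > intergenic, so a hit spanning an exon
    boundary is counted once as exonic.  A hit overlapping two genes goes
    to the gene whose exon it touches, else the longer gene.
    """
    if genes and not any(g.exons for g in genes):
        raise AnnotationError("gene models carry no exon features")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for hit_id, chrom, start, end in hits:
        chrom_genes = by_chrom.get(chrom, [])
        touching = [g for g in chrom_genes if start < g.end and g.start < end]
        category = "intergenic"
        gene_id: str | None = None
        if touching:
            exon_genes = [
                g
                for g in touching
                if any(start < e and s < end for s, e in g.exons)
            ]
            if exon_genes:
                gene = max(exon_genes, key=lambda g: g.length)
                category = "exon"
            else:
                gene = max(touching, key=lambda g: g.length)
                category = "intron"
            gene_id = gene.gene_id
        else:
            for g in chrom_genes:
                if g.strand == "+":
                    window = (g.start - upstream_bp, g.start)
                else:
                    window = (g.end, g.end + upstream_bp)
                if start < window[1] and window[0] < end:
                    category = "upstream_1500"
                    gene_id = g.gene_id
                    break
        out.append(InsertionContext(hit_id, gene_id, category))
    return out


def context_percentages(contexts: list[InsertionContext]) -> dict[str, float]:
    total = len(contexts)
    cats = ["exon", "intron", "upstream_1500", "intergenic"]
    if total == 0:
        return {c: 0.0 for c in cats}
    return {
        c: 100.0 * sum(1 for x in contexts if x.category == c) / total for c in cats
    }


def trg_stats(
    contexts: list[InsertionContext], genes: list[GeneModel]
) -> pd.DataFrame:
    """Gene-structure comparison of TRGs (genes with an exonic or intronic
    insertion) against all other genes.

    Returns one row per metric (exon_count, gene_length, mean_exon_length,
    mean_intron_length) with class means and the two-sample t-test p-value
    on log-transformed values; p is NaN when either class has < 2 genes.
    """
    trg_ids = {
        c.gene_id for c in contexts if c.category in ("exon", "intron") and c.gene_id
    }
    rows = []
    for g in genes:
        exon_lens = [e - s for s, e in g.exons]
        intron_lens = [e - s for s, e in g.introns]
        rows.append(
            {
                "gene_id": g.gene_id,
                "is_trg": g.gene_id in trg_ids,
                "exon_count": len(g.exons),
                "gene_length": g.length,
                "mean_exon_length": float(np.mean(exon_lens)) if exon_lens else np.nan,
                "mean_intron_length": float(np.mean(intron_lens))
                if intron_lens
                else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    metrics = ["exon_count", "gene_length", "mean_exon_length", "mean_intron_length"]
    out = []
    for metric in metrics:
        a = df.loc[df.is_trg, metric].dropna()
        b = df.loc[~df.is_trg, metric].dropna()
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(np.log(a + 1e-9), np.log(b + 1e-9))
        else:
            t, p = np.nan, np.nan
        out.append(
            {
                "metric": metric,
                "trg_n": len(a),
                "ntrg_n": len(b),
                "trg_mean": a.mean() if len(a) else np.nan,
                "ntrg_mean": b.mean() if len(b) else np.nan,
                "t": t,
                "p_value": p,
            }
        )
    return pd.DataFrame(out)


def density_row(
    n_insertions: int, n_genes: int, cumulative_kb: float
) -> dict[str, float]:
    """Per-gene (2 dp) and per-kb (4 dp) insertion densities."""
    return {
        "genes": n_genes,
        "cumulative_kb": cumulative_kb,
        "insertions": n_insertions,
        "insertions_per_gene": round(n_insertions / n_genes, 2) if n_genes else np.nan,
        "insertions_per_kb": round(n_insertions / cumulative_kb, 4)
        if cumulative_kb
        else np.nan,
    }


def size_class_density(
    contexts: list[InsertionContext],
    genes: list[GeneModel],
    quantile: float = 0.20,
) -> pd.DataFrame:
    """Insertion densities in the smallest/largest *quantile* of genes.

    Genes are ranked by length; the bottom and top 20% are the small and
    large classes.  Densities are reported per gene (2 decimals) and per
    kb (4 decimals) with large:small ratios (NA when undefined).
    """
    if len(genes) < 5:
        raise AnnotationError("need at least 5 genes for size classes")
    ranked = sorted(genes, key=lambda g: (g.length, g.gene_id))
    k = max(1, int(round(quantile * len(ranked))))
    classes = {
        "small": ranked[:k],
        "mid": ranked[k : len(ranked) - k],
        "large": ranked[len(ranked) - k :],
    }
    ins_by_gene: dict[str, int] = {}
    for c in contexts:
        if c.category in ("exon", "intron") and c.gene_id:
            ins_by_gene[c.gene_id] = ins_by_gene.get(c.gene_id, 0) + 1
    rows = {}
    for name, cls in classes.items():
        n_ins = sum(ins_by_gene.get(g.gene_id, 0) for g in cls)
        kb = sum(g.length for g in cls) / 1000.0
        rows[name] = {"size_class": name, **density_row(n_ins, len(cls), kb)}
    table = pd.DataFrame([rows["small"], rows["mid"], rows["large"]])
    small, large = rows["small"], rows["large"]

    def ratio(a: float, b: float) -> float:
        return round(a / b, 1) if b else np.nan

    table.attrs["large_to_small_per_gene"] = ratio(
        large["insertions_per_gene"], small["insertions_per_gene"]
    )
    table.attrs["large_to_small_per_kb"] = ratio(
        large["insertions_per_kb"], small["insertions_per_kb"]
    )
    return table


# ---------------------------------------------------------------------------
# gene capture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaptureReport:
    element_id: str
    gene_id: str
    identity: float
    aligned_bp: int
    exon_only: bool


def _spliced(gene: GeneModel, seq: str) -> str:
    return "".join(seq[s:e] for s, e in gene.exons)


def detect_gene_capture(
    internals: dict[str, str],
    genes: list[GeneModel],
    genome: dict[str, str],
    min_identity: float = 0.70,
    min_span: int = 50,
) -> list[CaptureReport]:
    """Find host-gene fragments captured inside element internal regions.

    Each internal sequence is aligned to every transcript (spliced exon
    sequence); matches at >= *min_identity* over >= *min_span* bp are
    reported.  ``exon_only`` is True when the fragment matches the
    spliced transcript at least as well as the unspliced gene, or when
    its unspliced footprint avoids introns -- i.e. the capture carries no
    intronic sequence.
    """
    out = []
    for el_id, internal in sorted(internals.items()):
        for gene in genes:
            gseq = genome[gene.chrom][gene.start : gene.end]
            tseq = _spliced(gene, genome[gene.chrom])
            t_hit = local_align(tseq, internal)
            if (
                t_hit is None
                or t_hit.identity < min_identity
                or t_hit.columns < min_span
            ):
                continue
            g_hit = local_align(gseq, internal)
            exon_only = True
            if g_hit is not None and g_hit.score > t_hit.score:
                foot = (gene.start + g_hit.target_start, gene.start + g_hit.target_end)
                overlaps_intron = any(
                    foot[0] < ie and is_ < foot[1] for is_, ie in gene.introns
                )
                exon_only = not overlaps_intron
            out.append(
                CaptureReport(
                    element_id=el_id,
                    gene_id=gene.gene_id,
                    identity=t_hit.identity,
                    aligned_bp=t_hit.columns,
                    exon_only=exon_only,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks
# ---------------------------------------------------------------------------

_CODON_TABLE: dict[str, str] = {}


def _codon_aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences

    @property
    def ratio(self) -> float:
        return self.ka / self.ks if self.ks > 0 else float("nan")


def synonymous_sites(codon: str) -> float:
    """Fraction-weighted count of synonymous sites in one codon.

    At each position the three possible substitutions are examined;
    changes creating stop codons are excluded from the denominator.
    """
    aa = _codon_aa(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = _codon_aa(alt)
            if alt_aa == "*":
                continue
            considered += 1
            if alt_aa == aa:
                syn += 1
        if considered:
            total += syn / considered
    return total


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Mean synonymous/nonsynonymous differences over mutation pathways.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are excluded (all pathways are used if
    every one is blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _codon_aa(nxt) == "*":
                blocked = True
            if _codon_aa(nxt) == _codon_aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("inf")
    return max(0.0, -0.75 * math.log(1 - 4.0 * p / 3.0))


def ka_ks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for two aligned in-frame coding sequences.

    Sites are averaged between the two sequences; multi-substitution
    codons average their differences over all mutation pathways; rates
    are Jukes-Cantor corrected.  Identical sequences give Ka = Ks = 0
    with an undefined ratio.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise FormatError("coding sequences differ in length")
    if len(cds_a) % 3 != 0:
        raise FormatError("coding sequence length is not a multiple of 3")
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    for c in codons_a[:-1] + codons_b[:-1]:
        if _codon_aa(c) == "*":
            raise FormatError(f"internal stop codon {c}")
    # trailing stops are not informative sites
    if codons_a and _codon_aa(codons_a[-1]) == "*" and _codon_aa(codons_b[-1]) == "*":
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
    S = sum(
        (synonymous_sites(a) + synonymous_sites(b)) / 2
        for a, b in zip(codons_a, codons_b)
    )
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for a, b in zip(codons_a, codons_b):
        sd, nd = _pathway_diffs(a, b)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KaKsResult(
        ka=_jukes_cantor(pn), ks=_jukes_cantor(ps), S=S, N=N, Sd=Sd, Nd=Nd
    )
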