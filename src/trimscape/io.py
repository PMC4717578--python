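"""Reading and writing the pipeline's file formats.

FASTA through Biopython, GFF3 written 1-based inclusive, methylation
tables as bedGraph-like TSV (0-based positions), small-RNA alignments as
BED6+length.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError
from .structural_scanner import CandidateElement
from .synthetic_data import GeneModel, TruthRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chrom, "trimscape", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", attrs]
            )
        )
        mrna_id = f"{g.gene_id}.1"
        lines.append(
            "\t".join(
                [g.chrom, "trimscape", "mRNA", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={mrna_id};Parent={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [g.chrom, "trimscape", "exon", str(s + 1), str(e), ".",
                     g.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (gene/mRNA/exon); the longest mRNA represents a gene."""
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_exons: dict[str, list[tuple[int, int]]] = {}
    mrna_span: dict[str, tuple[str, str, int, int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            continue
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
        fields = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        s, e = int(start) - 1, int(end)
        if ftype == "gene":
            genes[fields.get("ID", f"gene{len(genes)}")] = {
                "chrom": chrom, "strand": strand, "start": s, "end": e
            }
        elif ftype == "mRNA":
            mid = fields.get("ID", "")
            mrna_parent[mid] = fields.get("Parent", "")
            mrna_span[mid] = (chrom, strand, s, e)
        elif ftype == "exon":
            mrna_exons.setdefault(fields.get("Parent", ""), []).append((s, e))
    if genes and not mrna_exons:
        raise AnnotationError("GFF3 contains genes but no exon features")
    out = []
    for gid, info in genes.items():
        mrnas = [m for m, p in mrna_parent.items() if p == gid]
        if not mrnas:
            continue
        best = max(mrnas, key=lambda m: mrna_span[m][3] - mrna_span[m][2])
        exons = sorted(mrna_exons.get(best, []))
        out.append(
            GeneModel(gid, info["chrom"], info["strand"], info["start"], info["end"], exons)
        )
    return out


def write_candidates_gff3(cands: list[CandidateElement], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for i, c in enumerate(cands, 1):
        eid = f"TRIM{i}"
        lines.append(
            "\t".join(
                [c.chrom, "trimscape", "LTR_retrotransposon", str(c.start + 1),
                 str(c.end), f"{c.ltr_identity:.3f}", "+", ".", f"ID={eid}"]
            )
        )
        for name, (s, e) in (("ltr5", c.ltr5), ("ltr3", c.ltr3)):
            lines.append(
                "\t".join(
                    [c.chrom, "trimscape", "long_terminal_repeat", str(s + 1), str(e),
                     ".", "+", ".", f"Parent={eid};Name={name}"]
                )
            )
        if c.tsd:
            for s, e in (c.tsd[1], c.tsd[2]):
                lines.append(
                    "\t".join(
                        [c.chrom, "trimscape", "target_site_duplication", str(s + 1),
                         str(e), ".", "+", ".", f"Parent={eid};Name={c.tsd[0]}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_gff3(truth: list[TruthRecord], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for r in truth:
        attrs = f"ID={r.element_id};subfamily={r.subfamily_id}"
        if r.structure:
            attrs += f";structure={r.structure}"
        if r.tsd:
            attrs += f";tsd={r.tsd}"
        lines.append(
            "\t".join(
                [r.chrom, "trimscape", r.kind, str(r.start + 1), str(r.end), ".",
                 "+", ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "element_id": r.element_id, "chrom": r.chrom, "start": r.start,
                "end": r.end, "kind": r.kind, "tsd": r.tsd,
                "subfamily_id": r.subfamily_id, "structure": r.structure,
                "ltr_len": r.ltr_len,
            }
            for r in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def write_methylation_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_srna_bed(srna: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "read_id", "length", "strand"]
    srna[cols].to_csv(path, sep="\t", index=False, header=False)


def read_srna_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        names=["chrom", "start", "end", "read_id", "length", "strand"],
    )
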