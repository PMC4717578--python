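"""Grouping of miniature LTR elements into subfamilies and families.

Within one genome, elements are clustered into *subfamilies* by single
linkage under the 80/80 rule: two elements link when their best local
alignment shows >= 80% identity over >= 80% of the shorter element's
length.  Subfamily consensuses from different genomes are then linked
into *families* when they share a homologous span of >= 50 bp and >= 5%
of the query consensus length at >= 70% identity.  Families are labelled
by taxonomic conservation: shared between plant families, plant-family
specific, or species specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import edlib

from ._align import local_align, parse_cigar
from .errors import ConfigurationError


def pairwise_coverage_identity(a: str, b: str) -> tuple[float, float]:
    """Identity and shorter-sequence coverage of the best local alignment.

    identity = matches / aligned columns; coverage = aligned span of the
    shorter sequence / its length.  Symmetric in its arguments.
    """
    if not a or not b:
        return 0.0, 0.0
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    hit = local_align(longer, shorter)
    if hit is None:
        return 0.0, 0.0
    coverage = hit.query_span / len(shorter)
    return hit.identity, coverage


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller index becomes the root
            if ri > rj:
                ri, rj = rj, ri
            self.parent[rj] = ri

    def groups(self) -> list[list[int]]:
        by_root: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            by_root.setdefault(self.find(i), []).append(i)
        return [by_root[r] for r in sorted(by_root)]


def _shared_kmers(a: str, b: str, k: int = 10) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i : i + k] for i in range(0, len(a) - k + 1, 2)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


@dataclass
class Subfamily:
    """A within-genome cluster of elements with a consensus sequence."""

    id: str
    genome_id: str
    member_ids: list[str]
    consensus: str
    ltr_length: int = 0

    @property
    def consensus_length(self) -> int:
        return len(self.consensus)


@dataclass
class Family:
    """A cross-genome cluster of homologous subfamilies."""

    id: str
    subfamily_ids: list[str]
    genome_ids: list[str]
    conservation: str = ""


def star_consensus(sequences: list[str]) -> str:
    """Majority-base consensus from a star alignment to the longest member.

    Every member is globally aligned to the longest sequence; each of the
    reference's columns takes the majority base (ties keep the reference
    base).  Insertions relative to the reference are ignored, so the
    consensus length equals the reference length -- a deterministic,
    order-independent stand-in for a full multiple alignment.
    """
    if not sequences:
        return ""
    ref = max(sequences, key=len)
    counts = np.zeros((len(ref), 4), dtype=np.int32)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in sequences:
        if seq == ref:
            for i, c in enumerate(ref):
                if c in base_idx:
                    counts[i, base_idx[c]] += 1
            continue
        res = edlib.align(seq, ref, mode="NW", task="path")
        ri = qi = 0
        for n, op in parse_cigar(res["cigar"]):
            if op in ("=", "X", "M"):
                for _ in range(n):
                    c = seq[qi]
                    if c in base_idx:
                        counts[ri, base_idx[c]] += 1
                    ri += 1
                    qi += 1
            elif op == "D":  # in ref only
                ri += n
            elif op == "I":  # in query only
                qi += n
    out = []
    bases = "ACGT"
    for i, c in enumerate(ref):
        col = counts[i]
        if col.sum() == 0:
            out.append(c)
            continue
        best = int(col.max())
        winners = [bases[j] for j in range(4) if col[j] == best]
        out.append(c if c in winners else winners[0])
    return "".join(out)


def cluster_subfamilies(
    elements: dict[str, str],
    genome_id: str = "genome",
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    ltr_lengths: dict[str, int] | None = None,
) -> list[Subfamily]:
    """Single-linkage 80/80 clustering of one genome's elements.

    *elements* maps element id -> sequence.  Returns subfamilies sorted
    by id, each with a star-alignment consensus.
    """
    ids = sorted(elements)
    uf = UnionFind(len(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = elements[ids[i]], elements[ids[j]]
            if not _shared_kmers(a, b):
                continue
            ident, cov = pairwise_coverage_identity(a, b)
            if ident >= min_identity and cov >= min_coverage:
                uf.union(i, j)
    out = []
    for gi, group in enumerate(uf.groups()):
        members = [ids[i] for i in group]
        seqs = [elements[m] for m in members]
        ltr_len = 0
        if ltr_lengths:
            lens = [ltr_lengths[m] for m in members if m in ltr_lengths]
            if lens:
                ltr_len = int(np.median(lens))
        out.append(
            Subfamily(
                id=f"{genome_id}_sf{gi + 1}",
                genome_id=genome_id,
                member_ids=members,
                consensus=star_consensus(seqs),
                ltr_length=ltr_len,
            )
        )
    return out


def _family_link(
    query: Subfamily, other: Subfamily, min_span: int, min_frac: float, min_identity: float
) -> bool:
    hit = local_align(other.consensus, query.consensus)
    if hit is None:
        return False
    span = hit.query_span
    return (
        span >= min_span
        and span >= min_frac * query.consensus_length
        and hit.identity >= min_identity
    )


def group_families(
    subfamilies: list[Subfamily],
    min_span: int = 50,
    min_frac: float = 0.05,
    min_identity: float = 0.70,
) -> list[Family]:
    """Single-linkage clustering of subfamily consensuses into families.

    Two subfamilies link when, in at least one query direction, the best
    local alignment spans >= *min_span* bp and >= *min_frac* of the query
    consensus length at >= *min_identity*.
    """
    uf = UnionFind(len(subfamilies))
    for i in range(len(subfamilies)):
        for j in range(i + 1, len(subfamilies)):
            a, b = subfamilies[i], subfamilies[j]
            if _family_link(a, b, min_span, min_frac, min_identity) or _family_link(
                b, a, min_span, min_frac, min_identity
            ):
                uf.union(i, j)
    out = []
    for gi, group in enumerate(uf.groups()):
        members = [subfamilies[i] for i in group]
        out.append(
            Family(
                id=f"fam{gi + 1}",
                subfamily_ids=[m.id for m in members],
                genome_ids=sorted({m.genome_id for m in members}),
            )
        )
    return out


def classify_conservation(
    families: list[Family], taxonomy: dict[str, str]
) -> list[Family]:
    """Label each family by the taxonomic spread of its member genomes.

    *taxonomy* maps genome id -> plant family name.  Labels:
    ``shared_between_plant_families`` (>= 2 plant families),
    ``family_specific`` (>= 2 genomes of one plant family),
    ``species_specific`` (one genome).
    """
    out = []
    for fam in families:
        missing = [g for g in fam.genome_ids if g not in taxonomy]
        if missing:
            raise ConfigurationError(f"genomes missing from taxonomy: {missing}")
        plant_families = {taxonomy[g] for g in fam.genome_ids}
        if len(plant_families) >= 2:
            label = "shared_between_plant_families"
        elif len(fam.genome_ids) >= 2:
            label = "family_specific"
        else:
            label = "species_specific"
        out.append(
            Family(fam.id, list(fam.subfamily_ids), list(fam.genome_ids), label)
        )
    return out
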