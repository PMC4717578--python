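"""Methylation and small-RNA profiling of elements and genes.

Consumes per-cytosine bisulfite count tables (chrom, pos, context, mc,
total) and BED-like small-RNA alignments with read lengths.  Provides
binomial methylation calls with Benjamini-Hochberg correction, weighted
methylation levels (sum mC / sum coverage over a region's cytosines of
one context), element metaprofiles, 21/24-nt sRNA abundance in TPM,
family-level Type I/II/III classification and gene-body methylation
classes.

Type definitions (numeric thresholds are this package's calibration,
reported in output metadata):

* Type I  -- abundant 24-nt siRNA on the body, CHH body methylation and a
  clear body-over-flank methylation border;
* Type II -- little 24-nt siRNA; CG + CHG methylation in body *and*
  flanks, no border;
* Type III -- little 24-nt siRNA; CG-only body methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError

CONTEXTS = ("CG", "CHG", "CHH")


def _check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "pos", "context", "mc", "total"}
    missing = required - set(counts.columns)
    if missing:
        raise FormatError(f"methylation table missing columns {sorted(missing)}")
    bad = set(counts["context"].unique()) - set(CONTEXTS)
    if bad:
        raise FormatError(f"unknown methylation contexts {sorted(bad)}")
    return counts


def call_methylated_cytosines(
    counts: pd.DataFrame, nonconversion_rate: float, alpha: float = 0.01
) -> pd.Series:
    """Per-position methylation calls by one-sided binomial test.

    A position is methylated when P(X >= mc | total, nonconversion) stays
    below *alpha* after Benjamini-Hochberg correction over all covered
    positions.  Uncovered positions (total = 0) are skipped (False).
    """
    if not 0 <= nonconversion_rate < 1:
        raise FormatError("nonconversion_rate must be in [0, 1)")
    _check_counts(counts)
    called = pd.Series(False, index=counts.index)
    covered = counts["total"] > 0
    if covered.sum() == 0:
        return called
    sub = counts[covered]
    pvals = stats.binom.sf(sub["mc"] - 1, sub["total"], nonconversion_rate)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    called.loc[sub.index] = reject
    return called


def weighted_level(
    counts: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    context: str,
) -> float:
    """Sum(mC)/sum(total) over the region's cytosines of one context.

    Returns NaN when the region has no covered cytosines of the context.
    """
    if context not in CONTEXTS:
        raise FormatError(f"unknown context {context!r}")
    sel = counts[
        (counts["chrom"] == chrom)
        & (counts["pos"] >= start)
        & (counts["pos"] < end)
        & (counts["context"] == context)
    ]
    total = sel["total"].sum()
    if total == 0:
        return float("nan")
    return float(sel["mc"].sum() / total)


def metaprofile(
    elements: list[tuple[str, int, int]],
    counts: pd.DataFrame,
    bins: int = 20,
    flank: int = 2000,
) -> dict[str, np.ndarray]:
    """Pooled methylation metaprofile around elements.

    The body of each element is rescaled into *bins* bins; the two flanks
    are binned at fixed width ``flank / bins``.  Each cell is the
    weighted level of the pooled counts falling in it.  Returns, per
    context, an array of length ``3 * bins`` ordered upstream flank,
    body, downstream flank.
    """
    if not elements:
        raise FormatError("no elements for metaprofile")
    _check_counts(counts)
    mc = np.zeros((3, 3 * bins))
    tot = np.zeros((3, 3 * bins))
    ctx_idx = {c: i for i, c in enumerate(CONTEXTS)}
    flank_w = flank / bins
    by_chrom = dict(tuple(counts.groupby("chrom")))
    for chrom, start, end in elements:
        sub = by_chrom.get(chrom)
        if sub is None or end <= start:
            continue
        pos = sub["pos"].to_numpy()
        in_range = (pos >= start - flank) & (pos < end + flank)
        s = sub[in_range]
        p = s["pos"].to_numpy()
        bin_idx = np.empty(len(p), dtype=int)
        up = p < start
        down = p >= end
        body = ~(up | down)
        bin_idx[up] = np.minimum(((p[up] - (start - flank)) / flank_w).astype(int), bins - 1)
        bin_idx[body] = bins + np.minimum(
            ((p[body] - start) / (end - start) * bins).astype(int), bins - 1
        )
        bin_idx[down] = 2 * bins + np.minimum(
            ((p[down] - end) / flank_w).astype(int), bins - 1
        )
        ci = s["context"].map(ctx_idx).to_numpy()
        np.add.at(mc, (ci, bin_idx), s["mc"].to_numpy())
        np.add.at(tot, (ci, bin_idx), s["total"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        levels = np.where(tot > 0, mc / np.maximum(tot, 1), np.nan)
    return {c: levels[i] for c, i in ctx_idx.items()}


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------


def srna_abundance(
    elements: list[tuple[str, str, int, int]],
    alignments: pd.DataFrame,
    total_mapped_reads: int | None = None,
    lengths: tuple[int, ...] = (21, 24),
) -> pd.DataFrame:
    """21/24-nt read abundance over elements, in transcripts per million.

    *alignments* columns: chrom, start, end, read_id, length.  A read
    mapped at k loci contributes 1/k per locus.  TPM uses
    *total_mapped_reads* as denominator (default: the number of distinct
    reads in the table).
    """
    df = alignments.copy()
    multiplicity = df.groupby("read_id")["read_id"].transform("size")
    df["weight"] = 1.0 / multiplicity
    denom = total_mapped_reads if total_mapped_reads else df["read_id"].nunique()
    rows = []
    by_chrom = dict(tuple(df.groupby("chrom")))
    for el_id, chrom, start, end in elements:
        sub = by_chrom.get(chrom)
        row = {"element_id": el_id}
        for ln in lengths:
            if sub is None:
                row[f"tpm_{ln}nt"] = 0.0
                continue
            sel = sub[(sub["length"] == ln) & (sub["start"] < end) & (sub["end"] > start)]
            count = sel["weight"].sum()
            row[f"tpm_{ln}nt"] = 1e6 * count / denom if denom else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# family typing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpiThresholds:
    """Calibrated thresholds of the Type I/II/III rule set."""

    t_srna: float = 5.0  # TPM of 24-nt reads on the body
    t_chh: float = 0.10
    t_cg: float = 0.40
    t_chg: float = 0.10
    t_border: float = 0.10  # body-minus-flank summed methylation


@dataclass
class FamilyEpiType:
    family_id: str
    type: str  # I | II | III | unclassified
    body_levels: dict[str, float]
    flank_levels: dict[str, float]
    srna24_body: float
    thresholds: EpiThresholds = EpiThresholds()

    def metadata(self) -> dict:
        return {"family_id": self.family_id, "type": self.type, **asdict(self.thresholds)}


def classify_family_type(
    family_id: str,
    body_levels: dict[str, float],
    flank_levels: dict[str, float],
    srna24_body: float,
    thresholds: EpiThresholds | None = None,
) -> FamilyEpiType:
    """Type I/II/III assignment from body/flank levels and 24-nt sRNA.

    Type I: srna24 >= t_srna, CHH(body) >= t_chh, and summed body
    methylation exceeds summed flank methylation by >= t_border.
    Type III: srna24 < t_srna, CG(body) >= t_cg, CHG and CHH below their
    thresholds.  Everything else is Type II; missing levels give
    "unclassified".
    """
    th = thresholds or EpiThresholds()
    vals = [body_levels.get(c) for c in CONTEXTS] + [flank_levels.get(c) for c in CONTEXTS]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        label = "unclassified"
    else:
        body_sum = sum(body_levels[c] for c in CONTEXTS)
        flank_sum = sum(flank_levels[c] for c in CONTEXTS)
        if (
            srna24_body >= th.t_srna
            and body_levels["CHH"] >= th.t_chh
            and body_sum - flank_sum >= th.t_border
        ):
            label = "I"
        elif (
            srna24_body < th.t_srna
            and body_levels["CG"] >= th.t_cg
            and body_levels["CHG"] < th.t_chg
            and body_levels["CHH"] < th.t_chh
        ):
            label = "III"
        else:
            label = "II"
    return FamilyEpiType(
        family_id=family_id,
        type=label,
        body_levels=dict(body_levels),
        flank_levels=dict(flank_levels),
        srna24_body=srna24_body,
        thresholds=th,
    )


def family_epitypes(
    members_by_family: dict[str, list[tuple[str, int, int]]],
    counts: pd.DataFrame,
    srna: pd.DataFrame,
    total_mapped_reads: int | None = None,
    flank: int = 2000,
    thresholds: EpiThresholds | None = None,
) -> list[FamilyEpiType]:
    """Classify each family from pooled member bodies and flanks."""
    _check_counts(counts)
    out = []
    for fam_id, members in sorted(members_by_family.items()):
        body_mc = {c: 0.0 for c in CONTEXTS}
        body_tot = {c: 0.0 for c in CONTEXTS}
        flank_mc = {c: 0.0 for c in CONTEXTS}
        flank_tot = {c: 0.0 for c in CONTEXTS}
        for chrom, start, end in members:
            sub = counts[counts["chrom"] == chrom]
            for c in CONTEXTS:
                csub = sub[sub["context"] == c]
                body = csub[(csub["pos"] >= start) & (csub["pos"] < end)]
                fl = csub[
                    ((csub["pos"] >= start - flank) & (csub["pos"] < start))
                    | ((csub["pos"] >= end) & (csub["pos"] < end + flank))
                ]
                body_mc[c] += body["mc"].sum()
                body_tot[c] += body["total"].sum()
                flank_mc[c] += fl["mc"].sum()
                flank_tot[c] += fl["total"].sum()
        body_levels = {
            c: (body_mc[c] / body_tot[c]) if body_tot[c] else float("nan")
            for c in CONTEXTS
        }
        flank_levels = {
            c: (flank_mc[c] / flank_tot[c]) if flank_tot[c] else float("nan")
            for c in CONTEXTS
        }
        ab = srna_abundance(
            [(f"{fam_id}_{i}", ch, s, e) for i, (ch, s, e) in enumerate(members)],
            srna,
            total_mapped_reads,
        )
        srna24 = float(ab["tpm_24nt"].sum())
        out.append(
            classify_family_type(fam_id, body_levels, flank_levels, srna24, thresholds)
        )
    return out


# ---------------------------------------------------------------------------
# gene methylation classes
# ---------------------------------------------------------------------------


def classify_gene_methylation(
    counts: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    background_rate: float = 0.01,
    level_threshold: float = 0.05,
    alpha: float = 0.01,
    min_reads: int = 5,
) -> str:
    """CG-body-methylated / C-methylated / unmethylated / uncallable.

    C-methylated: CHG or CHH body level >= *level_threshold* and
    binomially enriched over *background_rate*; CG-body-methylated: not
    C-methylated but CG significantly above background; otherwise
    unmethylated.  Bodies with < *min_reads* per context are uncallable.
    """
    levels = {}
    sig = {}
    for c in CONTEXTS:
        sel = counts[
            (counts["chrom"] == chrom)
            & (counts["pos"] >= start)
            & (counts["pos"] < end)
            & (counts["context"] == c)
        ]
        total = int(sel["total"].sum())
        mc = int(sel["mc"].sum())
        if total < min_reads:
            return "uncallable"
        levels[c] = mc / total
        sig[c] = stats.binom.sf(mc - 1, total, background_rate) < alpha
    if (levels["CHG"] >= level_threshold and sig["CHG"]) or (
        levels["CHH"] >= level_threshold and sig["CHH"]
    ):
        return "C_methylated"
    if sig["CG"] and levels["CG"] >= level_threshold:
        return "CG_body_methylated"
    return "unmethylated"


def genic_methylation_correlation(
    family_genic_rate: dict[str, float], family_cg_body_fraction: dict[str, float]
) -> float:
    """Pearson R between families' genic-insertion rates and the fraction
    of their target genes that are CG-body-methylated."""
    keys = sorted(set(family_genic_rate) & set(family_cg_body_fraction))
    if len(keys) < 3:
        return float("nan")
    a = [family_genic_rate[k] for k in keys]
    b = [family_cg_body_fraction[k] for k in keys]
    r, _ = stats.pearsonr(a, b)
    return float(r)
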