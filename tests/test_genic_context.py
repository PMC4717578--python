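"""Gene-context classification, densities, gene capture and Ka/Ks."""

import math

import numpy as np
import pytest

from trimscape.errors import AnnotationError, FormatError
from trimscape.genic_context import (
    classify_insertions,
    context_percentages,
    density_row,
    detect_gene_capture,
    ka_ks_ng86,
    size_class_density,
    synonymous_sites,
    trg_stats,
)
from trimscape.synthetic_data import GeneModel, random_seq

from _oracles import oracle_codon_sites, oracle_kaks_counts


@pytest.fixture()
def gene():
    # + strand gene at 10000-13000 with three exons
    return GeneModel(
        "g1", "c", "+", 10_000, 13_000,
        [(10_000, 10_400), (11_000, 11_500), (12_500, 13_000)],
    )


class TestClassifyInsertions:
    def test_hit_inside_exon(self, gene):
        out = classify_insertions([("h1", "c", 10_100, 10_200)], [gene])
        assert out[0].category == "exon" and out[0].gene_id == "g1"

    def test_hit_inside_intron(self, gene):
        out = classify_insertions([("h1", "c", 10_500, 10_700)], [gene])
        assert out[0].category == "intron"

    def test_exon_intron_spanning_hit_is_exonic(self, gene):
        out = classify_insertions([("h1", "c", 10_300, 10_600)], [gene])
        assert out[0].category == "exon"

    def test_upstream_window_boundary(self, gene):
        near = classify_insertions([("h1", "c", 8_600, 8_700)], [gene])
        assert near[0].category == "upstream_1500"
        far = classify_insertions([("h2", "c", 8_300, 8_400)], [gene])
        assert far[0].category == "intergenic"

    def test_minus_strand_upstream_is_downstream_side(self):
        g = GeneModel("g1", "c", "-", 10_000, 12_000, [(10_000, 10_500), (11_500, 12_000)])
        out = classify_insertions([("h1", "c", 12_200, 12_300)], [g])
        assert out[0].category == "upstream_1500"

    def test_each_hit_single_category(self, gene):
        hits = [(f"h{i}", "c", 9_000 + i * 500, 9_100 + i * 500) for i in range(10)]
        out = classify_insertions(hits, [gene])
        assert len(out) == len(hits)
        pct = context_percentages(out)
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_genes_without_exons_rejected(self):
        g = GeneModel("g1", "c", "+", 0, 100, [])
        with pytest.raises(AnnotationError):
            classify_insertions([("h", "c", 10, 20)], [g])


class TestTrgStats:
    def _genes(self, rng):
        genes = []
        pos = 1000
        for i in range(40):
            n_ex = 2 if i < 20 else 6
            exons = []
            p = pos
            for j in range(n_ex):
                exons.append((p, p + 200))
                p += 400
            genes.append(GeneModel(f"g{i}", "c", "+", pos, exons[-1][1], exons))
            pos = p + 500
        return genes

    def test_enrichment_in_large_genes_detected(self, rng):
        genes = self._genes(rng)
        large = [g for g in genes if len(g.exons) == 6]
        contexts = classify_insertions(
            [(f"h{i}", "c", g.start + 250, g.start + 300) for i, g in enumerate(large)],
            genes,
        )
        stats_table = trg_stats(contexts, genes)
        row = stats_table[stats_table.metric == "gene_length"].iloc[0]
        assert row.trg_mean > row.ntrg_mean
        assert row.p_value < 0.05

    def test_trim_free_genome_has_no_trgs(self, rng):
        genes = self._genes(rng)
        table = trg_stats([], genes)
        assert (table.trg_n == 0).all()
        assert table.p_value.isna().all()


class TestSizeClassDensity:
    def test_printed_density_arithmetic(self):
        """The published soybean inputs reproduce 0.17, 0.0183 and 0.0028."""
        large = density_row(1554, 9273, 84_971)
        small = density_row(21, 9273, 7_621)
        assert large["insertions_per_gene"] == 0.17
        assert large["insertions_per_kb"] == 0.0183
        assert small["insertions_per_kb"] == 0.0028

    def test_zero_insertions_gives_zero_densities(self):
        genes = [
            GeneModel(f"g{i}", "c", "+", i * 2000, i * 2000 + 500 + 100 * i,
                      [(i * 2000, i * 2000 + 500 + 100 * i)])
            for i in range(10)
        ]
        table = size_class_density([], genes)
        assert (table.insertions == 0).all()
        assert math.isnan(table.attrs["large_to_small_per_gene"])

    def test_quantile_split_sizes(self):
        genes = [
            GeneModel(f"g{i}", "c", "+", 0, 1000 + i * 100, [(0, 1000 + i * 100)])
            for i in range(20)
        ]
        table = size_class_density([], genes)
        assert list(table.genes) == [4, 12, 4]


class TestGeneCapture:
    def _setup(self, rng, with_intron_fragment=False):
        exon1 = random_seq(300, 0.45, rng)
        intron = random_seq(400, 0.45, rng)
        exon2 = random_seq(300, 0.45, rng)
        bg = random_seq(2000, 0.45, rng)
        gseq = bg[:500] + exon1 + intron + exon2 + bg[500:]
        gene = GeneModel("g1", "c", "+", 500, 500 + 1000,
                         [(500, 800), (1200, 1500)])
        genome = {"c": gseq}
        if with_intron_fragment:
            fragment = gseq[700:1000]  # exon1 tail + intron head
        else:
            fragment = exon1[-170:] + exon2[:176]  # spliced 346-bp junction fragment
        # mutate to ~76% identity
        frag = list(fragment)
        for i in np.flatnonzero(rng.random(len(frag)) < 0.18):
            frag[i] = [b for b in "ACGT" if b != frag[i]][rng.integers(3)]
        internal = random_seq(50, 0.45, rng) + "".join(frag) + random_seq(50, 0.45, rng)
        return internal, gene, genome

    def test_spliced_fragment_reported_exon_only(self, rng):
        internal, gene, genome = self._setup(rng)
        reports = detect_gene_capture({"el1": internal}, [gene], genome)
        assert len(reports) == 1
        r = reports[0]
        assert r.exon_only is True
        assert r.identity >= 0.70 and r.aligned_bp >= 50

    def test_intronic_fragment_not_exon_only(self, rng):
        internal, gene, genome = self._setup(rng, with_intron_fragment=True)
        reports = detect_gene_capture({"el1": internal}, [gene], genome)
        assert len(reports) == 1
        assert reports[0].exon_only is False

    def test_no_homology_empty_report(self, rng):
        gene = GeneModel("g1", "c", "+", 100, 700, [(100, 400), (500, 700)])
        genome = {"c": random_seq(1000, 0.45, rng)}
        assert detect_gene_capture({"el1": random_seq(400, 0.45, rng)}, [gene], genome) == []


class TestKaKs:
    def test_identical_sequences_zero_rates(self):
        r = ka_ks_ng86("ATGGCTAAGGAA", "ATGGCTAAGGAA")
        assert r.ka == 0.0 and r.ks == 0.0
        assert math.isnan(r.ratio)

    def test_single_synonymous_change(self):
        # GGA->GGG is synonymous (Gly); Ka must stay 0
        r = ka_ks_ng86("ATGGGAAAA", "ATGGGGAAA")
        assert r.ka == 0.0
        assert r.ks > 0.0

    def test_single_nonsynonymous_change(self):
        # ATG AAA -> ATG AGA : Lys->Arg at codon 2
        r = ka_ks_ng86("ATGAAA", "ATGAGA")
        assert r.ka > 0.0 and r.ks == 0.0

    def test_site_counts_match_oracle(self):
        for codon in ("ATG", "TTT", "CTG", "TGG", "AGG", "GGG", "ATA"):
            assert synonymous_sites(codon) == pytest.approx(oracle_codon_sites(codon))

    def test_counts_match_pathway_oracle_on_random_pairs(self, rng):
        bases = "ACGT"
        checked = 0
        for _ in range(300):
            a = "".join(rng.choice(list(bases), 6))
            b = "".join(rng.choice(list(bases), 6))
            try:
                r = ka_ks_ng86(a, b)
            except FormatError:
                continue
            S, N, Sd, Nd = oracle_kaks_counts(a, b)
            assert r.S == pytest.approx(S)
            assert r.N == pytest.approx(N)
            assert r.Sd == pytest.approx(Sd)
            assert r.Nd == pytest.approx(Nd)
            checked += 1
        assert checked > 100

    def test_frame_violations_rejected(self):
        with pytest.raises(FormatError):
            ka_ks_ng86("ATGA", "ATGA")
        with pytest.raises(FormatError):
            ka_ks_ng86("ATGAAA", "ATG")
        with pytest.raises(FormatError):
            ka_ks_ng86("TAAAAA", "TAAAAA")
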