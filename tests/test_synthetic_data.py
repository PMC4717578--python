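"""The generator's contracts: structure, determinism, rates, pairing."""

import numpy as np
import pytest

from trimscape.errors import FormatError, SizingError
from trimscape.synthetic_data import (
    GenomePair,
    PartnerSpec,
    SimulationSpec,
    cytosine_contexts,
    emit_methylome,
    emit_srna,
    make_genome_pair,
    orthologous_position,
    reconstruct_background,
    simulate_genome,
    simulate_partner,
)


class TestSimulateGenome:
    def test_empty_spec_gives_empty_truth(self):
        sim = simulate_genome(SimulationSpec(genome_length=5000, n_trims=0, n_genes=0, seed=0))
        assert sim.truth == []
        assert len(sim.seq) == 5000

    def test_seed_determinism_byte_identical(self):
        spec = SimulationSpec(genome_length=40_000, n_trims=5, n_genes=3, seed=1)
        a, b = simulate_genome(spec), simulate_genome(spec)
        assert a.seq == b.seq
        assert [(r.start, r.end, r.tsd) for r in a.truth] == [
            (r.start, r.end, r.tsd) for r in b.truth
        ]

    def test_zero_divergence_ltrs_identical(self):
        spec = SimulationSpec(genome_length=300_000, n_trims=20, divergence=0.0, seed=2)
        sim = simulate_genome(spec)
        complete = [r for r in sim.truth if r.kind == "complete"]
        assert len(complete) == 20
        for r in complete:
            seq = sim.seq[r.start : r.end]
            assert seq[: r.ltr_len] == seq[-r.ltr_len :]

    def test_tsd_copies_flank_elements(self, diverged_sim):
        for r in diverged_sim.truth:
            if not r.tsd:
                continue
            seq = diverged_sim.seq
            assert seq[r.start - len(r.tsd) : r.start] == r.tsd
            assert seq[r.end : r.end + len(r.tsd)] == r.tsd

    def test_reconstruction_recovers_background(self, diverged_sim):
        assert (
            reconstruct_background(diverged_sim.seq, diverged_sim.truth)
            == diverged_sim.background
        )

    def test_insertions_do_not_overlap(self, diverged_sim):
        spans = sorted((r.start, r.end) for r in diverged_sim.truth)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_genes_are_multi_exon(self, diverged_sim):
        assert diverged_sim.genes
        for g in diverged_sim.genes:
            assert len(g.exons) >= 2
            assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end

    def test_sizing_error_names_deficit(self):
        with pytest.raises(SizingError):
            simulate_genome(SimulationSpec(genome_length=2000, n_trims=100, seed=0))

    def test_invalid_ranges_rejected(self):
        with pytest.raises(SizingError):
            SimulationSpec(ltr_len_range=(10, 400)).validate()
        with pytest.raises(SizingError):
            SimulationSpec(tsd_len_range=(3, 6)).validate()


class TestSimulatePartner:
    def test_dup_seq_has_requested_length(self):
        ps = simulate_partner(
            SimulationSpec(
                seed=3,
                partner_spec=PartnerSpec(
                    partner_length=5000, dup_seq_length=25, breakpoint_offset=130,
                    trim_length=408, ltr_length=115,
                ),
            )
        )
        assert len(ps.dup_seq) == 25

    def test_zero_deletion_partner_equals_trim(self):
        ps = simulate_partner(
            SimulationSpec(
                seed=4,
                partner_spec=PartnerSpec(
                    partner_length=408, trim_length=408, dup_seq_length=0,
                    breakpoint_offset=130, ltr_length=115,
                ),
            )
        )
        assert ps.partner_seq == ps.trim_seq

    def test_length_difference_equals_deletion(self):
        ps = simulate_partner(
            SimulationSpec(
                seed=5,
                partner_spec=PartnerSpec(
                    partner_length=4000, dup_seq_length=20, breakpoint_offset=200,
                    trim_length=500, ltr_length=100,
                ),
            )
        )
        assert len(ps.partner_seq) - len(ps.trim_seq) == ps.deleted_len

    def test_dup_copies_flank_deleted_segment(self):
        ps = simulate_partner(
            SimulationSpec(
                seed=6,
                partner_spec=PartnerSpec(
                    partner_length=5000, dup_seq_length=25, breakpoint_offset=130,
                    trim_length=408, ltr_length=115, dup_divergence=0.0,
                ),
            )
        )
        bp, dl = ps.breakpoint, ps.deleted_len
        assert ps.partner_seq[bp - 25 : bp] == ps.dup_seq
        assert ps.partner_seq[bp + dl - 25 : bp + dl] == ps.dup_seq

    def test_oversized_dup_rejected(self):
        with pytest.raises(SizingError):
            simulate_partner(
                SimulationSpec(
                    seed=7,
                    partner_spec=PartnerSpec(
                        partner_length=1000, trim_length=300, ltr_length=100,
                        dup_seq_length=150, breakpoint_offset=150,
                    ),
                )
            )


@pytest.fixture(scope="module")
def typed_sim():
    return simulate_genome(
        SimulationSpec(genome_length=60_000, n_trims=9, divergence=0.0, seed=13,
                       n_subfamilies=3)
    )


class TestMethylome:
    TYPES = {"sf1": "I", "sf2": "II", "sf3": "III"}

    def test_zero_coverage_gives_empty_table(self, typed_sim):
        df = emit_methylome(typed_sim.genome, typed_sim.truth, self.TYPES, seed=1,
                            coverage_mean=0.0)
        assert df.empty

    def test_determinism(self, typed_sim):
        a = emit_methylome(typed_sim.genome, typed_sim.truth, self.TYPES, seed=7)
        b = emit_methylome(typed_sim.genome, typed_sim.truth, self.TYPES, seed=7)
        assert a.equals(b)

    def test_type3_body_chh_low(self, typed_sim):
        df = emit_methylome(typed_sim.genome, typed_sim.truth, self.TYPES, seed=9)
        recs = [r for r in typed_sim.truth if r.subfamily_id == "sf3"]
        sel = df[df.context == "CHH"]
        mc = tot = 0
        for r in recs:
            body = sel[(sel.pos >= r.start) & (sel.pos < r.end)]
            mc += body.mc.sum()
            tot += body.total.sum()
        assert tot > 0 and mc / tot < 0.1

    def test_body_rates_within_three_se(self, typed_sim):
        """Empirical body rates converge to configured rates (3 binomial SE)."""
        df = emit_methylome(typed_sim.genome, typed_sim.truth, self.TYPES, seed=11)
        r = [t for t in typed_sim.truth if t.subfamily_id == "sf1"][0]
        for ctx in ("CG", "CHG", "CHH"):
            sel = df[(df.context == ctx) & (df.pos >= r.start) & (df.pos < r.end)]
            tot = sel.total.sum()
            rate = sel.mc.sum() / tot
            se = np.sqrt(0.85 * 0.15 / tot)
            assert abs(rate - 0.85) <= 3 * se

    def test_unknown_type_label_rejected(self, typed_sim):
        with pytest.raises(FormatError):
            emit_methylome(typed_sim.genome, typed_sim.truth, {"sf1": "IV"}, seed=1)

    def test_contexts_follow_sequence(self):
        seq = "CCGCAGCAT"
        pos, ctx = cytosine_contexts(seq)
        named = dict(zip(pos.tolist(), ctx.tolist()))
        assert set(named) == {0, 1, 3, 6}
        for p, c in named.items():
            if seq[p + 1] == "G":
                assert c == 0
            elif seq[p + 2] == "G":
                assert c == 1
            else:
                assert c == 2


class TestSrna:
    def test_type1_elements_dominate_24nt(self):
        sim = simulate_genome(
            SimulationSpec(genome_length=50_000, n_trims=6, seed=17, n_subfamilies=2)
        )
        types = {"sf1": "I", "sf2": "III"}
        df, total = emit_srna(sim.genome, sim.truth, types, seed=3)
        t1 = [r for r in sim.truth if r.subfamily_id == "sf1"]
        t3 = [r for r in sim.truth if r.subfamily_id == "sf2"]
        count = lambda recs: sum(
            ((df.length == 24) & (df.start < r.end) & (df.end > r.start)).sum()
            for r in recs
        )
        assert count(t1) > 10 * max(1, count(t3))
        assert total > 0


class TestGenomePair:
    def test_full_sharing_no_specific_records(self):
        pair = make_genome_pair(
            SimulationSpec(genome_length=150_000, n_trims=8, seed=19, divergence=0.0),
            shared_fraction=1.0,
        )
        assert pair.specific_records("a") == [] and pair.specific_records("b") == []

    def test_no_sharing_counts(self):
        pair = make_genome_pair(
            SimulationSpec(genome_length=200_000, n_trims=10, seed=23, divergence=0.0),
            shared_fraction=0.0,
        )
        assert len(pair.specific_records("a")) + len(pair.specific_records("b")) == 20

    def test_specific_record_absent_in_partner_genome(self):
        pair = make_genome_pair(
            SimulationSpec(genome_length=200_000, n_trims=10, seed=23, divergence=0.0),
            shared_fraction=0.5,
        )
        for r in pair.specific_records("a")[:3]:
            op = orthologous_position(pair, r.bg_pos, "b")
            gb = pair.genome_b[r.chrom]
            ga = pair.genome_a[r.chrom]
            # one TSD copy at the empty site, background contiguous
            assert gb[op - len(r.tsd) : op] == r.tsd
            # the element does not sit at the orthologous coordinate
            assert gb[op : op + (r.end - r.start)] != ga[r.start : r.end]
            # flanks are contiguous background around the site
            assert gb[op - 30 : op] == ga[r.start - 30 : r.start]

    def test_specific_insertions_have_5bp_tsd(self):
        pair = make_genome_pair(
            SimulationSpec(genome_length=150_000, n_trims=6, seed=29, divergence=0.0),
            shared_fraction=0.0,
        )
        assert all(len(r.tsd) == 5 for r in pair.truth_a + pair.truth_b)

    def test_shared_fraction_bounds(self):
        with pytest.raises(SizingError):
            make_genome_pair(SimulationSpec(seed=1), shared_fraction=1.5)
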