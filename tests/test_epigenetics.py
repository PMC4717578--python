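"""Methylation calls, weighted levels, metaprofiles, sRNA and typing."""

import numpy as np
import pandas as pd
import pytest

from trimscape.epigenetics import (
    call_methylated_cytosines,
    classify_family_type,
    classify_gene_methylation,
    family_epitypes,
    genic_methylation_correlation,
    metaprofile,
    srna_abundance,
    weighted_level,
)
from trimscape.errors import FormatError
from trimscape.synthetic_data import (
    SimulationSpec,
    emit_methylome,
    emit_srna,
    simulate_genome,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "mc", "total"])


class TestBinomialCalls:
    def test_saturated_position_called(self):
        df = _table([("c", i, "CG", 5, 5) for i in range(10)])
        called = call_methylated_cytosines(df, 0.01)
        assert called.all()

    def test_zero_mc_never_called(self):
        df = _table([("c", i, "CG", 0, 30) for i in range(10)])
        assert not call_methylated_cytosines(df, 0.01).any()

    def test_uncovered_positions_skipped(self):
        df = _table([("c", 0, "CG", 0, 0), ("c", 1, "CG", 8, 8)])
        called = call_methylated_cytosines(df, 0.01)
        assert not called[0] and called[1]

    def test_false_call_rate_bounded_under_null(self, rng):
        total = rng.poisson(25, size=2000) + 1
        mc = rng.binomial(total, 0.01)
        df = _table([("c", i, "CHH", m, t) for i, (m, t) in enumerate(zip(mc, total))])
        called = call_methylated_cytosines(df, 0.01, alpha=0.01)
        assert called.mean() <= 0.01 + 0.005

    def test_invalid_rate_rejected(self):
        with pytest.raises(FormatError):
            call_methylated_cytosines(_table([]), 1.5)


class TestWeightedLevel:
    def test_pooled_fraction_formula(self):
        df = _table([("c", 10, "CG", 3, 4), ("c", 20, "CG", 1, 4)])
        assert weighted_level(df, "c", 0, 100, "CG") == 0.5

    def test_fully_methylated(self):
        df = _table([("c", i, "CHG", 7, 7) for i in range(5)])
        assert weighted_level(df, "c", 0, 100, "CHG") == 1.0

    def test_empty_region_is_nan(self):
        df = _table([("c", 10, "CG", 3, 4)])
        assert np.isnan(weighted_level(df, "c", 500, 600, "CG"))

    def test_split_and_pool_invariance(self, rng):
        """Pooling two half-regions count-weighted equals the whole region."""
        rows = [("c", int(p), "CG", int(m), int(t)) for p, m, t in
                zip(rng.integers(0, 1000, 50), rng.integers(0, 5, 50),
                    rng.integers(5, 20, 50))]
        df = _table(rows)
        whole = weighted_level(df, "c", 0, 1000, "CG")
        parts = df[(df.pos < 500)], df[(df.pos >= 500)]
        mc = sum(p.mc.sum() for p in parts)
        tot = sum(p.total.sum() for p in parts)
        assert whole == pytest.approx(mc / tot)


class TestMetaprofile:
    def test_uniform_methylome_flat_profile(self, rng):
        pos = np.arange(0, 20_000, 7)
        total = rng.poisson(30, len(pos)) + 1
        mc = rng.binomial(total, 0.4)
        df = _table([("c", int(p), "CG", int(m), int(t))
                     for p, m, t in zip(pos, mc, total)])
        prof = metaprofile([("c", 8000, 12_000)], df, bins=10, flank=2000)
        cg = prof["CG"]
        se = 3 * np.sqrt(0.4 * 0.6 / (30 * len(pos) / (len(cg)) / 7))
        assert np.nanmax(np.abs(cg - 0.4)) < max(0.05, se)

    def test_type1_body_minus_flank_border(self, typed_sim_module):
        sim, meth, _, _ = typed_sim_module
        bodies = [(r.chrom, r.start, r.end) for r in sim.truth
                  if r.subfamily_id == "sf1"]
        prof = metaprofile(bodies, meth, bins=10, flank=2000)
        chh = prof["CHH"]
        body = np.nanmean(chh[10:20])
        flank = np.nanmean(np.concatenate([chh[:10], chh[20:]]))
        assert body - flank > 0.3


@pytest.fixture(scope="module")
def typed_sim_module():
    sim = simulate_genome(
        SimulationSpec(genome_length=60_000, n_trims=9, divergence=0.0, seed=13,
                       n_subfamilies=3)
    )
    types = {"sf1": "I", "sf2": "II", "sf3": "III"}
    meth = emit_methylome(sim.genome, sim.truth, types, seed=99)
    srna, total = emit_srna(sim.genome, sim.truth, types, seed=98)
    return sim, meth, srna, total


class TestSrnaAbundance:
    def test_no_overlap_zero(self):
        aln = pd.DataFrame(
            [("c", 100, 124, "r1", 24, "+")],
            columns=["chrom", "start", "end", "read_id", "length", "strand"],
        )
        out = srna_abundance([("e1", "c", 5000, 6000)], aln)
        assert out.tpm_24nt.iloc[0] == 0.0

    def test_tpm_formula(self):
        rows = [("c", 100 + i, 124 + i, f"r{i}", 24, "+") for i in range(10)]
        rows += [("c", 50_000 + i, 50_021 + i, f"x{i}", 21, "+") for i in range(990)]
        aln = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "read_id", "length", "strand"]
        )
        out = srna_abundance([("e1", "c", 90, 200)], aln)
        assert out.tpm_24nt.iloc[0] == pytest.approx(10_000.0)

    def test_multimapped_reads_share_weight(self):
        rows = [
            ("c", 100, 124, "r1", 24, "+"),
            ("c", 5000, 5024, "r1", 24, "+"),
            ("c", 110, 134, "r2", 24, "+"),
        ]
        aln = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "read_id", "length", "strand"]
        )
        out = srna_abundance([("e1", "c", 90, 200)], aln, total_mapped_reads=1000)
        # r1 contributes 1/2, r2 contributes 1 -> 1.5 reads
        assert out.tpm_24nt.iloc[0] == pytest.approx(1e6 * 1.5 / 1000)


class TestClassifyFamilyType:
    BODY_I = {"CG": 0.8, "CHG": 0.7, "CHH": 0.6}
    FLANK_LOW = {"CG": 0.05, "CHG": 0.04, "CHH": 0.03}

    def test_type1_rule(self):
        t = classify_family_type("f", self.BODY_I, self.FLANK_LOW, srna24_body=50.0)
        assert t.type == "I"

    def test_type3_rule(self):
        body = {"CG": 0.7, "CHG": 0.04, "CHH": 0.04}
        t = classify_family_type("f", body, self.FLANK_LOW, srna24_body=1.0)
        assert t.type == "III"

    def test_type2_fallthrough(self):
        body = {"CG": 0.7, "CHG": 0.6, "CHH": 0.05}
        flank = {"CG": 0.65, "CHG": 0.6, "CHH": 0.05}
        t = classify_family_type("f", body, flank, srna24_body=1.0)
        assert t.type == "II"

    def test_all_zero_input_stable(self):
        zero = {"CG": 0.0, "CHG": 0.0, "CHH": 0.0}
        labels = {classify_family_type("f", zero, zero, 0.0).type for _ in range(3)}
        assert labels == {"II"}

    def test_missing_levels_unclassified(self):
        body = {"CG": float("nan"), "CHG": 0.1, "CHH": 0.1}
        t = classify_family_type("f", body, self.FLANK_LOW, 0.0)
        assert t.type == "unclassified"

    def test_round_trip_with_simulator(self, typed_sim_module):
        sim, meth, srna, total = typed_sim_module
        members = {}
        for r in sim.truth:
            members.setdefault(r.subfamily_id, []).append((r.chrom, r.start, r.end))
        out = family_epitypes(members, meth, srna, total)
        assigned = {t.family_id: t.type for t in out}
        assert assigned == {"sf1": "I", "sf2": "II", "sf3": "III"}


class TestGeneMethylationClasses:
    def _gene_counts(self, cg, chg, chh, n=30, cov=20):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(n):
            for ctx, rate in (("CG", cg), ("CHG", chg), ("CHH", chh)):
                t = cov
                rows.append(("c", i * 10, ctx, int(round(rate * t)), t))
        return _table(rows)

    def test_cg_body_methylated(self):
        df = self._gene_counts(0.6, 0.01, 0.01)
        assert classify_gene_methylation(df, "c", 0, 1000) == "CG_body_methylated"

    def test_c_methylated(self):
        df = self._gene_counts(0.5, 0.02, 0.3)
        assert classify_gene_methylation(df, "c", 0, 1000) == "C_methylated"

    def test_unmethylated(self):
        df = self._gene_counts(0.0, 0.0, 0.0)
        assert classify_gene_methylation(df, "c", 0, 1000) == "unmethylated"

    def test_low_coverage_uncallable(self):
        df = _table([("c", 1, "CG", 1, 2), ("c", 2, "CHG", 0, 2), ("c", 3, "CHH", 0, 2)])
        assert classify_gene_methylation(df, "c", 0, 1000) == "uncallable"


class TestCorrelationUtility:
    def test_constructed_positive_correlation(self, rng):
        genic = {f"f{i}": 0.1 + 0.08 * i for i in range(8)}
        cg = {f"f{i}": 0.2 + 0.07 * i + rng.normal(0, 0.02) for i in range(8)}
        r = genic_methylation_correlation(genic, cg)
        assert r > 0.8
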