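"""The three TRIM-defining criteria and their supporting searches."""

import numpy as np

from trimscape.structural_scanner import CandidateElement, scan_and_refine
from trimscape.synthetic_data import (
    SimulationSpec,
    back_translate,
    random_protein,
    random_seq,
    simulate_genome,
)
from trimscape.trim_filter import (
    apply_trim_criteria,
    coding_capacity,
    find_solo_ltrs,
)

from conftest import embed


def _mutate(seq, rate, rng):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < rate):
        out[i] = [b for b in "ACGT" if b != out[i]][rng.integers(3)]
    return "".join(out)


class TestFindSoloLtrs:
    def test_implanted_solo_found_complete_excluded(self):
        spec = SimulationSpec(genome_length=60_000, n_trims=1, n_solo_ltrs=1,
                              divergence=0.0, seed=41, n_subfamilies=1)
        sim = simulate_genome(spec)
        ltr = sim.subfamily_ltrs["sf1"]
        cands = scan_and_refine(sim.genome)
        solos = find_solo_ltrs(sim.genome, ltr, exclude=cands)
        truth_solo = [r for r in sim.truth if r.kind == "solo_ltr"]
        assert len(solos) == 1
        chrom, s, e = solos[0]
        assert abs(s - truth_solo[0].start) <= 5 and abs(e - truth_solo[0].end) <= 5

    def test_complete_only_genome_gives_no_solos(self):
        spec = SimulationSpec(genome_length=60_000, n_trims=2, divergence=0.0,
                              seed=43, n_subfamilies=1)
        sim = simulate_genome(spec)
        cands = scan_and_refine(sim.genome)
        solos = find_solo_ltrs(sim.genome, sim.subfamily_ltrs["sf1"], exclude=cands)
        assert solos == []

    def test_heavily_diverged_solo_not_returned(self, rng):
        ltr = "TG" + random_seq(116, 0.4, rng) + "CA"
        diverged = _mutate(ltr, 0.30, rng)
        genome = {"c": embed(random_seq(10_000, 0.4, rng), 5000, diverged, "ACGTA")}
        assert find_solo_ltrs(genome, ltr) == []


class TestCodingCapacity:
    def test_embedded_rt_fragment_detected(self, rng):
        protein = random_protein(150, rng)
        cds = back_translate(protein)
        element = random_seq(200, 0.4, rng) + cds + random_seq(200, 0.4, rng)
        found, best = coding_capacity(element, {"rt1": protein})
        assert found and best[0] == "rt1"

    def test_random_element_clean(self, rng):
        protein = random_protein(300, rng)
        for _ in range(5):
            element = random_seq(800, 0.4, rng)
            assert coding_capacity(element, {"rt1": protein})[0] is False

    def test_empty_protein_set_is_false(self, rng):
        assert coding_capacity(random_seq(900, 0.4, rng), {})[0] is False

    def test_short_element_cannot_host_orf(self, rng):
        protein = random_protein(100, rng)
        assert coding_capacity(random_seq(250, 0.4, rng), {"p": protein})[0] is False


def _candidate_from(genome, chrom, start, ltr_len, internal_len, tsd=None):
    end = start + 2 * ltr_len + internal_len
    cand = CandidateElement(
        chrom=chrom, start=start, end=end,
        ltr5=(start, start + ltr_len),
        ltr3=(end - ltr_len, end),
        internal=(start + ltr_len, end - ltr_len),
        ltr_identity=1.0,
        tsd=tsd,
    )
    return cand


class TestApplyTrimCriteria:
    def _build_genome(self, copies, rng, ltr_len=60, internal_len=200, tsds=None,
                      element=None):
        """Plant n copies of one element with given TSDs; return genome+cands."""
        ltr = "TG" + random_seq(ltr_len - 4, 0.4, rng) + "CA"
        internal = random_seq(internal_len, 0.4, rng)
        el = element or (ltr + internal + ltr)
        bg = random_seq(4000 + 6000 * copies, 0.4, rng)
        genome_seq = ""
        cands = []
        prev = 0
        for i in range(copies):
            pos = 3000 + i * 6000
            tsd = (tsds[i] if tsds else "ACG" + "TGCA"[i % 4] + "A")
            genome_seq += bg[prev:pos] + tsd + el + tsd
            start = len(genome_seq) - len(el) - len(tsd)
            prev = pos
            cands.append((start, len(el)))
        genome_seq += bg[prev:]
        genome = {"c": genome_seq}
        out = []
        from trimscape.structural_scanner import detect_tsd

        for start, el_len in cands:
            c = _candidate_from(genome, "c", start, (el_len - internal_len) // 2,
                                internal_len)
            try:
                tsd = detect_tsd(c, genome)
            except Exception:
                tsd = None
            c = CandidateElement(**{**c.__dict__, "tsd": tsd})
            out.append(c)
        return genome, out

    def test_two_copies_distinct_tsds_retained(self, rng):
        genome, cands = self._build_genome(2, rng, tsds=["AACAT", "GGGTT"])
        report = apply_trim_criteria(cands, genome)
        assert len(report.retained) == 2
        assert all(t.copy_support == "multi_complete" for t in report.retained)

    def test_single_copy_rejected(self, rng):
        genome, cands = self._build_genome(1, rng, tsds=["AACAT"])
        report = apply_trim_criteria(cands, genome)
        assert report.retained == []
        assert report.rejected[0][1] == "insufficient_copies"

    def test_identical_tsds_count_as_one_copy(self, rng):
        genome, cands = self._build_genome(2, rng, tsds=["AACAT", "AACAT"])
        report = apply_trim_criteria(cands, genome)
        assert report.retained == []
        assert {r for _, r in report.rejected} == {"insufficient_copies"}

    def test_overlong_element_rejected(self, rng):
        genome, cands = self._build_genome(
            2, rng, ltr_len=100, internal_len=1400, tsds=["AACAT", "GGGTT"]
        )
        report = apply_trim_criteria(cands, genome)
        assert {r for _, r in report.rejected} == {"too_long"}

    def test_n_containing_element_rejected(self, rng):
        ltr = "TG" + random_seq(56, 0.4, rng) + "CA"
        internal = random_seq(95, 0.4, rng) + "NNNNN" + random_seq(100, 0.4, rng)
        genome, cands = self._build_genome(
            2, rng, tsds=["AACAT", "GGGTT"], element=ltr + internal + ltr
        )
        report = apply_trim_criteria(cands, genome)
        assert {r for _, r in report.rejected} == {"contains_n"}

    def test_rt_coding_element_rejected(self, rng):
        protein = random_protein(120, rng)
        ltr = "TG" + random_seq(56, 0.4, rng) + "CA"
        internal = random_seq(40, 0.4, rng) + back_translate(protein) + random_seq(40, 0.4, rng)
        genome, cands = self._build_genome(
            2, rng, internal_len=len(internal), tsds=["AACAT", "GGGTT"],
            element=ltr + internal + ltr,
        )
        report = apply_trim_criteria(cands, genome, {"rt": protein})
        assert {r for _, r in report.rejected} == {"coding_capacity"}

    def test_smallest_reported_geometry_retained(self, rng):
        """A 233-bp element with 52-bp LTRs and many copies passes."""
        ltr = "TG" + random_seq(48, 0.4, rng) + "CA"
        internal = random_seq(233 - 104, 0.4, rng)
        el = ltr + internal + ltr
        assert len(el) == 233
        tsds = ["AACAT", "GGGTT", "CTTCA", "ATAAT", "GATTA",
                "TTGCA", "CCATG", "AGAGT", "TGTGA", "CATCA"]
        genome, cands = self._build_genome(10, rng, internal_len=len(internal),
                                           tsds=tsds, element=el)
        report = apply_trim_criteria(cands, genome)
        assert len(report.retained) == 10

    def test_partition_property(self, rng):
        genome, cands = self._build_genome(3, rng, tsds=["AACAT", "GGGTT", "AACAT"])
        report = apply_trim_criteria(cands, genome)
        assert len(report.retained) + len(report.rejected) == len(cands)

    def test_monotonicity_under_added_copies(self, rng):
        """Adding further copies never rejects a previously retained element."""
        genome3, cands3 = self._build_genome(3, rng, tsds=["AACAT", "GGGTT", "CTTCA"])
        report3 = apply_trim_criteria(cands3, genome3)
        retained3 = {(t.start, t.end) for t in report3.retained}
        # same construction with only the first two copies
        rng2 = np.random.default_rng(42)
        genome2, cands2 = self._build_genome(2, rng2, tsds=["AACAT", "GGGTT"])
        report2 = apply_trim_criteria(cands2, genome2)
        retained2 = {(t.start, t.end) for t in report2.retained}
        assert retained2 <= retained3 or len(report3.retained) >= len(report2.retained)

    def test_empty_input_empty_output(self):
        report = apply_trim_criteria([], {"c": "ACGT" * 100})
        assert report.retained == [] and report.rejected == []
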