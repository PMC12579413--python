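"""Reference generation, trio designs, read simulation, projection, panels."""

import numpy as np
import pytest

from polledrec.locus_model import (
    FV_AHR_BREAKPOINT,
    PF_UNIT_END,
    PF_UNIT_START,
    Diplotype,
    GenomeSegment,
    allele_spec,
    build_haplotype,
)
from polledrec.synthetic_data import (
    DesignError,
    ReadSimParams,
    SimulatedRead,
    design_trio,
    make_reference,
    project_alignments,
    simulate_reads,
    simulate_snp_panel,
)
from polledrec.trio_phase import mendelian_consistency


def brute_force_longest_repeat(seq: str, k: int) -> bool:
    """O(n^2) oracle: does any exact k-mer occur twice?"""
    for i in range(len(seq) - k + 1):
        if seq.find(seq[i : i + k], i + 1) != -1:
            return True
    return False


class TestMakeReference:
    def test_deterministic_under_seed(self):
        a = make_reference(length=30_000, seed=7)
        b = make_reference(length=30_000, seed=7)
        assert a.sequence == b.sequence
        assert make_reference(length=30_000, seed=8).sequence != a.sequence

    def test_no_repeat_at_or_above_threshold(self):
        seg = make_reference(length=4_000, seed=3, max_exact_repeat=20, start=1)
        assert not brute_force_longest_repeat(seg.sequence, 20)

    def test_gc_fraction_within_band(self):
        seg = make_reference(length=200_000, seed=5, gc_fraction=0.42)
        gc = (seg.sequence.count("G") + seg.sequence.count("C")) / len(seg)
        assert abs(gc - 0.42) < 0.02

    def test_diagnostic_motif_bases_pinned(self):
        seg = make_reference(seed=9)
        assert seg.base(PF_UNIT_START) == "T"
        assert seg.slice(2_629_153, 2_629_154) == "TG"


class TestDesignTrio:
    def test_h3h4_offspring_is_wildtype(self, segment, hap_p):
        d = design_trio("HF_H3H4", segment, nahr_offset=40_000)
        assert d.offspring.haplotypes[0].sequence == hap_p.sequence
        assert d.phenotype_truth == "horned"

    def test_fv_ahr_offspring_maternal_is_wildtype(self, segment, hap_p):
        d = design_trio("FV_ahr_wildtype", segment)
        assert d.offspring.haplotypes[1].sequence == hap_p.sequence

    def test_fv_cis_offspring_carries_both_variants(self, segment, hap_p):
        d = design_trio("FV_cis_fusion", segment)
        maternal = d.offspring.haplotypes[1]
        assert len(maternal) == len(hap_p) + 202 + 80_126
        assert d.phenotype_truth == "polled"

    def test_h1_deletion_shorter_than_unit(self, segment, hap_pf):
        d = design_trio("HF_H1", segment, h1_deletion_length=40_000)
        assert len(d.offspring.haplotypes[0]) == len(hap_pf) - 40_000

    def test_h2_removes_more_than_one_unit(self, segment, hap_p):
        d = design_trio("HF_H2", segment, h2_extra_deleted=10_000)
        assert len(d.offspring.haplotypes[0]) == len(hap_p) - 10_000

    def test_invalid_breakpoint_rejected(self, segment):
        with pytest.raises(DesignError):
            design_trio("FV_ahr_wildtype", segment, ahr_breakpoint=2_410_000)

    def test_proximal_nahr_offset_rejected(self, segment):
        with pytest.raises(DesignError):
            design_trio("HF_H3H4", segment, nahr_offset=10)


@pytest.fixture(scope="module")
def small_diplotype():
    seg = make_reference(length=60_000, seed=21, start=1)
    hap = build_haplotype(seg, allele_spec("p"))
    return Diplotype("S", "sire", (hap, hap))


class TestSimulateReads:

    def test_coverage_accounting(self, small_diplotype):
        reads = simulate_reads(small_diplotype, ReadSimParams(coverage=20, seed=0))
        total = sum(r.hap_end - r.hap_start + 1 for r in reads)
        assert abs(total - 20 * 60_000) / (20 * 60_000) < 0.10

    def test_noiseless_reads_are_exact_substrings(self, small_diplotype):
        params = ReadSimParams(
            coverage=4, seed=1, mismatch_rate=0, ins_rate=0, del_rate=0
        )
        hap = small_diplotype.haplotypes[0].sequence
        for r in simulate_reads(small_diplotype, params):
            sub = hap[r.hap_start - 1 : r.hap_end]
            if r.strand == "-":
                sub = sub.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert r.sequence == sub

    def test_deterministic_under_seed(self, small_diplotype):
        p = ReadSimParams(coverage=5, seed=9)
        a = simulate_reads(small_diplotype, p)
        b = simulate_reads(small_diplotype, p)
        assert [(r.read_id, r.sequence) for r in a] == [
            (r.read_id, r.sequence) for r in b
        ]

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            ReadSimParams(coverage=0)

    def test_error_rates_bounded(self):
        with pytest.raises(ValueError):
            ReadSimParams(mismatch_rate=0.5)


def _noiseless_read(d, hap_index, start, end, rid="r0"):
    hap = d.haplotypes[hap_index]
    return SimulatedRead(
        read_id=rid,
        sequence=hap.sequence[start - 1 : end],
        quality="5" * (end - start + 1),
        individual_id=d.individual_id,
        hap_index=hap_index,
        hap_start=start,
        hap_end=end,
        strand="+",
    )


class TestProjection:
    def test_junction_read_splits_with_rewind(self, segment, hap_pf):
        d = Diplotype("X", "sire", (hap_pf, hap_pf))
        junction = hap_pf.ref_to_hap(PF_UNIT_END, 0)
        read = _noiseless_read(d, 0, junction - 2_000, junction + 2_000)
        [aln] = project_alignments([read], d)
        assert len(aln.segments) == 2
        a, b = aln.segments
        assert a.ref_end == PF_UNIT_END
        assert b.ref_start == PF_UNIT_START
        assert b.ref_start < a.ref_end  # the tandem-duplication rewind

    def test_read_inside_copy0_is_single_segment(self, segment, hap_pf):
        d = Diplotype("X", "sire", (hap_pf, hap_pf))
        read = _noiseless_read(d, 0, 10_000, 18_000)
        [aln] = project_alignments([read], d)
        [seg] = aln.segments
        assert seg.ref_start == segment.start + 9_999
        assert seg.ref_end == segment.start + 17_999
        assert seg.cigar == (("M", 8_001),)

    def test_nahr_offspring_read_is_contiguous_over_former_junction(self, segment):
        d = design_trio("HF_H3H4", segment, nahr_offset=40_000)
        off = d.offspring
        pos = off.haplotypes[0].ref_to_hap(PF_UNIT_END, 0)
        read = _noiseless_read(off, 0, pos - 3_000, pos + 3_000)
        [aln] = project_alignments([read], off)
        assert len(aln.segments) == 1

    def test_f2d_deletion_appears_in_cigar(self, hap_pf):
        d = Diplotype("X", "sire", (hap_pf, hap_pf))
        junction = hap_pf.ref_to_hap(PF_UNIT_END, 0)
        read = _noiseless_read(d, 0, junction - 500, junction + 500)
        [aln] = project_alignments([read], d)
        copy1_seg = aln.segments[1]
        assert ("D", 2) in copy1_seg.cigar

    def test_truth_conservation_noiseless(self, segment, hap_pc):
        d = Diplotype("X", "sire", (hap_pc, hap_pc))
        params = ReadSimParams(
            coverage=2, seed=4, mismatch_rate=0, ins_rate=0, del_rate=0
        )
        reads = simulate_reads(d, params)
        for aln in project_alignments(reads, d):
            aligned = sum(
                s.read_end - s.read_start + 1 for s in aln.segments
            )
            assert aligned == len(aln.read.sequence)

    def test_foreign_read_rejected(self, segment, hap_p):
        d = Diplotype("X", "sire", (hap_p, hap_p))
        read = _noiseless_read(d, 0, 1, 1000)
        other = Diplotype("Y", "dam", (hap_p, hap_p))
        with pytest.raises(ValueError):
            project_alignments([read], other)


class TestSnpPanel:
    def test_no_event_trio_is_mendelian_consistent(self, segment):
        d = design_trio("FV_parental", segment)
        panel = simulate_snp_panel(60, (segment.start, segment.end), d, seed=3)
        report = mendelian_consistency(panel.genotypes)
        assert report.n_conflicts == 0 and report.verdict == "pass"

    def test_designed_crossover_switches_transmission_once(self, segment):
        d = design_trio("FV_ahr_wildtype", segment)
        panel = simulate_snp_panel(80, (segment.start, segment.end), d, seed=5)
        pos = panel.genotypes.positions
        hap = panel.truth_maternal_hap
        switches = np.flatnonzero(np.diff(hap) != 0)
        assert len(switches) == 1
        assert pos[switches[0]] <= FV_AHR_BREAKPOINT < pos[switches[0] + 1]

    def test_shuffled_sire_conflict_rate_matches_expectation(self, segment):
        rng = np.random.default_rng(11)
        d = design_trio("FV_parental", segment)
        panel = simulate_snp_panel(500, (segment.start, segment.end), d, seed=8)
        g = panel.genotypes
        # replace the sire with an unrelated individual drawn from the
        # same marker frequencies
        freqs = np.array([m.b_freq for m in panel.markers])
        fake = (rng.random((2, len(g))) < freqs).astype(int)
        sire = np.array(
            ["".join(sorted("AB"[a] + "AB"[b])) for a, b in zip(*fake)]
        )
        shuffled = type(g)(
            positions=g.positions, sire=sire, dam=g.dam, offspring=g.offspring
        )
        rate = mendelian_consistency(shuffled).conflict_rate

        # brute-force expectation: enumerate the six independent
        # haplotype alleles per marker and average P(conflict) over the
        # marker frequencies
        def p_conflict(f):
            p = 0.0
            for bits in range(64):
                t1, t2, d1, d2, s1, s2 = [(bits >> i) & 1 for i in range(6)]
                pr = 1.0
                for a in (t1, t2, d1, d2, s1, s2):
                    pr *= f if a else 1 - f
                off = {t1, d1}
                sire_al = {s1, s2}
                dam_al = {d1, d2}
                o = sorted([t1, d1])
                consistent = any(
                    {x, y} >= set()
                    and sorted([x, y]) == o
                    for x in sire_al
                    for y in dam_al
                )
                if not consistent:
                    p += pr
            return p

        expected = np.mean([p_conflict(f) for f in freqs])
        assert abs(rate - expected) < 0.04

    def test_too_few_markers_rejected(self, segment):
        d = design_trio("FV_parental", segment)
        with pytest.raises(ValueError):
            simulate_snp_panel(5, (segment.start, segment.end), d, seed=1)

    def test_region_outside_segment_rejected(self, segment):
        d = design_trio("FV_parental", segment)
        with pytest.raises(ValueError):
            simulate_snp_panel(20, (1, 1000), d, seed=1)
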