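"""Sequence algebra of the POLLED alleles: builds, liftover, AHR/NAHR."""

import numpy as np
import pytest

from polledrec.locus_model import (
    FV_AHR_BREAKPOINT,
    PC_DEL_END,
    PC_DEL_START,
    PC_DUP_SOURCE_END,
    PC_DUP_SOURCE_START,
    PF_UNIT_END,
    PF_UNIT_START,
    PF_UNIT_LENGTH,
    AlleleSpec,
    BreakpointError,
    CoordinateError,
    Diplotype,
    EditOp,
    SpecError,
    ahr_product,
    allele_spec,
    build_haplotype,
    liftover,
    nahr_product,
    reconstruct_reference,
    sv_length,
    sv_net_change,
    variant_distance,
)


def _pf_oracle_sequence(segment):
    """Independent string construction of the P_F haplotype."""
    off = segment.start
    unit = segment.sequence[PF_UNIT_START - off : PF_UNIT_END - off + 1]
    copy1 = "A" + unit[1:37] + unit[39:]  # SNV at bp 1, TG deleted at bp 38-39
    left = segment.sequence[: PF_UNIT_END - off + 1]
    right = segment.sequence[PF_UNIT_END - off + 1 :]
    return left + copy1 + right


def _pc_oracle_sequence(segment):
    off = segment.start
    template = segment.sequence[
        PC_DUP_SOURCE_START - off : PC_DUP_SOURCE_END - off + 1
    ]
    return (
        segment.sequence[: PC_DEL_START - off]
        + template
        + segment.sequence[PC_DEL_END - off + 1 :]
    )


class TestSvLength:
    @pytest.mark.parametrize(
        "allele_id, expected",
        [("P_F", 80_128), ("P_C", 212)],
    )
    def test_printed_variant_lengths(self, allele_id, expected):
        assert sv_length(allele_spec(allele_id).edits[-1]) == expected

    def test_single_base_deletion(self):
        assert sv_length(EditOp("deletion", 100, 100)) == 1

    def test_delins_net_change(self):
        e = allele_spec("P_M").edits[0]  # 7 bp replaced by TCTGAA
        assert sv_length(e) == 7
        assert sv_net_change(e) == -1

    def test_pf_net_change_is_two_short_of_unit(self):
        assert sv_net_change(allele_spec("P_F").edits[0]) == 80_126

    def test_malformed_coordinates_rejected(self):
        with pytest.raises(CoordinateError):
            EditOp("deletion", 200, 100)


class TestBuildHaplotype:
    def test_wildtype_is_identity(self, segment, hap_p):
        assert hap_p.sequence == segment.sequence
        assert len(hap_p.blocks) == 1
        assert hap_p.blocks[0].copy_index == 0

    def test_pf_matches_string_oracle(self, segment, hap_pf):
        assert hap_pf.sequence == _pf_oracle_sequence(segment)
        assert len(hap_pf) == len(segment) + 80_126

    def test_pc_matches_string_oracle(self, segment, hap_pc):
        assert hap_pc.sequence == _pc_oracle_sequence(segment)
        assert len(hap_pc) == len(segment) + 212 - 10

    @pytest.mark.parametrize("allele_id", ["p", "P_C", "P_F", "P_M", "P_G"])
    def test_round_trip_reconstruction(self, segment, allele_id):
        h = build_haplotype(segment, allele_spec(allele_id))
        assert reconstruct_reference(h) == segment.sequence

    @pytest.mark.parametrize("allele_id", ["P_C", "P_F", "P_M", "P_G"])
    def test_blocks_tile_and_copy0_matches_reference(self, segment, allele_id):
        h = build_haplotype(segment, allele_spec(allele_id))
        pos = 1
        for b in h.blocks:  # tiling is also enforced by the constructor
            assert b.hap_start == pos
            pos = b.hap_end + 1
        assert pos == len(h) + 1

    def test_overlapping_edits_rejected(self, segment):
        with pytest.raises(SpecError):
            AlleleSpec(
                "custom",
                (EditOp("deletion", 2_500_000, 2_500_100),
                 EditOp("deletion", 2_500_050, 2_500_150)),
            )

    def test_out_of_bounds_edit_rejected(self, segment):
        spec = AlleleSpec("custom", (EditOp("deletion", 1, 10),))
        with pytest.raises(CoordinateError):
            build_haplotype(segment, spec)


class TestLiftover:
    def test_wildtype_identity_map(self, segment, hap_p):
        lift = liftover(hap_p, 5)
        assert lift == (segment.start + 4, 0, False)

    def test_first_base_after_pf_junction_reenters_unit(self, hap_pf):
        junction = hap_pf.ref_to_hap(PF_UNIT_END, copy_index=0)
        lift = liftover(hap_pf, junction + 1)
        assert (lift.ref_pos, lift.copy_index) == (PF_UNIT_START, 1)

    def test_last_base_of_duplicated_copy(self, hap_pf):
        junction = hap_pf.ref_to_hap(PF_UNIT_END, copy_index=0)
        lift = liftover(hap_pf, junction + 80_126)
        assert (lift.ref_pos, lift.copy_index) == (PF_UNIT_END, 1)

    def test_out_of_range_rejected(self, hap_p):
        with pytest.raises(CoordinateError):
            liftover(hap_p, len(hap_p) + 1)

    def test_liftover_ref_to_hap_round_trip(self, hap_pf):
        rng = np.random.default_rng(0)
        for pos in rng.integers(1, len(hap_pf) + 1, size=200):
            lift = hap_pf.liftover(int(pos))
            assert hap_pf.ref_to_hap(lift.ref_pos, lift.copy_index) == int(pos)


class TestNahrProduct:
    def test_distal_crossover_reconstructs_wildtype(self, segment, hap_pf, hap_p):
        product = nahr_product(hap_pf, 10_000)
        assert product.sequence == hap_p.sequence

    def test_identity_holds_across_sampled_offsets(self, hap_pf, hap_p):
        rng = np.random.default_rng(1)
        offsets = rng.integers(40, PF_UNIT_LENGTH + 1, size=25)
        for o in offsets:
            assert nahr_product(hap_pf, int(o)).sequence == hap_p.sequence

    def test_crossover_at_unit_start_keeps_both_diagnostics(self, segment, hap_pf):
        product = nahr_product(hap_pf, 1)
        off = PF_UNIT_START - segment.start
        assert product.sequence[off] == "A"  # the T>A SNV survives
        assert len(product) == len(segment) - 2  # P_F2D deletion survives

    def test_crossover_between_diagnostics_keeps_only_deletion(self, segment, hap_pf):
        product = nahr_product(hap_pf, 20)
        off = PF_UNIT_START - segment.start
        assert product.sequence[off] == segment.sequence[off]  # SNV lost
        assert len(product) == len(segment) - 2  # deletion retained

    def test_proximal_offsets_differ_from_wildtype(self, hap_pf, hap_p):
        for o in (1, 5, 20, 37):
            assert nahr_product(hap_pf, o).sequence != hap_p.sequence

    def test_haplotype_without_duplication_rejected(self, hap_p):
        with pytest.raises(SpecError):
            nahr_product(hap_p, 10)

    def test_offset_out_of_unit_rejected(self, hap_pf):
        with pytest.raises(CoordinateError):
            nahr_product(hap_pf, PF_UNIT_LENGTH + 1)


class TestAhrProduct:
    def test_crossover_between_variants_skips_both(self, hap_pf, hap_pc, hap_p):
        product = ahr_product(hap_pf, hap_pc, FV_AHR_BREAKPOINT)
        assert product.sequence == hap_p.sequence

    def test_reciprocal_product_is_cis_fusion(self, segment, hap_pf, hap_pc):
        product = ahr_product(hap_pc, hap_pf, FV_AHR_BREAKPOINT)
        pos_c = hap_pc.ref_to_hap(FV_AHR_BREAKPOINT, 0)
        pos_f = hap_pf.ref_to_hap(FV_AHR_BREAKPOINT, 0)
        oracle = hap_pc.sequence[:pos_c] + hap_pf.sequence[pos_f:]
        assert product.sequence == oracle
        assert len(product) == len(segment) + 202 + 80_126

    def test_recombining_identical_wildtypes_is_wildtype(self, hap_p):
        product = ahr_product(hap_p, hap_p, 2_500_000)
        assert product.sequence == hap_p.sequence

    def test_breakpoint_inside_deleted_tract_rejected(self, hap_pc, hap_p):
        with pytest.raises(BreakpointError):
            ahr_product(hap_pc, hap_p, PC_DEL_START + 2)

    def test_reciprocal_products_partition_total_length(self, hap_pf, hap_pc):
        rng = np.random.default_rng(2)
        for bp in rng.integers(PC_DEL_END + 1, PF_UNIT_END, size=10):
            a = ahr_product(hap_pf, hap_pc, int(bp))
            b = ahr_product(hap_pc, hap_pf, int(bp))
            assert len(a) + len(b) == len(hap_pf) + len(hap_pc)


class TestVariantDistance:
    def test_celtic_friesian_separation_rounds_to_200kb(self):
        d = variant_distance(allele_spec("P_C"), allele_spec("P_F"), rounding=10_000)
        assert d.bp == 200_000 and not d.contained

    def test_raw_separation(self):
        d = variant_distance(allele_spec("P_C"), allele_spec("P_F"))
        assert d.bp == PF_UNIT_START - PC_DEL_START == 199_790

    def test_self_distance_zero(self):
        assert variant_distance(allele_spec("P_F"), allele_spec("P_F")) == (0, False)

    def test_mongolian_contained_in_friesian(self):
        d = variant_distance(allele_spec("P_F"), allele_spec("P_M"))
        assert d.bp == 0 and d.contained

    def test_wildtype_has_no_span(self):
        with pytest.raises(SpecError):
            variant_distance(allele_spec("p"), allele_spec("P_F"))
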