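"""Decision rules: HF hypothesis classification and FV trio outcomes."""

import numpy as np
import pytest

from polledrec.depth_scan import CnvCall
from polledrec.hypothesis_engine import (
    FV_LABELS,
    HF_LABELS,
    EvidenceBundle,
    classify_fv,
    classify_hf,
    enumerate_gametes,
)
from polledrec.polled_diagnostics import DiagnosticSiteCounts, SiteGenotypeCall
from polledrec.splitread_scan import BreakpointCluster
from polledrec.trio_phase import SwitchCall


def call(site, dosage, n=40):
    k = {0: 0, 1: n // 3, 2: n // 2}.get(dosage, 0) if dosage is not None else 0
    return SiteGenotypeCall(
        site, dosage, 0.99, DiagnosticSiteCounts(site, n - k, k)
    )


def dup_cluster(left=2_689_243, right=2_649_118, support=6):
    return BreakpointCluster(left, right, "TANDEM_DUP", support, ("r1", "r2"))


def del_cluster(left=2_704_243, right=2_714_245, support=5):
    return BreakpointCluster(left, right, "DEL", support, ("r1", "r2"))


def gain(start=2_650_000, end=2_688_000):
    return CnvCall(start, end, "gain", 1.5, 100)


def loss(start=2_705_000, end=2_713_000):
    return CnvCall(start, end, "loss", 0.5, 60)


class TestClassifyHF:
    def test_pf2d_present_means_expected_transmission(self):
        # rule precedence: any other evidence is irrelevant
        e = EvidenceBundle(
            split_clusters=(dup_cluster(),),
            cnv_calls=(gain(),),
            pf_call=call("P_F2D_site", 1),
        )
        v = classify_hf(e)
        assert v.label == "EXPECTED_TRANSMISSION"
        assert v.phenotype_prediction == "polled"

    def test_subunit_dup_with_gain_is_h1(self):
        e = EvidenceBundle(
            split_clusters=(dup_cluster(),),
            cnv_calls=(gain(),),
            pf_call=call("P_F2D_site", 0),
        )
        assert classify_hf(e).label == "H1"

    def test_del_cluster_with_loss_is_h2(self):
        e = EvidenceBundle(
            split_clusters=(del_cluster(),),
            cnv_calls=(loss(),),
            pf_call=call("P_F2D_site", 0),
        )
        assert classify_hf(e).label == "H2"

    def test_clean_locus_is_h3_or_h4(self):
        e = EvidenceBundle(pf_call=call("P_F2D_site", 0))
        v = classify_hf(e)
        assert v.label == "H3_OR_H4"
        assert v.phenotype_prediction == "horned"

    def test_uncorroborated_depth_excursions_do_not_block_h3h4(self):
        e = EvidenceBundle(
            cnv_calls=(gain(2_450_000, 2_452_000), loss(2_500_000, 2_502_000)),
            pf_call=call("P_F2D_site", 0),
        )
        v = classify_hf(e)
        assert v.label == "H3_OR_H4"
        assert len(v.warnings) == 2

    def test_full_unit_dup_cluster_implies_pf_presence(self):
        # the split-read pattern of an intact unit outweighs a low
        # diagnostic read draw: joint evidence, as in the variant
        # confirmation workflow
        e = EvidenceBundle(
            split_clusters=(dup_cluster(2_709_243, 2_629_116),),
            cnv_calls=(gain(2_630_000, 2_708_000),),
            pf_call=call("P_F2D_site", 0),
        )
        assert classify_hf(e).label == "EXPECTED_TRANSMISSION"

    def test_subunit_dup_cluster_without_gain_is_inconsistent(self):
        e = EvidenceBundle(
            split_clusters=(dup_cluster(),),
            pf_call=call("P_F2D_site", 0),
        )
        assert classify_hf(e).label == "INCONSISTENT"

    def test_no_call_is_inconsistent(self):
        e = EvidenceBundle(pf_call=call("P_F2D_site", None, n=4))
        assert classify_hf(e).label == "INCONSISTENT"

    def test_missing_diagnostic_raises(self):
        with pytest.raises(ValueError):
            classify_hf(EvidenceBundle())

    def test_sub_threshold_clusters_surface_as_warnings(self):
        e = EvidenceBundle(
            low_support_clusters=(
                BreakpointCluster(2_650_000, 2_700_000, "TANDEM_DUP", 1, ("c",)),
            ),
            pf_call=call("P_F2D_site", 0),
        )
        v = classify_hf(e)
        assert v.label == "H3_OR_H4"
        assert any("sub-threshold" in w for w in v.warnings)


def switch(point=2_694_883, lo=None, hi=None, parent="dam"):
    lo = lo if lo is not None else point - 2_000
    hi = hi if hi is not None else point + 2_000
    return SwitchCall(parent, (lo, hi), (lo + hi) // 2, 1, 0)


class TestClassifyFV:
    def test_single_variant_no_switch_is_parental(self):
        e = EvidenceBundle(
            pc_call=call("P_C_site", 1), pf_call=call("P_F2D_site", 0)
        )
        assert classify_fv(e).label == "FV_PARENTAL"

    def test_both_absent_with_window_switch_is_ahr_wildtype(self):
        e = EvidenceBundle(
            pc_call=call("P_C_site", 0),
            pf_call=call("P_F2D_site", 0),
            switches=(switch(),),
        )
        v = classify_fv(e)
        assert v.label == "FV_AHR_WILDTYPE"
        assert v.phenotype_prediction == "horned"

    def test_wide_interval_overlapping_window_still_accepted(self):
        e = EvidenceBundle(
            pc_call=call("P_C_site", 0),
            pf_call=call("P_F2D_site", 0),
            switches=(switch(lo=2_687_000, hi=2_745_000),),
        )
        assert classify_fv(e).label == "FV_AHR_WILDTYPE"

    def test_both_present_is_cis_fusion(self):
        e = EvidenceBundle(
            pc_call=call("P_C_site", 1),
            pf_call=call("P_F2D_site", 1),
            switches=(switch(),),
        )
        v = classify_fv(e)
        assert v.label == "FV_CIS_FUSION"
        assert v.phenotype_prediction == "polled"

    def test_switch_outside_window_is_inconsistent(self):
        e = EvidenceBundle(
            pc_call=call("P_C_site", 0),
            pf_call=call("P_F2D_site", 0),
            switches=(switch(lo=2_770_000, hi=2_790_000),),
        )
        assert classify_fv(e).label == "INCONSISTENT"

    def test_non_trans_dam_rejected(self):
        e = EvidenceBundle(
            pc_call=call("P_C_site", 0), pf_call=call("P_F2D_site", 0)
        )
        with pytest.raises(ValueError):
            classify_fv(e, dam_is_trans=False)


class TestRuleTotality:
    def test_every_random_bundle_maps_to_exactly_one_label(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            clusters = tuple(
                BreakpointCluster(
                    int(rng.integers(2_420_000, 2_740_000)),
                    int(rng.integers(2_420_000, 2_740_000)),
                    rng.choice(["DEL", "TANDEM_DUP", "INV"]),
                    int(rng.integers(2, 20)),
                    ("r",),
                )
                for _ in range(rng.integers(0, 3))
            )
            cnvs = tuple(
                CnvCall(
                    int(s := rng.integers(2_420_000, 2_700_000)),
                    int(s + rng.integers(1_000, 60_000)),
                    rng.choice(["gain", "loss"]),
                    float(rng.uniform(0.3, 2.2)),
                    10,
                )
                for _ in range(rng.integers(0, 3))
            )
            switches = tuple(
                switch(point=int(rng.integers(2_420_000, 2_790_000)))
                for _ in range(rng.integers(0, 3))
            )
            e = EvidenceBundle(
                split_clusters=clusters,
                cnv_calls=cnvs,
                pc_call=call("P_C_site", int(rng.integers(0, 3))),
                pf_call=call("P_F2D_site", int(rng.integers(0, 3))),
                switches=switches,
            )
            assert classify_hf(e).label in HF_LABELS
            assert classify_fv(e).label in FV_LABELS


class TestEnumerateGametes:
    def test_trans_parent_recombinant_classes(self):
        g = enumerate_gametes("P_C/P_F", r=0.002)
        assert g["p"] == pytest.approx(0.001)
        assert g["P_C+P_F"] == pytest.approx(0.001)
        assert g["P_C"] == g["P_F"] == pytest.approx(0.499)

    def test_zero_recombination_parental_only(self):
        g = enumerate_gametes("P_C/P_F", r=0.0)
        assert g == {"P_C": 0.5, "P_F": 0.5, "p": 0.0, "P_C+P_F": 0.0}

    def test_free_recombination_limit(self):
        g = enumerate_gametes("P_C/P_F", r=0.5)
        assert all(v == pytest.approx(0.25) for v in g.values())

    def test_homozygote_single_class(self):
        assert enumerate_gametes("P_F/P_F") == {"P_F": 1.0}

    @pytest.mark.parametrize("r", [0.0, 0.1, 0.3, 0.5])
    def test_probabilities_sum_to_one(self, r):
        for geno in ("P_C/P_F", "P_F/p", "p/p", "P_C/P_C"):
            assert sum(enumerate_gametes(geno, r).values()) == pytest.approx(1.0)
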