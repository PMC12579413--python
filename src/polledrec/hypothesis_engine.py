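"""Decision procedures for the two trio puzzles.

A horned offspring from a polled-homozygous parent demands a germline
rearrangement.  For a trio whose sire is P_F/P_F (duplication
homozygote) the candidate explanations are:

* H1 - a deletion shorter than the 80,128 bp unit, leaving duplicated
  residue: expect a tandem-duplication split signature plus a <unit
  copy-number gain;
* H2 - a deletion longer than the unit, removing wild-type motifs:
  expect a deletion split signature plus a copy-number loss;
* H3/H4 - a deletion of exactly one unit (NAHR between the copies),
  reconstructing the wild-type sequence: expect *no* split clusters and
  *no* copy-number call at all.  H3 (hybrid of both copies) and H4
  (pure loss of the duplicated copy) are indistinguishable unless a
  variant differentiating the copies exists.

For a trio whose dam is P_C/P_F in trans, the transmitted maternal
haplotype is either parental, the allelic-crossover product skipping
both variants (wild type, horned), or - with equal prior likelihood -
the reciprocal cis fusion carrying both.

Depth evidence is coupled to split evidence: a copy-number call is only
treated as a real rearrangement when split reads with consistent
breakpoints corroborate it, so isolated coverage fluctuations do not
overturn a classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .depth_scan import CnvCall, DepthTrack
from .locus_model import (
    PC_DEL_END,
    PC_DEL_START,
    PC_DUP_SOURCE_START,
    PF_UNIT_END,
    PF_UNIT_LENGTH,
    PF_UNIT_START,
)
from .polled_diagnostics import SiteGenotypeCall, gamete_distribution
from .splitread_scan import BreakpointCluster
from .trio_phase import SwitchCall

__all__ = [
    "EvidenceBundle",
    "HypothesisCall",
    "classify_hf",
    "classify_fv",
    "enumerate_gametes",
    "HF_LABELS",
    "FV_LABELS",
]

HF_LABELS = ("EXPECTED_TRANSMISSION", "H1", "H2", "H3_OR_H4", "INCONSISTENT")
FV_LABELS = ("FV_PARENTAL", "FV_AHR_WILDTYPE", "FV_CIS_FUSION", "INCONSISTENT")


@dataclass(frozen=True)
class EvidenceBundle:
    """Detection outputs for one offspring over the locus."""

    split_clusters: tuple[BreakpointCluster, ...] = ()
    low_support_clusters: tuple[BreakpointCluster, ...] = ()
    cnv_calls: tuple[CnvCall, ...] = ()
    track: Optional[DepthTrack] = None
    pc_call: Optional[SiteGenotypeCall] = None
    pf_call: Optional[SiteGenotypeCall] = None
    switches: tuple[SwitchCall, ...] = ()  # maternal/paternal switch calls
    unit_length: int = PF_UNIT_LENGTH
    unit_span: tuple[int, int] = (PF_UNIT_START, PF_UNIT_END)


@dataclass(frozen=True)
class HypothesisCall:
    label: str
    rationale: tuple[str, ...]
    phenotype_prediction: str  # "polled" | "horned" | "unknown"
    warnings: tuple[str, ...] = ()


def _cluster_interval(cl: BreakpointCluster) -> tuple[int, int]:
    lo = min(cl.consensus_left, cl.consensus_right)
    hi = max(cl.consensus_left, cl.consensus_right)
    return lo, hi


def _corroborated_cnvs(e: EvidenceBundle, flank: int = 1000) -> list[CnvCall]:
    """CNV calls lying within the interval implied by a >=2-read cluster.

    Depth excursions without consistent split-read backing are treated
    as coverage noise, not rearrangements (copy-ratio changes of a real
    one-extra-copy event sit only ~2 sigma above sampling noise at
    ~20x, so raw threshold crossings fragment and false-positive).
    """
    out = []
    for cnv in e.cnv_calls:
        for cl in e.split_clusters:
            lo, hi = _cluster_interval(cl)
            if cnv.start <= hi + flank and cnv.end >= lo - flank:
                out.append(cnv)
                break
    return out


def _interval_mean_ratio(e: EvidenceBundle, lo: int, hi: int) -> Optional[float]:
    """Mean normalized depth over [lo, hi]; None if unassessable."""
    if e.track is None:
        return None
    ws = e.track.window_starts
    inside = (ws >= lo) & (ws + e.track.window - 1 <= hi)
    if inside.sum() < 3:
        return None
    return float(e.track.ratio[inside].mean())


def _depth_confirms(e: EvidenceBundle, lo: int, hi: int, direction: str) -> bool:
    """Copy-number confirmation of a cluster-implied interval.

    A >=2-read cluster already establishes the junction; the depth
    check vetoes a contradicting profile rather than re-proving the
    event.  With the track available, the mean ratio over the implied
    interval must lean at least one coverage-noise sd (~0.1 at 20x)
    toward the expected copy-number change: >=1.1 for a gain, <=0.9
    for a loss.  (The interval mean is the right estimator once the
    candidate interval is known - threshold-run CNV calls fragment at
    this coverage - but long-read coverage is lumpy, ~0.16 sd over
    tens of kb, so a midpoint boundary would veto real events.)
    Without a track, falls back to an overlapping threshold call.
    """
    if hi - lo + 1 < 1000:
        return False
    mean = _interval_mean_ratio(e, lo, hi)
    if mean is not None:
        return mean >= 1.1 if direction == "gain" else mean <= 0.9
    return any(
        c.direction == direction and c.start <= hi + 1000 and c.end >= lo - 1000
        for c in e.cnv_calls
    )


def _pf_cluster_present(e: EvidenceBundle, tol: int = 200) -> bool:
    """A tandem-duplication cluster spanning one full Friesian unit.

    The paper's variant confirmation rests on the split-read pattern as
    much as on the diagnostic sites, so a full-unit junction cluster
    counts as P_F presence even when the P_F2D read counts draw low.
    """
    for cl in e.split_clusters:
        if cl.signature != "TANDEM_DUP":
            continue
        lo, hi = _cluster_interval(cl)
        if abs((hi - lo + 1) - e.unit_length) <= tol:
            return True
    return False


def _pc_cluster_present(e: EvidenceBundle, tol: int = 50) -> bool:
    """A duplication-insertion cluster matching the Celtic junction."""
    for cl in e.split_clusters:
        if cl.signature != "TANDEM_DUP":
            continue
        if (
            abs(cl.consensus_left - (PC_DEL_START - 1)) <= tol
            and abs(cl.consensus_right - PC_DUP_SOURCE_START) <= tol
        ):
            return True
    return False


def _warnings(e: EvidenceBundle) -> tuple[str, ...]:
    w = []
    for cl in e.low_support_clusters:
        w.append(
            f"sub-threshold split cluster ({cl.signature}, support "
            f"{cl.support}) at ({cl.consensus_left}, {cl.consensus_right})"
        )
    corro = set(id(c) for c in _corroborated_cnvs(e))
    for cnv in e.cnv_calls:
        if id(cnv) not in corro:
            w.append(
                f"uncorroborated depth excursion {cnv.direction} "
                f"{cnv.start}-{cnv.end} (mean ratio {cnv.mean_ratio:.2f})"
            )
    return tuple(w)


def classify_hf(e: EvidenceBundle) -> HypothesisCall:
    """Classify offspring evidence from a P_F/P_F x p/p trio.

    Rule order: a detected P_F2D variant means ordinary transmission;
    otherwise a tandem-duplication cluster plus a sub-unit gain selects
    H1, a deletion cluster plus a loss selects H2, and a clean locus
    (no >=2-read cluster, no corroborated >=1 kb copy-number call)
    selects H3_OR_H4 - which are indistinguishable without a variant
    that differentiates the two copies.  Anything else is INCONSISTENT.
    """
    if e.pf_call is None:
        raise ValueError("classify_hf requires a P_F2D diagnostic call")
    rationale: list[str] = []
    warnings = _warnings(e)
    pf_diag = e.pf_call.dosage is not None and e.pf_call.present
    pf_cluster = _pf_cluster_present(e)
    if pf_diag or pf_cluster:
        evidence = " and ".join(
            s
            for s, ok in (
                ("P_F2D diagnostic reads", pf_diag),
                ("a full-unit tandem-duplication split cluster", pf_cluster),
            )
            if ok
        )
        rationale.append(f"P_F detected in the offspring ({evidence}): transmitted intact")
        return HypothesisCall("EXPECTED_TRANSMISSION", tuple(rationale), "polled", warnings)
    if e.pf_call.dosage is None:
        return HypothesisCall(
            "INCONSISTENT",
            ("diagnostic no-call at the P_F2D site (insufficient depth)",),
            "unknown",
            warnings,
        )
    rationale.append("P_F2D absent from the offspring")

    dup_clusters = [c for c in e.split_clusters if c.signature == "TANDEM_DUP"]
    del_clusters = [c for c in e.split_clusters if c.signature == "DEL"]
    corroborated = _corroborated_cnvs(e)

    for cl in dup_clusters:
        lo, hi = _cluster_interval(cl)
        span = hi - lo + 1
        if span < e.unit_length and _depth_confirms(e, lo, hi, "gain"):
            rationale.append(
                f"tandem-duplication split cluster implies a duplicated "
                f"residue of {span} bp (< {e.unit_length} bp unit), backed by "
                "a copy-number gain: deletion shorter than one unit"
            )
            return HypothesisCall("H1", tuple(rationale), "horned", warnings)
    for cl in del_clusters:
        lo, hi = _cluster_interval(cl)
        if _depth_confirms(e, lo, hi, "loss"):
            rationale.append(
                "deletion split cluster with a copy-number loss: more than "
                "one unit removed, including wild-type sequence"
            )
            return HypothesisCall("H2", tuple(rationale), "horned", warnings)
    if not e.split_clusters and not corroborated:
        rationale.append(
            "no split cluster supported by two or more reads and no "
            "corroborated copy-number call >= 1 kb: the locus is "
            "sequence-identical to wild type, so the paternal gamete lost "
            "exactly one unit (H3 and H4 are indistinguishable)"
        )
        return HypothesisCall("H3_OR_H4", tuple(rationale), "horned", warnings)
    return HypothesisCall(
        "INCONSISTENT",
        tuple(rationale) or ("evidence matches no hypothesis",),
        "unknown",
        warnings,
    )


def classify_fv(e: EvidenceBundle, dam_is_trans: bool = True) -> HypothesisCall:
    """Classify offspring evidence from a p/p x P_C/P_F(trans) trio.

    Exactly one variant present with no maternal switch: parental
    transmission.  Both absent with exactly one maternal switch between
    the Celtic span and the end of the Friesian unit: the
    allelic-crossover wild-type product.  Both present on the maternal
    side: the reciprocal cis fusion (phenotypically polled and easily
    mistaken for a homozygous-polled genotype).
    """
    if not dam_is_trans:
        raise ValueError("classify_fv requires a trans P_C/P_F dam")
    if e.pc_call is None or e.pf_call is None:
        raise ValueError("classify_fv requires P_C and P_F2D diagnostic calls")
    warnings = _warnings(e)
    pc_cluster = _pc_cluster_present(e)
    pf_cluster = _pf_cluster_present(e)
    pc_known = e.pc_call.dosage is not None or pc_cluster
    pf_known = e.pf_call.dosage is not None or pf_cluster
    if not (pc_known and pf_known):
        return HypothesisCall(
            "INCONSISTENT",
            ("diagnostic no-call (insufficient depth at a diagnostic site)",),
            "unknown",
            warnings,
        )
    pc = (e.pc_call.dosage is not None and e.pc_call.present) or pc_cluster
    pf = (e.pf_call.dosage is not None and e.pf_call.present) or pf_cluster
    maternal = [s for s in e.switches if s.parent == "dam"]
    # the switch interval (not its midpoint) is the primary localization;
    # accept it when it overlaps the window between the Celtic span and
    # the end of the Friesian unit (where the duplicated copy begins on
    # the P_F chromosome)
    in_window = [
        s
        for s in maternal
        if s.interval[0] <= e.unit_span[1] and s.interval[1] > PC_DEL_END
    ]
    if pc and pf:
        return HypothesisCall(
            "FV_CIS_FUSION",
            (
                "both P_C and P_F detected on the maternal haplotype: the "
                "crossover fused them in cis; the animal is polled and would "
                "be mistyped as homozygous polled by dosage-free tests",
            ),
            "polled",
            warnings,
        )
    if (pc or pf) and not maternal:
        which = "P_C" if pc else "P_F"
        return HypothesisCall(
            "FV_PARENTAL",
            (f"{which} transmitted unchanged; no maternal haplotype switch",),
            "polled",
            warnings,
        )
    if not pc and not pf and len(maternal) == 1 and len(in_window) == 1:
        s = in_window[0]
        return HypothesisCall(
            "FV_AHR_WILDTYPE",
            (
                "neither polled variant detected and exactly one maternal "
                f"haplotype switch localized to {s.interval[0]}-{s.interval[1]} "
                "bp, between the Celtic span and the end of the Friesian "
                "unit: the allelic crossover skipped both variants",
            ),
            "horned",
            warnings,
        )
    return HypothesisCall(
        "INCONSISTENT",
        (
            f"P_C present={pc}, P_F present={pf}, "
            f"maternal switches={len(maternal)}: no single-crossover "
            "explanation fits",
        ),
        "unknown",
        warnings,
    )


def enumerate_gametes(genotype: str, r: float = 0.0) -> dict[str, float]:
    """Gamete classes and probabilities for a parent genotype.

    Delegates to the diagnostics module's Mendelian model: a trans
    P_C/P_F parent yields wild-type and cis-fusion gametes each with
    probability r/2; homozygotes yield a single class (NAHR is a
    qualitative possibility without an assignable rate).
    """
    return gamete_distribution(genotype, r)
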