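"""In-silico analog of the diagnostic polled gene test.

The wet-lab test genotypes the Celtic variant by the presence of its
212 bp insertion and the Friesian variant by the presence of the 2 bp
TG deletion (P_F2D) carried by the duplicated copy, with zygosity read
off the ratio of reference to variant PCR signal: a P_F/P_F animal
yields similar peak heights (every chromosome carries one reference
unit and one deleted copy, 1:1), while a P_F/p heterozygote yields
roughly double-height reference signal (two reference units against
one deleted copy, 2:1).  Here PCR peak heights map to read counts over
the diagnostic sites and the zygosity call is the maximum binomial
likelihood over the expected variant fractions (0.02 and 0.98 instead
of 0 and 1, to tolerate sequencing error).

The module also provides Mendelian expectation and genetic-map
calculators: with ~200 kb between the Celtic and Friesian variants and
1.085 Mb per cM in female cattle, about two oocytes per 1,000 are
expected to recombine between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import binom

from .locus_model import (
    PC_DEL_END,
    PC_DEL_START,
    PC_DUP_SOURCE_START,
    PF_UNIT_START,
)
from .splitread_scan import AlignmentSegment

__all__ = [
    "DiagnosticSiteCounts",
    "SiteGenotypeCall",
    "PolledGenotypeCall",
    "GeneticMapParams",
    "GameteRate",
    "count_pc_site",
    "count_pf2d_site",
    "genotype_pc",
    "genotype_pf",
    "combine_calls",
    "gamete_distribution",
    "expected_offspring",
    "recombinant_gamete_rate",
    "genotype_summary",
    "PF2D_REF_START",
    "PF2D_REF_END",
]

# Reference coordinates of the TG pair deleted in the duplicated copy.
PF2D_REF_START = 2_629_153
PF2D_REF_END = 2_629_154

# Celtic junction as seen in reference-space alignments: reads carrying
# the insertion rewind from the base before the deleted tract back to
# the start of the 212 bp template.
PC_JUNCTION_LEFT = PC_DEL_START - 1
PC_JUNCTION_RIGHT = PC_DUP_SOURCE_START

DEFAULT_MIN_DEPTH = 10
_ERR = 0.02  # residual variant fraction expected from sequencing error


@dataclass(frozen=True)
class DiagnosticSiteCounts:
    site: str  # "P_C_site" | "P_F2D_site"
    ref_count: int
    var_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.var_count < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.ref_count + self.var_count


@dataclass(frozen=True)
class SiteGenotypeCall:
    """Dosage call at one diagnostic site."""

    site: str
    dosage: Optional[int]  # variant copies: 0/1/2, None = no-call
    confidence: float
    counts: DiagnosticSiteCounts

    @property
    def present(self) -> bool:
        return self.dosage is not None and self.dosage >= 1


@dataclass(frozen=True)
class PolledGenotypeCall:
    genotype: str  # p/p, P_C/p, P_C/P_C, P_F/p, P_F/P_F, P_C/P_F
    confidence: float
    phenotype_prediction: str  # "polled" | "horned"


# ---------------------------------------------------------------------------
# read counting over the diagnostic sites
# ---------------------------------------------------------------------------


def _cigar_has_deletion_at(
    seg: AlignmentSegment, ref_start: int, ref_end: int, min_len: int
) -> Optional[bool]:
    """True/False: a >=min_len deletion overlaps [ref_start, ref_end];
    None when the segment's CIGAR does not fully traverse the interval.
    """
    if seg.cigar is None:
        return None
    if seg.ref_start > ref_start - 1 or seg.ref_end < ref_end + 1:
        return None
    pos = seg.ref_start
    for op, n in seg.cigar:
        if op in ("M", "=", "X"):
            pos += n
        elif op == "D":
            if n >= min_len and pos <= ref_end and pos + n - 1 >= ref_start:
                return True
            pos += n
        # I consumes no reference
    return False


def count_pf2d_site(
    read_groups: Mapping[str, list[AlignmentSegment]],
    margin: int = 10,
) -> DiagnosticSiteCounts:
    """Count reads supporting the 2 bp P_F2D deletion vs the reference.

    Counted per site traversal: a segment traversing the site with a
    >=2 bp deletion in its alignment supports the variant; a segment
    crossing the site plus ``margin`` anchor bases without such a
    deletion supports the reference.  (A single long read spanning both
    copies of the Friesian unit legitimately contributes one traversal
    per copy, matching the per-chromosome-unit expectation the zygosity
    ratios are built on.)
    """
    ref_n = 0
    var_n = 0
    for segs in read_groups.values():
        for seg in segs:
            has = _cigar_has_deletion_at(
                seg, PF2D_REF_START, PF2D_REF_END, min_len=2
            )
            if has is True:
                var_n += 1
            elif has is False and (
                seg.ref_start <= PF2D_REF_START - margin
                and seg.ref_end >= PF2D_REF_END + margin
            ):
                ref_n += 1
    return DiagnosticSiteCounts("P_F2D_site", ref_n, var_n)


def count_pc_site(
    read_groups: Mapping[str, list[AlignmentSegment]],
    tol: int = 30,
    margin: int = 10,
) -> DiagnosticSiteCounts:
    """Count reads supporting the Celtic insertion junction vs reference.

    Variant support: two query-adjacent segments whose reference
    coordinates rewind from ~(P_C deletion start - 1) back to the 212 bp
    template start.  Reference support: a single segment spanning the
    deleted tract with anchor on both sides and no such junction.
    """
    ref_n = 0
    var_n = 0
    for segs in read_groups.values():
        has_junction = False
        for a, b in zip(segs, segs[1:]):
            if (
                abs(a.ref_end - PC_JUNCTION_LEFT) <= tol
                and abs(b.ref_start - PC_JUNCTION_RIGHT) <= tol
            ):
                has_junction = True
                break
        if has_junction:
            var_n += 1
            continue
        for seg in segs:
            if (
                seg.ref_start <= PC_DEL_START - margin
                and seg.ref_end >= PC_DEL_END + margin
            ):
                ref_n += 1
                break
    return DiagnosticSiteCounts("P_C_site", ref_n, var_n)


# ---------------------------------------------------------------------------
# zygosity calls
# ---------------------------------------------------------------------------


def _ml_call(
    counts: DiagnosticSiteCounts,
    fractions: Mapping[int, float],
    min_depth: int,
) -> SiteGenotypeCall:
    n = counts.total
    if n < min_depth:
        return SiteGenotypeCall(counts.site, None, 0.0, counts)
    k = counts.var_count
    liks = {d: binom.pmf(k, n, f) for d, f in fractions.items()}
    total = sum(liks.values())
    best = max(liks, key=liks.get)
    conf = liks[best] / total if total > 0 else 0.0
    return SiteGenotypeCall(counts.site, best, float(conf), counts)


def genotype_pc(
    counts: DiagnosticSiteCounts, min_depth: int = DEFAULT_MIN_DEPTH
) -> SiteGenotypeCall:
    """Celtic-site dosage: variant fractions ~0, 0.5, 1 for p/p, P_C/p,
    P_C/P_C."""
    return _ml_call(counts, {0: _ERR, 1: 0.5, 2: 1 - _ERR}, min_depth)


def genotype_pf(
    counts: DiagnosticSiteCounts, min_depth: int = DEFAULT_MIN_DEPTH
) -> SiteGenotypeCall:
    """Friesian-site dosage from the P_F2D ref:variant ratio.

    Expected ratios: p/p 1:0; P_F/p 2:1 (two reference units, one
    deleted copy - the "double height" heterozygote signal); P_F/P_F
    1:1 ("similar peak heights").
    """
    return _ml_call(counts, {0: _ERR, 1: 1 / 3, 2: 0.5}, min_depth)


_GENOTYPE_LABELS = {
    (0, 0): "p/p",
    (1, 0): "P_C/p",
    (2, 0): "P_C/P_C",
    (0, 1): "P_F/p",
    (0, 2): "P_F/P_F",
    (1, 1): "P_C/P_F",
}


def combine_calls(
    pc: SiteGenotypeCall, pf: SiteGenotypeCall
) -> Optional[PolledGenotypeCall]:
    """Join the two site calls into a locus genotype; None on no-call."""
    if pc.dosage is None or pf.dosage is None:
        return None
    key = (pc.dosage, pf.dosage)
    if key not in _GENOTYPE_LABELS:
        return PolledGenotypeCall("P_C/P_F", min(pc.confidence, pf.confidence), "polled")
    label = _GENOTYPE_LABELS[key]
    phenotype = "horned" if label == "p/p" else "polled"
    return PolledGenotypeCall(label, min(pc.confidence, pf.confidence), phenotype)


# ---------------------------------------------------------------------------
# Mendelian expectation and genetic-map calculators
# ---------------------------------------------------------------------------

_VALID_GENOTYPES = {"p/p", "P_C/p", "P_C/P_C", "P_F/p", "P_F/P_F", "P_C/P_F"}


def gamete_distribution(genotype: str, r: float = 0.0) -> dict[str, float]:
    """Gamete classes and probabilities for one parent.

    For a trans P_C/P_F parent a crossover between the two variant
    positions (probability r) produces, with equal likelihood, a
    wild-type gamete skipping both variants or a cis-fusion gamete
    carrying both.  NAHR in duplication homozygotes has no assignable
    rate and is not part of this expectation.
    """
    if genotype not in _VALID_GENOTYPES:
        raise ValueError(f"invalid genotype {genotype!r}")
    if not 0 <= r <= 0.5:
        raise ValueError("recombination fraction must be within [0, 0.5]")
    if genotype == "P_C/P_F":
        return {
            "P_C": (1 - r) / 2,
            "P_F": (1 - r) / 2,
            "p": r / 2,
            "P_C+P_F": r / 2,
        }
    a, b = genotype.split("/")
    if a == b:
        return {a: 1.0}
    return {a: 0.5, b: 0.5}


_POLLED_ALLELES = {"P_C", "P_F", "P_C+P_F"}


def expected_offspring(
    g_sire: str, g_dam: str, r: float = 0.0
) -> tuple[dict[str, float], dict[str, float]]:
    """Offspring genotype and phenotype distributions for a mating.

    Returns (genotype probabilities, phenotype probabilities); gamete
    distributions combine multiplicatively and polledness is dominant.
    """
    sire_g = gamete_distribution(g_sire, r)
    dam_g = gamete_distribution(g_dam, r)
    geno: dict[str, float] = {}
    pheno = {"polled": 0.0, "horned": 0.0}
    for ga, pa in sire_g.items():
        for gb, pb in dam_g.items():
            label = "/".join(sorted([ga, gb]))
            geno[label] = geno.get(label, 0.0) + pa * pb
            polled = ga in _POLLED_ALLELES or gb in _POLLED_ALLELES
            pheno["polled" if polled else "horned"] += pa * pb
    return geno, pheno


@dataclass(frozen=True)
class GeneticMapParams:
    """Female-cattle genetic map scale: Mb of physical distance per cM."""

    mb_per_cm: float = 1.085

    def __post_init__(self) -> None:
        if self.mb_per_cm <= 0:
            raise ValueError("mb_per_cm must be > 0")


@dataclass(frozen=True)
class GameteRate:
    centimorgan: float
    fraction: float
    per_1000: int


def recombinant_gamete_rate(
    distance_bp: float, m: GeneticMapParams = GeneticMapParams()
) -> GameteRate:
    """Expected recombinant-gamete rate for a physical distance.

    Uses the linear small-distance approximation cM/100 = recombination
    fraction; 200 kb at 1.085 Mb/cM gives ~0.00184, i.e. two recombinant
    oocytes per 1,000.
    """
    if distance_bp < 0:
        raise ValueError("distance must be >= 0")
    cm = distance_bp / (m.mb_per_cm * 1e6)
    fraction = cm / 100.0
    return GameteRate(cm, fraction, int(round(1000 * fraction)))


def genotype_summary(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-class percentages of a genotype count table."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be > 0")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    return {k: 100.0 * v / total for k, v in counts.items()}
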