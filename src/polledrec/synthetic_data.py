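"""Synthetic study data: reference segment, trio designs, reads, panels.

The module generates everything the real study's deposited data would
provide, at desk scale: a pseudo-random reference segment standing in
for BTA1 2.42-2.73 Mb, diploid trio members carrying the POLLED
alleles, nanopore-like long reads with exact truth provenance, split
alignments projected analytically from that provenance (no external
aligner), and a 50K-style SNP panel with phased parental truth.

Reads are projected to reference space through each haplotype's block
coordinate map, so a read spanning the tandem-duplication junction
yields two alignment segments whose reference coordinates jump
backward - the split-read signature the detection modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .locus_model import (
    FV_AHR_BREAKPOINT,
    PC_DEL_END,
    PF_UNIT_END,
    PF_UNIT_START,
    SEGMENT_LENGTH,
    SEGMENT_START,
    AlleleSpec,
    Diplotype,
    GenomeSegment,
    Haplotype,
    ahr_product,
    allele_spec,
    build_haplotype,
    delete_hap_interval,
    nahr_product,
)
from .splitread_scan import AlignmentSegment
from .trio_phase import PhasedParent, TrioGenotypes

__all__ = [
    "ReadSimParams",
    "SimulatedRead",
    "GameteEvent",
    "Transmission",
    "TrioDesign",
    "PanelMarker",
    "PanelSim",
    "ReadAlignment",
    "GenerationError",
    "DesignError",
    "COVERAGE_PRESETS",
    "N50_PRESETS",
    "SCENARIOS",
    "make_reference",
    "design_trio",
    "simulate_reads",
    "project_alignments",
    "simulate_snp_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Reference generation could not satisfy its constraints."""


class DesignError(ValueError):
    """A trio scenario was requested with inconsistent parameters."""


# Mean alignment coverages of the six sequenced animals (fold) and read
# length N50 (bp); used as simulation presets only.
COVERAGE_PRESETS = {
    "HF": {"sire": 22.98, "dam": 9.68, "offspring": 22.50},
    "FV": {"sire": 7.24, "dam": 12.01, "offspring": 8.80},
}
N50_PRESETS = {
    "HF": {"sire": 7786, "dam": 13986, "offspring": 3957},
    "FV": {"sire": 8379, "dam": 10001, "offspring": 14093},
}

SCENARIOS = (
    "HF_expected",
    "HF_H1",
    "HF_H2",
    "HF_H3H4",
    "FV_parental",
    "FV_ahr_wildtype",
    "FV_cis_fusion",
)


@dataclass(frozen=True)
class ReadSimParams:
    """Long-read simulation parameters.

    Lengths are lognormal (defaults give a read-length N50 of ~11 kb,
    inside the 8-14 kb range of the sequenced animals); error rates are
    ONT-like per-base probabilities.  Inserted bases duplicate the
    template base (homopolymer-style, the dominant nanopore indel mode).
    """

    coverage: float = 20.0
    length_log_mu: float = 9.0
    length_log_sigma: float = 0.55
    mismatch_rate: float = 0.02
    ins_rate: float = 0.01
    del_rate: float = 0.01
    min_length: int = 300
    chimera_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for r in (self.mismatch_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must be within [0, 0.2]")
        if self.chimera_rate != 0.0:
            raise NotImplementedError("chimeric-read simulation is not implemented")


@dataclass(frozen=True)
class SimulatedRead:
    """A read plus its exact provenance (haplotype interval and noise)."""

    read_id: str
    sequence: str
    quality: str
    individual_id: str
    hap_index: int
    hap_start: int
    hap_end: int
    strand: str
    del_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ins_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass(frozen=True)
class GameteEvent:
    parent: str  # "sire" | "dam"
    kind: str  # "none" | "ahr_crossover" | "nahr_crossover" | "deletion"
    position: int = 0  # reference bp for AHR; unit offset / hap coords otherwise


@dataclass(frozen=True)
class Transmission:
    """Which parental haplotype the transmitted gamete follows.

    ``crossovers`` are reference positions: markers at pos <= crossover
    come from the current haplotype, markers beyond it from the other.
    """

    start_hap: int
    crossovers: tuple[int, ...] = ()

    def hap_at(self, pos: int) -> int:
        flips = sum(1 for c in self.crossovers if pos > c)
        return (self.start_hap + flips) % 2


@dataclass(frozen=True)
class TrioDesign:
    scenario: str
    sire: Diplotype
    dam: Diplotype
    offspring: Diplotype
    gamete_events: tuple[GameteEvent, ...]
    transmissions: dict  # parent -> Transmission
    expected_label: str
    phenotype_truth: str  # "polled" | "horned"


@dataclass(frozen=True)
class PanelMarker:
    ref_pos: int
    alleles: tuple[str, str] = ("A", "B")
    b_freq: float = 0.5


@dataclass(frozen=True)
class PanelSim:
    """A simulated 50K-style trio genotype table plus phased truth."""

    markers: tuple[PanelMarker, ...]
    genotypes: TrioGenotypes
    sire_phase: PhasedParent
    dam_phase: PhasedParent
    truth_paternal_hap: np.ndarray  # transmitted sire haplotype index per marker
    truth_maternal_hap: np.ndarray


@dataclass(frozen=True)
class ReadAlignment:
    """Projected alignment of one read: >=1 reference-space segments."""

    read: SimulatedRead
    segments: tuple[AlignmentSegment, ...]


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def _has_duplicate_kmer(arr: np.ndarray, k: int) -> bool:
    if len(arr) <= k:
        return False
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    voids = np.ascontiguousarray(win).view(f"V{k}").ravel()
    return len(np.unique(voids)) < len(voids)


def make_reference(
    length: int = SEGMENT_LENGTH,
    seed: int = 0,
    gc_fraction: float = 0.42,
    max_exact_repeat: int = 50,
    start: int = SEGMENT_START,
    name: str = "1",
) -> GenomeSegment:
    """Pseudo-random reference segment free of long exact repeats.

    Rejection-samples until no exact duplicated ``max_exact_repeat``-mer
    exists, so the only long duplication in any simulated genome is the
    engineered one.  The bases at the Friesian unit start (T) and at the
    P_F2D site (TG) are pinned so the documented copy-specific edits are
    guaranteed to be visible against the reference.
    """
    if max_exact_repeat < 20:
        raise GenerationError("max_exact_repeat must be >= 20")
    if not 0 < gc_fraction < 1:
        raise GenerationError("gc_fraction must be in (0, 1)")
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    ss = np.random.SeedSequence([seed, 0x9E3779B9])
    for attempt, child in enumerate(ss.spawn(10)):
        rng = np.random.default_rng(child)
        arr = _BASES[rng.choice(4, size=length, p=p)]
        end = start + length - 1
        # pin the diagnostic motif bases when the locus is in range
        for pos, base in ((PF_UNIT_START, b"T"), (2_629_153, b"T"), (2_629_154, b"G")):
            if start <= pos <= end:
                arr[pos - start] = base[0]
        if not _has_duplicate_kmer(arr, max_exact_repeat):
            return GenomeSegment(name, start, end, arr.tobytes().decode("ascii"))
    raise GenerationError(
        f"could not generate a repeat-free sequence of length {length} "
        f"(max_exact_repeat={max_exact_repeat}) in 10 attempts"
    )


# ---------------------------------------------------------------------------
# trio scenarios
# ---------------------------------------------------------------------------

_EXPECTED_LABELS = {
    "HF_expected": "EXPECTED_TRANSMISSION",
    "HF_H1": "H1",
    "HF_H2": "H2",
    "HF_H3H4": "H3_OR_H4",
    "FV_parental": "FV_PARENTAL",
    "FV_ahr_wildtype": "FV_AHR_WILDTYPE",
    "FV_cis_fusion": "FV_CIS_FUSION",
}


def design_trio(
    scenario: str,
    segment: GenomeSegment,
    *,
    nahr_offset: int = 40_000,
    ahr_breakpoint: int = FV_AHR_BREAKPOINT,
    h1_deletion_length: int = 40_000,
    h2_extra_deleted: int = 10_000,
    fv_transmitted: str = "P_C",
) -> TrioDesign:
    """Construct the diplotypes of a named trio scenario.

    HF scenarios: sire P_F/P_F, dam p/p; the offspring's paternal
    haplotype is the designed germline product.  FV scenarios: sire p/p,
    dam P_C/P_F in trans; the offspring's maternal haplotype is either
    parental or an allelic-crossover product.
    """
    if scenario not in SCENARIOS:
        raise DesignError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")

    hap_p = build_haplotype(segment, allele_spec("p"))

    events: list[GameteEvent] = []
    transmissions = {"sire": Transmission(0), "dam": Transmission(0)}

    if scenario.startswith("HF"):
        hap_pf = build_haplotype(segment, allele_spec("P_F"))
        junction = hap_pf.ref_to_hap(PF_UNIT_END, copy_index=0)
        copy1_len = PF_UNIT_END - PF_UNIT_START + 1 - 2  # 80,126 bp
        if scenario == "HF_expected":
            paternal = hap_pf
            events.append(GameteEvent("sire", "none"))
        elif scenario == "HF_H1":
            if not 100 <= h1_deletion_length < copy1_len:
                raise DesignError("H1 deletion must be shorter than the duplicated copy")
            half = h1_deletion_length // 2
            lo = junction - half + 1
            hi = lo + h1_deletion_length - 1
            paternal = delete_hap_interval(hap_pf, lo, hi, "P_F_H1del")
            events.append(GameteEvent("sire", "deletion", lo))
        elif scenario == "HF_H2":
            if h2_extra_deleted < 2 or h2_extra_deleted > 100_000:
                raise DesignError("H2 extra deletion out of range")
            pre = h2_extra_deleted // 2
            post = h2_extra_deleted - pre
            lo = junction - pre + 1
            hi = junction + copy1_len + post
            paternal = delete_hap_interval(hap_pf, lo, hi, "P_F_H2del")
            events.append(GameteEvent("sire", "deletion", lo))
        else:  # HF_H3H4
            if nahr_offset <= 39:
                raise DesignError(
                    "an NAHR offset <= 39 would retain diagnostic variants; "
                    "H3/H4 requires a crossover beyond the copy-specific edits"
                )
            paternal = nahr_product(hap_pf, nahr_offset)
            events.append(GameteEvent("sire", "nahr_crossover", nahr_offset))
        sire = Diplotype("HF_sire", "sire", (hap_pf, hap_pf))
        dam = Diplotype("HF_dam", "dam", (hap_p, hap_p))
        offspring = Diplotype("HF_offspring", "offspring", (paternal, hap_p))
        phenotype = "polled" if scenario == "HF_expected" else "horned"
    else:
        hap_pc = build_haplotype(segment, allele_spec("P_C"))
        hap_pf = build_haplotype(segment, allele_spec("P_F"))
        dam_haps = (hap_pc, hap_pf)  # trans configuration
        if scenario == "FV_parental":
            if fv_transmitted not in {"P_C", "P_F"}:
                raise DesignError("fv_transmitted must be P_C or P_F")
            idx = 0 if fv_transmitted == "P_C" else 1
            maternal = dam_haps[idx]
            transmissions["dam"] = Transmission(idx)
            events.append(GameteEvent("dam", "none"))
            phenotype = "polled"
        else:
            if not PC_DEL_END < ahr_breakpoint <= PF_UNIT_END:
                raise DesignError(
                    "the AHR breakpoint must fall between the Celtic span and "
                    "the end of the Friesian unit to skip (or fuse) both variants"
                )
            if scenario == "FV_ahr_wildtype":
                maternal = ahr_product(hap_pf, hap_pc, ahr_breakpoint)
                transmissions["dam"] = Transmission(1, (ahr_breakpoint,))
                phenotype = "horned"
            else:  # FV_cis_fusion: the reciprocal exchange product
                maternal = ahr_product(hap_pc, hap_pf, ahr_breakpoint)
                transmissions["dam"] = Transmission(0, (ahr_breakpoint,))
                phenotype = "polled"
            events.append(GameteEvent("dam", "ahr_crossover", ahr_breakpoint))
        sire = Diplotype("FV_sire", "sire", (hap_p, hap_p))
        dam = Diplotype("FV_dam", "dam", dam_haps)
        offspring = Diplotype("FV_offspring", "offspring", (hap_p, maternal))

    return TrioDesign(
        scenario=scenario,
        sire=sire,
        dam=dam,
        offspring=offspring,
        gamete_events=tuple(events),
        transmissions=transmissions,
        expected_label=_EXPECTED_LABELS[scenario],
        phenotype_truth=phenotype,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _noisy_read(
    hap_arr: np.ndarray, start0: int, length: int, params: ReadSimParams, rng
) -> tuple[str, np.ndarray, np.ndarray]:
    """Apply substitution/indel noise to hap_arr[start0:start0+length].

    Returns (sequence, deleted hap positions, insertion hap positions),
    positions 1-based on the haplotype.
    """
    sub = hap_arr[start0 : start0 + length].copy()
    if params.mismatch_rate + params.ins_rate + params.del_rate == 0:
        return sub.tobytes().decode("ascii"), np.empty(0, np.int64), np.empty(0, np.int64)
    u = rng.random(length)
    mm, dr, ir = params.mismatch_rate, params.del_rate, params.ins_rate
    sub_mask = u < mm
    del_mask = (u >= mm) & (u < mm + dr)
    ins_mask = (u >= mm + dr) & (u < mm + dr + ir)
    n_sub = int(sub_mask.sum())
    if n_sub:
        # replace with a uniformly chosen different base
        idx = np.searchsorted(_BASES, sub[sub_mask])  # _BASES is sorted (ACGT)
        sub[sub_mask] = _BASES[(idx + rng.integers(1, 4, size=n_sub)) % 4]
    counts = np.ones(length, dtype=np.int64)
    counts[del_mask] = 0
    counts[ins_mask] = 2  # duplicated template base
    seq = np.repeat(sub, counts)
    del_pos = np.flatnonzero(del_mask) + start0 + 1
    ins_pos = np.flatnonzero(ins_mask) + start0 + 1
    return seq.tobytes().decode("ascii"), del_pos, ins_pos


def simulate_reads(d: Diplotype, params: ReadSimParams) -> list[SimulatedRead]:
    """Draw reads uniformly from both haplotypes to the target coverage.

    Each haplotype receives coverage/2 of its own length in bases, so a
    diploid wild-type individual at 20x yields ~20 x segment-length
    total bases and the reference-space depth over a heterozygous
    duplication is 1.5x the regional baseline (2.0x when homozygous).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EED]))
    reads: list[SimulatedRead] = []
    serial = 0
    for hap_index, hap in enumerate(d.haplotypes):
        hap_arr = np.frombuffer(hap.sequence.encode("ascii"), dtype=np.uint8)
        hap_len = len(hap_arr)
        target = params.coverage / 2.0 * hap_len
        emitted = 0
        while emitted < target:
            raw = int(rng.lognormal(params.length_log_mu, params.length_log_sigma))
            length = max(params.min_length, min(raw, hap_len))
            start0 = int(rng.integers(0, hap_len))  # 0-based start
            length = min(length, hap_len - start0)
            strand = "+" if rng.random() < 0.5 else "-"
            seq, del_pos, ins_pos = _noisy_read(hap_arr, start0, length, params, rng)
            if strand == "-":
                out_seq = seq.translate(_RC)[::-1]
            else:
                out_seq = seq
            read = SimulatedRead(
                read_id=f"{d.individual_id}_h{hap_index}_r{serial:06d}",
                sequence=out_seq,
                quality="5" * len(out_seq),  # constant Q20 placeholder
                individual_id=d.individual_id,
                hap_index=hap_index,
                hap_start=start0 + 1,
                hap_end=start0 + length,
                strand=strand,
                del_positions=del_pos,
                ins_positions=ins_pos,
            )
            reads.append(read)
            emitted += length
            serial += 1
    return reads


_RC = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# analytic alignment projection
# ---------------------------------------------------------------------------


def _merge_cigar(ops: list[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return tuple(out)


def _project_read(
    read: SimulatedRead, hap: Haplotype, join_tol: int, mapq: int
) -> tuple[AlignmentSegment, ...]:
    s, e = read.hap_start, read.hap_end
    blocks = hap.slice_blocks(s, e)
    dels = read.del_positions
    inss = read.ins_positions
    qlen = (e - s + 1) - len(dels) + len(inss)

    def qpos(t: int) -> int:
        # query index (1-based, original read orientation) of hap position t
        return (
            (t - s + 1)
            - int(np.searchsorted(dels, t))
            + int(np.searchsorted(inss, t))
        )

    # group mapped blocks into reference-collinear runs
    runs: list[list] = []  # each: list of ("map", lo, hi, rlo) / ("I", n) / ("D", n)
    cur: list = []
    last_ref_end: Optional[int] = None
    for b in blocks:
        lo = b.hap_start + (s - 1)
        hi = b.hap_end + (s - 1)
        if b.inserted:
            ln = hi - lo + 1
            if cur and ln <= join_tol:
                cur.append(("I", ln, lo, hi))
            else:
                if cur:
                    runs.append(cur)
                cur = []
                last_ref_end = None
            continue
        if cur and last_ref_end is not None:
            gap = b.ref_start - last_ref_end - 1
            if 0 <= gap <= join_tol:
                if gap:
                    cur.append(("D", gap, 0, 0))
            else:
                runs.append(cur)
                cur = []
        cur.append(("map", lo, hi, b.ref_start))
        last_ref_end = b.ref_end
    if cur:
        runs.append(cur)

    segments: list[AlignmentSegment] = []
    for run in runs:
        mapped = [x for x in run if x[0] == "map"]
        ref_start = mapped[0][3]
        ref_end = mapped[-1][3] + (mapped[-1][2] - mapped[-1][1])
        cigar: list[tuple[str, int]] = []
        for kind, a, b_, _r in run:
            if kind == "D":
                cigar.append(("D", a))
            elif kind == "I":
                cigar.append(("I", a))
            else:
                lo, hi = a, b_
                # weave read-level noise ops through the mapped stretch
                di = np.searchsorted(dels, [lo, hi + 1])
                ii = np.searchsorted(inss, [lo, hi + 1])
                events = sorted(
                    [(int(p), "D") for p in dels[di[0] : di[1]]]
                    + [(int(p), "I") for p in inss[ii[0] : ii[1]]]
                )
                t = lo
                for p, kind2 in events:
                    if kind2 == "D":
                        cigar.append(("M", p - t))
                        cigar.append(("D", 1))
                        t = p + 1
                    else:
                        cigar.append(("M", p - t + 1))
                        cigar.append(("I", 1))
                        t = p + 1
                cigar.append(("M", hi - t + 1))
        first_lo = mapped[0][1]
        read_start = qpos(first_lo) if first_lo > s else 1
        merged = list(_merge_cigar(cigar))
        # alignments cannot begin or end with D (shift the reference
        # bound instead) or with I (those bases become soft clip)
        while merged and merged[0][0] in "DI":
            op, n = merged.pop(0)
            if op == "D":
                ref_start += n
            else:
                read_start += n
        while merged and merged[-1][0] in "DI":
            op, n = merged.pop()
            if op == "D":
                ref_end -= n
        if not merged or ref_end < ref_start:
            continue
        qc = sum(n for op, n in merged if op in ("M", "I"))
        read_end = read_start + qc - 1
        if read_end > qlen or read_start < 1:
            continue  # degenerate edge case after heavy edge noise
        segments.append(
            AlignmentSegment(
                read_id=read.read_id,
                ref_start=ref_start,
                ref_end=ref_end,
                read_start=read_start,
                read_end=read_end,
                strand=read.strand,
                mapq=mapq,
                is_supplementary=False,
                cigar=tuple(merged),
                query_length=qlen,
            )
        )
    if not segments:
        return ()
    primary = max(range(len(segments)), key=lambda i: segments[i].read_end - segments[i].read_start)
    out = []
    for i, seg in enumerate(segments):
        out.append(seg if i == primary else seg.as_supplementary())
    return tuple(out)


def project_alignments(
    reads: Iterable[SimulatedRead],
    d: Diplotype,
    join_tol: int = 50,
    mapq: int = 60,
) -> list[ReadAlignment]:
    """Project reads to reference space through their source coord_map.

    A read spanning a tandem junction decomposes into two segments whose
    reference coordinates rewind; a read on a recombinant wild-type
    haplotype projects to a single contiguous segment.  Requires truth
    provenance - externally aligned real reads are imported via
    :mod:`polledrec.io` instead.
    """
    out: list[ReadAlignment] = []
    for read in reads:
        if read.individual_id != d.individual_id:
            raise ValueError(
                f"read {read.read_id} does not belong to {d.individual_id}"
            )
        hap = d.haplotypes[read.hap_index]
        segs = _project_read(read, hap, join_tol, mapq)
        if segs:
            out.append(ReadAlignment(read, segs))
    return out


# ---------------------------------------------------------------------------
# SNP panel simulation
# ---------------------------------------------------------------------------


def simulate_snp_panel(
    n_markers: int,
    region: tuple[int, int],
    trio: TrioDesign,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.9),
    genotype_error_rate: float = 0.0,
) -> PanelSim:
    """Simulate a biallelic marker panel over ``region`` for the trio.

    Parental haplotype alleles are drawn from per-marker population
    B-allele frequencies; offspring genotypes follow the designed gamete
    transmissions (crossovers flip the transmitted haplotype).
    """
    if n_markers < 10:
        raise ValueError("n_markers must be >= 10")
    seg = trio.sire.haplotypes[0].segment
    if seg is not None and not (seg.start <= region[0] <= region[1] <= seg.end):
        raise ValueError(f"region {region} outside segment [{seg.start}, {seg.end}]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x50A7]))
    positions = np.sort(
        rng.choice(np.arange(region[0], region[1] + 1), size=n_markers, replace=False)
    )
    freqs = rng.uniform(maf_range[0], maf_range[1], size=n_markers)
    # haplotype allele matrices: rows = (sire h0, sire h1, dam h0, dam h1)
    hap_alleles = (rng.random((4, n_markers)) < freqs).astype(np.int8)  # 1 == B

    t_sire = trio.transmissions["sire"]
    t_dam = trio.transmissions["dam"]
    pat_idx = np.array([t_sire.hap_at(int(p)) for p in positions], dtype=np.int8)
    mat_idx = np.array([t_dam.hap_at(int(p)) for p in positions], dtype=np.int8)
    paternal = hap_alleles[pat_idx, np.arange(n_markers)]
    maternal = hap_alleles[2 + mat_idx, np.arange(n_markers)]

    def geno(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.empty(n_markers, dtype="<U2")
        letters = np.array(["A", "B"])
        for i in range(n_markers):
            pair = sorted([letters[a[i]], letters[b[i]]])
            out[i] = "".join(pair)
        return out

    sire_g = geno(hap_alleles[0], hap_alleles[1])
    dam_g = geno(hap_alleles[2], hap_alleles[3])
    off_g = geno(paternal, maternal)

    if genotype_error_rate > 0:
        for g, freq_arr in ((sire_g, freqs), (dam_g, freqs), (off_g, freqs)):
            err = rng.random(n_markers) < genotype_error_rate
            for i in np.flatnonzero(err):
                g[i] = rng.choice(["AA", "AB", "BB"])

    letters = np.array(["A", "B"])
    genotypes = TrioGenotypes(
        positions=positions.astype(np.int64),
        sire=sire_g,
        dam=dam_g,
        offspring=off_g,
    )
    sire_phase = PhasedParent(
        "sire", (letters[hap_alleles[0]], letters[hap_alleles[1]])
    )
    dam_phase = PhasedParent(
        "dam", (letters[hap_alleles[2]], letters[hap_alleles[3]])
    )
    markers = tuple(
        PanelMarker(int(p), ("A", "B"), float(f)) for p, f in zip(positions, freqs)
    )
    return PanelSim(
        markers=markers,
        genotypes=genotypes,
        sire_phase=sire_phase,
        dam_phase=dam_phase,
        truth_paternal_hap=pat_idx.astype(np.int64),
        truth_maternal_hap=mat_idx.astype(np.int64),
    )
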