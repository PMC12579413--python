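"""Standard-format I/O: FASTA, FASTQ, SAM, TSV, BED/bedGraph, VCF.

SAM is the canonical alignment interchange (plain text, writable
without external tools); BAM is supported on read through pysam.
Writers stage output through a temporary file and rename atomically so
failed runs leave no partial files.  Query coordinates on alignment
segments are kept in reference-forward orientation throughout.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depth_scan import CnvCall, DepthTrack
from .locus_model import GenomeSegment
from .splitread_scan import AlignmentSegment, BreakpointCluster
from .synthetic_data import PanelSim, ReadAlignment, SimulatedRead
from .trio_phase import PhasedParent, SwitchCall, TrioGenotypes

__all__ = [
    "PipelineConfig",
    "write_fasta",
    "read_fasta_segment",
    "write_fastq",
    "read_fastq",
    "write_sam",
    "segments_from_sam",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_parent_phase_tsv",
    "read_parent_phase_tsv",
    "write_clusters_tsv",
    "write_clusters_vcf",
    "write_track_bedgraph",
    "write_cnv_bed",
    "write_switches_tsv",
    "write_read_truth_tsv",
    "load_config",
    "config_hash",
]

_RC = str.maketrans("ACGT", "TGCA")


class _AtomicWriter:
    """Write to ``path + '.tmp'`` and rename on successful close."""

    def __init__(self, path: str):
        self.path = path
        self.tmp = path + ".tmp"

    def __enter__(self):
        self.fh = open(self.tmp, "w")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(segment: GenomeSegment, path: str) -> None:
    rec = SeqRecord(
        Seq(segment.sequence),
        id=segment.name,
        description=f"start={segment.start} end={segment.end}",
    )
    with _AtomicWriter(path) as fh:
        SeqIO.write([rec], fh, "fasta")


def read_fasta_segment(path: str) -> GenomeSegment:
    rec = SeqIO.read(path, "fasta")
    fields = dict(
        kv.split("=", 1) for kv in rec.description.split() if "=" in kv
    )
    start = int(fields.get("start", 1))
    seq = str(rec.seq).upper()
    return GenomeSegment(rec.id, start, start + len(seq) - 1, seq)


def write_fastq(reads: Iterable[SimulatedRead], path: str) -> None:
    with _AtomicWriter(path) as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq), quals))
    return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}
_CIGAR_LETTER = {v: k for k, v in _CIGAR_CODE.items()}
_QUERY_OPS = {"M", "I", "S", "=", "X"}


def _sam_header(segment: GenomeSegment) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": segment.name, "LN": segment.end}],
            "PG": [{"ID": "polledrec", "PN": "polledrec"}],
        }
    )


def _cigar_to_tuples(cigar: Sequence[tuple[str, int]]) -> list[tuple[int, int]]:
    return [(_CIGAR_CODE[op], n) for op, n in cigar]


def write_sam(
    alignments: Iterable[ReadAlignment], segment: GenomeSegment, path: str
) -> None:
    """Write projected alignments as SAM with SA-tagged supplementaries."""
    header = _sam_header(segment)
    records = []
    for aln in alignments:
        read = aln.read
        qlen = aln.segments[0].query_length or len(read.sequence)
        seq_fwd = (
            read.sequence
            if read.strand == "+"
            else read.sequence.translate(_RC)[::-1]
        )
        sa_strings = []
        for seg in aln.segments:
            cig = "".join(f"{n}{op}" for op, n in (seg.cigar or ()))
            lead = seg.read_start - 1
            trail = qlen - seg.read_end
            full = (f"{lead}S" if lead else "") + cig + (f"{trail}S" if trail else "")
            sa_strings.append(
                f"{segment.name},{seg.ref_start},{seg.strand},{full},{seg.mapq},0"
            )
        for i, seg in enumerate(aln.segments):
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            a.reference_id = 0
            a.reference_start = seg.ref_start - 1
            a.mapping_quality = seg.mapq
            flag = 0
            if read.strand == "-":
                flag |= 0x10
            if seg.is_supplementary:
                flag |= 0x800
            a.flag = flag
            lead = seg.read_start - 1
            trail = qlen - seg.read_end
            cig: list[tuple[int, int]] = []
            if lead:
                cig.append((_CIGAR_CODE["S"], lead))
            cig.extend(_cigar_to_tuples(seg.cigar or ()))
            if trail:
                cig.append((_CIGAR_CODE["S"], trail))
            a.cigartuples = cig
            a.query_sequence = seq_fwd
            a.query_qualities = pysam.qualitystring_to_array("5" * len(seq_fwd))
            others = [s for j, s in enumerate(sa_strings) if j != i]
            if others:
                a.set_tag("SA", ";".join(others) + ";")
            records.append(a)
    tmp = path + ".tmp"
    with pysam.AlignmentFile(tmp, "wh", header=header) as out:
        for rec in records:
            out.write(rec)
    os.replace(tmp, path)


def segments_from_sam(path: str) -> list[AlignmentSegment]:
    """Load alignment segments from SAM/BAM (primary + supplementary).

    Query coordinates are reported in reference-forward orientation
    (clip-derived), matching the projection convention.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    out: list[AlignmentSegment] = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            ct = rec.cigartuples or []
            lead = 0
            trail = 0
            i = 0
            while i < len(ct) and ct[i][0] in (4, 5):
                lead += ct[i][1]
                i += 1
            j = len(ct)
            while j > i and ct[j - 1][0] in (4, 5):
                trail += ct[j - 1][1]
                j -= 1
            core = ct[i:j]
            qconsumed = sum(n for op, n in core if _CIGAR_LETTER[op] in _QUERY_OPS)
            qlen = lead + trail + qconsumed
            out.append(
                AlignmentSegment(
                    read_id=rec.query_name,
                    ref_start=rec.reference_start + 1,
                    ref_end=rec.reference_end,
                    read_start=lead + 1,
                    read_end=lead + qconsumed,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    is_supplementary=rec.is_supplementary,
                    cigar=tuple((_CIGAR_LETTER[op], n) for op, n in core),
                    query_length=qlen,
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_genotypes_tsv(t: TrioGenotypes, path: str, seed: Optional[int] = None) -> None:
    with _AtomicWriter(path) as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("marker\tpos\tsire\tdam\toffspring\n")
        for i in range(len(t)):
            fh.write(
                f"M{i:05d}\t{t.positions[i]}\t{t.sire[i] or '.'}\t"
                f"{t.dam[i] or '.'}\t{t.offspring[i] or '.'}\n"
            )


def read_genotypes_tsv(path: str) -> TrioGenotypes:
    pos, s, d, o = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("marker\t"):
                continue
            f = line.rstrip("\n").split("\t")
            pos.append(int(f[1]))
            for lst, val in ((s, f[2]), (d, f[3]), (o, f[4])):
                lst.append("" if val == "." else val)
    return TrioGenotypes(
        positions=np.array(pos, dtype=np.int64),
        sire=np.array(s, dtype="<U2"),
        dam=np.array(d, dtype="<U2"),
        offspring=np.array(o, dtype="<U2"),
    )


def write_parent_phase_tsv(
    sire: PhasedParent, dam: PhasedParent, positions: np.ndarray, path: str
) -> None:
    with _AtomicWriter(path) as fh:
        fh.write("pos\tsire_h1\tsire_h2\tdam_h1\tdam_h2\n")
        for i, p in enumerate(positions):
            fh.write(
                f"{p}\t{sire.hap_alleles[0][i]}\t{sire.hap_alleles[1][i]}\t"
                f"{dam.hap_alleles[0][i]}\t{dam.hap_alleles[1][i]}\n"
            )


def read_parent_phase_tsv(path: str) -> tuple[PhasedParent, PhasedParent, np.ndarray]:
    pos, s1, s2, d1, d2 = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("pos\t") or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            pos.append(int(f[0]))
            s1.append(f[1])
            s2.append(f[2])
            d1.append(f[3])
            d2.append(f[4])
    arr = lambda x: np.array(x, dtype="<U1")  # noqa: E731
    return (
        PhasedParent("sire", (arr(s1), arr(s2))),
        PhasedParent("dam", (arr(d1), arr(d2))),
        np.array(pos, dtype=np.int64),
    )


def write_clusters_tsv(clusters: Iterable[BreakpointCluster], path: str) -> None:
    with _AtomicWriter(path) as fh:
        fh.write("consensus_left\tconsensus_right\tsignature\tsupport\treads\n")
        for c in clusters:
            fh.write(
                f"{c.consensus_left}\t{c.consensus_right}\t{c.signature}\t"
                f"{c.support}\t{','.join(c.reads)}\n"
            )


def write_clusters_vcf(
    clusters: Iterable[BreakpointCluster], segment_name: str, path: str
) -> None:
    """Minimal VCF 4.2 with one symbolic SV record per cluster."""
    with _AtomicWriter(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write(
            '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Read support">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(clusters):
            svtype = {"DEL": "DEL", "TANDEM_DUP": "DUP", "INV": "INV"}.get(
                c.signature, "BND"
            )
            lo = min(c.consensus_left, c.consensus_right)
            hi = max(c.consensus_left, c.consensus_right)
            fh.write(
                f"{segment_name}\t{lo}\tsv{i}\tN\t<{svtype}>\t.\tPASS\t"
                f"SVTYPE={svtype};END={hi};SUPPORT={c.support}\n"
            )


def write_track_bedgraph(track: DepthTrack, chrom: str, path: str) -> None:
    with _AtomicWriter(path) as fh:
        fh.write("# window depth track: raw depth and median ratio\n")
        fh.write("chrom\tstart\tend\tdepth\tratio\n")
        for i, s in enumerate(track.window_starts):
            fh.write(
                f"{chrom}\t{s - 1}\t{s - 1 + track.window}\t"
                f"{track.raw[i]:.3f}\t{track.ratio[i]:.4f}\n"
            )


def write_cnv_bed(calls: Iterable[CnvCall], chrom: str, path: str) -> None:
    with _AtomicWriter(path) as fh:
        for c in calls:
            fh.write(
                f"{chrom}\t{c.start - 1}\t{c.end}\t{c.direction}\t"
                f"{c.mean_ratio:.3f}\t{c.n_windows}\n"
            )


def write_switches_tsv(switches: Iterable[SwitchCall], path: str) -> None:
    with _AtomicWriter(path) as fh:
        fh.write("parent\tinterval_start\tinterval_end\tpoint\tfrom_hap\tto_hap\n")
        for s in switches:
            fh.write(
                f"{s.parent}\t{s.interval[0]}\t{s.interval[1]}\t"
                f"{s.point_estimate}\t{s.from_hap}\t{s.to_hap}\n"
            )


def write_read_truth_tsv(reads: Iterable[SimulatedRead], path: str) -> None:
    with _AtomicWriter(path) as fh:
        fh.write("read_id\tindividual\thap_index\thap_start\thap_end\tstrand\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.individual_id}\t{r.hap_index}\t"
                f"{r.hap_start}\t{r.hap_end}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    scenario: str = "HF_H3H4"
    seed: int = 1
    coverage: float = 20.0
    tol_bp: int = 20
    min_support: int = 2
    min_mapq: int = 10
    min_anchor: int = 100
    join_tol: int = 50
    window: int = 200
    step: int = 100
    gain_thr: float = 1.4
    loss_thr: float = 0.6
    min_length: int = 1000
    panel_spacing: int = 5000

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError("need window >= step >= 1")
        if not self.loss_thr < 1 < self.gain_thr:
            raise ValueError("need loss_thr < 1 < gain_thr")
        if self.min_support < 1 or self.min_mapq < 0 or self.tol_bp < 0:
            raise ValueError("thresholds out of range")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
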