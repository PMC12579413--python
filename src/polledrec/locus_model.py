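"""Sequence model of the bovine *POLLED* locus (BTA1 ~2.42-2.73 Mb, ARS-UCD1.3).

Polledness in cattle is a dominant Mendelian trait governed by several
structural variants clustered in a ~300 kb non-coding interval on
chromosome 1.  This module encodes those alleles as explicit edit
operations on reference coordinates and implements the sequence algebra
the downstream analysis rests on:

* building a haplotype sequence (plus a haplotype->reference coordinate
  map) from an allele specification,
* allelic homologous recombination (AHR) between two haplotypes at a
  reference breakpoint,
* non-allelic homologous recombination (NAHR) between the two copies of
  a tandem segmental duplication, the mechanism by which an 80,128 bp
  "Friesian" duplication can delete itself back to the wild-type
  sequence.

Coordinates are 1-based and inclusive at every public interface, in the
style of HGVS genomic notation.  Built-in allele definitions:

========  ==========================================================
``p``     wild type (horned), zero edits
``P_C``   Celtic: 10 bp deletion at 2,429,326-2,429,335 replaced by a
          212 bp copy of 2,429,109-2,429,320 (complex InDel, net +202)
``P_F``   Friesian: tandem duplication of 2,629,116-2,709,243
          (80,128 bp); the inserted copy carries a SNV (T>A) at unit
          bp 1 and a 2 bp TG deletion ("P_F2D") at unit bp 38
``P_M``   Mongolian: 7 bp delins (TCTGAA) at 2,695,261-2,695,267 plus
          a 159 bp tandem duplication of 2,695,889-2,696,047
``P_G``   Guarani: tandem duplication of 2,614,828-2,724,315
========  ==========================================================
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

__all__ = [
    "GenomeSegment",
    "InternalEdit",
    "EditOp",
    "AlleleSpec",
    "Block",
    "Liftover",
    "Haplotype",
    "Diplotype",
    "VariantDistance",
    "allele_spec",
    "sv_length",
    "sv_net_change",
    "build_haplotype",
    "liftover",
    "nahr_product",
    "ahr_product",
    "variant_distance",
    "SEGMENT_START",
    "SEGMENT_LENGTH",
    "PC_DEL_START",
    "PC_DEL_END",
    "PC_DUP_SOURCE_START",
    "PC_DUP_SOURCE_END",
    "PF_UNIT_START",
    "PF_UNIT_END",
    "PF_UNIT_LENGTH",
    "PF_SNV_OFFSET",
    "PF_F2D_OFFSET",
    "PF_F2D_LENGTH",
    "PM_DELINS_START",
    "PM_DELINS_END",
    "PM_DUP_START",
    "PM_DUP_END",
    "PG_DUP_START",
    "PG_DUP_END",
    "FV_AHR_BREAKPOINT",
]

DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Default synthetic segment: spans the whole POLLED locus with generous
# flanks, so read-level edge effects stay outside the analysis region
# and the marker panel has informative sites distal to the locus.
SEGMENT_START = 2_400_001
SEGMENT_LENGTH = 400_000

# Celtic complex InDel, HGVS g.[2429326_2429335del;2429109_2429320dupins]
PC_DEL_START = 2_429_326
PC_DEL_END = 2_429_335
PC_DUP_SOURCE_START = 2_429_109
PC_DUP_SOURCE_END = 2_429_320

# Friesian tandem duplication, HGVS g.2629116_2709243dup (80,128 bp).
# The duplicated copy differs from the reference unit by a SNV (T>A) at
# unit bp 1 and a 2 bp TG deletion at unit bp 38 (the "P_F2D" marker).
PF_UNIT_START = 2_629_116
PF_UNIT_END = 2_709_243
PF_UNIT_LENGTH = PF_UNIT_END - PF_UNIT_START + 1  # 80,128
PF_SNV_OFFSET = 1
PF_F2D_OFFSET = 38
PF_F2D_LENGTH = 2

# Mongolian: [2695261_2695267delinsTCTGAA;2695889_2696047dupins]
PM_DELINS_START = 2_695_261
PM_DELINS_END = 2_695_267
PM_DELINS_PAYLOAD = "TCTGAA"
PM_DUP_START = 2_695_889
PM_DUP_END = 2_696_047

# Guarani: g.2614828_2724315dup
PG_DUP_START = 2_614_828
PG_DUP_END = 2_724_315

# Maternal AHR crossover localized in the Fleckvieh trio.
FV_AHR_BREAKPOINT = 2_694_883


class CoordinateError(ValueError):
    """A position or interval is outside the valid coordinate range."""


class SpecError(ValueError):
    """An allele specification is malformed or unsupported."""


class BreakpointError(ValueError):
    """A recombination breakpoint cannot be placed on a haplotype."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSegment:
    """A contiguous reference segment with absolute 1-based coordinates."""

    name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"segment start must be >= 1, got {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise CoordinateError(
                f"sequence length {len(self.sequence)} does not match "
                f"{self.start}-{self.end}"
            )
        if not set(self.sequence) <= DNA:
            bad = sorted(set(self.sequence) - DNA)
            raise CoordinateError(f"non-ACGT characters in sequence: {bad}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def slice(self, ref_start: int, ref_end: int) -> str:
        """Sequence of the closed interval [ref_start, ref_end]."""
        if not (self.start <= ref_start <= ref_end <= self.end):
            raise CoordinateError(
                f"[{ref_start}, {ref_end}] outside segment "
                f"[{self.start}, {self.end}]"
            )
        off = self.start
        return self.sequence[ref_start - off : ref_end - off + 1]

    def base(self, ref_pos: int) -> str:
        return self.slice(ref_pos, ref_pos)


class InternalEdit(NamedTuple):
    """An edit carried by the *inserted copy* of a tandem duplication.

    ``offset`` is 1-based within the duplication unit.
    """

    offset: int
    kind: str  # "snv" | "deletion"
    payload: str = ""  # replacement base for snv
    length: int = 1  # deleted bases for deletion


@dataclass(frozen=True)
class EditOp:
    """One edit operation on reference coordinates.

    kinds: ``deletion``, ``insertion`` (payload after ref_start),
    ``delins`` (replace [ref_start, ref_end] with payload), ``snv``,
    ``tandem_duplication`` (insert a copy of [ref_start, ref_end]
    immediately after ref_end, optionally with internal_edits).

    For duplication-derived insertions (the Celtic 212 bp dupins),
    ``payload_source`` names the template interval copied from the
    reference at build time instead of a literal payload.
    """

    kind: str
    ref_start: int
    ref_end: int
    payload: str = ""
    payload_source: Optional[tuple[int, int]] = None
    internal_edits: tuple[InternalEdit, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {
            "deletion",
            "insertion",
            "delins",
            "snv",
            "tandem_duplication",
        }:
            raise SpecError(f"unknown edit kind {self.kind!r}")
        if self.ref_start > self.ref_end:
            raise CoordinateError(
                f"ref_start {self.ref_start} > ref_end {self.ref_end}"
            )
        if self.ref_start < 1:
            raise CoordinateError("coordinates are 1-based")
        if self.kind == "snv":
            if self.ref_start != self.ref_end or len(self.payload) != 1:
                raise SpecError("snv must cover one base with a one-base payload")
        if self.internal_edits and self.kind != "tandem_duplication":
            raise SpecError("internal_edits are only valid on tandem duplications")
        unit = self.ref_end - self.ref_start + 1
        prev_end = 0
        for ie in self.internal_edits:
            span = ie.length if ie.kind == "deletion" else 1
            if not (1 <= ie.offset and ie.offset + span - 1 <= unit):
                raise SpecError(f"internal edit at offset {ie.offset} outside unit")
            if ie.offset <= prev_end:
                raise SpecError("internal_edits must be sorted and non-overlapping")
            prev_end = ie.offset + span - 1


@dataclass(frozen=True)
class AlleleSpec:
    """A POLLED allele as an ordered list of edits plus a dominance flag."""

    allele_id: str
    edits: tuple[EditOp, ...] = ()
    dominance: bool = False  # True = polled-dominant

    def __post_init__(self) -> None:
        prev_end = 0
        for e in self.edits:
            if e.ref_start <= prev_end:
                raise SpecError(
                    f"edits of {self.allele_id} must be sorted and non-overlapping"
                )
            prev_end = e.ref_end
            if e.kind == "tandem_duplication":
                # copy is inserted after ref_end; nothing else may start there
                prev_end = e.ref_end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval touched by the edit operations themselves."""
        if not self.edits:
            raise SpecError(f"allele {self.allele_id} has no edits")
        return (min(e.ref_start for e in self.edits), max(e.ref_end for e in self.edits))


class Block(NamedTuple):
    """One block of the haplotype->reference coordinate map.

    ``copy_index`` is 0 for the original copy, >=1 for bases of an
    inserted duplicated copy; ``inserted`` marks novel payload bases
    with no true reference equivalent (ref coords then anchor the
    nearest flanking reference base).
    """

    hap_start: int
    hap_end: int
    ref_start: int
    ref_end: int
    copy_index: int = 0
    inserted: bool = False


class Liftover(NamedTuple):
    ref_pos: int
    copy_index: int
    inserted: bool


@dataclass(frozen=True)
class Haplotype:
    """An edited sequence plus the block map back to reference space."""

    allele_id: str
    sequence: str
    blocks: tuple[Block, ...]
    segment: Optional[GenomeSegment] = None
    source_spec: Optional[AlleleSpec] = None
    # reversible-diff records: content removed/substituted during build
    deleted_ref: tuple[tuple[int, int, str], ...] = ()
    substituted_ref: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        pos = 1
        for b in self.blocks:
            if b.hap_start != pos:
                raise SpecError(
                    f"coord_map blocks do not tile: expected hap_start {pos}, "
                    f"got {b.hap_start}"
                )
            if b.hap_end < b.hap_start:
                raise SpecError("empty block")
            if not b.inserted and (b.hap_end - b.hap_start != b.ref_end - b.ref_start):
                raise SpecError("block haplotype/reference lengths differ")
            pos = b.hap_end + 1
        if pos != len(self.sequence) + 1:
            raise SpecError("coord_map does not cover the haplotype sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def _block_at(self, hap_pos: int) -> Block:
        if not (1 <= hap_pos <= len(self.sequence)):
            raise CoordinateError(
                f"haplotype position {hap_pos} outside 1..{len(self.sequence)}"
            )
        idx = bisect.bisect_right([b.hap_start for b in self.blocks], hap_pos) - 1
        return self.blocks[idx]

    def liftover(self, hap_pos: int) -> Liftover:
        """Reference coordinate and copy index of a haplotype position."""
        b = self._block_at(hap_pos)
        if b.inserted:
            return Liftover(b.ref_start, b.copy_index, True)
        return Liftover(b.ref_start + (hap_pos - b.hap_start), b.copy_index, False)

    def ref_to_hap(self, ref_pos: int, copy_index: int = 0) -> int:
        """Haplotype position of ``ref_pos`` on the given copy."""
        for b in self.blocks:
            if b.inserted or b.copy_index != copy_index:
                continue
            if b.ref_start <= ref_pos <= b.ref_end:
                return b.hap_start + (ref_pos - b.ref_start)
        raise CoordinateError(
            f"reference position {ref_pos} (copy {copy_index}) absent from haplotype"
        )

    def slice_blocks(self, hap_start: int, hap_end: int) -> tuple[Block, ...]:
        """Blocks covering [hap_start, hap_end], clipped and re-based to 1."""
        if not (1 <= hap_start <= hap_end <= len(self.sequence)):
            raise CoordinateError(f"[{hap_start}, {hap_end}] outside haplotype")
        out: list[Block] = []
        shift = hap_start - 1
        for b in self.blocks:
            if b.hap_end < hap_start or b.hap_start > hap_end:
                continue
            lo = max(b.hap_start, hap_start)
            hi = min(b.hap_end, hap_end)
            if b.inserted:
                out.append(Block(lo - shift, hi - shift, b.ref_start, b.ref_end, b.copy_index, True))
            else:
                out.append(
                    Block(
                        lo - shift,
                        hi - shift,
                        b.ref_start + (lo - b.hap_start),
                        b.ref_start + (hi - b.hap_start),
                        b.copy_index,
                        False,
                    )
                )
        return tuple(out)

    def duplication_unit(self) -> tuple[int, int]:
        """Reference span of the (single) tandem-duplication unit."""
        spec = self.source_spec
        if spec is not None:
            dups = [e for e in spec.edits if e.kind == "tandem_duplication"]
            if len(dups) != 1:
                raise SpecError(
                    f"haplotype {self.allele_id} must carry exactly one tandem "
                    f"duplication, found {len(dups)}"
                )
            return (dups[0].ref_start, dups[0].ref_end)
        copies = [b for b in self.blocks if b.copy_index >= 1 and not b.inserted]
        if not copies:
            raise SpecError(f"haplotype {self.allele_id} carries no duplication")
        return (min(b.ref_start for b in copies), max(b.ref_end for b in copies))


@dataclass(frozen=True)
class Diplotype:
    """Two haplotypes of one trio member."""

    individual_id: str
    role: str  # sire | dam | offspring
    haplotypes: tuple[Haplotype, Haplotype]

    def __post_init__(self) -> None:
        if self.role not in {"sire", "dam", "offspring"}:
            raise SpecError(f"unknown role {self.role!r}")
        if len(self.haplotypes) != 2:
            raise SpecError("a diplotype has exactly two haplotypes")


# ---------------------------------------------------------------------------
# built-in allele registry
# ---------------------------------------------------------------------------


def _builtin_specs() -> dict[str, AlleleSpec]:
    p = AlleleSpec("p", (), dominance=False)
    p_c = AlleleSpec(
        "P_C",
        (
            EditOp(
                "delins",
                PC_DEL_START,
                PC_DEL_END,
                payload_source=(PC_DUP_SOURCE_START, PC_DUP_SOURCE_END),
            ),
        ),
        dominance=True,
    )
    p_f = AlleleSpec(
        "P_F",
        (
            EditOp(
                "tandem_duplication",
                PF_UNIT_START,
                PF_UNIT_END,
                internal_edits=(
                    InternalEdit(PF_SNV_OFFSET, "snv", payload="A"),
                    InternalEdit(PF_F2D_OFFSET, "deletion", length=PF_F2D_LENGTH),
                ),
            ),
        ),
        dominance=True,
    )
    p_m = AlleleSpec(
        "P_M",
        (
            EditOp("delins", PM_DELINS_START, PM_DELINS_END, payload=PM_DELINS_PAYLOAD),
            EditOp("tandem_duplication", PM_DUP_START, PM_DUP_END),
        ),
        dominance=True,
    )
    p_g = AlleleSpec(
        "P_G",
        (EditOp("tandem_duplication", PG_DUP_START, PG_DUP_END),),
        dominance=True,
    )
    return {"p": p, "P_C": p_c, "P_F": p_f, "P_M": p_m, "P_G": p_g}


_REGISTRY = _builtin_specs()


def allele_spec(allele_id: str) -> AlleleSpec:
    """Return the built-in specification for one of p, P_C, P_F, P_M, P_G."""
    try:
        return _REGISTRY[allele_id]
    except KeyError:
        raise SpecError(
            f"unknown allele {allele_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sv_length(edit: EditOp) -> int:
    """Length of the structural event in bp.

    Duplications and deletions report the unit span; insertions and
    duplication-derived delins report the inserted length (e.g. the
    Celtic variant inserts a 212 bp copy while deleting 10 bp); plain
    delins report the replaced span (see :func:`sv_net_change` for the
    signed net).
    """
    if edit.payload_source is not None:
        s, e = edit.payload_source
        if s > e or s < 1:
            raise CoordinateError("malformed payload_source interval")
        return e - s + 1
    if edit.kind in {"deletion", "tandem_duplication", "delins"}:
        return edit.ref_end - edit.ref_start + 1
    if edit.kind == "insertion":
        return len(edit.payload)
    if edit.kind == "snv":
        return 1
    raise SpecError(f"unsupported edit kind {edit.kind!r}")


def sv_net_change(edit: EditOp) -> int:
    """Signed net change in haplotype length caused by the edit."""
    span = edit.ref_end - edit.ref_start + 1
    if edit.kind == "deletion":
        return -span
    if edit.kind == "insertion":
        return len(edit.payload)
    if edit.kind == "snv":
        return 0
    if edit.kind == "delins":
        ins = sv_length(edit) if edit.payload_source is not None else len(edit.payload)
        return ins - span
    if edit.kind == "tandem_duplication":
        copy_len = span
        for ie in edit.internal_edits:
            if ie.kind == "deletion":
                copy_len -= ie.length
        return copy_len
    raise SpecError(f"unsupported edit kind {edit.kind!r}")


def _copy_pieces(
    segment: GenomeSegment, edit: EditOp
) -> list[tuple[str, int, int]]:
    """(sequence, ref_start, ref_end) pieces of the duplicated copy.

    Internal SNVs substitute in place; internal deletions split the
    copy into multiple reference-collinear pieces.
    """
    unit = segment.slice(edit.ref_start, edit.ref_end)
    unit_len = len(unit)
    # apply snvs
    chars = list(unit)
    for ie in edit.internal_edits:
        if ie.kind == "snv":
            chars[ie.offset - 1] = ie.payload
    edited = "".join(chars)
    pieces: list[tuple[str, int, int]] = []
    cursor = 1  # 1-based offset within the unit
    for ie in edit.internal_edits:
        if ie.kind != "deletion":
            continue
        if ie.offset > cursor:
            pieces.append(
                (
                    edited[cursor - 1 : ie.offset - 1],
                    edit.ref_start + cursor - 1,
                    edit.ref_start + ie.offset - 2,
                )
            )
        cursor = ie.offset + ie.length
    if cursor <= unit_len:
        pieces.append(
            (
                edited[cursor - 1 :],
                edit.ref_start + cursor - 1,
                edit.ref_start + unit_len - 1,
            )
        )
    return pieces


def build_haplotype(segment: GenomeSegment, spec: AlleleSpec) -> Haplotype:
    """Apply an allele's edits to a reference segment, left to right."""
    for e in spec.edits:
        if not (segment.start <= e.ref_start and e.ref_end <= segment.end):
            raise CoordinateError(
                f"edit [{e.ref_start}, {e.ref_end}] outside segment "
                f"[{segment.start}, {segment.end}]"
            )
        if e.payload_source is not None:
            s, t = e.payload_source
            if not (segment.start <= s <= t <= segment.end):
                raise CoordinateError("payload_source outside segment")

    pieces: list[tuple[str, int, int, int, bool]] = []  # seq, rs, re, copy, inserted
    cursor = segment.start

    def emit_ref(upto: int) -> None:
        nonlocal cursor
        if upto >= cursor:
            pieces.append((segment.slice(cursor, upto), cursor, upto, 0, False))
            cursor = upto + 1

    deleted_ref: list[tuple[int, int, str]] = []
    substituted_ref: list[tuple[int, str]] = []

    for e in spec.edits:
        if e.ref_start < cursor:
            raise SpecError("overlapping edits")
        if e.kind == "deletion":
            emit_ref(e.ref_start - 1)
            deleted_ref.append((e.ref_start, e.ref_end, segment.slice(e.ref_start, e.ref_end)))
            cursor = e.ref_end + 1
        elif e.kind == "snv":
            emit_ref(e.ref_start - 1)
            substituted_ref.append((e.ref_start, segment.base(e.ref_start)))
            pieces.append((e.payload, e.ref_start, e.ref_end, 0, False))
            cursor = e.ref_end + 1
        elif e.kind == "insertion":
            emit_ref(e.ref_start)
            pieces.append((e.payload, e.ref_start, e.ref_start, 0, True))
        elif e.kind == "delins":
            emit_ref(e.ref_start - 1)
            deleted_ref.append((e.ref_start, e.ref_end, segment.slice(e.ref_start, e.ref_end)))
            if e.payload_source is not None:
                s, t = e.payload_source
                pieces.append((segment.slice(s, t), s, t, 1, False))
            else:
                anchor = max(e.ref_start - 1, segment.start)
                pieces.append((e.payload, anchor, anchor, 0, True))
            cursor = e.ref_end + 1
        elif e.kind == "tandem_duplication":
            emit_ref(e.ref_end)  # original copy stays in place
            for seq, rs, re_ in _copy_pieces(segment, e):
                pieces.append((seq, rs, re_, 1, False))
        else:  # pragma: no cover - EditOp already validates
            raise SpecError(f"unsupported edit kind {e.kind!r}")
    emit_ref(segment.end)

    seq_parts: list[str] = []
    blocks: list[Block] = []
    hap_pos = 1
    for seq, rs, re_, copy_idx, inserted in pieces:
        if not seq:
            continue
        seq_parts.append(seq)
        blocks.append(Block(hap_pos, hap_pos + len(seq) - 1, rs, re_, copy_idx, inserted))
        hap_pos += len(seq)

    return Haplotype(
        allele_id=spec.allele_id,
        sequence="".join(seq_parts),
        blocks=tuple(blocks),
        segment=segment,
        source_spec=spec,
        deleted_ref=tuple(deleted_ref),
        substituted_ref=tuple(substituted_ref),
    )


def reconstruct_reference(h: Haplotype) -> str:
    """Invert a built haplotype back to its reference sequence.

    Uses only the haplotype's own records (blocks plus the reversible
    diff captured at build time), so ``build -> reconstruct`` is a true
    round trip.
    """
    if h.segment is None:
        raise SpecError("haplotype does not record its source segment bounds")
    start, end = h.segment.start, h.segment.end
    out = [""] * (end - start + 1)
    for b in h.blocks:
        if b.inserted or b.copy_index != 0:
            continue
        for i in range(b.hap_end - b.hap_start + 1):
            out[b.ref_start - start + i] = h.sequence[b.hap_start - 1 + i]
    for rs, re_, seq in h.deleted_ref:
        for i, ch in enumerate(seq):
            out[rs - start + i] = ch
    for pos, base in h.substituted_ref:
        out[pos - start] = base
    if "" in out:
        raise SpecError("haplotype does not determine the full reference sequence")
    return "".join(out)


def liftover(h: Haplotype, hap_pos: int) -> Liftover:
    """Module-level convenience wrapper around :meth:`Haplotype.liftover`."""
    return h.liftover(hap_pos)


def concat_haplotypes(allele_id: str, parts: Sequence[Haplotype]) -> Haplotype:
    """Join haplotype fragments end to end, merging their block maps."""
    seq_parts: list[str] = []
    blocks: list[Block] = []
    offset = 0
    segment = parts[0].segment if parts else None
    for part in parts:
        seq_parts.append(part.sequence)
        for b in part.blocks:
            blocks.append(
                Block(
                    b.hap_start + offset,
                    b.hap_end + offset,
                    b.ref_start,
                    b.ref_end,
                    b.copy_index,
                    b.inserted,
                )
            )
        offset += len(part.sequence)
    return Haplotype(allele_id, "".join(seq_parts), tuple(blocks), segment=segment)


def slice_haplotype(h: Haplotype, hap_start: int, hap_end: int) -> Haplotype:
    """A haplotype fragment covering [hap_start, hap_end]."""
    return Haplotype(
        h.allele_id,
        h.sequence[hap_start - 1 : hap_end],
        h.slice_blocks(hap_start, hap_end),
        segment=h.segment,
    )


def delete_hap_interval(h: Haplotype, hap_start: int, hap_end: int, allele_id: str) -> Haplotype:
    """Remove a closed haplotype-coordinate interval (germline deletion)."""
    parts = []
    if hap_start > 1:
        parts.append(slice_haplotype(h, 1, hap_start - 1))
    if hap_end < len(h.sequence):
        parts.append(slice_haplotype(h, hap_end + 1, len(h.sequence)))
    return concat_haplotypes(allele_id, parts)


def nahr_product(h: Haplotype, crossover_offset: int) -> Haplotype:
    """Crossover between the two copies of a tandem duplication.

    The crossover is modelled in copy-alignment space: the product keeps
    the original-copy prefix up to ``crossover_offset - 1`` and switches
    to the duplicated copy from the homologous position onward, removing
    one full unit of sequence.  Because the only differences between the
    two copies of the Friesian duplication sit at unit bp 1 and 38-39,
    any crossover offset beyond them yields a product byte-identical to
    the wild-type haplotype.
    """
    if h.segment is None or h.source_spec is None:
        raise SpecError("nahr_product needs a haplotype built from a spec")
    dups = [e for e in h.source_spec.edits if e.kind == "tandem_duplication"]
    if len(dups) != 1:
        raise SpecError(
            f"haplotype must carry exactly one tandem duplication, found {len(dups)}"
        )
    dup = dups[0]
    unit_len = dup.ref_end - dup.ref_start + 1
    if not (1 <= crossover_offset <= unit_len):
        raise CoordinateError(
            f"crossover offset {crossover_offset} outside 1..{unit_len}"
        )

    # Internal edits at unit offsets >= crossover_offset come from the
    # duplicated copy and survive in the single-copy product; offsets
    # before it come from the original copy and vanish.
    surviving: list[EditOp] = []
    for ie in dup.internal_edits:
        if ie.kind == "snv":
            if ie.offset >= crossover_offset:
                surviving.append(
                    EditOp("snv", dup.ref_start + ie.offset - 1,
                           dup.ref_start + ie.offset - 1, payload=ie.payload)
                )
        elif ie.kind == "deletion":
            # a crossover inside the deleted tract keeps only its distal part
            del_start = max(ie.offset, crossover_offset)
            del_end = ie.offset + ie.length - 1
            if del_end >= crossover_offset:
                surviving.append(
                    EditOp(
                        "deletion",
                        dup.ref_start + del_start - 1,
                        dup.ref_start + del_end - 1,
                    )
                )
    others = [e for e in h.source_spec.edits if e.kind != "tandem_duplication"]
    product_spec = AlleleSpec(
        f"nahr({h.allele_id}@{crossover_offset})",
        tuple(sorted(others + surviving, key=lambda e: e.ref_start)),
        dominance=False,
    )
    return build_haplotype(h.segment, product_spec)


def ahr_product(hap_a: Haplotype, hap_b: Haplotype, breakpoint_ref: int) -> Haplotype:
    """Allelic crossover: hap_a through ``breakpoint_ref``, hap_b after it.

    The breakpoint must map to copy 0 (outside insertions) on both
    haplotypes.
    """
    try:
        pos_a = hap_a.ref_to_hap(breakpoint_ref, copy_index=0)
        pos_b = hap_b.ref_to_hap(breakpoint_ref, copy_index=0)
    except CoordinateError as exc:
        raise BreakpointError(
            f"breakpoint {breakpoint_ref} absent from copy 0 of a haplotype"
        ) from exc
    parts = [slice_haplotype(hap_a, 1, pos_a)]
    if pos_b < len(hap_b.sequence):
        parts.append(slice_haplotype(hap_b, pos_b + 1, len(hap_b.sequence)))
    return concat_haplotypes(
        f"ahr({hap_a.allele_id}|{hap_b.allele_id}@{breakpoint_ref})", parts
    )


class VariantDistance(NamedTuple):
    bp: int
    contained: bool


def variant_distance(a: AlleleSpec, b: AlleleSpec, rounding: int = 0) -> VariantDistance:
    """Distance between the proximal coordinates of two alleles' edit spans.

    If one allele's span lies entirely inside the other's (the Mongolian
    variant sits within the Friesian unit), the distance is 0 with the
    containment flag set.  ``rounding`` rounds to the nearest multiple.
    """
    sa, sb = a.span, b.span
    if sa == sb:
        return VariantDistance(0, False)
    if (sa[0] >= sb[0] and sa[1] <= sb[1]) or (sb[0] >= sa[0] and sb[1] <= sa[1]):
        return VariantDistance(0, True)
    dist = abs(sa[0] - sb[0])
    if rounding > 0:
        dist = round(dist / rounding) * rounding
    return VariantDistance(dist, False)
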