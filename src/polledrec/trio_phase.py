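"""Trio genotype consistency, parental-origin assignment, switch mapping.

Given sire/dam/offspring genotypes at ordered biallelic markers and the
parents' phased haplotypes, a recombination event in a parental gamete
appears as a *switch*: the offspring's transmitted allele sequence
matches one parental haplotype up to some point and the other beyond
it.  The switch is localized to the interval between the flanking
informative markers (markers heterozygous in that parent with an
unambiguous transmitted allele); isolated single-marker mismatches are
absorbed as genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TrioGenotypes",
    "PhasedParent",
    "SwitchCall",
    "MendelReport",
    "OriginAssignment",
    "UntestableError",
    "mendelian_consistency",
    "assign_parental_origin",
    "detect_switches",
]

MISSING = ""


class UntestableError(ValueError):
    """Not enough informative data to run the requested analysis."""


@dataclass(frozen=True)
class TrioGenotypes:
    """Ordered marker genotypes of a trio.

    Genotypes are unordered allele pairs over {A, B} written as sorted
    two-character strings ("AA", "AB", "BB"); empty string = missing.
    """

    positions: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    offspring: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.sire) == len(self.dam) == len(self.offspring) == n):
            raise ValueError("genotype arrays must have equal length")
        if n == 0:
            raise UntestableError("empty marker list")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        valid = {"AA", "AB", "BB", MISSING}
        for arr in (self.sire, self.dam, self.offspring):
            bad = set(arr.tolist()) - valid
            if bad:
                raise ValueError(f"invalid genotype strings: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class PhasedParent:
    """Two phased haplotype allele vectors over the marker list."""

    parent_id: str
    hap_alleles: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.hap_alleles) != 2 or len(self.hap_alleles[0]) != len(
            self.hap_alleles[1]
        ):
            raise ValueError("need two equally long haplotype vectors")


@dataclass(frozen=True)
class SwitchCall:
    """A localized parental-haplotype switch in the offspring."""

    parent: str
    interval: tuple[int, int]  # flanking informative markers (bp)
    point_estimate: int  # interval midpoint
    from_hap: int
    to_hap: int


@dataclass(frozen=True)
class MendelReport:
    n_markers: int
    n_tested: int
    n_conflicts: int
    conflict_rate: float
    n_opposing_homozygotes: int
    verdict: str  # "pass" | "fail" | "untestable"


def _alleles(g: str) -> tuple[str, str]:
    return (g[0], g[1])


def _is_consistent(sire: str, dam: str, off: str) -> bool:
    so = set(_alleles(sire))
    do = set(_alleles(dam))
    o = _alleles(off)
    return (o[0] in so and o[1] in do) or (o[1] in so and o[0] in do)


def mendelian_consistency(t: TrioGenotypes, threshold: float = 0.001) -> MendelReport:
    """Count markers where the offspring cannot have received one allele
    from each parent; verdict "pass" when the conflict rate is at or
    below ``threshold`` (default 0.1%).
    """
    n_tested = 0
    n_conflicts = 0
    n_opp = 0
    for s, d, o in zip(t.sire, t.dam, t.offspring):
        if MISSING in (s, d, o):
            continue
        n_tested += 1
        if not _is_consistent(s, d, o):
            n_conflicts += 1
            if s in ("AA", "BB") and o in ("AA", "BB") and s != o:
                n_opp += 1
            if d in ("AA", "BB") and o in ("AA", "BB") and d != o:
                n_opp += 1
    if n_tested == 0:
        return MendelReport(len(t), 0, 0, 0.0, 0, "untestable")
    rate = n_conflicts / n_tested
    return MendelReport(
        n_markers=len(t),
        n_tested=n_tested,
        n_conflicts=n_conflicts,
        conflict_rate=rate,
        n_opposing_homozygotes=n_opp,
        verdict="pass" if rate <= threshold else "fail",
    )


@dataclass(frozen=True)
class OriginAssignment:
    """Offspring alleles split by parental origin where unambiguous."""

    paternal: np.ndarray  # allele or "" where uninformative
    maternal: np.ndarray
    conflict: np.ndarray  # bool: Mendelian conflict, marker excluded


def assign_parental_origin(t: TrioGenotypes) -> OriginAssignment:
    """Assign offspring alleles to parents where transmission is forced.

    A marker is informative for a parent when every consistent
    assignment of the offspring's two alleles gives that parent the
    same allele (e.g. offspring AB with sire AA, dam BB).  Fully
    ambiguous markers (all three heterozygous) stay unassigned;
    conflicting markers are flagged and excluded.
    """
    n = len(t)
    paternal = np.full(n, MISSING, dtype="<U1")
    maternal = np.full(n, MISSING, dtype="<U1")
    conflict = np.zeros(n, dtype=bool)
    for i, (s, d, o) in enumerate(zip(t.sire, t.dam, t.offspring)):
        if MISSING in (s, d, o):
            continue
        o1, o2 = _alleles(o)
        cands = set()
        for pat, mat in {(o1, o2), (o2, o1)}:
            if pat in _alleles(s) and mat in _alleles(d):
                cands.add((pat, mat))
        if not cands:
            conflict[i] = True
            continue
        pats = {c[0] for c in cands}
        mats = {c[1] for c in cands}
        if len(pats) == 1:
            paternal[i] = next(iter(pats))
        if len(mats) == 1:
            maternal[i] = next(iter(mats))
    return OriginAssignment(paternal=paternal, maternal=maternal, conflict=conflict)


def _absorb_short_runs(values: list[int], min_run: int) -> list[int]:
    """Merge runs shorter than ``min_run`` into their neighbours."""
    if min_run <= 1 or not values:
        return values
    out = values[:]
    changed = True
    while changed:
        changed = False
        runs: list[tuple[int, int, int]] = []  # (value, start, end)
        for i, v in enumerate(out):
            if runs and runs[-1][0] == v:
                runs[-1] = (v, runs[-1][1], i)
            else:
                runs.append((v, i, i))
        if len(runs) <= 1:
            break
        for ri, (v, a, b) in enumerate(runs):
            if b - a + 1 < min_run:
                neigh = runs[ri - 1][0] if ri > 0 else runs[ri + 1][0]
                for i in range(a, b + 1):
                    out[i] = neigh
                changed = True
                break
    return out


def detect_switches(
    origin_alleles: np.ndarray,
    positions: np.ndarray,
    parent: PhasedParent,
    min_run: int = 2,
) -> list[SwitchCall]:
    """Locate haplotype switches in one parent's transmitted alleles.

    Only markers heterozygous in the parent and with a known transmitted
    allele are informative.  The transmitted sequence is matched to the
    parent's two haplotypes; each change of best-matching haplotype
    across consecutive informative markers (after absorbing runs shorter
    than ``min_run`` as genotyping error) yields a SwitchCall whose
    interval brackets the true crossover position.  With ``min_run=1``
    the reported switches are the minimum number consistent with the
    informative-marker sequence.
    """
    h1, h2 = parent.hap_alleles
    idx: list[int] = []
    match: list[int] = []
    for i, allele in enumerate(origin_alleles):
        if allele == MISSING or h1[i] == h2[i]:
            continue
        if allele == h1[i]:
            idx.append(i)
            match.append(0)
        elif allele == h2[i]:
            idx.append(i)
            match.append(1)
        # alleles matching neither haplotype: genotyping error, skipped
    if len(idx) < 2:
        raise UntestableError(
            f"parent {parent.parent_id}: fewer than 2 informative markers"
        )
    smoothed = _absorb_short_runs(match, min_run)
    calls: list[SwitchCall] = []
    for k in range(1, len(idx)):
        if smoothed[k] != smoothed[k - 1]:
            lo = int(positions[idx[k - 1]])
            hi = int(positions[idx[k]])
            calls.append(
                SwitchCall(
                    parent=parent.parent_id,
                    interval=(lo, hi),
                    point_estimate=(lo + hi) // 2,
                    from_hap=smoothed[k - 1],
                    to_hap=smoothed[k],
                )
            )
    return calls
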