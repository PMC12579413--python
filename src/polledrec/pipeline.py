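"""End-to-end scenario pipeline: simulate -> scan -> phase -> classify.

This is the glue the CLI and the validation suite share: it generates a
synthetic trio under a named scenario, simulates offspring reads,
projects them to reference space, runs the split-read and depth
scanners, the diagnostic genotyper and (for the Fleckvieh-style trio)
the SNP-panel switch analysis, and hands the assembled evidence to the
hypothesis engine.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .depth_scan import (
    DEFAULT_GAIN_THR,
    DEFAULT_LOSS_THR,
    DEFAULT_MIN_LENGTH,
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    CnvCall,
    DepthTrack,
    call_regions,
    compute_depth,
)
from .hypothesis_engine import EvidenceBundle, HypothesisCall, classify_fv, classify_hf
from .polled_diagnostics import (
    DiagnosticSiteCounts,
    SiteGenotypeCall,
    count_pc_site,
    count_pf2d_site,
    genotype_pc,
    genotype_pf,
)
from .splitread_scan import AlignmentSegment, BreakpointCluster, extract_splits, scan_splits
from .synthetic_data import (
    PanelSim,
    ReadSimParams,
    TrioDesign,
    design_trio,
    make_reference,
    project_alignments,
    simulate_reads,
    simulate_snp_panel,
)
from .trio_phase import (
    MendelReport,
    SwitchCall,
    UntestableError,
    assign_parental_origin,
    detect_switches,
    mendelian_consistency,
)

__all__ = ["ScenarioResult", "run_scenario", "DEFAULT_SCAN_REGION", "PANEL_SPACING"]

# Analysis window: the POLLED locus with flanks, trimmed clear of the
# simulated segment's ends so read-length edge effects stay outside.
DEFAULT_SCAN_REGION = (2_420_000, 2_740_000)
PANEL_SPACING = 5_000  # array-style density: one marker per 5 kb
# The switch analysis emulates the combination of array genotypes with
# the (much denser) WGS-phased SNPs the localization actually rests on.
SWITCH_MARKER_SPACING = 2_000


def _sub_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


@functools.lru_cache(maxsize=8)
def _cached_reference(seed: int, length: int):
    return make_reference(length=length, seed=seed)


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    seed: int
    design: TrioDesign
    n_reads: int
    clusters: tuple[BreakpointCluster, ...]
    low_support_clusters: tuple[BreakpointCluster, ...]
    track: DepthTrack
    cnv_calls: tuple[CnvCall, ...]
    pc_counts: DiagnosticSiteCounts
    pf_counts: DiagnosticSiteCounts
    pc_call: SiteGenotypeCall
    pf_call: SiteGenotypeCall
    switches: tuple[SwitchCall, ...]
    mendel: Optional[MendelReport]
    panel: Optional[PanelSim]
    evidence: EvidenceBundle
    verdict: HypothesisCall


def run_scenario(
    scenario: str,
    seed: int,
    coverage: float = 20.0,
    region: tuple[int, int] = DEFAULT_SCAN_REGION,
    segment_length: Optional[int] = None,
    sim_params: Optional[ReadSimParams] = None,
    **design_kwargs,
) -> ScenarioResult:
    """Run the full pipeline on one synthetic scenario and seed."""
    from .locus_model import SEGMENT_LENGTH

    segment = _cached_reference(seed, segment_length or SEGMENT_LENGTH)
    design = design_trio(scenario, segment, **design_kwargs)
    params = sim_params or ReadSimParams(coverage=coverage, seed=_sub_seed(seed, 1))
    reads = simulate_reads(design.offspring, params)
    aligns = project_alignments(reads, design.offspring)
    segments: list[AlignmentSegment] = [s for a in aligns for s in a.segments]

    clusters, weak = scan_splits(segments)
    track = compute_depth(segments, region, window=DEFAULT_WINDOW, step=DEFAULT_STEP)
    cnvs = call_regions(
        track,
        min_length=DEFAULT_MIN_LENGTH,
        gain_thr=DEFAULT_GAIN_THR,
        loss_thr=DEFAULT_LOSS_THR,
    )
    groups = extract_splits(segments)
    pc_counts = count_pc_site(groups)
    pf_counts = count_pf2d_site(groups)
    pc_call = genotype_pc(pc_counts)
    pf_call = genotype_pf(pf_counts)

    switches: tuple[SwitchCall, ...] = ()
    mendel: Optional[MendelReport] = None
    panel: Optional[PanelSim] = None
    if scenario.startswith("FV"):
        # panel markers span the whole segment (a genotyping array is not
        # restricted to the SV scan window), at ~1 marker / 5 kb
        panel_region = (segment.start, segment.end)
        n_markers = max(10, (panel_region[1] - panel_region[0]) // SWITCH_MARKER_SPACING)
        panel = simulate_snp_panel(
            n_markers, panel_region, design, seed=_sub_seed(seed, 2)
        )
        mendel = mendelian_consistency(panel.genotypes)
        origins = assign_parental_origin(panel.genotypes)
        try:
            switches = tuple(
                detect_switches(
                    origins.maternal, panel.genotypes.positions, panel.dam_phase
                )
            )
        except UntestableError:
            switches = ()

    evidence = EvidenceBundle(
        split_clusters=tuple(clusters),
        low_support_clusters=tuple(weak),
        cnv_calls=tuple(cnvs),
        track=track,
        pc_call=pc_call,
        pf_call=pf_call,
        switches=switches,
    )
    if scenario.startswith("HF"):
        verdict = classify_hf(evidence)
    else:
        verdict = classify_fv(evidence)

    return ScenarioResult(
        scenario=scenario,
        seed=seed,
        design=design,
        n_reads=len(reads),
        clusters=tuple(clusters),
        low_support_clusters=tuple(weak),
        track=track,
        cnv_calls=tuple(cnvs),
        pc_counts=pc_counts,
        pf_counts=pf_counts,
        pc_call=pc_call,
        pf_call=pf_call,
        switches=switches,
        mendel=mendel,
        panel=panel,
        evidence=evidence,
        verdict=verdict,
    )
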