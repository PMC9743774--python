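"""End-to-end orchestration: filtering -> de novo calling -> phasing -> stats.

The stages operate on in-memory objects (a catalog, a pedigree and one
CallSet per family unit) and are equally usable from files via the CLI.
Counts at every stage are collected into a run manifest, since the key
results of this kind of analysis are funnel counts (putative candidates ->
transmission-validated events -> phase-resolved events).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .catalog import Catalog
from .denovo import DeNovoEvent, Status, call_family, events_table
from .filtering import FilterConfig, FilterResult, TrioDenominator, filter_family
from .pedio import CallSet, FamilyUnit, Pedigree
from .phasing import PhaseResult, phase_event, phase_results_table
from .sim import FamilySim, SimResult

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    events: list[DeNovoEvent]
    denominators: list[TrioDenominator]
    filter_results: dict[str, FilterResult]   # unit_id -> FilterResult
    phase_results: list[PhaseResult] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def validated(self) -> list[DeNovoEvent]:
        return [e for e in self.events if e.status is Status.VALIDATED]

    def status_counts(self) -> dict[str, int]:
        return dict(Counter(e.status.value for e in self.events))


def analyze_families(
    catalog: Catalog,
    pedigree: Pedigree,
    unit_callsets: Sequence[tuple[FamilyUnit, CallSet]],
    cfg: FilterConfig = FilterConfig(),
    segdup_intervals=None,
    min_carriers: int = 2,
    min_support_reads: int = 10,
) -> PipelineResult:
    """Filter calls, build denominators and call de novo events per family."""
    events: list[DeNovoEvent] = []
    denominators: list[TrioDenominator] = []
    filter_results: dict[str, FilterResult] = {}
    for unit, callset in unit_callsets:
        fr = filter_family(callset, pedigree, unit, cfg, segdup_intervals)
        filter_results[unit.unit_id] = fr
        denominators.extend(fr.trios)
        events.extend(
            call_family(
                callset, pedigree, unit, fr, cfg,
                min_carriers=min_carriers, min_support_reads=min_support_reads,
            )
        )
    result = PipelineResult(
        events=events, denominators=denominators, filter_results=filter_results
    )
    result.manifest = {
        "n_loci": len(catalog),
        "n_family_units": len(unit_callsets),
        "n_trios": len(denominators),
        "n_candidate_events": len(events),
        "status_counts": result.status_counts(),
        "n_validated": len(result.validated),
    }
    return result


def sim_unit_callsets(
    sim: SimResult,
) -> list[tuple[FamilyUnit, CallSet]]:
    """Pair each pedigree family unit with its simulated CallSet."""
    by_family: dict[str, FamilySim] = {f.family_id: f for f in sim.families}
    pairs = []
    for unit in sim.pedigree.family_units():
        fam = by_family.get(unit.family_id)
        if fam is None:
            logger.warning("no simulated calls for unit %s", unit.unit_id)
            continue
        pairs.append((unit, fam.callset))
    return pairs


def analyze_sim(
    sim: SimResult,
    cfg: FilterConfig = FilterConfig(),
    min_carriers: int = 2,
    min_support_reads: int = 10,
) -> PipelineResult:
    return analyze_families(
        sim.catalog, sim.pedigree, sim_unit_callsets(sim), cfg,
        min_carriers=min_carriers, min_support_reads=min_support_reads,
    )


def analyze_sim_streaming(
    sim_cfg,
    cfg: FilterConfig = FilterConfig(),
    min_carriers: int = 2,
    min_support_reads: int = 10,
):
    """Simulate and analyze one family at a time, discarding each family's
    call matrices after use.  Behaves like ``analyze_sim(simulate(cfg))``
    (identical random stream) but with constant memory, which matters for
    large locus-count calibration runs.

    Returns (catalog, PipelineResult); filter results are not retained.
    """
    import numpy as np

    from .sim import iter_families, simulate_catalog

    sim_cfg.validate()
    rng = np.random.default_rng(sim_cfg.seed)
    catalog = simulate_catalog(sim_cfg, rng)
    events: list[DeNovoEvent] = []
    denominators: list[TrioDenominator] = []
    n_units = 0
    for fam in iter_families(sim_cfg, catalog, rng):
        ped = Pedigree(fam.individuals)
        for unit in ped.family_units():
            n_units += 1
            fr = filter_family(fam.callset, ped, unit, cfg)
            denominators.extend(fr.trios)
            events.extend(
                call_family(
                    fam.callset, ped, unit, fr, cfg,
                    min_carriers=min_carriers,
                    min_support_reads=min_support_reads,
                )
            )
    result = PipelineResult(
        events=events, denominators=denominators, filter_results={}
    )
    result.manifest = {
        "n_loci": len(catalog),
        "n_family_units": n_units,
        "n_trios": len(denominators),
        "n_candidate_events": len(events),
        "status_counts": result.status_counts(),
        "n_validated": len(result.validated),
    }
    return catalog, result


def phase_sim_events(
    sim: SimResult,
    result: PipelineResult,
    uss_threshold: float = 10.0,
    window_grid_kb=None,
) -> list[PhaseResult]:
    """Phase every validated event of a simulated cohort to its grandparent
    of origin, using the per-locus marker blocks."""
    from .phasing import DEFAULT_WINDOW_GRID_KB

    grid = window_grid_kb or DEFAULT_WINDOW_GRID_KB
    by_sample: dict[str, FamilySim] = {}
    for fam in sim.families:
        for s in fam.callset.samples:
            by_sample[s] = fam
    units = {u.family_id: u for u in sim.pedigree.family_units()}
    phase_results = []
    for event in result.validated:
        fam = by_sample[event.carrier]
        unit = units[fam.family_id]
        li = fam.callset.locus_index[event.locus.key]
        block = fam.marker_blocks.get(li)
        if block is None:
            logger.warning("no markers for locus %d in %s; event unphaseable",
                           li, fam.family_id)
            continue
        fr = result.filter_results[unit.unit_id]
        carrier_children = []
        for child in unit.children:
            j = fam.callset.sample_index.get(child.iid)
            if j is None or not fr.pass_calls[li, j]:
                continue
            call = fam.callset.call(li, child.iid)
            if event.denovo_allele in call.alleles():
                carrier_children.append(child.iid)
        gf, gm = sim.pedigree.parents_of(event.carrier)
        donor_calls = {
            gp.iid: fam.callset.call(li, gp.iid) for gp in (gf, gm) if gp is not None
        }
        phase_results.append(
            phase_event(
                event, block, sim.pedigree, unit, carrier_children,
                donor_calls=donor_calls, window_grid_kb=grid,
                uss_threshold=uss_threshold,
            )
        )
    result.phase_results = phase_results
    result.manifest["n_phaseable"] = len(phase_results)
    result.manifest["n_phase_resolved"] = sum(1 for r in phase_results if r.resolved)
    result.manifest["n_size_resolved"] = sum(
        1 for r in phase_results if r.step_flag in ("step", "within_unit_indel")
    )
    return phase_results


def phase_marker_events(
    pedigree: Pedigree,
    unit_callsets: Sequence[tuple[FamilyUnit, CallSet]],
    markers,
    result: PipelineResult,
    uss_threshold: float = 10.0,
    window_grid_kb=None,
    half_width_kb: float = 300.0,
) -> list[PhaseResult]:
    """Phase validated events from file-loaded data (a MarkerSet instead of
    per-family marker blocks)."""
    from .phasing import DEFAULT_WINDOW_GRID_KB

    grid = window_grid_kb or DEFAULT_WINDOW_GRID_KB
    by_carrier: dict[str, tuple[FamilyUnit, CallSet]] = {}
    for unit, callset in unit_callsets:
        for parent in pedigree.analyzable_parents(unit):
            by_carrier[parent.iid] = (unit, callset)
    phase_results = []
    for event in result.validated:
        unit, callset = by_carrier[event.carrier]
        li = callset.locus_index[event.locus.key]
        block = markers.block(event.locus.chrom, event.locus.start, half_width_kb)
        if block.n_sites == 0:
            logger.warning("no markers near %s:%d; event unphaseable",
                           event.locus.chrom, event.locus.start)
            continue
        fr = result.filter_results[unit.unit_id]
        carrier_children = []
        for child in unit.children:
            j = callset.sample_index.get(child.iid)
            if j is None or not fr.pass_calls[li, j]:
                continue
            if event.denovo_allele in callset.call(li, child.iid).alleles():
                carrier_children.append(child.iid)
        gf, gm = pedigree.parents_of(event.carrier)
        donor_calls = {
            gp.iid: callset.call(li, gp.iid)
            for gp in (gf, gm)
            if gp is not None and callset.sample_index.get(gp.iid) is not None
        }
        phase_results.append(
            phase_event(
                event, block, pedigree, unit, carrier_children,
                donor_calls=donor_calls, window_grid_kb=grid,
                uss_threshold=uss_threshold,
            )
        )
    result.phase_results = phase_results
    result.manifest["n_phaseable"] = len(phase_results)
    result.manifest["n_phase_resolved"] = sum(1 for r in phase_results if r.resolved)
    result.manifest["n_size_resolved"] = sum(
        1 for r in phase_results if r.step_flag in ("step", "within_unit_indel")
    )
    return phase_results


def run_all_sim(
    sim: SimResult,
    cfg: FilterConfig = FilterConfig(),
    uss_threshold: float = 10.0,
) -> PipelineResult:
    """Full pipeline on a simulated cohort (markers required for phasing)."""
    result = analyze_sim(sim, cfg)
    if any(fam.marker_blocks for fam in sim.families):
        phase_sim_events(sim, result, uss_threshold=uss_threshold)
    return result


def write_result_tables(result: PipelineResult, outdir) -> dict[str, str]:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    events_path = outdir / "denovo_events.tsv"
    events_table(result.events).to_csv(events_path, sep="\t", index=False)
    paths["events"] = str(events_path)
    denom_path = outdir / "trio_denominators.tsv"
    pd.DataFrame(
        [
            {"trio_id": d.trio_id, "parent": d.parent,
             "grandfather": d.grandfather, "grandmother": d.grandmother,
             "n_loci_pass": d.n_loci_pass}
            for d in result.denominators
        ]
    ).to_csv(denom_path, sep="\t", index=False)
    paths["denominators"] = str(denom_path)
    if result.phase_results:
        phase_path = outdir / "phase_results.tsv"
        phase_results_table(result.phase_results).to_csv(
            phase_path, sep="\t", index=False
        )
        paths["phase"] = str(phase_path)
    return paths
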