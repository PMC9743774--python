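"""De novo STR mutation detection and transmission validation.

A candidate de novo allele is an allele of a mid-generation (G2) individual
whose bp-length deviation matches neither allele of either of its parents
(G1).  Candidates are validated against the third generation: the allele
must be transmitted to at least two genotyped grandchildren, the other G2
parent must be genotyped and must not carry the same allele, and at least
ten reads must support the de novo allele in the carrier.

With nine children, the chance a real heterozygous de novo allele reaches
fewer than two of them under Mendelian transmission is 10/512 = 0.0195 —
the binomial false-negative model used to correct rate estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .catalog import StrLocus
from .pedio import CallSet, FamilyUnit, Pedigree, StrCall
from .filtering import FilterConfig, FilterResult

logger = logging.getLogger(__name__)


class Status(str, Enum):
    CANDIDATE = "candidate"
    VALIDATED = "validated"
    REJECTED_UNTRANSMITTED = "rejected_untransmitted"
    REJECTED_SHARED_OTHER_PARENT = "rejected_shared_other_parent"
    REJECTED_MISSING_OTHER_PARENT = "rejected_missing_other_parent"
    REJECTED_LOW_SUPPORT = "rejected_low_support"


@dataclass(frozen=True)
class DeNovoEvent:
    locus: StrLocus
    carrier: str
    carrier_sex: int
    denovo_allele: int
    carrier_other_allele: int
    father_gt: tuple[int, int]
    mother_gt: tuple[int, int]
    trio_id: str
    status: Status = Status.CANDIDATE
    n_g3_carriers: int = 0
    n_g3_genotyped: int = 0
    support_reads: int = 0
    support_is_per_allele: bool = True
    homozygous_denovo: bool = False

    def __post_init__(self) -> None:
        parental = set(self.father_gt) | set(self.mother_gt)
        assert self.denovo_allele not in parental, "de novo allele present in a parent"
        if self.status is Status.VALIDATED:
            assert self.n_g3_carriers >= 2 and self.support_reads >= 10


def detect_candidates(
    child: StrCall,
    father: StrCall,
    mother: StrCall,
    trio_id: str = "",
    carrier_sex: int = 0,
) -> list[DeNovoEvent]:
    """Compare a G2 genotype with its parents and emit 0-2 candidate events.

    An allele is a candidate iff its deviation equals no parental allele;
    Mendelian consistency is therefore assessed per allele against the pooled
    parental alleles (an allele matching any parent is never a candidate).
    A homozygous de novo genotype yields a single flagged event.  Missing
    genotypes in the trio yield no candidates.
    """
    if child.is_missing or father.is_missing or mother.is_missing:
        return []
    parental = father.alleles() | mother.alleles()
    c1, c2 = child.gt
    events = []
    homozygous = c1 == c2
    novel = [c1] if homozygous else [c1, c2]
    for allele in novel:
        if allele in parental:
            continue
        other = c2 if allele == c1 else c1
        if homozygous:
            other = allele
        support, per_allele = child.support_for(allele)
        if not per_allele:
            logger.debug(
                "%s %s: per-allele depth unavailable, using total depth",
                child.sample_id, child.locus.key,
            )
        events.append(
            DeNovoEvent(
                locus=child.locus,
                carrier=child.sample_id,
                carrier_sex=carrier_sex,
                denovo_allele=allele,
                carrier_other_allele=other,
                father_gt=tuple(father.gt),
                mother_gt=tuple(mother.gt),
                trio_id=trio_id,
                support_reads=support,
                support_is_per_allele=per_allele,
                homozygous_denovo=homozygous,
            )
        )
    return events


def validate_transmission(
    event: DeNovoEvent,
    g3_calls: Sequence[StrCall],
    partner_call: StrCall,
    min_carriers: int = 2,
    min_support_reads: int = 10,
) -> DeNovoEvent:
    """Update a candidate's status using the third generation and the partner.

    ``g3_calls`` should contain only children whose calls passed quality
    filters; failing/missing children count toward neither carriers nor the
    genotyped denominator.
    """
    if event.status is not Status.CANDIDATE:
        raise ValueError(f"event already has status {event.status}")
    genotyped = [c for c in g3_calls if not c.is_missing]
    carriers = [c for c in genotyped if event.denovo_allele in c.alleles()]
    updated = replace(
        event, n_g3_carriers=len(carriers), n_g3_genotyped=len(genotyped)
    )
    if partner_call.is_missing:
        return replace(updated, status=Status.REJECTED_MISSING_OTHER_PARENT)
    if event.denovo_allele in partner_call.alleles():
        return replace(updated, status=Status.REJECTED_SHARED_OTHER_PARENT)
    if len(genotyped) == 0:
        logger.warning(
            "no genotyped children for event at %s in %s",
            event.locus.key, event.carrier,
        )
        return replace(updated, status=Status.REJECTED_UNTRANSMITTED)
    if len(carriers) < min_carriers:
        return replace(updated, status=Status.REJECTED_UNTRANSMITTED)
    if event.support_reads < min_support_reads:
        return replace(updated, status=Status.REJECTED_LOW_SUPPORT)
    return replace(updated, status=Status.VALIDATED)


def false_negative_rate(n_children: int, min_carriers: int = 2) -> float:
    """P(a heterozygous de novo allele reaches < ``min_carriers`` of
    ``n_children``) under independent Mendelian transmission at 1/2."""
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    if min_carriers > n_children + 1:
        raise ValueError("min_carriers cannot exceed n_children + 1")
    return float(binom.cdf(min_carriers - 1, n_children, 0.5))


def expected_false_negatives(n_putative: int, fn_rate: float) -> tuple[float, int]:
    """Expected number of true mutations lost to the transmission filter.

    Returns the unrounded product and its integer part (a whole-event
    count: the expectation covers *at least* that many missed mutations).
    """
    if n_putative < 0:
        raise ValueError("n_putative must be >= 0")
    value = n_putative * fn_rate
    return value, int(value)


def concordance(
    calls_a: Iterable[tuple[int, int] | None],
    calls_b: Iterable[tuple[int, int] | None],
) -> tuple[int, int, float]:
    """Genotype concordance between two call sets.

    Genotypes are compared as unordered allele pairs; returns
    (matched, total, percentage to 2 decimals).
    """
    matched = total = 0
    for a, b in zip(calls_a, calls_b, strict=True):
        total += 1
        if a is not None and b is not None and sorted(a) == sorted(b):
            matched += 1
    if total == 0:
        raise ValueError("no genotype pairs to compare")
    return matched, total, round(100.0 * matched / total, 2)


# ---------------------------------------------------------------------------
# Family-level calling
# ---------------------------------------------------------------------------


def call_family(
    callset: CallSet,
    pedigree: Pedigree,
    unit: FamilyUnit,
    filter_result: FilterResult,
    cfg: FilterConfig = FilterConfig(),
    min_carriers: int = 2,
    min_support_reads: int = 10,
) -> list[DeNovoEvent]:
    """Detect and validate de novo events across all loci of one family unit.

    Loci are pre-screened with a vectorised Mendelian check (a candidate can
    only exist where some child allele differs from all four grandparental
    alleles), then confirmed with the per-call logic.
    """
    passes = filter_result.pass_calls
    events: list[DeNovoEvent] = []
    for parent in pedigree.analyzable_parents(unit):
        gf, gm = pedigree.parents_of(parent.iid)
        trio = filter_result.trio(parent.iid)
        jc = callset.sample_index.get(parent.iid)
        jf = callset.sample_index.get(gf.iid)
        jm = callset.sample_index.get(gm.iid)
        if jc is None or jf is None or jm is None:
            continue
        trio_mask = trio.pass_mask
        c1, c2 = callset.a1[:, jc], callset.a2[:, jc]
        parental = (
            callset.a1[:, jf], callset.a2[:, jf],
            callset.a1[:, jm], callset.a2[:, jm],
        )
        novel1 = np.ones(len(callset.loci), dtype=bool)
        novel2 = np.ones(len(callset.loci), dtype=bool)
        for pa in parental:
            novel1 &= c1 != pa
            novel2 &= c2 != pa
        screen = trio_mask & (novel1 | novel2)
        partner = unit.partner_of(parent.iid)
        jp = callset.sample_index.get(partner.iid)
        for i in np.nonzero(screen)[0]:
            child_call = callset.call(int(i), parent.iid)
            cands = detect_candidates(
                child_call,
                callset.call(int(i), gf.iid),
                callset.call(int(i), gm.iid),
                trio_id=trio.trio_id,
                carrier_sex=parent.sex,
            )
            if not cands:
                continue
            partner_call = (
                callset.call(int(i), partner.iid)
                if jp is not None
                else StrCall(sample_id=partner.iid, locus=callset.loci[i], gt=None)
            )
            if jp is not None and not passes[i, jp]:
                partner_call = StrCall(
                    sample_id=partner.iid, locus=callset.loci[i], gt=None
                )
            g3_calls = []
            for child in unit.children:
                jk = callset.sample_index.get(child.iid)
                if jk is None or not passes[i, jk]:
                    continue
                g3_calls.append(callset.call(int(i), child.iid))
            for ev in cands:
                events.append(
                    validate_transmission(
                        ev, g3_calls, partner_call,
                        min_carriers=min_carriers,
                        min_support_reads=min_support_reads,
                    )
                )
    return events


def events_table(events: Iterable[DeNovoEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "chrom": ev.locus.chrom,
                "start": ev.locus.start,
                "end": ev.locus.end,
                "period": ev.locus.period,
                "motif": ev.locus.motif,
                "carrier": ev.carrier,
                "carrier_sex": ev.carrier_sex,
                "trio_id": ev.trio_id,
                "denovo_allele": ev.denovo_allele,
                "carrier_other_allele": ev.carrier_other_allele,
                "father_gt": f"{ev.father_gt[0]}|{ev.father_gt[1]}",
                "mother_gt": f"{ev.mother_gt[0]}|{ev.mother_gt[1]}",
                "status": ev.status.value,
                "n_g3_carriers": ev.n_g3_carriers,
                "n_g3_genotyped": ev.n_g3_genotyped,
                "support_reads": ev.support_reads,
                "support_is_per_allele": ev.support_is_per_allele,
                "homozygous_denovo": ev.homozygous_denovo,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "period", "motif", "carrier", "carrier_sex",
            "trio_id", "denovo_allele", "carrier_other_allele", "father_gt",
            "mother_gt", "status", "n_g3_carriers", "n_g3_genotyped",
            "support_reads", "support_is_per_allele", "homozygous_denovo",
        ],
    )
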