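"""Grandparent-of-origin phasing of de novo STR alleles.

A de novo allele cannot be phased directly — it is, by construction, a
misinherited allele.  Instead the flanking-marker haplotype co-transmitted
with it is reconstructed from the third generation:

1. every family trio is phased by exact Mendelian logic (a heterozygous
   site is assigned a parental origin whenever only one assignment of the
   child's alleles to the parents is consistent; sites where all three
   members are heterozygous are uninformative and dropped);
2. for each grandchild carrying the de novo allele, the haplotype inherited
   from the carrier parent is extracted, and a per-site majority consensus
   is built over those haplotypes (ties unresolved);
3. the consensus is compared with the four phased grandparental haplotypes
   of the carrier's own parents; the match likelihood of each is the
   fraction of mutually resolved sites that agree.

The gap between the best and second-best likelihood, on a 0-100 scale, is
the unique solution score (uss); an assignment is accepted when uss reaches
a threshold (default 10).  Because regional haplotypes can be locally
similar, the comparison is run over a grid of window half-widths (10-300 kb)
and the window with the largest uss wins (smallest window on ties).

No population LD model or imputation is used: the three-generation
structure makes most sites decisive, and unresolved sites are simply
excluded from likelihood denominators.  Recombination inside a window is
not modelled; a recombined window manifests as depressed likelihoods and is
handled by the multi-window scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .denovo import DeNovoEvent
from .pedio import FEMALE, MALE, FamilyUnit, MarkerBlock, Pedigree, StrCall

DEFAULT_WINDOW_GRID_KB: tuple[int, ...] = tuple(range(10, 310, 10))
DEFAULT_USS_THRESHOLD = 10.0


class PhasingError(ValueError):
    pass


@dataclass
class TrioPhase:
    """Per-site parental origin of a child's alleles (-1 = unresolved)."""

    paternal: np.ndarray
    maternal: np.ndarray
    inconsistent: np.ndarray  # Mendelian-violating sites, excluded from matching

    @property
    def n_resolved(self) -> int:
        return int((self.paternal >= 0).sum())


def _carries(allele: np.ndarray, geno: np.ndarray) -> np.ndarray:
    return (geno[:, 0] == allele) | (geno[:, 1] == allele)


def phase_trio(block: MarkerBlock, child: str, father: str, mother: str) -> TrioPhase:
    """Phase a child's biallelic genotypes against its two parents.

    A site is resolved when exactly one assignment of the child's alleles to
    (paternal, maternal) is Mendelian-consistent; the classic all-three-
    heterozygous configuration is unresolved, and inconsistent sites are
    marked and excluded.
    """
    gc, gf, gm = block.geno(child), block.geno(father), block.geno(mother)
    c0, c1 = gc[:, 0], gc[:, 1]
    missing = (gc < 0).any(axis=1) | (gf < 0).any(axis=1) | (gm < 0).any(axis=1)
    v1 = _carries(c0, gf) & _carries(c1, gm)
    v2 = _carries(c1, gf) & _carries(c0, gm)
    same = c0 == c1
    ok = ~missing
    inconsistent = ok & ~v1 & ~v2
    resolved = ok & ((v1 & ~v2) | (v2 & ~v1) | (same & v1))
    n = block.n_sites
    paternal = np.full(n, -1, dtype=np.int8)
    maternal = np.full(n, -1, dtype=np.int8)
    use1 = resolved & v1
    use2 = resolved & ~v1 & v2
    paternal[use1], maternal[use1] = c0[use1], c1[use1]
    paternal[use2], maternal[use2] = c1[use2], c0[use2]
    return TrioPhase(paternal=paternal, maternal=maternal, inconsistent=inconsistent)


@dataclass
class GrandparentalHaplotypes:
    """The four phased haplotypes of the carrier's own parents.

    Rows are (grandfather transmitted, grandfather untransmitted,
    grandmother transmitted, grandmother untransmitted), where "transmitted"
    means the haplotype passed to the carrier parent; -1 marks sites whose
    phase could not be fixed.
    """

    haplotypes: np.ndarray  # (4, n_sites)
    owners: tuple[str, str, str, str]
    owner_sexes: tuple[int, int, int, int]


def grandparental_haplotypes(
    block: MarkerBlock,
    carrier: str,
    grandfather: str,
    grandmother: str,
    grandfather_sex: int = MALE,
    grandmother_sex: int = FEMALE,
) -> GrandparentalHaplotypes:
    """Phase the four grandparental haplotypes via the carrier trio.

    Homozygous grandparental sites are trivially phased; heterozygous sites
    are phased wherever the carrier trio identifies which allele the
    grandparent transmitted.
    """
    tp = phase_trio(block, carrier, grandfather, grandmother)
    n = block.n_sites
    haps = np.full((4, n), -1, dtype=np.int8)
    for row, (gp, origin) in enumerate(
        [(grandfather, tp.paternal), (grandmother, tp.maternal)]
    ):
        g = block.geno(gp)
        present = (g >= 0).all(axis=1)
        hom = present & (g[:, 0] == g[:, 1])
        t, u = haps[2 * row], haps[2 * row + 1]
        t[hom] = g[hom, 0]
        u[hom] = g[hom, 0]
        het = present & (g[:, 0] != g[:, 1]) & (origin >= 0)
        t[het] = origin[het]
        u[het] = g[het, 0] + g[het, 1] - origin[het]  # the other biallelic allele
    return GrandparentalHaplotypes(
        haplotypes=haps,
        owners=(grandfather, grandfather, grandmother, grandmother),
        owner_sexes=(grandfather_sex, grandfather_sex, grandmother_sex, grandmother_sex),
    )


def transmitted_haplotype(
    block: MarkerBlock, child: str, unit: FamilyUnit, carrier: str
) -> np.ndarray:
    """The child's haplotype inherited from the carrier parent."""
    tp = phase_trio(block, child, unit.father.iid, unit.mother.iid)
    if carrier == unit.father.iid:
        return tp.paternal
    if carrier == unit.mother.iid:
        return tp.maternal
    raise PhasingError(f"{carrier} is not a parent of unit {unit.unit_id}")


def build_consensus(haplotypes: Sequence[np.ndarray]) -> np.ndarray:
    """Per-site majority vote across carrier-offspring haplotypes.

    Requires at least two contributing haplotypes (a validated event always
    has >= 2 carriers); ties and all-missing sites are unresolved (-1).
    """
    if len(haplotypes) < 2:
        raise PhasingError("consensus requires >= 2 carrier offspring haplotypes")
    stack = np.stack(haplotypes)
    votes1 = (stack == 1).sum(axis=0)
    votes0 = (stack == 0).sum(axis=0)
    consensus = np.full(stack.shape[1], -1, dtype=np.int8)
    consensus[votes1 > votes0] = 1
    consensus[votes0 > votes1] = 0
    return consensus


@dataclass
class WindowMatch:
    """Match likelihoods of the consensus against the 4 grandparental
    haplotypes within one window."""

    window_kb: float
    likelihoods: np.ndarray          # (4,), NaN where undefined
    n_sites: np.ndarray              # mutually resolved sites per haplotype
    best_index: int | None
    uss: float
    resolved: bool


def match_grandparents(
    consensus: np.ndarray,
    gp: GrandparentalHaplotypes,
    window_mask: np.ndarray | None = None,
    uss_threshold: float = DEFAULT_USS_THRESHOLD,
    window_kb: float = float("nan"),
) -> WindowMatch:
    """Score the consensus haplotype against each grandparental haplotype.

    Likelihood = matching mutually-resolved sites / mutually-resolved sites.
    uss = 100 x (best - second best) over haplotypes with a defined
    likelihood; with fewer than two defined likelihoods the window is
    unresolvable.
    """
    haps = gp.haplotypes
    mask = np.ones(haps.shape[1], dtype=bool) if window_mask is None else window_mask
    usable = (consensus >= 0)[None, :] & (haps >= 0) & mask[None, :]
    den = usable.sum(axis=1)
    num = (usable & (haps == consensus[None, :])).sum(axis=1)
    with np.errstate(invalid="ignore"):
        lik = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    defined = den > 0
    if defined.sum() < 2:
        return WindowMatch(window_kb, lik, den, None, float("nan"), False)
    vals = lik[defined]
    order = np.argsort(vals)[::-1]
    best_val, second_val = vals[order[0]], vals[order[1]]
    uss = 100.0 * (best_val - second_val)
    best_index = int(np.flatnonzero(defined & (lik == best_val))[0])
    resolved = bool(uss >= uss_threshold)
    return WindowMatch(window_kb, lik, den, best_index, float(uss), resolved)


@dataclass
class PhaseResult:
    """Final origin assignment for one de novo event."""

    event: DeNovoEvent
    window_kb: float
    likelihoods: tuple[float, float, float, float]
    best_grandparent: str | None
    donor_sex: int | None
    uss: float
    resolved: bool
    phaseable: bool = True
    original_allele: int | None = None
    size_change_bp: int | None = None
    steps: int | None = None
    step_flag: str = "unresolved"  # step | within_unit_indel | unresolved


def size_change(
    event: DeNovoEvent, donor_call: StrCall
) -> tuple[int | None, int | None, int | None, str]:
    """Signed bp change and step count between original and de novo allele.

    The original allele is the one carried on the donor grandparent's
    transmitted haplotype; it is identifiable only when the donor is
    homozygous at the STR, otherwise the size change is unresolved.  A bp
    change that is not a whole number of repeat units is flagged as a
    within-unit indel (no step count).
    """
    if donor_call.is_missing:
        return None, None, None, "unresolved"
    x, y = donor_call.gt
    if x != y:
        return None, None, None, "unresolved"
    original = x
    delta = event.denovo_allele - original
    if delta == 0:
        raise PhasingError(
            "de novo allele equals the donor allele; contradicts de novo status"
        )
    period = event.locus.period
    if abs(delta) % period == 0:
        return original, delta, abs(delta) // period, "step"
    return original, delta, None, "within_unit_indel"


def phase_event(
    event: DeNovoEvent,
    block: MarkerBlock,
    pedigree: Pedigree,
    unit: FamilyUnit,
    carrier_child_ids: Sequence[str],
    donor_calls: Mapping[str, StrCall] | None = None,
    window_grid_kb: Iterable[float] = DEFAULT_WINDOW_GRID_KB,
    uss_threshold: float = DEFAULT_USS_THRESHOLD,
) -> PhaseResult:
    """Run the full per-event origin scan.

    ``carrier_child_ids`` are the genotyped grandchildren carrying the de
    novo allele; ``donor_calls`` maps the carrier's parents to their STR
    calls (used for the size change once a donor is identified).
    """
    carrier = pedigree[event.carrier]
    gf, gm = pedigree.parents_of(carrier.iid)
    if gf is None or gm is None:
        raise PhasingError(f"carrier {carrier.iid} lacks genotyped parents")
    gp = grandparental_haplotypes(
        block, carrier.iid, gf.iid, gm.iid, gf.sex or MALE, gm.sex or FEMALE
    )
    haps = [transmitted_haplotype(block, c, unit, carrier.iid) for c in carrier_child_ids]
    consensus = build_consensus(haps)

    best_resolved: WindowMatch | None = None
    best_any: WindowMatch | None = None
    for w in sorted(window_grid_kb):
        m = match_grandparents(consensus, gp, block.window_mask(w), uss_threshold, w)
        if m.best_index is None:
            continue
        if best_any is None or m.uss > best_any.uss:
            best_any = m
        if m.resolved and (best_resolved is None or m.uss > best_resolved.uss):
            best_resolved = m

    chosen = best_resolved or best_any
    if chosen is None:
        return PhaseResult(
            event=event, window_kb=float("nan"),
            likelihoods=(float("nan"),) * 4, best_grandparent=None,
            donor_sex=None, uss=float("nan"), resolved=False, phaseable=False,
        )
    donor = gp.owners[chosen.best_index]
    donor_sex = gp.owner_sexes[chosen.best_index]
    result = PhaseResult(
        event=event,
        window_kb=chosen.window_kb,
        likelihoods=tuple(float(x) for x in chosen.likelihoods),
        best_grandparent=donor,
        donor_sex=donor_sex,
        uss=chosen.uss,
        resolved=chosen.resolved,
    )
    if chosen.resolved and donor_calls is not None and donor in donor_calls:
        original, delta, steps, flag = size_change(event, donor_calls[donor])
        result.original_allele = original
        result.size_change_bp = delta
        result.steps = steps
        result.step_flag = flag
    return result


def phase_results_table(results: Iterable[PhaseResult]):
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.event.locus.chrom,
                "start": r.event.locus.start,
                "carrier": r.event.carrier,
                "denovo_allele": r.event.denovo_allele,
                "window_kb": r.window_kb,
                "lik_gf_t": r.likelihoods[0],
                "lik_gf_u": r.likelihoods[1],
                "lik_gm_t": r.likelihoods[2],
                "lik_gm_u": r.likelihoods[3],
                "uss": r.uss,
                "donor": r.best_grandparent,
                "donor_sex": r.donor_sex,
                "resolved": r.resolved,
                "phaseable": r.phaseable,
                "original_allele": r.original_allele,
                "size_change_bp": r.size_change_bp,
                "steps": r.steps,
                "step_flag": r.step_flag,
            }
        )
    return pd.DataFrame(rows)
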