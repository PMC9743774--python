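"""Three-generation pedigree simulator for STR de novo mutation analysis.

Families mirror the study design: two grandparental couples (G1), one
mid-generation couple (G2) and nine grandchildren (G3) by default.  Diploid
STR allele lengths evolve under a generalized stepwise mutation model: at
each meiosis a locus mutates with its per-generation rate (halved per
meiosis), the change is an integer number of repeat units with a
single-step-dominant geometric tail (P(1 step) = 0.9 by default) and a
slight expansion bias (0.55), reflecting the observed mutation spectrum.
Mutations are placed on meioses into both G2 and G3 — only G2 events are
called downstream, but G3 mutations exercise the shared/untransmitted edge
cases realistically.

Founder alleles are drawn from a symmetric, concentrated distribution of
step offsets around the reference length (stationarity is not enforced; the
pipeline never assumes it).  A "spaced" founder lattice (alleles several
repeat units apart) is available for rate-calibration studies in which
chance coincidence between a de novo allele and a grandparental or partner
allele must not confound recovery of the configured rate.

Flanking biallelic markers co-transmit with the STR haplotype within a
window (no recombination inside a window by default), providing the signal
for grandparent-of-origin phasing; per-allele genotyping error is
configurable.  Call-level noise (posterior quality, depth, stutter and
flanking-indel fractions, per-allele depths) is applied last.

Every simulated mutation is recorded in a truth table consistent with the
emitted genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, StrLocus, write_catalog
from .pedio import (
    FEMALE,
    MALE,
    CallSet,
    Individual,
    MarkerBlock,
    MarkerSet,
    Pedigree,
    write_marker_vcf,
    write_ped,
    write_str_vcf,
)

#: Per-generation, per-locus de novo rates by motif length.  Mono and di
#: follow the empirical estimates (6.82e-5, 7.88e-5); the longer motifs
#: decrease toward the hexanucleotide estimate (9.99e-6) with tri slightly
#: below tetra, matching the observed exception to the monotone trend.
DEFAULT_RATES: dict[int, float] = {
    1: 6.82e-5,
    2: 7.88e-5,
    3: 3.0e-5,
    4: 3.9e-5,
    5: 2.0e-5,
    6: 1.0e-5,
}

DEFAULT_LOCI_PER_PERIOD: dict[int, int] = {1: 40, 2: 40, 3: 30, 4: 30, 5: 20, 6: 20}

ROLES = ("gf1", "gm1", "gf2", "gm2", "fa", "mo")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort (seed is mandatory)."""

    seed: int
    n_families: int = 5
    n_children: int = 9
    loci_per_period: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LOCI_PER_PERIOD)
    )
    units_range: tuple[int, int] = (8, 20)
    perfect_fraction: float = 0.6
    mutation_rates: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    purity_rate_scaling: bool = False
    p_single_step: float = 0.9
    expansion_bias: float = 0.55
    founder_dist: str = "geometric"  # or "uniform"
    founder_geom_q: float = 0.4
    founder_allele_range: int = 8    # max |offset| in (spaced) repeat units
    founder_spacing_units: int = 1
    markers: bool = False
    marker_spacing_kb: float = 2.0
    marker_window_kb: float = 300.0
    marker_maf: float = 0.5
    marker_error: float = 0.0
    call_failure_rate: float = 0.0
    annotation_noise: bool = False
    mean_depth: int = 30

    def validate(self) -> None:
        problems = []
        if self.n_families < 1:
            problems.append("n_families must be >= 1")
        if self.n_children < 1:
            problems.append("n_children must be >= 1")
        for name in ("perfect_fraction", "expansion_bias", "p_single_step",
                     "marker_maf", "marker_error", "call_failure_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.p_single_step <= 1.0):
            problems.append("p_single_step must be in (0, 1]")
        for p, r in self.mutation_rates.items():
            if not (0.0 <= r <= 1.0):
                problems.append(f"mutation rate for period {p} outside [0, 1]")
        if self.founder_dist not in ("geometric", "uniform"):
            problems.append(f"unknown founder_dist {self.founder_dist!r}")
        if self.units_range[0] < 2 or self.units_range[0] > self.units_range[1]:
            problems.append("units_range must satisfy 2 <= lo <= hi")
        if self.founder_spacing_units < 1:
            problems.append("founder_spacing_units must be >= 1")
        if problems:
            raise SimConfigError("; ".join(problems))


@dataclass
class TruthRow:
    """One simulated mutation, exactly once, consistent with the genotypes."""

    family_id: str
    donor: str
    recipient: str
    meiosis: str               # "G1->G2" or "G2->G3"
    locus_index: int
    chrom: str
    start: int
    period: int
    original_allele: int
    denovo_allele: int
    change_bp: int
    n_child_carriers: int      # children inheriting the allele (G1->G2 only)
    child_carriers: tuple[str, ...] = ()


@dataclass
class FamilySim:
    family_id: str
    individuals: list[Individual]
    sample_ids: dict[str, str]          # role -> sample id
    callset: CallSet
    true_haplotypes: np.ndarray          # (n_samples, 2, L) true allele bp deviations
    g1_hap_choices: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    marker_blocks: dict[int, MarkerBlock] = field(default_factory=dict)
    true_marker_haps: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    truth: list[TruthRow] = field(default_factory=list)


@dataclass
class SimResult:
    config: SimConfig
    catalog: Catalog
    pedigree: Pedigree
    families: list[FamilySim]

    @property
    def truth(self) -> list[TruthRow]:
        return [row for fam in self.families for row in fam.truth]

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": t.family_id,
                "donor": t.donor,
                "recipient": t.recipient,
                "meiosis": t.meiosis,
                "locus_index": t.locus_index,
                "chrom": t.chrom,
                "start": t.start,
                "period": t.period,
                "original_allele": t.original_allele,
                "denovo_allele": t.denovo_allele,
                "change_bp": t.change_bp,
                "n_child_carriers": t.n_child_carriers,
                "child_carriers": ",".join(t.child_carriers),
            }
            for t in self.truth
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "family_id", "donor", "recipient", "meiosis", "locus_index",
                "chrom", "start", "period", "original_allele", "denovo_allele",
                "change_bp", "n_child_carriers", "child_carriers",
            ],
        )


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------


def _random_primitive_motif(period: int, rng: np.random.Generator) -> str:
    bases = "ACGT"
    while True:
        motif = "".join(bases[i] for i in rng.integers(0, 4, period))
        # reject motifs that are repetitions of a shorter unit (e.g. "ATAT")
        primitive = all(
            motif != motif[:d] * (period // d)
            for d in range(1, period)
            if period % d == 0
        )
        if primitive:
            return motif


def simulate_catalog(cfg: SimConfig, rng: np.random.Generator) -> Catalog:
    """Random STR catalog with reference sequences of controlled purity."""
    loci: list[StrLocus] = []
    sequences: dict[tuple[str, int], str] = {}
    idx = 0
    bases = "ACGT"
    for period in sorted(cfg.loci_per_period):
        for _ in range(cfg.loci_per_period[period]):
            motif = _random_primitive_motif(period, rng)
            n_units = int(rng.integers(cfg.units_range[0], cfg.units_range[1] + 1))
            seq = list(motif * n_units)
            if rng.random() >= cfg.perfect_fraction and len(seq) > 2:
                # interrupt the array with 1-2 interior substitutions
                for _ in range(int(rng.integers(1, 3))):
                    pos = int(rng.integers(1, len(seq) - 1))
                    old = seq[pos]
                    seq[pos] = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4]
            sequence = "".join(seq)
            chrom = f"chr{1 + idx // 200}"
            start = 1_000_000 + (idx % 200) * 1_000_000
            locus = StrLocus(chrom, start, start + len(sequence), period, motif)
            loci.append(locus)
            sequences[locus.key] = sequence
            idx += 1
    return Catalog(loci=loci, sequences=sequences)


def _locus_rates(cfg: SimConfig, catalog: Catalog) -> np.ndarray:
    """Per-generation rate per locus, optionally scaled by pure-run length."""
    rates = np.array([cfg.mutation_rates.get(l.period, 0.0) for l in catalog])
    if cfg.purity_rate_scaling:
        runs = np.array(
            [catalog.purity(l).longest_pure_run for l in catalog], dtype=float
        )
        rates = rates * runs / runs.mean()
    return np.clip(rates, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


def _draw_founder_alleles(cfg: SimConfig, periods: np.ndarray, size: tuple,
                          rng: np.random.Generator) -> np.ndarray:
    """Founder allele bp deviations, drawn as step offsets x period.

    Offsets are non-negative (the catalog reference is the shortest common
    allele), so every allele remains representable as a sequence; only de
    novo contractions can dip below the reference length.
    """
    r = cfg.founder_allele_range
    if cfg.founder_dist == "uniform":
        steps = rng.integers(0, r + 1, size=size) * cfg.founder_spacing_units
    else:
        offsets = np.arange(0, r + 1)
        w = cfg.founder_geom_q ** offsets
        steps = rng.choice(offsets, size=size, p=w / w.sum()) * cfg.founder_spacing_units
    return (steps * periods).astype(np.int32)


def _meiosis(parent_haps: np.ndarray, rate_per_meiosis: np.ndarray,
             periods: np.ndarray, cfg: SimConfig, rng: np.random.Generator):
    """One gamete: inherited haplotype choice plus stepwise mutations.

    Returns (allele, hap_choice, mutated_mask, original_alleles_at_mutated).
    """
    L = parent_haps.shape[1]
    hap = rng.integers(0, 2, L, dtype=np.int8)
    allele = parent_haps[hap, np.arange(L)].copy()
    mut = rng.random(L) < rate_per_meiosis
    original = allele[mut].copy()
    if mut.any():
        k = int(mut.sum())
        steps = rng.geometric(cfg.p_single_step, size=k)
        sign = np.where(rng.random(k) < cfg.expansion_bias, 1, -1)
        allele[mut] = allele[mut] + sign * steps * periods[mut]
    return allele, hap, mut, original


def _child_ids(cfg: SimConfig) -> list[str]:
    return [f"c{k:02d}" for k in range(1, cfg.n_children + 1)]


def _simulate_family(
    cfg: SimConfig,
    catalog: Catalog,
    locus_rates: np.ndarray,
    fam: int,
    rng: np.random.Generator,
) -> FamilySim:
    fam_id = f"F{fam:03d}"
    periods = np.array([l.period for l in catalog])
    L = len(catalog)
    roles = list(ROLES) + _child_ids(cfg)
    sid = {role: f"{fam_id}_{role}" for role in roles}
    rate_m = locus_rates / 2.0  # per-meiosis

    founder = _draw_founder_alleles(cfg, periods, (4, 2, L), rng)
    haps: dict[str, np.ndarray] = {
        "gf1": founder[0], "gm1": founder[1], "gf2": founder[2], "gm2": founder[3]
    }
    hap_choices: dict[tuple[str, str], np.ndarray] = {}
    truth: list[TruthRow] = []

    def record(donor, recipient, meiosis, mut, original, allele):
        for j, i in enumerate(np.nonzero(mut)[0]):
            locus = catalog.loci[int(i)]
            truth.append(
                TruthRow(
                    family_id=fam_id,
                    donor=sid[donor],
                    recipient=sid[recipient],
                    meiosis=meiosis,
                    locus_index=int(i),
                    chrom=locus.chrom,
                    start=locus.start,
                    period=locus.period,
                    original_allele=int(original[j]),
                    denovo_allele=int(allele[int(i)]),
                    change_bp=int(allele[int(i)] - original[j]),
                    n_child_carriers=0,
                )
            )

    def gamete(parent_role, child_role):
        allele, hap, mut, original = _meiosis(haps[parent_role], rate_m, periods, cfg, rng)
        hap_choices[(parent_role, child_role)] = hap
        return allele, mut, original

    # G1 -> G2
    fa_pat, mut1, orig1 = gamete("gf1", "fa")
    fa_mat, mut2, orig2 = gamete("gm1", "fa")
    mo_pat, mut3, orig3 = gamete("gf2", "mo")
    mo_mat, mut4, orig4 = gamete("gm2", "mo")
    haps["fa"] = np.stack([fa_pat, fa_mat])
    haps["mo"] = np.stack([mo_pat, mo_mat])
    record("gf1", "fa", "G1->G2", mut1, orig1, fa_pat)
    record("gm1", "fa", "G1->G2", mut2, orig2, fa_mat)
    record("gf2", "mo", "G1->G2", mut3, orig3, mo_pat)
    record("gm2", "mo", "G1->G2", mut4, orig4, mo_mat)

    # G2 -> G3
    for child in _child_ids(cfg):
        c_pat, mutp, origp = gamete("fa", child)
        c_mat, mutm, origm = gamete("mo", child)
        haps[child] = np.stack([c_pat, c_mat])
        record("fa", child, "G2->G3", mutp, origp, c_pat)
        record("mo", child, "G2->G3", mutm, origm, c_mat)

    _count_carriers(truth, haps, hap_choices, sid, cfg)

    individuals = _family_individuals(fam_id, sid, cfg)
    callset = _build_callset(cfg, catalog, roles, sid, haps, rng)
    fam_sim = FamilySim(
        family_id=fam_id,
        individuals=individuals,
        sample_ids=sid,
        callset=callset,
        true_haplotypes=np.stack([haps[r] for r in roles]),
        g1_hap_choices={
            k: v for k, v in hap_choices.items() if k[1] in ("fa", "mo")
        },
        truth=truth,
    )
    if cfg.markers:
        _simulate_markers(cfg, catalog, fam_sim, haps, hap_choices, rng)
    return fam_sim


def _count_carriers(truth, haps, hap_choices, sid, cfg) -> None:
    """Children carrying each G1->G2 de novo allele via the carrier parent."""
    children = _child_ids(cfg)
    for row in truth:
        if row.meiosis != "G1->G2":
            continue
        recipient_role = [r for r, s in sid.items() if s == row.recipient][0]
        # allele landed on the recipient's paternal (gf-derived) or maternal hap
        hap_idx = 0 if row.donor.endswith(("gf1", "gf2")) else 1
        carriers = []
        for child in children:
            choice = hap_choices[(recipient_role, child)][row.locus_index]
            if choice != hap_idx:
                continue
            child_hap = 0 if recipient_role == "fa" else 1
            if haps[child][child_hap, row.locus_index] == row.denovo_allele:
                carriers.append(sid[child])
        row.n_child_carriers = len(carriers)
        row.child_carriers = tuple(carriers)


def _family_individuals(fam_id: str, sid: dict[str, str], cfg: SimConfig) -> list[Individual]:
    inds = [
        Individual(sid["gf1"], fam_id, None, None, MALE),
        Individual(sid["gm1"], fam_id, None, None, FEMALE),
        Individual(sid["gf2"], fam_id, None, None, MALE),
        Individual(sid["gm2"], fam_id, None, None, FEMALE),
        Individual(sid["fa"], fam_id, sid["gf1"], sid["gm1"], MALE),
        Individual(sid["mo"], fam_id, sid["gf2"], sid["gm2"], FEMALE),
    ]
    for k, child in enumerate(_child_ids(cfg)):
        inds.append(
            Individual(sid[child], fam_id, sid["fa"], sid["mo"],
                       MALE if k % 2 == 0 else FEMALE)
        )
    return inds


def _build_callset(cfg, catalog, roles, sid, haps, rng) -> CallSet:
    L = len(catalog)
    samples = [sid[r] for r in roles]
    cs = CallSet(catalog.loci, samples)
    depth0 = cfg.mean_depth
    h_all = np.stack([haps[r] for r in roles])  # (S, 2, L)
    cs.a1[:] = h_all[:, 0, :].T
    cs.a2[:] = h_all[:, 1, :].T
    hom = cs.a1 == cs.a2
    if cfg.annotation_noise:
        for j in range(len(roles)):
            cs.quality[:, j] = rng.uniform(0.92, 1.0, L)
            cs.depth[:, j] = np.maximum(rng.poisson(depth0, L), 1)
            cs.stutter[:, j] = rng.uniform(0.0, 0.1, L)
            cs.flank[:, j] = rng.uniform(0.0, 0.1, L)
            ad1 = rng.binomial(cs.depth[:, j], 0.5)
            cs.ad1[:, j] = np.where(hom[:, j], cs.depth[:, j], ad1)
            cs.ad2[:, j] = np.where(hom[:, j], 0, cs.depth[:, j] - ad1)
    else:
        cs.quality.fill(0.99)
        cs.depth.fill(depth0)
        cs.stutter.fill(0.01)
        cs.flank.fill(0.01)
        cs.ad1[:] = np.where(hom, depth0, depth0 // 2)
        cs.ad2[:] = np.where(hom, 0, depth0 - depth0 // 2)
    if cfg.call_failure_rate > 0:
        fail = rng.random((L, len(roles))) < cfg.call_failure_rate
        mode = rng.integers(0, 4, (L, len(roles)))
        cs.quality[fail & (mode == 0)] = rng.uniform(
            0.0, 0.9, int((fail & (mode == 0)).sum())
        )
        cs.stutter[fail & (mode == 1)] = rng.uniform(
            0.16, 0.5, int((fail & (mode == 1)).sum())
        )
        cs.depth[fail & (mode == 2)] = rng.integers(
            0, 10, int((fail & (mode == 2)).sum())
        )
        drop = fail & (mode == 3)
        cs.a1[drop] = -(10**6)
        cs.a2[drop] = -(10**6)
    return cs


def _marker_positions(cfg: SimConfig, locus: StrLocus) -> np.ndarray:
    spacing = int(cfg.marker_spacing_kb * 1000)
    half = int(cfg.marker_window_kb * 1000)
    center = locus.start
    left = np.arange(center - half, center, spacing)
    right = np.arange(center + spacing, center + half + 1, spacing)
    return np.concatenate([left, right])


def _simulate_markers(cfg, catalog, fam_sim: FamilySim, haps, hap_choices, rng) -> None:
    """Marker haplotypes co-transmitted with the STR at each locus window."""
    sid = fam_sim.sample_ids
    children = _child_ids(cfg)
    roles = list(ROLES) + children
    for li, locus in enumerate(catalog.loci):
        pos = _marker_positions(cfg, locus)
        S = len(pos)
        mhap: dict[str, np.ndarray] = {}
        for founder_role in ("gf1", "gm1", "gf2", "gm2"):
            mhap[founder_role] = (
                rng.random((2, S)) < cfg.marker_maf
            ).astype(np.int8)
        for parent_role, (p1, p2) in (("fa", ("gf1", "gm1")), ("mo", ("gf2", "gm2"))):
            h1 = hap_choices[(p1, parent_role)][li]
            h2 = hap_choices[(p2, parent_role)][li]
            mhap[parent_role] = np.stack([mhap[p1][h1], mhap[p2][h2]])
        for child in children:
            hp = hap_choices[("fa", child)][li]
            hm = hap_choices[("mo", child)][li]
            mhap[child] = np.stack([mhap["fa"][hp], mhap["mo"][hm]])
        genotypes = np.zeros((S, len(roles), 2), dtype=np.int8)
        for j, role in enumerate(roles):
            observed = mhap[role].T.copy()  # (S, 2)
            if cfg.marker_error > 0:
                flips = rng.random(observed.shape) < cfg.marker_error
                observed = np.where(flips, 1 - observed, observed)
            genotypes[:, j, :] = np.sort(observed, axis=1)  # unphased
        fam_sim.marker_blocks[li] = MarkerBlock(
            chrom=locus.chrom,
            positions=pos,
            samples=[sid[r] for r in roles],
            genotypes=genotypes,
            focal_pos=locus.start,
        )
        fam_sim.true_marker_haps[li] = {sid[r]: mhap[r] for r in roles}


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------


def iter_families(cfg: SimConfig, catalog: Catalog, rng: np.random.Generator):
    """Yield simulated families one at a time (constant-memory streaming).

    Consuming this generator with the rng produced from ``cfg.seed`` right
    after :func:`simulate_catalog` gives the same families as
    :func:`simulate`.
    """
    locus_rates = _locus_rates(cfg, catalog)
    for fam in range(cfg.n_families):
        yield _simulate_family(cfg, catalog, locus_rates, fam, rng)


def simulate(cfg: SimConfig) -> SimResult:
    """Simulate a cohort of independent three-generation families."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    catalog = simulate_catalog(cfg, rng)
    families = list(iter_families(cfg, catalog, rng))
    individuals = [ind for fam in families for ind in fam.individuals]
    return SimResult(config=cfg, catalog=catalog, pedigree=Pedigree(individuals),
                     families=families)


def implant_mutation(
    fam_sim: FamilySim,
    catalog: Catalog,
    locus_index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    carrier_role: str = "fa",
    donor_role: str | None = None,
    delta_bp: int | None = None,
    min_carriers: int | None = 2,
    shared_with_partner: bool = False,
    force_het_donor: bool = False,
    force_hom_donor: bool = False,
    max_redraws: int = 200,
) -> TruthRow:
    """Force one de novo mutation into an already-simulated (rate-0) family.

    The carrier's inherited allele at ``locus_index`` is replaced by a
    mutated value guaranteed distinct from every other allele in the family
    at that locus, children re-inherit it, and the call set, marker blocks
    and truth table are updated consistently.  Options construct the edge
    cases: sharing the allele with the partner, forcing a heterozygous
    donor (ambiguous size change) or a homozygous one (resolvable size
    change), an explicit non-unit ``delta_bp`` (within-unit indel), or a
    carrier-count requirement.
    """
    locus = catalog.loci[locus_index]
    sid = fam_sim.sample_ids
    roles = _role_order(fam_sim)
    cs = fam_sim.callset
    li = locus_index
    grandparents = ("gf1", "gm1") if carrier_role == "fa" else ("gf2", "gm2")
    if donor_role is None:
        donor_role = grandparents[int(rng.integers(0, 2))]
    donor_col = cs.sample_index[sid[donor_role]]
    if force_het_donor and force_hom_donor:
        raise SimConfigError("cannot force both a het and a hom donor")
    if force_hom_donor:
        if cs.a1[li, donor_col] != cs.a2[li, donor_col]:
            cs.a2[li, donor_col] = cs.a1[li, donor_col]
            fam_sim.true_haplotypes[roles.index(donor_role), 1, li] = cs.a1[li, donor_col]
    if force_het_donor:
        if cs.a1[li, donor_col] == cs.a2[li, donor_col]:
            cs.a2[li, donor_col] = cs.a1[li, donor_col] + locus.period
            fam_sim.true_haplotypes[roles.index(donor_role), 1, li] = cs.a2[li, donor_col]
    # the original allele sits on the haplotype the donor actually transmitted
    donor_hap = int(fam_sim.g1_hap_choices[(donor_role, carrier_role)][li])
    original = int(
        (cs.a1 if donor_hap == 0 else cs.a2)[li, donor_col]
    )
    taken = set()
    for role in roles:
        col = cs.sample_index[sid[role]]
        taken.add(int(cs.a1[li, col]))
        taken.add(int(cs.a2[li, col]))
    if delta_bp is None:
        delta = locus.period
        sign = 1 if rng.random() < cfg.expansion_bias else -1
        delta_bp_val = sign * delta
        while original + delta_bp_val in taken:
            delta_bp_val += sign * locus.period
    else:
        delta_bp_val = delta_bp
        if original + delta_bp_val in taken:
            raise SimConfigError("explicit delta collides with an existing allele")
    denovo = original + delta_bp_val

    carrier_hap = 0 if donor_role in ("gf1", "gf2") else 1
    carrier_col = cs.sample_index[sid[carrier_role]]
    if carrier_hap == 0:
        cs.a1[li, carrier_col] = denovo
    else:
        cs.a2[li, carrier_col] = denovo
    fam_sim.true_haplotypes[roles.index(carrier_role), carrier_hap, li] = denovo

    # re-transmit to children: redraw until the carrier count satisfies the
    # requested bound (a validated event needs >= 2 carriers)
    children = [r for r in roles if r.startswith("c")]
    child_hap = 0 if carrier_role == "fa" else 1
    for _ in range(max_redraws):
        choices = rng.integers(0, 2, len(children))
        n_carry = int((choices == carrier_hap).sum())
        if min_carriers is None or n_carry >= min_carriers:
            break
    else:
        raise SimConfigError("could not reach requested carrier count")
    carriers = []
    for child, choice in zip(children, choices):
        col = cs.sample_index[sid[child]]
        inherited = denovo if choice == carrier_hap else int(
            (cs.a1 if 1 - carrier_hap == 0 else cs.a2)[li, carrier_col]
        )
        if child_hap == 0:
            cs.a1[li, col] = inherited
        else:
            cs.a2[li, col] = inherited
        fam_sim.true_haplotypes[roles.index(child), child_hap, li] = inherited
        if choice == carrier_hap:
            carriers.append(sid[child])
        # keep the marker co-transmission consistent with the new draw
        if li in fam_sim.marker_blocks:
            _retransmit_markers(fam_sim, li, carrier_role, child, choice, cfg, rng)

    if shared_with_partner:
        partner_role = "mo" if carrier_role == "fa" else "fa"
        pcol = cs.sample_index[sid[partner_role]]
        cs.a1[li, pcol] = denovo
        fam_sim.true_haplotypes[roles.index(partner_role), 0, li] = denovo

    _refresh_allele_depths(cs, li, cfg)
    row = TruthRow(
        family_id=fam_sim.family_id,
        donor=sid[donor_role],
        recipient=sid[carrier_role],
        meiosis="G1->G2",
        locus_index=li,
        chrom=locus.chrom,
        start=locus.start,
        period=locus.period,
        original_allele=original,
        denovo_allele=denovo,
        change_bp=delta_bp_val,
        n_child_carriers=len(carriers),
        child_carriers=tuple(carriers),
    )
    fam_sim.truth.append(row)
    return row


def _role_order(fam_sim: FamilySim) -> list[str]:
    prefix = fam_sim.family_id + "_"
    return [s[len(prefix):] for s in fam_sim.callset.samples]


def _retransmit_markers(fam_sim, li, carrier_role, child, choice, cfg, rng) -> None:
    block = fam_sim.marker_blocks[li]
    true_haps = fam_sim.true_marker_haps[li]
    sid = fam_sim.sample_ids
    carrier_hap_markers = true_haps[sid[carrier_role]][choice]
    child_haps = true_haps[sid[child]]
    slot = 0 if carrier_role == "fa" else 1
    child_haps[slot] = carrier_hap_markers
    observed = child_haps.T.copy()
    if cfg.marker_error > 0:
        flips = rng.random(observed.shape) < cfg.marker_error
        observed = np.where(flips, 1 - observed, observed)
    j = block.sample_index[sid[child]]
    block.genotypes[:, j, :] = np.sort(observed, axis=1)


def _refresh_allele_depths(cs: CallSet, li: int, cfg: SimConfig) -> None:
    for j in range(len(cs.samples)):
        if cs.a1[li, j] == cs.a2[li, j]:
            cs.ad1[li, j], cs.ad2[li, j] = cs.depth[li, j], 0
        else:
            cs.ad1[li, j] = cs.depth[li, j] // 2
            cs.ad2[li, j] = cs.depth[li, j] - cs.depth[li, j] // 2


def rate_calibration_config(rate: float, seed: int, n_families: int = 30,
                            n_loci: int | None = None,
                            n_children: int = 9) -> SimConfig:
    """Study conditions for estimator-recovery runs at a known true rate.

    Founder alleles sit on a lattice spaced five repeat units apart so that
    single-step de novo alleles never coincide with another family allele;
    the only systematic loss left is the binomial transmission filter, which
    the rate estimator corrects for.  Loci default to a count giving roughly
    30 expected events per replicate.
    """
    if n_loci is None:
        n_loci = max(2000, int(round(30 / (rate * 2 * n_families))))
    per_period = {2: n_loci}
    return SimConfig(
        seed=seed,
        n_families=n_families,
        n_children=n_children,
        loci_per_period=per_period,
        mutation_rates={2: rate},
        founder_dist="uniform",
        founder_spacing_units=5,
        founder_allele_range=8,
        markers=False,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def merge_callsets(families: Sequence[FamilySim], catalog: Catalog) -> CallSet:
    samples = [s for fam in families for s in fam.callset.samples]
    merged = CallSet(catalog.loci, samples)
    col = 0
    for fam in families:
        n = len(fam.callset.samples)
        sl = slice(col, col + n)
        for attr in ("a1", "a2", "quality", "depth", "stutter", "flank", "ad1", "ad2"):
            getattr(merged, attr)[:, sl] = getattr(fam.callset, attr)
        col += n
    return merged


def merged_marker_set(families: Sequence[FamilySim]) -> MarkerSet:
    samples = [s for fam in families for s in fam.callset.samples]
    sample_pos = {s: j for j, s in enumerate(samples)}
    pos: dict[str, list] = {}
    geno: dict[str, list] = {}
    for fam in families:
        for block in fam.marker_blocks.values():
            rows = np.full((block.n_sites, len(samples), 2), -1, dtype=np.int8)
            for s in block.samples:
                rows[:, sample_pos[s], :] = block.geno(s)
            pos.setdefault(block.chrom, []).append(block.positions)
            geno.setdefault(block.chrom, []).append(rows)
    chrom_pos = {}
    chrom_geno = {}
    for chrom in pos:
        p = np.concatenate(pos[chrom])
        g = np.concatenate(geno[chrom])
        order = np.argsort(p, kind="stable")
        chrom_pos[chrom] = p[order]
        chrom_geno[chrom] = g[order]
    return MarkerSet(chrom_pos, chrom_geno, samples)


def write_outputs(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the full simulated data set (STR VCF, marker VCF, PED, catalog,
    truth TSV) to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": outdir / "catalog.tsv",
        "ped": outdir / "families.ped",
        "str_vcf": outdir / "str_calls.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_catalog(sim.catalog, paths["catalog"])
    write_ped(sim.pedigree, paths["ped"])
    merged = merge_callsets(sim.families, sim.catalog)
    write_str_vcf(merged, sim.catalog, paths["str_vcf"])
    sim.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    if sim.config.markers:
        paths["marker_vcf"] = outdir / "markers.vcf"
        write_marker_vcf(merged_marker_set(sim.families), paths["marker_vcf"])
    return paths


# ---------------------------------------------------------------------------
# Fixture scenarios
# ---------------------------------------------------------------------------

SCENARIOS = (
    "clean",
    "shared_with_partner",
    "untransmitted",
    "donor_ambiguous",
    "within_unit_indel",
)


def build_scenario(name: str, seed: int = 11) -> tuple[SimResult, TruthRow, str]:
    """One-family fixture with a single constructed de novo mutation.

    Returns (simulated data, truth row, expected downstream outcome).
    """
    per_period = {6: 1} if name == "within_unit_indel" else {2: 1}
    cfg = SimConfig(
        seed=seed,
        n_families=1,
        loci_per_period=per_period,
        mutation_rates={p: 0.0 for p in per_period},
        markers=True,
        founder_dist="uniform",
        founder_spacing_units=4,
        founder_allele_range=4,
    )
    sim = simulate(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    fam = sim.families[0]
    kwargs: dict = {}
    expected = "validated"
    if name == "clean":
        kwargs["force_hom_donor"] = True
    if name == "shared_with_partner":
        kwargs["shared_with_partner"] = True
        expected = "rejected_shared_other_parent"
    elif name == "untransmitted":
        kwargs["min_carriers"] = None
        expected = "rejected_untransmitted"
    elif name == "donor_ambiguous":
        kwargs["force_het_donor"] = True
        expected = "validated_size_unresolved"
    elif name == "within_unit_indel":
        kwargs["delta_bp"] = 7
        kwargs["force_hom_donor"] = True
        expected = "validated_within_unit_indel"
    row = implant_mutation(fam, sim.catalog, 0, cfg, rng, **kwargs)
    if name == "untransmitted":
        # force the allele down to at most one child
        _limit_carriers(fam, sim.catalog, row, cfg, rng)
    return sim, row, expected


def _limit_carriers(fam: FamilySim, catalog: Catalog, row: TruthRow,
                    cfg: SimConfig, rng: np.random.Generator) -> None:
    cs = fam.callset
    li = row.locus_index
    keep = row.child_carriers[:1]
    carrier_col = cs.sample_index[row.recipient]
    other = int(cs.a2[li, carrier_col]) if cs.a1[li, carrier_col] == row.denovo_allele \
        else int(cs.a1[li, carrier_col])
    for child in row.child_carriers[1:]:
        col = cs.sample_index[child]
        if cs.a1[li, col] == row.denovo_allele:
            cs.a1[li, col] = other
        else:
            cs.a2[li, col] = other
    _refresh_allele_depths(cs, li, cfg)
    row.child_carriers = tuple(keep)
    row.n_child_carriers = len(keep)


def emit_fixtures(outdir: str | Path, seed: int = 11) -> dict[str, dict]:
    """Write all named fixture scenarios plus a registry of expectations."""
    outdir = Path(outdir)
    registry = {}
    for name in SCENARIOS:
        sim, row, expected = build_scenario(name, seed=seed)
        paths = write_outputs(sim, outdir / name)
        registry[name] = {
            "expected": expected,
            "denovo_allele": row.denovo_allele,
            "carrier": row.recipient,
            "donor": row.donor,
            "paths": {k: str(v) for k, v in paths.items()},
        }
    with open(outdir / "registry.json", "w") as fh:
        json.dump(registry, fh, indent=2)
    return registry
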