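"""Readers and writers for pedigreed STR genotype data.

Handles three-generation pedigrees in PED format, multi-sample STR genotype
VCFs with HipSTR-style per-call annotations, biallelic flanking-marker VCFs
used for parent-of-origin phasing, and BED annotation tracks.

Conventions fixed here (and only here):

* STR alleles are represented as base-pair length deviations from the
  reference allele (the HipSTR ``GB`` convention).  Two calls carry "the same
  allele" iff their deviations are equal.
* The catalog is 0-based half-open; VCF POS is 1-based.  ``start = POS - 1``.
* Phase present in the STR VCF is ignored; phasing is recomputed from the
  pedigree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .catalog import Catalog, StrLocus

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele in genotype matrices (never a real bp deviation).
MISSING = -(10**6)


class PedigreeError(ValueError):
    """Structured error for malformed pedigrees (cycles, sex conflicts...)."""


class VcfFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

MALE, FEMALE, UNKNOWN_SEX = 1, 2, 0


@dataclass
class Individual:
    iid: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: int = UNKNOWN_SEX
    generation: int | None = None

    @property
    def has_both_parents(self) -> bool:
        return self.father_id is not None and self.mother_id is not None


@dataclass
class FamilyUnit:
    """A non-extended three-generation unit: one mid-generation couple, their
    children, and whichever of the couple's parents are present."""

    unit_id: str
    family_id: str
    father: Individual
    mother: Individual
    children: list[Individual]

    def couple(self) -> tuple[Individual, Individual]:
        return (self.father, self.mother)

    def partner_of(self, iid: str) -> Individual:
        if iid == self.father.iid:
            return self.mother
        if iid == self.mother.iid:
            return self.father
        raise KeyError(f"{iid} is not in couple of unit {self.unit_id}")


class Pedigree:
    """Set of individuals with parent links and inferred generations.

    Founders (no parent in the pedigree) are generation 1, their children
    generation 2, grandchildren generation 3.  A married-in partner with no
    recorded parents is a founder by this rule; family-unit extraction places
    it in the couple regardless.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.iid}")
            self.individuals[ind.iid] = ind
        self._resolve_links()
        self._check_sex_roles()
        self._infer_generations()

    def _resolve_links(self) -> None:
        # Parent ids must resolve within the pedigree or be absent entirely.
        for ind in self.individuals.values():
            for attr in ("father_id", "mother_id"):
                pid = getattr(ind, attr)
                if pid is not None and pid not in self.individuals:
                    logger.debug("%s: parent %s not in pedigree; treated as missing",
                                 ind.iid, pid)
                    setattr(ind, attr, None)

    def _check_sex_roles(self) -> None:
        for ind in self.individuals.values():
            f = self.individuals.get(ind.father_id) if ind.father_id else None
            m = self.individuals.get(ind.mother_id) if ind.mother_id else None
            if f is not None and f.sex == FEMALE:
                raise PedigreeError(f"{f.iid} listed as father of {ind.iid} but recorded female")
            if m is not None and m.sex == MALE:
                raise PedigreeError(f"{m.iid} listed as mother of {ind.iid} but recorded male")

    def _infer_generations(self) -> None:
        depth: dict[str, int] = {}
        state: dict[str, int] = {}  # 0 unvisited / 1 in-progress / 2 done

        def visit(iid: str) -> int:
            if state.get(iid) == 1:
                raise PedigreeError(f"pedigree cycle involving {iid}")
            if state.get(iid) == 2:
                return depth[iid]
            state[iid] = 1
            ind = self.individuals[iid]
            parent_depths = [
                visit(pid) for pid in (ind.father_id, ind.mother_id) if pid is not None
            ]
            depth[iid] = 1 + max(parent_depths, default=0)
            state[iid] = 2
            return depth[iid]

        for iid in sorted(self.individuals):
            visit(iid)
        for iid, d in depth.items():
            self.individuals[iid].generation = d

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def children_of(self, father_id: str, mother_id: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals.values()
            if ind.father_id == father_id and ind.mother_id == mother_id
        ]

    def parents_of(self, iid: str) -> tuple[Individual | None, Individual | None]:
        ind = self.individuals[iid]
        f = self.individuals.get(ind.father_id) if ind.father_id else None
        m = self.individuals.get(ind.mother_id) if ind.mother_id else None
        return f, m

    def family_units(self) -> list[FamilyUnit]:
        """Split (possibly extended) pedigrees into non-extended units.

        One unit per parental couple in which at least one partner has both
        of its own parents in the pedigree (i.e. the couple is the middle
        generation of a three-generation structure).
        """
        couples: dict[tuple[str, str], list[Individual]] = {}
        for ind in self.individuals.values():
            if ind.father_id and ind.mother_id:
                couples.setdefault((ind.father_id, ind.mother_id), []).append(ind)
        units = []
        for (fid, mid), kids in sorted(couples.items()):
            father, mother = self.individuals[fid], self.individuals[mid]
            if not (father.has_both_parents or mother.has_both_parents):
                continue  # founder couple: grandparents, not a mid-generation unit
            kids = sorted(kids, key=lambda k: k.iid)
            units.append(
                FamilyUnit(
                    unit_id=f"{father.family_id}:{fid}+{mid}",
                    family_id=father.family_id,
                    father=father,
                    mother=mother,
                    children=kids,
                )
            )
        return units

    def analyzable_parents(self, unit: FamilyUnit) -> list[Individual]:
        """Members of the unit couple whose own parents are both present
        (the individuals in which de novo mutations can be sought)."""
        return [p for p in unit.couple() if p.has_both_parents]


def read_ped(path: str | Path) -> Pedigree:
    """Read a standard 6-column PED file (fam, iid, father, mother, sex, pheno)."""
    individuals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fam, iid, father, mother, sex = fields[:5]
            try:
                sex_code = int(sex)
            except ValueError:
                sex_code = UNKNOWN_SEX
            if sex_code not in (MALE, FEMALE):
                sex_code = UNKNOWN_SEX
            individuals.append(
                Individual(
                    iid=iid,
                    family_id=fam,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=sex_code,
                )
            )
    return Pedigree(individuals)


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind in pedigree.individuals.values():
            fh.write(
                f"{ind.family_id}\t{ind.iid}\t{ind.father_id or 0}\t"
                f"{ind.mother_id or 0}\t{ind.sex}\t-9\n"
            )


# ---------------------------------------------------------------------------
# STR calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrCall:
    """One sample x locus STR genotype with HipSTR-style annotations.

    ``gt`` holds the two allele lengths as bp deviations from the reference
    (``None`` when missing).  ``allele_depths`` aligns with ``gt``.
    """

    sample_id: str
    locus: StrLocus
    gt: tuple[int, int] | None
    quality: float = 0.0
    depth: int = 0
    stutter_fraction: float = 0.0
    flank_indel_fraction: float = 0.0
    allele_depths: tuple[int, int] | None = None

    @property
    def is_missing(self) -> bool:
        return self.gt is None

    def alleles(self) -> set[int]:
        return set(self.gt) if self.gt is not None else set()

    def support_for(self, allele: int) -> tuple[int, bool]:
        """Reads supporting ``allele``: (count, per_allele_available)."""
        if self.gt is None:
            return 0, False
        if self.allele_depths is not None:
            reads = sum(
                ad for a, ad in zip(self.gt, self.allele_depths) if a == allele
            )
            return reads, True
        return self.depth, False


class VcfFields:
    """Configurable FORMAT field names for HipSTR-style STR VCFs."""

    def __init__(self, gb="GB", q="Q", dp="DP", dstutter="DSTUTTER",
                 dflankindel="DFLANKINDEL", ad="ADC"):
        self.gb, self.q, self.dp = gb, q, dp
        self.dstutter, self.dflankindel, self.ad = dstutter, dflankindel, ad


DEFAULT_FIELDS = VcfFields()


class CallSet:
    """Matrix container of STR calls for a set of loci x samples.

    Per-call annotations are stored as dense arrays; :meth:`call` materialises
    a :class:`StrCall` view.  Allele matrices use :data:`MISSING` for missing
    calls, ``ad`` uses -1 when per-allele depths are unavailable.
    """

    def __init__(self, loci: Sequence[StrLocus], samples: Sequence[str]):
        L, S = len(loci), len(samples)
        self.loci = list(loci)
        self.samples = list(samples)
        self._locus_index: dict | None = None
        self.sample_index = {s: j for j, s in enumerate(self.samples)}
        self.a1 = np.full((L, S), MISSING, dtype=np.int32)
        self.a2 = np.full((L, S), MISSING, dtype=np.int32)
        self.quality = np.zeros((L, S), dtype=np.float64)
        self.depth = np.zeros((L, S), dtype=np.int32)
        self.stutter = np.zeros((L, S), dtype=np.float64)
        self.flank = np.zeros((L, S), dtype=np.float64)
        self.ad1 = np.full((L, S), -1, dtype=np.int32)
        self.ad2 = np.full((L, S), -1, dtype=np.int32)
        self.n_unmatched_records = 0

    @property
    def locus_index(self) -> dict:
        if self._locus_index is None:
            self._locus_index = {l.key: i for i, l in enumerate(self.loci)}
        return self._locus_index

    @property
    def missing(self) -> np.ndarray:
        return self.a1 == MISSING

    def set_call(self, i: int, j: int, gt, quality=0.0, depth=0, stutter=0.0,
                 flank=0.0, ad=None) -> None:
        if gt is None:
            self.a1[i, j] = self.a2[i, j] = MISSING
            return
        self.a1[i, j], self.a2[i, j] = gt
        self.quality[i, j] = quality
        self.depth[i, j] = depth
        self.stutter[i, j] = stutter
        self.flank[i, j] = flank
        if ad is not None:
            self.ad1[i, j], self.ad2[i, j] = ad

    def call(self, locus: StrLocus | int, sample: str) -> StrCall:
        i = locus if isinstance(locus, int) else self.locus_index[locus.key]
        j = self.sample_index.get(sample)
        loc = self.loci[i]
        if j is None or self.a1[i, j] == MISSING:
            return StrCall(sample_id=sample, locus=loc, gt=None)
        ad = None
        if self.ad1[i, j] >= 0:
            ad = (int(self.ad1[i, j]), int(self.ad2[i, j]))
        return StrCall(
            sample_id=sample,
            locus=loc,
            gt=(int(self.a1[i, j]), int(self.a2[i, j])),
            quality=float(self.quality[i, j]),
            depth=int(self.depth[i, j]),
            stutter_fraction=float(self.stutter[i, j]),
            flank_indel_fraction=float(self.flank[i, j]),
            allele_depths=ad,
        )


def _allele_sequence(ref_seq: str, motif: str, deviation: int) -> str:
    """Reference-anchored allele sequence for a bp length deviation."""
    n = len(ref_seq) + deviation
    if n < 1:
        raise VcfFormatError(f"deviation {deviation} leaves empty allele")
    if deviation <= 0:
        return ref_seq[:n]
    tail = (motif * (deviation // len(motif) + 1))[:deviation]
    return ref_seq + tail


def write_str_vcf(
    callset: CallSet,
    catalog: Catalog,
    path: str | Path,
    fields: VcfFields = DEFAULT_FIELDS,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a CallSet to a HipSTR-style VCF (GT/GB/Q/DP/DSTUTTER/DFLANKINDEL/AD)."""
    header = pysam.VariantHeader()
    if chrom_lengths is None:
        chrom_lengths = {}
        for locus in callset.loci:
            chrom_lengths[locus.chrom] = max(
                chrom_lengths.get(locus.chrom, 0), locus.end + 1_000_000
            )
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(fields.gb, 1, "String",
                       "Base-pair allele lengths relative to the reference")
    header.formats.add(fields.q, 1, "Float", "Posterior genotype probability")
    header.formats.add(fields.dp, 1, "Integer", "Read depth")
    header.formats.add(fields.dstutter, 1, "Float", "Fraction of reads with stutter")
    header.formats.add(fields.dflankindel, 1, "Float",
                       "Fraction of reads with flanking indels")
    header.formats.add(fields.ad, 2, "Integer", "Reads supporting each called allele")
    header.info.add("PERIOD", 1, "Integer", "Repeat unit length")
    header.info.add("MOTIF", 1, "String", "Repeat unit")
    for s in callset.samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, locus in enumerate(callset.loci):
            ref_seq = catalog.sequence(locus) or (
                locus.motif * (locus.ref_length // locus.period + 1)
            )[: locus.ref_length]
            devs = set()
            for j in range(len(callset.samples)):
                if callset.a1[i, j] != MISSING:
                    devs.add(int(callset.a1[i, j]))
                    devs.add(int(callset.a2[i, j]))
            devs.discard(0)
            alts = sorted(devs)
            allele_index = {0: 0}
            allele_index.update({d: k + 1 for k, d in enumerate(alts)})
            rec = vcf.new_record(
                contig=locus.chrom,
                start=locus.start,
                stop=locus.end,
                alleles=tuple(
                    [_allele_sequence(ref_seq, locus.motif, 0)]
                    + [_allele_sequence(ref_seq, locus.motif, d) for d in alts]
                ) if alts else (ref_seq, "."),
            )
            rec.info["PERIOD"] = locus.period
            rec.info["MOTIF"] = locus.motif
            for j, sample in enumerate(callset.samples):
                fmt = rec.samples[sample]
                if callset.a1[i, j] == MISSING:
                    fmt["GT"] = (None, None)
                    continue
                d1, d2 = int(callset.a1[i, j]), int(callset.a2[i, j])
                fmt["GT"] = (allele_index[d1], allele_index[d2])
                fmt[fields.gb] = f"{d1}|{d2}"
                fmt[fields.q] = float(callset.quality[i, j])
                fmt[fields.dp] = int(callset.depth[i, j])
                fmt[fields.dstutter] = float(callset.stutter[i, j])
                fmt[fields.dflankindel] = float(callset.flank[i, j])
                if callset.ad1[i, j] >= 0:
                    fmt[fields.ad] = (int(callset.ad1[i, j]), int(callset.ad2[i, j]))
            vcf.write(rec)


def read_str_vcf(
    path: str | Path,
    catalog: Catalog,
    fields: VcfFields = DEFAULT_FIELDS,
    samples: Sequence[str] | None = None,
) -> CallSet:
    """Read a HipSTR-style STR VCF into a CallSet keyed to catalog loci.

    Records at positions absent from the catalog are skipped (counted in
    ``CallSet.n_unmatched_records``); GB/GT inconsistencies set the call to
    missing.
    """
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        use_samples = list(samples) if samples is not None else vcf_samples
        records = []
        for rec in vcf:
            locus = catalog.get(rec.chrom, rec.start)
            records.append((rec.chrom, rec.start, locus,
                            {s: _parse_sample(rec, s, fields) for s in vcf_samples
                             if s in set(use_samples)}))
    matched_loci = [loc for _, _, loc, _ in records if loc is not None]
    callset = CallSet(matched_loci, use_samples)
    n_unmatched = 0
    n_inconsistent = 0
    for chrom, start, locus, calls in records:
        if locus is None:
            n_unmatched += 1
            continue
        i = callset.locus_index[locus.key]
        for sample, parsed in calls.items():
            j = callset.sample_index[sample]
            if parsed is None:
                continue
            if parsed == "inconsistent":
                n_inconsistent += 1
                continue
            callset.set_call(i, j, **parsed)
    callset.n_unmatched_records = n_unmatched
    if n_unmatched:
        logger.info("%d VCF records did not match the catalog and were skipped",
                    n_unmatched)
    if n_inconsistent:
        logger.info("%d calls with GT/GB inconsistency set to missing", n_inconsistent)
    return callset


def _parse_sample(rec, sample: str, fields: VcfFields):
    fmt = rec.samples[sample]
    gt_idx = fmt.get("GT")
    if gt_idx is None or any(a is None for a in gt_idx):
        return None
    gb = fmt.get(fields.gb)
    if gb is None:
        return "inconsistent"
    try:
        d1, d2 = (int(x) for x in str(gb).split("|"))
    except ValueError:
        return "inconsistent"
    # cross-check GB against the allele length implied by GT when possible
    try:
        ref_len = len(rec.alleles[0])
        implied = tuple(len(rec.alleles[k]) - ref_len for k in gt_idx)
        if implied != (d1, d2):
            return "inconsistent"
    except (IndexError, TypeError):
        return "inconsistent"
    ad = fmt.get(fields.ad)
    parsed = {
        "gt": (d1, d2),
        "quality": float(fmt.get(fields.q) or 0.0),
        "depth": int(fmt.get(fields.dp) or 0),
        "stutter": float(fmt.get(fields.dstutter) or 0.0),
        "flank": float(fmt.get(fields.dflankindel) or 0.0),
    }
    if ad is not None and ad[0] is not None:
        parsed["ad"] = (int(ad[0]), int(ad[1]))
    return parsed


# ---------------------------------------------------------------------------
# Flanking markers
# ---------------------------------------------------------------------------


@dataclass
class MarkerBlock:
    """Biallelic flanking-marker genotypes over a window around a focal STR.

    ``genotypes`` is (n_sites, n_samples, 2) with alleles coded 0/1 and -1
    for missing; markers are sorted by position.
    """

    chrom: str
    positions: np.ndarray
    samples: list[str]
    genotypes: np.ndarray
    focal_pos: int
    sample_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.argsort(self.positions, kind="stable")
        self.positions = np.asarray(self.positions)[order]
        self.genotypes = np.asarray(self.genotypes)[order]
        self.sample_index = {s: j for j, s in enumerate(self.samples)}

    def geno(self, sample: str) -> np.ndarray:
        return self.genotypes[:, self.sample_index[sample], :]

    def window_mask(self, half_width_kb: float) -> np.ndarray:
        half = int(half_width_kb * 1000)
        return np.abs(self.positions - self.focal_pos) <= half

    @property
    def n_sites(self) -> int:
        return len(self.positions)


class MarkerSet:
    """All biallelic markers for a family, extractable as per-event blocks."""

    def __init__(self, chrom_positions: dict[str, np.ndarray],
                 chrom_genotypes: dict[str, np.ndarray], samples: list[str]):
        self.samples = samples
        self._pos = {c: np.asarray(p) for c, p in chrom_positions.items()}
        self._geno = chrom_genotypes

    def block(self, chrom: str, focal_pos: int, half_width_kb: float = 300.0) -> MarkerBlock:
        pos = self._pos.get(chrom, np.empty(0, dtype=int))
        geno = self._geno.get(chrom, np.empty((0, len(self.samples), 2), dtype=np.int8))
        half = int(half_width_kb * 1000)
        mask = np.abs(pos - focal_pos) <= half
        return MarkerBlock(
            chrom=chrom,
            positions=pos[mask],
            samples=self.samples,
            genotypes=geno[mask],
            focal_pos=focal_pos,
        )


def write_marker_vcf(markers: MarkerSet, path: str | Path,
                     chrom_lengths: Mapping[str, int] | None = None) -> None:
    header = pysam.VariantHeader()
    chroms = sorted(markers._pos)
    for chrom in chroms:
        pos = markers._pos[chrom]
        length = (chrom_lengths or {}).get(chrom, int(pos.max()) + 1_000_000 if len(pos) else 1_000_000)
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in markers.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom in chroms:
            pos = markers._pos[chrom]
            geno = markers._geno[chrom]
            for i in range(len(pos)):
                rec = vcf.new_record(contig=chrom, start=int(pos[i]),
                                     alleles=("A", "G"))
                for j, s in enumerate(markers.samples):
                    g = geno[i, j]
                    rec.samples[s]["GT"] = (
                        (None, None) if g[0] < 0 else (int(g[0]), int(g[1]))
                    )
                vcf.write(rec)


def read_marker_vcf(path: str | Path) -> MarkerSet:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        pos: dict[str, list[int]] = {}
        geno: dict[str, list] = {}
        for rec in vcf:
            if len(rec.alleles) != 2:
                continue  # only biallelic markers are usable for phasing
            row = np.full((len(samples), 2), -1, dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is not None and None not in gt:
                    row[j] = gt
            pos.setdefault(rec.chrom, []).append(rec.start)
            geno.setdefault(rec.chrom, []).append(row)
    return MarkerSet(
        {c: np.array(p) for c, p in pos.items()},
        {c: np.array(g) for c, g in geno.items()},
        samples,
    )


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping intervals per chromosome; returns sorted starts/ends."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        starts, ends = [], []
        for s, e in ivals:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def _points_in(merged: dict[str, tuple[np.ndarray, np.ndarray]],
               chrom: str, points: np.ndarray) -> np.ndarray:
    if chrom not in merged:
        return np.zeros(len(points), dtype=bool)
    starts, ends = merged[chrom]
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(len(points), dtype=bool)
    hit[ok] = points[ok] < ends[idx[ok]]
    return hit


def track_length(merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> int:
    return int(sum((e - s).sum() for s, e in merged.values()))


def intersect_annotations(
    positions: Sequence[tuple[str, int]],
    tracks: Mapping[str, Iterable[tuple[str, int, int]]],
    chrom_sizes: Mapping[str, int],
):
    """Assign point events to annotation tracks and compute genomic fractions.

    Each event (chrom, pos) is counted for every track overlapping it (tracks
    are merged first so overlapping intervals within a track count once); an
    event overlapping no track is counted under ``"none"``.  The genomic
    fraction of a track is its merged length over the genome length from
    ``chrom_sizes``.  Returns a DataFrame (feature, observed, genomic_fraction).
    """
    import pandas as pd

    if not chrom_sizes:
        raise ValueError("chrom_sizes is required to compute genomic fractions")
    genome = sum(chrom_sizes.values())
    by_chrom: dict[str, list[int]] = {}
    for chrom, p in positions:
        by_chrom.setdefault(chrom, []).append(p)

    rows = []
    none_mask = {chrom: np.ones(len(pts), dtype=bool) for chrom, pts in by_chrom.items()}
    union_intervals: list[tuple[str, int, int]] = []
    for name, ivals in tracks.items():
        ivals = list(ivals)
        union_intervals.extend(ivals)
        merged = merge_intervals(ivals)
        observed = 0
        for chrom, pts in by_chrom.items():
            hits = _points_in(merged, chrom, np.array(pts))
            observed += int(hits.sum())
            none_mask[chrom] &= ~hits
        rows.append(
            {"feature": name, "observed": observed,
             "genomic_fraction": track_length(merged) / genome}
        )
    n_none = int(sum(m.sum() for m in none_mask.values()))
    union_fraction = track_length(merge_intervals(union_intervals)) / genome if union_intervals else 0.0
    rows.append({"feature": "none", "observed": n_none,
                 "genomic_fraction": 1.0 - union_fraction})
    return pd.DataFrame(rows, columns=["feature", "observed", "genomic_fraction"])
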