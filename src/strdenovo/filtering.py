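"""Call- and locus-level quality filtering of STR genotypes.

Mirrors the standard HipSTR/DumpSTR filter set: posterior quality strictly
above 0.9, flanking-indel and stutter read fractions strictly below 0.15,
call depth between 10 and 1000 inclusive, and global removal of loci
overlapping segmental duplications.  The per-trio denominator (number of
catalog loci at which the parent and both grandparents all pass) is the
denominator of every mutation-rate estimate downstream.

Boundary conventions are fixed and unit-tested: strict ``>`` / ``<`` for the
quality and fraction thresholds, inclusive bounds for depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, StrLocus
from .pedio import (
    CallSet,
    FamilyUnit,
    Pedigree,
    StrCall,
    _points_in,
    merge_intervals,
)

#: Reason codes a failing call may carry.
REASONS = ("missing", "low_quality", "flank_indel", "stutter", "low_depth", "high_depth")


@dataclass(frozen=True)
class FilterConfig:
    min_quality: float = 0.9
    max_flank_indel_fraction: float = 0.15
    max_stutter_fraction: float = 0.15
    min_depth: int = 10
    max_depth: int = 1000

    def __post_init__(self) -> None:
        for frac in (self.max_flank_indel_fraction, self.max_stutter_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction threshold {frac} outside [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")

    @classmethod
    def from_file(cls, path) -> "FilterConfig":
        """Read key=value (or simple YAML-style ``key: value``) overrides."""
        kwargs = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.replace(":", "=", 1).partition("=")
                key = key.strip()
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown filter setting {key!r}")
                caster = int if key.endswith("depth") else float
                kwargs[key] = caster(value.strip())
        return cls(**kwargs)


def filter_call(call: StrCall, cfg: FilterConfig = FilterConfig()) -> tuple[bool, list[str]]:
    """Pass/fail one call; a failing call reports every violated rule."""
    if call.is_missing:
        return False, ["missing"]
    reasons = []
    if not call.quality > cfg.min_quality:
        reasons.append("low_quality")
    if not call.flank_indel_fraction < cfg.max_flank_indel_fraction:
        reasons.append("flank_indel")
    if not call.stutter_fraction < cfg.max_stutter_fraction:
        reasons.append("stutter")
    if call.depth < cfg.min_depth:
        reasons.append("low_depth")
    if call.depth > cfg.max_depth:
        reasons.append("high_depth")
    return (not reasons), reasons


def pass_matrix(callset: CallSet, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Vectorised ``filter_call`` over a CallSet: (loci x samples) pass mask."""
    present = ~callset.missing
    return (
        present
        & (callset.quality > cfg.min_quality)
        & (callset.flank < cfg.max_flank_indel_fraction)
        & (callset.stutter < cfg.max_stutter_fraction)
        & (callset.depth >= cfg.min_depth)
        & (callset.depth <= cfg.max_depth)
    )


def reason_summary(callset: CallSet, cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Counts of calls failing each rule (a call may fail several)."""
    present = ~callset.missing
    counts = {
        "missing": int((~present).sum()),
        "low_quality": int((present & ~(callset.quality > cfg.min_quality)).sum()),
        "flank_indel": int((present & ~(callset.flank < cfg.max_flank_indel_fraction)).sum()),
        "stutter": int((present & ~(callset.stutter < cfg.max_stutter_fraction)).sum()),
        "low_depth": int((present & (callset.depth < cfg.min_depth)).sum()),
        "high_depth": int((present & (callset.depth > cfg.max_depth)).sum()),
    }
    return pd.DataFrame(
        {"reason": list(counts), "n_calls": list(counts.values())}
    )


def segdup_mask(loci: Sequence[StrLocus],
                segdup_intervals: Iterable[tuple[str, int, int]] | None) -> np.ndarray:
    """True where a locus overlaps a (merged) segmental-duplication interval."""
    excluded = np.zeros(len(loci), dtype=bool)
    if not segdup_intervals:
        return excluded
    merged = merge_intervals(segdup_intervals)
    by_chrom: dict[str, list[int]] = {}
    for idx, locus in enumerate(loci):
        by_chrom.setdefault(locus.chrom, []).append(idx)
    for chrom, idxs in by_chrom.items():
        if chrom not in merged:
            continue
        starts = np.array([loci[i].start for i in idxs])
        ends = np.array([loci[i].end for i in idxs])
        ms, me = merged[chrom]
        # interval overlap: some merged interval starts before locus end and
        # ends after locus start
        j = np.searchsorted(ms, ends, side="left") - 1
        ok = j >= 0
        hit = np.zeros(len(idxs), dtype=bool)
        hit[ok] = me[j[ok]] > starts[ok]
        excluded[np.array(idxs)] = hit
    return excluded


@dataclass
class TrioDenominator:
    """Per-trio count of loci where the parent and both grandparents pass."""

    trio_id: str
    parent: str
    grandfather: str
    grandmother: str
    n_loci_pass: int = 0
    pass_mask: np.ndarray | None = None


@dataclass
class FilterResult:
    """Pass masks and denominators for a family callset."""

    pass_calls: np.ndarray          # loci x samples
    segdup_excluded: np.ndarray     # loci
    trios: list[TrioDenominator] = field(default_factory=list)

    def trio(self, parent: str) -> TrioDenominator:
        for t in self.trios:
            if t.parent == parent:
                return t
        raise KeyError(parent)


def filter_family(
    callset: CallSet,
    pedigree: Pedigree,
    unit: FamilyUnit,
    cfg: FilterConfig = FilterConfig(),
    segdup_intervals: Iterable[tuple[str, int, int]] | None = None,
) -> FilterResult:
    """Apply call filters and build per-trio denominators for one family unit.

    Denominators cover grandparent+parent trios only: a locus counts for a
    trio when the mid-generation parent and both of its own parents pass and
    the locus is not excluded by the segmental-duplication track.
    Third-generation filtering happens later, at transmission checking.
    """
    passes = pass_matrix(callset, cfg)
    excluded = segdup_mask(callset.loci, segdup_intervals)
    passes = passes & ~excluded[:, None]
    trios = []
    for parent in pedigree.analyzable_parents(unit):
        gf, gm = pedigree.parents_of(parent.iid)
        cols = [callset.sample_index.get(s.iid) for s in (parent, gf, gm)]
        if any(c is None for c in cols):
            mask = np.zeros(len(callset.loci), dtype=bool)
        else:
            mask = passes[:, cols].all(axis=1)
        trios.append(
            TrioDenominator(
                trio_id=f"{unit.unit_id}:{parent.iid}",
                parent=parent.iid,
                grandfather=gf.iid,
                grandmother=gm.iid,
                n_loci_pass=int(mask.sum()),
                pass_mask=mask,
            )
        )
    return FilterResult(pass_calls=passes, segdup_excluded=excluded, trios=trios)


def assayable_fraction(
    denominators: Iterable[TrioDenominator], catalog: Catalog
) -> tuple[pd.DataFrame, float, float]:
    """Fraction of catalog loci passing, per trio plus averaged and pooled.

    Returns (per-trio table, mean of per-trio fractions, pooled fraction).
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    denominators = list(denominators)
    rows = [
        {"trio_id": t.trio_id, "n_loci_pass": t.n_loci_pass,
         "fraction": t.n_loci_pass / len(catalog)}
        for t in denominators
    ]
    df = pd.DataFrame(rows, columns=["trio_id", "n_loci_pass", "fraction"])
    mean_fraction = float(df["fraction"].mean()) if len(df) else float("nan")
    pooled = (
        float(sum(t.n_loci_pass for t in denominators))
        / (len(catalog) * len(denominators))
        if denominators
        else float("nan")
    )
    return df, mean_fraction, pooled
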