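"""STR reference catalog and repeat-purity classification.

A short tandem repeat (STR) locus is a genomic interval annotated with its
repeat unit ("motif", 1-6 bp) and the motif length ("period").  Loci whose
reference sequence is a single uninterrupted tandem array of the motif are
"perfect"; arrays containing interruptions are "imperfect".  Purity is
assessed by exact tandem scanning: the longest pure run is the longest
substring that is an exact concatenation of the motif (a trailing partial
unit is allowed), considering every cyclic rotation of the motif since the
phase of a repeat is arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class CatalogError(ValueError):
    """Raised for malformed catalog files or invalid locus definitions."""


@dataclass(frozen=True, order=True)
class StrLocus:
    """One STR catalog entry (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    period: int
    motif: str

    def __post_init__(self) -> None:
        if not (1 <= self.period <= 6):
            raise CatalogError(f"period must be in 1..6, got {self.period}")
        if len(self.motif) != self.period:
            raise CatalogError(
                f"motif {self.motif!r} length != period {self.period}"
            )
        if not set(self.motif) <= _VALID_BASES:
            raise CatalogError(f"motif {self.motif!r} has non-ACGT characters")
        if self.end <= self.start:
            raise CatalogError(f"end must exceed start ({self.start}, {self.end})")
        if self.period > self.ref_length:
            raise CatalogError(
                f"period {self.period} exceeds reference length {self.ref_length}"
            )

    @property
    def ref_length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.start)


@dataclass(frozen=True)
class PurityReport:
    """Outcome of exact-tandem purity scanning of a locus sequence."""

    is_perfect: bool
    longest_pure_run: int
    total_length: int

    def __post_init__(self) -> None:
        assert self.longest_pure_run <= self.total_length


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest cyclic rotation of ``motif``."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def classify_purity(sequence: str, motif: str) -> PurityReport:
    """Classify ``sequence`` as a perfect or imperfect array of ``motif``.

    The longest pure run is the maximal length (bp) of any substring that is
    an exact tandem concatenation of some cyclic rotation of ``motif``,
    allowing a trailing partial unit.  ``is_perfect`` is true iff the whole
    sequence is one such run.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not (1 <= len(motif) <= 6):
        raise ValueError(f"motif length must be 1..6, got {len(motif)!r}")
    if not set(sequence) <= _VALID_BASES:
        raise ValueError("sequence contains non-ACGT characters")
    if not set(motif) <= _VALID_BASES:
        raise ValueError("motif contains non-ACGT characters")

    p = len(motif)
    n = len(sequence)
    rotations = sorted({motif[i:] + motif[:i] for i in range(p)})
    best = 0
    for i in range(n):
        if best >= n - i:  # no longer run can start here
            break
        for rot in rotations:
            if rot[0] != sequence[i]:
                continue
            k = 0
            while i + k < n and sequence[i + k] == rot[k % p]:
                k += 1
            if k > best:
                best = k
    return PurityReport(is_perfect=(best == n), longest_pure_run=best, total_length=n)


@dataclass
class Catalog:
    """A collection of STR loci, sorted by (chrom, start), with fast lookup."""

    loci: list[StrLocus] = field(default_factory=list)
    sequences: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.chrom, l.start))
        self._by_pos = {l.key: l for l in self.loci}
        if len(self._by_pos) != len(self.loci):
            raise CatalogError("duplicate loci (same chrom and start) in catalog")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def get(self, chrom: str, start: int) -> StrLocus | None:
        return self._by_pos.get((chrom, start))

    def __contains__(self, locus: StrLocus) -> bool:
        return locus.key in self._by_pos

    def sequence(self, locus: StrLocus) -> str | None:
        """Reference repeat sequence of the locus, if the catalog carries one."""
        return self.sequences.get(locus.key)

    def purity(self, locus: StrLocus) -> PurityReport | None:
        seq = self.sequence(locus)
        if seq is None:
            return None
        return classify_purity(seq, locus.motif)


def load_catalog(path: str | Path) -> Catalog:
    """Load an STR catalog from a BED-like TSV.

    Columns: chrom, start (0-based), end, period, motif, and optionally the
    reference repeat sequence.  Lines starting with '#' are comments.
    """
    path = Path(path)
    loci: list[StrLocus] = []
    sequences: dict[tuple[str, int], str] = {}
    seen: set[tuple[str, int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise CatalogError(
                    f"{path}:{lineno}: expected >=5 tab-separated fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                period = int(fields[3])
                motif = fields[4].upper()
                locus = StrLocus(chrom, start, end, period, motif)
            except (ValueError, CatalogError) as exc:
                raise CatalogError(f"{path}:{lineno}: {exc}") from exc
            interval = (chrom, start, end)
            if interval in seen:
                raise CatalogError(f"{path}:{lineno}: duplicate interval {interval}")
            seen.add(interval)
            loci.append(locus)
            if len(fields) >= 6 and fields[5]:
                sequences[locus.key] = fields[5].upper()
    if not loci:
        logger.warning("catalog %s is empty", path)
    return Catalog(loci=loci, sequences=sequences)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tperiod\tmotif\tsequence\n")
        for locus in catalog:
            seq = catalog.sequence(locus) or ""
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{locus.period}\t{locus.motif}\t{seq}\n"
            )


def length_mutability_curve(
    events: Iterable,
    catalog: Catalog,
    pass_loci: Sequence[StrLocus],
    by: str = "longest_pure_run",
) -> pd.DataFrame:
    """Proportion of loci mutated as a function of repeat length.

    ``pass_loci`` is the denominator set (loci passing quality filters);
    ``events`` carry a ``.locus`` attribute and contribute the numerator as
    unique mutated loci.  ``by`` selects the length measure: the longest
    perfectly repeating segment or the total repeat length.  Bins with a zero
    denominator are omitted.
    """
    if by not in ("longest_pure_run", "total_length"):
        raise ValueError(f"unknown binning {by!r}")

    def measure(locus: StrLocus) -> int:
        if by == "total_length":
            return locus.ref_length
        report = catalog.purity(locus)
        if report is None:
            raise CatalogError(f"no sequence for locus {locus.key}; cannot bin by purity")
        return report.longest_pure_run

    mutated: set[tuple[str, int]] = set()
    for ev in events:
        if ev.locus not in catalog:
            raise CatalogError(f"event at unknown locus {ev.locus.key}")
        mutated.add(ev.locus.key)

    rows: dict[tuple[int, int], list[int]] = {}
    for locus in pass_loci:
        bin_key = (locus.period, measure(locus))
        denom_hit = rows.setdefault(bin_key, [0, 0])
        denom_hit[0] += 1
        if locus.key in mutated:
            denom_hit[1] += 1
    records = [
        {
            "period": period,
            "length": length,
            "n_loci": denom,
            "n_mutated": hit,
            "proportion_mutated": hit / denom,
        }
        for (period, length), (denom, hit) in sorted(rows.items())
        if denom > 0
    ]
    return pd.DataFrame.from_records(
        records,
        columns=["period", "length", "n_loci", "n_mutated", "proportion_mutated"],
    )
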