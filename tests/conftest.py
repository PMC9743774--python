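import numpy as np
import pytest

from strdenovo.catalog import Catalog, StrLocus
from strdenovo.pedio import CallSet, Individual, Pedigree


@pytest.fixture
def dinuc_locus() -> StrLocus:
    return StrLocus("chr1", 1000, 1020, 2, "AT")


@pytest.fixture
def small_catalog(dinuc_locus) -> Catalog:
    loci = [
        dinuc_locus,
        StrLocus("chr1", 5000, 5012, 3, "AGC"),
        StrLocus("chr2", 800, 830, 6, "ACGTAC"),
    ]
    seqs = {
        ("chr1", 1000): "AT" * 10,
        ("chr1", 5000): "AGC" * 4,
        ("chr2", 800): "ACGTAC" * 5,
    }
    return Catalog(loci=loci, sequences=seqs)


def make_family_individuals(fam="FAM1", n_children=9):
    """4 grandparents + couple + children, three-generation family naming."""
    inds = [
        Individual(f"{fam}_gf1", fam, None, None, 1),
        Individual(f"{fam}_gm1", fam, None, None, 2),
        Individual(f"{fam}_gf2", fam, None, None, 1),
        Individual(f"{fam}_gm2", fam, None, None, 2),
        Individual(f"{fam}_fa", fam, f"{fam}_gf1", f"{fam}_gm1", 1),
        Individual(f"{fam}_mo", fam, f"{fam}_gf2", f"{fam}_gm2", 2),
    ]
    for k in range(1, n_children + 1):
        inds.append(
            Individual(f"{fam}_c{k:02d}", fam, f"{fam}_fa", f"{fam}_mo",
                       1 if k % 2 else 2)
        )
    return inds


@pytest.fixture
def family_pedigree() -> Pedigree:
    return Pedigree(make_family_individuals())


def make_callset(catalog, pedigree, gt_by_sample, quality=0.99, depth=30,
                 ad=True):
    """CallSet where every locus carries the same per-sample genotype.

    ``gt_by_sample`` maps sample id -> (a1, a2) or None for missing.
    """
    samples = list(pedigree.individuals)
    cs = CallSet(catalog.loci, samples)
    for j, s in enumerate(samples):
        gt = gt_by_sample.get(s)
        if gt is None:
            continue
        a1, a2 = gt
        cs.a1[:, j] = a1
        cs.a2[:, j] = a2
        cs.quality[:, j] = quality
        cs.depth[:, j] = depth
        cs.stutter[:, j] = 0.01
        cs.flank[:, j] = 0.01
        if ad:
            hom = a1 == a2
            cs.ad1[:, j] = depth if hom else depth // 2
            cs.ad2[:, j] = 0 if hom else depth - depth // 2
    return cs
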