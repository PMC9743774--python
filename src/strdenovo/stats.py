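"""Mutational-dynamics summary statistics and tests.

Covers per-trio and per-motif mutation rates, perfect/imperfect repeat
mutability with a two-proportion Z test, the male/female transmission-bias
binomial test (overall and per family with Bonferroni correction), the
expansion/contraction balance, observed/expected enrichment of events in
annotation features, genome-wide extrapolation of per-individual mutation
counts, and the parental-age correlation.

Two tallies are kept distinct throughout: *events* (one per carrier x locus
de novo allele; per-individual counts) and *unique mutated loci* (a locus
counted once however many carriers share it; purity and per-motif tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .catalog import Catalog
from .denovo import DeNovoEvent, Status, false_negative_rate
from .filtering import TrioDenominator
from .pedio import FEMALE, MALE
from .phasing import PhaseResult


@dataclass
class RateTable:
    per_trio: pd.DataFrame     # trio_id, n_events, n_loci_pass, rate
    per_motif: pd.DataFrame    # period, n_unique_loci, n_locus_trio_pass, rate
    mean_rate: float           # mean of per-trio rates
    pooled_rate: float         # total events / total passing locus-trios


def mutation_rates(
    events: Sequence[DeNovoEvent],
    denominators: Sequence[TrioDenominator],
    catalog: Catalog,
    fn_correction: float | None = None,
) -> RateTable:
    """Mutation rates per trio and per motif length from validated events.

    Per-trio rate = validated events in the trio / loci passing for that
    trio.  Per-motif rate = unique mutated loci of that period / passing
    locus-trio count of that period (summed over trios).  When
    ``fn_correction`` (a detection probability, e.g. 1 - the transmission
    false-negative rate) is given, rates are divided by it.
    """
    validated = [e for e in events if e.status is Status.VALIDATED]
    denom_by_trio = {d.trio_id: d for d in denominators}
    for ev in validated:
        if ev.trio_id not in denom_by_trio:
            raise ValueError(f"event trio {ev.trio_id} has no denominator")
    correction = fn_correction if fn_correction else 1.0

    counts: dict[str, int] = {d.trio_id: 0 for d in denominators}
    for ev in validated:
        counts[ev.trio_id] += 1
    rows = []
    for d in denominators:
        if d.n_loci_pass == 0:
            import logging

            logging.getLogger(__name__).warning(
                "trio %s has zero passing loci; excluded from rates", d.trio_id
            )
            continue
        rows.append(
            {
                "trio_id": d.trio_id,
                "n_events": counts[d.trio_id],
                "n_loci_pass": d.n_loci_pass,
                "rate": counts[d.trio_id] / d.n_loci_pass / correction,
            }
        )
    per_trio = pd.DataFrame(rows, columns=["trio_id", "n_events", "n_loci_pass", "rate"])

    unique_loci: dict[int, set] = {p: set() for p in range(1, 7)}
    for ev in validated:
        unique_loci[ev.locus.period].add(ev.locus.key)
    # pass masks align with catalog order
    locus_periods = np.array([l.period for l in catalog])
    pass_by_period: dict[int, int] = {p: 0 for p in range(1, 7)}
    for d in denominators:
        if d.pass_mask is None:
            continue
        sel = locus_periods[d.pass_mask]
        for p in range(1, 7):
            pass_by_period[p] += int((sel == p).sum())
    motif_rows = []
    for p in range(1, 7):
        denom = pass_by_period[p]
        if denom == 0:
            continue
        n_unique = len(unique_loci[p])
        motif_rows.append(
            {
                "period": p,
                "n_unique_loci": n_unique,
                "n_locus_trio_pass": denom,
                "rate": n_unique / denom / correction,
            }
        )
    per_motif = pd.DataFrame(
        motif_rows, columns=["period", "n_unique_loci", "n_locus_trio_pass", "rate"]
    )
    mean_rate = float(per_trio["rate"].mean()) if len(per_trio) else float("nan")
    pooled = (
        per_trio["n_events"].sum() / per_trio["n_loci_pass"].sum() / correction
        if len(per_trio) and per_trio["n_loci_pass"].sum() > 0
        else float("nan")
    )
    return RateTable(per_trio=per_trio, per_motif=per_motif,
                     mean_rate=mean_rate, pooled_rate=float(pooled))


def purity_fractions(
    counts: Mapping[int, tuple[int, int, int, int]]
) -> pd.DataFrame:
    """Perfect/imperfect mutability fractions from printed-style counts.

    ``counts`` maps period -> (perfect de novo loci, imperfect de novo loci,
    total perfect loci, total imperfect loci).  Returns per-period rows plus
    an ``overall`` row; fraction = de novo loci / total loci of the class.
    """
    rows = []
    tot = [0, 0, 0, 0]
    for period in sorted(counts):
        pd_, id_, tp, ti = counts[period]
        for k, v in enumerate((pd_, id_, tp, ti)):
            tot[k] += v
        rows.append(
            {
                "period": period,
                "perfect_denovo": pd_,
                "imperfect_denovo": id_,
                "total_perfect": tp,
                "total_imperfect": ti,
                "fraction_perfect": pd_ / tp if tp else 0.0,
                "fraction_imperfect": id_ / ti if ti else 0.0,
            }
        )
    rows.append(
        {
            "period": "overall",
            "perfect_denovo": tot[0],
            "imperfect_denovo": tot[1],
            "total_perfect": tot[2],
            "total_imperfect": tot[3],
            "fraction_perfect": tot[0] / tot[2] if tot[2] else 0.0,
            "fraction_imperfect": tot[1] / tot[3] if tot[3] else 0.0,
        }
    )
    return pd.DataFrame(rows)


def purity_mutability(
    events: Sequence[DeNovoEvent],
    catalog: Catalog,
    pass_loci_keys: Iterable[tuple[str, int]],
) -> tuple[pd.DataFrame, float, float]:
    """Mutability of perfect vs imperfect repeats among assayed loci.

    Unique mutated loci are counted once; denominators are the perfect and
    imperfect loci among ``pass_loci_keys``.  Returns the per-period table
    (plus overall row) and the pooled two-proportion Z test (z, p).
    """
    validated = {e.locus.key for e in events if e.status is Status.VALIDATED}
    counts: dict[int, list[int]] = {}
    for locus in catalog:
        if locus.key not in set(pass_loci_keys):
            continue
        report = catalog.purity(locus)
        if report is None:
            raise ValueError(f"no sequence for locus {locus.key}")
        row = counts.setdefault(locus.period, [0, 0, 0, 0])
        mutated = locus.key in validated
        if report.is_perfect:
            row[2] += 1
            row[0] += int(mutated)
        else:
            row[3] += 1
            row[1] += int(mutated)
    table = purity_fractions({p: tuple(v) for p, v in counts.items()})
    overall = table[table["period"] == "overall"].iloc[0]
    if overall["total_perfect"] == 0 or overall["total_imperfect"] == 0:
        return table, float("nan"), float("nan")
    z, p = proportions_ztest(
        count=[overall["perfect_denovo"], overall["imperfect_denovo"]],
        nobs=[overall["total_perfect"], overall["total_imperfect"]],
    )
    return table, float(z), float(p)


def two_proportion_ztest(count: Sequence[int], nobs: Sequence[int]) -> tuple[float, float]:
    z, p = proportions_ztest(count=list(count), nobs=list(nobs))
    return float(z), float(p)


@dataclass
class BiasResult:
    n_male: int
    n_female: int
    ratio: float
    p_value: float


def transmission_bias(
    results: Iterable[PhaseResult] | tuple[int, int],
    grouping: str = "overall",
    family_of: Mapping[str, str] | None = None,
) -> BiasResult | pd.DataFrame:
    """Male vs female transmission of de novo alleles.

    Accepts either phase results (only resolved ones count) or a raw
    (n_male, n_female) pair.  ``grouping="per-family"`` needs ``family_of``
    (carrier id -> family id) and returns a table with Bonferroni-adjusted
    p-values (multiplied by the number of families, capped at 1).
    """
    if isinstance(results, tuple):
        male, female = results
        if grouping != "overall":
            raise ValueError("raw counts support only overall grouping")
        return _bias(male, female)
    resolved = [r for r in results if r.resolved and r.donor_sex in (MALE, FEMALE)]
    if grouping == "overall":
        male = sum(1 for r in resolved if r.donor_sex == MALE)
        female = len(resolved) - male
        return _bias(male, female)
    if grouping != "per-family":
        raise ValueError(f"unknown grouping {grouping!r}")
    if family_of is None:
        raise ValueError("per-family grouping needs a carrier->family mapping")
    per_fam: dict[str, list[int]] = {}
    for r in resolved:
        fam = family_of[r.event.carrier]
        mf = per_fam.setdefault(fam, [0, 0])
        mf[0 if r.donor_sex == MALE else 1] += 1
    n_fam = len(per_fam)
    rows = []
    for fam, (male, female) in sorted(per_fam.items()):
        b = _bias(male, female)
        rows.append(
            {
                "family": fam,
                "n_male": male,
                "n_female": female,
                "ratio": b.ratio,
                "p_value": b.p_value,
                "p_bonferroni": min(1.0, b.p_value * n_fam),
            }
        )
    return pd.DataFrame(rows)


def _bias(male: int, female: int) -> BiasResult:
    n = male + female
    p = sps.binomtest(male, n, 0.5).pvalue if n > 0 else float("nan")
    ratio = male / female if female > 0 else float("inf")
    return BiasResult(n_male=male, n_female=female, ratio=ratio, p_value=float(p))


def expansion_contraction(
    size_changes_bp: Sequence[int], periods: Sequence[int] | None = None
) -> pd.DataFrame:
    """Expansion (positive bp change) vs contraction counts and binomial p.

    Returns an overall row and per-motif rows when ``periods`` is given
    (strata without events are omitted).  Zero changes are impossible by
    construction and rejected.
    """
    changes = np.asarray(size_changes_bp)
    if (changes == 0).any():
        raise ValueError("zero size change contradicts de novo status")

    def row(label, vals):
        exp = int((vals > 0).sum())
        con = int((vals < 0).sum())
        p = sps.binomtest(exp, exp + con, 0.5).pvalue if exp + con else float("nan")
        return {"stratum": label, "n_expansion": exp, "n_contraction": con,
                "p_value": float(p)}

    rows = [row("overall", changes)]
    if periods is not None:
        periods = np.asarray(periods)
        for p_ in sorted(set(periods.tolist())):
            vals = changes[periods == p_]
            if len(vals):
                rows.append(row(f"period_{p_}", vals))
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    feature: str
    observed: int
    expected: float
    ratio: float
    p_value: float


def feature_enrichment(
    annotation_counts: pd.DataFrame, n_events: int
) -> list[EnrichmentResult]:
    """Exact binomial test of observed event counts against genomic fractions.

    ``annotation_counts`` is the (feature, observed, genomic_fraction) table
    from annotation intersection; expected = n_events x fraction.
    """
    results = []
    for _, r in annotation_counts.iterrows():
        frac = float(r["genomic_fraction"])
        observed = int(r["observed"])
        if frac <= 0.0:
            if observed > 0:
                raise ValueError(
                    f"feature {r['feature']} covers no genome but has events"
                )
            continue
        expected = n_events * frac
        p = sps.binomtest(observed, n_events, frac).pvalue if n_events else float("nan")
        results.append(
            EnrichmentResult(
                feature=str(r["feature"]),
                observed=observed,
                expected=expected,
                ratio=observed / expected if expected > 0 else float("inf"),
                p_value=float(p),
            )
        )
    return results


def extrapolate_genomewide(mean_events_per_individual: float,
                           assayable_fraction: float) -> float:
    """Scale the per-individual mutation count to the whole catalog."""
    if not (0.0 < assayable_fraction <= 1.0):
        raise ValueError("assayable fraction must be in (0, 1]")
    return mean_events_per_individual / assayable_fraction


def parental_age_correlation(
    events_per_individual: Mapping[str, int],
    paternal_age: Mapping[str, float],
    maternal_age: Mapping[str, float],
) -> tuple[float, float]:
    """Squared Pearson correlation of event counts with parental ages."""
    ids = sorted(set(events_per_individual) & set(paternal_age) & set(maternal_age))
    if len(ids) < 3:
        raise ValueError("need >= 3 individuals with ages")
    counts = np.array([events_per_individual[i] for i in ids], dtype=float)
    out = []
    for ages in (paternal_age, maternal_age):
        x = np.array([ages[i] for i in ids], dtype=float)
        if np.allclose(x, x[0]) or np.allclose(counts, counts[0]):
            out.append(float("nan"))
            continue
        r, _ = sps.pearsonr(x, counts)
        out.append(float(r * r))
    return out[0], out[1]


def transmission_power(
    n_transmissions: int, effect_size: float, alpha: float = 0.05,
    n_sim: int = 2000, seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided binomial sex-bias test.

    ``effect_size`` is the absolute deviation of the male transmission
    probability from 1/2 (e.g. 0.05 for a 5% effect).
    """
    rng = np.random.default_rng(seed)
    males = rng.binomial(n_transmissions, 0.5 + effect_size, size=n_sim)
    hits = 0
    pcache: dict[int, float] = {}
    for m in males:
        m = int(m)
        if m not in pcache:
            pcache[m] = sps.binomtest(m, n_transmissions, 0.5).pvalue
        hits += pcache[m] < alpha
    return hits / n_sim
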