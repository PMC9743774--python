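import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from strdenovo.catalog import Catalog, StrLocus
from strdenovo.denovo import DeNovoEvent, Status
from strdenovo.filtering import TrioDenominator
from strdenovo.phasing import PhaseResult
from strdenovo.stats import (
    BiasResult,
    expansion_contraction,
    extrapolate_genomewide,
    feature_enrichment,
    mutation_rates,
    parental_age_correlation,
    purity_fractions,
    purity_mutability,
    transmission_bias,
    transmission_power,
    two_proportion_ztest,
)


def _locus(i, period=2, motif="AT"):
    start = 1000 * (i + 1)
    return StrLocus("chr1", start, start + 5 * period, period, motif)


def _event(locus, trio="t1", carrier="fa", status=Status.VALIDATED):
    return DeNovoEvent(
        locus=locus, carrier=carrier, carrier_sex=1, denovo_allele=99,
        carrier_other_allele=0, father_gt=(0, 0), mother_gt=(0, 0),
        trio_id=trio, status=status, n_g3_carriers=3, n_g3_genotyped=9,
        support_reads=20,
    )


class TestMutationRates:
    def _catalog(self):
        loci = [_locus(i) for i in range(4)] + [
            _locus(i + 10, period=4, motif="ACGT") for i in range(4)
        ]
        return Catalog(loci=loci)

    def _denoms(self, catalog):
        full = np.ones(len(catalog), dtype=bool)
        half = full.copy()
        half[:4] = [True, True, False, False]
        return [
            TrioDenominator("t1", "fa", "gf1", "gm1", int(full.sum()), full),
            TrioDenominator("t2", "mo", "gf2", "gm2", int(half.sum()), half),
        ]

    def test_per_trio_and_per_motif(self):
        cat = self._catalog()
        denoms = self._denoms(cat)
        events = [
            _event(cat.loci[0], trio="t1"),
            _event(cat.loci[0], trio="t2"),        # same locus, other trio
            _event(cat.loci[4], trio="t1"),
            _event(cat.loci[1], trio="t1", status=Status.REJECTED_UNTRANSMITTED),
        ]
        rt = mutation_rates(events, denoms, cat)
        per = rt.per_trio.set_index("trio_id")
        assert per.loc["t1", "n_events"] == 2 and per.loc["t1", "n_loci_pass"] == 8
        assert per.loc["t2", "n_events"] == 1 and per.loc["t2", "n_loci_pass"] == 6
        assert per.loc["t1", "rate"] == pytest.approx(2 / 8)
        assert rt.mean_rate == pytest.approx((2 / 8 + 1 / 6) / 2)
        assert rt.pooled_rate == pytest.approx(3 / 14)
        motif = rt.per_motif.set_index("period")
        # locus 0 is mutated in two trios but counts once (unique loci)
        assert motif.loc[2, "n_unique_loci"] == 1
        assert motif.loc[2, "n_locus_trio_pass"] == 4 + 2
        assert motif.loc[4, "n_unique_loci"] == 1
        assert motif.loc[4, "n_locus_trio_pass"] == 4 + 4
        assert motif.loc[2, "rate"] == pytest.approx(1 / 6)

    def test_fn_correction_divides(self):
        cat = self._catalog()
        denoms = self._denoms(cat)
        events = [_event(cat.loci[0], trio="t1")]
        plain = mutation_rates(events, denoms, cat)
        corrected = mutation_rates(events, denoms, cat,
                                   fn_correction=1 - 10 / 512)
        factor = 1 / (1 - 10 / 512)
        assert corrected.pooled_rate == pytest.approx(plain.pooled_rate * factor)
        assert corrected.mean_rate == pytest.approx(plain.mean_rate * factor)

    def test_unknown_trio_rejected(self):
        cat = self._catalog()
        with pytest.raises(ValueError, match="ghost"):
            mutation_rates([_event(cat.loci[0], trio="ghost")],
                           self._denoms(cat), cat)

    def test_zero_denominator_trio_excluded(self):
        cat = self._catalog()
        empty = np.zeros(len(cat), dtype=bool)
        denoms = self._denoms(cat) + [
            TrioDenominator("t3", "x", "g1", "g2", 0, empty)
        ]
        rt = mutation_rates([], denoms, cat)
        assert set(rt.per_trio["trio_id"]) == {"t1", "t2"}


class TestPurity:
    def test_fractions_from_counts(self):
        table = purity_fractions({2: (770, 230, 143570, 153117)})
        row = table[table["period"] == 2].iloc[0]
        assert row["fraction_perfect"] == pytest.approx(770 / 143570)
        overall = table[table["period"] == "overall"].iloc[0]
        assert overall["total_perfect"] == 143570
        assert overall["fraction_imperfect"] == pytest.approx(230 / 153117)

    def test_mutability_and_ztest(self):
        perfect = [_locus(i) for i in range(6)]
        imperfect = [_locus(i + 20) for i in range(6)]
        seqs = {l.key: "AT" * 5 for l in perfect}
        seqs.update({l.key: "ATATCTATAT" for l in imperfect})
        cat = Catalog(loci=perfect + imperfect, sequences=seqs)
        # 3 of 6 perfect loci mutate, 1 of 6 imperfect
        events = [_event(l) for l in perfect[:3]] + [_event(imperfect[0])]
        table, z, p = purity_mutability(events, cat, [l.key for l in cat])
        overall = table[table["period"] == "overall"].iloc[0]
        assert overall["perfect_denovo"] == 3 and overall["imperfect_denovo"] == 1
        assert overall["total_perfect"] == overall["total_imperfect"] == 6
        z2, p2 = two_proportion_ztest([3, 1], [6, 6])
        assert z == pytest.approx(z2) and p == pytest.approx(p2)

    def test_empty_class_gives_nan_test(self):
        perfect = [_locus(i) for i in range(3)]
        cat = Catalog(loci=perfect, sequences={l.key: "AT" * 5 for l in perfect})
        table, z, p = purity_mutability([], cat, [l.key for l in cat])
        assert math.isnan(z) and math.isnan(p)

    def test_missing_sequence_rejected(self):
        cat = Catalog(loci=[_locus(0)])
        with pytest.raises(ValueError):
            purity_mutability([], cat, [cat.loci[0].key])


def _phase_result(carrier, donor_sex, resolved=True):
    ev = _event(_locus(0), carrier=carrier)
    return PhaseResult(
        event=ev, window_kb=10.0, likelihoods=(1.0, 0.0, 0.0, 0.0),
        best_grandparent="g", donor_sex=donor_sex, uss=50.0, resolved=resolved,
    )


class TestTransmissionBias:
    def test_printed_counts(self):
        b = transmission_bias((1117, 1085))
        assert isinstance(b, BiasResult)
        assert round(b.ratio, 2) == 1.03
        assert b.p_value == pytest.approx(
            sps.binomtest(1117, 2202, 0.5).pvalue
        )
        assert b.p_value >= 0.05  # no significant sex bias

    def test_phase_results_only_resolved_count(self):
        prs = ([_phase_result("fa", 1)] * 3 + [_phase_result("fa", 2)] * 2
               + [_phase_result("fa", 1, resolved=False)])
        b = transmission_bias(prs)
        assert (b.n_male, b.n_female) == (3, 2)

    def test_per_family_bonferroni(self):
        prs = ([_phase_result("f1_fa", 1)] * 6
               + [_phase_result("f2_mo", 2)] * 4 + [_phase_result("f2_mo", 1)])
        fam = {"f1_fa": "F1", "f2_mo": "F2"}
        df = transmission_bias(prs, grouping="per-family", family_of=fam)
        by = df.set_index("family")
        assert by.loc["F1", "n_male"] == 6 and by.loc["F1", "n_female"] == 0
        assert by.loc["F2", "n_male"] == 1 and by.loc["F2", "n_female"] == 4
        expect = sps.binomtest(6, 6, 0.5).pvalue
        assert by.loc["F1", "p_value"] == pytest.approx(expect)
        assert by.loc["F1", "p_bonferroni"] == pytest.approx(min(1, expect * 2))

    def test_raw_counts_reject_per_family(self):
        with pytest.raises(ValueError):
            transmission_bias((3, 2), grouping="per-family")


class TestExpansionContraction:
    def test_counts_and_strata(self):
        changes = [2, 4, -2, 6, -4, 2]
        periods = [2, 2, 2, 4, 4, 4]
        df = expansion_contraction(changes, periods)
        by = df.set_index("stratum")
        assert by.loc["overall", "n_expansion"] == 4
        assert by.loc["overall", "n_contraction"] == 2
        assert by.loc["period_2", "n_expansion"] == 2
        assert by.loc["period_2", "n_contraction"] == 1
        assert by.loc["period_4", "n_expansion"] == 2
        assert by.loc["overall", "p_value"] == pytest.approx(
            sps.binomtest(4, 6, 0.5).pvalue
        )

    def test_zero_change_rejected(self):
        with pytest.raises(ValueError):
            expansion_contraction([2, 0, -2])


class TestEnrichment:
    def test_ratio_and_pvalue(self):
        df = pd.DataFrame(
            {"feature": ["alu", "none"], "observed": [30, 70],
             "genomic_fraction": [0.1, 0.9]}
        )
        res = {r.feature: r for r in feature_enrichment(df, 100)}
        assert res["alu"].expected == pytest.approx(10.0)
        assert res["alu"].ratio == pytest.approx(3.0)
        assert res["alu"].p_value == pytest.approx(
            sps.binomtest(30, 100, 0.1).pvalue
        )
        assert res["alu"].p_value < 0.001

    def test_zero_fraction_with_events_rejected(self):
        df = pd.DataFrame(
            {"feature": ["x"], "observed": [1], "genomic_fraction": [0.0]}
        )
        with pytest.raises(ValueError, match="x"):
            feature_enrichment(df, 10)

    def test_zero_fraction_without_events_skipped(self):
        df = pd.DataFrame(
            {"feature": ["x"], "observed": [0], "genomic_fraction": [0.0]}
        )
        assert feature_enrichment(df, 10) == []


class TestExtrapolation:
    def test_scaling(self):
        assert extrapolate_genomewide(42.04, 0.49) == pytest.approx(85.8, abs=0.05)

    def test_bounds(self):
        with pytest.raises(ValueError):
            extrapolate_genomewide(10, 0.0)
        with pytest.raises(ValueError):
            extrapolate_genomewide(10, 1.2)


class TestParentalAge:
    def test_perfect_linear_r2(self):
        counts = {f"i{k}": 10 + 2 * k for k in range(5)}
        pat = {f"i{k}": 30.0 + k for k in range(5)}
        mat = {f"i{k}": 28.0 for k in range(5)}  # constant
        r2p, r2m = parental_age_correlation(counts, pat, mat)
        assert r2p == pytest.approx(1.0)
        assert math.isnan(r2m)

    def test_requires_three(self):
        with pytest.raises(ValueError):
            parental_age_correlation({"a": 1, "b": 2}, {"a": 1, "b": 2},
                                     {"a": 1, "b": 2})


class TestPower:
    def test_monotone_in_effect_and_null_calibrated(self):
        p_null = transmission_power(2202, 0.0, n_sim=400, seed=3)
        p_small = transmission_power(2202, 0.02, n_sim=400, seed=3)
        p_big = transmission_power(2202, 0.05, n_sim=400, seed=3)
        assert p_null < 0.1           # ~alpha under the null
        assert p_small < p_big
        assert p_big > 0.95           # 5% effect is easily detected at n=2202
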