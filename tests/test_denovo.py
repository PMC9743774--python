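import math

import numpy as np
import pytest

from strdenovo.catalog import StrLocus
from strdenovo.denovo import (
    DeNovoEvent,
    Status,
    call_family,
    concordance,
    detect_candidates,
    events_table,
    expected_false_negatives,
    false_negative_rate,
    validate_transmission,
)
from strdenovo.filtering import FilterConfig, filter_family
from strdenovo.pedio import StrCall

from conftest import make_callset


LOCUS = StrLocus("chr1", 1000, 1020, 2, "AT")


def call(sample, gt, ad=None, depth=30):
    return StrCall(sample_id=sample, locus=LOCUS, gt=gt, quality=0.99,
                   depth=depth, allele_depths=ad)


class TestDetectCandidates:
    def test_simple_candidate(self):
        evs = detect_candidates(call("c", (0, 2)), call("f", (0, 0)),
                                call("m", (0, 0)), trio_id="t")
        assert len(evs) == 1
        ev = evs[0]
        assert ev.denovo_allele == 2 and ev.carrier_other_allele == 0
        assert ev.status is Status.CANDIDATE and not ev.homozygous_denovo

    def test_allele_in_either_parent_not_candidate(self):
        assert detect_candidates(call("c", (0, 2)), call("f", (2, 4)),
                                 call("m", (0, 0))) == []
        assert detect_candidates(call("c", (0, 2)), call("f", (0, 0)),
                                 call("m", (2, 6))) == []

    def test_homozygous_denovo_single_flagged_event(self):
        evs = detect_candidates(call("c", (2, 2)), call("f", (0, 0)),
                                call("m", (0, 0)))
        assert len(evs) == 1
        assert evs[0].homozygous_denovo
        assert evs[0].carrier_other_allele == 2

    def test_two_novel_alleles_two_events(self):
        evs = detect_candidates(call("c", (2, 4)), call("f", (0, 0)),
                                call("m", (0, 0)))
        assert sorted(e.denovo_allele for e in evs) == [2, 4]

    def test_missing_member_no_candidates(self):
        assert detect_candidates(call("c", None), call("f", (0, 0)),
                                 call("m", (0, 0))) == []
        assert detect_candidates(call("c", (0, 2)), call("f", None),
                                 call("m", (0, 0))) == []

    def test_per_allele_support(self):
        evs = detect_candidates(call("c", (0, 2), ad=(10, 17)),
                                call("f", (0, 0)), call("m", (0, 0)))
        assert evs[0].support_reads == 17 and evs[0].support_is_per_allele

    def test_total_depth_fallback(self):
        evs = detect_candidates(call("c", (0, 2), depth=33),
                                call("f", (0, 0)), call("m", (0, 0)))
        assert evs[0].support_reads == 33 and not evs[0].support_is_per_allele


def _candidate(support=20):
    return detect_candidates(call("c", (0, 2), ad=(10, support)),
                             call("f", (0, 0)), call("m", (0, 0)))[0]


class TestValidateTransmission:
    def test_validated(self):
        ev = validate_transmission(
            _candidate(),
            [call(f"k{i}", (2, 0)) for i in range(3)] + [call("k3", (0, 0))],
            partner_call=call("p", (0, 0)),
        )
        assert ev.status is Status.VALIDATED
        assert ev.n_g3_carriers == 3 and ev.n_g3_genotyped == 4

    def test_untransmitted_below_two_carriers(self):
        ev = validate_transmission(
            _candidate(),
            [call("k0", (2, 0)), call("k1", (0, 0))],
            partner_call=call("p", (0, 0)),
        )
        assert ev.status is Status.REJECTED_UNTRANSMITTED

    def test_shared_other_parent(self):
        ev = validate_transmission(
            _candidate(),
            [call(f"k{i}", (2, 0)) for i in range(3)],
            partner_call=call("p", (2, 4)),
        )
        assert ev.status is Status.REJECTED_SHARED_OTHER_PARENT

    def test_missing_other_parent(self):
        ev = validate_transmission(
            _candidate(),
            [call(f"k{i}", (2, 0)) for i in range(3)],
            partner_call=call("p", None),
        )
        assert ev.status is Status.REJECTED_MISSING_OTHER_PARENT

    def test_low_support(self):
        ev = validate_transmission(
            _candidate(support=9),
            [call(f"k{i}", (2, 0)) for i in range(3)],
            partner_call=call("p", (0, 0)),
        )
        assert ev.status is Status.REJECTED_LOW_SUPPORT

    def test_missing_children_excluded_from_counts(self):
        ev = validate_transmission(
            _candidate(),
            [call("k0", (2, 0)), call("k1", None), call("k2", (2, 4))],
            partner_call=call("p", (0, 0)),
        )
        assert ev.n_g3_genotyped == 2 and ev.n_g3_carriers == 2
        assert ev.status is Status.VALIDATED

    def test_double_validation_rejected(self):
        ev = validate_transmission(
            _candidate(), [call(f"k{i}", (2, 0)) for i in range(2)],
            partner_call=call("p", (0, 0)),
        )
        with pytest.raises(ValueError):
            validate_transmission(ev, [], partner_call=call("p", (0, 0)))


class TestEventInvariants:
    def test_denovo_allele_must_be_novel(self):
        with pytest.raises(AssertionError):
            DeNovoEvent(locus=LOCUS, carrier="c", carrier_sex=1,
                        denovo_allele=2, carrier_other_allele=0,
                        father_gt=(0, 2), mother_gt=(0, 0), trio_id="t")

    def test_validated_requires_support(self):
        with pytest.raises(AssertionError):
            DeNovoEvent(locus=LOCUS, carrier="c", carrier_sex=1,
                        denovo_allele=2, carrier_other_allele=0,
                        father_gt=(0, 0), mother_gt=(0, 0), trio_id="t",
                        status=Status.VALIDATED, n_g3_carriers=1,
                        support_reads=50)


class TestFalseNegativeModel:
    def test_reference_value_exact(self):
        assert false_negative_rate(9, 2) == 10 / 512

    def test_exhaustive_oracle(self):
        for n in range(1, 13):
            for m in range(1, n + 2):
                expect = sum(math.comb(n, k) for k in range(m)) / 2**n
                assert false_negative_rate(n, m) == pytest.approx(
                    expect, abs=1e-12
                )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            false_negative_rate(0, 2)
        with pytest.raises(ValueError):
            false_negative_rate(9, 0)
        with pytest.raises(ValueError):
            false_negative_rate(3, 5)

    def test_expected_false_negatives(self):
        value, rounded = expected_false_negatives(5249, 10 / 512)
        assert rounded == 102
        assert value == pytest.approx(5249 * 10 / 512)
        value, rounded = expected_false_negatives(1000, 10 / 512)
        assert value == pytest.approx(19.53125)
        assert rounded == 19
        with pytest.raises(ValueError):
            expected_false_negatives(-1, 0.1)


class TestConcordance:
    def test_printed_values(self):
        a = [(0, 0)] * 363
        b = [(0, 0)] * 353 + [(0, 2)] * 10
        assert concordance(a, b) == (353, 363, 97.25)

    def test_unordered_pairs_match(self):
        assert concordance([(2, 0)], [(0, 2)]) == (1, 1, 100.0)

    def test_missing_counts_in_total_only(self):
        m, t, pct = concordance([(0, 0), None], [(0, 0), (0, 0)])
        assert (m, t) == (1, 2) and pct == 50.0

    def test_strict_length(self):
        with pytest.raises(ValueError):
            concordance([(0, 0)], [(0, 0), (0, 0)])

    def test_empty(self):
        with pytest.raises(ValueError):
            concordance([], [])


class TestCallFamily:
    def _setup(self, small_catalog, family_pedigree, partner_fail=False):
        gts = {iid: (0, 2) for iid in family_pedigree.individuals}
        # father carries a novel allele 6 at every locus; transmits to kids 1-4
        gts["FAM1_fa"] = (6, 0)
        for k in range(1, 5):
            gts[f"FAM1_c{k:02d}"] = (6, 2)
        cs = make_callset(small_catalog, family_pedigree, gts)
        if partner_fail:
            j = cs.sample_index["FAM1_mo"]
            cs.quality[:, j] = 0.5
        unit = family_pedigree.family_units()[0]
        fr = filter_family(cs, family_pedigree, unit, FilterConfig())
        return call_family(cs, family_pedigree, unit, fr)

    def test_validated_events(self, small_catalog, family_pedigree):
        events = self._setup(small_catalog, family_pedigree)
        assert len(events) == len(small_catalog)
        assert all(e.status is Status.VALIDATED for e in events)
        assert all(e.carrier == "FAM1_fa" and e.denovo_allele == 6
                   for e in events)
        assert all(e.n_g3_carriers == 4 for e in events)

    def test_partner_failing_filter_is_missing(self, small_catalog,
                                               family_pedigree):
        events = self._setup(small_catalog, family_pedigree, partner_fail=True)
        assert all(e.status is Status.REJECTED_MISSING_OTHER_PARENT
                   for e in events)

    def test_events_table_columns(self, small_catalog, family_pedigree):
        events = self._setup(small_catalog, family_pedigree)
        df = events_table(events)
        assert len(df) == len(events)
        assert {"chrom", "start", "status", "denovo_allele",
                "n_g3_carriers"} <= set(df.columns)
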