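"""Frequencies, Hardy-Weinberg, linkage, censuses, hybrid screen, accounting."""

import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from simcyto import lineage
from simcyto.popgen import (DegenerateTestError, LarvaRecord, PopgenError,
                            UndefinedFrequencyError, classify_linkage,
                            format_frequency, frequency_table,
                            genotype_counts, hw_test, hybrid_screen,
                            rearranged_frequency, sex_chromosome_census,
                            shared_rearrangement_accounting)


def _larva(i, genotypes, sex="female", species="sp", site=1, config=None):
    cfg = config or ("X0X0" if sex == "female" else "X0Y0")
    return LarvaRecord(f"L{i:03d}", site, species, sex, genotypes, cfg)


class TestFrequencies:
    def test_is22_frequency_from_printed_counts(self, records):
        """ss=29, si=34, ii=7 at site 1 gives 48/140 = 0.34."""
        chol1 = [r for r in records
                 if r.species == "cholodkovskii" and r.site == 1]
        assert genotype_counts(chol1, "IS-22") == (29, 34, 7)
        freq = rearranged_frequency(records, "IS-22")[("cholodkovskii", 1)]
        assert freq == Fraction(48, 140)
        assert format_frequency(freq) == "0.34"

    def test_all_ss_and_all_ii(self):
        recs = [_larva(i, {"A": 0, "B": 2}) for i in range(10)]
        freqs_a = rearranged_frequency(recs, "A")
        freqs_b = rearranged_frequency(recs, "B")
        assert freqs_a[("sp", 1)] == 0
        assert freqs_b[("sp", 1)] == 1

    def test_synthetic_104_of_140(self):
        """104 rearranged constituents among 140 round to 0.74."""
        recs = ([_larva(i, {"X": 2}) for i in range(39)]
                + [_larva(100 + i, {"X": 1}) for i in range(26)]
                + [_larva(200 + i, {"X": 0}) for i in range(5)])
        f = rearranged_frequency(recs, "X")[("sp", 1)]
        assert f == Fraction(104, 140)
        assert format_frequency(f) == "0.74"

    def test_empty_group_is_undefined_not_zero(self):
        recs = [_larva(0, {"A": None})]
        with pytest.raises(UndefinedFrequencyError):
            rearranged_frequency(recs, "A")

    def test_presentation_dialect(self):
        assert format_frequency(Fraction(1, 140)) == "<0.01"
        assert format_frequency(Fraction(2, 140)) == "0.01"
        assert format_frequency(Fraction(1, 40)) == "0.02"   # half-even at 0.025
        assert format_frequency(Fraction(35, 40)) == "0.88"
        assert format_frequency(Fraction(0)) == ""
        assert format_frequency(Fraction(1)) == "1.00"
        assert format_frequency(Fraction(999, 1000)) == "0.99"  # 1.00 means fixed

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=30))
    def test_bounded_and_monotone_under_added_carrier(self, copies):
        recs = [_larva(i, {"A": g}) for i, g in enumerate(copies)]
        f = rearranged_frequency(recs, "A")[("sp", 1)]
        assert 0 <= f <= 1
        more = recs + [_larva(999, {"A": 2})]
        f2 = rearranged_frequency(more, "A")[("sp", 1)]
        assert f2 >= f


class TestHardyWeinberg:
    def test_printed_example(self):
        res = hw_test(29, 34, 7)
        assert res.chi_square == pytest.approx(0.42, abs=0.005)
        assert res.df == 1
        assert not res.reject
        assert float(res.allele_freq) == pytest.approx(0.34, abs=0.005)

    def test_exact_proportions_give_zero(self):
        assert hw_test(25, 50, 25).chi_square == pytest.approx(0.0, abs=1e-12)

    def test_no_heterozygotes(self):
        # expected (5, 10, 5) against observed (10, 0, 10)
        assert hw_test(10, 0, 10).chi_square == pytest.approx(20.0)

    def test_monomorphic_signals(self):
        with pytest.raises(DegenerateTestError):
            hw_test(12, 0, 0)
        with pytest.raises(DegenerateTestError):
            hw_test(0, 0, 12)

    def test_type_one_error_calibration(self):
        """Under Hardy-Weinberg sampling the test rejects at about 5%."""
        rng = np.random.default_rng(20160627)
        n, p, reps = 400, 0.3, 800
        rejections = 0
        for _ in range(reps):
            g = rng.binomial(1, p, size=(n, 2)).sum(axis=1)
            res = hw_test(int((g == 0).sum()), int((g == 1).sum()),
                          int((g == 2).sum()))
            rejections += res.reject
        assert 0.03 <= rejections / reps <= 0.07


class TestLinkage:
    def test_fixture_calls(self, records):
        nig = [r for r in records if r.species == "nigricoxum"]
        dec = [r for r in records if r.species == "decimatum"]
        chol = [r for r in records if r.species == "cholodkovskii"]
        assert classify_linkage(nig, "IIS-4").call == "X_linked"
        assert classify_linkage(nig, "IIS-10").call == "Y_linked"
        assert classify_linkage(nig, "IL-18").call == "fixed"
        assert classify_linkage(dec, "IS-23").call == "Y_linked_with_X_occurrence"
        assert classify_linkage(dec, "IS-24").call == "Y_linked"
        assert classify_linkage(dec, "IS-25").call == "Y_linked"
        assert classify_linkage(dec, "IIS-7").call == "autosomal_polymorphic"
        assert classify_linkage(chol, "IS-22").call == "autosomal_polymorphic"
        assert classify_linkage(chol, "T(I;III)").call == "fixed"

    def test_single_sex_indeterminate(self, records):
        females = [r for r in records if r.sex == "female"]
        assert classify_linkage(females, "IIS-4").call == "indeterminate"

    def test_invariant_to_order_and_ids(self, records):
        dec = [r for r in records if r.species == "decimatum"]
        shuffled = dec[:]
        random.Random(3).shuffle(shuffled)
        relabelled = [LarvaRecord(f"Z{i}", r.site, r.species, r.sex,
                                  r.genotypes, r.sex_config, r.flags)
                      for i, r in enumerate(shuffled)]
        for name in ("IS-23", "IS-24", "IIS-7"):
            assert (classify_linkage(relabelled, name).call
                    == classify_linkage(dec, name).call)


class TestCensus:
    def test_decimatum_male_census(self, records):
        census = sex_chromosome_census(records, "decimatum")
        pct = {cfg: float(p) for cfg, (_, p) in census["male"].items()}
        assert pct["X0Y0"] == 25.0
        assert pct["X0Y1"] == 31.2
        assert pct["X0Y2"] == 25.0
        assert pct["X0Y3"] == 6.2
        assert pct["X0Y4"] == 6.2
        assert census["male"]["unresolved"][0] == 1
        assert sum(k for k, _ in census["male"].values()) == 16

    def test_nigricoxum_uniform_configs(self, records):
        census = sex_chromosome_census(records, "nigricoxum")
        assert census["female"] == {"X1X1": (12, Fraction(100))}
        assert census["male"] == {"X1Y1": (10, Fraction(100))}

    def test_all_males_undifferentiated(self):
        recs = [_larva(i, {"A": 0}, sex="male") for i in range(5)]
        census = sex_chromosome_census(recs, "sp")
        assert census["male"]["X0Y0"] == (5, Fraction(100))

    def test_no_males_is_an_error(self):
        recs = [_larva(i, {"A": 0}) for i in range(5)]
        with pytest.raises(PopgenError):
            sex_chromosome_census(recs, "sp")


class TestHybridScreen:
    def test_single_partial_candidate_in_sympatry(self, records):
        symp = lineage.sympatric_records(records)
        screen = hybrid_screen(symp, lineage.DIAGNOSTICS_CHOLODKOVSKII,
                               lineage.DIAGNOSTICS_DECIMATUM)
        assert screen.n_screened == 116
        assert len(screen.candidates) == 1
        cand = screen.candidates[0]
        assert not cand.full
        assert set(cand.het_a) == {"IS-20", "IS-21"}     # lacks IIIL-16
        assert set(cand.het_b) == {"IIS-7", "IIL-18"}
        assert cand.completeness == Fraction(4, 5)

    def test_pure_parentals_yield_no_candidates(self):
        parents = ([_larva(i, {"A": 2, "B": 2, "C": 0, "D": 0}) for i in range(20)]
                   + [_larva(100 + i, {"A": 0, "B": 0, "C": 2, "D": 2})
                      for i in range(20)])
        screen = hybrid_screen(parents, ["A", "B"], ["C", "D"])
        assert screen.candidates == ()

    def test_injected_f1_is_full_hybrid(self):
        f1 = _larva(0, {"A": 1, "B": 1, "C": 1, "D": 1})
        screen = hybrid_screen([f1], ["A", "B"], ["C", "D"])
        assert len(screen.candidates) == 1 and screen.candidates[0].full

    def test_overlapping_sets_rejected(self):
        with pytest.raises(PopgenError):
            hybrid_screen([], ["A", "B"], ["B", "C"])


class TestSharedAccounting:
    def test_palearctic_pair(self, table):
        """56 distinct, 24 shared, 8 shared polymorphisms between the
        sympatric Palearctic species."""
        assert shared_rearrangement_accounting(
            table, ("cholodkovskii", "decimatum")) == (56, 24, 8)

    def test_disjoint_taxa_share_nothing(self):
        recs = ([_larva(i, {"A": 2, "B": 0}, species="t1") for i in range(4)]
                + [_larva(10 + i, {"A": 0, "B": 2}, species="t2", site=2)
                   for i in range(4)])
        tbl = frequency_table(recs, ["A", "B"])
        assert shared_rearrangement_accounting(tbl, ("t1", "t2")) == (2, 0, 0)

    def test_taxon_against_itself(self, table):
        distinct, shared, _ = shared_rearrangement_accounting(
            table, ("cholodkovskii", "cholodkovskii"))
        assert shared == distinct
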