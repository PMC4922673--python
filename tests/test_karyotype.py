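"""Rearrangement algebra: inversions, interchanges, derivations, distances."""

import random

import pytest
from hypothesis import given, strategies as st

from simcyto.distance import DepthExceededError, min_inversion_distance
from simcyto.karyotype import (ArmSequence, BreakpointError, Chromosome,
                               DerivationScenario, IncomparableSequenceError,
                               InvalidKaryotypeError, Karyotype, RegistryError,
                               apply_deletion, apply_interchange,
                               apply_inversion, apply_step,
                               fragment_decomposition, reorder_fragments,
                               verify_derivation)


@st.composite
def _segments(draw, n=17):
    left = draw(st.integers(0, n - 1))
    right = draw(st.integers(left + 1, n))
    return left, right


class TestInversion:
    @given(_segments())
    def test_involution(self, registry, seg):
        """Applying the same inversion twice restores the sequence exactly."""
        seq = registry.standard["IS"]
        once = apply_inversion(seq, *seg)
        twice = apply_inversion(once, *seg)
        assert twice.tokens == seq.tokens

    @given(_segments())
    def test_band_multiset_conserved(self, registry, seg):
        seq = registry.standard["IS"]
        out = apply_inversion(seq, *seg)
        assert sorted(out.idents()) == sorted(seq.idents())
        assert len(out) == len(seq)

    def test_single_token_reversal_is_identity_unsigned(self, registry):
        seq = registry.standard["IL"]
        out = apply_inversion(seq, 4, 5)
        assert out.unsigned_equals(seq)
        assert out.tokens != seq.tokens  # orientation flag did flip

    @pytest.mark.parametrize("bounds", [(-1, 5), (5, 5), (8, 3), (0, 99)])
    def test_bad_breakpoints(self, registry, bounds):
        with pytest.raises(BreakpointError):
            apply_inversion(registry.standard["IS"], *bounds)

    def test_segment_reversed_in_place(self, registry):
        seq = registry.standard["IIIS"]  # sections 76..83
        out = apply_inversion(seq, 2, 6)
        assert [t.section for t in out.tokens] == [76, 77, 81, 80, 79, 78, 82, 83]
        assert all(t.inverted for t in out.tokens[2:6])
        assert not any(t.inverted for t in out.tokens[:2] + out.tokens[6:])


class TestDeletion:
    def test_removes_declared_band_count(self, registry):
        seq = registry.standard["IIIL"]
        out = apply_deletion(seq, 85, 2)
        assert len(out) == len(seq) - 2
        assert not any(t.section == 85 for t in out.tokens)

    def test_too_many_bands(self, registry):
        with pytest.raises(BreakpointError):
            apply_deletion(registry.standard["IIIL"], 85, 3)


class TestInterchange:
    def test_whole_arm_interchange_and_inverse(self, registry):
        kt = registry.standard_karyotype()
        t13 = registry["T(I;III)"]
        moved = apply_step(kt, t13)
        assert set(moved.pairing) == {frozenset({"IS", "IIIL"}),
                                      frozenset({"IL", "IIIS"}),
                                      frozenset({"IIS", "IIL"})}
        # band content untouched, only arm-to-chromosome assignment changed
        assert moved.band_count() == kt.band_count()
        back = apply_interchange(moved, [["IS", "IL"], ["IIS", "IIL"], ["IIIS", "IIIL"]],
                                 {"IS+IL": "I", "IIS+IIL": "II", "IIIS+IIIL": "III"})
        assert back.pairing == kt.pairing
        assert [c.centric_origin for c in back.chromosomes] == ["I", "II", "III"]

    def test_identity_pairing(self, registry):
        kt = registry.standard_karyotype()
        same = apply_interchange(kt, [["IS", "IL"], ["IIS", "IIL"], ["IIIS", "IIIL"]])
        assert same.pairing == kt.pairing

    def test_orphaned_arm_rejected(self, registry):
        kt = registry.standard_karyotype()
        with pytest.raises(InvalidKaryotypeError):
            apply_interchange(kt, [["IS", "IL"], ["IIS", "IIL"], ["IIIS", "IIS"]])

    def test_duplicated_centric_rejected(self):
        with pytest.raises(InvalidKaryotypeError):
            Karyotype((Chromosome(("IS", "IL"), "I"),
                       Chromosome(("IIS", "IIL"), "I"),
                       Chromosome(("IIIS", "IIIL"), "III")))


class TestDerivations:
    def test_all_lineage_scenarios_verify(self, registry, scenarios):
        """Every arm of every species derives from the standard via its
        registered steps, and alphabetical fragment reordering recovers the
        standard sequence."""
        assert len(scenarios) == 19
        for scn in scenarios:
            scenario = DerivationScenario(scn["start_label"], scn["arm"],
                                          tuple(scn["steps"]), tuple(scn["end_tokens"]))
            ok, fragments = verify_derivation(scenario, registry)
            assert ok, f"{scn['taxon']} {scn['arm']} failed"
            state = registry.standard[scn["arm"]]
            for name in scenario.steps:
                state = apply_step(state, registry[name])
            assert reorder_fragments(state, fragments) == registry.standard[scn["arm"]].idents()

    def test_empty_step_list_single_fragment(self, registry):
        scenario = DerivationScenario("subgeneric standard", "IIIS", (),
                                      tuple(registry.standard["IIIS"].labels()))
        ok, fragments = verify_derivation(scenario, registry)
        assert ok and len(fragments) == 1 and fragments[0].label == "a"

    def test_wrong_final_step_fails(self, registry, scenarios):
        scn = next(s for s in scenarios
                   if s["taxon"] == "nigricoxum" and s["arm"] == "IL")
        steps = tuple(scn["steps"][:-1]) + ("IL-22",)   # wrong last inversion
        scenario = DerivationScenario(scn["start_label"], scn["arm"], steps,
                                      tuple(scn["end_tokens"]))
        ok, _ = verify_derivation(scenario, registry)
        assert not ok

    def test_unknown_step_name(self, registry, scenarios):
        scn = scenarios[0]
        scenario = DerivationScenario(scn["start_label"], scn["arm"],
                                      ("IS-999",), tuple(scn["end_tokens"]))
        with pytest.raises(RegistryError):
            verify_derivation(scenario, registry)

    def test_x_and_y_sequences_differ_by_two_inversions(self, registry, scenarios):
        """The nigricoxum Y (IIS-1,5,6,10) is two inversions from the X
        (IIS-1,4,5,6): IIS-4 absent, IIS-10 present."""
        seqs = {s["sequence"]: s for s in scenarios
                if s["taxon"] == "nigricoxum" and s["arm"] == "IIS"}
        assert set(seqs["X"]["steps"]) - set(seqs["Y"]["steps"]) == {"IIS-4"}
        assert set(seqs["Y"]["steps"]) - set(seqs["X"]["steps"]) == {"IIS-10"}
        assert seqs["X"]["end_tokens"] != seqs["Y"]["end_tokens"]


def _id_search(start, goal, limit):
    """Independent iterative-deepening oracle for reversal distance."""
    def reversals(state):
        n = len(state)
        for i in range(n - 1):
            for j in range(i + 2, n + 1):
                yield state[:i] + state[i:j][::-1] + state[j:]

    def dfs(state, depth):
        if state == goal:
            return True
        if depth == 0:
            return False
        return any(dfs(nxt, depth - 1) for nxt in reversals(state))

    for d in range(limit + 1):
        if dfs(start, d):
            return d
    raise AssertionError("oracle exhausted")


class TestInversionDistance:
    def test_identity(self, registry):
        seq = registry.standard["IIIS"]
        assert min_inversion_distance(seq, seq) == 0

    def test_single_reversal(self):
        a = tuple(range(5))
        b = a[:1] + a[1:4][::-1] + a[4:]
        assert min_inversion_distance(a, b) == 1

    def test_incomparable(self):
        with pytest.raises(IncomparableSequenceError):
            min_inversion_distance((1, 2, 3), (1, 2, 4))

    def test_depth_bound_is_loud(self):
        a = tuple(range(6))
        b = (1, 0, 3, 2, 5, 4)
        with pytest.raises(DepthExceededError):
            min_inversion_distance(a, b, max_depth=1)

    def test_matches_iterative_deepening_oracle(self):
        rng = random.Random(20160627)
        base = tuple(range(7))
        for _ in range(6):
            perm = list(base)
            rng.shuffle(perm)
            perm = tuple(perm)
            d = min_inversion_distance(base, perm, max_depth=8)
            # oracle: no shorter scenario exists, and one of length d does
            assert _id_search(base, perm, d) == d

    def test_symmetry_and_triangle_inequality(self):
        rng = random.Random(11)
        base = tuple(range(6))
        for _ in range(5):
            p1 = tuple(rng.sample(base, 6))
            p2 = tuple(rng.sample(base, 6))
            d12 = min_inversion_distance(p1, p2, max_depth=8)
            d21 = min_inversion_distance(p2, p1, max_depth=8)
            assert d12 == d21
            d1b = min_inversion_distance(p1, base, max_depth=8)
            db2 = min_inversion_distance(base, p2, max_depth=8)
            assert d12 <= d1b + db2


class TestFragments:
    def test_fragment_labels_tile_the_start(self, registry):
        seq = registry.standard["IL"]
        derived = apply_inversion(apply_inversion(seq, 3, 14), 6, 18)
        frags = fragment_decomposition(derived, seq)
        assert reorder_fragments(derived, frags) == seq.idents()
        labels = sorted(f.label for f in frags)
        assert labels == [chr(ord("a") + i) for i in range(len(frags))]

    def test_foreign_band_rejected(self, registry):
        foreign = ArmSequence.from_labels("IS", ["1", "2", "99"])
        with pytest.raises(IncomparableSequenceError):
            fragment_decomposition(foreign, registry.standard["IS"])
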