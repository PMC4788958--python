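import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odemerge import (
    InputSignal,
    MergePolicy,
    ToyPairSpec,
    auto_match,
    classify_conflicts,
    generate_toy_pair,
    merge_models,
    simulate,
    validate_model,
)
from odemerge.merge import MergeError
from odemerge.overlap import MatchEntry, MatchSet


def matched_pair(spec):
    a, b, _ = generate_toy_pair(spec)
    ms = classify_conflicts(auto_match(a, b), a, b)
    return a, b, ms


class TestMergeCounts:
    def test_disjoint_models_counts_are_sums(self):
        spec = ToyPairSpec(overlap_species=0, overlap_reactions=0, seed=2)
        a, b, ms = matched_pair(spec)
        assert ms.entries == []
        merged = merge_models(a, b, ms, MergePolicy())
        assert len(merged.model.species) == len(a.species) + len(b.species)
        assert len(merged.model.reactions) == len(a.reactions) + len(b.reactions)
        assert len(merged.model.compartments) == len(a.compartments) + len(b.compartments)

    def test_case_shape_counts(self):
        spec = ToyPairSpec(overlap_species=5, overlap_reactions=4, seed=2)
        a, b, ms = matched_pair(spec)
        merged = merge_models(a, b, ms, MergePolicy())
        assert len(merged.model.species) == len(a.species) + len(b.species) - 5
        assert len(merged.model.reactions) == len(a.reactions) + len(b.reactions) - 4

    @settings(max_examples=10, deadline=None)
    @given(
        na=st.integers(0, 2),
        nb=st.integers(0, 2),
        m=st.integers(2, 6),
        r=st.integers(1, 5),
        seed=st.integers(0, 50),
    )
    def test_count_conservation_property(self, na, nb, m, r, seed):
        try:
            spec = ToyPairSpec(na, nb, m, r, seed=seed)
            a, b, ms = matched_pair(spec)
        except ValueError:
            return  # infeasible shape
        merged = merge_models(a, b, ms, MergePolicy())
        for cls, elems_a, elems_b, elems_m in (
            ("species", a.species, b.species, merged.model.species),
            ("reaction", a.reactions, b.reactions, merged.model.reactions),
            ("compartment", a.compartments, b.compartments, merged.model.compartments),
        ):
            assert len(elems_m) == len(elems_a) + len(elems_b) - ms.count(cls), cls


class TestPolicy:
    def spec(self):
        return ToyPairSpec(seed=6, divergence=10.0)

    def test_policy_a_keeps_a_values(self):
        a, b, ms = matched_pair(self.spec())
        merged = merge_models(a, b, ms, MergePolicy("A"))
        for entry in ms.entries:
            if entry.element_class == "parameter":
                assert merged.model.get_parameter(entry.ref_a).value == a.get_parameter(
                    entry.ref_a
                ).value

    def test_policy_b_takes_b_values_exactly(self):
        a, b, ms = matched_pair(self.spec())
        merged = merge_models(a, b, ms, MergePolicy("B"))
        for entry in ms.entries:
            if entry.element_class == "parameter":
                assert merged.model.get_parameter(entry.ref_a).value == b.get_parameter(
                    entry.ref_b
                ).value
            if entry.element_class == "species":
                assert merged.model.get_species(entry.ref_a).initial_amount == b.get_species(
                    entry.ref_b
                ).initial_amount

    def test_switching_policy_changes_only_overlap(self):
        a, b, ms = matched_pair(self.spec())
        ma = merge_models(a, b, ms, MergePolicy("A")).model
        mb = merge_models(a, b, ms, MergePolicy("B")).model
        overlap_params = {e.ref_a for e in ms.entries if e.element_class == "parameter"}
        for pa, pb in zip(ma.parameters, mb.parameters):
            assert pa.id == pb.id
            if pa.id not in overlap_params:
                assert pa.value == pb.value
        overlap_species = {e.ref_a for e in ms.entries if e.element_class == "species"}
        for sa, sb in zip(ma.species, mb.species):
            if sa.id not in overlap_species:
                assert sa.initial_amount == sb.initial_amount

    def test_per_element_override(self):
        a, b, ms = matched_pair(self.spec())
        target = next(e.ref_a for e in ms.entries if e.element_class == "parameter")
        merged = merge_models(
            a, b, ms, MergePolicy("A", per_element_source={target: "B"})
        )
        ref_b = next(e.ref_b for e in ms.entries if e.ref_a == target)
        assert merged.model.get_parameter(target).value == b.get_parameter(ref_b).value


class TestMergeValidity:
    def test_merged_model_validates(self):
        a, b, ms = matched_pair(ToyPairSpec(seed=9))
        merged = merge_models(a, b, ms, MergePolicy())
        assert validate_model(merged.model).valid

    def test_provenance_covers_every_element(self):
        a, b, ms = matched_pair(ToyPairSpec(seed=9))
        merged = merge_models(a, b, ms, MergePolicy())
        assert set(merged.provenance) == merged.model.all_ids()
        assert set(merged.provenance.values()) <= {"A-only", "B-only", "overlap"}

    def test_id_collisions_are_suffixed(self):
        spec = ToyPairSpec(overlap_species=0, overlap_reactions=0, seed=2)
        a, b, _ = generate_toy_pair(spec)
        # force a collision between unmatched elements
        b.compartments[0].id = a.compartments[0].id
        for sp in b.species:
            sp.compartment = a.compartments[0].id
        for r in b.reactions:
            pass
        ms = classify_conflicts(auto_match(a, b), a, b)
        merged = merge_models(a, b, ms, MergePolicy())
        ids = [c.id for c in merged.model.compartments]
        assert len(ids) == len(set(ids)) == 2

    def test_dangling_match_refs_rejected(self):
        a, b, ms = matched_pair(ToyPairSpec(seed=9))
        bad = MatchSet(entries=[MatchEntry("species", "ghost", "cas1")])
        with pytest.raises(MergeError, match="ghost"):
            merge_models(a, b, bad, MergePolicy())

    def test_unresolved_blocking_conflict_requires_decision(self):
        a, b, ms = matched_pair(ToyPairSpec(seed=9))
        b.get_reaction("deact1").kinetic_law = "k_deact1 * cas1_p * cas1_p"
        ms = classify_conflicts(auto_match(a, b), a, b)
        assert any(e.has_conflict("different-kinetics") for e in ms.entries)
        with pytest.raises(MergeError, match="manual"):
            merge_models(a, b, ms, MergePolicy("A"))
        # an explicit per-element decision unblocks the merge
        merged = merge_models(
            a, b, ms, MergePolicy("A", per_element_source={"deact1": "A"})
        )
        assert validate_model(merged.model).valid


class TestBehaviorPreservation:
    def test_isolated_input_reproduces_model_a(self):
        """With policy A and B silent, the merged model reproduces model A's
        outputs within integration tolerance."""
        a, b, ms = matched_pair(ToyPairSpec(seed=11, divergence=10.0))
        merged = merge_models(a, b, ms, MergePolicy("A"))
        grid = np.linspace(0.0, 150.0, 31)
        ta = simulate(a, InputSignal.of(A_Lig=1.0), grid)
        tm = simulate(merged.model, InputSignal.of(A_Lig=1.0), grid)
        for sid in a.dynamic_species_ids():
            scale = max(1e-12, float(np.max(np.abs(ta.values[sid]))))
            np.testing.assert_allclose(
                ta.values[sid], tm.values[sid], rtol=1e-6, atol=1e-6 * scale
            )

    def test_silent_side_branch_stays_at_zero(self):
        a, b, ms = matched_pair(ToyPairSpec(seed=11))
        merged = merge_models(a, b, ms, MergePolicy("A"))
        grid = np.linspace(0.0, 150.0, 16)
        tm = simulate(merged.model, InputSignal.of(B_Lig=1.0), grid)
        for sid in merged.exclusive_elements("A"):
            if sid in tm.values and sid.startswith("A_rec"):
                # dense-output interpolation noise only
                np.testing.assert_allclose(tm.values[sid], 0.0, atol=1e-12)
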