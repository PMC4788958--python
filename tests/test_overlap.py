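import pytest

from odemerge import (
    ToyPairSpec,
    apply_edits,
    auto_match,
    classify_conflicts,
    generate_toy_pair,
)
from odemerge.model import Compartment, KineticModel, Parameter, Reaction, Species
from odemerge.overlap import EditError, MatchSet

UNIPROT = ("is", "urn:miriam:uniprot:P28482")


def tiny_model(mid, species_name, uris=(UNIPROT,)):
    # distinct compartments so only species matches are at play
    return KineticModel(
        model_id=mid,
        compartments=[Compartment(id=f"{mid}_c", name=f"cell_{mid}")],
        species=[
            Species(id=f"{mid}_s1", compartment=f"{mid}_c", name=species_name, cv_uris=uris)
        ],
    )


class TestAutoMatch:
    def test_same_uri_different_names_matched(self):
        a = tiny_model("a", "ERK")
        b = tiny_model("b", "ERK2")
        ms = auto_match(a, b)
        assert ms.pairs("species") == {("a_s1", "b_s1")}

    def test_disjoint_models_nothing_matched(self):
        a = tiny_model("a", "ERK", uris=(("is", "urn:x:1"),))
        b = tiny_model("b", "Akt", uris=(("is", "urn:x:2"),))
        ms = auto_match(a, b)
        assert ms.entries == []
        assert len(ms.unmatched_a) == 2  # compartment + species
        assert len(ms.unmatched_b) == 2

    def test_ambiguous_candidates_left_unmatched_and_flagged(self):
        a = tiny_model("a", "ERK")
        b = tiny_model("b", "ERK")
        b.species.append(Species(id="b_s2", compartment="b_c", name="ERK", cv_uris=(UNIPROT,)))
        ms = auto_match(a, b)
        assert ms.pairs("species") == set()
        assert any(
            amb["flag"]["kind"] == "annotation-name-disagreement" for amb in ms.ambiguities
        )

    def test_exact_name_breaks_uri_group_ties(self):
        # unmodified and modified forms share one URI set; names lacking
        # modification tokens still separate them when they agree exactly
        a = tiny_model("a", "Akt")
        a.species.append(Species(id="a_p", compartment="a_c", name="pAkt", cv_uris=(UNIPROT,)))
        b = tiny_model("b", "Akt")
        b.species.append(Species(id="b_p", compartment="b_c", name="pAkt", cv_uris=(UNIPROT,)))
        ms = auto_match(a, b)
        assert ms.pairs("species") == {("a_s1", "b_s1"), ("a_p", "b_p")}

    def test_symmetry_up_to_role_swap(self):
        a, b, _ = generate_toy_pair(ToyPairSpec(seed=7))
        ab = auto_match(a, b)
        ba = auto_match(b, a)
        for cls in ("compartment", "species", "reaction", "parameter"):
            assert ab.pairs(cls) == {(y, x) for x, y in ba.pairs(cls)}

    def test_self_match_is_complete(self):
        a, _, _ = generate_toy_pair(ToyPairSpec(seed=7))
        ms = auto_match(a, a)
        assert all(x == y for x, y in ms.pairs())
        assert ms.unmatched_a == [] and ms.unmatched_b == []

    def test_ground_truth_recovery(self):
        for seed in (0, 5):
            spec = ToyPairSpec(seed=seed, overlap_species=5, overlap_reactions=4)
            a, b, truth = generate_toy_pair(spec)
            ms = auto_match(a, b)
            for cls in ("compartment", "species", "reaction"):
                assert ms.pairs(cls) == truth.pairs(cls), cls

    def test_partition_invariant(self):
        a, b, _ = generate_toy_pair(ToyPairSpec(seed=2))
        ms = auto_match(a, b)
        matched_a = {(e.element_class, e.ref_a) for e in ms.entries}
        assert matched_a.isdisjoint(set(ms.unmatched_a))
        all_a = {(cls, el.id) for cls, el in _classed_elements(a)}
        assert matched_a | set(ms.unmatched_a) == all_a
        # one-to-one
        refs_a = [e.ref_a for e in ms.entries]
        refs_b = [e.ref_b for e in ms.entries]
        assert len(refs_a) == len(set(refs_a)) and len(refs_b) == len(set(refs_b))


def _classed_elements(model):
    for cls, elems in (
        ("compartment", model.compartments),
        ("species", model.species),
        ("reaction", model.reactions),
        ("parameter", model.parameters),
    ):
        for el in elems:
            yield cls, el


class TestEdits:
    def setup_method(self):
        self.a = tiny_model("a", "ERK", uris=(("is", "urn:x:1"),))
        self.a.species.append(Species(id="a_s2", compartment="a_c", name="Foo"))
        self.b = tiny_model("b", "Bar", uris=(("is", "urn:x:2"),))
        self.ms = auto_match(self.a, self.b)

    def test_add_match_marks_manual(self):
        out = apply_edits(
            self.ms, [{"op": "add-match", "ref_a": "a_s1", "ref_b": "b_s1"}]
        )
        entry = out.entry_for_a("a_s1")
        assert entry.source == "manual"
        assert entry.confidence == "user-asserted"
        assert ("species", "a_s1") not in out.unmatched_a

    def test_remove_match_returns_elements_to_unmatched(self):
        added = apply_edits(self.ms, [{"op": "add-match", "ref_a": "a_s1", "ref_b": "b_s1"}])
        out = apply_edits(added, [{"op": "remove-match", "ref_a": "a_s1", "ref_b": "b_s1"}])
        assert out.entries == []
        assert ("species", "a_s1") in out.unmatched_a
        assert ("species", "b_s1") in out.unmatched_b

    def test_class_mismatch_rejected(self):
        self.a.reactions.append(
            Reaction(id="a_r1", reactants=[("a_s1", 1.0)], products=[], kinetic_law="1")
        )
        ms = auto_match(self.a, self.b)
        with pytest.raises(EditError, match="different classes"):
            apply_edits(ms, [{"op": "add-match", "ref_a": "a_r1", "ref_b": "b_s1"}])

    def test_many_to_one_rejected(self):
        added = apply_edits(self.ms, [{"op": "add-match", "ref_a": "a_s1", "ref_b": "b_s1"}])
        with pytest.raises(EditError, match="one-to-one"):
            apply_edits(added, [{"op": "add-match", "ref_a": "a_s2", "ref_b": "b_s1"}])

    def test_unknown_refs_rejected(self):
        with pytest.raises(EditError):
            apply_edits(self.ms, [{"op": "add-match", "ref_a": "ghost", "ref_b": "b_s1"}])

    def test_original_matchset_not_mutated(self):
        apply_edits(self.ms, [{"op": "add-match", "ref_a": "a_s1", "ref_b": "b_s1"}])
        assert self.ms.entries == []


def modifier_vs_reactant_pair():
    def build(mid, as_modifier):
        model = KineticModel(
            model_id=mid,
            compartments=[Compartment(id="cell", name="cell")],
            species=[
                Species(id="S1", compartment="cell", name="S1", cv_uris=(("is", "urn:x:s1"),)),
                Species(id="S2", compartment="cell", name="S2", cv_uris=(("is", "urn:x:s2"),)),
            ],
            parameters=[Parameter(id="k", value=1.0)],
        )
        if as_modifier:
            model.reactions.append(
                Reaction(
                    id="make",
                    reactants=[],
                    products=[("S2", 1.0)],
                    modifiers=["S1"],
                    kinetic_law="k * S1",
                )
            )
        else:
            model.reactions.append(
                Reaction(
                    id="make",
                    reactants=[("S1", 1.0)],
                    products=[("S2", 1.0)],
                    kinetic_law="k * S1",
                )
            )
        return model

    return build("m1", True), build("m2", False)


class TestConflicts:
    def test_modifier_vs_reactant_flag(self):
        a, b = modifier_vs_reactant_pair()
        ms = auto_match(a, b)
        # structurally different, so not auto-matched; assert manually then classify
        ms = apply_edits(ms, [{"op": "add-match", "ref_a": "make", "ref_b": "make"}])
        out = classify_conflicts(ms, a, b)
        entry = out.entry_for_a("make")
        assert entry.has_conflict("modifier-vs-reactant")

    def test_identical_structure_different_parameters_no_flag(self):
        spec = ToyPairSpec(seed=3, divergence=10.0)
        a, b, _ = generate_toy_pair(spec)
        out = classify_conflicts(auto_match(a, b), a, b)
        for entry in out.entries:
            assert entry.conflicts == [], entry.ref_a

    def test_self_match_zero_flags(self):
        a, _, _ = generate_toy_pair(ToyPairSpec(seed=3))
        out = classify_conflicts(auto_match(a, a), a, a)
        assert all(e.conflicts == [] for e in out.entries)

    def test_different_kinetics_flag(self):
        a, b, _ = generate_toy_pair(ToyPairSpec(seed=3))
        b.get_reaction("deact1").kinetic_law = "k_deact1 * cas1_p * cas1_p"
        ms = auto_match(a, b)
        out = classify_conflicts(ms, a, b)
        entry = out.entry_for_a("deact1")
        assert entry is not None and entry.has_conflict("different-kinetics")

    def test_different_state_note_on_unmatched(self):
        a = tiny_model("a", "ERK")  # unmodified
        b = tiny_model("b", "ERK_pT188")  # modified, same database entry
        ms = auto_match(a, b)
        assert ms.pairs("species") == set()
        out = classify_conflicts(ms, a, b)
        assert any(n["flag"]["kind"] == "different-state" for n in out.notes)

    def test_modification_site_note_on_unmatched(self):
        a = tiny_model("a", "ERK_pT188")
        b = tiny_model("b", "ERK_pY190")
        out = classify_conflicts(auto_match(a, b), a, b)
        assert any(n["flag"]["kind"] == "modification-site" for n in out.notes)

    def test_level_of_detail_only_via_manual_flag(self):
        a, b, _ = generate_toy_pair(ToyPairSpec(seed=3))
        ms = classify_conflicts(auto_match(a, b), a, b)
        assert not any(e.has_conflict("level-of-detail") for e in ms.entries)
        flagged = apply_edits(
            ms,
            [
                {
                    "op": "flag",
                    "ref_a": "deact1",
                    "ref_b": "deact1",
                    "kind": "level-of-detail",
                    "detail": "lumped on one side",
                }
            ],
        )
        assert flagged.entry_for_a("deact1").has_conflict("level-of-detail")


class TestSerialization:
    def test_json_round_trip(self):
        a, b, _ = generate_toy_pair(ToyPairSpec(seed=1))
        ms = classify_conflicts(auto_match(a, b), a, b)
        again = MatchSet.from_dict(__import__("json").loads(ms.to_json()))
        assert again.pairs() == ms.pairs()
        assert again.unmatched_a == ms.unmatched_a

    def test_match_table_columns(self):
        a, b, _ = generate_toy_pair(ToyPairSpec(seed=1))
        ms = auto_match(a, b)
        table = ms.to_table(a, b)
        assert list(table.columns) == [
            "class", "id_A", "name_A", "id_B", "name_B", "source", "conflicts",
        ]
        assert len(table) == len(ms.entries)
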