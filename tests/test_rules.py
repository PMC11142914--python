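"""Rule firing, the missing-data penalty, and MYCIN accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcbfuzzy import (
    EmptyRecordError,
    InputError,
    Rule,
    Rulebook,
    RulebookError,
    SpeciesRecord,
    TraitDefinition,
    TraitSpec,
    accumulate,
    fire_rule,
    infer_species,
    missing_penalty,
)

from conftest import make_family


def mycin_closed_form(ms):
    """Independent oracle: 1 - prod(1 - m_i)."""
    return 1.0 - float(np.prod([1.0 - m for m in ms]))


RULE = Rule("t", "very_high", "F", "very_high")  # default weight 0.5


class TestFireRule:
    def test_full_premise_capped_at_weight(self):
        assert fire_rule(RULE, 1.0) == pytest.approx(0.5)

    def test_below_threshold_does_not_fire(self):
        assert fire_rule(RULE, 0.19) is None
        assert fire_rule(RULE, 0.2) is None  # strict "exceeded"
        assert fire_rule(RULE, 0.2000001) is not None

    def test_product_combiner_scales_by_premise(self):
        assert fire_rule(RULE, 0.6) == pytest.approx(0.30)

    def test_min_combiner_caps_at_weight(self):
        assert fire_rule(RULE, 0.6, combiner="min") == pytest.approx(0.5)
        assert fire_rule(RULE, 0.3, combiner="min") == pytest.approx(0.3)

    def test_premise_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            fire_rule(RULE, 1.2)

    def test_weight_validation(self):
        with pytest.raises(RulebookError):
            Rule("t", "low", "F", "low", weight=0.0)
        with pytest.raises(RulebookError):
            Rule("t", "low", "F", "low", weight=1.5)


class TestAccumulate:
    @pytest.mark.parametrize(
        "ms,expected",
        [
            ([], 0.0),
            ([0.3], 0.3),
            ([0.5, 0.5], 0.75),
            ([0.5, 0.5, 0.5], 0.875),
            ([1.0, 0.2], 1.0),
        ],
    )
    def test_frozen_examples(self, ms, expected):
        assert accumulate(ms) == pytest.approx(expected, abs=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            accumulate([0.5, 1.2])
        with pytest.raises(InputError):
            accumulate([-0.1])

    @given(ms=st.lists(st.floats(0, 1), max_size=12))
    @settings(max_examples=300)
    def test_matches_closed_form_oracle(self, ms):
        assert accumulate(ms) == pytest.approx(mycin_closed_form(ms), abs=1e-12)

    @given(ms=st.lists(st.floats(0, 1), max_size=10), seed=st.integers(0, 99))
    @settings(max_examples=200)
    def test_permutation_invariance(self, ms, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(ms))
        assert accumulate(ms) == pytest.approx(accumulate(shuffled), abs=1e-12)

    @given(ms=st.lists(st.floats(0, 1), max_size=8), extra=st.floats(0, 1))
    @settings(max_examples=200)
    def test_monotone_and_bounded(self, ms, extra):
        base = accumulate(ms)
        assert accumulate(ms + [extra]) >= base - 1e-15
        if all(m < 1.0 for m in ms):
            assert base < 1.0

    def test_weight_half_k_rule_cap(self):
        for k in range(1, 8):
            assert accumulate([0.5] * k) <= 1.0 - 0.5**k + 1e-12


class TestMissingPenalty:
    def test_single_index_default_strength(self, tiny_rulebook):
        trait = tiny_rulebook.traits["t2"].definition  # linked to F only
        assert missing_penalty(trait, tiny_rulebook) == {"F": 0.5}

    def test_penalty_applies_to_every_linked_index(self, tiny_rulebook):
        trait = tiny_rulebook.traits["t1"].definition  # linked to F and B
        assert missing_penalty(trait, tiny_rulebook) == {"B": 0.5, "F": 0.5}

    def test_undeclared_trait_is_schema_error(self, tiny_rulebook):
        alien = TraitDefinition("zz", linked_indices=frozenset({"F"}))
        with pytest.raises(RulebookError):
            missing_penalty(alien, tiny_rulebook)

    def test_configurable_penalty_degree(self, tiny_rulebook):
        from dataclasses import replace

        rb = replace(tiny_rulebook, missing_penalty_degree=0.4)
        trait = rb.traits["t2"].definition
        assert missing_penalty(trait, rb) == {"F": pytest.approx(0.2)}


class TestInferSpecies:
    def test_single_rule_single_conclusion(self):
        """One trait on its very-high plateau, one rule -> F very_high 0.5."""
        traits = {
            "t": TraitSpec(
                TraitDefinition("t", linked_indices=frozenset({"F"})),
                family=make_family("t"),
            )
        }
        rb = Rulebook(traits=traits, rules=(Rule("t", "very_high", "F", "very_high"),))
        rec = SpeciesRecord("sp", "finfish", {"t": 95.0})  # vh plateau
        acc = infer_species(rec, rb)
        assert acc["F"].degrees["very_high"] == pytest.approx(0.5)
        assert sum(acc["F"].degrees.values()) == pytest.approx(0.5)

    def test_trait_order_does_not_matter(self, tiny_rulebook):
        a = SpeciesRecord("sp", "x", {"t1": 30.0, "t2": 77.0})
        b = SpeciesRecord("sp", "x", {"t2": 77.0, "t1": 30.0})
        assert infer_species(a, tiny_rulebook) == infer_species(b, tiny_rulebook)

    def test_all_missing_closed_form(self):
        """n all-missing traits linked to F give F low = 1 - 0.5^n."""
        for n in (1, 2, 3, 5):
            traits = {
                f"t{i}": TraitSpec(
                    TraitDefinition(f"t{i}", linked_indices=frozenset({"F"})),
                    family=make_family(f"t{i}"),
                )
                for i in range(n)
            }
            rules = tuple(
                Rule(f"t{i}", "low", "F", "low") for i in range(n)
            )
            rb = Rulebook(traits=traits, rules=rules)
            rec = SpeciesRecord("sp", "x", {})
            acc = infer_species(rec, rb)
            assert acc["F"].degrees["low"] == pytest.approx(1.0 - 0.5**n)

    def test_empty_rulebook_is_an_error(self):
        rb = Rulebook(traits={}, rules=())
        with pytest.raises(EmptyRecordError):
            infer_species(SpeciesRecord("sp", "x", {}), rb)

    def test_undeclared_trait_rejected(self, tiny_rulebook):
        rec = SpeciesRecord("sp", "x", {"t1": 10.0, "mystery": 5.0})
        with pytest.raises(RulebookError):
            infer_species(rec, tiny_rulebook)

    def test_unresolved_rulebook_rejected(self):
        traits = {
            "t": TraitSpec(TraitDefinition("t", linked_indices=frozenset({"F"})))
        }
        rb = Rulebook(traits=traits, rules=())
        with pytest.raises(RulebookError):
            infer_species(SpeciesRecord("sp", "x", {"t": 1.0}), rb)


class TestRulebookValidation:
    def test_rule_must_reference_declared_trait(self):
        traits = {
            "t": TraitSpec(TraitDefinition("t", linked_indices=frozenset({"F"})))
        }
        with pytest.raises(RulebookError):
            Rulebook(traits=traits, rules=(Rule("other", "low", "F", "low"),))

    def test_rule_index_must_be_linked(self):
        traits = {
            "t": TraitSpec(TraitDefinition("t", linked_indices=frozenset({"F"})))
        }
        with pytest.raises(RulebookError):
            Rulebook(traits=traits, rules=(Rule("t", "low", "B", "low"),))

    def test_duplicate_premise_rejected(self):
        traits = {
            "t": TraitSpec(TraitDefinition("t", linked_indices=frozenset({"F"})))
        }
        rules = (Rule("t", "low", "F", "low"), Rule("t", "low", "F", "medium"))
        with pytest.raises(RulebookError):
            Rulebook(traits=traits, rules=rules)

    def test_remove_trait_strips_rules_and_penalty(self, tiny_rulebook):
        rb = tiny_rulebook.remove_trait("t1")
        assert "t1" not in rb.traits
        assert all(r.trait_id != "t1" for r in rb.rules)
        rec = SpeciesRecord("sp", "x", {})
        acc = infer_species(rec, rb)
        # only t2's penalty remains
        assert acc["F"].degrees["low"] == pytest.approx(0.5)
        assert acc["B"].degrees["low"] == 0.0

    def test_content_hash_tracks_rule_changes(self, tiny_rulebook):
        from dataclasses import replace

        h0 = tiny_rulebook.content_hash()
        flipped = list(tiny_rulebook.rules)
        flipped[0] = replace(flipped[0], conclusion="very_high")
        rb2 = replace(tiny_rulebook, rules=tuple(flipped))
        assert rb2.content_hash() != h0
        assert tiny_rulebook.content_hash() == h0
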