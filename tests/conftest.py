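import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from fcbfuzzy import (
    FuzzySetFamily,
    MembershipFunction,
    Rule,
    Rulebook,
    TraitDefinition,
    TraitSpec,
)


def make_family(trait_id="t", lo=0.0, hi=100.0):
    """A hand-placed, fully explicit family on [0, 100]."""
    scale = (hi - lo) / 100.0

    def s(*bps):
        return tuple(lo + b * scale for b in bps)

    return FuzzySetFamily(
        trait_id=trait_id,
        functions={
            "low": MembershipFunction("low", "trapezoid", s(0, 0, 20, 35)),
            "medium": MembershipFunction("medium", "triangular", s(20, 40, 60)),
            "high": MembershipFunction("high", "triangular", s(45, 65, 85)),
            "very_high": MembershipFunction(
                "very_high", "trapezoid", s(70, 85, 100, 100)
            ),
        },
        domain=(lo, hi),
    )


def monotone_rules(trait_id, index):
    cats = ("low", "medium", "high", "very_high")
    return [Rule(trait_id, c, index, c) for c in cats]


@pytest.fixture
def family():
    return make_family()


@pytest.fixture
def tiny_rulebook():
    """Two explicit traits: t1 -> F and B (monotone), t2 -> F (monotone)."""
    traits = {
        "t1": TraitSpec(
            TraitDefinition("t1", linked_indices=frozenset({"F", "B"})),
            family=make_family("t1"),
        ),
        "t2": TraitSpec(
            TraitDefinition("t2", linked_indices=frozenset({"F"})),
            family=make_family("t2"),
        ),
    }
    rules = (
        monotone_rules("t1", "F") + monotone_rules("t1", "B")
        + monotone_rules("t2", "F")
    )
    return Rulebook(traits=traits, rules=tuple(rules))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fitted_default():
    """Default rulebook resolved on the default 54-species synthetic table."""
    from fcbfuzzy import FCBModel, SyntheticConfig, generate_table

    records = generate_table(SyntheticConfig(seed=20240917))
    model = FCBModel(records)
    return model, model.fit()
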