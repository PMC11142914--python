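"""Fuzzy inference: heuristic rules, the missing-data penalty, and MYCIN
accumulation of conclusion memberships per FCB index.

Each rule maps one linguistic category of one trait to a potential category
of one index, with a weight (default 0.5, i.e. 50% belief in the rule, so a
fully satisfied premise concludes with membership at most 0.5).  A rule fires
only when the premise membership strictly exceeds the firing threshold
(default 0.2).  Conclusions landing in the same (index, category) slot are
combined with the MYCIN update

    AccMem <- AccMem + m * (1 - AccMem)

which is associative and commutative (it equals 1 - prod(1 - m_i)), so the
order in which traits are processed never matters.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

from .errors import EmptyRecordError, InputError, RulebookError
from .fuzzy import (
    CATEGORIES,
    DEFAULT_FLOOR,
    INDICES,
    FuzzySetFamily,
    TraitDefinition,
    build_family_from_quantiles,
    fuzzify,
    is_missing,
    MISSING,
)

#: Potential-category index values used at defuzzification.
DEFAULT_INDEX_VALUES = {"low": 1.0, "medium": 25.0, "high": 75.0, "very_high": 100.0}

DEFAULT_WEIGHT = 0.5
DEFAULT_THRESHOLD = 0.2


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: identifier, taxon label, and trait values.

    Trait values may be None/NaN (missing).  Traits absent from the mapping
    are treated identically to missing values.
    """

    species_id: str
    taxon: str
    traits: dict[str, float | None] = field(default_factory=dict)


@dataclass(frozen=True)
class Rule:
    """If trait is <premise category> then index potential is <conclusion>."""

    trait_id: str
    premise: str
    index: str
    conclusion: str
    weight: float = DEFAULT_WEIGHT

    def __post_init__(self):
        if self.premise not in CATEGORIES:
            raise RulebookError(f"unknown premise category {self.premise!r}")
        if self.conclusion not in CATEGORIES:
            raise RulebookError(f"unknown conclusion category {self.conclusion!r}")
        if self.index not in INDICES:
            raise RulebookError(f"unknown index {self.index!r}")
        if not 0.0 < self.weight <= 1.0:
            raise RulebookError(
                f"rule weight must lie in (0, 1], got {self.weight}"
            )


@dataclass(frozen=True)
class TraitSpec:
    """A trait declaration plus how to obtain its fuzzy-set family.

    Either an explicit family is given, or one is estimated from data with
    the quantile recipe at ``fuzziness`` when the rulebook is resolved.
    """

    definition: TraitDefinition
    family: FuzzySetFamily | None = None
    fuzziness: float = 0.5


@dataclass(frozen=True)
class AccumulatedMembership:
    """MYCIN-accumulated memberships of one species in one index."""

    index: str
    degrees: dict[str, float]
    contributing_rules: dict[str, int] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.degrees.values())


@dataclass(frozen=True)
class Rulebook:
    """Complete configuration of the expert system.

    Holds trait declarations (with fuzzy-set specs), the rule list, the two
    0.2 thresholds (fuzzification retention and rule firing, independently
    configurable), defuzzification index values, and the missing-data
    penalty degree.
    """

    traits: dict[str, TraitSpec]
    rules: tuple[Rule, ...]
    firing_threshold: float = DEFAULT_THRESHOLD
    retention_floor: float = DEFAULT_FLOOR
    index_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_VALUES)
    )
    missing_penalty_degree: float = 1.0
    combiner: str = "product"
    default_weight: float = DEFAULT_WEIGHT

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        if not 0.0 < self.firing_threshold < 1.0:
            raise RulebookError(
                f"firing_threshold must lie in (0, 1), got {self.firing_threshold}"
            )
        if not 0.0 <= self.retention_floor < 1.0:
            raise RulebookError(
                f"retention_floor must lie in [0, 1), got {self.retention_floor}"
            )
        if not 0.0 <= self.missing_penalty_degree <= 1.0:
            raise RulebookError("missing_penalty_degree must lie in [0, 1]")
        if self.combiner not in ("product", "min"):
            raise RulebookError(f"unknown combiner {self.combiner!r}")
        if set(self.index_values) != set(CATEGORIES):
            raise RulebookError(
                "index_values must map exactly the four potential categories"
            )
        seen = set()
        for r in self.rules:
            if r.trait_id not in self.traits:
                raise RulebookError(
                    f"rule references undeclared trait {r.trait_id!r}"
                )
            linked = self.traits[r.trait_id].definition.linked_indices
            if r.index not in linked:
                raise RulebookError(
                    f"rule {r.trait_id}/{r.premise} -> {r.index}: trait is "
                    f"linked only to {sorted(linked)}"
                )
            key = (r.trait_id, r.premise, r.index)
            if key in seen:
                raise RulebookError(
                    f"duplicate rule for (trait={r.trait_id!r}, "
                    f"premise={r.premise!r}, index={r.index!r})"
                )
            seen.add(key)

    # -- convenience ------------------------------------------------------
    @property
    def trait_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.traits))

    @property
    def covered_indices(self) -> frozenset[str]:
        """Indices that at least one declared trait is linked to."""
        out: set[str] = set()
        for spec in self.traits.values():
            out |= spec.definition.linked_indices
        return frozenset(out)

    def rules_for(self, trait_id: str, premise: str) -> list[Rule]:
        return [
            r for r in self.rules
            if r.trait_id == trait_id and r.premise == premise
        ]

    def remove_trait(self, trait_id: str) -> "Rulebook":
        """A new rulebook without the trait, its rules, or its penalty."""
        if trait_id not in self.traits:
            raise RulebookError(f"cannot remove undeclared trait {trait_id!r}")
        return replace(
            self,
            traits={k: v for k, v in self.traits.items() if k != trait_id},
            rules=tuple(r for r in self.rules if r.trait_id != trait_id),
        )

    def remove_traits(self, trait_ids) -> "Rulebook":
        rb = self
        for tid in trait_ids:
            rb = rb.remove_trait(tid)
        return rb

    def resolve_families(self, trait_values: dict[str, list[float]]) -> "Rulebook":
        """Fill in quantile-recipe families from observed trait values.

        ``trait_values`` maps trait_id to the non-missing observations; traits
        that already carry an explicit family are left untouched.
        """
        traits = {}
        for tid, spec in self.traits.items():
            if spec.family is not None:
                traits[tid] = spec
            else:
                fam = build_family_from_quantiles(
                    trait_values.get(tid, []),
                    fuzziness=spec.fuzziness,
                    trait_id=tid,
                )
                traits[tid] = replace(spec, family=fam)
        return replace(self, traits=traits)

    @property
    def is_resolved(self) -> bool:
        return all(s.family is not None for s in self.traits.values())

    def content_hash(self) -> str:
        """Stable hash of the full configuration, for output provenance."""
        payload = {
            "traits": {
                tid: {
                    "linked": sorted(s.definition.linked_indices),
                    "units": s.definition.units,
                    "fuzziness": s.fuzziness,
                    "family": None if s.family is None else {
                        c: list(s.family.functions[c].breakpoints)
                        for c in CATEGORIES
                    },
                }
                for tid, s in sorted(self.traits.items())
            },
            "rules": sorted(
                (r.trait_id, r.premise, r.index, r.conclusion, r.weight)
                for r in self.rules
            ),
            "firing_threshold": self.firing_threshold,
            "retention_floor": self.retention_floor,
            "index_values": self.index_values,
            "missing_penalty_degree": self.missing_penalty_degree,
            "combiner": self.combiner,
            "default_weight": self.default_weight,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def fire_rule(
    rule: Rule,
    premise_degree: float,
    threshold: float = DEFAULT_THRESHOLD,
    combiner: str = "product",
) -> float | None:
    """Conclusion membership from one rule, or None if it does not fire.

    Fires only when the premise degree strictly exceeds the threshold.  The
    conclusion strength is ``weight * premise`` (default) or
    ``min(weight, premise)``; either way it is capped by the rule weight.
    """
    if not 0.0 <= premise_degree <= 1.0:
        raise InputError(
            f"premise degree must lie in [0, 1], got {premise_degree}"
        )
    if premise_degree <= threshold:
        return None
    if combiner == "product":
        return rule.weight * premise_degree
    if combiner == "min":
        return min(rule.weight, premise_degree)
    raise RulebookError(f"unknown combiner {combiner!r}")


def missing_penalty(
    trait: TraitDefinition, rulebook: Rulebook
) -> dict[str, float]:
    """Low-potential conclusions emitted when a trait value is missing.

    Returns {index: conclusion membership}; the conclusion always lands in
    the *low* potential category of every index the trait informs, with
    strength ``default_weight * missing_penalty_degree``.
    """
    if trait.trait_id not in rulebook.traits:
        raise RulebookError(
            f"trait {trait.trait_id!r} is not declared in the rulebook"
        )
    m = rulebook.default_weight * rulebook.missing_penalty_degree
    return {idx: m for idx in sorted(trait.linked_indices)}


def accumulate(memberships) -> float:
    """Combine conclusion memberships with the MYCIN recurrence.

    Sequentially applies ``acc <- acc + m * (1 - acc)``; an empty list gives
    0.  The result is permutation-invariant and monotone in every input.
    """
    acc = 0.0
    for m in memberships:
        m = float(m)
        if not 0.0 <= m <= 1.0 or not math.isfinite(m):
            raise InputError(f"membership degrees must lie in [0, 1], got {m}")
        acc = acc + m * (1.0 - acc)
    return acc


def infer_species(
    record: SpeciesRecord, rulebook: Rulebook
) -> dict[str, AccumulatedMembership]:
    """Run the full inference chain for one species.

    Every trait declared in the rulebook is processed: present values are
    fuzzified and fire their rules; missing values (absent key, None or NaN)
    emit the low-potential penalty for each linked index.  Conclusions are
    accumulated per (index, potential category) with MYCIN.
    """
    if not rulebook.is_resolved:
        raise RulebookError(
            "rulebook has unresolved fuzzy-set families; call "
            "resolve_families() with the trait table first"
        )
    unknown = set(record.traits) - set(rulebook.traits)
    if unknown:
        raise RulebookError(
            f"species {record.species_id!r} carries undeclared traits "
            f"{sorted(unknown)}"
        )
    declared = rulebook.trait_ids
    if not declared:
        raise EmptyRecordError(
            f"species {record.species_id!r}: rulebook declares no traits"
        )

    conclusions: dict[str, dict[str, list[float]]] = {
        idx: {c: [] for c in CATEGORIES} for idx in INDICES
    }
    for tid in declared:  # sorted; order is irrelevant by commutativity
        spec = rulebook.traits[tid]
        value = record.traits.get(tid, MISSING)
        if is_missing(value):
            for idx, m in missing_penalty(spec.definition, rulebook).items():
                conclusions[idx]["low"].append(m)
            continue
        cm = fuzzify(value, spec.family, floor=rulebook.retention_floor)
        for premise_cat, degree in cm.degrees.items():
            for rule in rulebook.rules_for(tid, premise_cat):
                m = fire_rule(
                    rule, degree, rulebook.firing_threshold, rulebook.combiner
                )
                if m is not None:
                    conclusions[rule.index][rule.conclusion].append(m)

    out = {}
    for idx in INDICES:
        degrees = {c: accumulate(ms) for c, ms in conclusions[idx].items()}
        counts = {c: len(ms) for c, ms in conclusions[idx].items()}
        out[idx] = AccumulatedMembership(
            index=idx, degrees=degrees, contributing_rules=counts
        )
    return out
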