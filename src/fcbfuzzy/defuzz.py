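"""Defuzzification: collapse accumulated memberships into 1-100 scores.

The crisp score is the membership-weighted average of fixed category index
values (low = 1, medium = 25, high = 75, very high = 100 by default):

    FinInd = sum(AccMem_x * Ind_x) / sum(AccMem_x)

A species with zero accumulated membership everywhere for an index has no
defined score; that is treated as an error, never silently reported as 0 —
the missing-data penalty makes it unreachable for any trait the rulebook
declares, so hitting it signals a data or rulebook defect.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import UndefinedScoreError
from .fuzzy import CATEGORIES, INDICES
from .rules import (
    AccumulatedMembership,
    Rulebook,
    SpeciesRecord,
    infer_species,
)


@dataclass(frozen=True)
class FCBScore:
    """Defuzzified food-security, climate, and biodiversity scores (1-100)."""

    species_id: str
    taxon: str
    f_score: float
    c_score: float
    b_score: float

    @property
    def mean_score(self) -> float:
        return (self.f_score + self.c_score + self.b_score) / 3.0

    def as_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "taxon": self.taxon,
            "f_score": self.f_score,
            "c_score": self.c_score,
            "b_score": self.b_score,
            "mean_score": self.mean_score,
        }


def defuzzify(
    acc: AccumulatedMembership | dict,
    index_values: dict[str, float] | None = None,
) -> float:
    """Membership-weighted average of the category index values."""
    from .rules import DEFAULT_INDEX_VALUES

    degrees = acc.degrees if isinstance(acc, AccumulatedMembership) else acc
    iv = index_values if index_values is not None else DEFAULT_INDEX_VALUES
    num = 0.0
    den = 0.0
    for cat in CATEGORIES:
        m = float(degrees.get(cat, 0.0))
        num += m * iv[cat]
        den += m
    if den <= 0.0:
        idx = acc.index if isinstance(acc, AccumulatedMembership) else "?"
        raise UndefinedScoreError(idx)
    return num / den


def score_species(
    record: SpeciesRecord, rulebook: Rulebook
) -> tuple[FCBScore, dict[str, AccumulatedMembership]]:
    """Infer and defuzzify all three indices for one species.

    Indices that no declared trait links to are outside the rulebook's scope
    and come back as NaN; a *covered* index left with zero accumulated
    membership is a defect and raises.
    """
    accs = infer_species(record, rulebook)
    covered = rulebook.covered_indices
    scores = {}
    for idx in INDICES:
        if idx not in covered:
            scores[idx] = float("nan")
            continue
        try:
            scores[idx] = defuzzify(accs[idx], rulebook.index_values)
        except UndefinedScoreError as exc:
            raise UndefinedScoreError(idx, record.species_id) from exc
    return (
        FCBScore(
            species_id=record.species_id,
            taxon=record.taxon,
            f_score=scores["F"],
            c_score=scores["C"],
            b_score=scores["B"],
        ),
        accs,
    )


def score_table(
    records, rulebook: Rulebook
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every species; return (scores, long-format memberships).

    The scores frame has one row per species (species_id, taxon, f_score,
    c_score, b_score, mean_score); the memberships frame is the audit trail
    with one row per (species, index, potential category).
    """
    rows, mem_rows = [], []
    for rec in records:
        score, accs = score_species(rec, rulebook)
        rows.append(score.as_dict())
        for idx in INDICES:
            for cat in CATEGORIES:
                mem_rows.append(
                    {
                        "species_id": rec.species_id,
                        "index": idx,
                        "category": cat,
                        "acc_membership": accs[idx].degrees[cat],
                        "n_conclusions": accs[idx].contributing_rules[cat],
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(mem_rows)
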