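"""Model/Results facade over the fuzzy scoring pipeline.

``FCBModel`` binds a species-by-trait table to a rulebook; ``fit()``
estimates the quantile-recipe fuzzy-set families from the observed trait
distributions, runs inference and defuzzification for every species, and
returns an ``FCBResults`` with the scores, the accumulated-membership audit
trail, and methods for the downstream analyses (rankings, Kendall
correlations, taxa comparisons, jackknife sensitivity).
"""

from __future__ import annotations

import pandas as pd

from .defuzz import score_table
from .errors import InputError
from .io import read_trait_table, trait_values_by_trait
from .rules import Rulebook, SpeciesRecord
from .synthetic import default_rulebook


class FCBModel:
    """Fuzzy expert system for FCB contribution potential.

    Parameters
    ----------
    data :
        Either a pandas DataFrame with columns ``species_id, taxon,
        <trait columns>`` (NaN = missing) or a list of ``SpeciesRecord``.
    rulebook :
        The system configuration; defaults to the shipped rulebook.
    """

    def __init__(self, data, rulebook: Rulebook | None = None):
        self.rulebook = rulebook if rulebook is not None else default_rulebook()
        if isinstance(data, pd.DataFrame):
            self.records = _records_from_dataframe(data, self.rulebook)
        else:
            self.records = list(data)
        if not self.records:
            raise InputError("no species to score")

    @classmethod
    def from_csv(cls, path, rulebook: Rulebook | None = None) -> "FCBModel":
        rb = rulebook if rulebook is not None else default_rulebook()
        return cls(read_trait_table(path, rb), rulebook=rb)

    def fit(self) -> "FCBResults":
        """Estimate fuzzy-set families from the data and score all species."""
        rb = self.rulebook
        if not rb.is_resolved:
            rb = rb.resolve_families(trait_values_by_trait(self.records))
        scores, memberships = score_table(self.records, rb)
        return FCBResults(self, rb, scores, memberships)


class FCBResults:
    """Fitted scores plus the downstream analyses.

    Attributes
    ----------
    scores : DataFrame
        One row per species: f_score, c_score, b_score, mean_score (1-100).
    memberships : DataFrame
        Long-format accumulated memberships per (species, index, category).
    rulebook : Rulebook
        The resolved configuration (explicit breakpoints for every trait).
    """

    def __init__(self, model, rulebook, scores, memberships):
        self.model = model
        self.rulebook = rulebook
        self.scores = scores
        self.memberships = memberships

    # -- downstream analyses ---------------------------------------------
    def rank_table(self) -> pd.DataFrame:
        from .stats import rank_table
        return rank_table(self.scores)

    def correlations(self) -> pd.DataFrame:
        from .stats import index_correlations
        return index_correlations(self.scores)

    def compare_taxa(self, index: str = "F", p_adjust: str = "holm"):
        from .stats import group_compare
        col = {"F": "f_score", "C": "c_score", "B": "b_score",
               "mean": "mean_score"}[index]
        return group_compare(
            self.scores[col].to_numpy(),
            self.scores["taxon"].to_numpy(),
            p_adjust=p_adjust,
        )

    def extreme_subset(self, index: str = "F", k: int = 10, tail: str = "top",
                       seed: int | None = None):
        from .stats import extreme_subset_test
        col = {"F": "f_score", "C": "c_score", "B": "b_score"}[index]
        return extreme_subset_test(
            self.scores[col].to_numpy(), k=k, tail=tail, seed=seed
        )

    def jackknife(self, mode: str = "single", n_remove: int = 1,
                  reps: int = 50, seed: int | None = None,
                  denominator: str = "baseline_max") -> pd.DataFrame:
        from .sensitivity import jackknife_multi, jackknife_single
        if mode == "single":
            return jackknife_single(
                self.model.records, self.rulebook, denominator=denominator
            )
        if mode == "multi":
            return jackknife_multi(
                self.model.records, self.rulebook, n_remove=n_remove,
                reps=reps, seed=seed, denominator=denominator,
            )
        raise InputError(f"mode must be 'single' or 'multi', got {mode!r}")

    def plot_jackknife(self, deviations=None, index: str = "F", ax=None):
        from .sensitivity import plot_jackknife
        if deviations is None:
            deviations = self.jackknife()
        return plot_jackknife(deviations, ax=ax, index=index)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Text report: score distributions, taxa medians, correlations."""
        lines = []
        n = len(self.scores)
        lines.append("FCB contribution potential — fuzzy expert system fit")
        lines.append("=" * 60)
        lines.append(
            f"species: {n}    traits: {len(self.rulebook.traits)}    "
            f"rules: {len(self.rulebook.rules)}"
        )
        lines.append(f"rulebook hash: {self.rulebook.content_hash()}")
        lines.append("")
        desc = self.scores[["f_score", "c_score", "b_score", "mean_score"]]
        stats = desc.agg(["mean", "std", "min", "median", "max"]).round(1)
        lines.append("score distributions (1-100):")
        lines.append(stats.to_string())
        lines.append("")
        med = (
            self.scores.groupby("taxon")[["f_score", "c_score", "b_score"]]
            .median()
            .round(1)
        )
        lines.append("median scores by taxon:")
        lines.append(med.to_string())
        lines.append("")
        corr = self.correlations().round(4)
        lines.append("Kendall rank correlations between indices:")
        lines.append(corr.to_string(index=False))
        return "\n".join(lines)


def _records_from_dataframe(df: pd.DataFrame, rulebook: Rulebook):
    required = {"species_id", "taxon"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"data frame lacks mandatory column(s) {sorted(missing)}")
    trait_cols = [c for c in df.columns if c not in required]
    unknown = [c for c in trait_cols if c not in rulebook.traits]
    if unknown:
        raise InputError(f"column(s) {unknown} are not declared in the rulebook")
    records = []
    for _, row in df.iterrows():
        traits = {
            c: (None if pd.isna(row[c]) else float(row[c])) for c in trait_cols
        }
        records.append(
            SpeciesRecord(
                species_id=str(row["species_id"]),
                taxon=str(row["taxon"]),
                traits=traits,
            )
        )
    return records
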