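"""Jackknife trait-removal sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from fcbfuzzy import (
    InputError,
    Rule,
    Rulebook,
    SpeciesRecord,
    TraitDefinition,
    TraitSpec,
    jackknife_multi,
    jackknife_single,
    max_index,
    score_table,
    summarize_jackknife,
)

from conftest import make_family, monotone_rules


class TestMaxIndex:
    def test_single_species(self):
        df = pd.DataFrame({"f_score": [61.0], "c_score": [66.0], "b_score": [68.0]})
        assert max_index(df, "F") == 61.0
        assert max_index(df, "C") == 66.0
        assert max_index(df, "B") == 68.0

    def test_matches_brute_force_max(self, fitted_default):
        _, res = fitted_default
        assert max_index(res.scores, "F") == res.scores["f_score"].to_numpy().max()

    def test_empty_and_unknown_index_rejected(self):
        with pytest.raises(InputError):
            max_index(pd.DataFrame({"f_score": []}), "F")
        with pytest.raises(InputError):
            max_index(pd.DataFrame({"f_score": [1.0]}), "Z")


class TestJackknifeSingle:
    def test_removing_nothing_changes_nothing(self, fitted_default):
        model, res = fitted_default
        again, _ = score_table(model.records, res.rulebook.remove_traits(()))
        pd.testing.assert_frame_equal(res.scores, again)

    def test_trait_without_rules_for_an_index_is_a_noop_there(self, fitted_default):
        model, res = fitted_default
        dev = jackknife_single(model.records, res.rulebook)
        # ph_sensitivity informs only C; F and B must be untouched
        sub = dev[dev["removed_traits"] == "ph_sensitivity"]
        for idx in ("F", "B"):
            assert (sub.loc[sub["index"] == idx, "deviation"] == 0.0).all()
        assert (sub.loc[sub["index"] == "C", "deviation"] != 0.0).any()

    def test_percent_variation_definition(self, fitted_default):
        model, res = fitted_default
        dev = jackknife_single(model.records, res.rulebook)
        denom = {idx: max_index(res.scores, idx) for idx in ("F", "C", "B")}
        expect = dev.apply(
            lambda r: r["deviation"] / denom[r["index"]] * 100.0, axis=1
        )
        np.testing.assert_allclose(
            dev["percent_variation"].to_numpy(dtype=float),
            expect.to_numpy(dtype=float),
        )

    def test_removing_a_top_category_trait_never_raises_scores(self):
        """A trait concluding only to the very-high category can only pull
        scores toward the maximum; removing it gives non-positive deviations
        for every species (mass removed at the top index value)."""
        traits = {
            "up": TraitSpec(
                TraitDefinition("up", linked_indices=frozenset({"F"})),
                family=make_family("up"),
            ),
            "base": TraitSpec(
                TraitDefinition("base", linked_indices=frozenset({"F"})),
                family=make_family("base"),
            ),
        }
        up_rules = [
            Rule("up", premise, "F", "very_high")
            for premise in ("low", "medium", "high", "very_high")
        ]
        rb = Rulebook(
            traits=traits,
            rules=tuple(up_rules + monotone_rules("base", "F")),
        )
        rng = np.random.default_rng(7)
        records = [
            SpeciesRecord(
                f"s{i}", "x",
                {"up": rng.uniform(0, 100), "base": rng.uniform(0, 100)},
            )
            for i in range(30)
        ]
        dev = jackknife_single(records, rb)
        f_dev = dev.loc[
            (dev["index"] == "F") & (dev["removed_traits"] == "up"), "deviation"
        ]
        assert (f_dev <= 1e-12).all()
        assert (f_dev < 0).any()

    def test_duplicate_trait_removal_closed_form(self):
        """Two identical traits firing the same conclusion: removal changes
        AccMem from 1-(1-m)^2 to m, with a hand-computable score shift."""
        fam = make_family
        traits = {
            "a": TraitSpec(
                TraitDefinition("a", linked_indices=frozenset({"F"})),
                family=fam("a"),
            ),
            "b": TraitSpec(
                TraitDefinition("b", linked_indices=frozenset({"F"})),
                family=fam("b"),
            ),
            "c": TraitSpec(
                TraitDefinition("c", linked_indices=frozenset({"F"})),
                family=fam("c"),
            ),
        }
        rules = (
            Rule("a", "very_high", "F", "very_high"),
            Rule("b", "very_high", "F", "very_high"),
            Rule("c", "low", "F", "low"),
        )
        rb = Rulebook(traits=traits, rules=rules)
        # values on plateaus: premises 1.0 -> conclusions m = 0.5
        rec = SpeciesRecord("sp", "x", {"a": 95.0, "b": 95.0, "c": 5.0})
        baseline = (0.75 * 100 + 0.5 * 1) / (0.75 + 0.5)  # vh acc = 1-(1-.5)^2
        reduced = (0.5 * 100 + 0.5 * 1) / (0.5 + 0.5)     # vh acc = 0.5
        dev = jackknife_single([rec], rb)
        row = dev[(dev["removed_traits"] == "b") & (dev["index"] == "F")]
        assert row["baseline_score"].iloc[0] == pytest.approx(baseline)
        assert row["deviation"].iloc[0] == pytest.approx(reduced - baseline)

    def test_removal_leaving_an_index_undefined_is_flagged_not_fatal(self):
        traits = {
            "only_b": TraitSpec(
                TraitDefinition("only_b", linked_indices=frozenset({"B"})),
                family=make_family("only_b"),
            ),
            "f1": TraitSpec(
                TraitDefinition("f1", linked_indices=frozenset({"F"})),
                family=make_family("f1"),
            ),
            "c1": TraitSpec(
                TraitDefinition("c1", linked_indices=frozenset({"C"})),
                family=make_family("c1"),
            ),
        }
        rules = tuple(
            monotone_rules("only_b", "B") + monotone_rules("f1", "F")
            + monotone_rules("c1", "C")
        )
        rb = Rulebook(traits=traits, rules=rules)
        rec = SpeciesRecord("sp", "x", {"only_b": 50.0, "f1": 50.0, "c1": 50.0})
        dev = jackknife_single([rec], rb)
        flagged = dev[(dev["removed_traits"] == "only_b") & (dev["index"] == "B")]
        assert flagged["undefined"].all()
        assert flagged["deviation"].isna().all()
        # F rows for the same removal are intact
        ok = dev[(dev["removed_traits"] == "only_b") & (dev["index"] == "F")]
        assert not ok["undefined"].any()

    def test_needs_two_traits(self, fitted_default):
        model, res = fitted_default
        rb = res.rulebook.remove_traits(res.rulebook.trait_ids[1:])
        with pytest.raises(InputError):
            jackknife_single(model.records, rb)


class TestJackknifeMulti:
    def test_same_seed_reproducible(self, fitted_default):
        model, res = fitted_default
        a = jackknife_multi(model.records, res.rulebook, 3, reps=5, seed=11)
        b = jackknife_multi(model.records, res.rulebook, 3, reps=5, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_single_removal_marginals_match_exhaustive(self, fitted_default):
        model, res = fitted_default
        exhaustive = jackknife_single(model.records, res.rulebook)
        sampled = jackknife_multi(
            model.records, res.rulebook, n_remove=1, reps=30, seed=5
        )
        key = ["removed_traits", "species_id", "index"]
        merged = sampled.merge(
            exhaustive[key + ["deviation"]], on=key, suffixes=("", "_exh")
        )
        assert len(merged) == len(sampled)
        np.testing.assert_allclose(
            merged["deviation"].to_numpy(dtype=float),
            merged["deviation_exh"].to_numpy(dtype=float),
        )

    def test_n_remove_range_validated(self, fitted_default):
        model, res = fitted_default
        n = len(res.rulebook.trait_ids)
        with pytest.raises(InputError):
            jackknife_multi(model.records, res.rulebook, n, reps=2, seed=0)
        with pytest.raises(InputError):
            jackknife_multi(model.records, res.rulebook, 0, reps=2, seed=0)

    def test_leave_one_trait_matches_direct_one_trait_pipeline(self, fitted_default):
        from dataclasses import replace

        model, res = fitted_default
        n = len(res.rulebook.trait_ids)
        dev = jackknife_multi(
            model.records, res.rulebook, n_remove=n - 1, reps=4, seed=21
        )
        for removed_label, group in dev.groupby("removed_traits"):
            removed = set(removed_label.split("+"))
            (kept,) = set(res.rulebook.trait_ids) - removed
            rb_one = res.rulebook.remove_traits(
                [t for t in res.rulebook.trait_ids if t != kept]
            )
            records_one = [
                replace(r, traits={k: v for k, v in r.traits.items() if k == kept})
                for r in model.records
            ]
            direct, _ = score_table(records_one, rb_one)
            direct = direct.set_index("species_id")
            col = {"F": "f_score", "C": "c_score", "B": "b_score"}
            for _, row in group[~group["undefined"]].iterrows():
                expect = direct.loc[row["species_id"], col[row["index"]]]
                got = row["baseline_score"] + row["deviation"]
                assert got == pytest.approx(expect, abs=1e-9)


def test_summary_reports_median_min_max(fitted_default):
    model, res = fitted_default
    dev = jackknife_single(model.records, res.rulebook)
    summ = summarize_jackknife(dev)
    assert set(summ["index"]) == {"F", "C", "B"}
    one = summ[(summ["removed_traits"] == "fecundity") & (summ["index"] == "F")]
    sub = dev[
        (dev["removed_traits"] == "fecundity") & (dev["index"] == "F")
    ]["percent_variation"]
    assert one["median_pct"].iloc[0] == pytest.approx(sub.median())
    assert one["min_pct"].iloc[0] == pytest.approx(sub.min())
    assert one["max_pct"].iloc[0] == pytest.approx(sub.max())
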