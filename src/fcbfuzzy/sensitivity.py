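"""Jackknife sensitivity analysis: remove traits, re-score, measure deviation.

Removing a trait removes the trait itself, all rules referencing it, and its
missing-data penalty — the trait ceases to exist rather than becoming
"missing".  Deviations are reported in index points
(score_removed - score_baseline) and as percent variation, i.e. deviation
divided by the maximum baseline score across species for that index
(optionally the theoretical maximum 100), times 100.

Two modes: exhaustive single-trait removal, and repeated random removal of
k traits at a time (default 50 replicates per k), which traces how the
indices degrade as fewer inputs are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedScoreError
from .fuzzy import INDICES
from .rules import Rulebook
from .defuzz import score_table

_IDX_COL = {"F": "f_score", "C": "c_score", "B": "b_score"}


def max_index(scores: pd.DataFrame, index: str) -> float:
    """Maximum baseline score across species for one index.

    This is the percent-variation denominator; it is fixed by the baseline
    run and does not change across removals.
    """
    if index not in _IDX_COL:
        raise InputError(f"unknown index {index!r}")
    col = scores[_IDX_COL[index]]
    if len(col) == 0:
        raise InputError("cannot take the maximum of an empty score table")
    return float(col.max())


def _deviation_rows(records, rulebook, baseline, denominators, removed, rep=None):
    """Deviations of a reduced system from baseline, one row per species x index."""
    from dataclasses import replace as _replace

    reduced = rulebook.remove_traits(removed)
    removed_set = set(removed)
    # the trait ceases to exist: strip it from the records too, so it is
    # neither fuzzified nor penalized as missing
    records = [
        _replace(
            rec,
            traits={k: v for k, v in rec.traits.items() if k not in removed_set},
        )
        for rec in records
    ]
    removed_label = "+".join(sorted(removed))
    base = baseline.set_index("species_id")
    covered_before = rulebook.covered_indices
    covered_after = reduced.covered_indices
    rows = []
    try:
        scores, _ = score_table(records, reduced)
        scores = scores.set_index("species_id")
        failed = set()
    except UndefinedScoreError:
        # at least one species lost all conclusions for an index; fall back
        # to per-species scoring so the failures are reported, not fatal
        scores, failed = _score_per_species(records, reduced)
    for rec in records:
        for idx in sorted(covered_before):
            col = _IDX_COL[idx]
            b = float(base.loc[rec.species_id, col])
            if idx not in covered_after or (rec.species_id, idx) in failed:
                dev = np.nan
                undefined = True
            else:
                dev = float(scores.loc[rec.species_id, col]) - b
                undefined = False
            rows.append(
                {
                    "removed_traits": removed_label,
                    "n_removed": len(removed),
                    "replicate_id": rep,
                    "species_id": rec.species_id,
                    "index": idx,
                    "baseline_score": b,
                    "deviation": dev,
                    "percent_variation": dev / denominators[idx] * 100.0,
                    "undefined": undefined,
                }
            )
    return rows


def _score_per_species(records, rulebook):
    """Score species one at a time, collecting undefined (species, index)."""
    from .defuzz import defuzzify
    from .rules import infer_species

    rows, failed = [], set()
    for rec in records:
        accs = infer_species(rec, rulebook)
        row = {"species_id": rec.species_id}
        for idx in INDICES:
            try:
                row[_IDX_COL[idx]] = defuzzify(accs[idx], rulebook.index_values)
            except UndefinedScoreError:
                row[_IDX_COL[idx]] = np.nan
                failed.add((rec.species_id, idx))
        rows.append(row)
    return pd.DataFrame(rows).set_index("species_id"), failed


def _denominators(baseline: pd.DataFrame, denominator: str) -> dict[str, float]:
    if denominator == "baseline_max":
        return {idx: max_index(baseline, idx) for idx in INDICES}
    if denominator == "theoretical":
        return {idx: 100.0 for idx in INDICES}
    raise InputError(
        f"denominator must be 'baseline_max' or 'theoretical', got {denominator!r}"
    )


def jackknife_single(
    records, rulebook: Rulebook, denominator: str = "baseline_max"
) -> pd.DataFrame:
    """Exhaustive single-trait removal.

    Returns a tidy frame with one row per (removed trait, species, index):
    baseline score, deviation in index points, percent variation, and an
    ``undefined`` flag where the removal left an index with no conclusions.
    """
    records = list(records)
    if not records:
        raise InputError("need at least one species")
    if len(rulebook.trait_ids) < 2:
        raise InputError("need at least two traits to jackknife")
    baseline, _ = score_table(records, rulebook)
    denoms = _denominators(baseline, denominator)
    rows = []
    for tid in rulebook.trait_ids:
        rows.extend(_deviation_rows(records, rulebook, baseline, denoms, (tid,)))
    return pd.DataFrame(rows)


def jackknife_multi(
    records,
    rulebook: Rulebook,
    n_remove: int,
    reps: int = 50,
    seed: int | None = None,
    denominator: str = "baseline_max",
) -> pd.DataFrame:
    """Random removal of ``n_remove`` traits, repeated ``reps`` times.

    Subsets are drawn uniformly without replacement within each replicate;
    the seed makes the whole distribution reproducible.
    """
    records = list(records)
    if not records:
        raise InputError("need at least one species")
    n_traits = len(rulebook.trait_ids)
    if not 1 <= n_remove <= n_traits - 1:
        raise InputError(
            f"n_remove must lie in [1, {n_traits - 1}] for {n_traits} traits, "
            f"got {n_remove}"
        )
    if reps < 1:
        raise InputError("reps must be positive")
    rng = np.random.default_rng(seed)
    baseline, _ = score_table(records, rulebook)
    denoms = _denominators(baseline, denominator)
    trait_ids = np.array(rulebook.trait_ids)
    rows = []
    for rep in range(reps):
        removed = tuple(rng.choice(trait_ids, size=n_remove, replace=False))
        rows.extend(
            _deviation_rows(records, rulebook, baseline, denoms, removed, rep=rep)
        )
    return pd.DataFrame(rows)


def jackknife_curve(
    records,
    rulebook: Rulebook,
    reps: int = 50,
    seed: int | None = None,
    denominator: str = "baseline_max",
) -> pd.DataFrame:
    """Deviation distributions for every removal count k = 1 .. n_traits - 1.

    Each k gets its own ``reps`` random subsets (seeded independently but
    reproducibly from ``seed``).
    """
    n_traits = len(rulebook.trait_ids)
    ss = np.random.SeedSequence(seed)
    frames = []
    for k, child in zip(
        range(1, n_traits), ss.spawn(n_traits - 1)
    ):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        frames.append(
            jackknife_multi(
                records, rulebook, n_remove=k, reps=reps, seed=sub_seed,
                denominator=denominator,
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_jackknife(deviations: pd.DataFrame) -> pd.DataFrame:
    """Median / min / max percent variation per (removed trait set, index)."""
    ok = deviations[~deviations["undefined"]]
    out = (
        ok.groupby(["removed_traits", "n_removed", "index"])["percent_variation"]
        .agg(["median", "min", "max", "count"])
        .reset_index()
        .rename(
            columns={
                "median": "median_pct",
                "min": "min_pct",
                "max": "max_pct",
                "count": "n_species",
            }
        )
    )
    n_undef = (
        deviations[deviations["undefined"]]
        .groupby(["removed_traits", "n_removed", "index"])
        .size()
        .rename("n_undefined")
        .reset_index()
    )
    out = out.merge(
        n_undef, on=["removed_traits", "n_removed", "index"], how="left"
    )
    out["n_undefined"] = out["n_undefined"].fillna(0).astype(int)
    return out


def plot_jackknife(deviations: pd.DataFrame, ax=None, index: str = "F"):
    """Violin plot of percent variation per removed trait for one index."""
    import matplotlib.pyplot as plt

    sub = deviations[
        (deviations["index"] == index) & (~deviations["undefined"])
    ]
    groups = sorted(sub["removed_traits"].unique())
    data = [
        sub.loc[sub["removed_traits"] == g, "percent_variation"].to_numpy()
        for g in groups
    ]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.6 * len(groups)), 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1))
    ax.set_xticklabels(groups, rotation=60, ha="right", fontsize=7)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_ylabel("% variation from baseline")
    ax.set_title(f"Jackknife sensitivity, index {index}")
    return ax
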