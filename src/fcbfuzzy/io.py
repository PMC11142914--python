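"""Readers, writers, rulebook serialization, and pipeline orchestration.

CSV is the canonical table format.  Trait tables have a header row
``species_id, taxon, <trait columns...>``; empty cells are missing values.
Output CSVs carry ``#``-prefixed header comments recording the rulebook
content hash, the seed, and the package version, so every artifact is
traceable to the exact configuration that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InputError, RulebookError
from .fuzzy import (
    CATEGORIES,
    FuzzySetFamily,
    MembershipFunction,
    TraitDefinition,
)
from .rules import Rule, Rulebook, SpeciesRecord, TraitSpec

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("species_id", "taxon")


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def read_trait_table(path, rulebook: Rulebook | None = None) -> list[SpeciesRecord]:
    """Parse a trait CSV into species records.

    If a rulebook is given, trait columns it does not declare are rejected
    with a named-column error.  Non-numeric cells name the offending row and
    column.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(
            f"{path}: missing mandatory column(s) {missing_cols}; expected "
            f"header species_id, taxon, <trait columns>"
        )
    trait_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    if rulebook is not None:
        unknown = [c for c in trait_cols if c not in rulebook.traits]
        if unknown:
            raise InputError(
                f"{path}: column(s) {unknown} are not declared in the rulebook"
            )
    records = []
    for i, row in df.iterrows():
        traits: dict[str, float | None] = {}
        for col in trait_cols:
            cell = row[col]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() == "":
                traits[col] = None
                continue
            try:
                traits[col] = float(str(cell).strip())
            except ValueError:
                raise InputError(
                    f"{path}: cannot parse {cell!r} as a number "
                    f"(row {i + 2}, column {col!r})"
                ) from None
        records.append(
            SpeciesRecord(
                species_id=str(row["species_id"]),
                taxon=str(row["taxon"]),
                traits=traits,
            )
        )
    return records


def trait_values_by_trait(records) -> dict[str, list[float]]:
    """Pool non-missing observations per trait (for quantile fitting)."""
    out: dict[str, list[float]] = {}
    for rec in records:
        for tid, v in rec.traits.items():
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                out.setdefault(tid, []).append(float(v))
    return out


def _provenance_header(rulebook: Rulebook | None, seed) -> str:
    bits = [f"# fcbfuzzy v{__version__}"]
    if rulebook is not None:
        bits.append(f"# rulebook_hash: {rulebook.content_hash()}")
    if seed is not None:
        bits.append(f"# seed: {seed}")
    return "\n".join(bits) + "\n"


def write_csv(df: pd.DataFrame, path, rulebook=None, seed=None) -> None:
    """Write a frame with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(rulebook, seed))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_scores(path) -> pd.DataFrame:
    """Read a scores CSV back (full float precision round-trip)."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# rulebook YAML
# ---------------------------------------------------------------------------

def rulebook_to_dict(rb: Rulebook) -> dict:
    traits = {}
    for tid, spec in rb.traits.items():
        d = spec.definition
        entry: dict = {
            "display_name": d.display_name,
            "units": d.units,
            "value_domain": [
                None if not np.isfinite(d.value_domain[0]) else float(d.value_domain[0]),
                None if not np.isfinite(d.value_domain[1]) else float(d.value_domain[1]),
            ],
            "linked_indices": sorted(d.linked_indices),
        }
        if spec.family is not None:
            entry["breakpoints"] = {
                c: list(spec.family.functions[c].breakpoints) for c in CATEGORIES
            }
            entry["domain"] = list(spec.family.domain)
        else:
            entry["quantile_recipe"] = {"fuzziness": spec.fuzziness}
        traits[tid] = entry
    return {
        "traits": traits,
        "rules": [
            {
                "trait": r.trait_id, "premise": r.premise, "index": r.index,
                "conclusion": r.conclusion, "weight": r.weight,
            }
            for r in rb.rules
        ],
        "firing_threshold": rb.firing_threshold,
        "retention_floor": rb.retention_floor,
        "index_values": dict(rb.index_values),
        "missing_penalty_degree": rb.missing_penalty_degree,
        "combiner": rb.combiner,
        "default_weight": rb.default_weight,
    }


def rulebook_from_dict(doc: dict) -> Rulebook:
    if not isinstance(doc, dict) or "traits" not in doc or "rules" not in doc:
        raise RulebookError(
            "rulebook document must be a mapping with 'traits' and 'rules'"
        )
    traits: dict[str, TraitSpec] = {}
    for tid, entry in doc["traits"].items():
        if not isinstance(entry, dict):
            raise RulebookError(f"traits.{tid}: expected a mapping")
        lo, hi = entry.get("value_domain", [None, None])
        definition = TraitDefinition(
            trait_id=tid,
            display_name=entry.get("display_name", tid),
            units=entry.get("units", ""),
            value_domain=(
                -np.inf if lo is None else float(lo),
                np.inf if hi is None else float(hi),
            ),
            linked_indices=frozenset(entry.get("linked_indices", ())),
        )
        if "breakpoints" in entry:
            bps = entry["breakpoints"]
            missing = set(CATEGORIES) - set(bps)
            if missing:
                raise RulebookError(
                    f"traits.{tid}.breakpoints: missing categories {sorted(missing)}"
                )
            functions = {
                c: MembershipFunction(
                    c,
                    "trapezoid" if c in ("low", "very_high") else "triangular",
                    tuple(bps[c]),
                )
                for c in CATEGORIES
            }
            if "domain" in entry:
                domain = tuple(float(v) for v in entry["domain"])
            else:
                domain = (
                    min(f.support[0] for f in functions.values()),
                    max(f.support[1] for f in functions.values()),
                )
            family = FuzzySetFamily(
                trait_id=tid, functions=functions, domain=domain,
                provenance="explicit breakpoints",
            )
            traits[tid] = TraitSpec(definition=definition, family=family)
        else:
            recipe = entry.get("quantile_recipe", {}) or {}
            traits[tid] = TraitSpec(
                definition=definition,
                fuzziness=float(recipe.get("fuzziness", 0.5)),
            )
    rules = []
    for i, r in enumerate(doc["rules"]):
        try:
            rules.append(
                Rule(
                    trait_id=r["trait"], premise=r["premise"], index=r["index"],
                    conclusion=r["conclusion"],
                    weight=float(r.get("weight", doc.get("default_weight", 0.5))),
                )
            )
        except (KeyError, TypeError) as exc:
            raise RulebookError(f"rules[{i}]: malformed rule entry: {exc}") from exc
    return Rulebook(
        traits=traits,
        rules=tuple(rules),
        firing_threshold=float(doc.get("firing_threshold", 0.2)),
        retention_floor=float(doc.get("retention_floor", 0.2)),
        index_values={
            k: float(v)
            for k, v in doc.get(
                "index_values",
                {"low": 1, "medium": 25, "high": 75, "very_high": 100},
            ).items()
        },
        missing_penalty_degree=float(doc.get("missing_penalty_degree", 1.0)),
        combiner=doc.get("combiner", "product"),
        default_weight=float(doc.get("default_weight", 0.5)),
    )


def rulebook_to_yaml(rb: Rulebook, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(rulebook_to_dict(rb), fh, sort_keys=False)


def rulebook_from_yaml(path) -> Rulebook:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise RulebookError(f"{path}: invalid YAML: {exc}") from exc
    try:
        return rulebook_from_dict(doc)
    except RulebookError as exc:
        raise RulebookError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    traits_csv: str
    rulebook_path: str | None
    out_dir: str
    stages: tuple[str, ...] = ("score", "stats", "jackknife")
    seed: int | None = None
    jackknife_reps: int = 50
    jackknife_mode: str = "single"
    n_remove: int = 1
    overrides: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Score -> statistics -> jackknife, writing all artifacts to out_dir."""
    from .defuzz import score_table
    from .sensitivity import (
        jackknife_multi, jackknife_single, summarize_jackknife,
    )
    from .stats import group_compare, index_correlations, rank_table
    from .synthetic import default_rulebook

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.rulebook_path:
        rulebook = rulebook_from_yaml(config.rulebook_path)
    else:
        rulebook = default_rulebook()
    for key, value in config.overrides.items():
        from dataclasses import replace
        rulebook = replace(rulebook, **{key: value})

    records = read_trait_table(config.traits_csv, rulebook)
    if not records:
        raise InputError(f"{config.traits_csv}: no species rows")
    rulebook = rulebook.resolve_families(trait_values_by_trait(records))
    logger.info("pipeline: %d species, rulebook %s",
                len(records), rulebook.content_hash())

    scores, memberships = score_table(records, rulebook)
    if "score" in config.stages:
        artifacts["scores"] = out / "scores.csv"
        write_csv(scores, artifacts["scores"], rulebook, config.seed)
        artifacts["memberships"] = out / "memberships.csv"
        write_csv(memberships, artifacts["memberships"], rulebook, config.seed)

    if "stats" in config.stages:
        artifacts["ranks"] = out / "ranks.csv"
        write_csv(rank_table(scores), artifacts["ranks"], rulebook, config.seed)
        artifacts["correlations"] = out / "correlations.csv"
        write_csv(
            index_correlations(scores), artifacts["correlations"],
            rulebook, config.seed,
        )
        taxa_rows = []
        for idx, col in (("F", "f_score"), ("C", "c_score"), ("B", "b_score")):
            gc = group_compare(scores[col].to_numpy(), scores["taxon"].to_numpy())
            taxa_rows.append(
                {"index": idx, "H": gc.h_statistic, "p_value": gc.p_value}
            )
            dunn = gc.dunn.copy()
            dunn.insert(0, "index", idx)
            key = f"dunn_{idx}"
            artifacts[key] = out / f"dunn_{idx}.csv"
            write_csv(dunn, artifacts[key], rulebook, config.seed)
        artifacts["group_tests"] = out / "group_tests.csv"
        write_csv(
            pd.DataFrame(taxa_rows), artifacts["group_tests"],
            rulebook, config.seed,
        )

    if "jackknife" in config.stages:
        if config.jackknife_mode == "single":
            dev = jackknife_single(records, rulebook)
        else:
            dev = jackknife_multi(
                records, rulebook, n_remove=config.n_remove,
                reps=config.jackknife_reps, seed=config.seed,
            )
        artifacts["jackknife"] = out / "jackknife_deviations.csv"
        write_csv(dev, artifacts["jackknife"], rulebook, config.seed)
        artifacts["jackknife_summary"] = out / "jackknife_summary.csv"
        write_csv(
            summarize_jackknife(dev), artifacts["jackknife_summary"],
            rulebook, config.seed,
        )
    return artifacts
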