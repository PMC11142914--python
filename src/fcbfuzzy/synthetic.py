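"""Synthetic species-by-trait tables with FishBase-like structure.

The generator emulates the statistical shape of a staple-aquaculture trait
table: four taxa (finfish, crustaceans, molluscs, algae; 24/10/12/8 species
by default, 54 in total), thirteen traits with realistic marginals
(log-normal for sizes, fecundity and range extents; normal for growth rate,
trophic level and nutrient density), taxon-specific locations (algae around
trophic level 1, molluscs around 2, finfish spanning roughly 2-5), and
missingness concentrated in the non-fish taxa.

Taxon structure is controlled by a single effect-size dial: every sampled
location is ``base + taxa_effect * offset``.  ``taxa_effect = 0`` therefore
gives exactly exchangeable taxa (for null calibration), 1 the realistic
defaults, and larger values a stronger, more easily recovered group signal.

``default_rulebook()`` ships a complete reconstruction of the trait-to-FCB
linkage: monotone category maps for positively linked traits and reversed
maps for inverted ones (e.g. very-high fecundity concludes very-high food
potential but *low* biodiversity potential; very-high trophic level
concludes low climate potential via feed efficiency; wide environmental
tolerances favour food and climate potential; wide latitudinal or
geographic ranges penalize biodiversity potential).  The index-sharing
structure has six traits common to F and C, three to F and B, and one to
C and B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .fuzzy import CATEGORIES, TraitDefinition
from .rules import Rule, Rulebook, SpeciesRecord, TraitSpec

TAXA = ("finfish", "crustaceans", "molluscs", "algae")

# dist: "normal" (loc, scale) or "lognormal" (loc/scale on the log scale);
# offsets shift the location per taxon, scaled by taxa_effect; clip bounds
# keep values in a biologically sensible range.
_TRAITS: dict[str, dict] = {
    "vbgf_k": dict(
        units="1/yr", dist="normal", loc=0.45, scale=0.20,
        offsets={"finfish": 0.0, "crustaceans": 0.40, "molluscs": -0.20, "algae": 0.40},
        clip=(0.02, None),
    ),
    "max_size_cm": dict(
        units="cm", dist="lognormal", loc=math.log(40.0), scale=0.8,
        offsets={"finfish": 0.4, "crustaceans": -0.7, "molluscs": -1.2, "algae": 0.5},
        clip=(0.5, None),
    ),
    "fecundity": dict(
        units="eggs", dist="lognormal", loc=math.log(1e5), scale=1.5,
        offsets={"finfish": 1.0, "crustaceans": 1.0, "molluscs": 1.2, "algae": -2.0},
        clip=(1.0, None),
    ),
    "macronutrient_density": dict(
        units="fraction of RDI", dist="normal", loc=0.35, scale=0.12,
        offsets={"finfish": 0.05, "crustaceans": 0.0, "molluscs": 0.10, "algae": 0.15},
        clip=(0.01, 1.0),
    ),
    "trophic_level": dict(
        units="unitless", dist="normal", loc=2.5, scale=0.40,
        offsets={"finfish": 0.7, "crustaceans": 0.3, "molluscs": -0.5, "algae": -1.5},
        scale_offsets={"finfish": 1.0},  # finfish span roughly 2-5
        clip=(1.0, 5.0),
    ),
    "nitrate_range": dict(
        units="umol/L", dist="lognormal", loc=math.log(15.0), scale=0.6,
        offsets={"finfish": 0.0, "crustaceans": -0.2, "molluscs": 0.3, "algae": 0.6},
        clip=(0.1, None),
    ),
    "phosphate_range": dict(
        units="umol/L", dist="lognormal", loc=math.log(1.5), scale=0.6,
        offsets={"finfish": 0.0, "crustaceans": -0.2, "molluscs": 0.3, "algae": 0.6},
        clip=(0.01, None),
    ),
    "temperature_range": dict(
        units="degC", dist="lognormal", loc=math.log(12.0), scale=0.4,
        offsets={"finfish": 0.0, "crustaceans": 0.0, "molluscs": 0.3, "algae": 0.2},
        clip=(0.5, None),
    ),
    "salinity_range": dict(
        units="PSU", dist="lognormal", loc=math.log(10.0), scale=0.5,
        offsets={"finfish": 0.0, "crustaceans": 0.0, "molluscs": 0.3, "algae": 0.2},
        clip=(0.1, None),
    ),
    "po2_range": dict(
        units="mL/L", dist="lognormal", loc=math.log(3.0), scale=0.4,
        offsets={"finfish": 0.1, "crustaceans": 0.0, "molluscs": 0.3, "algae": 0.2},
        clip=(0.1, None),
    ),
    "ph_sensitivity": dict(
        units="pH units", dist="normal", loc=0.5, scale=0.20,
        offsets={"finfish": 0.0, "crustaceans": 0.1, "molluscs": 0.2, "algae": -0.1},
        clip=(0.01, 2.0),
    ),
    "latitudinal_range": dict(
        units="deg latitude", dist="lognormal", loc=math.log(30.0), scale=0.5,
        offsets={"finfish": 0.3, "crustaceans": 0.0, "molluscs": -0.1, "algae": -0.3},
        clip=(1.0, 180.0),
    ),
    "geographic_range": dict(
        units="10^6 km^2", dist="lognormal", loc=math.log(5.0), scale=0.8,
        offsets={"finfish": 0.4, "crustaceans": 0.0, "molluscs": -0.1, "algae": -0.4},
        clip=(0.01, None),
    ),
}

#: (positively linked indices, inversely linked indices) per trait.  A
#: positive link maps each trait category to the same potential category; an
#: inverse link reverses the order (very_high trait -> low potential).
_LINKAGE: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "vbgf_k": (("F",), ("B",)),
    "max_size_cm": (("F",), ("B",)),
    "fecundity": (("F",), ("B",)),
    "macronutrient_density": (("F",), ()),
    "trophic_level": ((), ("F", "C")),
    "nitrate_range": (("F", "C"), ()),
    "phosphate_range": (("F", "C"), ()),
    "temperature_range": (("F", "C"), ()),
    "salinity_range": (("F", "C"), ()),
    "po2_range": (("F", "C"), ()),
    "ph_sensitivity": ((), ("C",)),
    "latitudinal_range": ((), ("B",)),
    "geographic_range": (("C",), ("B",)),
}

_DEFAULT_N = {"finfish": 24, "crustaceans": 10, "molluscs": 12, "algae": 8}
_DEFAULT_MISSING = {
    "finfish": 0.05, "crustaceans": 0.15, "molluscs": 0.15, "algae": 0.25,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic trait-table generator.

    ``offset_overrides`` replaces the default per-taxon location offsets for
    chosen traits ({trait_id: {taxon: offset}}); overrides are still scaled
    by ``taxa_effect``, so effect 0 always yields exchangeable taxa.
    """

    n_per_taxon: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N))
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSING)
    )
    taxa_effect: float = 1.0
    offset_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        for taxon in self.n_per_taxon:
            if taxon not in TAXA:
                raise InputError(f"unknown taxon {taxon!r}; allowed: {TAXA}")
        for taxon, n in self.n_per_taxon.items():
            if n < 0:
                raise InputError(f"negative species count for {taxon!r}")
        for taxon, p in self.missingness.items():
            if taxon not in TAXA:
                raise InputError(f"unknown taxon {taxon!r} in missingness")
            if not 0.0 <= p <= 1.0:
                raise InputError(
                    f"missingness must be a probability, got {p} for {taxon!r}"
                )
        for tid, per_taxon in self.offset_overrides.items():
            if tid not in _TRAITS:
                raise InputError(f"unknown trait {tid!r} in offset_overrides")
            for taxon in per_taxon:
                if taxon not in TAXA:
                    raise InputError(
                        f"unknown taxon {taxon!r} in offset_overrides[{tid!r}]"
                    )

    @property
    def n_total(self) -> int:
        return sum(self.n_per_taxon.values())


def null_scenario_config(seed: int | None = None) -> SyntheticConfig:
    """Fully exchangeable taxa: zero effect size and uniform missingness.

    Differential missingness is itself a real taxa-level signal (the
    missing-data penalty lowers scores), so a true null must equalize it.
    """
    return SyntheticConfig(
        taxa_effect=0.0, missingness={t: 0.10 for t in TAXA}, seed=seed
    )


def recovery_scenario_config(
    taxa_effect: float = 2.0, seed: int | None = None
) -> SyntheticConfig:
    """A scenario where algae and molluscs are given FCB-favourable traits.

    Used for structure-recovery checks: extractive taxa get low growth rate,
    small size, low fecundity and narrow latitudinal/geographic ranges (all
    favourable for biodiversity potential under the default rulebook) on top
    of the default low-trophic, nutrient-dense, tolerance-wide profile that
    favours their food and climate potential.  Fed taxa get the opposite
    shifts, so the configured group ordering is unambiguous.
    """
    overrides = {
        # biodiversity-favourable (these traits are inversely linked to B):
        "vbgf_k": {"algae": -0.15, "molluscs": -0.20,
                   "crustaceans": 0.30, "finfish": 0.15},
        "max_size_cm": {"algae": -0.5, "molluscs": -1.0,
                        "crustaceans": 0.3, "finfish": 0.6},
        "fecundity": {"algae": -1.5, "molluscs": -1.0,
                      "crustaceans": 1.0, "finfish": 1.0},
        "latitudinal_range": {"algae": -0.4, "molluscs": -0.4,
                              "crustaceans": 0.3, "finfish": 0.4},
        "geographic_range": {"algae": -0.4, "molluscs": -0.4,
                             "crustaceans": 0.3, "finfish": 0.5},
        # food-favourable: nutrient-dense, low-trophic, tolerance-wide
        "macronutrient_density": {"algae": 0.20, "molluscs": 0.15,
                                  "crustaceans": -0.05, "finfish": -0.05},
        "trophic_level": {"algae": -1.5, "molluscs": -0.8,
                          "crustaceans": 0.4, "finfish": 0.7},
        "nitrate_range": {"algae": 0.6, "molluscs": 0.5,
                          "crustaceans": -0.3, "finfish": -0.3},
        "phosphate_range": {"algae": 0.6, "molluscs": 0.5,
                            "crustaceans": -0.3, "finfish": -0.3},
        "temperature_range": {"algae": 0.4, "molluscs": 0.4,
                              "crustaceans": -0.3, "finfish": -0.3},
        "salinity_range": {"algae": 0.4, "molluscs": 0.4,
                           "crustaceans": -0.3, "finfish": -0.3},
        "po2_range": {"algae": 0.4, "molluscs": 0.4,
                      "crustaceans": -0.3, "finfish": -0.3},
    }
    # uniform missingness: the configured signal is the trait distributions,
    # not differential data availability
    return SyntheticConfig(
        taxa_effect=taxa_effect,
        missingness={t: 0.10 for t in TAXA},
        offset_overrides=overrides,
        seed=seed,
    )


def generate_table(config: SyntheticConfig) -> list[SpeciesRecord]:
    """Draw a reproducible synthetic species x trait table."""
    rng = np.random.default_rng(config.seed)
    records = []
    for taxon in TAXA:
        n = config.n_per_taxon.get(taxon, 0)
        p_miss = config.missingness.get(taxon, 0.0)
        for i in range(n):
            traits: dict[str, float | None] = {}
            for tid, spec in _TRAITS.items():
                offsets = config.offset_overrides.get(tid, spec["offsets"])
                loc = spec["loc"] + config.taxa_effect * offsets.get(taxon, 0.0)
                scale = spec["scale"] * (
                    1.0
                    + config.taxa_effect
                    * spec.get("scale_offsets", {}).get(taxon, 0.0)
                )
                draw = rng.normal(loc, scale)
                value = math.exp(draw) if spec["dist"] == "lognormal" else draw
                lo, hi = spec.get("clip", (None, None))
                if lo is not None:
                    value = max(value, lo)
                if hi is not None:
                    value = min(value, hi)
                traits[tid] = None if rng.random() < p_miss else float(value)
            records.append(
                SpeciesRecord(
                    species_id=f"{taxon[:4]}_{i + 1:02d}",
                    taxon=taxon,
                    traits=traits,
                )
            )
    return records


def table_to_dataframe(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"species_id": rec.species_id, "taxon": rec.taxon}
        row.update(
            {k: (np.nan if v is None else v) for k, v in rec.traits.items()}
        )
        rows.append(row)
    cols = ["species_id", "taxon"] + list(_TRAITS)
    return pd.DataFrame(rows)[cols]


def _monotone_rules(trait_id: str, index: str, invert: bool) -> list[Rule]:
    cats = CATEGORIES[::-1] if invert else CATEGORIES
    return [
        Rule(trait_id=trait_id, premise=premise, index=index, conclusion=concl)
        for premise, concl in zip(CATEGORIES, cats)
    ]


def default_rulebook(fuzziness: float = 0.5) -> Rulebook:
    """The shipped rulebook: all 13 traits, quantile-recipe fuzzy sets,
    weight 0.5, thresholds 0.2, index values {1, 25, 75, 100}."""
    traits: dict[str, TraitSpec] = {}
    rules: list[Rule] = []
    for tid, (pos, neg) in _LINKAGE.items():
        spec = _TRAITS[tid]
        traits[tid] = TraitSpec(
            definition=TraitDefinition(
                trait_id=tid,
                display_name=tid.replace("_", " "),
                units=spec["units"],
                value_domain=(
                    spec.get("clip", (None, None))[0] or 0.0,
                    spec.get("clip", (None, None))[1] or math.inf,
                ),
                linked_indices=frozenset(pos) | frozenset(neg),
            ),
            fuzziness=fuzziness,
        )
        for idx in pos:
            rules.extend(_monotone_rules(tid, idx, invert=False))
        for idx in neg:
            rules.extend(_monotone_rules(tid, idx, invert=True))
    return Rulebook(traits=traits, rules=tuple(rules))
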