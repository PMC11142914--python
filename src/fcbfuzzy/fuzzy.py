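"""Fuzzification: traits, membership functions, and fuzzy-set families.

Each trait carries four overlapping linguistic categories (low, medium, high,
very high).  The low and very-high sets are trapezoids, the middle two are
triangles; a crisp trait value is converted into graded memberships in every
category whose degree exceeds a retention floor (default 0.2, strict).  A
missing value is represented by the ``MISSING`` sentinel and is turned into a
low-potential penalty downstream by the inference engine.

Fuzzy-set breakpoints may be given explicitly or derived from the observed
trait distribution by a quartile recipe: the low plateau ends at Q25, the
very-high plateau begins at Q75, the medium apex sits at the median and the
high apex midway between median and Q75; shoulder widths are
``fuzziness * (Q75 - Q25)``.  Quantiles use linear interpolation (numpy's
default, the common "type 7" convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDistributionError,
    InputError,
    InsufficientDataError,
    RulebookError,
)

logger = logging.getLogger(__name__)

#: Linguistic categories, ordered from lowest to highest potential.
CATEGORIES = ("low", "medium", "high", "very_high")

INDICES = ("F", "C", "B")

#: Default retention floor: degrees must strictly exceed this to be kept.
DEFAULT_FLOOR = 0.2


class _Missing:
    """Sentinel for a missing trait value (distinct from any float)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


MISSING = _Missing()


def is_missing(x) -> bool:
    """True for the MISSING sentinel, None, or NaN."""
    if x is MISSING or x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class TraitDefinition:
    """Declaration of one input trait and the indices it informs."""

    trait_id: str
    display_name: str = ""
    units: str = ""
    value_domain: tuple[float, float] = (-math.inf, math.inf)
    linked_indices: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.trait_id:
            raise RulebookError("trait_id must be a non-empty string")
        object.__setattr__(self, "linked_indices", frozenset(self.linked_indices))
        bad = self.linked_indices - set(INDICES)
        if bad:
            raise RulebookError(
                f"trait {self.trait_id!r}: unknown indices {sorted(bad)}; "
                f"allowed: {INDICES}"
            )
        if not self.linked_indices:
            raise RulebookError(
                f"trait {self.trait_id!r} is linked to no FCB index; "
                "a trait with no linkage cannot contribute and is rejected"
            )
        lo, hi = self.value_domain
        if not lo < hi:
            raise RulebookError(
                f"trait {self.trait_id!r}: value_domain must satisfy lo < hi"
            )


@dataclass(frozen=True)
class MembershipFunction:
    """One piecewise-linear fuzzy set (trapezoid or triangle).

    Trapezoid breakpoints (a, b, c, d): degree 0 outside [a, d], 1 on the
    plateau [b, c], linear on the shoulders.  Triangle breakpoints (a, b, c):
    apex at b.  Coincident breakpoints give vertical edges (degree jumps),
    which is how boundary plateaus such as ``a == b == domain minimum`` are
    expressed.
    """

    category: str
    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise RulebookError(f"unknown category {self.category!r}")
        if self.shape == "trapezoid":
            if self.category not in ("low", "very_high"):
                raise RulebookError(
                    f"trapezoid shape is reserved for low/very_high, got "
                    f"{self.category!r}"
                )
            if len(self.breakpoints) != 4:
                raise RulebookError("trapezoid needs 4 breakpoints (a, b, c, d)")
        elif self.shape == "triangular":
            if self.category not in ("medium", "high"):
                raise RulebookError(
                    f"triangular shape is reserved for medium/high, got "
                    f"{self.category!r}"
                )
            if len(self.breakpoints) != 3:
                raise RulebookError("triangle needs 3 breakpoints (a, b, c)")
        else:
            raise RulebookError(f"unknown shape {self.shape!r}")
        bp = tuple(float(v) for v in self.breakpoints)
        if any(not math.isfinite(v) for v in bp):
            raise RulebookError(f"{self.category}: breakpoints must be finite")
        if any(bp[i] > bp[i + 1] for i in range(len(bp) - 1)):
            raise RulebookError(
                f"{self.category}: breakpoints must be weakly increasing, got {bp}"
            )
        object.__setattr__(self, "breakpoints", bp)

    @property
    def support(self) -> tuple[float, float]:
        """Closed interval outside which the degree is exactly 0."""
        return self.breakpoints[0], self.breakpoints[-1]

    def __call__(self, x: float) -> float:
        return evaluate_membership(self, x)


def evaluate_membership(fn: MembershipFunction, x: float) -> float:
    """Degree of membership of crisp value ``x`` in the set ``fn``, in [0, 1]."""
    x = float(x)
    if not math.isfinite(x):
        raise InputError(f"trait value must be finite, got {x!r}")
    bp = fn.breakpoints
    if fn.shape == "trapezoid":
        a, b, c, d = bp
        if x < a or x > d:
            return 0.0
        if b <= x <= c:
            return 1.0
        if x < b:  # a < x < b, so a < b
            return (x - a) / (b - a)
        return (d - x) / (d - c)
    a, b, c = bp
    if x < a or x > c:
        return 0.0
    if x == b:
        return 1.0
    if x < b:
        return (x - a) / (b - a)
    return (c - x) / (c - b)


@dataclass(frozen=True)
class FuzzySetFamily:
    """The four membership functions for one trait, plus their provenance."""

    trait_id: str
    functions: dict[str, MembershipFunction]
    domain: tuple[float, float]
    provenance: str = "explicit"

    def __post_init__(self):
        if set(self.functions) != set(CATEGORIES):
            raise RulebookError(
                f"trait {self.trait_id!r}: need exactly one function per "
                f"category {CATEGORIES}, got {sorted(self.functions)}"
            )
        for cat, fn in self.functions.items():
            if fn.category != cat:
                raise RulebookError(
                    f"trait {self.trait_id!r}: function under key {cat!r} is "
                    f"declared for category {fn.category!r}"
                )
        lo, hi = self.domain
        if not lo < hi:
            raise RulebookError(f"trait {self.trait_id!r}: domain must have lo < hi")
        self._check_overlap()
        self._check_coverage()

    # -- invariants -------------------------------------------------------
    def _grid(self, lo: float, hi: float, n: int = 513) -> np.ndarray:
        pts = set(np.linspace(lo, hi, n))
        for fn in self.functions.values():
            pts.update(b for b in fn.breakpoints if lo <= b <= hi)
        return np.array(sorted(pts))

    def _check_overlap(self):
        for c1, c2 in zip(CATEGORIES[:-1], CATEGORIES[1:]):
            f1, f2 = self.functions[c1], self.functions[c2]
            lo = max(f1.support[0], f2.support[0])
            hi = min(f1.support[1], f2.support[1])
            if lo > hi:
                raise RulebookError(
                    f"trait {self.trait_id!r}: categories {c1!r} and {c2!r} "
                    "have disjoint supports (no fuzziness)"
                )
            grid = self._grid(lo, hi, 129)
            joint = max(min(f1(x), f2(x)) for x in grid)
            if joint <= 0.0:
                raise RulebookError(
                    f"trait {self.trait_id!r}: categories {c1!r} and {c2!r} "
                    "do not overlap anywhere (no fuzziness)"
                )

    def _check_coverage(self):
        grid = self._grid(*self.domain)
        degs = np.array(
            [[self.functions[c](x) for x in grid] for c in CATEGORIES]
        )
        uncovered = grid[degs.max(axis=0) <= 0.0]
        if uncovered.size:
            raise RulebookError(
                f"trait {self.trait_id!r}: no category has positive degree at "
                f"x={uncovered[0]:g} (coverage gap in {self.domain})"
            )

    # -- evaluation -------------------------------------------------------
    def evaluate_all(self, x: float) -> dict[str, float]:
        """Degrees in all four categories, after clamping to the domain."""
        lo, hi = self.domain
        if x < lo or x > hi:
            logger.warning(
                "trait %s: value %g outside domain [%g, %g]; clamped",
                self.trait_id, x, lo, hi,
            )
            x = min(max(x, lo), hi)
        return {c: self.functions[c](x) for c in CATEGORIES}


@dataclass(frozen=True)
class CategoryMemberships:
    """Retained graded memberships of one trait value (degrees > floor)."""

    trait_id: str
    degrees: dict[str, float]

    def __post_init__(self):
        if len(self.degrees) > 4:
            raise InputError("at most four categories may be retained")


def build_family_from_quantiles(
    values,
    fuzziness: float = 0.5,
    trait_id: str = "",
) -> FuzzySetFamily:
    """Derive a fuzzy-set family from the observed distribution of a trait.

    Anchors: low plateau [min, Q25]; very-high plateau [Q75, max]; medium apex
    at the median; high apex at (median + Q75) / 2.  Shoulders extend by
    ``fuzziness * IQR`` beyond their anchor, which guarantees that adjacent
    categories overlap and the whole [min, max] range is covered.

    Raises
    ------
    InsufficientDataError
        fewer than 4 finite values.
    DegenerateDistributionError
        all values identical.
    """
    if not 0.0 < fuzziness < 1.0:
        raise InputError(f"fuzziness must lie in (0, 1), got {fuzziness}")
    vals = np.asarray(
        [float(v) for v in values if not is_missing(v)], dtype=float
    )
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        raise InsufficientDataError(
            f"trait {trait_id!r}: need at least 4 finite values to place "
            f"quartile-anchored fuzzy sets, got {vals.size}"
        )
    mn, mx = float(vals.min()), float(vals.max())
    if mn == mx:
        raise DegenerateDistributionError(
            f"trait {trait_id!r}: all {vals.size} values equal {mn:g}; "
            "fuzzy sets are undefined for a degenerate distribution"
        )
    q25, med, q75 = (float(q) for q in np.quantile(vals, [0.25, 0.5, 0.75]))
    if q75 <= q25:
        # heavy ties: quartiles collapse; fall back to range-based anchors
        r = mx - mn
        q25, med, q75 = mn + 0.25 * r, mn + 0.5 * r, mn + 0.75 * r
    w = fuzziness * (q75 - q25)
    h_apex = 0.5 * (med + q75)
    functions = {
        "low": MembershipFunction("low", "trapezoid", (mn, mn, q25, q25 + w)),
        "medium": MembershipFunction("medium", "triangular", (q25 - w, med, h_apex)),
        "high": MembershipFunction("high", "triangular", (med, h_apex, q75 + w)),
        "very_high": MembershipFunction(
            "very_high", "trapezoid", (q75 - w, q75, mx, mx)
        ),
    }
    return FuzzySetFamily(
        trait_id=trait_id,
        functions=functions,
        domain=(mn, mx),
        provenance=(
            f"quantile recipe: n={vals.size}, Q25={q25:g}, median={med:g}, "
            f"Q75={q75:g}, fuzziness={fuzziness:g}"
        ),
    )


def fuzzify(x, family: FuzzySetFamily, floor: float = DEFAULT_FLOOR):
    """Convert a crisp trait value into retained category memberships.

    Degrees less than or equal to ``floor`` are dropped (strict "exceeds").
    A missing value returns the ``MISSING`` sentinel; the inference engine
    translates that into the low-potential penalty.
    """
    if is_missing(x):
        return MISSING
    if not 0.0 <= floor < 1.0:
        raise InputError(f"retention floor must lie in [0, 1), got {floor}")
    degrees = family.evaluate_all(float(x))
    retained = {c: d for c, d in degrees.items() if d > floor}
    return CategoryMemberships(trait_id=family.trait_id, degrees=retained)
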