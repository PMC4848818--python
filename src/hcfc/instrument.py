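"""Questionnaire structure: factors, items, reversal flags, category count.

An instrument is an ordered collection of named factors, each measuring one
aspect of health capability through two or more ordinal (Likert) items.
Items flagged ``reversed`` are worded so that a *high* raw response means
*low* capability (e.g. "I feel tired all the time"); reversal is applied at
scoring time so that higher always means better.

The built-in instrument, :func:`builtin_hcfc8`, is the 20-item / 8-factor
Health Capability of Family Caregivers questionnaire (HCFC-8), whose items
stem from the Whoqol-bref, the Caregiver Reaction Assessment and the Carer
Satisfaction with Community Services scales.  Each factor designates one
*marker item* whose factor loading is fixed at 1 in the latent-variable
model to set the factor's scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ItemSpec",
    "FactorSpec",
    "InstrumentSpec",
    "InstrumentError",
    "builtin_hcfc8",
    "reverse_code",
    "load_instrument",
    "save_instrument",
]


class InstrumentError(ValueError):
    """Raised when an instrument definition violates a structural invariant."""


@dataclass(frozen=True)
class ItemSpec:
    """A single ordinal item.

    Parameters
    ----------
    name
        Short machine key, used as the data column header.
    label
        Human-readable wording shown in reports.
    reversed
        If True, raw responses are inverted (``c -> n_categories + 1 - c``)
        before scoring, so that high always means high capability.
    """

    name: str
    label: str = ""
    reversed: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise InstrumentError("item name must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.name.replace("_", " "))


@dataclass(frozen=True)
class FactorSpec:
    """A named latent factor and the items that measure it.

    ``marker`` is the item whose loading is fixed at 1; it defaults to the
    first listed item.
    """

    name: str
    items: tuple[ItemSpec, ...]
    label: str = ""
    marker: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise InstrumentError("factor name must be non-empty")
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if len(items) < 2:
            raise InstrumentError(
                f"factor {self.name!r} has {len(items)} item(s); at least 2 required"
            )
        if not self.label:
            object.__setattr__(self, "label", self.name.replace("_", " "))
        if not self.marker:
            object.__setattr__(self, "marker", items[0].name)
        if self.marker not in {it.name for it in items}:
            raise InstrumentError(
                f"marker {self.marker!r} is not an item of factor {self.name!r}"
            )

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(it.name for it in self.items)


@dataclass(frozen=True)
class InstrumentSpec:
    """An ordered set of factors plus the common number of ordinal categories."""

    factors: tuple[FactorSpec, ...]
    n_categories: int = 5
    name: str = "instrument"

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        object.__setattr__(self, "factors", factors)
        if self.n_categories < 2:
            raise InstrumentError(
                f"n_categories must be >= 2, got {self.n_categories}"
            )
        seen: dict[str, str] = {}
        for fac in factors:
            for it in fac.items:
                if it.name in seen:
                    raise InstrumentError(
                        f"item {it.name!r} appears in factors "
                        f"{seen[it.name]!r} and {fac.name!r}; items must "
                        "belong to exactly one factor"
                    )
                seen[it.name] = fac.name
        fnames = [f.name for f in factors]
        if len(set(fnames)) != len(fnames):
            raise InstrumentError("factor names must be unique")

    # -- convenience views -------------------------------------------------

    @property
    def items(self) -> tuple[ItemSpec, ...]:
        return tuple(it for fac in self.factors for it in fac.items)

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(it.name for it in self.items)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def item_factor_index(self) -> tuple[int, ...]:
        """Factor index of each item, in item order."""
        out = []
        for k, fac in enumerate(self.factors):
            out.extend([k] * len(fac.items))
        return tuple(out)

    def marker_mask(self) -> tuple[bool, ...]:
        """True for each item that is its factor's marker."""
        return tuple(
            it.name == fac.marker for fac in self.factors for it in fac.items
        )

    def reversed_mask(self) -> tuple[bool, ...]:
        return tuple(it.reversed for it in self.items)

    def factor_of(self, item_name: str) -> FactorSpec:
        for fac in self.factors:
            if item_name in fac.item_names:
                return fac
        raise KeyError(item_name)


def reverse_code(response, n_categories: int):
    """Invert an ordinal response: ``c -> n_categories + 1 - c``.

    Missing responses (None or NaN) are returned unchanged.  The map is an
    involution: applying it twice restores the raw response.
    """
    if n_categories < 2:
        raise InstrumentError(f"n_categories must be >= 2, got {n_categories}")
    if response is None:
        return None
    if isinstance(response, float) and math.isnan(response):
        return response
    if not (1 <= response <= n_categories):
        raise InstrumentError(
            f"response {response} outside 1..{n_categories}"
        )
    return type(response)(n_categories + 1 - response)


_HCFC8 = (
    # (factor key, factor label, marker or None->first, [(item, label, reversed)])
    (
        "psychological_functioning",
        "Psychological functioning",
        None,
        [
            ("self_esteem", "Self-esteem", False),
            ("body_image", "Body image", False),
            ("negative_affects", "Negative affects", True),
        ],
    ),
    (
        "physical_functioning",
        "Physical functioning",
        "health_got_worse",
        [
            ("feeling_tired", "Feeling tired all the time", True),
            ("health_got_worse", "Health got worse", True),
        ],
    ),
    (
        "self_efficacy_health_services",
        "Self-efficacy towards health services",
        None,
        [
            ("confidence_who_to_contact", "Confidence to know who to contact", False),
            ("ability_get_information", "Ability to get information", False),
        ],
    ),
    (
        "lifestyle_value",
        "Lifestyle value",
        None,
        [
            ("want_to_care", "Want to care", False),
            ("enjoy_caring", "Enjoy caring", False),
            ("caring_feels_good", "Caring makes one feel good", False),
        ],
    ),
    (
        "family_support",
        "Family support",
        None,
        [
            ("difficulty_getting_help", "Difficulty getting help", True),
            ("feeling_abandoned", "Feeling abandoned by the family", True),
            ("family_works_together", "Family works together", False),
        ],
    ),
    (
        "social_capital",
        "Social capital",
        None,
        [
            ("personal_relationships", "Personal relationships", False),
            ("sexual_activity", "Sexual activity", False),
            ("social_support", "Social support", False),
        ],
    ),
    (
        "material_conditions_security",
        "Material conditions / security",
        None,
        [
            ("financial_resources", "Financial resources", False),
            ("safety_security", "Freedom and physical safety and security", False),
        ],
    ),
    (
        "health_services_interactions",
        "Quality of information and healthcare services",
        None,
        [
            ("help_received", "Help received", False),
            ("information_availability", "Availability of information", False),
        ],
    ),
)


def builtin_hcfc8() -> InstrumentSpec:
    """The built-in HCFC-8 instrument: 8 factors, 20 items, 5 categories.

    Marker items default to the first item of each factor, except physical
    functioning, whose scale is anchored on "health got worse" (its loading
    is the one reported as 1.00, against 2.83 for "feeling tired").
    """
    factors = []
    for fname, flabel, marker, items in _HCFC8:
        fac = FactorSpec(
            name=fname,
            label=flabel,
            items=tuple(ItemSpec(n, lab, rev) for n, lab, rev in items),
            marker=marker or "",
        )
        factors.append(fac)
    return InstrumentSpec(factors=tuple(factors), n_categories=5, name="HCFC-8")


# -- serialization ---------------------------------------------------------


def save_instrument(spec: InstrumentSpec, path) -> None:
    """Write an instrument definition as a YAML document."""
    doc = {
        "name": spec.name,
        "n_categories": spec.n_categories,
        "factors": [
            {
                "name": fac.name,
                "label": fac.label,
                "marker": fac.marker,
                "items": [
                    {"name": it.name, "label": it.label, "reversed": it.reversed}
                    for it in fac.items
                ],
            }
            for fac in spec.factors
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_instrument(path) -> InstrumentSpec:
    """Read an instrument definition from a YAML document.

    Raises :class:`InstrumentError` naming the offending field on malformed
    documents, duplicate item names or empty factors.
    """
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise InstrumentError(f"malformed instrument document: {exc}") from exc
    if not isinstance(doc, dict) or "factors" not in doc:
        raise InstrumentError("instrument document must be a mapping with a 'factors' list")
    factors = []
    for fdoc in doc["factors"]:
        if not isinstance(fdoc, dict) or "name" not in fdoc:
            raise InstrumentError("each factor must be a mapping with a 'name'")
        items = tuple(
            ItemSpec(
                name=idoc["name"],
                label=idoc.get("label", ""),
                reversed=bool(idoc.get("reversed", False)),
            )
            for idoc in fdoc.get("items", [])
        )
        if len(items) < 2:
            raise InstrumentError(f"factor {fdoc['name']!r}: fewer than 2 items")
        factors.append(
            FactorSpec(
                name=fdoc["name"],
                label=fdoc.get("label", ""),
                items=items,
                marker=fdoc.get("marker", ""),
            )
        )
    return InstrumentSpec(
        factors=tuple(factors),
        n_categories=int(doc.get("n_categories", 5)),
        name=doc.get("name", "instrument"),
    )
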