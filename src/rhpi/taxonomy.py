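"""Food taxonomy: the controlled vocabulary of groups and subgroups.

Purchased items are classified into 11 food groups subdivided into 27
subgroups.  Every other module keys on the subgroup and group labels defined
here: the scorer reads group shares ("Fruits and vegetables", "Meat/fish/eggs",
...) and subgroup shares ("Cheese", "Red meat", "Unrefined starches", ...),
and three groups ("Condiments", "Water", "Baby food") are excluded from the
analysis denominator entirely.

The default taxonomy ships the canonical group/subgroup structure; the
item -> subgroup mapping is user data (supplied via YAML or built by the
synthetic generator), because item catalogues are panel-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "FoodTaxonomy",
    "DEFAULT_SUBGROUP_TO_GROUP",
    "DEFAULT_EXCLUDED_GROUPS",
    "default_taxonomy",
]

#: Canonical subgroup -> group structure (11 groups, 27 subgroups).
DEFAULT_SUBGROUP_TO_GROUP: dict[str, str] = {
    # Fruits and vegetables
    "Vegetables": "Fruits and vegetables",
    "Fruits": "Fruits and vegetables",
    "Dried fruits and nuts": "Fruits and vegetables",
    # Meat, fish and eggs
    "Red meat": "Meat/fish/eggs",
    "Processed meat": "Meat/fish/eggs",
    "Eggs and poultry": "Meat/fish/eggs",
    "Fish": "Meat/fish/eggs",
    # Starches (legumes are folded into unrefined starches)
    "Unrefined starches": "Starches",
    "Refined grains": "Starches",
    # Dairy
    "Milk and yoghurt": "Dairy products",
    "Cheese": "Dairy products",
    # Mixed dishes
    "Ready meals": "Mixed dishes",
    "Savoury dishes": "Mixed dishes",
    # Added fats
    "Vegetable fats": "Fats",
    "Animal fats": "Fats",
    # Discretionary foods
    "Savoury snacks": "Discretionary foods",
    "Sugar sweetened beverages": "Discretionary foods",
    "Calorie free beverages": "Discretionary foods",
    "Fruit juices": "Discretionary foods",
    "Sugared cereals": "Discretionary foods",
    "Dairy desserts": "Discretionary foods",
    "Sweet snacks": "Discretionary foods",
    "Sauces": "Discretionary foods",
    # Single-subgroup groups
    "Alcoholic beverages": "Alcoholic beverages",
    "Condiments": "Condiments",
    "Water": "Water",
    "Baby food": "Baby food",
}

#: Groups never counted in the total-expenditure denominator.
DEFAULT_EXCLUDED_GROUPS: frozenset[str] = frozenset(
    {"Condiments", "Water", "Baby food"}
)

#: Labels that the scoring configuration must be able to resolve.
REQUIRED_LABELS: tuple[str, ...] = (
    "Fruits",
    "Vegetables",
    "Starches",
    "Dairy products",
    "Meat/fish/eggs",
    "Fruits and vegetables",
    "Cheese",
    "Milk and yoghurt",
    "Eggs and poultry",
    "Fish",
    "Red meat",
    "Processed meat",
    "Unrefined starches",
    "Refined grains",
    "Vegetable fats",
    "Animal fats",
    "Discretionary foods",
    "Mixed dishes",
    "Alcoholic beverages",
)


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomies."""


@dataclass(frozen=True)
class FoodTaxonomy:
    """Maps item ids to subgroup and group labels.

    Parameters
    ----------
    items
        item-id -> subgroup label.
    subgroup_to_group
        subgroup label -> group label; every subgroup belongs to exactly one
        group by construction of the mapping.
    excluded_groups
        group labels excluded from the share denominator (default:
        condiments, water, baby food).
    """

    items: Mapping[str, str]
    subgroup_to_group: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_TO_GROUP)
    )
    excluded_groups: frozenset[str] = DEFAULT_EXCLUDED_GROUPS

    def __post_init__(self) -> None:
        unknown = {sg for sg in self.items.values() if sg not in self.subgroup_to_group}
        if unknown:
            raise TaxonomyError(
                f"items mapped to unknown subgroups: {sorted(unknown)}"
            )
        groups = set(self.subgroup_to_group.values())
        bad_excluded = set(self.excluded_groups) - groups
        if bad_excluded:
            raise TaxonomyError(f"excluded groups not in taxonomy: {sorted(bad_excluded)}")
        missing = [
            lbl
            for lbl in REQUIRED_LABELS
            if lbl not in groups and lbl not in self.subgroup_to_group
        ]
        if missing:
            raise TaxonomyError(f"taxonomy does not resolve required labels: {missing}")

    # -- lookups ---------------------------------------------------------

    @property
    def subgroups(self) -> list[str]:
        return list(self.subgroup_to_group)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.subgroup_to_group.values():
            seen.setdefault(g)
        return list(seen)

    def subgroup_of(self, item_id: str) -> str:
        try:
            return self.items[item_id]
        except KeyError:
            raise KeyError(f"unknown item id: {item_id!r}") from None

    def group_of_subgroup(self, subgroup: str) -> str:
        try:
            return self.subgroup_to_group[subgroup]
        except KeyError:
            raise KeyError(f"unknown subgroup: {subgroup!r}") from None

    def group_of(self, item_id: str) -> str:
        return self.group_of_subgroup(self.subgroup_of(item_id))

    def is_excluded(self, subgroup: str) -> bool:
        return self.group_of_subgroup(subgroup) in self.excluded_groups

    def subgroups_of_group(self, group: str) -> list[str]:
        out = [sg for sg, g in self.subgroup_to_group.items() if g == group]
        if not out:
            raise KeyError(f"unknown group: {group!r}")
        return out

    def known_item(self, item_id: str) -> bool:
        return item_id in self.items

    # -- serialisation ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "subgroup_to_group": dict(self.subgroup_to_group),
            "excluded_groups": sorted(self.excluded_groups),
            "items": dict(self.items),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "FoodTaxonomy":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            items=doc.get("items", {}),
            subgroup_to_group=doc.get(
                "subgroup_to_group", dict(DEFAULT_SUBGROUP_TO_GROUP)
            ),
            excluded_groups=frozenset(
                doc.get("excluded_groups", DEFAULT_EXCLUDED_GROUPS)
            ),
        )


def default_taxonomy(items: Mapping[str, str] | None = None) -> FoodTaxonomy:
    """Taxonomy with the canonical 11-group / 27-subgroup structure.

    With no ``items``, each subgroup gets a single placeholder item whose id
    is the subgroup label — convenient for share-level work where item
    identity is irrelevant.
    """
    if items is None:
        items = {sg: sg for sg in DEFAULT_SUBGROUP_TO_GROUP}
    return FoodTaxonomy(items=dict(items))


def validate_labels(labels: Iterable[str], taxonomy: FoodTaxonomy) -> None:
    """Raise TaxonomyError if any label is neither a group nor a subgroup."""
    groups = set(taxonomy.groups)
    bad = [
        lbl
        for lbl in labels
        if lbl not in groups and lbl not in taxonomy.subgroup_to_group
    ]
    if bad:
        raise TaxonomyError(f"labels not resolvable in taxonomy: {bad}")
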