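"""Behavioral repertoire (ethogram) for male flesh-fly agonistic encounters.

The analysis repertoire has 16 mutually exclusive behaviors in four
categories: non-interactive, interactive/non-aggressive, low-intensity
aggression (a single collapsed code, ``Lo``), and high-intensity
aggression.  Six raw low-intensity scoring names (chop, uppercut, back
kick, head butt, fencing, boxing) are collapsed to ``Lo`` at analysis
time because each occurs too rarely to analyze on its own.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union


class Category(str, enum.Enum):
    """Four-way functional classification of behaviors."""

    NON_INTERACTIVE = "non_interactive"
    INTERACTIVE_NONAGGRESSIVE = "interactive_nonaggressive"
    LOW_INTENSITY_AGGRESSION = "low_intensity_aggression"
    HIGH_INTENSITY_AGGRESSION = "high_intensity_aggression"


#: Raw scoring names that collapse into the single low-intensity code.
LOW_INTENSITY_RAW = frozenset(
    {"chop", "uppercut", "back kick", "head butt", "fencing", "boxing"}
)

#: Code assigned to collapsed low-intensity aggression.
LOW_INTENSITY_CODE = "Lo"


class EthogramError(ValueError):
    """Raised for invalid ethogram definitions or unknown codes."""


@dataclass(frozen=True)
class Behavior:
    """One discrete behavior: short code, descriptive name, category."""

    code: str
    name: str
    category: Category

    def __post_init__(self) -> None:
        if not self.code:
            raise EthogramError("behavior code must be non-empty")


@dataclass
class Ethogram:
    """Ordered, closed repertoire of behaviors.

    The order of ``behaviors`` fixes the row/column order of every
    transition matrix built against this ethogram.
    """

    behaviors: list[Behavior] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.behaviors:
            if b.code in seen:
                raise EthogramError(f"duplicate behavior code: {b.code!r}")
            seen.add(b.code)

    @property
    def k(self) -> int:
        return len(self.behaviors)

    @property
    def codes(self) -> list[str]:
        return [b.code for b in self.behaviors]

    def __contains__(self, code: str) -> bool:
        return any(b.code == code for b in self.behaviors)

    def __getitem__(self, code: str) -> Behavior:
        for b in self.behaviors:
            if b.code == code:
                return b
        raise KeyError(code)

    def category_of(self, code: str) -> Category:
        """Category of ``code``; raises :class:`EthogramError` if unknown."""
        try:
            return self[code].category
        except KeyError:
            raise EthogramError(f"unknown behavior code: {code!r}") from None

    def codes_in_category(self, category: Category) -> list[str]:
        return [b.code for b in self.behaviors if b.category is category]

    @property
    def high_intensity(self) -> frozenset[str]:
        """Codes of the full-body-contact aggressive behaviors."""
        return frozenset(self.codes_in_category(Category.HIGH_INTENSITY_AGGRESSION))


def collapse_low_intensity(raw_code: str) -> str:
    """Map a raw low-intensity scoring name to ``Lo``; pass others through.

    Idempotent: analysis codes (including ``Lo`` itself) are unchanged.
    Matching is case-insensitive and tolerates underscores for spaces.
    """
    normalized = raw_code.strip().lower().replace("_", " ")
    if normalized in LOW_INTENSITY_RAW:
        return LOW_INTENSITY_CODE
    return raw_code


def load_ethogram(path: Union[str, Path]) -> Ethogram:
    """Read an ethogram definition CSV (``code,name,category`` header)."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "name", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise EthogramError(
                f"{path}: expected columns {sorted(required)}, got {reader.fieldnames}"
            )
        behaviors = []
        for row in reader:
            try:
                category = Category(row["category"].strip())
            except ValueError:
                raise EthogramError(
                    f"{path}: unknown category token {row['category']!r} "
                    f"for code {row['code']!r}"
                ) from None
            behaviors.append(
                Behavior(code=row["code"].strip(), name=row["name"].strip(), category=category)
            )
    return Ethogram(behaviors)


def default_ethogram() -> Ethogram:
    """The packaged 16-behavior paired-male analysis ethogram."""
    ref = resources.files("ethoseq.data").joinpath("ethogram.csv")
    with resources.as_file(ref) as p:
        return load_ethogram(p)
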