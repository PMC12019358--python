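"""Drug-name → contraceptive-modality mapping via an editable regex table.

The six modalities form a closed set. Products that are non-drug
contraceptives (condoms, diaphragms, spermicides, pH modulators) or
emergency contraception map to the ``EXCLUDED`` sentinel; anything the
table does not recognise maps to ``UNMAPPED``.
"""

from __future__ import annotations

import enum
import re
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["Modality", "EXCLUDED", "UNMAPPED", "PatternTable", "load_default_table"]


class Modality(str, enum.Enum):
    """Contraceptive delivery modality."""

    ORAL = "Oral"
    IMPLANT = "Implant"
    IUD = "IUD"
    INJECTABLE = "Injectable"
    TRANSDERMAL = "Transdermal"
    INTRAVAGINAL = "Intravaginal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "Modality":
        for m in cls:
            if m.value.lower() == name.strip().lower():
                return m
        raise ValueError(f"unknown modality name: {name!r}")


# Sentinels returned by mapping when a name is recognised-but-removed or unknown.
EXCLUDED = "excluded"
UNMAPPED = "unmapped"


class PatternTable:
    """Ordered, case-insensitive regex table.

    Exclusion patterns are evaluated before modality patterns; modality
    groups are evaluated in the order they appear in the YAML file, so
    route-specific patterns can shadow the broad oral ones.
    """

    def __init__(self, excluded: list[str], modalities: dict[str, list[str]]):
        self._excluded = [re.compile(p, re.IGNORECASE) for p in excluded]
        self._groups: list[tuple[Modality, list[re.Pattern]]] = []
        for name, pats in modalities.items():
            mod = Modality.from_name(name)
            self._groups.append((mod, [re.compile(p, re.IGNORECASE) for p in pats]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PatternTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw.get("excluded", []), raw.get("modalities", {}))

    def map(self, text: str):
        """Map free text to a :class:`Modality`, ``EXCLUDED`` or ``UNMAPPED``."""
        if not text or not text.strip():
            raise ValueError("drug_name must be non-empty")
        for pat in self._excluded:
            if pat.search(text):
                return EXCLUDED
        for mod, pats in self._groups:
            for pat in pats:
                if pat.search(text):
                    return mod
        return UNMAPPED

    def find_first(self, text: str):
        """Earliest pattern hit in ``text`` by character position.

        Returns ``(position, Modality)`` for the left-most modality match,
        ``(position, EXCLUDED)`` if an exclusion pattern matches earlier,
        or ``None`` when nothing matches. Used to resolve free-text spans
        that mention several products to the nearest one.
        """
        best: tuple[int, object] | None = None
        for pat in self._excluded:
            m = pat.search(text)
            if m and (best is None or m.start() < best[0]):
                best = (m.start(), EXCLUDED)
        for mod, pats in self._groups:
            for pat in pats:
                m = pat.search(text)
                if m and (best is None or m.start() < best[0]):
                    best = (m.start(), mod)
        return best

    def find_last(self, text: str):
        """Latest pattern hit in ``text`` by character position (see find_first)."""
        best: tuple[int, object] | None = None
        for pat in self._excluded:
            for m in pat.finditer(text):
                if best is None or m.start() > best[0]:
                    best = (m.start(), EXCLUDED)
        for mod, pats in self._groups:
            for pat in pats:
                for m in pat.finditer(text):
                    if best is None or m.start() > best[0]:
                        best = (m.start(), mod)
        return best

    def entries(self) -> list[tuple[Modality, str]]:
        """Flat (modality, raw pattern) list, mainly for cross-checks."""
        return [(mod, p.pattern) for mod, pats in self._groups for p in pats]


def load_default_table() -> PatternTable:
    """Load the pattern table shipped with the package."""
    with resources.as_file(
        resources.files("switchscope").joinpath("data/modality_patterns.yaml")
    ) as p:
        return PatternTable.from_yaml(p)
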