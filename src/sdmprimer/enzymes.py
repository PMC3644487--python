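"""Restriction-enzyme catalogs.

A catalog is an ordered collection of named IUPAC recognition patterns with
an optional enabled subset. The on-disk format is one enzyme per line,
``NAME<tab-or-space>SITE``; ``#`` comments and blank lines are skipped.
A packaged default catalog (REBASE-derived subset of common commercial
Type II enzymes) is provided; a user file overrides it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

from .seq_core import (
    InvalidSequenceError,
    expand_iupac,
    iupac_degeneracy,
    is_palindromic,
)

logger = logging.getLogger(__name__)

__all__ = ["RestrictionEnzyme", "EnzymeCatalog", "EnzymeParseError",
           "parse_enzyme_list", "default_catalog"]


class EnzymeParseError(ValueError):
    """Malformed enzyme-list input (message carries the line number)."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named recognition sequence (IUPAC codes allowed)."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        # validates symbols as a side effect
        iupac_degeneracy(self.recognition)

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.recognition)

    @property
    def degeneracy(self) -> int:
        return iupac_degeneracy(self.recognition)

    def realizations(self) -> frozenset[str]:
        """All concrete DNA strings matching the recognition pattern."""
        return expand_iupac(self.recognition)


@dataclass
class EnzymeCatalog:
    """Ordered enzyme collection with an optional enabled selection."""

    enzymes: list[RestrictionEnzyme] = field(default_factory=list)
    selection: set[str] | None = None

    def __post_init__(self) -> None:
        if self.selection is not None:
            unknown = self.selection - {e.name for e in self.enzymes}
            if unknown:
                raise KeyError(f"selection names absent from catalog: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.enzymes)

    def __iter__(self):
        return iter(self.enzymes)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.enzymes)

    def get(self, name: str) -> RestrictionEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(name)

    def enabled(self) -> list[RestrictionEnzyme]:
        """Enzymes active for a run (all if no selection was made)."""
        if self.selection is None:
            return list(self.enzymes)
        return [e for e in self.enzymes if e.name in self.selection]

    def select(self, names: list[str] | set[str]) -> "EnzymeCatalog":
        return EnzymeCatalog(list(self.enzymes), set(names))

    def serialize(self) -> str:
        return "".join(f"{e.name}\t{e.recognition}\n" for e in self.enzymes)


def parse_enzyme_list(text: str) -> EnzymeCatalog:
    """Parse ``NAME SITE`` lines (tab or space delimited) into a catalog.

    Duplicate names: last occurrence wins, with a logged warning.
    """
    by_name: dict[str, RestrictionEnzyme] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise EnzymeParseError(
                f"line {lineno}: expected 'NAME SITE', got {len(fields)} field(s): {raw!r}"
            )
        name, site = fields
        try:
            enzyme = RestrictionEnzyme(name, site)
        except InvalidSequenceError as exc:
            raise EnzymeParseError(f"line {lineno}: {exc}") from exc
        if name in by_name:
            logger.warning("duplicate enzyme %r at line %d: last definition wins",
                           name, lineno)
            order.remove(name)
        by_name[name] = enzyme
        order.append(name)
    return EnzymeCatalog([by_name[n] for n in order])


def default_catalog() -> EnzymeCatalog:
    """The packaged default catalog of common Type II recognition sites."""
    text = resources.files("sdmprimer").joinpath("data/enzymes.tsv").read_text()
    return parse_enzyme_list(text)
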