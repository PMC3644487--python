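"""Amino-acid substitution requests and candidate-sequence enumeration.

Given one or more substitutions (e.g. G255A), a local window around the
mutated codons is extracted and every nucleotide realization of the
requested protein change is enumerated over the codon degeneracy of the
target residues. With two serine substitutions this yields 6 x 6 = 36
candidate sequences; a forced codon collapses the corresponding factor
to 1.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .seq_core import (
    CodingSequence,
    InvalidSequenceError,
    synonymous_codons,
    translate,
    translate_codon,
)

__all__ = ["MutationSpec", "MutationWindow", "CandidateSequence",
           "build_window", "enumerate_candidates", "TooManyCandidatesError"]

DEFAULT_FLANK_CODONS = 3
DEFAULT_CANDIDATE_CAP = 10_000

_SPEC_RE = re.compile(
    r"^([A-Z\*])(\d+)([A-Z\*])(?:=([ACGTacgt]{3}))?$"
)


class TooManyCandidatesError(RuntimeError):
    """Combinatorial candidate count exceeded the configured cap."""


@dataclass(frozen=True)
class MutationSpec:
    """One requested residue substitution, 1-based in CDS codon coordinates."""

    aa_position: int
    wt_residue: str
    target_residue: str
    forced_codon: str | None = None

    def __post_init__(self) -> None:
        if self.aa_position < 1:
            raise ValueError("aa_position is 1-based and must be >= 1")
        for r in (self.wt_residue, self.target_residue):
            synonymous_codons(r)  # validates the letter
        if self.forced_codon is not None:
            codon = self.forced_codon.upper()
            if translate_codon(codon) != self.target_residue:
                raise ValueError(
                    f"forced codon {codon} encodes {translate_codon(codon)}, "
                    f"not the target residue {self.target_residue}"
                )
            object.__setattr__(self, "forced_codon", codon)

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse ``G255A`` or ``G255A=GCA`` notation."""
        m = _SPEC_RE.match(text.strip())
        if not m:
            raise ValueError(
                f"cannot parse mutation {text!r}; expected e.g. G255A or G255A=GCA"
            )
        wt, pos, target, codon = m.groups()
        return cls(int(pos), wt, target, codon)

    def __str__(self) -> str:
        base = f"{self.wt_residue}{self.aa_position}{self.target_residue}"
        return base + (f"={self.forced_codon}" if self.forced_codon else "")

    def target_codons(self) -> list[str]:
        """Codon choices for the target residue, in fixed lexicographic order."""
        if self.forced_codon:
            return [self.forced_codon]
        return sorted(synonymous_codons(self.target_residue))


@dataclass(frozen=True)
class MutationWindow:
    """The local region (complete codons) extracted around the mutations."""

    first_codon: int
    last_codon: int
    wt_bases: str
    wt_residues: str

    @property
    def n_codons(self) -> int:
        return self.last_codon - self.first_codon + 1

    @property
    def start_base(self) -> int:
        """1-based position of the window's first base in the CDS."""
        return 3 * (self.first_codon - 1) + 1

    def codon_offset(self, aa_position: int) -> int:
        """0-based codon index within the window of a CDS codon position."""
        if not self.first_codon <= aa_position <= self.last_codon:
            raise IndexError(f"codon {aa_position} outside window "
                             f"{self.first_codon}..{self.last_codon}")
        return aa_position - self.first_codon


@dataclass(frozen=True)
class CandidateSequence:
    """A mutated realization of the window, with site gains/losses annotated."""

    bases: str
    changed_positions: frozenset[int]  # 1-based offsets within the window
    residues: str
    sites_gained: tuple = ()
    sites_lost: tuple = ()

    @property
    def n_changes(self) -> int:
        return len(self.changed_positions)

    @property
    def gc_pct(self) -> float:
        return 100.0 * sum(b in "GC" for b in self.bases) / len(self.bases)

    def with_sites(self, gained, lost) -> "CandidateSequence":
        return replace(self, sites_gained=tuple(gained), sites_lost=tuple(lost))


def _hamming_positions(a: str, b: str) -> frozenset[int]:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return frozenset(i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y)


def make_candidate(window: MutationWindow, bases: str) -> CandidateSequence:
    """Build a candidate from explicit window bases, deriving the change set."""
    return CandidateSequence(
        bases=bases,
        changed_positions=_hamming_positions(window.wt_bases, bases),
        residues=translate(bases),
    )


def build_window(
    cds: CodingSequence,
    specs: list[MutationSpec],
    flank_codons: int = DEFAULT_FLANK_CODONS,
) -> MutationWindow:
    """Extract the codon window spanning all mutations plus a symmetric flank.

    The flank is clipped at the sequence ends. Each spec's claimed wild-type
    residue is validated against the translation.
    """
    if not specs:
        raise ValueError("at least one mutation spec is required")
    protein = cds.translation()
    for spec in specs:
        if spec.aa_position > cds.n_codons:
            raise IndexError(
                f"mutation position {spec.aa_position} beyond the last complete "
                f"codon ({cds.n_codons})"
            )
        found = protein[spec.aa_position - 1]
        if found != spec.wt_residue:
            raise InvalidSequenceError(
                f"wild-type residue mismatch at codon {spec.aa_position}: "
                f"spec says {spec.wt_residue}, translation shows {found}"
            )
    positions = sorted(s.aa_position for s in specs)
    if len(positions) != len(set(positions)):
        raise ValueError("duplicate mutation positions")
    first = max(1, positions[0] - flank_codons)
    last = min(cds.n_codons, positions[-1] + flank_codons)
    bases = cds.bases[3 * (first - 1): 3 * last]
    return MutationWindow(first, last, bases, translate(bases))


def enumerate_candidates(
    window: MutationWindow,
    specs: list[MutationSpec],
    cap: int = DEFAULT_CANDIDATE_CAP,
) -> list[CandidateSequence]:
    """All nucleotide realizations of the requested substitutions.

    The count is the product over specs of the target-residue codon
    degeneracy (1 for a forced codon). Ordering is deterministic:
    codon sets are iterated lexicographically, first spec slowest.
    """
    choices = [spec.target_codons() for spec in specs]
    total = math.prod(len(c) for c in choices)
    if total > cap:
        raise TooManyCandidatesError(
            f"{total} candidate sequences exceed the cap of {cap}; "
            "force codons (e.g. S12S=AGC) to reduce the combinatorics"
        )
    offsets = [window.codon_offset(s.aa_position) for s in specs]

    def assign(combo: tuple[str, ...]) -> str:
        codons = [window.wt_bases[3 * i: 3 * i + 3]
                  for i in range(window.n_codons)]
        for off, codon in zip(offsets, combo):
            codons[off] = codon
        return "".join(codons)

    out = []
    for combo in _product_lex(choices):
        out.append(make_candidate(window, assign(combo)))
    return out


def _product_lex(choices: list[list[str]]):
    import itertools
    return itertools.product(*choices)
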