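"""Fundamental sequence types and genetic-code utilities.

Everything downstream (candidate enumeration, silent-site engineering,
primer design) works on plain uppercase ACGT strings addressed in 1-based
coordinates; this module owns input normalization, translation under the
standard genetic code, codon degeneracy and IUPAC ambiguity expansion.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "CodingSequence",
    "InvalidSequenceError",
    "IUPAC_CODES",
    "expand_iupac",
    "iupac_to_regex",
    "reverse_complement",
    "reverse_complement_iupac",
    "synonymous_codons",
    "translate",
    "translate_codon",
]


class InvalidSequenceError(ValueError):
    """Raised when an input sequence or pattern fails validation."""


#: IUPAC nucleotide ambiguity codes and the concrete bases each denotes.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# complement of an ambiguity code = code of the complemented base set
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

_NORMALIZE_STRIP = re.compile(r"[\s\d]+")


def _normalize(raw: str) -> str:
    """Uppercase and strip whitespace/digits (ruler artifacts from pasted text)."""
    return _NORMALIZE_STRIP.sub("", raw).upper()


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame DNA coding sequence.

    Position 1 of ``bases`` is codon position 1; a trailing partial codon
    (1-2 nt) is tolerated but inert for all codon-addressed operations.
    """

    bases: str

    def __post_init__(self) -> None:
        normalized = _normalize(self.bases)
        bad = set(normalized) - set("ACGT")
        if bad:
            raise InvalidSequenceError(
                f"sequence contains non-ACGT characters: {sorted(bad)}"
            )
        if len(normalized) < 3:
            raise InvalidSequenceError(
                f"sequence too short ({len(normalized)} nt); need at least one codon"
            )
        object.__setattr__(self, "bases", normalized)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_codons(self) -> int:
        """Number of complete codons."""
        return len(self.bases) // 3

    def codon(self, index: int) -> str:
        """Return the 1-based ``index``-th codon."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} out of range 1..{self.n_codons}")
        return self.bases[3 * (index - 1): 3 * index]

    def translation(self) -> str:
        return translate(self.bases)


def translate_codon(codon: str) -> str:
    """Standard-genetic-code image of a single codon ('*' for stops)."""
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise InvalidSequenceError(f"not a valid codon: {codon!r}")
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def translate(seq: str | CodingSequence) -> str:
    """Translate a DNA string under the standard code.

    Trailing bases beyond the last complete codon are ignored.
    """
    bases = seq.bases if isinstance(seq, CodingSequence) else _normalize(seq)
    if len(bases) < 3:
        raise InvalidSequenceError("nothing to translate: fewer than 3 nt")
    if set(bases) - set("ACGT"):
        raise InvalidSequenceError("sequence contains non-ACGT characters")
    n = len(bases) - len(bases) % 3
    return str(Seq(bases[:n]).translate(table=1))


@lru_cache(maxsize=None)
def synonymous_codons(aa: str) -> frozenset[str]:
    """All standard-code codons encoding one-letter residue ``aa`` ('*' = stop)."""
    if aa == "*":
        return frozenset(_STANDARD_TABLE.stop_codons)
    codons = frozenset(
        c for c, r in _STANDARD_TABLE.forward_table.items() if r == aa
    )
    if not codons:
        raise InvalidSequenceError(f"unknown residue letter: {aa!r}")
    return codons


def expand_iupac(pattern: str) -> frozenset[str]:
    """Expand an IUPAC ambiguity pattern to its set of concrete DNA strings.

    The cardinality of the result equals the product of per-symbol
    degeneracies (e.g. ``"NN"`` expands to 16 dimers).
    """
    try:
        choices = [IUPAC_CODES[s] for s in pattern.upper()]
    except KeyError as exc:
        raise InvalidSequenceError(f"illegal IUPAC symbol: {exc.args[0]!r}") from None
    if not choices:
        raise InvalidSequenceError("empty pattern")
    return frozenset("".join(p) for p in itertools.product(*choices))


def iupac_degeneracy(pattern: str) -> int:
    """Number of concrete sequences an IUPAC pattern denotes."""
    n = 1
    for s in pattern.upper():
        try:
            n *= len(IUPAC_CODES[s])
        except KeyError:
            raise InvalidSequenceError(f"illegal IUPAC symbol: {s!r}") from None
    return n


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a plain character-class regex."""
    parts = []
    for s in pattern.upper():
        try:
            bases = IUPAC_CODES[s]
        except KeyError:
            raise InvalidSequenceError(f"illegal IUPAC symbol: {s!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a plain ACGT string."""
    if set(seq) - set("ACGT"):
        raise InvalidSequenceError("reverse_complement requires a plain ACGT string")
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (complementing ambiguity codes)."""
    if set(pattern.upper()) - set(IUPAC_CODES):
        raise InvalidSequenceError("invalid IUPAC pattern")
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def is_palindromic(pattern: str) -> bool:
    """True if an IUPAC pattern equals its own reverse complement."""
    return pattern.upper() == reverse_complement_iupac(pattern)


def read_sequence_text(text: str) -> CodingSequence:
    """Parse plain text or a single-record FASTA block into a CodingSequence."""
    stripped = text.lstrip()
    if stripped.startswith(">"):
        lines = stripped.splitlines()
        records = sum(1 for ln in lines if ln.startswith(">"))
        if records > 1:
            raise InvalidSequenceError(
                "multi-record FASTA is not supported; provide a single CDS"
            )
        body = "".join(ln for ln in lines[1:])
        return CodingSequence(body)
    return CodingSequence(text)
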