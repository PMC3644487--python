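"""Restriction-site search and silent site engineering.

Three operations on a mutated candidate window:

* ``find_sites`` — regex search for every enabled recognition pattern,
  overlapping matches included, both strands for non-palindromic sites.
* ``remove_sites_silently`` — re-assign synonymous codons over the codons a
  site spans so the site disappears with the minimum number of nucleotide
  changes (GC content closest to 50% breaks ties); overlapping sites are
  eliminated jointly.
* ``insert_sites_silently`` — the reverse sliding-window: each recognition
  pattern is placed at every codon-frame offset, its concrete realizations
  are completed to whole codons, and wherever the resulting codons are
  synonymous with the window's own residues the site is written in as
  nucleotides, leaving the protein sequence untouched.

All coordinates are 1-based, matching the ``NdeI @11`` reporting convention.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass

import pandas as pd

from .enzymes import EnzymeCatalog, RestrictionEnzyme
from .mutagenesis import CandidateSequence, MutationWindow, make_candidate
from .seq_core import (
    expand_iupac,
    iupac_to_regex,
    is_palindromic,
    reverse_complement_iupac,
    synonymous_codons,
)

logger = logging.getLogger(__name__)

__all__ = ["SiteMatch", "SilentEdit", "UnremovableSiteError", "find_sites",
           "remove_sites_silently", "insert_sites_silently", "preselect",
           "annotate_sites", "INSERTION_REALIZATION_CAP"]

#: Degenerate recognition patterns with more realizations than this are
#: skipped during insertion (search stays bounded); they are still searched.
INSERTION_REALIZATION_CAP = 256


@dataclass(frozen=True, order=True)
class SiteMatch:
    """One recognition-site occurrence (1-based inclusive start)."""

    start: int
    enzyme_name: str
    strand: str = "+"
    length: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def __str__(self) -> str:
        tag = "" if self.strand == "+" else " (-)"
        return f"{self.enzyme_name} @{self.start}{tag}"


@dataclass(frozen=True)
class SilentEdit:
    """A translation-preserving re-write of the window."""

    positions: frozenset[int]  # 1-based window offsets changed
    before: str
    after: str

    @property
    def n_changes(self) -> int:
        return len(self.positions)

    @property
    def gc_after(self) -> float:
        return 100.0 * sum(b in "GC" for b in self.after) / len(self.after)


class UnremovableSiteError(RuntimeError):
    """No synonymous re-assignment of the spanned codons destroys the site."""


from functools import lru_cache


@lru_cache(maxsize=4096)
def _compiled(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({iupac_to_regex(pattern)}))")


def _pattern_matches(seq: str, enzyme: RestrictionEnzyme) -> list[SiteMatch]:
    out = []
    for m in _compiled(enzyme.recognition).finditer(seq):
        out.append(SiteMatch(m.start() + 1, enzyme.name, "+", enzyme.site_length))
    if not is_palindromic(enzyme.recognition):
        rc = reverse_complement_iupac(enzyme.recognition)
        for m in _compiled(rc).finditer(seq):
            out.append(SiteMatch(m.start() + 1, enzyme.name, "-", enzyme.site_length))
    return out


def find_sites(seq: str, catalog: EnzymeCatalog) -> list[SiteMatch]:
    """All occurrences of enabled recognition sites, overlapping included.

    Palindromic patterns are reported once (strand '+'); non-palindromic
    patterns are additionally searched as their reverse complement and
    reported with strand '-'.
    """
    matches: list[SiteMatch] = []
    for enzyme in catalog.enabled():
        matches.extend(_pattern_matches(seq, enzyme))
    return sorted(matches)


def annotate_sites(
    window: MutationWindow, candidate: CandidateSequence, catalog: EnzymeCatalog
) -> CandidateSequence:
    """Record site gains/losses of a candidate relative to the wild-type window."""
    wt = set(find_sites(window.wt_bases, catalog))
    mut = set(find_sites(candidate.bases, catalog))
    return candidate.with_sites(gained=sorted(mut - wt), lost=sorted(wt - mut))


def _spanned_codons(matches: list[SiteMatch], n_codons: int) -> list[int]:
    codons: set[int] = set()
    for m in matches:
        first = (m.start - 1) // 3
        last = (m.end - 1) // 3
        codons.update(range(max(0, first), min(n_codons, last + 1)))
    return sorted(codons)


def remove_sites_silently(
    window: MutationWindow,
    candidate: CandidateSequence,
    matches: list[SiteMatch],
    catalog: EnzymeCatalog | None = None,
    gc_target: float = 50.0,
) -> CandidateSequence:
    """Destroy the listed site occurrences with minimal silent changes.

    Only the codons the matched sites span are re-assigned; among all
    synonymous assignments that leave no occurrence of the matched enzymes
    anywhere in the window (and, when a catalog is given, do not disturb
    sites of any other enabled enzyme), the one with the fewest nucleotide
    changes wins, ties broken by window GC% closest to ``gc_target``, then
    lexicographically.
    """
    if not matches:
        return candidate
    bases = candidate.bases
    n_codons = len(bases) // 3
    target_names = {m.enzyme_name for m in matches}
    if catalog is not None:
        target_enzymes = [e for e in catalog.enabled() if e.name in target_names]
        other_enzymes = [e for e in catalog.enabled() if e.name not in target_names]
    else:
        raise ValueError("a catalog is required to re-verify site removal")
    target_cat = EnzymeCatalog(target_enzymes)
    other_cat = EnzymeCatalog(other_enzymes)
    other_before = set(find_sites(bases, other_cat))

    editable = _spanned_codons(matches, n_codons)
    choices = [sorted(synonymous_codons(candidate.residues[i])) for i in editable]

    best: tuple | None = None
    for combo in itertools.product(*choices):
        codons = [bases[3 * i: 3 * i + 3] for i in range(n_codons)]
        for i, codon in zip(editable, combo):
            codons[i] = codon
        new_bases = "".join(codons)
        if find_sites(new_bases, target_cat):
            continue
        if set(find_sites(new_bases, other_cat)) != other_before:
            continue  # the edit must not disturb other enzymes' sites
        n = sum(a != b for a, b in zip(bases, new_bases))
        gc = 100.0 * sum(b in "GC" for b in new_bases) / len(new_bases)
        key = (n, abs(gc - gc_target), new_bases)
        if best is None or key < best[0]:
            best = (key, new_bases)
    if best is None:
        raise UnremovableSiteError(
            f"no synonymous re-assignment of codons {editable} removes "
            f"{sorted(target_names)} without side effects"
        )
    result = make_candidate(window, best[1])
    return result.with_sites(gained=candidate.sites_gained, lost=sorted(matches))


def _codon_realizations(site: str, offset: int) -> int:
    """Size of the codon-completed realization set for a site placed at a
    codon-frame ``offset`` (0-2): pattern degeneracy times 4 per flanking
    pad base needed to complete the partial codons."""
    from .seq_core import iupac_degeneracy

    left_pad = offset
    right_pad = (3 - (offset + len(site)) % 3) % 3
    return iupac_degeneracy(site) * 4 ** (left_pad + right_pad)


def insert_sites_silently(
    window: MutationWindow,
    candidate: CandidateSequence,
    catalog: EnzymeCatalog,
    realization_cap: int = INSERTION_REALIZATION_CAP,
) -> list[tuple[CandidateSequence, SiteMatch]]:
    """All silent insertions of enabled recognition sites into the candidate.

    For every enzyme, strand and placement, the concrete realizations of the
    recognition pattern are completed to whole codons with every base choice
    consistent with the window's own residues; each distinct resulting base
    string that (re-verified) carries the new site and leaves every other
    enabled site untouched is emitted with its SiteMatch. Translation is
    preserved by construction. A site already realized in place is returned
    as a zero-change insertion.
    """
    bases = candidate.bases
    n_codons = len(bases) // 3
    before = set(find_sites(bases, catalog))
    seen: set[tuple[str, SiteMatch]] = set()
    out: list[tuple[CandidateSequence, SiteMatch]] = []

    for enzyme in catalog.enabled():
        patterns = [(enzyme.recognition, "+")]
        if not enzyme.palindromic:
            patterns.append((reverse_complement_iupac(enzyme.recognition), "-"))
        if enzyme.degeneracy > realization_cap:
            logger.warning(
                "skipping %s for insertion: %d realizations exceed the cap of %d",
                enzyme.name, enzyme.degeneracy, realization_cap,
            )
            continue
        for pattern, strand in patterns:
            L = len(pattern)
            if L > len(bases):
                continue
            realizations = sorted(expand_iupac(pattern))
            for p in range(len(bases) - L + 1):  # 0-based site start
                c0, c1 = p // 3, (p + L - 1) // 3
                for real in realizations:
                    combos = _codon_choices(candidate.residues, real, p, c0, c1)
                    if combos is None:
                        continue
                    for combo in itertools.product(*combos):
                        codons = [bases[3 * i: 3 * i + 3] for i in range(n_codons)]
                        for i, codon in zip(range(c0, c1 + 1), combo):
                            codons[i] = codon
                        new_bases = "".join(codons)
                        match = SiteMatch(p + 1, enzyme.name, strand, L)
                        key = (new_bases, match)
                        if key in seen:
                            continue
                        seen.add(key)
                        after = set(find_sites(new_bases, catalog))
                        if after != before | {match}:
                            continue  # created/destroyed sites beyond the identifier
                        out.append((make_candidate(window, new_bases), match))
    out.sort(key=lambda t: (t[0].n_changes, t[1], t[0].bases))
    return out


def _codon_choices(residues: str, realization: str, p: int, c0: int, c1: int):
    """Synonymous codon choices per spanned codon that realize the site.

    Returns None if some spanned codon cannot carry its overlap of the site
    while keeping its residue.
    """
    combos = []
    for i in range(c0, c1 + 1):
        lo, hi = max(3 * i, p), min(3 * i + 3, p + len(realization))
        fixed = {j - 3 * i: realization[j - p] for j in range(lo, hi)}
        allowed = [
            codon for codon in sorted(synonymous_codons(residues[i]))
            if all(codon[k] == b for k, b in fixed.items())
        ]
        if not allowed:
            return None
        combos.append(allowed)
    return combos


def preselect(candidates: list[CandidateSequence]) -> pd.DataFrame:
    """Pre-evaluation table of all candidates, deterministically sorted.

    Sort order: fewest nucleotide changes, then window GC% closest to 50,
    then base string. One row per candidate; the caller picks exactly one
    row for primer design.
    """
    if not candidates:
        raise ValueError("no candidate sequences to pre-select from")
    rows = []
    for cand in candidates:
        rows.append({
            "bases": cand.bases,
            "residues": cand.residues,
            "n_changes": cand.n_changes,
            "gc_pct": round(cand.gc_pct, 2),
            "changed_positions": ",".join(map(str, sorted(cand.changed_positions))),
            "sites_gained": "; ".join(str(s) for s in cand.sites_gained),
            "sites_lost": "; ".join(str(s) for s in cand.sites_lost),
        })
    df = pd.DataFrame(rows)
    df["_gc_dist"] = (df["gc_pct"] - 50.0).abs()
    df = (df.sort_values(["n_changes", "_gc_dist", "bases"], kind="mergesort")
            .drop(columns="_gc_dist").reset_index(drop=True))
    df.index = pd.RangeIndex(1, len(df) + 1, name="row")
    return df
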