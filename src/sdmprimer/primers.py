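"""Partially overlapping mutagenic primer pairs.

Forward primers share a fixed 5' start (``five_anchor`` template-identical
bases upstream of the first changed nucleotide) and enumerate 3' ends from
``three_min`` to ``three_max`` wild-type bases past the last change; reverse
primers are built with the same geometry on the antisense strand and are
reported 5'->3' in their own coordinates. Forward and reverse overlap over
the mutated core, which every primer must contain in full.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enzymes import EnzymeCatalog
from .mutagenesis import CandidateSequence, MutationWindow
from .scoring import ScoreBreakdown, ScoringConfig, score_primer
from .seq_core import CodingSequence, reverse_complement
from .sites import SiteMatch, find_sites
from .thermo import PrimerMetrics, compute_metrics

__all__ = ["DesignParams", "PrimerCandidate", "design_primer_pairs",
           "count_nt_changes", "apply_candidate"]


@dataclass(frozen=True)
class DesignParams:
    """Primer-geometry parameters (defaults give 29-33 nt oligos for a
    7-nt-wide change set, the usual double-mutant span)."""

    min_len: int = 25
    max_len: int = 45
    five_anchor: int = 10
    three_min: int = 12
    three_max: int = 16

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.three_min > self.three_max:
            raise ValueError("three_min must not exceed three_max")
        if min(self.min_len, self.five_anchor, self.three_min) < 1:
            raise ValueError("lengths and anchors must be positive")


@dataclass(frozen=True)
class PrimerCandidate:
    """One oriented oligo with its metric panel and score."""

    index: int
    orientation: str  # "forward" | "reverse"
    bases: str        # 5'->3' (reverse primers on the antisense strand)
    template_start: int  # 1-based 5' position in its strand's coordinates
    metrics: PrimerMetrics
    score: ScoreBreakdown
    re_sites: tuple[SiteMatch, ...]  # positions within the primer itself


def count_nt_changes(primer_bases: str, template: str, template_start: int) -> int:
    """Hamming distance between a primer and the template substring under it.

    ``template_start`` is the 1-based position of the primer's 5' base on the
    (strand-appropriate) template.
    """
    start = template_start - 1
    end = start + len(primer_bases)
    if start < 0 or end > len(template):
        raise ValueError(
            f"primer at {template_start} (+{len(primer_bases)} nt) overhangs "
            f"the {len(template)}-nt template"
        )
    return sum(a != b for a, b in zip(primer_bases, template[start:end]))


def apply_candidate(cds: CodingSequence, window: MutationWindow,
                    candidate: CandidateSequence) -> str:
    """The full-length mutated template (sense strand)."""
    start = window.start_base - 1
    return (cds.bases[:start] + candidate.bases
            + cds.bases[start + len(candidate.bases):])


def _enumerate_one_strand(
    mutated: str, wildtype: str, changes: list[int], params: DesignParams,
    orientation: str, catalog: EnzymeCatalog, config: ScoringConfig | None,
) -> list[PrimerCandidate]:
    first, last = changes[0], changes[-1]
    start = first - params.five_anchor
    if start < 1:
        raise ValueError(
            f"{orientation} primer needs {params.five_anchor} anchor bases 5' "
            f"of the first change at {first}; short by {1 - start} nt"
        )
    if last + params.three_min > len(mutated):
        raise ValueError(
            f"{orientation} primer needs at least {params.three_min} bases 3' "
            f"of the last change at {last}; short by "
            f"{last + params.three_min - len(mutated)} nt"
        )
    out = []
    for ext in range(params.three_min, params.three_max + 1):
        end = last + ext
        if end > len(mutated):
            break
        bases = mutated[start - 1: end]
        if not params.min_len <= len(bases) <= params.max_len:
            continue
        n_changes = count_nt_changes(bases, wildtype, start)
        metrics = compute_metrics(bases, n_changes)
        out.append(PrimerCandidate(
            index=0,
            orientation=orientation,
            bases=bases,
            template_start=start,
            metrics=metrics,
            score=score_primer(metrics, config),
            re_sites=tuple(find_sites(bases, catalog)),
        ))
    return out


def design_primer_pairs(
    template: CodingSequence,
    selected: CandidateSequence,
    window: MutationWindow,
    params: DesignParams | None = None,
    catalog: EnzymeCatalog | None = None,
    scoring_config: ScoringConfig | None = None,
) -> list[PrimerCandidate]:
    """Forward and reverse primer series for the selected mutated candidate.

    Returns the forward block first, then the reverse block, with 1-based
    ordinals across both. Each primer covers every changed nucleotide and
    carries metrics, score and re-verified restriction sites (positions
    1-based within the primer's own 5'->3' sequence).
    """
    params = params or DesignParams()
    catalog = catalog or EnzymeCatalog([])
    if not selected.changed_positions:
        raise ValueError("selected candidate has no changed nucleotides; "
                         "there is nothing to mutagenise")
    L = len(template.bases)
    sense_changes = sorted(window.start_base - 1 + off
                           for off in selected.changed_positions)
    mutated_sense = apply_candidate(template, window, selected)
    mutated_anti = reverse_complement(mutated_sense)
    wildtype_anti = reverse_complement(template.bases)
    anti_changes = sorted(L - pos + 1 for pos in sense_changes)

    primers = _enumerate_one_strand(
        mutated_sense, template.bases, sense_changes, params,
        "forward", catalog, scoring_config)
    primers += _enumerate_one_strand(
        mutated_anti, wildtype_anti, anti_changes, params,
        "reverse", catalog, scoring_config)
    return [
        PrimerCandidate(i, p.orientation, p.bases, p.template_start,
                        p.metrics, p.score, p.re_sites)
        for i, p in enumerate(primers, start=1)
    ]
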