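"""End-to-end run: window -> candidates -> silent site engineering ->
candidate selection -> primer pairs -> report table.

The report reproduces the standard output schema of silent-site SDM primer
sheets: ordinal, orientation, 5'->3' sequence, integer score percent,
mismatch count, Tm, length, GC%, terminal dG values, run/repeat counts,
restriction-site count, 3'-GC% and a comment column listing each site as
``NAME @position`` within the primer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enzymes import EnzymeCatalog, default_catalog, parse_enzyme_list
from .mutagenesis import (
    DEFAULT_FLANK_CODONS,
    CandidateSequence,
    MutationSpec,
    MutationWindow,
    build_window,
    enumerate_candidates,
)
from .primers import DesignParams, PrimerCandidate, design_primer_pairs
from .scoring import ScoringConfig
from .seq_core import CodingSequence, read_sequence_text
from .sites import (
    UnremovableSiteError,
    annotate_sites,
    find_sites,
    insert_sites_silently,
    preselect,
    remove_sites_silently,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_report",
            "build_candidate_pool", "select_candidate", "report_table",
            "REPORT_COLUMNS"]

REPORT_COLUMNS = [
    "No.", "Orientation", "Primer (5'-3')", "Score [%]", "nt changes",
    "Tm [°C]", "nt", "GC%", "3'ΔG", "5'ΔG", "Runs", "Rep.",
    "RE sites", "3'GC%", "Comments",
]


@dataclass
class RunConfig:
    """Everything one run needs; fully serializable so identical inputs give
    byte-identical TSV output."""

    sequence: str | Path | CodingSequence
    mutations: list[str | MutationSpec]
    enzyme_file: str | Path | None = None
    selection: list[str] | None = None
    flank_codons: int = DEFAULT_FLANK_CODONS
    design: DesignParams = field(default_factory=DesignParams)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    candidate: int | None = None  # 1-based preselect row; None = auto
    output: str | Path | None = None
    output_format: str = "tsv"  # tsv | xlsx


@dataclass
class PipelineResult:
    cds: CodingSequence
    specs: list[MutationSpec]
    window: MutationWindow
    catalog: EnzymeCatalog
    pool: list[CandidateSequence]
    preselection: pd.DataFrame
    selected: CandidateSequence
    primers: list[PrimerCandidate]
    table: pd.DataFrame
    warnings: list[str]


def _load_sequence(source) -> CodingSequence:
    if isinstance(source, CodingSequence):
        return source
    path = Path(source)
    if path.exists():
        return read_sequence_text(path.read_text())
    return read_sequence_text(str(source))


def _load_catalog(config: RunConfig) -> EnzymeCatalog:
    if config.enzyme_file is not None:
        catalog = parse_enzyme_list(Path(config.enzyme_file).read_text())
    else:
        catalog = default_catalog()
    if config.selection is not None:
        catalog = catalog.select(set(config.selection))
    return catalog


def build_candidate_pool(
    window: MutationWindow,
    specs: list[MutationSpec],
    catalog: EnzymeCatalog,
) -> list[CandidateSequence]:
    """Enumerated candidates plus every silent insertion/removal variant.

    All variants are re-annotated against the wild-type window, so an
    inserted site appears in ``sites_gained`` and a removed one in
    ``sites_lost``. Distinct base strings only; deterministic order.
    """
    base_candidates = enumerate_candidates(window, specs)
    wt_sites = set(find_sites(window.wt_bases, catalog))
    pool: dict[str, CandidateSequence] = {}

    def add(cand: CandidateSequence) -> None:
        if cand.bases not in pool:
            pool[cand.bases] = annotate_sites(window, cand, catalog)

    for cand in base_candidates:
        add(cand)
        for variant, _match in insert_sites_silently(window, cand, catalog):
            add(variant)
        # pre-existing sites that survived the mutation can be silently
        # removed to serve as a loss-of-site identifier
        surviving = [m for m in find_sites(cand.bases, catalog) if m in wt_sites]
        by_enzyme: dict[str, list] = {}
        for m in surviving:
            by_enzyme.setdefault(m.enzyme_name, []).append(m)
        for matches in by_enzyme.values():
            try:
                add(remove_sites_silently(window, cand, matches, catalog))
            except UnremovableSiteError as exc:
                logger.info("removal skipped: %s", exc)
    return [pool[b] for b in sorted(pool)]


def select_candidate(
    table: pd.DataFrame,
    pool: list[CandidateSequence],
    catalog: EnzymeCatalog,
    candidate: int | None,
    warnings: list[str],
) -> CandidateSequence:
    """Pick the candidate to primerise: an explicit 1-based preselect row, or
    the best identifier-bearing row (fewest changes, GC closest to 50)."""
    by_bases = {c.bases: c for c in pool}
    if candidate is not None:
        if not 1 <= candidate <= len(table):
            raise IndexError(f"candidate row {candidate} outside 1..{len(table)}")
        return by_bases[table.loc[candidate, "bases"]]
    if catalog.enabled():
        tagged = table[(table["sites_gained"] != "") | (table["sites_lost"] != "")]
        if len(tagged):
            return by_bases[tagged.iloc[0]["bases"]]
        warnings.append(
            "no candidate gains or loses a restriction site with the enabled "
            "enzymes; the design will carry no screening identifier"
        )
    else:
        warnings.append("no enzymes enabled; the design will carry no "
                        "screening identifier")
    return by_bases[table.iloc[0]["bases"]]


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def report_table(primers: list[PrimerCandidate],
                 extra_comment: str = "") -> pd.DataFrame:
    """The 15-column report sheet, one row per primer, all cells as strings
    with fixed numeric formats (score and 3'GC% integer, the rest 2 dp)."""
    rows = []
    for p in primers:
        sites = "; ".join(str(s) for s in p.re_sites)
        comment = f"RE sites: {sites}" if sites else ""
        if extra_comment:
            comment = f"{comment}; {extra_comment}" if comment else extra_comment
        rows.append({
            "No.": str(p.index),
            "Orientation": p.orientation.capitalize(),
            "Primer (5'-3')": p.bases,
            "Score [%]": str(p.score.percent_int),
            "nt changes": str(p.metrics.n_changes),
            "Tm [°C]": _fmt(p.metrics.tm_c),
            "nt": str(p.metrics.length_nt),
            "GC%": _fmt(p.metrics.gc_pct),
            "3'ΔG": _fmt(p.metrics.dg3_kcal),
            "5'ΔG": _fmt(p.metrics.dg5_kcal),
            "Runs": str(p.metrics.runs),
            "Rep.": str(p.metrics.repeats),
            "RE sites": str(len(p.re_sites)),
            "3'GC%": str(round(p.metrics.gc3_pct)),
            "Comments": comment,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(table: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write the report as UTF-8 TSV (normative) or xlsx (optional extra)."""
    if table.empty:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if fmt == "tsv":
        path.write_text(
            "\t".join(table.columns) + "\n" +
            "".join("\t".join(row) + "\n" for row in table.itertuples(index=False)),
            encoding="utf-8",
        )
    elif fmt == "xlsx":
        table.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown report format: {fmt!r}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full design and (optionally) write the report file."""
    warnings: list[str] = []
    try:
        cds = _load_sequence(config.sequence)
    except Exception as exc:
        raise type(exc)(f"[sequence] {exc}") from exc
    specs = [m if isinstance(m, MutationSpec) else MutationSpec.parse(m)
             for m in config.mutations]
    try:
        catalog = _load_catalog(config)
    except Exception as exc:
        raise type(exc)(f"[enzymes] {exc}") from exc
    window = build_window(cds, specs, config.flank_codons)
    pool = build_candidate_pool(window, specs, catalog)
    table = preselect(pool)
    selected = select_candidate(table, pool, catalog, config.candidate, warnings)
    if not selected.changed_positions:
        raise ValueError("[select] the chosen candidate is identical to the "
                         "wild type; pick a mutated row")
    primers = design_primer_pairs(cds, selected, window, config.design,
                                  catalog, config.scoring)
    report = report_table(primers)
    for w in warnings:
        logger.warning("%s", w)
    if config.output is not None:
        write_report(report, config.output, config.output_format)
    return PipelineResult(cds, specs, window, catalog, pool, table, selected,
                          primers, report, warnings)
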