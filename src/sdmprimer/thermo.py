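"""Physical primer metrics: GC content, nearest-neighbor Tm, terminal duplex
stabilities, mononucleotide runs and tandem dinucleotide repeats.

Two parameter tables are shipped:

* ``NN_DH_DS`` — unified nearest-neighbor enthalpies/entropies
  (Allawi & SantaLucia 1997, kcal/mol and cal/(mol*K)) used for the
  two-state Tm estimate with the SantaLucia entropy salt correction.
  Defaults: 50 mM monovalent cation, 250 nM primer in excess over template.
* ``NN_DG37`` — the Breslauer 1986 dinucleotide free energies
  (kcal/mol at 37 degC) used for the 5'/3' terminal-pentamer duplex
  stabilities; the classic "unstable 3' end / stable 5' end" bands are
  defined on this scale.

Both tables are module-level dicts and can be swapped by the caller.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .seq_core import InvalidSequenceError

__all__ = ["PrimerMetrics", "gc_percent", "gc3_percent", "melting_temperature",
           "end_stability", "count_runs", "count_repeats", "compute_metrics",
           "NN_DH_DS", "NN_DG37"]

GC3_WINDOW = 4          # 3'-terminal bases in the 3'-GC content
END_PENTAMER = 5        # terminal bases in the end-stability duplex
RUN_THRESHOLD = 4       # minimum mononucleotide run length counted
REPEAT_UNITS = 4        # minimum tandem dinucleotide units counted

R_GAS = 1.987  # cal/(mol*K)

# Unified NN dH (kcal/mol), dS (cal/mol/K); symmetric under reverse complement.
_NN_CORE = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_RC = str.maketrans("ACGT", "TGCA")
NN_DH_DS: dict[str, tuple[float, float]] = {}
for _k, _v in _NN_CORE.items():
    NN_DH_DS[_k] = _v
    NN_DH_DS[_k.translate(_RC)[::-1]] = _v

#: Duplex initiation terms keyed by the terminal base (applied at both ends).
NN_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}

# Breslauer 1986 dG37 (kcal/mol), negative = favorable duplex formation.
_DG_CORE = {
    "AA": -1.9, "AT": -1.5, "TA": -0.9, "CA": -1.9, "GT": -1.3,
    "CT": -1.6, "GA": -1.6, "CG": -3.6, "GC": -3.1, "GG": -3.1,
}
NN_DG37: dict[str, float] = {}
for _k, _v in _DG_CORE.items():
    NN_DG37[_k] = _v
    NN_DG37[_k.translate(_RC)[::-1]] = _v


@dataclass(frozen=True)
class PrimerMetrics:
    """The full metric panel of one oligo."""

    length_nt: int
    gc_pct: float
    gc3_pct: float
    tm_c: float
    dg3_kcal: float
    dg5_kcal: float
    runs: int
    repeats: int
    n_changes: int


def _check(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    if set(seq) - set("ACGT"):
        raise InvalidSequenceError("sequence contains non-ACGT characters")
    return seq


def gc_percent(seq: str) -> float:
    """Overall GC content in percent (2-decimal reporting resolution)."""
    seq = _check(seq)
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


def gc3_percent(seq: str, window: int = GC3_WINDOW) -> float:
    """GC content of the ``window`` 3'-terminal bases, in percent."""
    seq = _check(seq)
    if len(seq) < window:
        raise InvalidSequenceError(
            f"sequence shorter than the {window}-base 3' window"
        )
    tail = seq[-window:]
    return 100.0 * sum(b in "GC" for b in tail) / window


def melting_temperature(
    seq: str,
    na_mM: float = 50.0,
    primer_nM: float = 250.0,
    nn_table: dict[str, tuple[float, float]] = NN_DH_DS,
    init_table: dict[str, tuple[float, float]] = NN_INIT,
) -> float:
    """Two-state nearest-neighbor melting temperature in degrees Celsius.

    dH/dS are summed over stacked dinucleotides plus terminal initiation
    terms; the entropy is salt-corrected by 0.368*(N-1)*ln[monovalent], and
    Tm = 1000*dH / (dS + R*ln(C_primer)) - 273.15 with the primer assumed in
    excess over the template.
    """
    seq = _check(seq)
    if len(seq) < 8:
        raise InvalidSequenceError("Tm model needs at least 8 nt")
    dh = init_table[seq[0]][0] + init_table[seq[-1]][0]
    ds = init_table[seq[0]][1] + init_table[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = nn_table[seq[i:i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k = primer_nM * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(k)) - 273.15


def duplex_dg(seq: str, dg_table: dict[str, float] = NN_DG37) -> float:
    """Duplex-formation free energy of a short sequence (sum of NN steps)."""
    seq = _check(seq)
    return sum(dg_table[seq[i:i + 2]] for i in range(len(seq) - 1))


def end_stability(
    seq: str,
    pentamer: int = END_PENTAMER,
    dg_table: dict[str, float] = NN_DG37,
) -> tuple[float, float]:
    """(dg5, dg3): duplex dG of the 5'- and 3'-terminal ``pentamer`` bases.

    Negative values are favorable; a primer wants a relatively unstable
    3' end (less mispriming) and a stable 5' anchor.
    """
    seq = _check(seq)
    if len(seq) < pentamer:
        raise InvalidSequenceError(f"sequence shorter than {pentamer} nt")
    return duplex_dg(seq[:pentamer], dg_table), duplex_dg(seq[-pentamer:], dg_table)


_RUN_RE = re.compile(r"A{%d,}|C{%d,}|G{%d,}|T{%d,}"
                     % ((RUN_THRESHOLD,) * 4))

_DIMERS = [a + b for a in "ACGT" for b in "ACGT" if a != b]


def count_runs(seq: str, threshold: int = RUN_THRESHOLD) -> int:
    """Number of maximal mononucleotide runs of length >= ``threshold``."""
    seq = _check(seq)
    if threshold == RUN_THRESHOLD:
        return sum(1 for _ in _RUN_RE.finditer(seq))
    pat = re.compile("|".join(f"{b}{{{threshold},}}" for b in "ACGT"))
    return sum(1 for _ in pat.finditer(seq))


def count_repeats(seq: str, min_units: int = REPEAT_UNITS) -> int:
    """Number of maximal tandem dinucleotide repeat tracts with >= ``min_units``
    units; overlapping phase-shifted matches of the same tract count once."""
    seq = _check(seq)
    intervals: list[tuple[int, int]] = []
    for dimer in _DIMERS:
        pat = re.compile(f"(?:{dimer}){{{min_units},}}")
        intervals.extend(m.span() for m in pat.finditer(seq))
    if not intervals:
        return 0
    intervals.sort()
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return len(merged)


def compute_metrics(seq: str, n_changes: int, **tm_kwargs) -> PrimerMetrics:
    """Assemble the full metric panel for one primer sequence."""
    dg5, dg3 = end_stability(seq)
    return PrimerMetrics(
        length_nt=len(seq),
        gc_pct=gc_percent(seq),
        gc3_pct=gc3_percent(seq),
        tm_c=melting_temperature(seq, **tm_kwargs),
        dg3_kcal=dg3,
        dg5_kcal=dg5,
        runs=count_runs(seq),
        repeats=count_repeats(seq),
        n_changes=n_changes,
    )
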