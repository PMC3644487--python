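"""Reference data for the AKT1 worked example.

The silent-NdeI identifier for the Arabidopsis AKT1 pore double mutant
G255A;G257A is the classic demonstration of this design strategy; the
published primer sheet for that experiment (forward series 29-33 nt, reverse
series 32-35 nt, all carrying the NdeI site) is reproduced here verbatim so
metric computations can be checked against known-good oligos.
"""

from __future__ import annotations

__all__ = ["AKT1_REFERENCE_PRIMERS"]

#: ordinal -> (orientation, 5'->3' sequence). Reverse primers are given on
#: the antisense strand, as ordered from a vendor.
AKT1_REFERENCE_PRIMERS: dict[int, tuple[str, str]] = {
    1: ("forward", "ACCACTGTTGCATATGCTGATCTGCATCC"),
    2: ("forward", "ACCACTGTTGCATATGCTGATCTGCATCCT"),
    3: ("forward", "ACCACTGTTGCATATGCTGATCTGCATCCTG"),
    4: ("forward", "ACCACTGTTGCATATGCTGATCTGCATCCTGT"),
    5: ("forward", "ACCACTGTTGCATATGCTGATCTGCATCCTGTG"),
    22: ("reverse", "GCAGATCAGCATATGCAACAGTGGTTAGAGTAG"),
    23: ("reverse", "TGCAGATCAGCATATGCAACAGTGGTTAGAGTAG"),
    24: ("reverse", "ATGCAGATCAGCATATGCAACAGTGGTTAGAGTAG"),
    25: ("reverse", "GCAGATCAGCATATGCAACAGTGGTTAGAGTA"),
    26: ("reverse", "TGCAGATCAGCATATGCAACAGTGGTTAGAGTA"),
}
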