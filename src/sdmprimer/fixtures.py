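"""Reproducible synthetic test inputs.

``generate_fixture`` draws a seeded random in-frame CDS (uniform over the 61
sense codons, so no internal stops) plus random substitution requests whose
wild-type residues are guaranteed to match the translation.

``akt1_pore_fixture`` embeds the Arabidopsis AKT1 pore region around the GYG
selectivity-filter motif (the classic silent-NdeI worked example) at codons
255-257 of a synthetic carrier CDS, so the double G255A;G257A and single
G255T designs can be exercised without any download.
"""

from __future__ import annotations

import random

from .mutagenesis import MutationSpec
from .seq_core import CodingSequence, translate

__all__ = ["generate_fixture", "akt1_pore_fixture", "AKT1_REGION",
           "AKT1_REGION_FIRST_CODON"]

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if translate(a + b + c) != "*"
)

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Sense-strand AKT1 pore region, codons 249-262 (the GYG motif is codons
#: 255-257: GGA TAC GGT). NdeI (CATATG) and SnaBI (TACGTA) are absent from
#: the wild type, as required for a clean screening identifier.
AKT1_REGION = "TCTACTCTAACCACTGTTGGATACGGTGATCTGCATCCTGTG"
AKT1_REGION_FIRST_CODON = 249


def generate_fixture(
    seed: int, n_codons: int, n_mutations: int,
    forbidden: tuple[str, ...] = (),
) -> tuple[CodingSequence, list[MutationSpec]]:
    """Seeded random CDS and substitution specs.

    Mutated positions avoid the outermost 4 codons so a default flank always
    fits. ``forbidden`` motifs are rejection-sampled out of the sequence.
    """
    if n_codons < n_mutations + 8:
        raise ValueError("need n_codons >= n_mutations + 8")
    rng = random.Random(seed)
    for _ in range(1000):
        bases = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))
        if not any(motif in bases for motif in forbidden):
            break
    else:
        raise RuntimeError("could not draw a sequence avoiding the forbidden motifs")
    cds = CodingSequence(bases)
    protein = cds.translation()
    positions = rng.sample(range(5, n_codons - 3), n_mutations)
    specs = []
    for pos in sorted(positions):
        wt = protein[pos - 1]
        target = rng.choice([r for r in _RESIDUES if r != wt])
        specs.append(MutationSpec(pos, wt, target))
    return cds, specs


def akt1_pore_fixture(n_codons: int = 320, seed: int = 20130322) -> CodingSequence:
    """Synthetic carrier CDS with the real AKT1 pore region at codons 249-262.

    Filler codons are drawn deterministically and rejection-sampled so the
    wild-type sequence contains neither CATATG (NdeI) nor TACGTA (SnaBI),
    mirroring the experimental template in which both identifier sites were
    absent before mutagenesis.
    """
    first = AKT1_REGION_FIRST_CODON
    n_region = len(AKT1_REGION) // 3
    if n_codons < first + n_region + 10:
        raise ValueError("carrier too short for the embedded pore region")
    rng = random.Random(seed)
    for _ in range(1000):
        head = "ATG" + "".join(rng.choice(_SENSE_CODONS)
                               for _ in range(first - 2))
        tail = "".join(rng.choice(_SENSE_CODONS)
                       for _ in range(n_codons - first - n_region + 1))
        bases = head + AKT1_REGION + tail
        if "CATATG" not in bases and "TACGTA" not in bases:
            return CodingSequence(bases)
    raise RuntimeError("could not assemble an identifier-free carrier sequence")
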