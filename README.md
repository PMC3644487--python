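# sdmprimer

Design of site-directed mutagenesis (SDM) primer pairs that carry a
**silent restriction-site identifier**.

## The problem

QuikChange-style SDM introduces a point mutation with a pair of mutagenic
primers and removes the wild-type template by DpnI digestion. That digestion
is incomplete in practice, so a sizable fraction of recovered clones are
un-mutated and can only be told apart by sequencing. A classic remedy is to
spend the degeneracy of the genetic code: alongside the coding mutation, the
primers introduce (or remove) a restriction-endonuclease recognition site
through *silent* nucleotide changes. A cheap diagnostic digest then
distinguishes mutant from wild-type clones before anything is sent for
sequencing.

Designing such primers by hand — enumerating codon options, hunting for
realizable recognition sites across codon boundaries, keeping the primer
thermodynamics sane — is tedious and error-prone. `sdmprimer` automates the
whole path from an in-frame CDS plus a substitution request (e.g. `G255A`)
to a scored table of ready-to-order oligos.

## What it computes

1. **Candidate enumeration.** Every nucleotide realization of the requested
   amino-acid substitutions in a local codon window (default: mutated codons
   ± 3 codons of flank). With two serine substitutions, 6 × 6 = 36
   candidates; a forced codon (`G255A=GCA`) collapses that factor.
2. **Silent site engineering.** Each candidate is scanned with a
   restriction-enzyme catalog (regex over IUPAC patterns, overlapping
   matches and both strands). Pre-existing sites can be silently *removed*
   with the provably minimal number of nucleotide changes (exhaustive search
   over the synonymous codons the site spans; GC% closest to 50 breaks
   ties), and new sites are silently *inserted* by a reverse sliding-window:
   each recognition sequence is completed to whole codons at every frame
   offset (an out-of-frame 6-mer has 64 codon completions) and written in
   wherever the codons stay synonymous with the protein.
3. **Primer design.** Partially overlapping forward/reverse primer series:
   a fixed 5′ anchor (10 nt of template-identical sequence upstream of the
   first changed base) and enumerated 3′ extensions (12–16 nt past the last
   change), on both strands.
4. **Scoring.** Each oligo gets a weighted, 1000-point score over seven
   parameters — GC content (×2), nucleotide mismatches (×3), Tm, 3′-GC
   content, 3′-ΔG, 5′-ΔG and runs/repeats (×1 each). Each parameter is worth
   100 raw points at its optimum (Tm 66–74 °C, GC 40–60 %, 3′-GC 50 %,
   3′-ΔG −4.74…−5.62 kcal/mol, 5′-ΔG −13.50…−12.62 kcal/mol, no
   runs/repeats, ≥ 2 mismatches with 1–2 free, 3–4 costing 50, 5–6 costing
   80, ≥ 7 scoring zero). A perfect primer scores 1000 points = 100 %.

Tm is a two-state nearest-neighbor estimate (unified ΔH/ΔS table, 50 mM
monovalent salt, 250 nM primer); end stabilities are terminal-pentamer
duplex ΔG sums. See `docs/methods.md` for every numeric choice.

## Worked example: the AKT1 pore double mutant

The K⁺-channel AKT1 of *Arabidopsis thaliana* carries the GYG selectivity
filter at codons 255–257. Mutating both glycines to alanine
(G255A; G257A) while silently adding an NdeI site (CATATG):

```python
from sdmprimer import RunConfig, run_pipeline
from sdmprimer.fixtures import akt1_pore_fixture

result = run_pipeline(RunConfig(
    sequence=akt1_pore_fixture(),      # carrier CDS with the real pore region
    mutations=["G255A", "G257A"],
    selection=["NdeI"],
))
print(result.selected.bases, result.selected.sites_gained)
print(result.table.head(3).to_string(index=False))
```

prints (abridged):

```
ACCACTGTTGCATATGCTGATCTGCAT (SiteMatch(start=11, enzyme_name='NdeI', strand='+', length=6),)
No. Orientation                  Primer (5'-3') Score [%] nt changes Tm [°C] nt   GC%  3'ΔG  5'ΔG Runs Rep. RE sites 3'GC%           Comments
  1     Forward   ACCACTGTTGCATATGCTGATCTGCATCC        67          3   64.14 29 48.28 -8.10 -7.60    0    0        1    50 RE sites: NdeI @11
  2     Forward  ACCACTGTTGCATATGCTGATCTGCATCCT        67          3   64.82 30 46.67 -7.80 -7.60    0    0        1    50 RE sites: NdeI @11
  3     Forward ACCACTGTTGCATATGCTGATCTGCATCCTG        64          3   65.27 31 48.39 -8.20 -7.60    0    0        1    75 RE sites: NdeI @11
```

Three nucleotide changes produce the double Ala mutant **and** a unique
NdeI site (position 11 of the primer): two changes are the coding mutations
(GGA→G**C**A, GGT→G**C**T) and one is silent (TAC→TA**T**, still Tyr),
completing CATATG across the mutated codons. Digesting miniprep DNA with
NdeI immediately identifies mutated clones. The same run from the shell:

```bash
sdm-design --seq akt1.fasta --mut G255A --mut G257A --select NdeI -o report.tsv
```

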