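# Methods

This note records the models, parameter choices and numerical conventions
behind `sdmprimer`, and what the synthetic fixtures do and do not exercise.

## Scope and assumptions

The input is a single in-frame DNA coding sequence (plain text or
single-record FASTA, up to ~40 kb); position 1 is codon position 1, and a
trailing partial codon is tolerated but never addressed by codon
operations. Translation uses the standard genetic code only. Substitution
mutations only — insertions and deletions are out of scope, as are
alternative genetic codes, RNA input and multi-record FASTA.

## Candidate enumeration

A mutation request names a codon position, the expected wild-type residue
(validated against the translation) and a target residue, optionally with a
forced codon. The mutated window spans all mutated codons plus a symmetric
flank of 3 codons per side (configurable), clipped at the sequence ends —
for two mutations two codons apart this gives the familiar 9-residue
stretch. All codon realizations of the targets are enumerated in
lexicographic codon order (deterministic output), with a combinatorial cap
of 10,000 candidates; beyond it the user is advised to force codons.

## Restriction-site search

Recognition sequences are IUPAC patterns (4–8 nt in the shipped catalog),
compiled to character-class regexes and searched inside a lookahead so
overlapping occurrences are all reported. Coordinates are 1-based positions
of the site's first base. Palindromic patterns (equal to their IUPAC
reverse complement) are reported once on the '+' strand; non-palindromic
patterns are additionally searched as their reverse complement and flagged
strand '−'. Non-palindromic sites are fully supported but unusual for this
application, which historically used palindromic Type II sites.

The shipped default catalog is a REBASE-derived subset of common commercial
Type II enzymes (recognition strings only; cut geometry is irrelevant to
screening by presence/absence of a site). A user file of `NAME SITE` lines
(tab or space delimited, `#` comments allowed) overrides it.

## Silent removal

To destroy unwanted occurrences, only the codons a matched site spans are
re-assigned (flanking codons are never touched). All synonymous
assignments of those codons are enumerated exhaustively — the span of a
≤ 8 nt site is at most 4 codons, ≤ 6⁴ assignments — and an assignment is
accepted only if no occurrence of the targeted enzymes remains anywhere in
the window *and* the occurrence sets of all other enabled enzymes are
untouched (the identifier must stay unique and side-effect free).
Overlapping occurrences are therefore eliminated jointly, with the least
number of changes that removes them all. Among accepted assignments the
ordering is: fewest nucleotide changes, then window GC% closest to 50%
(the midpoint of the scoring optimum; the direction of the GC tie-break is
configurable), then lexicographic. If no assignment qualifies (e.g. a site
forced by Met/Trp codons) an explicit `UnremovableSiteError` is raised.

## Silent insertion (reverse sliding window)

For every enabled enzyme, strand and placement of the recognition sequence
over the window, the pattern is expanded to concrete realizations and each
realization is completed to whole codons: a 6-mer placed out of frame
splits across three codons and needs 1 + 2 flanking pad bases, giving
4³ = 64 codon completions. For each spanned codon, the synonymous codons of
the window's own residue that are consistent with the realization's fixed
bases are enumerated; every combination yields a candidate base string with
the site written in and the protein unchanged by construction. Each
distinct output is re-verified: the resulting occurrence set must equal the
input's plus exactly the new site (a site already realized in place is
reported as a zero-change insertion). Degenerate patterns with more than
256 realizations are excluded from insertion (still searched) to bound the
scan.

Exhaustive brute-force oracles in the test suite confirm, on 200 seeded
random windows of 4–6 codons, that removal attains the true minimum
Hamming distance and that insertion is exactly as complete as enumeration
over the full synonymous space allows.

## Candidate pre-selection

The pre-evaluation table lists every enumerated candidate plus every
insertion/removal variant (distinct base strings, re-annotated against the
wild-type window), sorted by (nucleotide changes, |GC − 50|, base string).
Non-interactively the tool picks the best *identifier-bearing* row — a
candidate that gains or loses at least one enabled site; a plain
minimal-change mutation never carries an identifier and would otherwise
always win, defeating the point of the method. If no identifier is
achievable the best plain candidate is used and a warning issued. An
explicit `--candidate N` overrides the automatic choice.

## Primer geometry

Primer pairs partially overlap rather than mirror each other completely,
which favors primer–template annealing over primer self-annealing. Forward
primers share a fixed 5′ start `five_anchor` = 10 template-identical nt
upstream of the first changed base and enumerate 3′ ends `three_min..three_max`
= 12–16 template-identical nt past the last change; reverse primers apply
the same geometry on the antisense strand and are reported 5′→3′ in their
own coordinates, with restriction-site positions indexed within the primer
itself. Length bounds default to 25–45 nt. For a 7-nt-wide change set these
defaults give the canonical 29–33 nt series. The published reverse series
for the AKT1 example ran 32–35 nt with staggered 5′ starts; how those
lengths were varied is not derivable, so a single shared parameter set is
used for both orientations.

## Thermodynamics

* **Tm** — two-state nearest-neighbor model with the unified ΔH/ΔS
  parameter set (Allawi & SantaLucia 1997), terminal initiation terms, the
  entropic salt correction 0.368·(N−1)·ln[monovalent], and
  Tm = 1000·ΔH / (ΔS + R·ln C) − 273.15 with the primer (250 nM default)
  in excess. Defaults: 50 mM monovalent cation. The implementation is an
  explicit summation; the test suite checks it to 2 decimals against an
  independently coded route (Biopython's `Tm_NN` on the same table and
  conditions). Published Tm values for the AKT1 primers (≈ 70–77 °C) are
  ~8 °C above this model's output; the model and buffer behind those values
  are not recoverable, so that comparison is a logged soft check, not an
  assertion, and the defaults were chosen on physical grounds only.
* **End stability** — ΔG of duplex formation of the 5 terminal bases at
  each end, summed over the Breslauer 1986 dinucleotide free energies
  (negative = favorable, no initiation term). This table makes the classic
  optimum bands meaningful: the least stable pentamers (TA/AT repeats) sum
  to ≈ −4.8 kcal/mol and the most stable (CG/GC) to ≈ −13.4 kcal/mol.
  No strand-symmetric dinucleotide table reproduces the published example
  ΔG cells exactly (the linear system they induce is inconsistent), so
  exact reproduction of those cells is explicitly not claimed. Both tables
  are plain module-level dicts and can be swapped.
* **Runs / repeats** — counts of maximal mononucleotide runs of ≥ 4 and of
  maximal tandem dinucleotide tracts of ≥ 4 units (phase-shifted overlaps
  merged); thresholds configurable. The 3′-GC content uses the 4 terminal
  bases (the only window width consistent with the published example
  values, which step in quarters).

## Scoring

Seven parameters, weights GC ×2, mismatches ×3, the rest ×1 (Σ = 10; raw
scores 0–100, so the maximum is 1000 points = 100%). Optimal ranges are
closed intervals: Tm 66–74 °C, GC 40–60 %, 3′-GC = 50 %, 3′-ΔG −5.62…−4.74,
5′-ΔG −13.50…−12.62 kcal/mol, zero runs+repeats. Mismatch tiers: 1–2
changes free, 3–4 cost 50 raw points, 5–6 cost 80, ≥ 7 score zero. Seven
itself is unstated territory between the published tiers; it is scored 0
(reading "more than seven" as the terminal tier's loose phrasing); zero
changes scores 100 with a warning since a mutagenic primer should carry at
least two. Outside an optimal range, points fall off by documented step
schedules of the distance (e.g. Tm: 80/60/40/20 raw points at ≤ 1/2/4/8 °C
beyond the range). The true deduction schedules behind published score
columns are not recoverable from their totals; the defaults here are the
package's own, validated for monotonicity, and fully user-configurable via
a JSON config (`ScoringConfig.save/load`). Report percentages are rounded
to integers. Runs and repeat tracts are pooled into the seventh parameter
so the weights sum to 10.

## Output

The report is a 15-column sheet (ordinal, orientation, 5′→3′ sequence,
integer score %, nt changes, Tm, length, GC%, 3′ΔG, 5′ΔG, runs, repeats,
site count, 3′GC%, comments) written as UTF-8 TSV with fixed numeric
formats (2 decimals for Tm/GC/ΔG, integers for score and 3′GC%), so
identical inputs give byte-identical files; xlsx export is an optional
extra and carries the same cells.

## Synthetic fixtures

`generate_fixture` draws uniform random sense codons (no internal stops)
with seeded, reproducible substitution requests; `akt1_pore_fixture` embeds
the real 42-nt AKT1 pore region (codons 249–262, GYG filter at 255–257) in
a deterministic 320-codon carrier rejection-sampled to contain neither
CATATG nor TACGTA, mirroring the wild-type template of the original
experiment. These fixtures exercise coordinate handling, codon
combinatorics and site engineering exactly, but a uniform codon draw has no
codon-usage bias, no repeats/low-complexity structure and no GC skew, so
passing tests say nothing about expression-level effects of silent changes
in a real host — the tool likewise only warns that silent mutations can
affect expression. Oracle tests use windows of ≤ 6 codons because the
brute-force synonymous space (≤ 6⁶) must stay enumerable; the
implementation itself has no such limit.

## Known limitations

* No hairpin/self-dimer folding energy; secondary structure is
  operationalized as runs, repeats and end-ΔG only.
* Site uniqueness is enforced within the mutated window; a whole-sequence
  occurrence count is available but the tool does not verify uniqueness
  across an entire plasmid.
* Printed Tm/ΔG/score columns of the historical worked example are
  reproduced only up to the model choices documented above; GC%, 3′-GC%,
  lengths and site positions are reproduced exactly.
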