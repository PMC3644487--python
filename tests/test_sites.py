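"""Restriction-site search and silent engineering, checked against
brute-force enumeration over the synonymous codon space."""

import itertools
import random
import re

import pytest

from sdmprimer import (
    EnzymeCatalog,
    RestrictionEnzyme,
    UnremovableSiteError,
    find_sites,
    insert_sites_silently,
    preselect,
    remove_sites_silently,
    reverse_complement,
    synonymous_codons,
    translate,
)
from sdmprimer.examples import AKT1_REFERENCE_PRIMERS
from sdmprimer.mutagenesis import MutationWindow, make_candidate
from sdmprimer.seq_core import iupac_to_regex, reverse_complement_iupac
from sdmprimer.sites import SiteMatch, _codon_realizations, annotate_sites

NDEI = EnzymeCatalog([RestrictionEnzyme("NdeI", "CATATG")])


def window_from(bases: str) -> MutationWindow:
    return MutationWindow(1, len(bases) // 3, bases, translate(bases))


# ---------------------------------------------------------------- find_sites

def test_find_sites_uses_the_published_coordinate_convention():
    fwd = AKT1_REFERENCE_PRIMERS[1][1]
    rev = AKT1_REFERENCE_PRIMERS[22][1]
    assert find_sites(fwd, NDEI) == [SiteMatch(11, "NdeI", "+", 6)]
    assert find_sites(rev, NDEI) == [SiteMatch(10, "NdeI", "+", 6)]
    assert find_sites("AAAA", NDEI) == []


def test_find_sites_reports_overlapping_matches():
    cat = EnzymeCatalog([RestrictionEnzyme("TaqI", "TCGA")])
    assert [m.start for m in find_sites("TCGATCGA", cat)] == [1, 5]
    # overlapping palindrome occurrences
    assert [m.start for m in find_sites("CATATATG", NDEI)] == []
    assert [m.start for m in find_sites("GCGCGC", EnzymeCatalog(
        [RestrictionEnzyme("X", "GCGC")]))] == [1, 3]


def test_find_sites_searches_both_strands_for_non_palindromes():
    bsa = EnzymeCatalog([RestrictionEnzyme("BsaI", "GGTCTC")])
    assert find_sites("AAGGTCTCAA", bsa) == [SiteMatch(3, "BsaI", "+", 6)]
    assert find_sites("AA" + reverse_complement("GGTCTC") + "AA", bsa) == \
        [SiteMatch(3, "BsaI", "-", 6)]


def test_find_sites_agrees_with_biopython_restriction():
    from Bio.Restriction import NdeI as BioNdeI
    from Bio.Seq import Seq

    rng = random.Random(7)
    for _ in range(20):
        seq = "".join(rng.choice("ACGT") for _ in range(80))
        ours = [m.start for m in find_sites(seq, NDEI)]
        # Bio.Restriction reports 1-based cut positions; NdeI cuts CA^TATG,
        # so the recognition start is cut - 2 on the sense strand.
        theirs = [c - 2 for c in BioNdeI.search(Seq(seq))]
        assert ours == theirs


# ---------------------------------------------------------------- removal

def brute_force_min_removal(window, candidate, matches, catalog):
    """Independent oracle: exhaustively re-assign the spanned codons and
    return the minimal Hamming distance destroying every target-enzyme
    occurrence in the window (None if impossible)."""
    bases = candidate.bases
    names = {m.enzyme_name for m in matches}
    patterns = []
    for e in catalog.enabled():
        if e.name in names:
            patterns.append(re.compile(f"(?=({iupac_to_regex(e.recognition)}))"))
            if e.recognition != reverse_complement_iupac(e.recognition):
                patterns.append(re.compile(
                    f"(?=({iupac_to_regex(reverse_complement_iupac(e.recognition))}))"))
    codon_idx = sorted({i for m in matches
                        for i in range((m.start - 1) // 3, (m.end - 1) // 3 + 1)
                        if i < len(bases) // 3})
    options = [sorted(synonymous_codons(candidate.residues[i])) for i in codon_idx]
    best = None
    for combo in itertools.product(*options):
        codons = [bases[3 * i: 3 * i + 3] for i in range(len(bases) // 3)]
        for i, c in zip(codon_idx, combo):
            codons[i] = c
        new = "".join(codons)
        if any(p.search(new) for p in patterns):
            continue
        d = sum(a != b for a, b in zip(bases, new))
        if best is None or d < best:
            best = d
    return best


def test_removal_minimal_example_ecori():
    ecori = EnzymeCatalog([RestrictionEnzyme("EcoRI", "GAATTC")])
    w = window_from("GAATTC")  # Glu-Phe
    cand = make_candidate(w, w.wt_bases)
    out = remove_sites_silently(w, cand, find_sites(w.wt_bases, ecori), ecori)
    assert out.bases == "GAGTTC"  # 1 change; GC tie-break picks 50% GC
    assert out.n_changes == 1
    assert translate(out.bases) == "EF"
    assert find_sites(out.bases, ecori) == []


def test_removal_returns_candidate_unchanged_without_matches():
    w = window_from("GAATTC")
    cand = make_candidate(w, w.wt_bases)
    assert remove_sites_silently(w, cand, [], NDEI) is cand


def test_unremovable_site_is_explicit():
    site = EnzymeCatalog([RestrictionEnzyme("Hypo", "ATGTGG")])
    w = window_from("ATGTGG")  # Met-Trp: both codons non-degenerate
    cand = make_candidate(w, w.wt_bases)
    with pytest.raises(UnremovableSiteError):
        remove_sites_silently(w, cand, find_sites(w.wt_bases, site), site)


def test_overlapping_sites_removed_jointly():
    taq = EnzymeCatalog([RestrictionEnzyme("TaqI", "TCGA")])
    w = window_from("TCGATCGA")  # S-I-R + trailing? -> 8nt not codon multiple
    w = window_from("TCGATCGAT")  # Ser-Ile-Asp
    cand = make_candidate(w, w.wt_bases)
    matches = find_sites(w.wt_bases, taq)
    assert len(matches) == 2
    out = remove_sites_silently(w, cand, matches, taq)
    assert find_sites(out.bases, taq) == []
    oracle = brute_force_min_removal(w, cand, matches, taq)
    assert out.n_changes == oracle


# ---------------------------------------------------------------- insertion

def test_ndei_insertion_into_the_double_ala_pore_window():
    # T T V A Y A D L H with Ala codons GCA/GCT: choosing GCA TAT realizes
    # CATATG across the two mutated codons
    w = window_from("ACCACTGTTGGATACGGTGATCTGCAT")
    mutant = "ACCACTGTTGCATATGCTGATCTGCAT"
    cand = make_candidate(w, "ACCACTGTTGCATACGCTGATCTGCAT")  # A Y A, no site yet
    results = insert_sites_silently(w, cand, NDEI)
    assert any(c.bases == mutant and m == SiteMatch(11, "NdeI", "+", 6)
               for c, m in results)
    for c, m in results:
        assert translate(c.bases) == translate(cand.bases)
        assert m in find_sites(c.bases, NDEI)


def test_insertion_with_site_already_realized_is_zero_change():
    w = window_from("GCTCATATGGCT")  # Ala-His-Met-Ala encodes CATATG
    cand = make_candidate(w, w.wt_bases)
    results = insert_sites_silently(w, cand, NDEI)
    assert [(c.bases, m.start) for c, m in results] == [(w.wt_bases, 4)]


def test_codon_realization_counts():
    # a non-degenerate 6-mer split NN/NNN/N needs 1 + 2 pad bases: 4^3 = 64
    assert _codon_realizations("CATATG", 1) == 64
    assert _codon_realizations("CATATG", 2) == 64
    assert _codon_realizations("CATATG", 0) == 1   # in frame: no pad bases
    assert _codon_realizations("GANTC", 1) == 4 * 4 ** (1 + 0)


def brute_force_insertions(window, candidate, catalog):
    """Independent oracle: for every placement, enumerate every synonymous
    re-assignment of the codons the site would span and record each distinct
    base string that carries the new site and leaves all other enabled-site
    occurrences untouched."""
    bases = candidate.bases
    n_codons = len(bases) // 3
    before = set(find_sites(bases, catalog))
    found = set()
    for enzyme in catalog.enabled():
        pats = [(enzyme.recognition, "+")]
        if enzyme.recognition != reverse_complement_iupac(enzyme.recognition):
            pats.append((reverse_complement_iupac(enzyme.recognition), "-"))
        for pattern, strand in pats:
            L = len(pattern)
            rx = re.compile(iupac_to_regex(pattern))
            for p in range(len(bases) - L + 1):
                c0, c1 = p // 3, (p + L - 1) // 3
                idx = list(range(c0, min(c1 + 1, n_codons)))
                if (p + L - 1) // 3 >= n_codons:
                    continue
                options = [sorted(synonymous_codons(candidate.residues[i]))
                           for i in idx]
                for combo in itertools.product(*options):
                    codons = [bases[3 * i: 3 * i + 3] for i in range(n_codons)]
                    for i, c in zip(idx, combo):
                        codons[i] = c
                    new = "".join(codons)
                    if not rx.match(new, p):
                        continue
                    match = SiteMatch(p + 1, enzyme.name, strand, L)
                    if set(find_sites(new, catalog)) != before | {match}:
                        continue
                    found.add((new, match))
    return found


ORACLE_ENZYMES = [
    RestrictionEnzyme("NdeI", "CATATG"),
    RestrictionEnzyme("EcoRI", "GAATTC"),
    RestrictionEnzyme("TaqI", "TCGA"),
    RestrictionEnzyme("HinfI", "GANTC"),
    RestrictionEnzyme("BsaI", "GGTCTC"),
    RestrictionEnzyme("HincII", "GTYRAC"),
]


@pytest.mark.parametrize("block", range(10))
def test_silent_engineering_oracles_on_random_windows(block):
    """On 200 seeded 4-6 codon windows, exhaustive search over synonymous
    codon assignments confirms (a) minimal-change site removal and (b)
    complete, sound silent insertion; translation is always preserved."""
    sense = [c for c in map("".join, itertools.product("ACGT", repeat=3))
             if translate(c) != "*"]
    for sub in range(20):
        rng = random.Random(1000 * block + sub)
        n = rng.randint(4, 6)
        enzyme = rng.choice(ORACLE_ENZYMES)
        catalog = EnzymeCatalog([enzyme])
        bases = "".join(rng.choice(sense) for _ in range(n))
        # plant a site realization at a random offset half the time so the
        # removal path is exercised, not just the empty case
        if rng.random() < 0.5:
            real = rng.choice(sorted(enzyme.realizations()))
            p = rng.randrange(0, 3 * n - len(real) + 1)
            planted = bases[:p] + real + bases[p + len(real):]
            if "*" not in translate(planted):
                bases = planted
        w = window_from(bases)
        cand = make_candidate(w, bases)

        matches = find_sites(bases, catalog)
        if matches:
            oracle_min = brute_force_min_removal(w, cand, matches, catalog)
            if oracle_min is None:
                with pytest.raises(UnremovableSiteError):
                    remove_sites_silently(w, cand, matches, catalog)
            else:
                out = remove_sites_silently(w, cand, matches, catalog)
                assert translate(out.bases) == w.wt_residues
                assert find_sites(out.bases, catalog) == []
                n_changes = sum(a != b for a, b in zip(bases, out.bases))
                assert n_changes == oracle_min

        impl = {(c.bases, m) for c, m in insert_sites_silently(w, cand, catalog)}
        oracle = brute_force_insertions(w, cand, catalog)
        assert impl == oracle
        for new_bases, m in impl:
            assert translate(new_bases) == w.wt_residues


# ---------------------------------------------------------------- preselect

def test_preselect_sort_order_matches_comparator_oracle():
    rng = random.Random(3)
    sense = [c for c in map("".join, itertools.product("ACGT", repeat=3))
             if translate(c) != "*"]
    w = window_from("".join(rng.choice(sense) for _ in range(4)))
    cands = []
    for _ in range(25):
        combo = "".join(rng.choice(sorted(synonymous_codons(r)))
                        for r in w.wt_residues)
        cands.append(make_candidate(w, combo))
    table = preselect(cands)
    keys = [(c.n_changes, abs(round(c.gc_pct, 2) - 50.0), c.bases)
            for c in cands]
    expected = [k[2] for k in sorted(set(keys))]
    # preselect keeps duplicates; compare the full sorted base column
    expected_full = [b for _, _, b in sorted(keys)]
    assert list(table["bases"]) == expected_full


def test_preselect_rejects_empty_input():
    with pytest.raises(ValueError):
        preselect([])


def test_annotate_sites_gain_and_loss():
    w = window_from("GAATTCGCT")  # EcoRI present in wild type
    cat = EnzymeCatalog([RestrictionEnzyme("EcoRI", "GAATTC")])
    gained = annotate_sites(w, make_candidate(w, "GAATTCGCT"), cat)
    assert gained.sites_gained == () and gained.sites_lost == ()
    lost = annotate_sites(w, make_candidate(w, "GAGTTCGCT"), cat)
    assert [str(s) for s in lost.sites_lost] == ["EcoRI @1"]
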