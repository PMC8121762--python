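"""Peptide-to-precursor mapping, homolog alignment and interval projection."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from gutpeptidomics import io as gio
from gutpeptidomics.atlas import (
    HomologAlignment,
    PeptideObservation,
    Precursor,
    PrecursorAtlas,
    align_homologs,
    build_alignment_plot,
    interval_identity,
    is_ambiguous,
    map_peptide,
    peptide_name,
    project_interval,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# map_peptide


def test_full_precursor_maps_to_itself():
    p = Precursor("X1", "G1", "mouse", "MAWTESTSEQ")
    hits = map_peptide("MAWTESTSEQ", [p])
    assert hits == [(p, 1, len(p.sequence))]
    assert not is_ambiguous(hits)


def test_gastrin_style_naming():
    # a 21-residue peptide at prepro positions 59-79 is called "Gast p59-79"
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACDEFHILMNPSTVWY"), size=100))
    p = Precursor("G1", "Gast", "mouse", seq)
    pep = seq[58:79]
    hits = map_peptide(pep, [p])
    prec, start, end = hits[0]
    assert (start, end) == (59, 79)
    assert peptide_name(prec.gene, start, end) == "Gast p59-79"


def test_map_matches_brute_force_scan():
    rng = np.random.default_rng(7)
    letters = list("ACDG")
    db = [
        Precursor(f"P{i}", f"g{i}", "mouse", "".join(rng.choice(letters, size=60)))
        for i in range(5)
    ]
    for _ in range(200):
        src = db[rng.integers(len(db))]
        s = int(rng.integers(0, len(src.sequence) - 5))
        ln = int(rng.integers(4, 10))
        pep = src.sequence[s : s + ln]
        expected = []
        for prec in sorted(db, key=lambda p: p.accession):
            for i in range(len(prec.sequence) - len(pep) + 1):
                if prec.sequence[i : i + len(pep)] == pep:
                    expected.append((prec.accession, i + 1, i + len(pep)))
        got = [(p.accession, a, b) for p, a, b in map_peptide(pep, db)]
        assert got == expected
        for p, a, b in map_peptide(pep, db):
            assert p.sequence[a - 1 : b] == pep  # completeness invariant


def test_map_rejects_invalid_letters_and_empty_db():
    p = Precursor("X1", "G1", "mouse", "MAWTESTSEQ")
    with pytest.raises(ValueError):
        map_peptide("AXB", [p])
    with pytest.raises(ValueError):
        map_peptide("MAW", [])


# ---------------------------------------------------------------------------
# align_homologs


def _pair(a, b):
    return (
        Precursor("M1", "G", "mouse", a),
        Precursor("H1", "G", "human", b),
    )


def test_identical_sequences_align_gap_free():
    al = align_homologs(*_pair("MKWVTFISLL", "MKWVTFISLL"))
    assert "-" not in al.aligned_a + al.aligned_b
    assert al.match_line == "|" * 10
    assert al.identity == 1.0


def test_single_substitution_single_mismatch_column():
    al = align_homologs(*_pair("AAA", "AAT"))
    assert al.match_line.count("|") == 2
    assert len(al.match_line) == 3


def test_match_line_convention():
    # K vs R scores +2 in BLOSUM62: chemically similar, marked ':'
    al = align_homologs(*_pair("AKA", "ARA"))
    assert al.match_line == "|:|"


def _brute_force_score(a, b, open_=-10.0, ext=-1.0):
    """Exhaustive affine-gap global alignment score by path enumeration."""

    def go(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, BLOSUM62[a[i], b[j]] + go(i + 1, j + 1, "M"))
        if i < len(a):
            cost = ext if prev == "A" else open_
            best = max(best, cost + go(i + 1, j, "A"))
        if j < len(b):
            cost = ext if prev == "B" else open_
            best = max(best, cost + go(i, j + 1, "B"))
        return best

    return go(0, 0, None)


def test_alignment_score_matches_exhaustive_enumeration():
    rng = np.random.default_rng(11)
    letters = list("ACDE")
    for _ in range(40):
        a = "".join(rng.choice(letters, size=rng.integers(1, 7)))
        b = "".join(rng.choice(letters, size=rng.integers(1, 7)))
        al = align_homologs(*_pair(a, b))
        assert al.score == pytest.approx(_brute_force_score(a, b))
        # symmetry under a symmetric substitution matrix
        assert al.score == pytest.approx(align_homologs(*_pair(b, a)).score)


def test_alignment_recovers_inputs_without_gaps():
    al = align_homologs(*_pair("ACDEFGHIK", "ACDFGHIK"))
    assert al.aligned_a.replace("-", "") == "ACDEFGHIK"
    assert al.aligned_b.replace("-", "") == "ACDFGHIK"


def test_align_rejects_empty():
    with pytest.raises(ValueError):
        m = Precursor("M1", "G", "mouse", "A")
        m.sequence = ""  # bypass constructor check to hit the aligner guard
        align_homologs(m, Precursor("H1", "G", "human", "A"))


# ---------------------------------------------------------------------------
# project_interval


def _manual_alignment(aligned_a, aligned_b):
    """Build a HomologAlignment directly from gapped strings (test helper)."""
    match, a2b, b2a = [], [], []
    pa = pb = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            pa += 1
        if cb != "-":
            pb += 1
        match.append("|" if (ca == cb and ca != "-") else " ")
        if ca != "-":
            a2b.append(pb if cb != "-" else None)
        if cb != "-":
            b2a.append(pa if ca != "-" else None)
    return HomologAlignment(aligned_a, aligned_b, "".join(match), a2b, b2a, 0.0)


def test_identity_projection():
    al = _manual_alignment("ACDEF", "ACDEF")
    assert project_interval(al, 2, 4) == ((2, 4), 1.0)


def test_fully_gapped_interval_projects_to_nothing():
    al = _manual_alignment("AC-DEF", "--G---")
    # positions 3..5 of A (D,E,F) all lie opposite gaps
    interval, cov = project_interval(al, 3, 5)
    assert interval is None and cov == 0.0


def test_projection_matches_position_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        # random gapped pair over a 10-column alignment
        cols = []
        for _c in range(12):
            kind = rng.integers(3)
            if kind == 0:
                cols.append(("A", "-"))
            elif kind == 1:
                cols.append(("-", "C"))
            else:
                cols.append(("A", "C"))
        aligned_a = "".join(x for x, _ in cols)
        aligned_b = "".join(y for _, y in cols)
        if "A" not in aligned_a or "C" not in aligned_b:
            continue
        al = _manual_alignment(aligned_a, aligned_b)
        la = len(aligned_a.replace("-", ""))
        s = int(rng.integers(1, la + 1))
        e = int(rng.integers(s, la + 1))
        images = [al.map_a_to_b[i - 1] for i in range(s, e + 1)]
        mapped = [x for x in images if x is not None]
        interval, cov = project_interval(al, s, e)
        if mapped:
            assert interval == (min(mapped), max(mapped))
            assert cov == pytest.approx(len(mapped) / (e - s + 1))
            # round trip: every non-gap position maps back inside
            back, _ = project_interval(
                _manual_alignment(aligned_b, aligned_a), *interval
            )
            assert back[0] <= s + (e - s) and back[1] >= s - (e - s)
        else:
            assert interval is None and cov == 0.0


def test_project_out_of_range():
    al = _manual_alignment("ACD", "ACD")
    with pytest.raises(ValueError):
        project_interval(al, 0, 2)
    with pytest.raises(ValueError):
        project_interval(al, 2, 9)


def test_interval_identity_counts_identical_columns():
    al = _manual_alignment("ACDEF", "ACXEF".replace("X", "W"))
    assert interval_identity(al, 1, 5) == pytest.approx(4 / 5)
    assert interval_identity(al, 3, 3) == 0.0


# ---------------------------------------------------------------------------
# alignment plots


def _plot_atlas():
    seq = "MKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHRFKDLGE"
    return PrecursorAtlas(
        [
            Precursor("M1", "G", "mouse", seq, signal_end=18),
            Precursor("H1", "G", "human", seq, signal_end=18),
        ]
    )


def test_plot_without_observations_has_alignment_only():
    doc = build_alignment_plot(_plot_atlas(), "G", [], min_area=1e4)
    assert doc.peptides == []
    assert doc.alignment.identity == 1.0


def test_plot_threshold_retains_only_abundant_peptides(tmp_path):
    atlas = _plot_atlas()
    obs = [
        PeptideObservation("M1", 19, 25, "s1", "stomach", 1e3),
        PeptideObservation("M1", 26, 33, "s1", "stomach", 1e5,
                           mods=[("amidation", 8)]),
    ]
    doc = build_alignment_plot(atlas, "G", obs, min_area=1e4)
    assert len(doc.peptides) == 1
    kept = doc.peptides[0]
    assert (kept.start, kept.end) == (26, 33)
    assert kept.amidated  # amidation marker at the C-terminal coordinate
    doc.to_tsv(tmp_path / "plot.tsv")
    doc.to_svg(tmp_path / "plot.svg")
    svg = (tmp_path / "plot.svg").read_text()
    assert 'stroke="red"' in svg  # the amidation box is drawn


def test_plot_unknown_gene_errors():
    with pytest.raises(KeyError):
        build_alignment_plot(_plot_atlas(), "Nope", [], 1e4)


# ---------------------------------------------------------------------------
# FASTA round trip


def test_precursor_fasta_round_trip(tmp_path):
    precs = [
        Precursor("M1", "Gast", "mouse", "MKWVTFISLLFLFSSAYS", signal_end=10),
        Precursor("H1", "Gast", "human", "MKWVTFISLL"),
    ]
    path = tmp_path / "prec.fasta"
    gio.write_precursors(precs, path)
    back = gio.read_precursors(path)
    assert [(p.accession, p.gene, p.species, p.sequence, p.signal_end) for p in back] == [
        (p.accession, p.gene, p.species, p.sequence, p.signal_end) for p in precs
    ]
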