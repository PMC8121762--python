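"""Mapping peptides onto prepropeptides and cross-species alignment.

All coordinates are 1-based inclusive on the PREPRO sequence (signal
peptide included), following the field's "Gast p59-79" / "Prepro-PYY
Serine-41" numbering.  Homologous mouse/human precursors are globally
aligned (Needleman–Wunsch, BLOSUM62, gap open 10 / extend 1) and peptide
intervals can be projected across the alignment to ask whether a mouse
peptide has a conserved, observed human counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .chemistry import validate_sequence

VALID_SPECIES = ("mouse", "human")


@dataclass
class Precursor:
    """A prepropeptide: full translated precursor, signal peptide included."""

    accession: str
    gene: str
    species: str
    sequence: str
    signal_end: int | None = None  # 1-based position of last signal residue

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty precursor sequence")
        if self.species not in VALID_SPECIES:
            raise ValueError(f"{self.accession}: species must be one of {VALID_SPECIES}")
        if self.signal_end is not None and not 0 <= self.signal_end < len(self.sequence):
            raise ValueError(f"{self.accession}: signal_end {self.signal_end} out of range")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideObservation:
    """One identified peptide, located on its precursor.

    ``mods`` is a list of ``(mod_name, position)`` with positions 1-based
    on the peptide itself.  ``peak_area`` is the XIC peak area in
    arbitrary intensity units.
    """

    precursor_accession: str
    start: int
    end: int
    sample_id: str
    region: str
    peak_area: float
    mods: list[tuple[str, int]] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval ({self.start}, {self.end})")
        if self.length > 65:
            raise ValueError(f"peptide span {self.length} exceeds the 65-residue search limit")
        if self.peak_area <= 0:
            raise ValueError("peak_area must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def amidated(self) -> bool:
        return any(name == "amidation" for name, _ in self.mods)

    @property
    def pyroglu(self) -> bool:
        return any(name.startswith("pyroglu") for name, _ in self.mods)

    def has_mod(self, name: str) -> bool:
        return any(n == name for n, _ in self.mods)


def peptide_name(gene: str, start: int, end: int, amidated: bool = False) -> str:
    """Field-convention peptide name, e.g. ``Gast p59-79`` / ``ChgA p435-462a``.

    The trailing ``a`` marks C-terminal amidation.
    """
    return f"{gene} p{start}-{end}" + ("a" if amidated else "")


def observation_id(obs: PeptideObservation, gene: str) -> str:
    """Stable peptide identifier for an observation (gene + coordinates)."""
    return peptide_name(gene, obs.start, obs.end, obs.amidated)


@dataclass
class HomologAlignment:
    """A global mouse/human precursor alignment with its match line.

    ``match_line`` uses ``'|'`` for identical residues, ``':'`` for
    chemically similar residues (positive BLOSUM62 score, not identical)
    and ``' '`` otherwise.  ``map_a_to_b[i]`` gives the 1-based position
    on B aligned to position ``i+1`` of A, or ``None`` opposite a gap.
    """

    aligned_a: str
    aligned_b: str
    match_line: str
    map_a_to_b: list[int | None]
    map_b_to_a: list[int | None]
    score: float

    @property
    def identity(self) -> float:
        """Fraction of alignment columns that are identical residues."""
        return self.match_line.count("|") / len(self.match_line)


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(open_gap: float = -10.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _similar(a: str, b: str) -> bool:
    return a != b and _BLOSUM62[a, b] > 0


def align_homologs(a: Precursor, b: Precursor) -> HomologAlignment:
    """Optimal global alignment of two homologous precursors.

    Intended for a mouse/human pair of the same gene; raises when either
    sequence is empty.  Ties between equally optimal alignments are
    broken deterministically (first traceback).
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner()
    alignment = aligner.align(a.sequence, b.sequence)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    match = []
    map_a_to_b: list[int | None] = []
    map_b_to_a: list[int | None] = []
    pos_a = pos_b = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            pos_a += 1
        if cb != "-":
            pos_b += 1
        if ca == "-" or cb == "-":
            match.append(" ")
        elif ca == cb:
            match.append("|")
        elif _similar(ca, cb):
            match.append(":")
        else:
            match.append(" ")
        if ca != "-":
            map_a_to_b.append(pos_b if cb != "-" else None)
        if cb != "-":
            map_b_to_a.append(pos_a if ca != "-" else None)
    return HomologAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        match_line="".join(match),
        map_a_to_b=map_a_to_b,
        map_b_to_a=map_b_to_a,
        score=alignment.score,
    )


def map_peptide(
    sequence: str, db: list[Precursor] | dict[str, Precursor]
) -> list[tuple[Precursor, int, int]]:
    """All exact occurrences of a peptide in a precursor database.

    Returns ``(precursor, start, end)`` triples with 1-based inclusive
    prepro coordinates, sorted by accession then start; every occurrence
    in every precursor is reported.  An empty list means no match.
    """
    validate_sequence(sequence)
    if isinstance(db, dict):
        precursors = list(db.values())
    else:
        precursors = list(db)
    if not precursors:
        raise ValueError("precursor database is empty")
    hits: list[tuple[Precursor, int, int]] = []
    for prec in sorted(precursors, key=lambda p: p.accession):
        pos = prec.sequence.find(sequence)
        while pos != -1:
            hits.append((prec, pos + 1, pos + len(sequence)))
            pos = prec.sequence.find(sequence, pos + 1)
    return hits


def is_ambiguous(hits: list[tuple[Precursor, int, int]]) -> bool:
    """A peptide is ambiguous when it maps to more than one location."""
    return len(hits) > 1


def project_interval(
    al: HomologAlignment, start: int, end: int
) -> tuple[tuple[int, int] | None, float]:
    """Project a 1-based interval on species A onto species B.

    Returns the smallest interval on B covering every aligned image of
    ``[start, end]``, plus the coverage fraction (non-gap positions over
    the interval length).  A fully gapped interval projects to ``None``
    with coverage 0.
    """
    if not 1 <= start <= end <= len(al.map_a_to_b):
        raise ValueError(f"interval ({start}, {end}) out of range")
    images = [al.map_a_to_b[i - 1] for i in range(start, end + 1)]
    mapped = [x for x in images if x is not None]
    coverage = len(mapped) / (end - start + 1)
    if not mapped:
        return None, 0.0
    return (min(mapped), max(mapped)), coverage


def interval_identity(al: HomologAlignment, start: int, end: int) -> float:
    """Fraction of positions in an A-interval aligned to identical residues."""
    if not 1 <= start <= end <= len(al.map_a_to_b):
        raise ValueError(f"interval ({start}, {end}) out of range")
    # walk alignment columns, counting '|' columns whose A-position is inside
    pos_a = 0
    identical = 0
    for col, ca in enumerate(al.aligned_a):
        if ca != "-":
            pos_a += 1
            if start <= pos_a <= end and al.match_line[col] == "|":
                identical += 1
    return identical / (end - start + 1)


class PrecursorAtlas:
    """A database of precursors with mouse/human homolog pairs per gene."""

    def __init__(self, precursors: list[Precursor]):
        self.by_accession: dict[str, Precursor] = {}
        for p in precursors:
            if p.accession in self.by_accession:
                raise ValueError(f"duplicate accession {p.accession}")
            self.by_accession[p.accession] = p
        self._alignments: dict[str, HomologAlignment] = {}

    @property
    def precursors(self) -> list[Precursor]:
        return list(self.by_accession.values())

    def get(self, accession: str) -> Precursor:
        return self.by_accession[accession]

    def genes(self) -> list[str]:
        return sorted({p.gene for p in self.by_accession.values()})

    def homolog_pair(self, gene: str) -> tuple[Precursor, Precursor | None]:
        """(mouse precursor, human precursor or None) for a gene."""
        mouse = [p for p in self.by_accession.values() if p.gene == gene and p.species == "mouse"]
        human = [p for p in self.by_accession.values() if p.gene == gene and p.species == "human"]
        if not mouse:
            raise KeyError(f"no mouse precursor for gene {gene!r}")
        return mouse[0], (human[0] if human else None)

    def alignment(self, gene: str) -> HomologAlignment | None:
        """Cached mouse→human alignment for a gene (None without a homolog)."""
        if gene not in self._alignments:
            mouse, human = self.homolog_pair(gene)
            if human is None:
                return None
            self._alignments[gene] = align_homologs(mouse, human)
        return self._alignments[gene]

    def map_peptide(self, sequence: str) -> list[tuple[Precursor, int, int]]:
        return map_peptide(sequence, self.precursors)


# ---------------------------------------------------------------------------
# Alignment-plot documents


@dataclass
class PlotPeptide:
    """One retained peptide row of an alignment-plot document."""

    peptide_id: str
    start: int
    end: int
    peak_area: float
    shade: float  # log-scaled area in [0, 1] relative to the document
    amidated: bool
    pyroglu: bool
    carbamidomethyl: bool


@dataclass
class AlignmentPlot:
    """Renderer-neutral alignment-plot document for one gene.

    Mirrors the published figure convention: mouse sequence on top,
    human below, a match line between, one shaded bar per retained
    peptide, red markers for C-terminal amidation, yellow for
    pyroglutamate, pink for carbamidomethylation.
    """

    gene: str
    alignment: HomologAlignment
    peptides: list[PlotPeptide]
    min_area: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# gene={self.gene}\tmin_area={self.min_area:g}\n")
            fh.write(f"# mouse\t{self.alignment.aligned_a}\n")
            fh.write(f"# match\t{self.alignment.match_line}\n")
            fh.write(f"# human\t{self.alignment.aligned_b}\n")
            fh.write(
                "peptide_id\tstart\tend\tpeak_area\tshade\t"
                "amidated\tpyroglu\tcarbamidomethyl\n"
            )
            for p in self.peptides:
                fh.write(
                    f"{p.peptide_id}\t{p.start}\t{p.end}\t{p.peak_area:g}\t"
                    f"{p.shade:.4f}\t{int(p.amidated)}\t{int(p.pyroglu)}\t"
                    f"{int(p.carbamidomethyl)}\n"
                )

    def to_svg(self, path, char_w: int = 8, row_h: int = 14) -> None:
        """Write a minimal SVG rendering of the document."""
        ncol = len(self.alignment.aligned_a)
        width = 60 + ncol * char_w
        height = row_h * (5 + len(self.peptides))
        lines = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
            f'font-family="monospace" font-size="{row_h - 2}">',
            f'<text x="4" y="{row_h}">{self.gene}</text>',
        ]
        for i, (label, seq) in enumerate(
            [
                ("mouse", self.alignment.aligned_a),
                ("", self.alignment.match_line),
                ("human", self.alignment.aligned_b),
            ]
        ):
            y = row_h * (2 + i)
            lines.append(
                f'<text x="60" y="{y}" xml:space="preserve" textLength="{ncol * char_w}">'
                f"{seq}</text>"
            )
            if label:
                lines.append(f'<text x="4" y="{y}">{label}</text>')
        # one bar per peptide, blue opacity encodes log-scaled area
        for j, p in enumerate(self.peptides):
            y = row_h * (5 + j)
            x0 = 60 + (p.start - 1) * char_w
            w = (p.end - p.start + 1) * char_w
            opacity = 0.15 + 0.85 * p.shade
            lines.append(
                f'<rect x="{x0}" y="{y - row_h + 3}" width="{w}" height="{row_h - 4}" '
                f'fill="steelblue" fill-opacity="{opacity:.3f}"/>'
            )
            if p.amidated:
                lines.append(
                    f'<rect x="{x0 + w - char_w}" y="{y - row_h + 3}" width="{char_w}" '
                    f'height="{row_h - 4}" fill="none" stroke="red"/>'
                )
            if p.pyroglu:
                lines.append(
                    f'<rect x="{x0}" y="{y - row_h + 3}" width="{char_w}" '
                    f'height="{row_h - 4}" fill="none" stroke="gold"/>'
                )
            if p.carbamidomethyl:
                lines.append(
                    f'<rect x="{x0}" y="{y - row_h + 3}" width="{w}" '
                    f'height="{row_h - 4}" fill="none" stroke="pink"/>'
                )
        lines.append("</svg>")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def build_alignment_plot(
    atlas: PrecursorAtlas,
    gene: str,
    observations: list[PeptideObservation],
    min_area: float = 1e4,
) -> AlignmentPlot:
    """Build the alignment-plot document for one gene.

    Retains observations on the gene's mouse precursor with
    ``peak_area >= min_area`` (figures in this field typically use 1e4 or
    1e5 depending on precursor abundance); shading is the log10 peak area
    rescaled to [0, 1] over the retained set.
    """
    if gene not in atlas.genes():
        raise KeyError(f"unknown gene {gene!r}")
    mouse, human = atlas.homolog_pair(gene)
    alignment = atlas.alignment(gene)
    if alignment is None:
        # render against itself so single-species genes still plot
        alignment = align_homologs(
            mouse, Precursor(mouse.accession + "_self", gene, "human", mouse.sequence)
        )
    retained = [
        o
        for o in observations
        if o.precursor_accession == mouse.accession and o.peak_area >= min_area
    ]
    retained.sort(key=lambda o: (o.start, o.end, -o.peak_area))
    if retained:
        logs = [math.log10(o.peak_area) for o in retained]
        lo, hi = min(logs), max(logs)
        span = (hi - lo) or 1.0
    peptides = []
    for o in retained:
        shade = (math.log10(o.peak_area) - lo) / span
        peptides.append(
            PlotPeptide(
                peptide_id=observation_id(o, gene),
                start=o.start,
                end=o.end,
                peak_area=o.peak_area,
                shade=shade,
                amidated=o.amidated,
                pyroglu=o.pyroglu,
                carbamidomethyl=o.has_mod("carbamidomethyl"),
            )
        )
    return AlignmentPlot(gene=gene, alignment=alignment, peptides=peptides, min_area=min_area)
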