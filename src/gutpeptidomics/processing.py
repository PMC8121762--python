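"""Cleavage-site classification, PTM consistency and ladder filtering.

Prohormone convertases (PC1/3, PC2) cleave on the C-terminal side of
mono- and dibasic (K/R) sites; carboxypeptidase-E then trims the exposed
basic residues, and peptidylglycine alpha-amidating monooxygenase (PAM)
converts a C-terminal glycine into an amide.  The classifiers here encode
that canonical processing chain.  Ex-vivo exoproteolysis produces peptide
"ladders" — series of identifications differing by one or two terminal
residues — which are clustered and suppressed with the standard
10 %-of-most-abundant filter applied per propeptide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .atlas import PeptideObservation, Precursor

BASIC = "KR"


@dataclass(frozen=True)
class TerminusCall:
    """Classification of one cleavage point on a precursor.

    ``position`` is the cut point between prepro residues ``position``
    and ``position + 1`` (0 and precursor length denote the precursor
    ends).  ``flanking`` holds the two residues on each side of the cut
    ('' padded at the ends).
    """

    side: str  # 'N' or 'C'
    position: int
    klass: str  # dibasic | monobasic | signal_boundary | nonbasic
    flanking: str


def classify_terminus(prec: Precursor, pos: int, side: str) -> TerminusCall:
    """Classify the cut between prepro residues ``pos`` and ``pos+1``.

    Dibasic: the two residues immediately preceding the cut form
    KK/KR/RK/RR, allowing for up to two basic residues already trimmed
    off by carboxypeptidase (i.e. still present just after the cut).
    Monobasic: exactly one K/R precedes.  Precedence:
    signal_boundary > dibasic > monobasic > nonbasic.
    """
    seq = prec.sequence
    n = len(seq)
    if side not in ("N", "C"):
        raise ValueError(f"side must be 'N' or 'C', got {side!r}")
    if not 0 <= pos <= n:
        raise ValueError(f"cut position {pos} outside 0..{n}")
    flanking = seq[max(0, pos - 2) : pos] + "|" + seq[pos : pos + 2]

    if prec.signal_end is not None and pos == prec.signal_end:
        return TerminusCall(side, pos, "signal_boundary", flanking)

    def pair_at(cut: int) -> str:
        return seq[max(0, cut - 2) : cut]

    # shift the effective cut past up to 2 trimmed basic residues
    klass = "nonbasic"
    for trim in range(3):
        cut = pos + trim
        if cut > n:
            break
        if trim > 0 and any(aa not in BASIC for aa in seq[pos : pos + trim]):
            break
        pair = pair_at(cut)
        if len(pair) == 2 and all(aa in BASIC for aa in pair):
            klass = "dibasic"
            break
        if pair and pair[-1] in BASIC:
            klass = "monobasic"  # keep scanning: a longer trim may reveal dibasic
    return TerminusCall(side, pos, klass, flanking)


def check_amidation(prec: Precursor, obs: PeptideObservation) -> str:
    """Is an observed C-terminal amide consistent with a glycine donor?

    Amidation consumes a glycine immediately following the peptide in
    the precursor (canonically Gly-Lys/Arg...); returns ``consistent``,
    ``inconsistent`` or ``not_amidated``.
    """
    if obs.end > len(prec.sequence):
        raise ValueError(f"observation end {obs.end} beyond precursor length")
    if not obs.amidated:
        return "not_amidated"
    if obs.end < len(prec.sequence) and prec.sequence[obs.end] == "G":
        return "consistent"
    return "inconsistent"


@dataclass
class PeptideCluster:
    """A ladder cluster: observations linked by <=2-residue terminal trims."""

    precursor_accession: str
    members: list[PeptideObservation]
    cluster_id: int

    @property
    def canonical(self) -> PeptideObservation:
        """Member with the largest peak area (deterministic tie-break)."""
        return max(
            self.members, key=lambda o: (o.peak_area, -o.start, -o.end, o.sample_id)
        )

    @property
    def span(self) -> tuple[int, int]:
        return min(o.start for o in self.members), max(o.end for o in self.members)


def _linked(a: PeptideObservation, b: PeptideObservation) -> bool:
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap < 1:
        return False
    return abs(a.start - b.start) <= 2 or abs(a.end - b.end) <= 2


def cluster_ladders(observations: list[PeptideObservation]) -> list[PeptideCluster]:
    """Single-linkage clustering of ladder variants on one precursor.

    Two observations link when they overlap and their N- or C-termini
    differ by at most two residues.  Every observation lands in exactly
    one cluster; clusters are reported, never merged into a single
    longest variant, so ladder information is retained.
    """
    if not observations:
        return []
    accessions = {o.precursor_accession for o in observations}
    if len(accessions) != 1:
        raise ValueError(f"observations span multiple precursors: {sorted(accessions)}")
    n = len(observations)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if _linked(observations[i], observations[j]):
                union(i, j)

    groups: dict[int, list[PeptideObservation]] = {}
    for i, obs in enumerate(observations):
        groups.setdefault(find(i), []).append(obs)
    clusters = []
    ordered = sorted(groups.values(), key=lambda ms: (ms[0].start, ms[0].end))
    for cid, members in enumerate(ordered):
        clusters.append(
            PeptideCluster(
                precursor_accession=observations[0].precursor_accession,
                members=members,
                cluster_id=cid,
            )
        )
    return clusters


def filter_minor_fragments(
    observations: list[PeptideObservation], frac: float = 0.10
) -> list[PeptideObservation]:
    """Drop low-abundance ladder fragments, per propeptide.

    Within each precursor, a peptide (identified by coordinates + mods)
    is kept only when its maximum peak area across samples reaches
    ``frac`` of the most abundant peptide of that precursor.  The
    comparison uses per-peptide maxima across samples, so the filter is
    idempotent and a precursor's most abundant peptide always survives.
    """
    if not 0 < frac < 1:
        raise ValueError(f"frac must be in (0, 1), got {frac}")

    def peptide_key(o: PeptideObservation):
        return (o.precursor_accession, o.start, o.end, tuple(sorted(o.mods)))

    max_area: dict[tuple, float] = {}
    for o in observations:
        k = peptide_key(o)
        max_area[k] = max(max_area.get(k, 0.0), o.peak_area)
    prec_max: dict[str, float] = {}
    for (acc, *_rest), area in max_area.items():
        prec_max[acc] = max(prec_max.get(acc, 0.0), area)
    return [
        o
        for o in observations
        if max_area[peptide_key(o)] >= frac * prec_max[o.precursor_accession]
    ]


def annotate_observations(
    prec: Precursor, observations: list[PeptideObservation]
) -> list[dict]:
    """Terminus, amidation and cluster annotation for one precursor's peptides.

    Returns one record per observation with ``n_term_class``,
    ``c_term_class``, ``amidation_status`` and ``cluster_id`` fields,
    ready for tabular export.
    """
    clusters = cluster_ladders(observations)
    cluster_of = {}
    for c in clusters:
        for m in c.members:
            cluster_of[id(m)] = c.cluster_id
    records = []
    for o in observations:
        records.append(
            {
                "observation": o,
                "n_term_class": classify_terminus(prec, o.start - 1, "N").klass,
                "c_term_class": classify_terminus(prec, o.end, "C").klass,
                "amidation_status": check_amidation(prec, o),
                "cluster_id": cluster_of[id(o)],
            }
        )
    return records


def group_by_precursor(
    observations: list[PeptideObservation],
) -> dict[str, list[PeptideObservation]]:
    """Split an observation list by precursor accession (order-stable)."""
    out: dict[str, list[PeptideObservation]] = {}
    for o in observations:
        out.setdefault(o.precursor_accession, []).append(o)
    return out
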