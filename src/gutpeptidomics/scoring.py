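"""Ranking peptides as candidate bioactive hormones.

A candidate hormone should look like one: excised at convertase-style
basic cleavage sites, abundant in both mouse and human gut tissue,
conserved between the species, and released from the epithelium in
response to a secretory stimulus.  Each criterion is a boolean; the
composite score (0-4) counts how many hold, and candidates are ranked by
composite, then abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import (
    PeptideObservation,
    PrecursorAtlas,
    interval_identity,
    observation_id,
    project_interval,
)
from .processing import classify_terminus

BASIC_LIKE = ("dibasic", "monobasic", "signal_boundary")


@dataclass
class ScoringThresholds:
    """Quantitative cut-offs for the qualitative candidate criteria.

    ``min_abundance``: peak area required to call a peptide "highly
    abundant" (default 1e5, the plotting cut used for abundant
    precursors); ``min_identity``: alignment identity over the peptide
    span to call it conserved (default 0.7); ``min_fold``: fold over
    basal above which secretion counts as regulated (default 2, the
    stated criterion for stimulated release).
    """

    min_abundance: float = 1e5
    min_identity: float = 0.7
    min_fold: float = 2.0


@dataclass
class CandidateScore:
    peptide_id: str
    basic_flanked: bool
    abundant_both_species: bool
    conserved: bool
    regulated_secretion: bool
    composite: int
    rank: int
    max_area: float


def _flank_ok(prec, pos: int, side: str, amidated_c: bool = False) -> bool:
    """Does a terminus look like a physiological processing site?

    Precursor ends count as valid flanks (mature protein termini), as
    does the signal-peptide boundary.  For an amidated C-terminus the
    consumed glycine is skipped before classifying, since amidation
    removes the Gly that preceded the basic residues.
    """
    n = len(prec.sequence)
    if pos in (0, n):
        return True
    if side == "C" and amidated_c and pos < n and prec.sequence[pos] == "G":
        pos = pos + 1
        if pos == n:
            return True
    return classify_terminus(prec, pos, side).klass in BASIC_LIKE


def score_candidates(
    atlas: PrecursorAtlas,
    mouse_observations: list[PeptideObservation],
    human_observations: list[PeptideObservation],
    secretion: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
) -> list[CandidateScore]:
    """Score unique mouse peptides against the four hormone-like criteria.

    ``secretion`` must carry ``peptide_id``, ``region`` and
    ``fold_over_basal`` columns (see :func:`gutpeptidomics.stats.secretion_table`).
    Peptides are identified by gene + prepro coordinates (+ amidation);
    multiple observations of the same peptide are pooled by maximum peak
    area.  A precursor without a human homolog scores ``conserved`` and
    ``abundant_both_species`` false with a warning rather than an error.
    """
    thr = thresholds or ScoringThresholds()

    # pool observations into unique peptides
    peptides: dict[str, dict] = {}
    for o in mouse_observations:
        prec = atlas.get(o.precursor_accession)
        pid = observation_id(o, prec.gene)
        entry = peptides.setdefault(
            pid, {"obs": o, "prec": prec, "max_area": 0.0}
        )
        if o.peak_area > entry["max_area"]:
            entry["max_area"] = o.peak_area
            entry["obs"] = o

    # human max areas by (accession, interval overlap) lookup
    human_by_acc: dict[str, list[PeptideObservation]] = {}
    for o in human_observations:
        human_by_acc.setdefault(o.precursor_accession, []).append(o)

    fold_by_pid: dict[str, float] = {}
    if len(secretion):
        for pid, grp in secretion.groupby("peptide_id"):
            folds = grp["fold_over_basal"].dropna()
            if len(folds):
                fold_by_pid[str(pid)] = float(folds.max())

    scores: list[CandidateScore] = []
    for pid, entry in peptides.items():
        o: PeptideObservation = entry["obs"]
        prec = entry["prec"]
        gene = prec.gene

        basic_flanked = _flank_ok(prec, o.start - 1, "N") and _flank_ok(
            prec, o.end, "C", amidated_c=o.amidated
        )

        conserved = False
        abundant_both = False
        _, human_prec = atlas.homolog_pair(gene)
        if human_prec is None:
            warnings.warn(f"{gene}: no human homolog; conservation criteria set false")
        else:
            al = atlas.alignment(gene)
            interval, coverage = project_interval(al, o.start, o.end)
            if interval is not None and coverage > 0:
                identity = interval_identity(al, o.start, o.end)
                conserved = identity >= thr.min_identity
                h_start, h_end = interval
                human_hits = [
                    h
                    for h in human_by_acc.get(human_prec.accession, [])
                    if min(h.end, h_end) - max(h.start, h_start) + 1 >= 1
                ]
                human_max = max((h.peak_area for h in human_hits), default=0.0)
                abundant_both = (
                    entry["max_area"] >= thr.min_abundance
                    and human_max >= thr.min_abundance
                )

        fold = fold_by_pid.get(pid, float("nan"))
        regulated = bool(np.isfinite(fold) and fold > thr.min_fold)

        composite = sum([basic_flanked, abundant_both, conserved, regulated])
        scores.append(
            CandidateScore(
                peptide_id=pid,
                basic_flanked=basic_flanked,
                abundant_both_species=abundant_both,
                conserved=conserved,
                regulated_secretion=regulated,
                composite=composite,
                rank=0,
                max_area=entry["max_area"],
            )
        )

    scores.sort(key=lambda s: (-s.composite, -s.max_area, s.peptide_id))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def scores_to_frame(scores: list[CandidateScore]) -> pd.DataFrame:
    """Tabular view of a ranked candidate list."""
    return pd.DataFrame(
        [
            {
                "peptide_id": s.peptide_id,
                "basic_flanked": s.basic_flanked,
                "abundant_both_species": s.abundant_both_species,
                "conserved": s.conserved,
                "regulated_secretion": s.regulated_secretion,
                "composite": s.composite,
                "rank": s.rank,
                "max_area": s.max_area,
            }
            for s in scores
        ]
    )
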