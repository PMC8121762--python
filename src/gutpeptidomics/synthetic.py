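"""Seeded generator for every input the pipeline consumes.

The generator emulates the data-generating process of an
enteroendocrine-cell peptidomics study: prepropeptides with a signal
peptide, planted dibasic convertase sites and amidation motifs; a human
homolog derived by point mutations to a target identity; proteolytic
processing with basic-residue trimming, amidation, pyroglutamate and
exoprotease ladders; log-normal peak areas; a lean-vs-DIO cohort with a
planted decrease of L-cell precursors in the distal colon; stimulated
secretion with a constitutive (cytosolic) decoy; and noisy
concentration-time PK profiles for the synthesised candidates.

Randomness: one named PRNG stream per artefact type, derived from
(master seed, artefact label), so the same seed reproduces every output
byte-for-byte and adding artefact types never perturbs existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as gio
from .atlas import PeptideObservation, Precursor, PrecursorAtlas, peptide_name
from .chemistry import monoisotopic_mass
from .pk import LN2, PKDataset, simulate
from .stats import AbundanceMatrix

REGIONS = ["stomach", "proximal_SI", "distal_SI", "mid_colon", "distal_colon"]

BASIC = "KR"
#: residue alphabet for generated segments: no K/R (cleavage sites are
#: planted explicitly) and no G (amidation donors are planted explicitly)
SEGMENT_ALPHABET = "ACDEFHILMNPQSTVWY"
SIGNAL_ALPHABET = "LAVIFMW"


@dataclass
class PlannedPeptide:
    """One peptide planted in a precursor layout."""

    length: int
    start: int | None = None  # explicit 1-based prepro start, else auto
    amidated: bool = False
    n_flank: str = "dibasic"  # 'dibasic' | 'none' (signal boundary / no flank)
    candidate: bool = False
    secretion_class: str | None = None  # regulated | constitutive | basal_undetected
    acyl: str | None = None  # e.g. 'octanoyl'
    acyl_pos: int | None = None  # 1-based on the peptide


@dataclass
class GenePlan:
    """Layout plan for one gene's mouse precursor (human derived from it)."""

    gene: str
    signal_len: int | None
    peptides: list[PlannedPeptide]
    home_region: str
    dio_target: bool = False
    low_prevalence: bool = False
    flanked: bool = True  # False: cytosolic decoy, no basic sites at all
    tail_len: int = 8
    spacer_len: int = 8


def default_gene_plans() -> list[GenePlan]:
    """The shipped study design.

    Plants three candidate analogues — a gastrin-derived p59-79 span, an
    amidated granin C-terminal span (p435-462a) and a somatostatin-like
    span starting at the signal boundary (p25-36) — alongside L-cell
    precursors (Pyy/Gcg/Insl5) decreased in the DIO distal colon, an
    acylated ghrelin-like peptide, a low-prevalence secretin-like gene
    and a constitutive cytosolic decoy (Tyb4-like).
    """
    return [
        GenePlan(
            "Gast",
            21,
            [PlannedPeptide(21, start=59, candidate=True, secretion_class="regulated")],
            home_region="stomach",
        ),
        GenePlan(
            "ChgA",
            18,
            [
                PlannedPeptide(20),
                PlannedPeptide(
                    28, start=435, amidated=True, candidate=True,
                    secretion_class="regulated",
                ),
            ],
            home_region="stomach",
        ),
        GenePlan(
            "Sst",
            24,
            [
                PlannedPeptide(
                    12, start=25, n_flank="none", candidate=True,
                    secretion_class="regulated",
                ),
                PlannedPeptide(14),
            ],
            home_region="stomach",
        ),
        GenePlan(
            "Pyy",
            28,
            [
                PlannedPeptide(
                    36, start=29, amidated=True, n_flank="none",
                    secretion_class="basal_undetected",
                )
            ],
            home_region="distal_colon",
            dio_target=True,
        ),
        GenePlan(
            "Gcg",
            20,
            [
                PlannedPeptide(30, amidated=True, secretion_class="basal_undetected"),
                PlannedPeptide(33, secretion_class="basal_undetected"),
            ],
            home_region="distal_colon",
            dio_target=True,
        ),
        GenePlan(
            "Insl5",
            22,
            [PlannedPeptide(24, secretion_class="basal_undetected")],
            home_region="distal_colon",
            dio_target=True,
        ),
        GenePlan(
            "Ghrl",
            23,
            [PlannedPeptide(28, start=24, n_flank="none", acyl="octanoyl", acyl_pos=3)],
            home_region="stomach",
        ),
        GenePlan(
            "Secr",
            18,
            [PlannedPeptide(27)],
            home_region="proximal_SI",
            low_prevalence=True,
        ),
        GenePlan(
            "Tyb4",
            None,
            [PlannedPeptide(43, start=8, n_flank="none", secretion_class="constitutive")],
            home_region="distal_colon",
            flanked=False,
        ),
    ]


@dataclass
class PKTruth:
    """Generating one-compartment parameters for one analyte."""

    t_half: float  # min
    ka_over_ke: float = 5.0
    V_L_per_kg: float = 0.15
    F: float = 0.85

    @property
    def ke(self) -> float:
        return LN2 / self.t_half


def default_pk_truth() -> dict[str, PKTruth]:
    """Generating PK parameters per candidate gene.

    Terminal half-lives follow the published s.c. values for the
    gastrin-derived (18.1 min) and granin-derived (36.0 min) candidates;
    the granin candidate's bioavailability is 0.5.  The
    somatostatin-like candidate is modelled as very short-lived and
    barely bioavailable (it was undetectable after i.v. dosing).
    """
    return {
        "Gast": PKTruth(t_half=18.1, F=0.85),
        "ChgA": PKTruth(t_half=36.0, F=0.50),
        "Sst": PKTruth(t_half=4.0, F=0.05),
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the shipped study design."""

    seed: int = 17
    homolog_identity: float = 0.85
    ladder_depth: int = 2
    abundance_mu: float = float(np.log(2e5))
    abundance_sigma: float = 0.8
    candidate_mu: float = float(np.log(2e6))
    candidate_sigma: float = 0.4
    sample_sigma: float = 0.25  # within-group lognormal spread of areas
    pyroglu_prob: float = 0.5
    dio_effect: float = 4.0  # fold-decrease of L-cell precursors in DIO
    dio_region: str = "distal_colon"
    n_per_group: int = 10
    n_obs_samples: int = 3
    missing_rate: float = 0.05
    low_prevalence_rate: float = 0.5
    stimulation_fold: dict = field(
        default_factory=lambda: {"regulated": 6.0, "constitutive": 1.0}
    )
    secretion_noise: float = 0.1
    noise_cv: float = 0.10  # PK measurement noise
    genes: list[GenePlan] = field(default_factory=default_gene_plans)
    pk_truth: dict[str, PKTruth] = field(default_factory=default_pk_truth)

    def __post_init__(self) -> None:
        if not 0 < self.homolog_identity <= 1:
            raise ValueError("homolog_identity must be in (0, 1]")
        if self.dio_effect <= 0 or any(f <= 0 for f in self.stimulation_fold.values()):
            raise ValueError("fold parameters must be > 0")
        if self.ladder_depth < 0:
            raise ValueError("ladder_depth must be >= 0")

    @property
    def n_precursors(self) -> int:
        return len(self.genes)

    def plan(self, gene: str) -> GenePlan:
        for g in self.genes:
            if g.gene == gene:
                return g
        raise KeyError(f"no plan for gene {gene!r}")


def _rng(cfg: SyntheticConfig, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# Precursor construction


def _segment(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SEGMENT_ALPHABET), size=n))


def _build_mouse(plan: GenePlan, rng: np.random.Generator) -> tuple[str, list[tuple]]:
    """Build the mouse precursor; return (sequence, planted peptide coords).

    Planted coords are (start, end, planned) with 1-based prepro
    positions of the mature peptide (amidation G excluded).
    """
    parts: list[str] = []
    pos = 0  # residues emitted so far
    planted: list[tuple[int, int, PlannedPeptide]] = []
    if plan.signal_len:
        sig = "M" + "".join(rng.choice(list(SIGNAL_ALPHABET), size=plan.signal_len - 1))
        parts.append(sig)
        pos += plan.signal_len
    for pp in plan.peptides:
        flank = "KR" if (pp.n_flank == "dibasic" and plan.flanked) else ""
        if pp.start is not None:
            gap = pp.start - 1 - len(flank) - pos
            if gap < 0:
                raise ValueError(
                    f"{plan.gene}: planted start {pp.start} overlaps previous elements"
                )
        else:
            gap = plan.spacer_len
        parts.append(_segment(rng, gap))
        pos += gap
        parts.append(flank)
        pos += len(flank)
        pep = _segment(rng, pp.length)
        if pp.acyl:
            if pp.acyl_pos is None or not 1 <= pp.acyl_pos <= pp.length:
                raise ValueError(f"{plan.gene}: bad acyl position")
            pep = pep[: pp.acyl_pos - 1] + "S" + pep[pp.acyl_pos :]
        start = pos + 1
        parts.append(pep)
        pos += pp.length
        planted.append((start, pos, pp))
        if pp.amidated:
            parts.append("G")
            pos += 1
        if plan.flanked:
            parts.append("KR")
            pos += 2
    parts.append(_segment(rng, plan.tail_len))
    return "".join(parts), planted


def _protected_positions(seq: str, planted: list[tuple], plan: GenePlan) -> set[int]:
    """0-based positions that mutations must not touch (motifs + candidates)."""
    protected = {i for i, aa in enumerate(seq) if aa in BASIC or aa == "G"}
    for start, end, pp in planted:
        if pp.candidate:
            protected.update(range(start - 1, end))
        if pp.acyl_pos is not None:
            protected.add(start - 1 + pp.acyl_pos - 1)
    return protected


def generate_precursor_pair(
    cfg: SyntheticConfig, gene: str
) -> tuple[Precursor, Precursor]:
    """A (mouse, human) precursor pair for one gene of the study design.

    The mouse sequence carries the planted signal peptide, dibasic sites
    and amidation motifs; the human homolog is derived by point
    mutations (no indels) at non-motif positions to reach the configured
    global identity.  Raises when the identity target cannot be reached
    without touching protected motif positions.
    """
    plan = cfg.plan(gene)
    rng = _rng(cfg, f"precursor:{gene}")
    seq, planted = _build_mouse(plan, rng)
    n = len(seq)
    n_mut = round((1.0 - cfg.homolog_identity) * n)
    protected = _protected_positions(seq, planted, plan)
    mutable = [i for i in range(n) if i not in protected]
    if n_mut > len(mutable):
        raise ValueError(
            f"{gene}: identity target {cfg.homolog_identity} unreachable "
            f"({n_mut} mutations needed, {len(mutable)} mutable positions)"
        )
    sites = rng.choice(mutable, size=n_mut, replace=False) if n_mut else []
    human = list(seq)
    for i in sites:
        choices = [aa for aa in SEGMENT_ALPHABET if aa != seq[i]]
        human[i] = rng.choice(choices)
    mouse_prec = Precursor(
        accession=f"M_{gene}", gene=gene, species="mouse",
        sequence=seq, signal_end=plan.signal_len,
    )
    human_prec = Precursor(
        accession=f"H_{gene}", gene=gene, species="human",
        sequence="".join(human), signal_end=plan.signal_len,
    )
    return mouse_prec, human_prec


# ---------------------------------------------------------------------------
# Processing simulation


def _fragments(seq: str, signal_end: int | None) -> list[tuple[int, int]]:
    """Maximal non-basic segments, split and truncated at the signal boundary."""
    n = len(seq)
    frags: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if seq[i] in BASIC:
            i += 1
            continue
        j = i
        while j < n and seq[j] not in BASIC:
            j += 1
        s, e = i + 1, j  # 1-based inclusive
        if signal_end:
            if e <= signal_end:
                s = None  # entirely signal peptide: degraded
            elif s <= signal_end:
                s = signal_end + 1
        if s is not None:
            frags.append((s, e))
        i = j
    return frags


def simulate_processing(
    precursor: Precursor,
    cfg: SyntheticConfig,
    sample_ids: list[str] | None = None,
    region: str | None = None,
) -> list[PeptideObservation]:
    """Observed peptides from convertase-style processing of one precursor.

    Cuts at every planted dibasic site (scanned from the sequence, with
    basic residues trimmed), strips a trailing glycine as C-terminal
    amidation, adds N-terminal pyroglutamate on Gln/Glu starts with the
    configured probability, and decorates each canonical product with
    exoprotease ladder variants up to ``ladder_depth`` at lower peak
    areas.  Fragments entirely within the signal peptide, shorter than 4
    residues or longer than the 65-residue search limit are not observed.
    """
    seq = precursor.sequence
    if not any(
        seq[i] in BASIC and seq[i + 1] in BASIC for i in range(len(seq) - 1)
    ):
        raise ValueError(f"{precursor.accession}: no dibasic site to process")
    plan = cfg.plan(precursor.gene)
    region = region or plan.home_region
    prefix = "m" if precursor.species == "mouse" else "h"
    sample_ids = sample_ids or [f"{prefix}{i + 1}" for i in range(cfg.n_obs_samples)]
    rng = _rng(cfg, f"processing:{precursor.accession}")

    acyl_by_start = {
        start: pp for start, _end, pp in _planted_lookup(precursor, cfg) if pp.acyl
    }

    candidates = {
        (start, end) for start, end, pp in _planted_lookup(precursor, cfg) if pp.candidate
    }

    observations: list[PeptideObservation] = []
    for s, e in _fragments(seq, precursor.signal_end):
        mods: list[tuple[str, int]] = []
        # amidation: trailing glycine donated to the amide, basics follow
        if seq[e - 1] == "G" and e < len(seq) and seq[e] in BASIC and e - 1 >= s:
            e = e - 1
            mods.append(("amidation", e - s + 1))
        length = e - s + 1
        if not 4 <= length <= 65:
            continue
        if seq[s - 1] in "QE" and rng.random() < cfg.pyroglu_prob:
            mods.append((f"pyroglu_{seq[s - 1]}", 1))
        pp = acyl_by_start.get(s)
        if pp is not None and pp.acyl is not None:
            mods.append((pp.acyl, pp.acyl_pos))
        if (s, e) in candidates:
            base = float(rng.lognormal(cfg.candidate_mu, cfg.candidate_sigma))
        else:
            base = float(rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma))

        variants: list[tuple[int, int, list, float]] = [(s, e, mods, base)]
        for d in range(1, cfg.ladder_depth + 1):
            frac_n = float(rng.uniform(0.05, 0.5))
            frac_c = float(rng.uniform(0.05, 0.5))
            if e - (s + d) + 1 >= 4:  # N-terminal trim keeps C-terminal mods
                kept = [
                    (nm, p - d) for nm, p in mods if p - d >= 1 and not nm.startswith("pyroglu")
                ]
                variants.append((s + d, e, kept, base * frac_n))
            if (e - d) - s + 1 >= 4:  # C-terminal trim loses amidation
                kept = [(nm, p) for nm, p in mods if nm != "amidation" and p <= e - d - s + 1]
                variants.append((s, e - d, kept, base * frac_c))
        for vs, ve, vmods, varea in variants:
            for sid in sample_ids:
                area = varea * float(np.exp(rng.normal(0.0, cfg.sample_sigma)))
                observations.append(
                    PeptideObservation(
                        precursor_accession=precursor.accession,
                        start=vs,
                        end=ve,
                        mods=list(vmods),
                        sample_id=sid,
                        region=region,
                        peak_area=area,
                        sequence=seq[vs - 1 : ve],
                    )
                )
    return observations


def _planted_lookup(precursor: Precursor, cfg: SyntheticConfig):
    """Planted (start, end, planned) triples for a precursor's gene.

    Coordinates are identical for the mouse and human member of a pair
    (the homolog is derived without indels).
    """
    plan = cfg.plan(precursor.gene)
    rng = _rng(cfg, f"precursor:{precursor.gene}")
    _seq, planted = _build_mouse(plan, rng)
    return planted


def _decoy_observations(
    precursor: Precursor, cfg: SyntheticConfig
) -> list[PeptideObservation]:
    """Observations for an unflanked cytosolic decoy (no convertase sites)."""
    plan = cfg.plan(precursor.gene)
    rng = _rng(cfg, f"processing:{precursor.accession}")
    prefix = "m" if precursor.species == "mouse" else "h"
    observations = []
    for start, end, _pp in _planted_lookup(precursor, cfg):
        base = float(rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma))
        for i in range(cfg.n_obs_samples):
            area = base * float(np.exp(rng.normal(0.0, cfg.sample_sigma)))
            observations.append(
                PeptideObservation(
                    precursor_accession=precursor.accession,
                    start=start,
                    end=end,
                    mods=[],
                    sample_id=f"{prefix}{i + 1}",
                    region=plan.home_region,
                    peak_area=area,
                    sequence=precursor.sequence[start - 1 : end],
                )
            )
    return observations


# ---------------------------------------------------------------------------
# Full study


@dataclass
class SyntheticStudy:
    """Everything the pipeline consumes, plus the generating truth."""

    config: SyntheticConfig
    atlas: PrecursorAtlas
    mouse_observations: list[PeptideObservation]
    human_observations: list[PeptideObservation]
    cohort: AbundanceMatrix
    secretion: pd.DataFrame
    truth: dict

    def pk_pair(self, gene: str, **kwargs) -> tuple[PKDataset, PKDataset]:
        return generate_pk(self.config, gene, **kwargs)


def _canonical_ids(cfg: SyntheticConfig, atlas: PrecursorAtlas) -> list[dict]:
    """One record per canonical processed peptide of every mouse precursor."""
    records = []
    for plan in cfg.genes:
        prec = atlas.get(f"M_{plan.gene}")
        planted = {
            (start, end): pp for start, end, pp in _planted_lookup(prec, cfg)
        }
        if plan.flanked:
            frag_list = []
            for s, e in _fragments(prec.sequence, prec.signal_end):
                amidated = (
                    prec.sequence[e - 1] == "G"
                    and e < len(prec.sequence)
                    and prec.sequence[e] in BASIC
                    and e - 1 >= s
                )
                if amidated:
                    e = e - 1
                if 4 <= e - s + 1 <= 65:
                    frag_list.append((s, e, amidated))
        else:
            frag_list = [(s, e, False) for (s, e) in planted]
        for s, e, amidated in frag_list:
            pp = planted.get((s, e))
            records.append(
                {
                    "peptide_id": peptide_name(plan.gene, s, e, amidated),
                    "gene": plan.gene,
                    "start": s,
                    "end": e,
                    "dio_target": plan.dio_target,
                    "low_prevalence": plan.low_prevalence,
                    "secretion_class": pp.secretion_class if pp else None,
                    "candidate": bool(pp.candidate) if pp else False,
                    "home_region": plan.home_region,
                }
            )
    return records


def generate_cohort(cfg: SyntheticConfig, atlas: PrecursorAtlas | None = None) -> AbundanceMatrix:
    """Lean-vs-DIO peak-area matrix over the five gut regions.

    Peptides from DIO-target (L-cell) genes are reduced by
    ``dio_effect`` in the DIO group, in the distal colon only; all other
    peptide/region combinations are exchangeable between groups.
    Low-prevalence genes are missing in ~half the samples of each group
    (they should fall to the prevalence filter); other entries go
    missing at ``missing_rate``.
    """
    atlas = atlas or _make_atlas(cfg)
    rng = _rng(cfg, "cohort")
    records = _canonical_ids(cfg, atlas)
    sample_ids, groups, regions = [], [], []
    for region in REGIONS:
        for group in ("lean", "DIO"):
            for i in range(cfg.n_per_group):
                sample_ids.append(f"{group}{i + 1}_{region}")
                groups.append(group)
                regions.append(region)
    samples = pd.DataFrame({"group": groups, "region": regions}, index=sample_ids)
    data = np.full((len(records), len(sample_ids)), np.nan)
    for r, rec in enumerate(records):
        base_by_region = {
            region: float(rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma))
            for region in REGIONS
        }
        miss_rate = cfg.low_prevalence_rate if rec["low_prevalence"] else cfg.missing_rate
        for c, sid in enumerate(sample_ids):
            region, group = samples.at[sid, "region"], samples.at[sid, "group"]
            if rng.random() < miss_rate:
                continue
            mean = base_by_region[region]
            if rec["dio_target"] and group == "DIO" and region == cfg.dio_region:
                mean /= cfg.dio_effect
            data[r, c] = mean * float(np.exp(rng.normal(0.0, cfg.sample_sigma)))
    areas = pd.DataFrame(data, index=[r["peptide_id"] for r in records], columns=sample_ids)
    return AbundanceMatrix(areas, samples)


def generate_secretion(cfg: SyntheticConfig, atlas: PrecursorAtlas | None = None) -> pd.DataFrame:
    """Basal/stimulated supernatant areas for the secretion-annotated peptides.

    Regulated (vesicular) peptides are released at the configured
    stimulation fold (>2); the constitutive decoy stays near fold 1;
    basal-undetected peptides get NaN basal areas so no fold can be
    calculated downstream.
    """
    atlas = atlas or _make_atlas(cfg)
    rng = _rng(cfg, "secretion")
    rows = []
    for rec in _canonical_ids(cfg, atlas):
        klass = rec["secretion_class"]
        if klass is None:
            continue
        base = float(rng.lognormal(cfg.abundance_mu - 1.0, 0.5))
        noise = float(np.exp(rng.normal(0.0, cfg.secretion_noise)))
        if klass == "basal_undetected":
            basal, stim = np.nan, base * noise
        else:
            fold = cfg.stimulation_fold[klass]
            basal, stim = base, base * fold * noise
        rows.append(
            {
                "peptide_id": rec["peptide_id"],
                "region": rec["home_region"],
                "basal_area": basal,
                "stimulated_area": stim,
                "secretion_class": klass,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PKDesign:
    """Sampling design of a PK experiment (defaults: 8 points over 90 min)."""

    times: tuple = (5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0)
    iv_dose: float = 1.0  # mg/kg
    sc_dose: float = 1.0  # mg/kg
    replicate: int = 0


def generate_pk(
    cfg: SyntheticConfig, gene: str, design: PKDesign | None = None
) -> tuple[PKDataset, PKDataset]:
    """(i.v., s.c.) concentration-time datasets for one candidate gene.

    Concentrations are in ng/mL, generated from the configured
    one-compartment truth with multiplicative lognormal noise of CV
    ``noise_cv``; the two arms share clearance, with the s.c. arm scaled
    by the bioavailability fraction.
    """
    design = design or PKDesign()
    truth = cfg.pk_truth[gene]
    rng = _rng(cfg, f"pk:{gene}:{design.replicate}")
    times = np.asarray(design.times, dtype=float)
    # V in L/kg with dose in mg/kg -> C in mg/L; /1000 gives ng/mL scaling
    v_units = truth.V_L_per_kg / 1000.0
    ke = truth.ke
    ka = truth.ka_over_ke * ke
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    mw = _candidate_mw(cfg, gene)
    c_iv = simulate(ke, v_units, design.iv_dose, "iv", times)
    c_sc = simulate(ke, v_units / truth.F, design.sc_dose, "sc", times, ka=ka)
    if sigma > 0:
        c_iv = c_iv * np.exp(rng.normal(0.0, sigma, size=times.size))
        c_sc = c_sc * np.exp(rng.normal(0.0, sigma, size=times.size))
    analyte = _candidate_id(cfg, gene)
    iv = PKDataset(
        route="iv", dose=design.iv_dose, times=times, concentrations=c_iv,
        unit="ng/mL", analyte=analyte, molecular_weight=mw,
    )
    sc = PKDataset(
        route="sc", dose=design.sc_dose, times=times, concentrations=c_sc,
        unit="ng/mL", analyte=analyte, molecular_weight=mw,
    )
    return iv, sc


def _candidate_span(cfg: SyntheticConfig, gene: str) -> tuple[int, int, PlannedPeptide]:
    mouse, _human = generate_precursor_pair(cfg, gene)
    for start, end, pp in _planted_lookup(mouse, cfg):
        if pp.candidate:
            return start, end, pp
    raise KeyError(f"gene {gene!r} has no planted candidate peptide")


def _candidate_id(cfg: SyntheticConfig, gene: str) -> str:
    start, end, pp = _candidate_span(cfg, gene)
    return peptide_name(gene, start, end, pp.amidated)


def _candidate_mw(cfg: SyntheticConfig, gene: str) -> float:
    mouse, _ = generate_precursor_pair(cfg, gene)
    start, end, _pp = _candidate_span(cfg, gene)
    return monoisotopic_mass(mouse.sequence[start - 1 : end])


def _make_atlas(cfg: SyntheticConfig) -> PrecursorAtlas:
    precursors = []
    for plan in cfg.genes:
        mouse, human = generate_precursor_pair(cfg, plan.gene)
        precursors += [mouse, human]
    return PrecursorAtlas(precursors)


def generate_study(cfg: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate the complete synthetic study for a configuration."""
    cfg = cfg or SyntheticConfig()
    atlas = _make_atlas(cfg)
    mouse_obs: list[PeptideObservation] = []
    human_obs: list[PeptideObservation] = []
    for plan in cfg.genes:
        mouse, human = atlas.get(f"M_{plan.gene}"), atlas.get(f"H_{plan.gene}")
        if plan.flanked:
            mouse_obs += simulate_processing(mouse, cfg)
            human_obs += simulate_processing(human, cfg)
        else:
            mouse_obs += _decoy_observations(mouse, cfg)
            human_obs += _decoy_observations(human, cfg)
    cohort = generate_cohort(cfg, atlas)
    secretion = generate_secretion(cfg, atlas)
    records = _canonical_ids(cfg, atlas)
    truth = {
        "seed": cfg.seed,
        "candidates": [r["peptide_id"] for r in records if r["candidate"]],
        "dio_target_peptides": [r["peptide_id"] for r in records if r["dio_target"]],
        "decoy_peptides": [
            r["peptide_id"] for r in records if r["secretion_class"] == "constitutive"
        ],
        "low_prevalence_peptides": [
            r["peptide_id"] for r in records if r["low_prevalence"]
        ],
        "dio_effect": cfg.dio_effect,
        "dio_region": cfg.dio_region,
        "pk_truth": {
            g: {"t_half": t.t_half, "ka": t.ka_over_ke * t.ke, "ke": t.ke,
                "V_L_per_kg": t.V_L_per_kg, "F": t.F}
            for g, t in cfg.pk_truth.items()
        },
    }
    return SyntheticStudy(
        config=cfg,
        atlas=atlas,
        mouse_observations=mouse_obs,
        human_observations=human_obs,
        cohort=cohort,
        secretion=secretion,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write FASTA + TSVs + a JSON manifest of the generating truth."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_precursors(study.atlas.precursors, out / "precursors.fasta")
    gio.write_observations(study.mouse_observations, out / "observations_mouse.tsv")
    gio.write_observations(study.human_observations, out / "observations_human.tsv")
    gio.write_abundance(study.cohort, out / "cohort_areas.tsv", out / "cohort_samples.tsv")
    gio.write_secretion(study.secretion, out / "secretion.tsv")
    for gene in study.config.pk_truth:
        iv, sc = generate_pk(study.config, gene)
        gio.write_pk_dataset(iv, out / f"pk_{gene}_iv.tsv")
        gio.write_pk_dataset(sc, out / f"pk_{gene}_sc.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(study.truth, fh, indent=1)
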