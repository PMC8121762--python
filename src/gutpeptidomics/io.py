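"""File formats: FASTA precursors and the pipeline's TSV dialects."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .atlas import PeptideObservation, Precursor
from .pk import PKDataset
from .stats import AbundanceMatrix

# ---------------------------------------------------------------------------
# Precursors: FASTA with header "accession|gene|species|signal_end"


def write_precursors(precursors: list[Precursor], path) -> None:
    records = []
    for p in precursors:
        signal = "" if p.signal_end is None else str(p.signal_end)
        rid = f"{p.accession}|{p.gene}|{p.species}|{signal}"
        records.append(SeqRecord(Seq(p.sequence), id=rid, description=""))
    SeqIO.write(records, path, "fasta")


def read_precursors(path) -> list[Precursor]:
    precursors = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = rec.id.split("|")
        if len(fields) != 4:
            raise ValueError(f"bad precursor header {rec.id!r}")
        accession, gene, species, signal = fields
        precursors.append(
            Precursor(
                accession=accession,
                gene=gene,
                species=species,
                sequence=str(rec.seq),
                signal_end=int(signal) if signal else None,
            )
        )
    return precursors


# ---------------------------------------------------------------------------
# Observations: PEAKS-export-like TSV


def _mods_to_str(mods: list[tuple[str, int]]) -> str:
    return ";".join(f"{name}@{pos}" for name, pos in mods)


def _mods_from_str(s: str) -> list[tuple[str, int]]:
    if not s:
        return []
    out = []
    for item in s.split(";"):
        name, pos = item.rsplit("@", 1)
        out.append((name, int(pos)))
    return out


OBS_COLUMNS = [
    "peptide",
    "precursor_accession",
    "start",
    "end",
    "mods",
    "sample_id",
    "region",
    "peak_area",
]


def write_observations(observations: list[PeptideObservation], path) -> None:
    rows = [
        {
            "peptide": o.sequence or "",
            "precursor_accession": o.precursor_accession,
            "start": o.start,
            "end": o.end,
            "mods": _mods_to_str(o.mods),
            "sample_id": o.sample_id,
            "region": o.region,
            "peak_area": o.peak_area,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_observations(path) -> list[PeptideObservation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"mods": str},
                     float_precision="round_trip")
    observations = []
    for _, r in df.iterrows():
        observations.append(
            PeptideObservation(
                precursor_accession=r["precursor_accession"],
                start=int(r["start"]),
                end=int(r["end"]),
                mods=_mods_from_str(r["mods"]),
                sample_id=str(r["sample_id"]),
                region=str(r["region"]),
                peak_area=float(r["peak_area"]),
                sequence=r["peptide"] or None,
            )
        )
    return observations


# ---------------------------------------------------------------------------
# Abundance matrix: wide TSV + sample sheet


def write_abundance(m: AbundanceMatrix, areas_path, samples_path) -> None:
    m.areas.to_csv(areas_path, sep="\t", index_label="peptide_id")
    m.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_abundance(areas_path, samples_path) -> AbundanceMatrix:
    areas = pd.read_csv(areas_path, sep="\t", index_col="peptide_id",
                        float_precision="round_trip")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    samples.index = samples.index.astype(str)
    areas.columns = areas.columns.astype(str)
    return AbundanceMatrix(areas, samples)


# ---------------------------------------------------------------------------
# Secretion tables


def write_secretion(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_secretion(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# PK datasets


def write_pk_dataset(ds: PKDataset, path) -> None:
    df = pd.DataFrame(
        {
            "time_min": ds.times,
            "concentration": ds.concentrations,
            "unit": ds.unit,
            "route": ds.route,
            "dose_mg_per_kg": ds.dose,
            "analyte": ds.analyte,
            "mw_g_per_mol": ds.molecular_weight if ds.molecular_weight else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pk_dataset(path) -> PKDataset:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    mw = df["mw_g_per_mol"].iloc[0]
    return PKDataset(
        route=str(df["route"].iloc[0]),
        dose=float(df["dose_mg_per_kg"].iloc[0]),
        times=df["time_min"].to_numpy(dtype=float),
        concentrations=df["concentration"].to_numpy(dtype=float),
        unit=str(df["unit"].iloc[0]),
        analyte=str(df["analyte"].iloc[0]),
        molecular_weight=None if pd.isna(mw) else float(mw),
    )
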