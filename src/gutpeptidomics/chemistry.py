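"""Monoisotopic mass and m/z arithmetic for modified peptides.

Masses are monoisotopic throughout, matching high-resolution Orbitrap
identification practice.  The modification registry covers the set used in
endogenous-peptidomics searches of secretory tissue: C-terminal amidation,
N-terminal pyroglutamate (from Gln or Glu), N-terminal acetylation,
carbamidomethyl-Cys (reduction/alkylation artefact), phosphorylation and
the ghrelin acylations (octanoyl, decanoyl).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


#: Monoisotopic residue masses (Da) of the 20 canonical amino acids.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER = 18.0105646863
PROTON = 1.007276

#: Peptide length limit of the upstream database search.
MAX_PEPTIDE_LENGTH = 65


@dataclass(frozen=True)
class ModSpec:
    """A named modification: where it attaches and its monoisotopic shift.

    ``site`` is one of ``"N-term"``, ``"C-term"`` or ``"residue:<aa>"``
    where ``<aa>`` may list several acceptable residues (e.g.
    ``"residue:STY"`` for phosphorylation).
    """

    name: str
    site: str
    delta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta):
            raise ValueError(f"modification {self.name!r}: delta must be finite")
        if self.site not in ("N-term", "C-term") and not self.site.startswith("residue:"):
            raise ValueError(f"modification {self.name!r}: bad site {self.site!r}")

    @property
    def residues(self) -> str:
        """Acceptable residue letters for a residue-site mod ('' otherwise)."""
        if self.site.startswith("residue:"):
            return self.site.split(":", 1)[1]
        return ""


def default_registry() -> dict[str, ModSpec]:
    """The built-in modification registry.

    Deltas are the standard monoisotopic values: amidation replaces the
    C-terminal OH by NH2 (−0.98402); pyroglutamate cyclises Gln (−NH3,
    −17.02655) or Glu (−H2O, −18.01056); acetylation +42.01057;
    carbamidomethyl +57.02146; phospho +79.96633; octanoyl +126.10447;
    decanoyl +154.13577.
    """
    mods = [
        ModSpec("amidation", "C-term", -0.98402),
        ModSpec("pyroglu_Q", "N-term", -17.02655),
        ModSpec("pyroglu_E", "N-term", -18.01056),
        ModSpec("acetyl", "N-term", +42.01057),
        ModSpec("carbamidomethyl", "residue:C", +57.02146),
        ModSpec("phospho", "residue:STY", +79.96633),
        ModSpec("octanoyl", "residue:ST", +126.10447),
        ModSpec("decanoyl", "residue:ST", +154.13577),
    ]
    return {m.name: m for m in mods}


def registry_to_tsv(registry: dict[str, ModSpec], path) -> None:
    """Serialise a modification registry as TSV (name, site, delta)."""
    with open(path, "w") as fh:
        fh.write("name\tsite\tdelta\n")
        for m in registry.values():
            fh.write(f"{m.name}\t{m.site}\t{m.delta:.5f}\n")


def registry_from_tsv(path) -> dict[str, ModSpec]:
    """Read a modification registry written by :func:`registry_to_tsv`."""
    registry: dict[str, ModSpec] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["name", "site", "delta"]:
            raise ValueError(f"unexpected registry header: {header}")
        for line in fh:
            name, site, delta = line.rstrip("\n").split("\t")
            if name in registry:
                raise ValueError(f"duplicate modification name {name!r}")
            registry[name] = ModSpec(name, site, float(delta))
    return registry


@dataclass
class ModifiedPeptide:
    """An amino-acid sequence plus a list of (ModSpec, position) pairs.

    Positions are 1-based on the peptide.  Terminal mods must sit at the
    corresponding terminus; at most one N-terminal and one C-terminal mod.
    """

    sequence: str
    mods: list[tuple[ModSpec, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        n_term = sum(1 for m, _ in self.mods if m.site == "N-term")
        c_term = sum(1 for m, _ in self.mods if m.site == "C-term")
        if n_term > 1 or c_term > 1:
            raise ValueError("at most one N-terminal and one C-terminal mod allowed")
        for mod, pos in self.mods:
            if mod.site == "N-term" and pos != 1:
                raise ValueError(f"N-terminal mod {mod.name} must be at position 1")
            if mod.site == "C-term" and pos != len(self.sequence):
                raise ValueError(f"C-terminal mod {mod.name} must be at the last position")
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod {mod.name} position {pos} outside peptide")
            if mod.residues and self.sequence[pos - 1] not in mod.residues:
                raise ValueError(
                    f"mod {mod.name} requires one of {mod.residues!r} at position {pos}, "
                    f"found {self.sequence[pos - 1]!r}"
                )


def validate_sequence(sequence: str) -> None:
    """Raise ValueError unless ``sequence`` is 1–65 canonical residues."""
    if not 1 <= len(sequence) <= MAX_PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide length {len(sequence)} outside 1..{MAX_PEPTIDE_LENGTH}"
        )
    for i, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} at position {i}")


def monoisotopic_mass(peptide: ModifiedPeptide | str) -> float:
    """Monoisotopic mass (Da) of a peptide: residues + water + mod deltas."""
    if isinstance(peptide, str):
        peptide = ModifiedPeptide(peptide)
    mass = WATER + sum(RESIDUE_MASS[aa] for aa in peptide.sequence)
    mass += sum(mod.delta for mod, _ in peptide.mods)
    return mass


def mz(mass: float, charge: int) -> float:
    """m/z of a [M+zH]z+ ion; charge must be a positive integer."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON) / charge
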