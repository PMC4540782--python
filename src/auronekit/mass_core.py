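"""Exact peptide/protein mass arithmetic with crosslink and modification deltas.

Every calculated mass in the package rests on this module: residue masses on
the monoisotopic and average scales, water and proton constants, and the
bookkeeping for disulfide/thioether crosslinks (each costing two hydrogens)
and covalent modifications.  Chain coordinates are 1-based inclusive on the
mature protein (transit peptide excluded before any computation).

Conventions
-----------
* Intact-protein masses are compared on the **average** scale; peptide-level
  masses on the **monoisotopic** scale.
* A crosslink removes ``2 H``: 2 x 1.00794 Da (average), 2 x 1.00783 Da
  (monoisotopic).
* The proton mass is 1.00728 Da (electron mass neglected).
* The generic "+X" modification observed on the active enzyme is modelled as
  exactly +80.00 Da on the average scale; the peptide-level candidates carry
  their true monoisotopic deltas (phospho +79.96633, sulfo +79.95682).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

Scale = Literal["mono", "avg"]

PROTON: float = 1.00728
H2_MONO: float = 2 * 1.00783
H2_AVG: float = 2 * 1.00794
WATER_MONO: float = 18.010565
WATER_AVG: float = 18.01528

# Monoisotopic residue masses (Da), standard 20 amino acids.
_RESIDUE_MONO = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

# Average residue masses (Da).
_RESIDUE_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

STANDARD_RESIDUES = frozenset(_RESIDUE_MONO)


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue and constant masses on both scales.

    The default instance holds the standard 20 amino acids; alternative
    tables (e.g. with fixed carbamidomethyl-Cys) can be derived by replacing
    entries.
    """

    residue_mono: dict[str, float] = field(default_factory=lambda: dict(_RESIDUE_MONO))
    residue_avg: dict[str, float] = field(default_factory=lambda: dict(_RESIDUE_AVG))
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON

    def residues(self, scale: Scale) -> dict[str, float]:
        _check_scale(scale)
        return self.residue_mono if scale == "mono" else self.residue_avg

    def water(self, scale: Scale) -> float:
        _check_scale(scale)
        return self.water_mono if scale == "mono" else self.water_avg

    def h2(self, scale: Scale) -> float:
        """Mass of the two hydrogens removed per crosslink."""
        _check_scale(scale)
        return H2_MONO if scale == "mono" else H2_AVG

    def to_tsv(self, path: str | Path) -> None:
        """Export the table for audit (residue, mono, avg)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["residue", "monoisotopic_da", "average_da"])
            for letter in sorted(self.residue_mono):
                w.writerow([letter, self.residue_mono[letter], self.residue_avg[letter]])
            w.writerow(["water", self.water_mono, self.water_avg])
            w.writerow(["proton", self.proton, self.proton])


DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class ModificationSpec:
    """A covalent modification with per-scale mass deltas.

    ``targets`` names residue letters or the terminus flags ``"nterm"`` /
    ``"cterm"`` the modification may sit on; it is annotation only — mass
    computation does not localize.
    """

    name: str
    delta_mono: float
    delta_avg: float
    targets: frozenset[str] = frozenset()
    max_count: int = 1

    def __post_init__(self) -> None:
        if self.max_count < 0:
            raise ValueError("max_count must be >= 0")
        for d in (self.delta_mono, self.delta_avg):
            if d != d or d in (float("inf"), float("-inf")):
                raise ValueError("modification deltas must be finite")

    def delta(self, scale: Scale) -> float:
        _check_scale(scale)
        return self.delta_mono if scale == "mono" else self.delta_avg


# Catalog of the modifications relevant to aurone synthase proteoforms.
MOD_X80 = ModificationSpec("X(+80)", 80.0, 80.0, frozenset({"Y", "S", "T"}))
MOD_PHOSPHO = ModificationSpec("phospho", 79.96633, 79.9799, frozenset({"Y", "S", "T"}))
MOD_SULFO = ModificationSpec("sulfo", 79.95682, 80.0632, frozenset({"Y"}))
MOD_OXIDATION = ModificationSpec("oxidation", 15.99491, 15.9994,
                                 frozenset({"M", "W", "H", "C"}), max_count=3)
MOD_CARBAMIDOMETHYL = ModificationSpec("carbamidomethyl", 57.02146, 57.0513,
                                       frozenset({"C"}))


@dataclass(frozen=True)
class CrosslinkSpec:
    """A covalent bridge costing two hydrogens per link.

    Disulfides open under reducing conditions; the Cys-His thioether of plant
    catechol oxidases does not.
    """

    kind: Literal["disulfide", "thioether"]
    reducible: bool

    def __post_init__(self) -> None:
        if self.kind == "thioether" and self.reducible:
            raise ValueError("a thioether crosslink is not reducible")

    def delta_per_link(self, scale: Scale) -> float:
        return -DEFAULT_TABLE.h2(scale)


DISULFIDE = CrosslinkSpec("disulfide", reducible=True)
THIOETHER = CrosslinkSpec("thioether", reducible=False)


@dataclass(frozen=True)
class Chain:
    """One independently hydrolyzed backbone (contributes one water).

    ``start``/``end`` are 1-based inclusive coordinates in the mature
    protein.
    """

    id: str
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.id!r}: sequence must be non-empty")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"chain {self.id!r}: coordinates {self.start}-{self.end} do not "
                f"match sequence length {len(self.sequence)}"
            )
        _validate_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteoformHypothesis:
    """Chains + crosslink counts + modifications + reduction condition.

    Under ``condition="reducing"`` the effective disulfide count used in the
    mass computation is zero; the thioether count is unchanged.
    """

    chains: tuple[Chain, ...]
    n_disulfide: int = 0
    n_thioether: int = 0
    modifications: tuple[tuple[ModificationSpec, int], ...] = ()
    condition: Literal["non_reducing", "reducing"] = "non_reducing"

    def __post_init__(self) -> None:
        if self.n_disulfide < 0 or self.n_thioether < 0:
            raise ValueError("crosslink counts must be >= 0")

    @property
    def effective_disulfides(self) -> int:
        return 0 if self.condition == "reducing" else self.n_disulfide

    @property
    def n_modifications(self) -> int:
        return sum(count for _, count in self.modifications)

    def label(self) -> str:
        """Human-readable summary, Table-2 style ('//' joins chains)."""
        seq = "//".join(
            f"{c.sequence[:3]}−{c.sequence[-6:]}" if len(c) > 12 else c.sequence
            for c in self.chains
        )
        mods = "".join(
            f" + {count}x{m.name}" if count > 1 else f" + {m.name}"
            for m, count in self.modifications if count
        )
        return seq + mods


def _check_scale(scale: str) -> None:
    if scale not in ("mono", "avg"):
        raise ValueError(f"scale must be 'mono' or 'avg', got {scale!r}")


def _validate_sequence(sequence: str) -> None:
    for pos, letter in enumerate(sequence, start=1):
        if letter not in STANDARD_RESIDUES:
            raise ValueError(
                f"unknown residue {letter!r} at position {pos}"
            )


def chain_mass(chain: Chain | str, scale: Scale,
               table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral mass of one backbone: sum of residues plus one water.

    Accepts a :class:`Chain` or a bare sequence string.
    """
    sequence = chain.sequence if isinstance(chain, Chain) else chain
    if not sequence:
        raise ValueError("sequence must be non-empty")
    _validate_sequence(sequence)
    residues = table.residues(scale)
    return sum(residues[c] for c in sequence) + table.water(scale)


def proteoform_mass(h: ProteoformHypothesis, scale: Scale,
                    table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral mass of a proteoform hypothesis.

    Sum of chain masses, minus 2 H per effective crosslink (disulfides are
    switched off under reducing conditions, the thioether never is), plus the
    modification deltas.
    """
    if not h.chains:
        raise ValueError("hypothesis must contain at least one chain")
    total = sum(chain_mass(c, scale, table) for c in h.chains)
    n_links = h.effective_disulfides + h.n_thioether
    total -= n_links * table.h2(scale)
    for mod, count in h.modifications:
        if count < 0 or count > mod.max_count:
            raise ValueError(
                f"modification {mod.name!r}: count {count} outside [0, {mod.max_count}]"
            )
        total += count * mod.delta(scale)
    return total


def mz_from_mass(neutral: float, z: int,
                 table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """m/z of the z-fold protonated ion of a neutral species."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral + z * table.proton) / z


def mass_from_mz(observed: float, z: int,
                 table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral mass implied by an observed m/z at charge z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if observed <= table.proton:
        raise ValueError(f"observed m/z {observed} is not physical")
    return z * (observed - table.proton)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    accession: str
    description: str
    sequence: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read single- or multi-record FASTA.

    The accession is taken from the second ``|``-field of UniProt-style
    headers (``db|ACC|name``), otherwise from the record id.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        accession = parts[1] if len(parts) >= 3 else rec.id
        records.append(FastaRecord(rec.id, accession, rec.description,
                                   str(rec.seq).upper()))
    return records
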