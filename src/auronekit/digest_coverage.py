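"""In-silico tryptic digestion and peptide-to-protein sequence coverage.

Trypsin cleaves C-terminal to Lys/Arg except when the next residue is
proline.  Coverage is the fraction of protein residues touched by at least
one exact peptide match (every substring occurrence counts; overlaps count
once), reported both as an exact percentage and as a round-half-up integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int       # 1-based inclusive
    end: int
    missed_cleavages: int


@dataclass(frozen=True)
class DigestResult:
    peptides: tuple[Peptide, ...]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]


@dataclass
class CoverageMask:
    protein_length: int
    covered: np.ndarray

    def __post_init__(self) -> None:
        self.covered = np.asarray(self.covered, dtype=bool)
        if len(self.covered) != self.protein_length:
            raise ValueError("mask length inconsistent with protein_length")

    @property
    def n_covered(self) -> int:
        return int(self.covered.sum())


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices after which trypsin cleaves (K/R not before P)."""
    return [i for i in range(len(sequence) - 1)
            if sequence[i] in "KR" and sequence[i + 1] != "P"]


def tryptic_digest(sequence: str, missed_max: int = 0) -> DigestResult:
    """All tryptic peptides with up to ``missed_max`` missed cleavages.

    The zero-missed peptides tile the protein exactly.
    """
    sequence = sequence.upper()
    if missed_max < 0:
        raise ValueError("missed_max must be >= 0")
    bounds = [0] + [i + 1 for i in cleavage_sites(sequence)] + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_max, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(Peptide(sequence[start:end], start + 1, end,
                                    missed_cleavages=j - i - 1))
    peptides.sort(key=lambda p: (p.start, p.end))
    return DigestResult(tuple(peptides))


def map_peptides(protein: str, peptide_sequences: Iterable[str]
                 ) -> tuple[CoverageMask, list[str]]:
    """Mark every exact substring occurrence of every peptide as covered.

    Matching is case-insensitive and does not equate Ile/Leu.  Returns the
    coverage mask and the list of peptides with no match.
    """
    protein = protein.upper()
    mask = np.zeros(len(protein), dtype=bool)
    unmatched = []
    for pep in peptide_sequences:
        pep_u = pep.upper()
        if not pep_u:
            continue
        hit = False
        start = protein.find(pep_u)
        while start != -1:
            mask[start:start + len(pep_u)] = True
            hit = True
            start = protein.find(pep_u, start + 1)
        if not hit:
            unmatched.append(pep)
    return CoverageMask(len(protein), mask), unmatched


def coverage_percent(mask: CoverageMask) -> tuple[float, int]:
    """Coverage as (exact float percent, round-half-up integer percent)."""
    if mask.protein_length <= 0:
        raise ValueError("protein_length must be > 0")
    pct = 100.0 * mask.n_covered / mask.protein_length
    return pct, int(floor(pct + 0.5))
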