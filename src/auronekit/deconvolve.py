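"""Charge deconvolution of multiply-protonated ESI peak lists.

A 40–60 kDa protein electrosprayed in positive mode appears as an envelope of
peaks at ``(M + z*H+)/z`` for a contiguous window of charge states.  The
neutral mass is recovered from the adjacent-charge relation: for two peaks
``a > b`` belonging to the same species at charges ``z`` and ``z+1``,

    z = (b - proton) / (a - b)

is (nearly) integer, and both peaks must map to the same neutral mass.  All
candidate neutral masses that survive this consistency check are clustered
(single linkage) within a mass tolerance; each cluster is reported as an
intensity-weighted mean with its spread across charge states.

Estimates supported by fewer than two charge states are discarded as
unverifiable — a single peak never determines a mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mass_core import PROTON

# Cluster tolerances matching the experimental spreads: +-0.3–1.7 Da for
# intact proteins, low-mDa for peptides.
DEFAULT_TOL_INTACT = 1.0
DEFAULT_TOL_PEPTIDE = 0.02
DEFAULT_Z_INTACT = (20, 60)
DEFAULT_Z_PEPTIDE = (1, 4)


@dataclass
class PeakList:
    """Centroided stick spectrum: m/z (strictly increasing) and intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.mz)

    @classmethod
    def from_pairs(cls, pairs, metadata=None) -> "PeakList":
        """Build from (mz, intensity) pairs in any order; co-incident m/z
        values are merged by summing intensities."""
        arr = np.asarray(list(pairs), dtype=float)
        if arr.size == 0:
            return cls(np.array([]), np.array([]), metadata or {})
        mz, inv = np.unique(arr[:, 0], return_inverse=True)
        inten = np.zeros_like(mz)
        np.add.at(inten, inv, arr[:, 1])
        return cls(mz, inten, metadata or {})

    @classmethod
    def read(cls, path: str | Path, metadata=None) -> "PeakList":
        """Two-column TSV/CSV (mz, intensity); header line optional."""
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else r"\s+"
        df = pd.read_csv(path, sep=sep, comment="#", header=None,
                         skip_blank_lines=True)
        # drop a header row if the first row is not numeric
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        df = df.astype(float)
        return cls.from_pairs(df.iloc[:, :2].to_numpy(), metadata)

    def write(self, path: str | Path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class ChargeAssignment:
    mz: float
    intensity: float
    z: int
    neutral_mass: float


@dataclass(frozen=True)
class NeutralMassEstimate:
    """Deconvolution output: mass +- spread across supporting charge states."""

    mass: float
    mass_sd: float
    z_support: frozenset[int]
    total_intensity: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.mass_sd < 0:
            raise ValueError("mass_sd must be >= 0")


def assign_charges(peaks: PeakList, z_range: tuple[int, int] = DEFAULT_Z_INTACT,
                   tol_da: float = DEFAULT_TOL_INTACT) -> list[ChargeAssignment]:
    """Charge states from the adjacent-charge relation on all peak pairs.

    For peaks ``a > b`` (m/z), the charge of ``a`` is estimated as
    ``round((b - proton)/(a - b))``; the pair is kept only when both members
    map to the same neutral mass within ``tol_da``.  Returns one assignment
    per distinct (peak, charge); an empty list when nothing is consistent.
    """
    zmin, zmax = z_range
    if not (1 <= zmin <= zmax <= 100):
        raise ValueError(f"z_range must lie within [1, 100], got {z_range}")
    if len(peaks) < 2:
        return []
    mz = peaks.mz
    inten = peaks.intensity
    out: dict[tuple[int, int], ChargeAssignment] = {}
    n = len(mz)
    for i in range(n):          # b = mz[i] at charge z+1
        for j in range(i + 1, n):   # a = mz[j] at charge z
            a, b = mz[j], mz[i]
            z_est = (b - PROTON) / (a - b)
            z = int(round(z_est))
            if z < zmin or z + 1 > zmax:
                continue
            m_a = z * (a - PROTON)
            m_b = (z + 1) * (b - PROTON)
            if abs(m_a - m_b) > tol_da:
                continue
            out.setdefault((j, z), ChargeAssignment(a, inten[j], z, m_a))
            out.setdefault((i, z + 1), ChargeAssignment(b, inten[i], z + 1, m_b))
    return sorted(out.values(), key=lambda c: (c.mz, c.z))


def deconvolute(peaks: PeakList, z_range: tuple[int, int] = DEFAULT_Z_INTACT,
                tol_da: float = DEFAULT_TOL_INTACT) -> list[NeutralMassEstimate]:
    """Neutral masses of the species present in a multiply-charged spectrum.

    Candidate neutral masses from :func:`assign_charges` are clustered by
    single linkage at ``tol_da``; clusters supported by at least two charge
    states are reported as intensity-weighted mean +- sd, sorted by total
    intensity (descending).
    """
    if len(peaks) == 0:
        raise ValueError("peak list is empty")
    assignments = assign_charges(peaks, z_range, tol_da)
    if not assignments:
        return []
    assignments.sort(key=lambda c: c.neutral_mass)
    masses = np.array([c.neutral_mass for c in assignments])
    breaks = np.flatnonzero(np.diff(masses) > tol_da) + 1
    estimates = []
    for cluster in np.split(np.arange(len(assignments)), breaks):
        members = [assignments[k] for k in cluster]
        z_support = frozenset(c.z for c in members)
        if len(z_support) < 2:
            continue
        w = np.array([c.intensity for c in members])
        m = np.array([c.neutral_mass for c in members])
        if w.sum() <= 0:
            w = np.ones_like(w)
        mean = float(np.average(m, weights=w))
        sd = float(np.sqrt(np.average((m - mean) ** 2, weights=w)))
        estimates.append(NeutralMassEstimate(
            mass=mean, mass_sd=sd, z_support=z_support,
            total_intensity=float(sum(c.intensity for c in members))))
    estimates.sort(key=lambda e: -e.total_intensity)
    return estimates


def estimates_to_dataframe(estimates: list[NeutralMassEstimate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"mass_da": e.mass, "mass_sd_da": e.mass_sd,
         "z_min": min(e.z_support), "z_max": max(e.z_support),
         "n_charges": len(e.z_support), "total_intensity": e.total_intensity}
        for e in estimates
    ])


def write_estimates(estimates: list[NeutralMassEstimate], path: str | Path,
                    fmt: str = "tsv") -> None:
    if fmt == "tsv":
        estimates_to_dataframe(estimates).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = [
            {"mass_da": e.mass, "mass_sd_da": e.mass_sd,
             "z_support": sorted(e.z_support), "total_intensity": e.total_intensity}
            for e in estimates
        ]
        Path(path).write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")
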