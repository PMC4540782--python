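"""Proteoform hypothesis enumeration and tolerance matching.

The active aurone synthase is a ragged-ended two-chain species: a catalytic
core with an unspecifically proteolyzed C-terminus, plus a short C-terminal
peptide attached through a disulfide; the latent pro-enzyme is a single chain
with its own ragged C-terminus.  On top of the backbone variants sit a
generic +80 Da modification (phosphorylation or sulfation — the intact-mass
data cannot distinguish them) and up to a few ~16 Da oxidations.

This module enumerates that hypothesis space as a Cartesian product of
C-terminal windows, peptide presence, modification counts and reduction
condition, computes each hypothesis mass through
:func:`auronekit.mass_core.proteoform_mass`, and matches the deconvoluted
neutral masses against it with parsimony-aware ranking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .mass_core import (
    Chain,
    ModificationSpec,
    ProteoformHypothesis,
    MOD_OXIDATION,
    Scale,
    proteoform_mass,
)
from .deconvolve import NeutralMassEstimate

# Default match tolerances: from the printed experimental spreads (intact)
# and the stated instrument accuracy (peptide scale).
DEFAULT_INTACT_TOL_FLOOR = 0.5   # Da
DEFAULT_PEPTIDE_TOL_PPM = 5.0


@dataclass(frozen=True)
class SearchSpace:
    """The proteoform hypothesis space for one mature sequence.

    Windows are 1-based inclusive coordinate intervals on the mature
    protein.  ``core_end_window`` enumerates the ragged C-terminus of the
    catalytic core; ``attached_peptide`` is ``(start, (end_lo, end_hi))`` for
    the disulfide-attached C-terminal peptide; ``latent_end_window``
    enumerates the uncleaved pro-enzyme C-terminus.  Disulfide counts per
    topology are declared, not inferred from cysteine positions.
    """

    sequence: str
    core_end_window: tuple[int, int] | None = None
    attached_peptide: tuple[int, tuple[int, int]] | None = None
    latent_end_window: tuple[int, int] | None = None
    mods: tuple[ModificationSpec, ...] = ()
    oxidation_max: int = 0
    conditions: tuple[str, ...] = ("non_reducing",)
    n_disulfide_core_only: int = 2
    n_disulfide_with_peptide: int = 3
    n_disulfide_latent: int = 3
    n_thioether: int = 1

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, win in (("core_end_window", self.core_end_window),
                          ("latent_end_window", self.latent_end_window)):
            if win is not None and not (1 <= win[0] <= win[1] <= n):
                raise ValueError(f"{name} {win} outside sequence bounds 1..{n}")
        if self.attached_peptide is not None:
            start, (lo, hi) = self.attached_peptide
            if not (1 <= start <= lo <= hi <= n):
                raise ValueError(
                    f"attached_peptide ({start}, ({lo}, {hi})) outside 1..{n}")
            if self.core_end_window is not None and self.core_end_window[1] >= start:
                raise ValueError("core_end_window overlaps attached peptide")


@dataclass(frozen=True)
class Assignment:
    hypothesis: ProteoformHypothesis
    calc_mass: float
    observed: NeutralMassEstimate
    delta_da: float       # observed.mass - calc_mass
    delta_ppm: float
    rank: int


def _subchain(sequence: str, label: str, start: int, end: int) -> Chain:
    return Chain(label, sequence[start - 1:end], start, end)


def _mod_combinations(space: SearchSpace):
    """All modification-count vectors, unmodified first (deterministic)."""
    mods = list(space.mods)
    if space.oxidation_max > 0:
        ox = ModificationSpec(MOD_OXIDATION.name, MOD_OXIDATION.delta_mono,
                              MOD_OXIDATION.delta_avg, MOD_OXIDATION.targets,
                              max_count=space.oxidation_max)
        mods.append(ox)
    ranges = [range(m.max_count + 1) for m in mods]
    for counts in itertools.product(*ranges):
        yield tuple((m, c) for m, c in zip(mods, counts) if c > 0)


def enumerate_hypotheses(space: SearchSpace) -> list[ProteoformHypothesis]:
    """Cartesian product of backbone topology x modifications x condition.

    Topologies, in deterministic order: core alone (per core end), core with
    attached peptide (per core end x peptide end), latent single chain (per
    latent end).
    """
    topologies: list[tuple[tuple[Chain, ...], int]] = []
    if space.core_end_window is not None:
        lo, hi = space.core_end_window
        for core_end in range(lo, hi + 1):
            core = _subchain(space.sequence, "core", 1, core_end)
            topologies.append(((core,), space.n_disulfide_core_only))
            if space.attached_peptide is not None:
                p_start, (p_lo, p_hi) = space.attached_peptide
                for p_end in range(p_lo, p_hi + 1):
                    pep = _subchain(space.sequence, "peptide", p_start, p_end)
                    topologies.append(((core, pep), space.n_disulfide_with_peptide))
    if space.latent_end_window is not None:
        lo, hi = space.latent_end_window
        for end in range(lo, hi + 1):
            latent = _subchain(space.sequence, "latent", 1, end)
            topologies.append(((latent,), space.n_disulfide_latent))

    out = []
    for condition in space.conditions:
        for chains, n_ds in topologies:
            for mods in _mod_combinations(space):
                out.append(ProteoformHypothesis(
                    chains=chains, n_disulfide=n_ds,
                    n_thioether=space.n_thioether,
                    modifications=mods, condition=condition))
    return out


def match(observed: list[NeutralMassEstimate], space: SearchSpace,
          tol: float | None = None, scale: Scale = "avg"
          ) -> list[Assignment]:
    """Pair every observed mass with all hypotheses within tolerance.

    The per-estimate tolerance defaults to ``max(3 * mass_sd, 0.5 Da)``.
    Candidates are ranked by |delta|; ties break toward parsimony (fewer
    modifications, then fewer chains), so an oxidized satellite never
    outranks an unmodified hypothesis at equal |delta|.  Estimates with no
    hypothesis in tolerance yield no assignments; see
    :func:`unmatched_estimates`.
    """
    if not observed:
        raise ValueError("no observed estimates given")
    hypotheses = enumerate_hypotheses(space)
    if not hypotheses:
        raise ValueError("search space enumerates no hypotheses")
    calc = [(h, proteoform_mass(h, scale)) for h in hypotheses]
    out: list[Assignment] = []
    for est in observed:
        tol_i = tol if tol is not None else max(3 * est.mass_sd,
                                                DEFAULT_INTACT_TOL_FLOOR)
        cands = [(h, m) for h, m in calc if abs(est.mass - m) <= tol_i]
        cands.sort(key=lambda hm: (abs(est.mass - hm[1]),
                                   hm[0].n_modifications, len(hm[0].chains)))
        for rank, (h, m) in enumerate(cands, start=1):
            delta = est.mass - m
            out.append(Assignment(h, m, est, delta, 1e6 * delta / m, rank))
    return out


def unmatched_estimates(observed: list[NeutralMassEstimate],
                        assignments: list[Assignment]
                        ) -> list[NeutralMassEstimate]:
    matched = {id(a.observed) for a in assignments}
    return [e for e in observed if id(e) not in matched]


@dataclass(frozen=True)
class ShiftExplanation:
    components: tuple[str, ...]
    delta: float
    error: float


# Known average-scale deltas for explaining intact-mass differences: the
# +80 candidates, oxidation, water, one crosslink (2H), single-residue
# losses.
_SHIFT_CATALOG: tuple[tuple[str, float], ...] = (
    ("phosphorylation", 79.9799),
    ("sulfation", 80.0632),
    ("oxidation", 15.9994),
    ("water", 18.01528),
    ("2H (one crosslink)", 2.01588),
    ("loss of Gly", 57.0519), ("loss of Ala", 71.0788),
    ("loss of Ser", 87.0782), ("loss of Pro", 97.1167),
    ("loss of Val", 99.1326), ("loss of Thr", 101.1051),
    ("loss of Cys", 103.1388), ("loss of Leu/Ile", 113.1594),
    ("loss of Asn", 114.1038), ("loss of Asp", 115.0886),
    ("loss of Gln", 128.1307), ("loss of Lys", 128.1741),
    ("loss of Glu", 129.1155), ("loss of Met", 131.1926),
    ("loss of His", 137.1411), ("loss of Phe", 147.1766),
    ("loss of Arg", 156.1875), ("loss of Tyr", 163.1760),
    ("loss of Trp", 186.2132),
)


def explain_shift(m1: float, m2: float, tol: float) -> list[ShiftExplanation]:
    """Combinations (<= 2 items) of known deltas matching |m1 - m2|.

    Sorted by absolute error; empty when nothing matches within ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    target = abs(m1 - m2)
    found: list[ShiftExplanation] = []
    for k in (1, 2):
        for combo in itertools.combinations_with_replacement(_SHIFT_CATALOG, k):
            s = sum(d for _, d in combo)
            err = s - target
            if abs(err) <= tol:
                found.append(ShiftExplanation(
                    tuple(name for name, _ in combo), s, err))
    found.sort(key=lambda e: (abs(e.error), len(e.components)))
    return found
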