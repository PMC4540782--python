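"""Synthetic generators for every input the pipeline consumes.

All generators are deterministic under an integer seed and implement their
forward models in code paths separate from the fitting module, so parameter
recovery tests are non-circular: the suicide generator integrates the decay
ODE numerically while the fitter's model is the closed form, and the latent
activation generator uses the piecewise analytic solution while the
simulator in :mod:`auronekit.kinetics` integrates with fixed steps.

The module also ships ``SYNTHETIC_AUS1_MATURE``, a **synthetic stand-in**
for the mature aurone synthase sequence (the real accession is not bundled):
a 517-residue sequence whose residue composition was solved so that the
crosslink/cleavage mass bookkeeping reproduces the published intact-mass
values of the active two-chain species, its reduced core, and the latent
pro-enzyme.  Architecture: catalytic core A1..E350 ("API...IENSKE"), a
linker 351-437 removed on proteolytic activation, the disulfide-attached
peptide 438-452 (DGVFTTPCDPEYAGG, the real deduced sequence), and a
C-terminal tail 453-517 ending "...PIPKA".  Only the mass arithmetic is
faithful; the composition outside the fixed anchors is not biological.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mass_core import PROTON
from .deconvolve import PeakList
from .digest_coverage import CoverageMask, map_peptides, tryptic_digest
from .kinetics import InitialRateSet, ProgressCurve

# --------------------------------------------------------------------------
# Synthetic stand-in for the mature aurone synthase sequence (see module
# docstring).  517 aa; average-scale chain masses reproduce the published
# calculated proteoform masses within 0.003 Da.
SYNTHETIC_AUS1_MATURE = (
    "APIRPGRKHQHCAREQCKPSCNVQDVHYAEVTGRTQPGCCGLINQYPGCRTRDLQVCSPE"
    "HVHDGNLPQYQTGINDKCAMVMDNFYGARRKKIGPIYSDKQVRNSNRILTKQCYIRKIIF"
    "QSICHLNKQHKGKDPAKRKITTPAYVYEGILSITTVYSIVGCKIGENNYYNQRCHNCKAH"
    "EHNTHFRNMTNQLFDEISRHDVSTQIDLIGTIIEFDSGVRHNRGRSSDTIEGVQPPGHIV"
    "EIEDTTQSQICRASPQQLVQDQECAKLYPAAHDMCKHGHGHFKIIASCSSKVCICHYKAR"
    "CDTRYCFIMIKCNNMRFVSLDQTMKSCAPCYKTHRMIFLGRVDKIENSKEGHHSQVSKKD"
    "SMGSGCCHSCTKVVMHCVRLPRFPMHKEQFAYTTPCIKIRYEVKCQLGDGTCVDFDTQFV"
    "FLHLGYGCIIPLQCSPLDGVFTTPCDPEYAGGKARGYVATMQHHNHASDHVSHRKHDHGM"
    "YQFNLIPCQRQDGHIKFTHQPQQHKMPNPHSHPIPKA"
)

# Stand-in coordinates (1-based inclusive, mature numbering).
CORE_END = 350            # core = 1..350, "API...IENSKE"
LINKER_SPAN = (351, 437)  # removed on proteolytic activation
PEPTIDE_SPAN = (438, 452)  # DGVFTTPCDPEYAGG, stays disulfide-attached
MATURE_END = 517          # latent pro-enzyme ends "...PIPKA"


@dataclass(frozen=True)
class SynthSpec:
    """Scenario + parameters for reproducible generation."""

    seed: int
    scenario: str             # envelope | mixture | rates | suicide | latent | digest
    parameters: dict = field(default_factory=dict)


def synth_charge_envelope(mass: float, z_range: tuple[int, int],
                          ppm_noise: float = 0.0,
                          intensity_model: str = "gaussian",
                          seed: int = 0, amplitude: float = 100.0) -> PeakList:
    """Stick spectrum of one multiply-protonated species.

    One stick per charge in ``z_range`` at ``(M + z*H+)/z`` with Gaussian
    m/z jitter of ``ppm_noise`` ppm and a Gaussian-shaped intensity envelope
    over charge states (or flat with ``intensity_model="flat"``).
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    zmin, zmax = z_range
    if zmin > zmax:
        raise ValueError("empty charge range")
    rng = np.random.default_rng(seed)
    z = np.arange(zmin, zmax + 1)
    mz = (mass + z * PROTON) / z
    if ppm_noise:
        mz = mz * (1.0 + rng.normal(0.0, ppm_noise * 1e-6, size=len(z)))
    if intensity_model == "gaussian":
        center = 0.5 * (zmin + zmax)
        width = max((zmax - zmin) / 4.0, 1.0)
        inten = amplitude * np.exp(-0.5 * ((z - center) / width) ** 2)
    elif intensity_model == "flat":
        inten = np.full(len(z), amplitude)
    else:
        raise ValueError(f"unknown intensity model {intensity_model!r}")
    return PeakList.from_pairs(list(zip(mz, inten)),
                               metadata={"synthetic_mass": mass})


def synth_mixture(masses: Sequence[float], ratios: Sequence[float],
                  z_range: tuple[int, int], ppm_noise: float = 0.0,
                  seed: int = 0, amplitude: float = 100.0) -> PeakList:
    """Superposition of charge envelopes for co-occurring species."""
    if len(masses) != len(ratios):
        raise ValueError("masses and ratios must have equal length")
    pairs = []
    for k, (m, r) in enumerate(zip(masses, ratios)):
        env = synth_charge_envelope(m, z_range, ppm_noise, seed=seed + k,
                                    amplitude=amplitude * r)
        pairs.extend(zip(env.mz, env.intensity))
    return PeakList.from_pairs(pairs, metadata={"synthetic_masses": list(masses)})


def synth_initial_rates(Km: float, Vmax: float, S_grid: Sequence[float],
                        cv: float = 0.0, n_rep: int = 1,
                        seed: int = 0) -> InitialRateSet:
    """Michaelis–Menten initial rates with multiplicative Gaussian noise.

    ``v = Vmax*S/(Km+S) * (1 + N(0, cv))`` per replicate; Km and S in µM.
    """
    if Km <= 0 or Vmax <= 0 or n_rep < 1:
        raise ValueError("Km, Vmax must be > 0 and n_rep >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    S = np.tile(np.asarray(S_grid, dtype=float), n_rep)
    rep = np.repeat(np.arange(n_rep), len(S_grid))
    v = Vmax * S / (Km + S)
    if cv:
        v = v * (1.0 + rng.normal(0.0, cv, size=len(S)))
    return InitialRateSet(S, v, replicate=rep)


def _suicide_forward(E0_nM, r_partition, k_obs, t):
    """Numerical forward model: integrate dP/dt = k_obs*(P_inf - P).

    Deliberately a different code path from the closed form used by the
    fitter.
    """
    P_inf = r_partition * E0_nM * 1e-3
    n_fine = 20 * len(t)
    fine_t = np.linspace(t[0], t[-1], n_fine)
    h = fine_t[1] - fine_t[0]
    P = np.empty(n_fine)
    P[0] = 0.0
    for i in range(1, n_fine):
        # midpoint rule for the linear decay ODE
        k1 = k_obs * (P_inf - P[i - 1])
        k2 = k_obs * (P_inf - (P[i - 1] + 0.5 * h * k1))
        P[i] = P[i - 1] + h * k2
    return np.interp(t, fine_t, P)


def _latent_forward(E0_nM, c_star, a0, v_spec, t):
    """Analytic piecewise solution of the threshold-activation model."""
    vE = v_spec * E0_nM
    alpha = a0 * vE
    beta = (1.0 - a0) * vE / c_star
    t_star = np.log(1.0 + beta * c_star / alpha) / beta
    P = np.where(t < t_star,
                 (alpha / beta) * np.expm1(beta * t),
                 c_star + vE * (t - t_star))
    return P


def latent_onset_time(E0_nM: float, c_star: float, a0: float,
                      v_spec: float) -> float:
    """Time at which the analytic latent curve reaches the critical level."""
    vE = v_spec * E0_nM
    beta = (1.0 - a0) * vE / c_star
    return float(np.log(1.0 + (1.0 - a0) / a0) / beta)


def synth_progress_curves(scenario: str, params: dict,
                          E0_list: Sequence[float], noise_sd: float = 0.0,
                          seed: int = 0) -> list[ProgressCurve]:
    """Progress-curve families for the suicide and latent scenarios.

    ``scenario="suicide"``: params r_partition, k_obs (min^-1), and either
    t_grid or t_max/n_points.  ``scenario="latent"``: params c_star (µM),
    a0, v_spec (µM min^-1 nM^-1), and optionally t_grid; without one, each
    curve is sampled on 400 points up to the time where the product reaches
    ``p_stop`` (default 3*c_star).  Additive Gaussian noise of ``noise_sd``
    (signal units) is applied per point.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    curves = []
    for E0 in E0_list:
        if E0 <= 0:
            raise ValueError("enzyme concentrations must be > 0")
        if scenario == "suicide":
            if "t_grid" in params:
                t = np.asarray(params["t_grid"], dtype=float)
            else:
                t = np.linspace(0.0, params.get("t_max", 60.0),
                                params.get("n_points", 200))
            P = _suicide_forward(E0, params["r_partition"], params["k_obs"], t)
            substrate = params.get("substrate", "sulfuretin")
        elif scenario == "latent":
            c_star, a0, v_spec = params["c_star"], params["a0"], params["v_spec"]
            if "t_grid" in params:
                t = np.asarray(params["t_grid"], dtype=float)
            else:
                p_stop = params.get("p_stop", 3.0 * c_star)
                t_on = latent_onset_time(E0, c_star, a0, v_spec)
                t_end = t_on + (p_stop - c_star) / (v_spec * E0)
                t = np.linspace(0.0, t_end, params.get("n_points", 400))
            P = _latent_forward(E0, c_star, a0, v_spec, t)
            substrate = params.get("substrate", "fisetin")
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        if noise_sd:
            P = P + rng.normal(0.0, noise_sd, size=len(t))
        curves.append(ProgressCurve(t, P, enzyme_conc=float(E0),
                                    substrate=substrate,
                                    substrate_conc0=params.get("S0", float("nan"))))
    return curves


@dataclass
class SyntheticCoverageSample:
    sequence: str
    peptides: list[str]
    mask: CoverageMask
    exact: bool                 # achieved covered count == requested count


_NON_KR = list("ACDEFGHILMNQSTVWY")
_NON_KRP = [c for c in _NON_KR if c != "P"]


def synth_protein_and_peptides(length: int, coverage_target: float,
                               seed: int = 0) -> SyntheticCoverageSample:
    """Random protein plus a tryptic-peptide subset hitting a coverage target.

    The protein is built from random tryptic tiles of length 5-15 (each
    ending K/R, never followed by P), so its zero-missed digest consists of
    unique, unambiguous peptides.  A subset of tiles whose lengths sum to
    ``floor(coverage_target * length)`` is chosen by exact subset-sum DP;
    when no exact subset exists the smallest achievable overshoot is used
    and ``exact`` is False.
    """
    if not 0 <= coverage_target <= 1:
        raise ValueError("coverage_target must lie in [0, 1]")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    chunks = []
    total = 0
    while total < length:
        n = int(rng.integers(5, 16))
        body = "".join(rng.choice(_NON_KR, size=n - 1))
        first = rng.choice(_NON_KRP)
        tile = first + body[:-1] + ("K" if rng.random() < 0.5 else "R")
        chunks.append(tile[: length - total])
        total += len(chunks[-1])
    sequence = "".join(chunks)

    digest = tryptic_digest(sequence, missed_max=0)
    tiles = digest.peptides
    target_count = int(np.floor(coverage_target * length))

    # exact subset-sum over tile lengths
    sums = {0: []}
    for idx, p in enumerate(tiles):
        new = {}
        for s, picks in sums.items():
            s2 = s + len(p.sequence)
            if s2 <= length and s2 not in sums and s2 not in new:
                new[s2] = picks + [idx]
        sums.update(new)
    if target_count in sums:
        chosen, exact = sums[target_count], True
    else:
        feasible = [s for s in sums if s >= target_count]
        best = min(feasible) if feasible else max(sums)
        chosen, exact = sums[best], False
    peptides = [tiles[i].sequence for i in chosen]
    mask, unmatched = map_peptides(sequence, peptides)
    if unmatched or (exact and mask.n_covered != target_count):
        exact = False            # peptide-string collision (vanishingly rare)
    return SyntheticCoverageSample(sequence, peptides, mask, exact)
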