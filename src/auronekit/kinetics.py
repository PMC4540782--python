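"""Enzyme-kinetics models and fitters for aurone synthase.

Covers the photometric workflow end to end:

* Beer–Lambert conversion of absorbance to product concentration using
  differential extinction coefficients (``delta_epsilon``, L mol^-1 cm^-1).
* Michaelis–Menten estimation from initial rates by Levenberg–Marquardt
  nonlinear least squares, with standard errors from the covariance at the
  optimum.
* Catalytic-efficiency (kcat/Km) estimation in the pseudo-first-order regime
  ([S] << Km) by a straight-line fit through the origin.
* Suicide inactivation: during turnover the enzyme irreversibly dies, so the
  product approaches a plateau proportional to the enzyme amount,
  ``P(t) = r * E0 * (1 - exp(-k_obs t))`` with partition ratio ``r``.
* Threshold-triggered allosteric activation of the latent pro-enzyme: the
  reaction product is itself the activator, giving sigmoid lag curves whose
  steady-state rate begins once the product reaches a critical concentration
  ``c*`` that is independent of the enzyme concentration.

Units: concentrations are µM internally (enzyme in nM, converted where
needed), time in minutes, rates in µM min^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats
from scipy.signal import savgol_filter

NM_TO_UM = 1e-3


class KineticsWarning(UserWarning):
    """Diagnostic warnings from the fitters (honest non-convergence etc.)."""


@dataclass(frozen=True)
class ExtinctionEntry:
    """Differential extinction coefficient of a substrate/product pair."""

    substrate: str
    wavelength: float            # nm
    delta_epsilon: float         # L mol^-1 cm^-1
    path_length: float = 1.0     # cm

    def __post_init__(self) -> None:
        if self.delta_epsilon <= 0:
            raise ValueError("delta_epsilon must be > 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")


# Table of assay wavelengths and extinction coefficients for the substrates
# characterized in this project.
EXTINCTION_TABLE = {
    "butein": ExtinctionEntry("butein", 415, 9320),
    "marein": ExtinctionEntry("marein", 425, 13559),
    "fisetin": ExtinctionEntry("fisetin", 280, 5345),
    "4-tert-butylcatechol": ExtinctionEntry("4-tert-butylcatechol", 400, 1150),
    "chlorogenic acid": ExtinctionEntry("chlorogenic acid", 400, 2566),
    "4-methylcatechol": ExtinctionEntry("4-methylcatechol", 400, 1350),
    "catechol": ExtinctionEntry("catechol", 390, 1450),
}


@dataclass
class InitialRateSet:
    """Initial rates at varied substrate concentrations (replicates stacked)."""

    substrate_conc: np.ndarray   # µM
    rate: np.ndarray             # µM min^-1 (or AU min^-1, see extinction)
    replicate: np.ndarray | None = None
    extinction: ExtinctionEntry | None = None

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_conc.shape != self.rate.shape:
            raise ValueError("substrate_conc and rate must have equal length")
        if np.any(self.substrate_conc <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.rate.shape:
                raise ValueError("replicate ids must match data length")


@dataclass
class ProgressCurve:
    """Time series of product (µM) or absorbance with enzyme metadata."""

    time: np.ndarray             # min
    signal: np.ndarray
    enzyme_conc: float           # nM
    substrate: str = ""
    substrate_conc0: float = float("nan")   # µM
    is_concentration: bool = True

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be > 0")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ProgressCurve":
        """CSV with columns time_min, signal and '# key=value' header lines."""
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
        df = pd.read_csv(path, comment="#")
        return cls(df["time_min"].to_numpy(), df["signal"].to_numpy(),
                   enzyme_conc=float(meta.get("enzyme_nM", "nan")),
                   substrate=meta.get("substrate", ""),
                   substrate_conc0=float(meta.get("substrate_uM", "nan")),
                   is_concentration=meta.get("signal_unit", "uM") == "uM")

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# enzyme_nM={self.enzyme_conc}\n")
            if self.substrate:
                fh.write(f"# substrate={self.substrate}\n")
            if np.isfinite(self.substrate_conc0):
                fh.write(f"# substrate_uM={self.substrate_conc0}\n")
            fh.write(f"# signal_unit={'uM' if self.is_concentration else 'AU'}\n")
            pd.DataFrame({"time_min": self.time, "signal": self.signal}
                         ).to_csv(fh, index=False)


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameter estimates with uncertainties."""

    Km: float                    # same units as the input concentrations (µM)
    Km_se: float
    Vmax: float                  # rate units of the input
    Vmax_se: float
    converged: bool
    kcat: float | None = None            # s^-1
    kcat_over_Km: float | None = None    # mM^-1 s^-1
    warning: str | None = None

    @property
    def Km_mM(self) -> float:
        return self.Km * 1e-3


@dataclass(frozen=True)
class EfficiencyFit:
    """Pseudo-first-order catalytic efficiency."""

    slope: float                 # min^-1 (rate per µM substrate)
    slope_se: float
    kcat_over_Km: float | None   # mM^-1 s^-1 (needs enzyme molarity)
    warning: str | None = None


@dataclass(frozen=True)
class SuicideFit:
    P_inf: float                 # µM
    k_obs: float                 # min^-1
    r_partition: float           # product molecules per enzyme molecule
    P_inf_se: float = float("nan")
    k_obs_se: float = float("nan")
    warning: str | None = None


@dataclass(frozen=True)
class AllostericModel:
    """Threshold activation of the latent enzyme by its own product.

    The active fraction rises linearly from the basal value ``a0`` to 1 as
    the product approaches the critical concentration ``c_star``; beyond it
    the enzyme is fully active (piecewise-linear minimal model).
    ``v_spec`` is the fully-active rate per nM enzyme at the assay substrate
    concentration, in µM min^-1 nM^-1.
    """

    c_star: float                # µM
    a0: float
    v_spec: float                # µM min^-1 per nM enzyme

    def __post_init__(self) -> None:
        if self.c_star <= 0:
            raise ValueError("c_star must be > 0")
        if not 0 < self.a0 < 1:
            raise ValueError("a0 must lie in (0, 1)")
        if self.v_spec <= 0:
            raise ValueError("v_spec must be > 0")


def absorbance_to_concentration(signal, entry: ExtinctionEntry):
    """Beer–Lambert: absorbance -> product concentration in µM."""
    return np.asarray(signal, dtype=float) / (
        entry.delta_epsilon * entry.path_length) * 1e6


def concentration_to_absorbance(conc_um, entry: ExtinctionEntry):
    return np.asarray(conc_um, dtype=float) * (
        entry.delta_epsilon * entry.path_length) * 1e-6


def _mm_rate(S, Vmax, Km):
    return Vmax * S / (Km + S)


def fit_michaelis_menten(data: InitialRateSet, init: dict | None = None,
                         enzyme_molar_nM: float | None = None,
                         enzyme_mass: float | None = None) -> MMFit:
    """Levenberg–Marquardt fit of v = Vmax*S/(Km+S).

    Needs at least four distinct substrate concentrations.  If an enzyme
    molarity (nM) is supplied, kcat (s^-1) and kcat/Km (mM^-1 s^-1) are
    derived; alternatively ``enzyme_mass`` (g/mol) converts a mass-specific
    Vmax (µmol min^-1 mg^-1) to kcat.
    """
    S, v = data.substrate_conc, data.rate
    if len(np.unique(S)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    model = Model(_mm_rate, independent_vars=["S"])
    params = model.make_params(
        Vmax=dict(value=(init or {}).get("Vmax", 1.2 * float(v.max())), min=0),
        Km=dict(value=(init or {}).get("Km", float(np.median(S))), min=0),
    )
    result = model.fit(v, params, S=S)
    Km = float(result.params["Km"].value)
    Vmax = float(result.params["Vmax"].value)
    Km_se = float(result.params["Km"].stderr or np.nan)
    Vmax_se = float(result.params["Vmax"].stderr or np.nan)
    converged = bool(result.success) and Km > 0 and Vmax > 0
    warning = None
    if Km > 10 * float(S.max()):
        converged = False
        warning = (f"Km estimate {Km:.3g} lies beyond 10x the largest substrate "
                   "concentration; the data do not constrain saturation")
    elif not result.success:
        warning = "nonlinear fit did not converge"
    if warning:
        warnings.warn(warning, KineticsWarning, stacklevel=2)

    kcat = kcat_over_km = None
    if enzyme_molar_nM is not None:
        kcat = Vmax / (enzyme_molar_nM * NM_TO_UM) / 60.0     # s^-1
        kcat_over_km = kcat / (Km * 1e-3)                     # mM^-1 s^-1
    elif enzyme_mass is not None:
        # Vmax in µmol min^-1 mg^-1: kcat = Vmax * M / 60 / 1e6
        kcat = Vmax * enzyme_mass / 60.0 / 1e6
        kcat_over_km = kcat / (Km * 1e-3)
    return MMFit(Km, Km_se, Vmax, Vmax_se, converged, kcat, kcat_over_km, warning)


def fit_pseudo_first_order(data: InitialRateSet, enzyme_molar_nM: float | None = None,
                           enzyme_mass: float | None = None,
                           assumed_Km_uM: float | None = None) -> EfficiencyFit:
    """Slope of v vs S through the origin, in the [S] << Km regime.

    With the enzyme molarity the slope converts to kcat/Km in mM^-1 s^-1.
    A lack-of-fit check (significant quadratic curvature at the 5 % level)
    warns when the pseudo-first-order assumption fails.
    """
    S, v = data.substrate_conc, data.rate
    if np.any(v < 0):
        raise ValueError("negative rates are not physical")
    if assumed_Km_uM is not None and float(S.max()) > 0.1 * assumed_Km_uM:
        warnings.warn("substrate range exceeds 0.1*Km; pseudo-first-order "
                      "slope will underestimate kcat/Km", KineticsWarning,
                      stacklevel=2)
    slope = float(np.sum(S * v) / np.sum(S * S))
    resid = v - slope * S
    dof = len(S) - 1
    slope_se = float(np.sqrt(np.sum(resid ** 2) / dof / np.sum(S * S))) if dof else np.nan

    warning = None
    if len(S) >= 4:
        # curvature test: add a quadratic term; significant t => lack of fit
        X = np.column_stack([S, S ** 2])
        coef, res_ss, *_ = np.linalg.lstsq(X, v, rcond=None)
        dof2 = len(S) - 2
        if dof2 > 0:
            rss2 = float(np.sum((v - X @ coef) ** 2))
            se_q = np.sqrt(rss2 / dof2 * np.linalg.inv(X.T @ X)[1, 1])
            if se_q > 0:
                t = abs(coef[1]) / se_q
                if 2 * stats.t.sf(t, dof2) < 0.05:
                    warning = ("significant curvature in v vs S: the "
                               "pseudo-first-order assumption ([S] << Km) fails")
                    warnings.warn(warning, KineticsWarning, stacklevel=2)

    eff = None
    if enzyme_molar_nM is not None:
        # slope [min^-1] = (kcat/Km)[µM^-1 min^-1] * E0[µM]
        eff = slope / (enzyme_molar_nM * NM_TO_UM) / 60.0 * 1e3   # mM^-1 s^-1
    return EfficiencyFit(slope, slope_se, eff, warning)


def simulate_suicide(E0_nM: float, r_partition: float, k_obs: float,
                     t_grid: Sequence[float], substrate: str = "sulfuretin",
                     substrate_conc0: float = float("nan")) -> ProgressCurve:
    """Suicide-inactivation progress curve P(t) = r*E0*(1 - exp(-k_obs t)).

    The plateau r*E0 (µM, with E0 converted from nM) is proportional to the
    enzyme amount — the signature of an enzyme that dies during catalysis.
    """
    if E0_nM <= 0 or r_partition <= 0 or k_obs <= 0:
        raise ValueError("E0, r_partition and k_obs must be > 0")
    t = np.asarray(t_grid, dtype=float)
    P = r_partition * E0_nM * NM_TO_UM * (1.0 - np.exp(-k_obs * t))
    return ProgressCurve(t, P, enzyme_conc=E0_nM, substrate=substrate,
                         substrate_conc0=substrate_conc0)


def _exp_plateau(t, P_inf, k_obs):
    return P_inf * (1.0 - np.exp(-k_obs * t))


def fit_suicide(curve: ProgressCurve) -> SuicideFit:
    """Least-squares estimates of (P_inf, k_obs); r = P_inf / E0.

    Warns when no plateau is detectable (late-time slope above 10 % of the
    initial slope), in which case P_inf extrapolates beyond the data.
    """
    t, P = curve.time, curve.signal
    if len(t) < 6:
        raise ValueError("need >= 6 time points including the plateau region")
    model = Model(_exp_plateau, independent_vars=["t"])
    dt0 = max(t[1] - t[0], 1e-9)
    k0 = max((P[1] - P[0]) / dt0 / max(P.max(), 1e-12), 1e-3)
    params = model.make_params(P_inf=dict(value=float(P.max()), min=0),
                               k_obs=dict(value=float(k0), min=0))
    result = model.fit(P, params, t=t)
    P_inf = float(result.params["P_inf"].value)
    k_obs = float(result.params["k_obs"].value)

    warning = None
    n_dec = max(len(t) // 10, 2)
    late = np.polyfit(t[-n_dec:], P[-n_dec:], 1)[0]
    init_slope = np.polyfit(t[:max(n_dec, 2)], P[:max(n_dec, 2)], 1)[0]
    if init_slope > 0 and late > 0.1 * init_slope:
        warning = ("no plateau detectable: late-time slope exceeds 10 % of the "
                   "initial slope; P_inf is an extrapolation")
        warnings.warn(warning, KineticsWarning, stacklevel=2)
    return SuicideFit(
        P_inf, k_obs, P_inf / (curve.enzyme_conc * NM_TO_UM),
        float(result.params["P_inf"].stderr or np.nan),
        float(result.params["k_obs"].stderr or np.nan), warning)


def simulate_latent_activation(E0_nM: float, model: AllostericModel,
                               activating: bool, t_grid: Sequence[float],
                               step: float | None = None,
                               substrate: str = "fisetin",
                               substrate_conc0: float = float("nan")
                               ) -> ProgressCurve:
    """Integrate the threshold-activation model on a fixed-step grid.

    dP/dt = v_spec*E0*(a0 + (1-a0)*min(P/c_star, 1)) while activating;
    a chalcone-type substrate (``activating=False``) stays at the basal rate,
    giving an exactly linear curve.  The integration step must not exceed
    ``0.01 * c_star / (v_spec * E0)``.
    """
    if E0_nM <= 0:
        raise ValueError("E0 must be > 0")
    t = np.asarray(t_grid, dtype=float)
    vE = model.v_spec * E0_nM                      # µM min^-1, fully active
    if not activating:
        P = model.a0 * vE * t
        return ProgressCurve(t, P, enzyme_conc=E0_nM, substrate=substrate,
                             substrate_conc0=substrate_conc0)
    max_step = 0.01 * model.c_star / vE
    if step is None:
        step = max_step / 5
    elif step > max_step:
        raise ValueError(
            f"integration step {step:.4g} exceeds the stability bound "
            f"{max_step:.4g} = 0.01*c_star/(v_spec*E0)")
    # fixed-step Euler on a fine grid, then linear interpolation onto t_grid
    t_end = float(t[-1])
    n = int(np.ceil(t_end / step)) + 1
    fine_t = np.linspace(0.0, t_end, n)
    h = fine_t[1] - fine_t[0] if n > 1 else 0.0
    P_fine = np.empty(n)
    P_fine[0] = 0.0
    for i in range(1, n):
        p = P_fine[i - 1]
        frac = model.a0 + (1 - model.a0) * min(p / model.c_star, 1.0)
        P_fine[i] = p + h * vE * frac
    P = np.interp(t, fine_t, P_fine)
    return ProgressCurve(t, P, enzyme_conc=E0_nM, substrate=substrate,
                         substrate_conc0=substrate_conc0)


def lag_time(curve: ProgressCurve) -> float:
    """Intersection of the extrapolated steady-state line with the time axis."""
    t, P = curve.time, curve.signal
    n_tail = max(len(t) // 5, 3)
    slope, intercept = np.polyfit(t[-n_tail:], P[-n_tail:], 1)
    return float(-intercept / slope)


@dataclass(frozen=True)
class CriticalConcentrationEstimate:
    c_star: float                # µM (units of the curves' signal)
    c_star_sd: float
    per_curve: tuple[float, ...]
    inconsistent: bool           # across-curve sd > 15 % of the mean
    excluded: int = 0


def _critical_from_curve(curve: ProgressCurve, threshold: float = 0.95,
                         smooth: bool = True) -> float | None:
    """Product level at which the running slope reaches its steady value.

    The transition is located at the first crossing of ``threshold`` x the
    steady-state slope; because the model's running slope is affine in P
    below c*, the exact 100 % crossing is obtained by a linear extrapolation
    of slope vs product level fitted over the rising phase.  Returns None
    when the curve has no resolvable lag/steady-state structure.
    """
    t, P = curve.time, curve.signal
    if len(t) < 10:
        return None
    sig = P
    if smooth and len(t) >= 31:
        sig = savgol_filter(P, window_length=31, polyorder=3)
    s = np.gradient(sig, t)
    n_tail = max(int(len(t) * 0.15), 3)
    s_inf = float(np.median(s[-n_tail:]))
    if s_inf <= 0:
        return None
    cross = np.flatnonzero(s >= threshold * s_inf)
    if len(cross) == 0 or cross[0] == 0:
        return None               # never crosses, or no lag phase at all
    k = cross[0]
    if len(t) - k < 3:
        return None               # no steady-state region after the crossing
    rising = np.flatnonzero((s < threshold * s_inf) & (s > 0.2 * s_inf)
                            & (np.arange(len(s)) < k))
    if len(rising) >= 3:
        b, a = np.polyfit(P[rising], s[rising], 1)
        if b > 0:
            c = (s_inf - a) / b
            if 0 < c <= float(P.max()):
                return float(c)
    # degenerate rising phase: fall back to the product level at the crossing
    return float(np.interp(threshold * s_inf, s[k - 1:k + 1], P[k - 1:k + 1]))


def estimate_critical_concentration(curves: Sequence[ProgressCurve],
                                    threshold: float = 0.95,
                                    smooth: bool = True
                                    ) -> CriticalConcentrationEstimate:
    """Across-curve estimate of the critical activating product level.

    Each curve contributes the product concentration at which its running
    slope first reaches the steady-state value; under threshold activation
    this level is independent of the enzyme concentration.  Curves without a
    steady-state region are excluded with a warning; the estimate is flagged
    inconsistent when the across-curve spread exceeds 15 % of the mean.
    """
    if len({c.enzyme_conc for c in curves}) < 2:
        raise ValueError("need >= 2 progress curves at distinct enzyme "
                         "concentrations")
    values, excluded = [], 0
    for c in curves:
        est = _critical_from_curve(c, threshold, smooth)
        if est is None:
            excluded += 1
            warnings.warn(
                f"curve at E0={c.enzyme_conc} nM has no resolvable "
                "steady-state transition; excluded", KineticsWarning,
                stacklevel=2)
        else:
            values.append(est)
    if len(values) < 2:
        raise ValueError("fewer than two curves with a resolvable transition")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    inconsistent = sd > 0.15 * mean
    if inconsistent:
        warnings.warn("across-curve spread of the critical concentration "
                      "exceeds 15 % of the mean: threshold model inconsistent "
                      "with the data", KineticsWarning, stacklevel=2)
    return CriticalConcentrationEstimate(mean, sd, tuple(values),
                                         inconsistent, excluded)
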