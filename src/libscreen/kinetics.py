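"""Enzyme kinetics: initial rates, HPLC quantitation, Michaelis-Menten and
competitive-inhibition fitting, pH-rate ionization fits, and the derived
constants (efficiency, rate enhancement, catalytic proficiency) that place a
catalyst against its uncatalysed background reaction.

Models
------
Michaelis-Menten:      v / E0 = kcat * S / (KM + S)
Competitive inhibition: v / E0 = kcat * S / (KM * (1 + I/Ki) + S)
                        (shared kcat and KM across inhibitor levels)
pH-rate (single deprotonation, rate rising with pH):
                        k2(pH) = k_lim / (1 + 10**(pKa - pH))

Derived constants:  efficiency  = kcat / KM          (M^-1 s^-1)
                    enhancement = kcat / k_uncat     (dimensionless)
                    proficiency = efficiency / k_uncat  (M^-1)

All quantities are SI (seconds, molar). Fits are unweighted nonlinear least
squares on v/E0 (an optional relative-error weighting flag is provided);
standard errors come from the curvature (Jacobian) of the fit and
confidence intervals use Student's t with n - p degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "QuantSpec",
    "RateDataset",
    "KineticFit",
    "InsufficientDataError",
    "FitConvergenceError",
    "initial_rate",
    "quantify_amount",
    "fit_mm",
    "fit_competitive_inhibition",
    "lineweaver_burk",
    "fit_ph_rate",
    "derived_constants",
    "round_sig",
    "matches_printed",
    "mm_rate",
    "competitive_rate",
    "ph_rate",
]


class InsufficientDataError(ValueError):
    """Too few eligible data points for the requested computation."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; diagnostics attached."""


# ---------------------------------------------------------------------------
# model functions

def mm_rate(S, kcat, KM, E0=1.0):
    """Michaelis-Menten rate v = kcat*E0*S/(KM+S)."""
    S = np.asarray(S, dtype=float)
    return kcat * E0 * S / (KM + S)


def competitive_rate(S, I, kcat, KM, Ki, E0=1.0):
    """Competitive inhibition: apparent KM scaled by (1 + I/Ki)."""
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    return kcat * E0 * S / (KM * (1.0 + I / Ki) + S)


def ph_rate(pH, k_lim, pKa):
    """Single-ionization pH-rate profile rising to k_lim at high pH."""
    pH = np.asarray(pH, dtype=float)
    return k_lim / (1.0 + 10.0 ** (pKa - pH))


# ---------------------------------------------------------------------------
# data containers

@dataclass(frozen=True)
class QuantSpec:
    """HPLC peak quantitation: amount n = AUC * F / (d * epsilon)."""

    AUC: float  # absorbance * s
    F: float    # flow rate, L/s
    d: float    # pathlength, cm
    epsilon: float  # extinction coefficient, M^-1 cm^-1

    def __post_init__(self) -> None:
        for name in ("AUC", "F", "d", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def quantify_amount(spec: QuantSpec) -> float:
    """Amount of substance (mol) from an HPLC peak area."""
    return spec.AUC * spec.F / (spec.d * spec.epsilon)


@dataclass
class RateDataset:
    """Initial rates at substrate (and optional inhibitor) concentrations.

    E0 in M, S and I in M, v in M/s.
    """

    E0: float
    S: np.ndarray
    v: np.ndarray
    I: np.ndarray | None = None
    replicate: str = "1"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.I is None:
            self.I = np.zeros_like(self.S)
        self.I = np.asarray(self.I, dtype=float)
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        if (self.S < 0).any() or (self.I < 0).any():
            raise ValueError("concentrations must be non-negative")
        if not len(self.S) == len(self.v) == len(self.I):
            raise ValueError("S, v, I must have equal lengths")


@dataclass
class KineticFit:
    """Fitted constants with standard errors from the fit curvature."""

    params: dict[str, float]
    ses: dict[str, float]
    cov: np.ndarray
    n_points: int
    model: str
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def dof(self) -> int:
        return self.n_points - len(self.params)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Student-t confidence interval for one parameter."""
        tcrit = stats.t.ppf(0.5 + level / 2, max(self.dof, 1))
        v, se = self.params[name], self.ses[name]
        return v - tcrit * se, v + tcrit * se

    def __getitem__(self, name: str) -> float:
        return self.params[name]


# ---------------------------------------------------------------------------
# initial rates

def initial_rate(t, signal, total_signal: float, conversion_limit: float = 0.10,
                 calibration: float = 1.0) -> float:
    """Initial rate from a progress curve.

    Least-squares slope over the points with conversion (signal /
    total_signal) below ``conversion_limit``, converted to M/s via
    ``calibration`` (M of product per signal unit). Requires at least three
    eligible points.
    """
    t = np.asarray(t, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if total_signal <= 0:
        raise ValueError("total_signal must be positive")
    keep = signal / total_signal < conversion_limit
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} points below {conversion_limit:.0%} conversion")
    slope = np.polyfit(t[keep], signal[keep], 1)[0]
    return float(slope * calibration)


# ---------------------------------------------------------------------------
# fitting

def _pool(datasets) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(datasets, RateDataset):
        datasets = [datasets]
    E0s = {d.E0 for d in datasets}
    if len(E0s) != 1:
        raise ValueError("pooled replicates must share E0")
    S = np.concatenate([d.S for d in datasets])
    v = np.concatenate([d.v for d in datasets])
    I = np.concatenate([d.I for d in datasets])
    return E0s.pop(), S, v, I


def _curve_fit(f, x, y, p0, names, model, sigma=None):
    try:
        popt, pcov = optimize.curve_fit(f, x, y, p0=p0, sigma=sigma,
                                        absolute_sigma=False, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitConvergenceError(f"{model} fit failed: {exc}") from exc
    if not np.all(np.isfinite(popt)):
        raise FitConvergenceError(f"{model} fit produced non-finite parameters")
    ses = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return (dict(zip(names, popt)), dict(zip(names, ses)), pcov)


def fit_mm(datasets, relative_weights: bool = False) -> KineticFit:
    """Fit the Michaelis-Menten law to one dataset or pooled replicates.

    Nonlinear least squares on v/E0 against S. Start values: kcat0 =
    max(v)/E0, KM0 = median(S). Requires >= 4 distinct substrate levels.
    """
    E0, S, v, _ = _pool(datasets)
    if len(np.unique(S)) < 4:
        raise InsufficientDataError("need at least 4 distinct substrate concentrations")
    y = v / E0
    p0 = (max(y.max(), 1e-12), max(np.median(S), 1e-12))
    # relative weighting: sd proportional to the rate (multiplicative noise)
    sigma = np.abs(y) + y.max() * 1e-9 if relative_weights else None
    params, ses, cov = _curve_fit(lambda s, kcat, KM: mm_rate(s, kcat, KM),
                                  S, y, p0, ("kcat", "KM"), "Michaelis-Menten", sigma)
    if params["kcat"] <= 0 or params["KM"] <= 0:
        raise FitConvergenceError("Michaelis-Menten fit converged to non-positive constants")
    return KineticFit(params, ses, cov, len(S), "michaelis_menten",
                      diagnostics={"E0": E0, "relative_weights": relative_weights})


def fit_competitive_inhibition(datasets, relative_weights: bool = False) -> KineticFit:
    """Global competitive-inhibition fit across inhibitor levels.

    All points share kcat and KM; Ki scales the apparent KM with inhibitor.
    Requires at least two inhibitor levels including I=0. When the data
    carry no inhibition signal the Ki estimate is unbounded; this is
    flagged in ``diagnostics['ki_unbounded']`` rather than raised.
    """
    if isinstance(datasets, RateDataset):
        datasets = [datasets]
    E0, S, v, I = _pool(datasets)
    levels = np.unique(I)
    if len(levels) < 2 or 0.0 not in levels:
        raise ValueError("need >= 2 inhibitor levels including I=0")
    y = v / E0

    base = fit_mm([d for d in datasets if np.all(d.I == 0)] or datasets)
    kcat0, KM0 = base["kcat"], base["KM"]
    # Ki start from apparent-KM algebra at the highest inhibitor level
    Ihi = levels[-1]
    sel = I == Ihi
    try:
        app = fit_mm(RateDataset(E0, S[sel], v[sel]))
        KMapp = app["KM"]
        Ki0 = Ihi * KM0 / max(KMapp - KM0, KM0 * 1e-3)
    except (InsufficientDataError, FitConvergenceError):
        Ki0 = float(np.median(levels[levels > 0]))
    sigma = np.abs(y) + y.max() * 1e-9 if relative_weights else None
    params, ses, cov = _curve_fit(
        lambda x, kcat, KM, Ki: competitive_rate(x[0], x[1], kcat, KM, Ki),
        np.vstack([S, I]), y, (kcat0, KM0, Ki0), ("kcat", "KM", "Ki"),
        "competitive inhibition", sigma)
    unbounded = (not np.isfinite(ses["Ki"])) or ses["Ki"] > 10 * abs(params["Ki"])
    return KineticFit(params, ses, cov, len(S), "competitive_inhibition",
                      diagnostics={"E0": E0, "ki_unbounded": bool(unbounded),
                                   "inhibitor_levels": levels.tolist(),
                                   "relative_weights": relative_weights})


def lineweaver_burk(datasets) -> "pd.DataFrame":
    """Per-inhibitor-level double-reciprocal regression (diagnostic).

    Regresses 1/v on 1/S within each inhibitor level. For competitive
    inhibition all levels share the intercept 1/(kcat*E0) while slopes grow
    linearly with I; a secondary regression of slope on I yields a
    Lineweaver-Burk Ki estimate, stored in ``DataFrame.attrs['Ki']``.
    """
    import pandas as pd

    if isinstance(datasets, RateDataset):
        datasets = [datasets]
    E0, S, v, I = _pool(datasets)
    if np.any(S <= 0) or np.any(v <= 0):
        raise ValueError("double-reciprocal needs strictly positive S and v")
    rows = []
    for level in np.unique(I):
        sel = I == level
        slope, intercept = np.polyfit(1.0 / S[sel], 1.0 / v[sel], 1)
        rows.append({"I": level, "slope": slope, "intercept": intercept,
                     "n": int(sel.sum())})
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        m, b = np.polyfit(df["I"], df["slope"], 1)  # slope_I = (KM/(kcat E0)) (1 + I/Ki)
        df.attrs["Ki"] = float(b / m) if m != 0 else math.inf
    return df


def fit_ph_rate(pH, k2) -> KineticFit:
    """Fit an apparent single-ionization pKa to second-order rates vs pH."""
    pH = np.asarray(pH, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if len(np.unique(pH)) < 4:
        raise InsufficientDataError("need at least 4 pH points")
    p0 = (k2.max(), float(np.median(pH)))
    params, ses, cov = _curve_fit(ph_rate, pH, k2, p0, ("k_lim", "pKa"), "pH-rate")
    return KineticFit(params, ses, cov, len(pH), "ph_rate")


# ---------------------------------------------------------------------------
# derived-constant calculus

def derived_constants(kcat: float, KM: float, k_uncat: float) -> dict[str, float]:
    """Efficiency kcat/KM, rate enhancement kcat/k_uncat and catalytic
    proficiency (kcat/KM)/k_uncat. Inputs in SI (s^-1, M, s^-1)."""
    for name, val in (("kcat", kcat), ("KM", KM), ("k_uncat", k_uncat)):
        if val <= 0:
            raise ValueError(f"{name} must be strictly positive")
    eff = kcat / KM
    return {"efficiency": eff, "enhancement": kcat / k_uncat,
            "proficiency": eff / k_uncat}


def round_sig(x: float, n: int) -> float:
    """Round to ``n`` significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    q = 10.0 ** (exp - n + 1)
    return math.copysign(math.floor(abs(x) / q + 0.5) * q, x)


def matches_printed(computed: float, printed: float, sig_figs: int) -> bool:
    """True when ``computed`` agrees with a printed value to its printed
    precision: within half a unit (inclusive) of the printed last digit."""
    if printed == 0:
        return computed == 0
    exp = math.floor(math.log10(abs(printed)))
    tol = 0.5 * 10.0 ** (exp - sig_figs + 1)
    return abs(computed - printed) <= tol * (1 + 1e-9)
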