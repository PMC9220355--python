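"""Assay reduction: activities, IC50 fitting and the energy–potency bridge.

Photometric LPMO assays follow coerulignone formation at 469 nm
(epsilon = 53,200 M^-1 cm^-1); one unit (U) converts 1 umol of
coerulignone per minute. The turbidimetric assay follows the loss of light
scattering of a cellulose (PASC) suspension at 620 nm; its "rate" is the
slope of intensity versus time over a stated window. Residual activity is
the percentage of the activity measured in plain acetate buffer.

Dose–response series are reduced with a single-exponential decay
``A(c) = A0 exp(-k c)`` whose half-activity concentration is
``IC50 = ln 2 / k``; a model-free log-linear interpolation between the two
concentrations bracketing A0/2 is reported alongside as a cross-check.

Thermodynamic bridges: the Cheng–Prusoff conversion
``K_i = IC50 / (1 + [S]/K_M)`` (competitive inhibition), the exponential
link ``K_D = exp(-dG_bind / RT)`` with ``K_i ~ 1/K_D``, and the empirical
linear relation ``ln(IC50) = a + b * dG_bind`` fitted by ordinary least
squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .units import R_GAS


@dataclass(frozen=True)
class AssayConditions:
    """Photometric assay constants needed to turn slopes into activities."""

    epsilon: float  # molar absorption coefficient, M^-1 cm^-1
    path_length: float  # cm
    reaction_volume: float  # L
    enzyme_mass: float  # g
    wavelength: float = 469.0  # nm
    stoichiometry: int = 1  # umol substrate per umol coerulignone

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")
        if self.stoichiometry not in (1, 2):
            raise ValueError("stoichiometry must be 1 or 2")


@dataclass
class DoseResponseSeries:
    """Activity (or rate) versus inhibitor concentration for one compound."""

    inhibitor_id: str
    concentrations: np.ndarray  # mM, sorted ascending
    activities: np.ndarray
    reference_activity: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.activities, dtype=float)
        if c.shape != a.shape:
            raise ValueError("concentrations and activities differ in length")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(c, kind="stable")
        self.concentrations = c[order]
        self.activities = a[order]


@dataclass
class IC50Result:
    inhibitor_id: str
    ic50: float  # mM
    a0: float
    k: float  # mM^-1
    ic50_se: float
    a0_se: float
    k_se: float
    rss: float
    ic50_interp: float | None = None  # model-free log-linear crossing


@dataclass
class CorrelationResult:
    a: float  # intercept, ln(mM)
    b: float  # slope, per kJ/mol
    r_squared: float
    n: int
    a_se: float = float("nan")
    b_se: float = float("nan")


@dataclass
class TurbidityRate:
    """Magnitude of the intensity change per minute plus its direction."""

    rate: float  # per-minute magnitude
    direction: int  # +1 increasing, -1 decreasing, 0 flat
    stderr: float


def beer_lambert_conc(absorbance: float, epsilon: float, path: float) -> float:
    """Concentration (M) from absorbance via the Beer–Lambert law, A/(eps*l)."""
    if epsilon <= 0 or path <= 0:
        raise ValueError("epsilon and path length must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    return absorbance / (epsilon * path)


def specific_activity(
    slope: float, blank_slope: float, cond: AssayConditions
) -> float:
    """Specific activity in U per gram of enzyme from a photometric slope.

    The blank (no-enzyme) rate is subtracted first, then the net slope
    (AU/min) is converted with Beer–Lambert to a molar product-formation
    rate, scaled by the reaction volume to umol/min and normalised by the
    enzyme mass. Net rates below zero are clipped to 0 with a warning.
    """
    if cond.enzyme_mass <= 0:
        raise ValueError("enzyme mass must be positive")
    net = slope - blank_slope
    if net < 0:
        warnings.warn(
            "rate below blank rate; clipping specific activity at 0",
            stacklevel=2,
        )
        return 0.0
    molar_rate = net / (cond.epsilon * cond.path_length)  # M min^-1
    umol_per_min = molar_rate * cond.reaction_volume * 1e6
    return umol_per_min / cond.enzyme_mass


def residual_activity(activity: float, reference_activity: float) -> float:
    """Percent activity relative to the uninhibited reference."""
    if reference_activity <= 0:
        raise ValueError("reference activity must be positive")
    return 100.0 * activity / reference_activity


def turbidity_rate(
    times_s: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float],
) -> TurbidityRate:
    """Least-squares slope of an assay trace over a time window, per minute.

    The turbidimetric readout may rise or fall depending on the detector
    sign convention, so the magnitude and a direction flag are reported
    separately.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    t_start, t_end = window
    if t_start < t.min() or t_end > t.max() or t_end <= t_start:
        raise ValueError(
            f"window [{t_start}, {t_end}] s outside trace span "
            f"[{t.min()}, {t.max()}] s"
        )
    mask = (t >= t_start) & (t <= t_end)
    if mask.sum() < 10:
        raise ValueError("fewer than 10 trace points in the rate window")
    res = stats.linregress(t[mask], y[mask])
    per_min = res.slope * 60.0
    direction = 0 if per_min == 0 else (1 if per_min > 0 else -1)
    return TurbidityRate(rate=abs(per_min), direction=direction, stderr=res.stderr * 60.0)


class NoInhibitionError(ValueError):
    """Raised when a dose–response series shows no measurable decay."""


def _interp_ic50(c: np.ndarray, a: np.ndarray, half: float) -> float | None:
    """Log-linear interpolation of the concentration crossing ``half``."""
    for i in range(len(c) - 1):
        a1, a2 = a[i], a[i + 1]
        if a1 >= half >= a2 and a1 > 0 and a2 > 0 and a1 != a2:
            f = (math.log(a1) - math.log(half)) / (math.log(a1) - math.log(a2))
            return float(c[i] + f * (c[i + 1] - c[i]))
    return None


def fit_ic50(series: DoseResponseSeries) -> IC50Result:
    """Fit a single-exponential decay and report the half-activity point.

    The model ``A(c) = A0 exp(-k c)`` is fitted by unweighted nonlinear
    least squares. Initial values: A0 from the maximum activity, k from a
    log-linear regression on the positive activities. IC50 = ln 2 / k, with
    a standard error propagated from the covariance of k
    (``dIC50 = ln2 * dk / k^2``).
    """
    c = series.concentrations
    a = series.activities
    if len(np.unique(c)) < 3:
        raise ValueError("at least 3 distinct concentrations are required")
    if np.any(a < 0):
        raise ValueError("activities must be non-negative")
    if a[0] < a.max():
        warnings.warn(
            "activity at the lowest concentration is not the maximum",
            stacklevel=2,
        )

    a0_init = float(a.max())
    pos = a > 0
    if pos.sum() >= 2 and np.ptp(c[pos]) > 0:
        k_init = -float(np.polyfit(c[pos], np.log(a[pos]), 1)[0])
    else:
        k_init = 1.0
    if k_init <= 0:
        raise NoInhibitionError(
            f"{series.inhibitor_id}: no inhibition detected (activities do not decay)"
        )

    def model(x, a0, k):
        return a0 * np.exp(-k * x)

    popt, pcov = optimize.curve_fit(
        model, c, a, p0=(a0_init, k_init), maxfev=10000
    )
    a0, k = popt
    if k <= 0:
        raise NoInhibitionError(
            f"{series.inhibitor_id}: no inhibition detected (fitted k <= 0)"
        )
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    ic50 = math.log(2.0) / k
    ic50_se = math.log(2.0) * perr[1] / k**2
    rss = float(np.sum((a - model(c, *popt)) ** 2))
    return IC50Result(
        inhibitor_id=series.inhibitor_id,
        ic50=ic50,
        a0=float(a0),
        k=float(k),
        ic50_se=float(ic50_se),
        a0_se=float(perr[0]),
        k_se=float(perr[1]),
        rss=rss,
        ic50_interp=_interp_ic50(c, a, a0 / 2.0),
    )


def cheng_prusoff_ki(ic50: float, s: float, k_m: float) -> float:
    """Competitive-inhibition K_i from IC50, substrate concentration and K_M."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if s < 0:
        raise ValueError("substrate concentration must be non-negative")
    if k_m <= 0:
        raise ValueError("K_M must be positive")
    return ic50 / (1.0 + s / k_m)


def kd_from_dg(dg_bind: float, temperature: float = 298.15) -> tuple[float, float]:
    """Exponential link between binding free energy and the constants.

    Returns ``(K_D, K_i_approx)`` with ``K_D = exp(-dG/(R T))`` and
    ``K_i ~ 1/K_D``. Note the convention: this K_D grows with stronger
    (more negative dG) binding, i.e. it behaves as an association constant,
    and K_i is its reciprocal.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rt = R_GAS * temperature / 1000.0  # kJ/mol
    kd = math.exp(-dg_bind / rt)
    return kd, 1.0 / kd


def correlate_ic50_dg(
    ic50_mM: np.ndarray, energies: np.ndarray
) -> CorrelationResult:
    """OLS fit of ln(IC50) on a binding (free) energy, ln(IC50) = a + b*dG."""
    ic50 = np.asarray(ic50_mM, dtype=float)
    e = np.asarray(energies, dtype=float)
    if ic50.shape != e.shape:
        raise ValueError("IC50 and energy arrays differ in length")
    if len(ic50) < 3:
        raise ValueError("at least 3 pairs are required")
    if np.any(ic50 <= 0):
        raise ValueError("all IC50 values must be positive")
    if np.ptp(e) == 0:
        raise ValueError("degenerate energies: all x values are equal")
    res = stats.linregress(e, np.log(ic50))
    return CorrelationResult(
        a=float(res.intercept),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=len(ic50),
        a_se=float(res.intercept_stderr),
        b_se=float(res.stderr),
    )
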