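"""Binding-isotherm and two-state denaturation curve fits.

Fluorescence-polarization titrations are fit to a 1:1 binding function in
protomer units: each peptide binds each protomer of the dimer independently,
so the 2:1 peptide:dimer stoichiometry collapses to a single-site hyperbola

    P([T]) = p_free + (p_bound - p_free) * [T] / (Kd + [T]).

A quadratic ligand-depletion variant uses the exact bound fraction at the
stated tracer concentration; at 10 nM tracer and micromolar Kd it coincides
with the hyperbola to well under a percent.

Denaturation curves use a minimal two-state model with linear folded and
unfolded baselines.  Thermal melts: van't Hoff temperature dependence with
ΔCp = 0 (not estimable from a single melt),

    f_u(T) = 1 / (1 + exp((ΔH/R) (1/T - 1/Tm))),   T in kelvin.

Chemical (urea) denaturation: linear extrapolation, ΔG(u) = ΔG0 - m u, with
f_u(u) = 1 / (1 + exp(ΔG(u)/RT)) and midpoint Cm = ΔG0/m.

All fits use nonlinear least squares (scipy) with Kd parameterized as log Kd
so the estimate can never go negative; standard errors are asymptotic
(Jacobian-based).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize

from .errors import FitError, NoTransitionError

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "MeltCurve",
    "UreaCurve",
    "TwoStateFit",
    "fit_fp_binding",
    "fit_two_state_thermal",
    "fit_two_state_chemical",
]

R_GAS = 8.314462618e-3  # kJ / (mol K)


@dataclasses.dataclass
class TitrationCurve:
    """Protein concentrations (µM, protomer units) vs polarization (mP)."""

    protein_conc: np.ndarray
    polarization: np.ndarray

    def __post_init__(self) -> None:
        self.protein_conc = np.asarray(self.protein_conc, float)
        self.polarization = np.asarray(self.polarization, float)
        if self.protein_conc.shape != self.polarization.shape:
            raise ValueError("concentration and signal lengths differ")
        if np.any(self.protein_conc < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(self.protein_conc)
        self.protein_conc = self.protein_conc[order]
        self.polarization = self.polarization[order]
        if np.any(np.diff(self.protein_conc) <= 0):
            raise ValueError("concentrations must be distinct")


@dataclasses.dataclass
class BindingFit:
    kd: float  # µM
    p_free: float
    p_bound: float
    kd_se: float
    p_free_se: float
    p_bound_se: float
    model: str  # {hyperbolic, quadratic_depletion}
    residual_norm: float
    warnings: list[str]


@dataclasses.dataclass
class MeltCurve:
    temperature: np.ndarray  # °C
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.signal = np.asarray(self.signal, float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclasses.dataclass
class UreaCurve:
    urea: np.ndarray  # M
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.urea = np.asarray(self.urea, float)
        self.signal = np.asarray(self.signal, float)
        if self.urea.shape != self.signal.shape:
            raise ValueError("urea and signal lengths differ")
        if np.any(np.diff(self.urea) <= 0):
            raise ValueError("urea concentrations must be strictly increasing")


@dataclasses.dataclass
class TwoStateFit:
    midpoint: float  # Tm in °C, or Cm in M
    slope_term: float  # ΔH (kJ/mol) for thermal, m-value (kJ/mol/M) for chemical
    folded_baseline: tuple[float, float]  # intercept, slope
    unfolded_baseline: tuple[float, float]
    midpoint_se: float
    slope_term_se: float
    residual_norm: float
    kind: str  # {thermal, chemical}


# ---------------------------------------------------------------------------
# binding


def hyperbolic_model(conc: np.ndarray, kd: float, p_free: float, p_bound: float) -> np.ndarray:
    conc = np.asarray(conc, float)
    return p_free + (p_bound - p_free) * conc / (kd + conc)


def quadratic_depletion_model(
    conc: np.ndarray, kd: float, p_free: float, p_bound: float, tracer: float
) -> np.ndarray:
    """Exact 1:1 bound fraction of the tracer at total protein `conc` (same units)."""
    conc = np.asarray(conc, float)
    s = conc + kd + tracer
    frac_bound = (s - np.sqrt(s * s - 4.0 * conc * tracer)) / (2.0 * tracer)
    return p_free + (p_bound - p_free) * frac_bound


def fit_fp_binding(
    curve: TitrationCurve,
    model: str = "hyperbolic",
    tracer_conc: float = 0.010,  # µM (10 nM fluorescent peptide)
) -> BindingFit:
    """Fit a 1:1 binding isotherm to a polarization titration.

    Kd is fit on a log scale; reported standard errors are asymptotic and
    propagated back to the linear Kd scale.  A warning (not an error) is
    issued when fewer than 5 points are given or the data do not bracket the
    fitted midpoint.
    """
    if model not in ("hyperbolic", "quadratic_depletion"):
        raise ValueError(f"unknown binding model {model!r}")
    warnings: list[str] = []
    x = curve.protein_conc
    y = curve.polarization
    if x.size < 5:
        warnings.append(f"only {x.size} titration points; fit may be unstable")

    p_free0 = float(y[0])
    p_bound0 = float(y[-1])
    half = p_free0 + 0.5 * (p_bound0 - p_free0)
    kd0 = float(x[np.argmin(np.abs(y - half))])
    kd0 = max(kd0, 1e-6)

    if model == "hyperbolic":
        def func(conc, log_kd, p_free, p_bound):
            return hyperbolic_model(conc, math.exp(log_kd), p_free, p_bound)
    else:
        def func(conc, log_kd, p_free, p_bound):
            return quadratic_depletion_model(conc, math.exp(log_kd), p_free, p_bound, tracer_conc)

    try:
        popt, pcov = optimize.curve_fit(
            func, x, y, p0=[math.log(kd0), p_free0, p_bound0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"binding fit did not converge: {exc}") from exc
    log_kd, p_free, p_bound = popt
    kd = math.exp(log_kd)
    perr = np.sqrt(np.diag(pcov))
    kd_se = kd * perr[0]  # delta method: se(kd) = kd * se(log kd)
    if p_bound == p_free:
        raise FitError("degenerate fit: no polarization change")
    if not (x.min() <= kd <= x.max()):
        warnings.append(f"fitted Kd {kd:.3g} µM lies outside the titrated range")
    resid = y - func(x, *popt)
    return BindingFit(
        kd=float(kd),
        p_free=float(p_free),
        p_bound=float(p_bound),
        kd_se=float(kd_se),
        p_free_se=float(perr[1]),
        p_bound_se=float(perr[2]),
        model=model,
        residual_norm=float(np.linalg.norm(resid)),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# denaturation


def thermal_fraction_unfolded(t_celsius: np.ndarray, tm_celsius: float, dh: float) -> np.ndarray:
    """van't Hoff two-state fraction unfolded; ΔH in kJ/mol."""
    t = np.asarray(t_celsius, float) + 273.15
    tm = tm_celsius + 273.15
    arg = np.clip(dh / R_GAS * (1.0 / t - 1.0 / tm), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(arg))


def thermal_model(
    t: np.ndarray, tm: float, dh: float, af: float, bf: float, au: float, bu: float
) -> np.ndarray:
    f = thermal_fraction_unfolded(t, tm, dh)
    return (1.0 - f) * (af + bf * t) + f * (au + bu * t)


def chemical_fraction_unfolded(
    urea: np.ndarray, dg0: float, m: float, temperature_k: float = 298.15
) -> np.ndarray:
    """Linear-extrapolation fraction unfolded; ΔG0 in kJ/mol, m in kJ/mol/M."""
    dg = dg0 - m * np.asarray(urea, float)
    arg = np.clip(dg / (R_GAS * temperature_k), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(arg))


def chemical_model(
    u: np.ndarray, dg0: float, m: float, af: float, bf: float, au: float, bu: float,
    temperature_k: float = 298.15,
) -> np.ndarray:
    f = chemical_fraction_unfolded(u, dg0, m, temperature_k)
    return (1.0 - f) * (af + bf * u) + f * (au + bu * u)


def _check_transition(
    x: np.ndarray, y: np.ndarray, midpoint: float, amplitude: float, resid: np.ndarray
) -> None:
    """Reject fits with no genuine transition inside the data range."""
    if not (x.min() <= midpoint <= x.max()):
        raise NoTransitionError(
            f"fitted midpoint {midpoint:.2f} lies outside the data range "
            f"[{x.min():.2f}, {x.max():.2f}]"
        )
    # amplitude must dominate the residual scatter and a straight line must
    # fit measurably worse than the two-state model
    noise = float(np.std(resid)) if resid.size else 0.0
    if abs(amplitude) < max(5.0 * noise, 1e-12 * max(1.0, float(np.ptp(y)))):
        raise NoTransitionError("transition amplitude indistinguishable from noise")
    line = np.polyval(np.polyfit(x, y, 1), x)
    sse_line = float(np.sum((y - line) ** 2))
    sse_fit = float(np.sum(resid**2))
    if sse_line <= 1e-30 or sse_fit > 0.5 * sse_line:
        raise NoTransitionError("two-state model fits no better than a straight line")


def fit_two_state_thermal(curve: MeltCurve) -> TwoStateFit:
    """Fit a thermal melt to the two-state model with linear baselines.

    Returns Tm in °C and the van't Hoff ΔH (kJ/mol).  Raises
    :class:`NoTransitionError` when the data contain no credible sigmoidal
    transition (flat traces, baseline-only drifts).
    """
    t = curve.temperature
    y = curve.signal
    if t.size < 10:
        raise ValueError("thermal fit needs at least 10 points")

    # initial guesses: midpoint at the steepest gradient
    grad = np.gradient(y, t)
    tm0 = float(t[np.argmax(np.abs(grad))])
    af0, au0 = float(y[0]), float(y[-1])
    p0 = [tm0, 300.0, af0, 0.0, au0, 0.0]
    try:
        with warnings.catch_warnings():
            # degenerate (transition-free) traces trip a covariance warning; such
            # fits are rejected below, so the warning is noise
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(thermal_model, t, y, p0=p0, maxfev=40000)
    except RuntimeError as exc:
        raise NoTransitionError(f"thermal fit did not converge: {exc}") from exc
    tm, dh, af, bf, au, bu = popt
    if dh <= 0:
        raise NoTransitionError("fitted van't Hoff enthalpy is non-positive")
    resid = y - thermal_model(t, *popt)
    amplitude = (au + bu * tm) - (af + bf * tm)
    _check_transition(t, y, tm, amplitude, resid)
    perr = np.sqrt(np.diag(pcov))
    return TwoStateFit(
        midpoint=float(tm),
        slope_term=float(dh),
        folded_baseline=(float(af), float(bf)),
        unfolded_baseline=(float(au), float(bu)),
        midpoint_se=float(perr[0]),
        slope_term_se=float(perr[1]),
        residual_norm=float(np.linalg.norm(resid)),
        kind="thermal",
    )


def fit_two_state_chemical(curve: UreaCurve, temperature_k: float = 298.15) -> TwoStateFit:
    """Fit a urea denaturation curve by linear extrapolation.

    Returns the midpoint Cm = ΔG0/m (M) and the m-value (kJ/mol/M).
    """
    u = curve.urea
    y = curve.signal
    if u.size < 10:
        raise ValueError("chemical denaturation fit needs at least 10 points")

    grad = np.gradient(y, u)
    cm0 = float(u[np.argmax(np.abs(grad))])
    cm0 = min(max(cm0, u.min() + 1e-6), u.max() - 1e-6) if u.size else cm0
    m0 = 10.0
    p0 = [m0 * max(cm0, 0.1), m0, float(y[0]), 0.0, float(y[-1]), 0.0]

    def func(x, dg0, m, af, bf, au, bu):
        return chemical_model(x, dg0, m, af, bf, au, bu, temperature_k)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(func, u, y, p0=p0, maxfev=40000)
    except RuntimeError as exc:
        raise NoTransitionError(f"chemical denaturation fit did not converge: {exc}") from exc
    dg0, m, af, bf, au, bu = popt
    if m <= 0 or dg0 <= 0:
        raise NoTransitionError("fitted unfolding free energy or m-value is non-positive")
    cm = dg0 / m
    resid = y - func(u, *popt)
    amplitude = (au + bu * cm) - (af + bf * cm)
    _check_transition(u, y, cm, amplitude, resid)
    perr = np.sqrt(np.diag(pcov))
    # se(Cm) by the delta method from se(ΔG0), se(m) and their covariance
    var_cm = (
        pcov[0, 0] / m**2
        + (dg0**2 / m**4) * pcov[1, 1]
        - 2.0 * (dg0 / m**3) * pcov[0, 1]
    )
    cm_se = math.sqrt(max(0.0, float(var_cm)))
    return TwoStateFit(
        midpoint=float(cm),
        slope_term=float(m),
        folded_baseline=(float(af), float(bf)),
        unfolded_baseline=(float(au), float(bu)),
        midpoint_se=cm_se,
        slope_term_se=float(perr[1]),
        residual_norm=float(np.linalg.norm(resid)),
        kind="chemical",
    )
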