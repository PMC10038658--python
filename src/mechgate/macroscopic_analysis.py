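"""Whole-cell current analysis: peak I-V extraction, Boltzmann activation
and availability fits, exponential kinetics, difference currents and the
perfusion shear-stress calculator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


@dataclass
class SweepSet:
    """Whole-cell two-pulse sweeps for one cell and condition.

    ``sweeps`` maps the step-1 test voltage (mV) to the current trace (pA);
    ``step1_window`` marks the step-1 samples.  ``step2_peaks`` optionally
    stores the step-2 (availability) peak per test voltage.
    """

    sweeps: dict[float, np.ndarray]
    sampling_rate: float
    capacitance_pF: float
    condition: str = "control"
    cell_id: str = ""
    step1_window: slice = field(default_factory=lambda: slice(None))
    step2_peaks: dict[float, float] | None = None

    def __post_init__(self):
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be > 0")


def peak_currents(ss: SweepSet, polarity: str = "negative", skip_samples: int = 2) -> pd.DataFrame:
    """Per-voltage peak current within the step-1 window.

    ``polarity`` 'negative' takes the minimum (inward peak), 'positive' the
    maximum.  The first ``skip_samples`` samples of the window are excluded
    (capacitive instant).  Returns a DataFrame with columns voltage_mV,
    peak_pA and peak_pA_per_pF.
    """
    rows = []
    for v in sorted(ss.sweeps):
        x = ss.sweeps[v][ss.step1_window][skip_samples:]
        if x.size == 0:
            raise ValueError("empty step-1 window")
        peak = float(x.min() if polarity == "negative" else x.max())
        rows.append((v, peak, peak / ss.capacitance_pF))
    return pd.DataFrame(rows, columns=["voltage_mV", "peak_pA", "peak_pA_per_pF"])


# ---------------------------------------------------------------------------
# Boltzmann fits


def boltzmann_iv(V, e_rev, g_max, v_half, dv):
    """Peak current model I(V) = (V - E_rev)·G_max / (1 + exp((V_half - V)/dV)).

    With dV > 0 conductance rises with depolarization (the sign convention
    in which tabulated positive activation slopes describe an activating
    channel)."""
    return (V - e_rev) * g_max / (1.0 + np.exp((v_half - V) / dv))


def boltzmann_iv_printed(V, e_rev, g_max, v_half, dv):
    """The same equation with the exponent written (V - V_half)/dV; the two
    conventions coincide under dV -> -dV."""
    return (V - e_rev) * g_max / (1.0 + np.exp((V - v_half) / dv))


@dataclass
class BoltzmannActivationResults:
    e_rev: float
    g_max: float
    v_half: float
    dv: float
    bse: np.ndarray
    rss: float
    converged: bool
    convention: str

    def conductance(self, V) -> np.ndarray:
        """Normalized conductance curve G(V)/G_max."""
        V = np.asarray(V, float)
        s = 1.0 if self.convention == "rising" else -1.0
        return 1.0 / (1.0 + np.exp(s * (self.v_half - V) / self.dv))

    def summary(self) -> str:
        names = ["E_rev (mV)", "G_max (nS)", "V_1/2a (mV)", "dV_a (mV)"]
        vals = [self.e_rev, self.g_max, self.v_half, self.dv]
        lines = ["Boltzmann activation fit", "-" * 40]
        lines += [f"{n:12s} {v:10.3f}  (SE {s:.3f})" for n, v, s in zip(names, vals, self.bse)]
        lines.append(f"RSS = {self.rss:.4g}   converged: {self.converged}")
        return "\n".join(lines)


class BoltzmannActivation:
    """Fit of the peak I-V relation with a Boltzmann-weighted ohmic current.

    ``iv`` is a DataFrame with columns voltage_mV and a current column
    (peak_pA or peak_pA_per_pF).  Needs at least 6 voltages spanning the
    midpoint."""

    def __init__(self, iv: pd.DataFrame, current_col: str = "peak_pA"):
        if len(iv) < 6:
            raise ValueError("need at least 6 voltages")
        self.V = iv["voltage_mV"].to_numpy(float)
        self.I = iv[current_col].to_numpy(float)

    def _init(self):
        # E_rev: extrapolate from the most depolarized ohmic-ish points
        e_rev = 55.0 if self.I.min() < 0 else 0.0
        g = self.I / np.where(np.abs(self.V - e_rev) < 1, np.nan, self.V - e_rev)
        g_max = np.nanmax(g) if np.isfinite(g).any() else 1.0
        g_max = max(g_max, 1e-4)
        gn = np.clip(g / g_max, 0, 1)
        v_half = float(np.interp(0.5, np.sort(gn[np.isfinite(gn)]),
                                 self.V[np.argsort(np.nan_to_num(gn))]))
        return [e_rev, g_max, v_half, 8.0]

    def fit(
        self, convention: str = "rising", init=None, weights: str | None = None
    ) -> BoltzmannActivationResults:
        """Least-squares fit.  ``weights='relative'`` weights residuals by
        1/|I| (appropriate when the noise scales with the current)."""
        f = boltzmann_iv if convention == "rising" else boltzmann_iv_printed
        p0 = list(init) if init is not None else self._init()
        sigma = None
        if weights == "relative":
            scale = np.abs(self.I)
            sigma = np.maximum(scale, 0.05 * scale.max() if scale.max() > 0 else 1.0)
        try:
            popt, pcov = curve_fit(f, self.V, self.I, p0=p0, sigma=sigma, maxfev=20000)
            converged = True
            bse = np.sqrt(np.diag(pcov))
        except RuntimeError:
            popt, bse, converged = np.array(p0), np.full(4, np.nan), False
            logger.warning("Boltzmann activation fit did not converge")
        resid = self.I - f(self.V, *popt)
        return BoltzmannActivationResults(
            e_rev=float(popt[0]), g_max=float(popt[1]), v_half=float(popt[2]),
            dv=float(popt[3]), bse=bse, rss=float(resid @ resid),
            converged=converged, convention=convention,
        )


@dataclass
class AvailabilityResults:
    v_half: float
    dv: float
    bse: np.ndarray
    rss: float
    converged: bool

    def curve(self, V) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((self.v_half - np.asarray(V, float)) / self.dv))

    def summary(self) -> str:
        return (
            "Availability (steady-state inactivation) fit\n"
            + "-" * 44
            + f"\nV_1/2i = {self.v_half:.3f} mV (SE {self.bse[0]:.3f})"
            + f"\ndV_i   = {self.dv:.3f} mV (SE {self.bse[1]:.3f})"
            + f"\nRSS = {self.rss:.4g}   converged: {self.converged}"
        )


class Availability:
    """Fit of normalized step-2 peaks vs step-1 (conditioning) voltage.

    Uses the tabulated sign convention I(V) = 1/(1 + exp((V_half - V)/dV)),
    in which a NEGATIVE slope dV describes availability that falls with
    depolarization (the physical case).  A fitted dV > 0 means the data
    rise with voltage — not an availability curve — and the result is
    flagged unconverged."""

    def __init__(self, V, I_norm):
        self.V = np.asarray(V, float)
        self.I = np.asarray(I_norm, float)

    def fit(self, init=None) -> AvailabilityResults:
        f = lambda V, vh, dv: 1.0 / (1.0 + np.exp((vh - V) / dv))
        p0 = list(init) if init is not None else [float(np.median(self.V)), -7.0]
        try:
            popt, pcov = curve_fit(f, self.V, self.I, p0=p0, maxfev=20000)
            converged = True
            bse = np.sqrt(np.diag(pcov))
        except RuntimeError:
            popt, bse, converged = np.array(p0), np.full(2, np.nan), False
        resid = self.I - f(self.V, *popt)
        rss = float(resid @ resid)
        if converged and popt[1] > 0:
            logger.warning("availability fit slope is positive (data rise with "
                           "voltage); not an availability curve")
            converged = False
        if converged and rss > 0.05 * max(len(self.V), 1):
            logger.warning("availability fit residuals are large; data may not be sigmoid")
            converged = False
        return AvailabilityResults(float(popt[0]), float(popt[1]), bse, rss, converged)


# ---------------------------------------------------------------------------
# kinetics


@dataclass
class KineticsResults:
    tau_a: float  # activation time constant, ms
    tau_i: float | None  # inactivation time constant, ms (None if single)
    a1: float
    a2: float
    c: float
    bse: np.ndarray
    rss: float
    converged: bool
    identifiable: bool

    def summary(self) -> str:
        tau_i = "-" if self.tau_i is None else f"{self.tau_i:.3f} ms"
        return (
            "Exponential kinetics fit\n" + "-" * 30
            + f"\ntau_a = {self.tau_a:.3f} ms\ntau_i = {tau_i}"
            + f"\nA1={self.a1:.3f}  A2={self.a2:.3f}  C={self.c:.3f}"
            + f"\nconverged: {self.converged}  identifiable: {self.identifiable}"
        )


class CurrentKinetics:
    """Exponential fit of a current time course,
    I(t) = A1·exp(-t/tau_a) + A2·exp(-t/tau_i) + C.

    For non-inactivating channels use ``n_exp=1`` (A2 fixed to 0).  Time in
    seconds on input; time constants reported in ms."""

    def __init__(self, t, i, window: slice | None = None):
        t = np.asarray(t, float)
        i = np.asarray(i, float)
        if window is not None:
            t, i = t[window], i[window]
        self.t = t - t[0]
        self.i = i

    def fit(self, n_exp: int = 1, init=None) -> KineticsResults:
        spread = self.i.max() - self.i.min()
        if spread < 1e-12 or spread < 1e-6 * max(abs(self.i).max(), 1e-30):
            return KineticsResults(np.nan, None if n_exp == 1 else np.nan,
                                   0.0, 0.0, float(self.i.mean()),
                                   np.full(3, np.nan), 0.0, False, False)
        T = self.t[-1]
        if n_exp == 1:
            f = lambda t, a1, tau, c: a1 * np.exp(-t / tau) + c
            p0 = init if init is not None else [self.i[0] - self.i[-1], T / 5, self.i[-1]]
            try:
                popt, pcov = curve_fit(f, self.t, self.i, p0=p0, maxfev=20000)
                conv = True
                bse = np.sqrt(np.diag(pcov))
            except RuntimeError:
                popt, bse, conv = np.array(p0), np.full(3, np.nan), False
            resid = self.i - f(self.t, *popt)
            return KineticsResults(
                tau_a=float(popt[1]) * 1e3, tau_i=None, a1=float(popt[0]), a2=0.0,
                c=float(popt[2]), bse=bse, rss=float(resid @ resid),
                converged=conv, identifiable=conv and popt[1] > 0,
            )
        f = lambda t, a1, ta, a2, ti, c: a1 * np.exp(-t / ta) + a2 * np.exp(-t / ti) + c
        if init is not None:
            p0 = list(init)
        else:
            # amplitudes are linear given the taus: scan a small tau grid,
            # solve the linear subproblem, start from the best candidate
            best = None
            for ta in (T / 100, T / 30, T / 10):
                for ti in (T / 10, T / 3, T):
                    if ti <= ta * 2:
                        continue
                    M = np.column_stack(
                        [np.exp(-self.t / ta), np.exp(-self.t / ti), np.ones_like(self.t)]
                    )
                    coef, *_ = np.linalg.lstsq(M, self.i, rcond=None)
                    rss = float(((M @ coef - self.i) ** 2).sum())
                    if best is None or rss < best[0]:
                        best = (rss, [coef[0], ta, coef[1], ti, coef[2]])
            p0 = best[1]
        lb = [-np.inf, 1e-7, -np.inf, 1e-7, -np.inf]
        ub = [np.inf] * 5
        try:
            popt, pcov = curve_fit(f, self.t, self.i, p0=p0, bounds=(lb, ub), maxfev=40000)
            conv = True
            bse = np.sqrt(np.diag(pcov))
        except RuntimeError:
            popt, bse, conv = np.array(p0), np.full(5, np.nan), False
        resid = self.i - f(self.t, *popt)
        taus = sorted([abs(popt[1]), abs(popt[3])])
        return KineticsResults(
            tau_a=taus[0] * 1e3, tau_i=taus[1] * 1e3, a1=float(popt[0]),
            a2=float(popt[2]), c=float(popt[4]), bse=bse,
            rss=float(resid @ resid), converged=conv,
            identifiable=conv and popt[1] > 0 and popt[3] > 0,
        )


# ---------------------------------------------------------------------------
# difference currents and shear stress


def difference_current(shear: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Pointwise I_shear - I_control (mechanically recruited current)."""
    shear = np.asarray(shear, float)
    control = np.asarray(control, float)
    if shear.shape != control.shape:
        raise ValueError("traces must have identical shape")
    return shear - control


@dataclass(frozen=True)
class ShearParams:
    """Parallel-plate perfusion chamber parameters.

    viscosity_cP: solution viscosity; flow_mL_min: volumetric flow;
    depth_mm / width_mm: chamber solution depth and width."""

    viscosity_cP: float = 1.02
    flow_mL_min: float = 10.0
    depth_mm: float = 1.0
    width_mm: float = 9.0

    def __post_init__(self):
        if min(self.viscosity_cP, self.flow_mL_min, self.depth_mm, self.width_mm) <= 0:
            raise ValueError("all shear parameters must be > 0")


def shear_stress(p: ShearParams) -> float:
    """Wall shear stress tau = 6*eta*Q/(h^2*w) in dyn/cm^2.

    Unit conversion: cP -> dyn*s/cm^2 (x0.01), mL/min -> cm^3/s (/60),
    mm -> cm (x0.1)."""
    eta = p.viscosity_cP * 0.01
    q = p.flow_mL_min / 60.0
    h = p.depth_mm * 0.1
    w = p.width_mm * 0.1
    return 6.0 * eta * q / (h * h * w)
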