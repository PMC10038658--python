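"""MSA vs MSO model discrimination.

Generates model predictions for the experimental observables (Po versus
voltage per pressure, Po versus pressure per voltage, Po time courses for
pressure steps), refits the pressure sensitivities of each variant to a
measured Po table, and ranks the variants by residual sum of squares.
The qualitative signatures being discriminated: under suction the MSA
model shifts the activation midpoint with an invariant maximum, while the
MSO model raises the maximum and steepens the curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .kinetic_model import (
    KineticScheme,
    RestingPotentialModel,
    default_scheme,
    po_voltage_curve,
    po_pressure_curve,
    stationary_open_probability,
    transient_occupancy,
    Conditions,
)

logger = logging.getLogger(__name__)


def po_model_table(s: KineticScheme, V, P, rp: RestingPotentialModel | None) -> np.ndarray:
    """Model Po at paired (V, P) arrays, resting-potential scatter included
    (64-point Gauss-Hermite over the offset distribution)."""
    V = np.asarray(V, float)
    P = np.asarray(P, float)
    if rp is None or rp.sd == 0:
        off = 0.0 if rp is None else rp.mean
        return stationary_open_probability(s, V - off, P)
    x, w = np.polynomial.hermite_e.hermegauss(64)
    offsets = rp.mean + rp.sd * x
    po = stationary_open_probability(s, V[..., None] - offsets, P[..., None])
    return po @ (w / np.sqrt(2 * np.pi))


@dataclass
class PredictionSet:
    """Model predictions over an experimental design grid."""

    po_vs_voltage: pd.DataFrame  # columns pressure_mmHg, voltage_mV, po
    po_vs_pressure: pd.DataFrame  # columns voltage_mV, pressure_mmHg, po
    po_time: list = field(default_factory=list)  # (times, po(t)) per episode
    variant: str = ""


def predict(
    s: KineticScheme,
    voltages=np.arange(-110.0, -15.0, 5.0),
    pressures=(0.0, -10.0, -30.0, -50.0),
    rp: RestingPotentialModel | None = None,
    episodes=None,
    dt: float = 1e-3,
) -> PredictionSet:
    """Assemble Po(V) per pressure, Po(P) per voltage, and optional Po(t)
    time courses for pressure-step episodes."""
    voltages = np.asarray(voltages, float)
    pressures = np.asarray(pressures, float)
    rows_v = []
    for P in pressures:
        po = po_voltage_curve(s, voltages, P, rp)
        rows_v += [(P, v, p) for v, p in zip(voltages, po)]
    rows_p = []
    for v in voltages:
        po = po_pressure_curve(s, pressures, v)
        rows_p += [(v, P, p) for P, p in zip(pressures, po)]
    po_time = []
    if episodes:
        for segs in episodes:
            conds = [(Conditions(seg.V, seg.P), seg.duration) for seg in segs]
            q0 = conds[0][0]
            from .kinetic_model import build_generator, stationary_occupancy

            p0 = stationary_occupancy(build_generator(s, q0))
            t, occ = transient_occupancy(s, conds, p0, dt)
            po_time.append((t, occ[:, s.open_index]))
    return PredictionSet(
        po_vs_voltage=pd.DataFrame(rows_v, columns=["pressure_mmHg", "voltage_mV", "po"]),
        po_vs_pressure=pd.DataFrame(rows_p, columns=["voltage_mV", "pressure_mmHg", "po"]),
        po_time=po_time,
        variant=s.variant,
    )


@dataclass
class PressureSensitivityResults:
    """Refitted pressure sensitivities for one model variant."""

    variant: str
    kp_forward: float
    kp_backward: float
    se_forward: float
    se_backward: float
    rss: float
    n_points: int
    identifiable: bool
    scheme: KineticScheme
    n_iterations: int = 0

    def summary(self) -> str:
        return (
            f"Pressure-sensitivity fit ({self.variant})\n" + "-" * 40
            + f"\nkp_forward  = {self.kp_forward:9.5f} 1/mmHg (SE {self.se_forward:.5f})"
            + f"\nkp_backward = {self.kp_backward:9.5f} 1/mmHg (SE {self.se_backward:.5f})"
            + f"\nRSS = {self.rss:.5g} over {self.n_points} (V,P) cells"
            + f"\nidentifiable: {self.identifiable}"
        )


class PressureSensitivityModel:
    """Weighted least-squares refit of a variant's kp parameters to a Po
    table keyed by (V, P).

    All other scheme parameters stay at their defaults; initialization at
    the default kp values.  With a single pressure level the sensitivities
    are unidentifiable and the result is flagged.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        variant: str,
        rp: RestingPotentialModel | None = None,
        weights=None,
        free: tuple = ("forward",),
    ):
        req = {"voltage_mV", "pressure_mmHg", "po"}
        if not req <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(req)}")
        g = data.groupby(["voltage_mV", "pressure_mmHg"], as_index=False)["po"].mean()
        self.V = g["voltage_mV"].to_numpy(float)
        self.P = g["pressure_mmHg"].to_numpy(float)
        self.po = g["po"].to_numpy(float)
        self.w = np.ones_like(self.po) if weights is None else np.asarray(weights, float)
        self.variant = variant.upper()
        self.rp = rp
        self.base = default_scheme(self.variant)
        # Stationary Po depends on the kp difference (forward - backward)
        # only, so the default fit frees kp_forward and holds kp_backward at
        # its printed value; pass free=("forward", "backward") to fit both
        # (their difference is then the meaningful quantity).
        if not set(free) <= {"forward", "backward"}:
            raise ValueError("free must be a subset of ('forward', 'backward')")
        self.free = tuple(free)

    def fit(self) -> PressureSensitivityResults:
        identifiable = len(np.unique(self.P)) >= 2
        if not identifiable:
            logger.warning("single pressure level: kp unidentifiable")
        defaults = {"forward": -0.05, "backward": -0.005}

        def unpack(theta):
            vals = dict(defaults)
            for name, v in zip(self.free, theta):
                vals[name] = v
            return vals["forward"], vals["backward"]

        def resid(theta):
            s = self.base.with_pressure_sensitivity(*unpack(theta))
            return (po_model_table(s, self.V, self.P, self.rp) - self.po) * self.w

        x0 = np.array([defaults[n] for n in self.free])
        res = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=2000)
        kp_f, kp_b = unpack(res.x)
        r = res.fun
        dof = max(len(r) - len(self.free), 1)
        s2 = float(r @ r) / dof
        try:
            cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
            se_free = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se_free = np.full(len(self.free), np.nan)
        se_map = dict(zip(self.free, se_free))
        se = np.array([se_map.get("forward", 0.0), se_map.get("backward", 0.0)])
        if not identifiable:
            se = np.array([np.inf, np.inf])
        return PressureSensitivityResults(
            variant=self.variant,
            kp_forward=float(kp_f), kp_backward=float(kp_b),
            se_forward=float(se[0]), se_backward=float(se[1]),
            rss=float(r @ r), n_points=len(r),
            identifiable=identifiable,
            scheme=self.base.with_pressure_sensitivity(kp_f, kp_b),
            n_iterations=int(res.nfev),
        )


def fit_pressure_sensitivity(
    data, variant, rp=None, free=("forward",)
) -> PressureSensitivityResults:
    """Convenience wrapper over :class:`PressureSensitivityModel`."""
    return PressureSensitivityModel(data, variant, rp=rp, free=free).fit()


def paired_ttest(diffs) -> tuple[float, float]:
    """Two-tailed paired t-test on a vector of within-cell differences.

    Implemented directly: t = mean / (sd/sqrt(n)); p from Student's t with
    n-1 degrees of freedom.  Returns (t, p)."""
    d = np.asarray(diffs, float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        return np.nan, np.nan
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(np.abs(d).max(), 1.0):
        return (np.inf if d.mean() != 0 else 0.0), (0.0 if d.mean() != 0 else 1.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def fit_resting_potential(
    control: pd.DataFrame, variant: str = "MSO", sd_bounds=(0.5, 40.0)
) -> RestingPotentialModel:
    """Fit the resting-potential Gaussian (mean, sd) to zero-pressure Po(V)
    data; the two variants are identical at P=0 so the fit is shared."""
    g = control.groupby("voltage_mV", as_index=False)["po"].mean()
    V = g["voltage_mV"].to_numpy(float)
    po = g["po"].to_numpy(float)
    s = default_scheme(variant)

    def resid(theta):
        rp = RestingPotentialModel(theta[0], theta[1])
        return po_model_table(s, V, np.zeros_like(V), rp) - po

    res = least_squares(
        resid, [20.0, 12.0],
        bounds=([-40.0, sd_bounds[0]], [60.0, sd_bounds[1]]),
        xtol=1e-10, ftol=1e-10,
    )
    return RestingPotentialModel(float(res.x[0]), float(res.x[1]))


@dataclass
class ComparisonReport:
    """Which variant better explains a Po table, with supporting numbers."""

    rss: dict  # variant -> {pressure level or "total": rss}
    winner: str | None
    kp: dict  # variant -> (kp_forward, kp_backward)
    kp_se: dict
    resting_potential: RestingPotentialModel | None
    ttests: pd.DataFrame | None  # per-voltage paired ΔPo t-tests
    identifiable: bool = True

    def to_json(self, path=None) -> str:
        doc = {
            "winner": self.winner,
            "identifiable": self.identifiable,
            "rss": {k: {str(p): v for p, v in d.items()} for k, d in self.rss.items()},
            "kp": {k: list(v) for k, v in self.kp.items()},
            "kp_se": {k: list(v) for k, v in self.kp_se.items()},
            "resting_potential": (
                None
                if self.resting_potential is None
                else {"mean": self.resting_potential.mean, "sd": self.resting_potential.sd}
            ),
            "ttests": None if self.ttests is None else self.ttests.to_dict("records"),
        }
        s = json.dumps(doc, indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(s + "\n")
        return s

    def summary(self) -> str:
        lines = ["MSA vs MSO comparison", "-" * 36]
        for v in sorted(self.rss):
            lines.append(f"{v}: total RSS = {self.rss[v]['total']:.5g}  "
                         f"kp = ({self.kp[v][0]:.4f}, {self.kp[v][1]:.4f})")
        lines.append(f"winner: {self.winner}" if self.identifiable
                     else "pressure contrast absent: variants not discriminable")
        return "\n".join(lines)


def compare(
    data: pd.DataFrame,
    rp: RestingPotentialModel | None = None,
    fit_rp: bool = True,
) -> ComparisonReport:
    """Fit both variants (each with its own best kp) to a Po table and rank
    them by residual sum of squares.

    ``data`` columns: voltage_mV, pressure_mmHg, po and optionally cell (for
    the per-voltage paired t-test on ΔPo).  The resting-potential model is
    fitted once on the zero-pressure data and shared by both variants.
    """
    pressures = np.unique(data["pressure_mmHg"])
    identifiable = len(pressures) >= 2
    if not identifiable:
        logger.warning("data covers a single pressure; variants cannot be discriminated")
        return ComparisonReport(
            rss={}, winner=None, kp={}, kp_se={}, resting_potential=rp,
            ttests=None, identifiable=False,
        )
    if rp is None and fit_rp:
        control = data[data["pressure_mmHg"] == 0.0]
        if len(control):
            rp = fit_resting_potential(control)
    rss, kp, kp_se = {}, {}, {}
    for variant in ("MSA", "MSO"):
        fitres = PressureSensitivityModel(data, variant, rp=rp).fit()
        per_level = {}
        g = data.groupby(["voltage_mV", "pressure_mmHg"], as_index=False)["po"].mean()
        model = po_model_table(
            fitres.scheme, g["voltage_mV"].to_numpy(float),
            g["pressure_mmHg"].to_numpy(float), rp,
        )
        resid2 = (model - g["po"].to_numpy(float)) ** 2
        for P in pressures:
            per_level[float(P)] = float(resid2[g["pressure_mmHg"] == P].sum())
        per_level["total"] = float(resid2.sum())
        rss[variant] = per_level
        kp[variant] = (fitres.kp_forward, fitres.kp_backward)
        kp_se[variant] = (fitres.se_forward, fitres.se_backward)
    winner = min(rss, key=lambda v: rss[v]["total"])

    ttests = None
    if "cell" in data.columns:
        test_p = [P for P in pressures if P != 0.0]
        rows = []
        for P in test_p:
            for V in np.unique(data["voltage_mV"]):
                sub = data[data["voltage_mV"] == V]
                a = sub[sub["pressure_mmHg"] == 0.0].groupby("cell")["po"].mean()
                b = sub[sub["pressure_mmHg"] == P].groupby("cell")["po"].mean()
                common = a.index.intersection(b.index)
                d = (b[common] - a[common]).to_numpy()
                t, p = paired_ttest(d)
                rows.append((float(V), float(P), float(np.mean(d)) if len(d) else np.nan,
                             t, p, len(common)))
        ttests = pd.DataFrame(
            rows, columns=["voltage_mV", "pressure_mmHg", "mean_dpo", "t", "p", "n_cells"]
        )
    return ComparisonReport(
        rss=rss, winner=winner, kp=kp, kp_se=kp_se,
        resting_potential=rp, ttests=ttests, identifiable=True,
    )
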