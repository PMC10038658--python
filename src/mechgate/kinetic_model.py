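"""Linear six-state gating model with voltage- and pressure-dependent rates.

The channel is modeled as a reversible birth-death chain

    C1 - C2 - C3 - C4 - C5 - O6

with four voltage-sensor activation steps (C1..C5, multiplicities 4:3:2:1
forward and 1:2:3:4 backward, the standard aggregation for four identical
subunits) followed by a concerted, voltage-insensitive pore-opening step
(C5-O6).  Every rate constant follows

    k(V, P) = k0 * exp(kv * V + kp * P)

with V the membrane potential in mV, P the patch pressure in mmHg (suction
negative), k0 in 1/s, kv in 1/mV and kp in 1/mmHg.

Two model variants differ only in where pressure sensitivity lives:

* MSA (mechanosensitive activation): kp != 0 on the C1..C5 transitions,
  kp = 0 on C5-O6.
* MSO (mechanosensitive opening): kp != 0 only on C5-O6.

At P = 0 the two variants are identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

# Exponent cap: rates saturate rather than overflow (exp(700) ~ 1e304).
_EXP_CAP = 700.0

#: Default model parameters: pre-exponential rates (1/s), voltage
#: sensitivities (1/mV) and pressure sensitivities (1/mmHg).
DEFAULT_PARAMS = {
    "k0_activation": 800.0,
    "k0_deactivation": 0.1,
    "k0_opening": 70.0,
    "k0_closing": 55.0,
    "kv_activation": 0.055,
    "kv_deactivation": -0.055,
    "kp_forward": -0.05,
    "kp_backward": -0.005,
}

STATE_LABELS = ("C1", "C2", "C3", "C4", "C5", "O6")


@dataclass(frozen=True)
class RateLaw:
    """One transition's rate law k(V,P) = k0*exp(kv*V + kp*P).

    k0 is the rate at zero voltage and pressure (1/s); kv (1/mV) and kp
    (1/mmHg) encode voltage and pressure sensitivity (zero means none).
    """

    k0: float
    kv: float = 0.0
    kp: float = 0.0

    def __post_init__(self):
        if not self.k0 > 0:
            raise ValueError(f"k0 must be > 0, got {self.k0}")
        if not (np.isfinite(self.kv) and np.isfinite(self.kp)):
            raise ValueError("kv and kp must be finite")


@dataclass(frozen=True)
class Conditions:
    """Membrane potential V (mV) and patch pressure P (mmHg, suction < 0)."""

    V: float
    P: float = 0.0


def rate(rl: RateLaw, c: Conditions | None = None, *, V=None, P=None):
    """Evaluate a rate law at conditions; vectorized over V and P arrays.

    Overflowing exponents saturate to a large finite rate (with a logged
    warning) instead of producing inf.
    """
    if c is not None:
        V, P = c.V, c.P
    V = np.asarray(V, dtype=float)
    P = 0.0 if P is None else np.asarray(P, dtype=float)
    expo = rl.kv * V + rl.kp * P + np.log(rl.k0)
    if np.any(expo > _EXP_CAP):
        logger.warning("rate law exponent overflow; saturating to exp(%g)", _EXP_CAP)
        expo = np.minimum(expo, _EXP_CAP)
    out = np.exp(expo)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Transition:
    """Directed edge of the chain with its rate law and multiplicity.

    The multiplicity (number of equivalent subunit movements) scales k0;
    ``law`` already includes it, ``base_k0`` is the per-subunit value.
    """

    source: str
    target: str
    law: RateLaw
    multiplicity: int = 1

    @property
    def base_k0(self) -> float:
        return self.law.k0 / self.multiplicity


@dataclass(frozen=True)
class KineticScheme:
    """Six-state chain (or a truncated sub-chain) with per-edge rate laws.

    ``forward[i]`` is the transition states[i] -> states[i+1]; ``backward[i]``
    the reverse.  Exactly one state (the last) is conducting.
    """

    states: tuple[str, ...]
    forward: tuple[Transition, ...]
    backward: tuple[Transition, ...]
    variant: str = "custom"

    def __post_init__(self):
        n = len(self.states)
        if len(self.forward) != n - 1 or len(self.backward) != n - 1:
            raise ValueError("need exactly n-1 forward and backward transitions")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_index(self) -> int:
        """Index of the single conducting state (last in the chain)."""
        return len(self.states) - 1

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        trans = []
        for t in list(self.forward) + list(self.backward):
            trans.append(
                {
                    "from": t.source,
                    "to": t.target,
                    "k0": t.base_k0,
                    "kv": t.law.kv,
                    "kp": t.law.kp,
                    "multiplicity": t.multiplicity,
                }
            )
        return {"states": list(self.states), "transitions": trans, "variant": self.variant}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        states = tuple(d["states"])
        idx = {s: i for i, s in enumerate(states)}
        fwd: dict[int, Transition] = {}
        bwd: dict[int, Transition] = {}
        for t in d["transitions"]:
            i, j = idx[t["from"]], idx[t["to"]]
            m = int(t.get("multiplicity", 1))
            law = RateLaw(k0=t["k0"] * m, kv=t.get("kv", 0.0), kp=t.get("kp", 0.0))
            tr = Transition(t["from"], t["to"], law, m)
            if j == i + 1:
                fwd[i] = tr
            elif j == i - 1:
                bwd[j] = tr
            else:
                raise ValueError(f"non-adjacent transition {t['from']}->{t['to']}")
        n = len(states)
        if sorted(fwd) != list(range(n - 1)) or sorted(bwd) != list(range(n - 1)):
            raise ValueError("transitions do not form a complete chain")
        return cls(
            states=states,
            forward=tuple(fwd[i] for i in range(n - 1)),
            backward=tuple(bwd[i] for i in range(n - 1)),
            variant=d.get("variant", "custom"),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "KineticScheme":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    # -- parameter surgery -------------------------------------------------

    def with_pressure_sensitivity(self, kp_fwd: float, kp_bwd: float) -> "KineticScheme":
        """Return a copy with new kp values on the variant's pressure-sensitive
        transitions (pore step for MSO, activation steps for MSA)."""
        if self.variant not in ("MSA", "MSO"):
            raise ValueError("pressure-sensitivity surgery needs an MSA or MSO scheme")
        n = self.n_states
        pore = n - 2  # final edge index
        fwd, bwd = list(self.forward), list(self.backward)

        def patch(tr, kp):
            return replace(tr, law=replace(tr.law, kp=kp))

        if self.variant == "MSO":
            fwd[pore] = patch(fwd[pore], kp_fwd)
            bwd[pore] = patch(bwd[pore], kp_bwd)
        else:
            for i in range(pore):
                fwd[i] = patch(fwd[i], kp_fwd)
                bwd[i] = patch(bwd[i], kp_bwd)
        return replace(self, forward=tuple(fwd), backward=tuple(bwd))


def default_scheme(variant: str = "MSO", params: dict | None = None) -> KineticScheme:
    """Build the six-state model with the default parameter set.

    variant: "MSA" puts pressure sensitivity on the four activation steps,
    "MSO" on the pore-opening step.  ``params`` may override any key of
    :data:`DEFAULT_PARAMS`.
    """
    variant = variant.upper()
    if variant not in ("MSA", "MSO"):
        raise ValueError(f"unknown variant {variant!r}; expected 'MSA' or 'MSO'")
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        p.update(params)

    act_kp = p["kp_forward"] if variant == "MSA" else 0.0
    deact_kp = p["kp_backward"] if variant == "MSA" else 0.0
    open_kp = p["kp_forward"] if variant == "MSO" else 0.0
    close_kp = p["kp_backward"] if variant == "MSO" else 0.0

    fwd, bwd = [], []
    for i in range(4):  # activation steps C1->C2 .. C4->C5
        mf, mb = 4 - i, i + 1
        fwd.append(
            Transition(
                STATE_LABELS[i],
                STATE_LABELS[i + 1],
                RateLaw(mf * p["k0_activation"], p["kv_activation"], act_kp),
                mf,
            )
        )
        bwd.append(
            Transition(
                STATE_LABELS[i + 1],
                STATE_LABELS[i],
                RateLaw(mb * p["k0_deactivation"], p["kv_deactivation"], deact_kp),
                mb,
            )
        )
    # concerted pore opening: voltage-insensitive in both variants
    fwd.append(Transition("C5", "O6", RateLaw(p["k0_opening"], 0.0, open_kp), 1))
    bwd.append(Transition("O6", "C5", RateLaw(p["k0_closing"], 0.0, close_kp), 1))
    return KineticScheme(STATE_LABELS, tuple(fwd), tuple(bwd), variant)


def two_state_scheme(
    k_open: float = 70.0,
    k_close: float = 55.0,
    kp_open: float = -0.05,
    kp_close: float = -0.005,
) -> KineticScheme:
    """Truncated C5-O6 model: the channel at saturating voltage, where
    deactivation is negligible and gating flickers between the last two
    states."""
    return KineticScheme(
        states=("C5", "O6"),
        forward=(Transition("C5", "O6", RateLaw(k_open, 0.0, kp_open)),),
        backward=(Transition("O6", "C5", RateLaw(k_close, 0.0, kp_close)),),
        variant="custom",
    )


@dataclass(frozen=True)
class GeneratorMatrix:
    """Q-matrix of the chain at fixed conditions (rows sum to zero)."""

    Q: np.ndarray
    conditions: Conditions
    states: tuple[str, ...]


def build_generator(s: KineticScheme, c: Conditions) -> GeneratorMatrix:
    """Evaluate all rate laws at ``c`` and assemble the tridiagonal Q-matrix."""
    n = s.n_states
    Q = np.zeros((n, n))
    for i in range(n - 1):
        Q[i, i + 1] = rate(s.forward[i].law, c)
        Q[i + 1, i] = rate(s.backward[i].law, c)
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    return GeneratorMatrix(Q, c, s.states)


def stationary_occupancy(q: GeneratorMatrix) -> np.ndarray:
    """Equilibrium occupancy π of the chain (πQ = 0, Σπ = 1).

    Uses the exact birth-death product formula, computed in log space:
    π_j ∝ Π_{i<j} f_i/b_i.  Detailed balance holds by construction.
    """
    Q = q.Q
    n = Q.shape[0]
    f = np.array([Q[i, i + 1] for i in range(n - 1)])
    b = np.array([Q[i + 1, i] for i in range(n - 1)])
    if np.any(f <= 0) or np.any(b <= 0):
        raise np.linalg.LinAlgError("chain has a zero rate; equilibrium undefined")
    logpi = np.concatenate([[0.0], np.cumsum(np.log(f) - np.log(b))])
    logpi -= logsumexp(logpi)
    return np.exp(logpi)


def stationary_open_probability(s: KineticScheme, V, P) -> np.ndarray:
    """Stationary Po over (V, P) arrays (broadcast), via the product formula.

    Vectorized equivalent of building the generator and taking the open-state
    component of :func:`stationary_occupancy` at each grid point.
    """
    V, P = np.broadcast_arrays(np.asarray(V, float), np.asarray(P, float))
    n = s.n_states
    logratio = np.zeros((n - 1,) + V.shape)
    for i in range(n - 1):
        fl, bl = s.forward[i].law, s.backward[i].law
        logratio[i] = (
            np.log(fl.k0)
            - np.log(bl.k0)
            + (fl.kv - bl.kv) * V
            + (fl.kp - bl.kp) * P
        )
    logpi = np.concatenate(
        [np.zeros((1,) + V.shape), np.cumsum(logratio, axis=0)], axis=0
    )
    logpo = logpi[-1] - logsumexp(logpi, axis=0)
    out = np.exp(logpo)
    return float(out) if out.ndim == 0 else out


def transient_occupancy(
    s: KineticScheme,
    segments: list[tuple[Conditions, float]],
    p0: np.ndarray,
    dt: float,
):
    """Piecewise matrix-exponential solution of dp/dt = pQ over segments.

    segments: list of (Conditions, duration s); conditions switch
    instantaneously at boundaries.  Returns (times, occupancies) with the
    initial sample p0 at t=0 included; segment durations are rounded to a
    whole number of dt steps.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (s.n_states,) or np.any(p0 < -1e-12) or abs(p0.sum() - 1) > 1e-8:
        raise ValueError("p0 must be a probability vector over the scheme's states")
    times = [0.0]
    occ = [p0]
    t = 0.0
    p = p0
    for c, dur in segments:
        if not dur > 0:
            raise ValueError("segment durations must be > 0")
        nsteps = max(1, int(round(dur / dt)))
        T = expm(build_generator(s, c).Q * dt)
        for _ in range(nsteps):
            p = p @ T
            t += dt
            times.append(t)
            occ.append(p)
    return np.array(times), np.vstack(occ)


@dataclass(frozen=True)
class RestingPotentialModel:
    """Gaussian scatter of the (unmeasurable) cell resting potential.

    In cell-attached recordings the true membrane potential differs from the
    commanded one by an unknown, cell-specific offset.  ``mean`` (mV, >= 0 in
    practice) is the hyperpolarizing offset: V_true = V_command - offset, with
    offset ~ N(mean, sd^2) across cells.  A positive mean therefore shifts the
    apparent Po-vs-command curve toward positive voltages and, with sd > 0,
    makes it shallower — the behaviour seen when comparing single-channel Po
    curves to whole-cell activation.
    """

    mean: float = 20.0
    sd: float = 12.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _gauss_hermite_po(s, Vcmd, P, rp, order):
    x, w = np.polynomial.hermite_e.hermegauss(order)  # weights for N(0,1)
    offsets = rp.mean + rp.sd * x
    Vt = np.asarray(Vcmd, float)[..., None] - offsets
    po = stationary_open_probability(s, Vt, np.asarray(P, float)[..., None])
    return po @ (w / np.sqrt(2 * np.pi))


def po_voltage_curve(
    s: KineticScheme, V_grid, P: float = 0.0, rp: RestingPotentialModel | None = None
) -> np.ndarray:
    """Stationary Po versus commanded voltage at fixed pressure.

    With a resting-potential model the curve is the Gaussian-weighted average
    Po(Vcmd) = ∫ Po(Vcmd - v) N(v; mean, sd²) dv, evaluated by Gauss-Hermite
    quadrature (order refined until stable to 1e-6).
    """
    V_grid = np.atleast_1d(np.asarray(V_grid, float))
    Pv = np.full_like(V_grid, float(P))
    if rp is None or rp.sd == 0:
        po = stationary_open_probability(s, V_grid, Pv)
        if rp is not None and rp.mean != 0:
            po = stationary_open_probability(s, V_grid - rp.mean, Pv)
        return np.atleast_1d(po)
    po = _gauss_hermite_po(s, V_grid, Pv, rp, 64)
    check = _gauss_hermite_po(s, V_grid, Pv, rp, 96)
    if np.max(np.abs(po - check)) > 1e-6:
        po = _gauss_hermite_po(s, V_grid, Pv, rp, 256)
    return po


def po_pressure_curve(s: KineticScheme, P_grid, V: float) -> np.ndarray:
    """Stationary Po versus pressure at fixed voltage."""
    P_grid = np.atleast_1d(np.asarray(P_grid, float))
    return np.atleast_1d(
        stationary_open_probability(s, np.full_like(P_grid, float(V)), P_grid)
    )
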