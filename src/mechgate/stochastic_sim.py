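"""Stochastic single-channel simulation and trace rendering.

Simulates state trajectories of a kinetic scheme under episodic
voltage/pressure protocols (exact Gillespie sampling with piecewise-constant
rates) and renders them into realistic recordings: ohmic unitary current,
band-limited Gaussian noise, and a causal 4-pole Bessel low-pass filter —
the standard anti-alias chain of a patch-clamp rig.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .kinetic_model import (
    Conditions,
    KineticScheme,
    build_generator,
    stationary_occupancy,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant stimulus segment."""

    V: float  # commanded potential, mV
    P: float  # pipette pressure, mmHg (suction negative)
    duration: float  # s


@dataclass(frozen=True)
class StimulusProtocol:
    """Episodic stimulus: ordered episodes of (V, P, duration) segments.

    Segment durations are aligned to integer sample counts at the protocol's
    sampling rate (rounded on construction, with a log message if changed).
    """

    episodes: tuple[tuple[Segment, ...], ...]
    holding_V: float = -120.0
    holding_P: float = 0.0
    interval_s: float = 3.0
    sampling_rate: float = 20_000.0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be > 0")
        snapped = []
        changed = False
        for ep in self.episodes:
            segs = []
            for seg in ep:
                if seg.duration <= 0:
                    raise ValueError("segment durations must be > 0")
                n = max(1, round(seg.duration * self.sampling_rate))
                d = n / self.sampling_rate
                if abs(d - seg.duration) > 1e-12:
                    changed = True
                segs.append(Segment(seg.V, seg.P, d))
            snapped.append(tuple(segs))
        if changed:
            logger.info("segment durations rounded to integer sample counts")
        object.__setattr__(self, "episodes", tuple(snapped))

    def episode_duration(self, i: int = 0) -> float:
        return sum(seg.duration for seg in self.episodes[i])


_LADDER_VOLTAGES = (-100.0, -80.0, -60.0, -40.0, -20.0)


def make_protocol(kind: str, **params) -> StimulusProtocol:
    """Build one of the standard stimulation protocols.

    kind:
      ladder            five 400 ms voltage steps (-100..-20 mV in 20 mV
                        increments) from a -120 mV hold, each split into a
                        200 ms 0-mmHg half and a 200 ms test-pressure half.
                        Pass ``slow_gating=True`` for the 4 s-step / 2 s-half
                        timing used for slow-gating mutants.
      reversibility     1 s voltage steps; test pressure applied for 500 ms
                        in the middle of each step, 0 mmHg before and after;
                        7.5 s inter-sweep interval.
      whole_cell_nachbac two-pulse protocol: step 1 through 0 mV in 10 mV
                        increments from a -120 mV hold, step 2 to -50 mV.
      whole_cell_nav15  two-pulse protocol: step 1 through -10 mV in 5 mV
                        increments from a -130 mV hold, step 2 to -40 mV.

    params: pressure (mmHg, must be <= 0), voltages, step/segment durations,
    sampling_rate — all with protocol-appropriate defaults.
    """
    pressure = float(params.pop("pressure", -10.0))
    if pressure > 0:
        raise ValueError("test pressure must be suction (<= 0 mmHg)")
    fs = float(params.pop("sampling_rate", 20_000.0))

    if kind == "ladder":
        slow = params.pop("slow_gating", False)
        step = float(params.pop("step_duration", 4.0 if slow else 0.4))
        voltages = params.pop("voltages", _LADDER_VOLTAGES)
        _reject_extra(kind, params)
        half = step / 2.0
        eps = tuple(
            (Segment(v, 0.0, half), Segment(v, pressure, half)) for v in voltages
        )
        return StimulusProtocol(eps, holding_V=-120.0, interval_s=3.0, sampling_rate=fs)

    if kind == "reversibility":
        step = float(params.pop("step_duration", 1.0))
        pdur = float(params.pop("pressure_duration", 0.5))
        pre = float(params.pop("pre_duration", 0.25))
        voltages = params.pop("voltages", _LADDER_VOLTAGES)
        _reject_extra(kind, params)
        post = step - pre - pdur
        if post <= 0:
            raise ValueError("pre + pressure durations exceed the step")
        eps = tuple(
            (
                Segment(v, 0.0, pre),
                Segment(v, pressure, pdur),
                Segment(v, 0.0, post),
            )
            for v in voltages
        )
        return StimulusProtocol(eps, holding_V=-120.0, interval_s=7.5, sampling_rate=fs)

    if kind in ("whole_cell_nachbac", "whole_cell_nav15"):
        nachbac = kind == "whole_cell_nachbac"
        hold = -120.0 if nachbac else -130.0
        vmax = 0.0 if nachbac else -10.0
        dv = 10.0 if nachbac else 5.0
        step1 = float(params.pop("step1_duration", 0.5))
        step2_v = float(params.pop("step2_voltage", -50.0 if nachbac else -40.0))
        step2 = float(params.pop("step2_duration", 0.4 if nachbac else 0.05))
        voltages = params.pop(
            "voltages", tuple(np.arange(hold + dv, vmax + dv / 2, dv))
        )
        interval = float(params.pop("interval", 4.75 if nachbac else 1.0))
        _reject_extra(kind, params)
        eps = tuple(
            (Segment(float(v), pressure if pressure else 0.0, step1),
             Segment(step2_v, pressure if pressure else 0.0, step2))
            for v in voltages
        )
        return StimulusProtocol(eps, holding_V=hold, interval_s=interval, sampling_rate=fs)

    raise ValueError(f"unknown protocol kind {kind!r}")


def _reject_extra(kind, params):
    if params:
        raise ValueError(f"unknown parameters for {kind!r}: {sorted(params)}")


@dataclass(frozen=True)
class StatePath:
    """A single stochastic state trajectory over one episode.

    ``states[i]`` is occupied from ``entry_times[i]`` until the next entry
    (or ``duration`` for the last).  Entry times are strictly increasing and
    start at 0.
    """

    states: np.ndarray  # int state indices
    entry_times: np.ndarray  # s
    duration: float
    open_index: int = -1  # index of the conducting state in the scheme
    seed: int | None = None

    def __post_init__(self):
        if len(self.states) != len(self.entry_times):
            raise ValueError("states and entry_times must have equal length")
        if len(self.entry_times) and self.entry_times[0] != 0.0:
            raise ValueError("first entry must be at t=0")

    def occupancy_fraction(self, state_index: int, t0: float, t1: float) -> float:
        """Fraction of [t0, t1] spent in ``state_index``."""
        starts = self.entry_times
        ends = np.append(starts[1:], self.duration)
        sel = self.states == state_index
        lo = np.maximum(starts[sel], t0)
        hi = np.minimum(ends[sel], t1)
        return float(np.clip(hi - lo, 0.0, None).sum() / (t1 - t0))


def simulate_state_path(
    s: KineticScheme,
    episode: tuple[Segment, ...],
    rp_offset: float = 0.0,
    seed=None,
    initial_state: int | None = None,
    holding: Conditions | None = None,
) -> StatePath:
    """Exact Gillespie realization of the scheme over one episode.

    Rates are piecewise-constant within segments, evaluated at the true
    membrane potential V_cmd - rp_offset (rp_offset is the cell's
    hyperpolarizing resting-potential offset) and the segment's pressure.
    At segment boundaries the exponential clock restarts, which is exact by
    memorylessness.  The initial state is drawn from the stationary
    distribution at the holding conditions (default: scheme hold at the
    first segment's voltage is NOT used; pass ``holding`` explicitly or an
    ``initial_state``).
    """
    rng = np.random.default_rng(seed)
    n = s.n_states
    if initial_state is None:
        hold = holding if holding is not None else Conditions(-120.0, 0.0)
        hold_true = Conditions(hold.V - rp_offset, hold.P)
        pi = stationary_occupancy(build_generator(s, hold_true))
        state = int(rng.choice(n, p=pi))
    else:
        state = int(initial_state)

    states = [state]
    entries = [0.0]
    t = 0.0
    seg_start = 0.0
    for seg in episode:
        c = Conditions(seg.V - rp_offset, seg.P)
        Q = build_generator(s, c).Q
        exit_rates = -np.diag(Q)
        seg_end = seg_start + seg.duration
        t = seg_start
        while True:
            r = exit_rates[state]
            if r <= 0:
                break
            t_next = t + rng.exponential(1.0 / r)
            if t_next >= seg_end:
                break
            t = t_next
            # tridiagonal chain: move up or down
            up = Q[state, state + 1] if state + 1 < n else 0.0
            state = state + 1 if rng.random() * r < up else state - 1
            states.append(state)
            entries.append(t)
        seg_start = seg_end
    return StatePath(
        np.asarray(states, dtype=np.int64),
        np.asarray(entries, dtype=float),
        duration=seg_start,
        open_index=s.open_index,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass(frozen=True)
class ObservationModel:
    """How a state trajectory becomes a recorded current.

    gamma_pS: unitary (single-channel) conductance; e_rev_mV: reversal
    potential; unitary current is ohmic, i = gamma*(V - E_rev), inward
    negative.  noise_sd_pA is the POST-filter standard deviation of the
    added Gaussian noise; cutoff_hz / filter_order define the causal Bessel
    low-pass applied to signal plus noise.
    """

    gamma_pS: float = 6.7
    e_rev_mV: float = 55.0
    baseline_pA: float = 0.0
    noise_sd_pA: float = 0.25
    cutoff_hz: float = 5000.0
    filter_order: int = 4

    def __post_init__(self):
        if self.gamma_pS < 0 or self.noise_sd_pA < 0:
            raise ValueError("gamma and noise sd must be >= 0")

    def unitary_current(self, V_mV) -> np.ndarray:
        """Open-channel current (pA) at commanded voltage."""
        return self.gamma_pS * 1e-3 * (np.asarray(V_mV, float) - self.e_rev_mV)


@dataclass
class TraceRecording:
    """A sampled current trace aligned to its stimulus.

    current is in pA (physical convention: inward negative); voltage (mV)
    and pressure (mmHg) are the per-sample commanded stimulus.
    """

    current: np.ndarray
    voltage: np.ndarray
    pressure: np.ndarray
    sampling_rate: float
    bandwidth: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.current) == len(self.voltage) == len(self.pressure)):
            raise ValueError("current/voltage/pressure must have equal length")
        if self.bandwidth > self.sampling_rate / 2:
            raise ValueError("bandwidth cannot exceed Nyquist")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.current)) / self.sampling_rate

    def write(self, path) -> None:
        """Write TSV (time_s, current_pA, voltage_mV, pressure_mmHg) plus a
        JSON sidecar with acquisition metadata."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("time_s\tcurrent_pA\tvoltage_mV\tpressure_mmHg\n")
            t = self.time
            for i in range(len(t)):
                fh.write(
                    "%.9g\t%.6g\t%.6g\t%.6g\n"
                    % (t[i], self.current[i], self.voltage[i], self.pressure[i])
                )
        sidecar = {
            "sampling_rate_hz": self.sampling_rate,
            "bandwidth_hz": self.bandwidth,
            **self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, path) -> "TraceRecording":
        path = Path(path)
        data = np.loadtxt(path, skiprows=1)
        data = np.atleast_2d(data)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        fs = meta.pop("sampling_rate_hz")
        bw = meta.pop("bandwidth_hz")
        return cls(
            current=data[:, 1],
            voltage=data[:, 2],
            pressure=data[:, 3],
            sampling_rate=fs,
            bandwidth=bw,
            metadata=meta,
        )


def episode_sample_arrays(episode, sampling_rate):
    """Per-sample commanded (V, P) arrays for an episode's segments."""
    V, P = [], []
    for seg in episode:
        n = round(seg.duration * sampling_rate)
        V.append(np.full(n, seg.V))
        P.append(np.full(n, seg.P))
    return np.concatenate(V), np.concatenate(P)


def _bessel_sos(cutoff, fs, order):
    return signal.bessel(order, cutoff, btype="low", fs=fs, output="sos", norm="mag")


def _noise_gain(sos, fs, nfreq=2048):
    """sd ratio (output/input) of the filter on white noise."""
    _, h = signal.sosfreqz(sos, worN=nfreq, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 2)))


def lowpass(x: np.ndarray, cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    """Causal Bessel low-pass, initialized at steady state of the first
    sample (no startup transient for constant inputs)."""
    sos = _bessel_sos(cutoff, fs, order)
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def _open_fraction_per_sample(path: StatePath, open_index: int, n_samples: int, fs: float):
    """Box-car integral of the open indicator over each sample tick."""
    starts = path.entry_times
    ends = np.append(starts[1:], path.duration)
    sel = path.states == open_index
    o_start, o_end = starts[sel], ends[sel]
    if len(o_start) == 0:
        return np.zeros(n_samples)
    # cumulative open time as a piecewise-linear function of time
    durs = o_end - o_start
    cum_hi = np.cumsum(durs)
    cum_lo = cum_hi - durs
    bp_t = np.concatenate([[0.0], np.column_stack([o_start, o_end]).ravel(), [path.duration]])
    cum = np.concatenate([[0.0], np.column_stack([cum_lo, cum_hi]).ravel(), [cum_hi[-1]]])
    edges = np.arange(n_samples + 1) / fs
    cum_at_edges = np.interp(edges, bp_t, cum)
    return np.diff(cum_at_edges) * fs


def render_trace(
    path: StatePath,
    om: ObservationModel,
    episode: tuple[Segment, ...],
    sampling_rate: float = 20_000.0,
    seed=None,
    metadata: dict | None = None,
) -> TraceRecording:
    """Render a state path into a noisy, filtered current recording.

    Each sample is the box-car average of the ideal current over its tick
    (sub-sample dwells weight the amplitude), plus white Gaussian noise
    pre-scaled so that the post-filter noise sd equals ``om.noise_sd_pA``;
    signal plus noise then pass through the causal Bessel low-pass.
    """
    fs = sampling_rate
    if om.cutoff_hz >= fs / 2:
        raise ValueError("filter cutoff must be below Nyquist")
    V, P = episode_sample_arrays(episode, fs)
    n = len(V)
    if path.open_index < 0:
        raise ValueError("state path does not record its conducting state index")
    open_frac = _open_fraction_per_sample(path, path.open_index, n, fs)
    ideal = om.baseline_pA + open_frac * om.unitary_current(V)
    x = ideal
    if om.noise_sd_pA > 0:
        sos = _bessel_sos(om.cutoff_hz, fs, om.filter_order)
        g = _noise_gain(sos, fs)
        rng = np.random.default_rng(seed)
        x = ideal + rng.standard_normal(n) * (om.noise_sd_pA / g)
    y = lowpass(x, om.cutoff_hz, fs, om.filter_order)
    meta = {}
    if metadata:
        meta.update(metadata)
    return TraceRecording(
        current=y,
        voltage=V,
        pressure=P,
        sampling_rate=fs,
        bandwidth=om.cutoff_hz,
        metadata=meta,
    )


def ensemble_average(
    s: KineticScheme,
    episode: tuple[Segment, ...],
    om: ObservationModel,
    n: int,
    seed=None,
    rp_offset: float = 0.0,
    sampling_rate: float = 20_000.0,
    holding: Conditions | None = None,
) -> TraceRecording:
    """Pointwise mean of n rendered sweeps (macroscopic average).

    With zero observation noise this converges to the scaled open-occupancy
    time course of the model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n)
    acc = None
    last = None
    for i in range(n):
        pathi = simulate_state_path(
            s,
            episode,
            rp_offset=rp_offset,
            seed=np.random.default_rng(children[2 * i]),
            holding=holding,
        )
        tr = render_trace(pathi, om, episode, sampling_rate, seed=children[2 * i + 1])
        acc = tr.current.copy() if acc is None else acc + tr.current
        last = tr
    return TraceRecording(
        current=acc / n,
        voltage=last.voltage,
        pressure=last.pressure,
        sampling_rate=sampling_rate,
        bandwidth=om.cutoff_hz,
        metadata={"n_sweeps": n},
    )
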