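"""Seeded synthetic studies emulating the single-channel and whole-cell
experiments, so every pipeline stage is testable without recordings.

A study is a cohort of cell-attached patches, each holding one channel
obeying the six-state model.  Cells differ by a Gaussian-scattered
resting-potential offset (default mean +20 mV, sd 12 mV — reproducing the
shallower, ~20 mV right-shifted single-channel Po curve relative to
whole-cell activation).  Sweeps follow the paired-pressure voltage-ladder
protocol; traces carry sub-pA unitary currents in band-limited Gaussian
noise.  Sweeps are generated unconditionally (eventless sweeps included);
any selection happens downstream in the dwell analysis, reproducing the
selection bias of real analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetic_model import (
    Conditions,
    KineticScheme,
    RestingPotentialModel,
    default_scheme,
    transient_occupancy,
    build_generator,
    stationary_occupancy,
)
from .stochastic_sim import (
    ObservationModel,
    Segment,
    StimulusProtocol,
    TraceRecording,
    episode_sample_arrays,
    make_protocol,
    render_trace,
    simulate_state_path,
)
from .idealization import refilter, half_amplitude_idealize, paired_po_response
from .model_compare import paired_ttest

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Parameters of a synthetic single-channel study.

    Defaults mirror a realistic cohort: 12 cells, 150 ladder sweeps per
    cell, one test pressure, 20 kHz sampling with 5 kHz online bandwidth,
    0.25 pA post-filter noise.  ``kp_forward``/``kp_backward`` override the
    scheme's pressure sensitivities (e.g. a pore-hinge mutant is emulated
    by scaling kp_forward down)."""

    variant: str = "MSO"
    n_cells: int = 12
    sweeps_per_cell: int = 150
    pressures: tuple = (-10.0,)
    protocol_kind: str = "ladder"
    protocol_params: dict = field(default_factory=dict)
    observation: ObservationModel = field(default_factory=ObservationModel)
    resting_potential: RestingPotentialModel = field(
        default_factory=RestingPotentialModel
    )
    kp_forward: float | None = None
    kp_backward: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if any(p > 0 for p in self.pressures):
            raise ValueError("pressures must be suction (<= 0 mmHg)")

    def scheme(self) -> KineticScheme:
        s = default_scheme(self.variant)
        if self.kp_forward is not None or self.kp_backward is not None:
            kf = self.kp_forward if self.kp_forward is not None else -0.05
            kb = self.kp_backward if self.kp_backward is not None else -0.005
            s = s.with_pressure_sensitivity(kf, kb)
        return s

    def protocol(self, pressure: float) -> StimulusProtocol:
        return make_protocol(self.protocol_kind, pressure=pressure, **self.protocol_params)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["observation"] = asdict(self.observation)
        d["resting_potential"] = asdict(self.resting_potential)
        d["pressures"] = list(self.pressures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["observation"] = ObservationModel(**d["observation"])
        d["resting_potential"] = RestingPotentialModel(**d["resting_potential"])
        d["pressures"] = tuple(d["pressures"])
        return cls(**d)


def generate_cells(cfg: StudyConfig) -> list[dict]:
    """Draw per-cell resting-potential offsets (mV, hyperpolarizing) and
    per-cell seed material from the master seed."""
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    offsets = rng.normal(cfg.resting_potential.mean, cfg.resting_potential.sd, cfg.n_cells)
    cell_seeds = ss.spawn(cfg.n_cells)
    return [
        {"cell_id": f"cell{i:03d}", "resting_offset_mV": float(offsets[i]),
         "seed": cell_seeds[i]}
        for i in range(cfg.n_cells)
    ]


def _sweep_pressure(cfg, sweep_index):
    return float(cfg.pressures[sweep_index % len(cfg.pressures)])


def simulate_ladder_cohort(cfg: StudyConfig) -> pd.DataFrame:
    """Fast cohort simulation: exact per-segment open occupancies from the
    stochastic state paths, without rendering noisy traces.

    Returns one row per (cell, sweep, voltage step, pressure segment) with
    the segment's open-time fraction.  Ideal for steady-state Po analyses;
    use :func:`rendered_ladder_po_table` when the full recording chain
    (noise, filtering, idealization) matters.
    """
    scheme = cfg.scheme()
    rows = []
    for cell in generate_cells(cfg):
        rng = np.random.default_rng(cell["seed"])
        off = cell["resting_offset_mV"]
        for sw in range(cfg.sweeps_per_cell):
            pressure = _sweep_pressure(cfg, sw)
            proto = cfg.protocol(pressure)
            for ep in proto.episodes:
                path = simulate_state_path(
                    scheme, ep, rp_offset=off, seed=rng,
                    holding=Conditions(proto.holding_V, proto.holding_P),
                )
                t0 = 0.0
                for seg in ep:
                    po = path.occupancy_fraction(scheme.open_index, t0, t0 + seg.duration)
                    rows.append(
                        (cell["cell_id"], sw, seg.V, seg.P, po)
                    )
                    t0 += seg.duration
    return pd.DataFrame(rows, columns=["cell", "sweep", "voltage_mV", "pressure_mmHg", "po"])


def rendered_ladder_po_table(
    cfg: StudyConfig, analysis_cutoff_hz: float = 500.0
) -> pd.DataFrame:
    """Full-chain cohort: render noisy traces, digitally refilter to the
    analysis bandwidth, idealize by half-amplitude threshold, and return the
    per-segment Po table (same columns as :func:`simulate_ladder_cohort`).

    The open-level amplitude seed for thresholding comes from the
    observation model's unitary current at each step voltage; 2/cutoff
    after each segment boundary is excluded as filter settle time.
    """
    scheme = cfg.scheme()
    om = cfg.observation
    settle = 2.0 / analysis_cutoff_hz
    rows = []
    for cell in generate_cells(cfg):
        rng = np.random.default_rng(cell["seed"])
        off = cell["resting_offset_mV"]
        for sw in range(cfg.sweeps_per_cell):
            pressure = _sweep_pressure(cfg, sw)
            proto = cfg.protocol(pressure)
            fs = proto.sampling_rate
            for ep in proto.episodes:
                path = simulate_state_path(
                    scheme, ep, rp_offset=off, seed=rng,
                    holding=Conditions(proto.holding_V, proto.holding_P),
                )
                noise_seed = int(rng.integers(0, 2**31))
                tr = render_trace(path, om, ep, fs, seed=noise_seed)
                tr = refilter(tr, analysis_cutoff_hz)
                amp = float(abs(om.unitary_current(ep[0].V)))
                it = half_amplitude_idealize(tr, amp, noise_sd=None)
                po0, po1, _ = paired_po_response(it, ep, settle_s=settle)
                rows.append((cell["cell_id"], sw, ep[0].V, ep[0].P, po0))
                rows.append((cell["cell_id"], sw, ep[1].V, ep[1].P, po1))
    return pd.DataFrame(rows, columns=["cell", "sweep", "voltage_mV", "pressure_mmHg", "po"])


def analyze_ladder_cohort(po_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort paired-pressure summary per voltage.

    Collapses the Po table to per-cell means at each (voltage, pressure),
    forms within-cell ΔPo = Po(test P) - Po(0), and runs the paired
    two-tailed t-test across cells.  Returns one row per (voltage, test
    pressure)."""
    pressures = sorted(p for p in po_table["pressure_mmHg"].unique() if p != 0.0)
    rows = []
    for P in pressures:
        for V in sorted(po_table["voltage_mV"].unique()):
            sub = po_table[po_table["voltage_mV"] == V]
            a = sub[sub["pressure_mmHg"] == 0.0].groupby("cell")["po"].mean()
            b = sub[sub["pressure_mmHg"] == P].groupby("cell")["po"].mean()
            common = a.index.intersection(b.index)
            d = (b[common] - a[common]).to_numpy()
            t, p = paired_ttest(d)
            rows.append((V, P, float(a[common].mean()), float(b[common].mean()),
                         float(d.mean()), t, p, len(common)))
    return pd.DataFrame(
        rows,
        columns=["voltage_mV", "pressure_mmHg", "po_control", "po_pressure",
                 "mean_dpo", "t", "p", "n_cells"],
    )


def generate_study(cfg: StudyConfig, out_dir) -> dict:
    """Write a complete on-disk study: per-sweep TSV traces with JSON
    sidecars, one blank (eventless) sweep per cell for subtraction, and a
    manifest sufficient to regenerate everything byte-identically (same
    config, same master seed -> same files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = cfg.scheme()
    om = cfg.observation
    files = []
    cells_meta = []
    for cell in generate_cells(cfg):
        rng = np.random.default_rng(cell["seed"])
        off = cell["resting_offset_mV"]
        cells_meta.append({"cell_id": cell["cell_id"], "resting_offset_mV": off})
        for sw in range(cfg.sweeps_per_cell):
            pressure = _sweep_pressure(cfg, sw)
            proto = cfg.protocol(pressure)
            fs = proto.sampling_rate
            currents, volts, press = [], [], []
            for ep in proto.episodes:
                path = simulate_state_path(
                    scheme, ep, rp_offset=off, seed=rng,
                    holding=Conditions(proto.holding_V, proto.holding_P),
                )
                noise_seed = int(rng.integers(0, 2**31))
                tr = render_trace(path, om, ep, fs, seed=noise_seed)
                currents.append(tr.current)
                volts.append(tr.voltage)
                press.append(tr.pressure)
            rec = TraceRecording(
                current=np.concatenate(currents),
                voltage=np.concatenate(volts),
                pressure=np.concatenate(press),
                sampling_rate=fs,
                bandwidth=om.cutoff_hz,
                metadata={
                    "cell_id": cell["cell_id"], "sweep": sw,
                    "resting_offset_mv": off, "seed": cfg.seed,
                },
            )
            fname = f"{cell['cell_id']}_sweep{sw:04d}.tsv"
            rec.write(out / fname)
            files.append(fname)
        # blank: closed channel, noise only
        proto = cfg.protocol(_sweep_pressure(cfg, 0))
        fs = proto.sampling_rate
        blanks_i, blanks_v, blanks_p = [], [], []
        for ep in proto.episodes:
            V, P = episode_sample_arrays(ep, fs)
            from .stochastic_sim import _bessel_sos, _noise_gain, lowpass

            noise_seed = int(rng.integers(0, 2**31))
            nrng = np.random.default_rng(noise_seed)
            if om.noise_sd_pA > 0:
                sos = _bessel_sos(om.cutoff_hz, fs, om.filter_order)
                g = _noise_gain(sos, fs)
                x = nrng.standard_normal(len(V)) * (om.noise_sd_pA / g)
                x = lowpass(x, om.cutoff_hz, fs, om.filter_order)
            else:
                x = np.zeros(len(V))
            blanks_i.append(x + om.baseline_pA)
            blanks_v.append(V)
            blanks_p.append(P)
        blank = TraceRecording(
            current=np.concatenate(blanks_i),
            voltage=np.concatenate(blanks_v),
            pressure=np.concatenate(blanks_p),
            sampling_rate=fs,
            bandwidth=om.cutoff_hz,
            metadata={"cell_id": cell["cell_id"], "blank": True, "seed": cfg.seed},
        )
        bname = f"{cell['cell_id']}_blank.tsv"
        blank.write(out / bname)
        files.append(bname)

    from mechgate import __version__

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "cells": cells_meta,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def regenerate_study(manifest_path, out_dir) -> dict:
    """Rebuild a study from its manifest (byte-identical to the original)."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = StudyConfig.from_dict(manifest["config"])
    return generate_study(cfg, out_dir)


# ---------------------------------------------------------------------------
# whole-cell synthetic data


def whole_cell_study(
    cfg: StudyConfig,
    n_channels: int = 500,
    shear_effective_mmHg: float = -10.0,
    capacitance_pF: float = 10.0,
    noise_sd_pA: float = 5.0,
    sampling_rate: float = 2000.0,
    conditions=("control", "shear", "post"),
):
    """Synthetic whole-cell two-pulse sweep sets per cell and condition.

    Macroscopic currents are N independent channels x unitary current x
    open occupancy from the deterministic matrix-exponential solution.
    Fluid shear has no printed pressure calibration, so it is mapped to an
    effective patch pressure (default -10 mmHg equivalent) during the
    'shear' condition; 'post' returns to zero.  Returns
    {cell_id: {condition: SweepSet}}.
    """
    from .macroscopic_analysis import SweepSet

    scheme = cfg.scheme()
    om = cfg.observation
    proto = make_protocol("whole_cell_nachbac", sampling_rate=sampling_rate)
    dt = 1.0 / sampling_rate
    ss = np.random.SeedSequence(cfg.seed)
    out = {}
    for ci, cell in enumerate(generate_cells(cfg)):
        rng = np.random.default_rng(cell["seed"])
        cell_sets = {}
        for cond in conditions:
            peff = shear_effective_mmHg if cond == "shear" else 0.0
            sweeps = {}
            step2 = {}
            for ep in proto.episodes:
                v1 = ep[0].V
                conds = [(Conditions(seg.V, peff), seg.duration) for seg in ep]
                p_hold = stationary_occupancy(
                    build_generator(scheme, Conditions(proto.holding_V, peff))
                )
                t, occ = transient_occupancy(scheme, conds, p_hold, dt)
                po = occ[:, scheme.open_index]
                V, _ = episode_sample_arrays(ep, sampling_rate)
                npts = min(len(V), len(po) - 1)
                i = (
                    n_channels * om.unitary_current(V[:npts]) * po[1:npts + 1]
                    + rng.standard_normal(npts) * noise_sd_pA
                )
                sweeps[v1] = i
                n1 = round(ep[0].duration * sampling_rate)
                step2_trace = i[n1:]
                step2[v1] = float(step2_trace.min()) if len(step2_trace) else 0.0
            n1 = round(proto.episodes[0][0].duration * sampling_rate)
            cell_sets[cond] = SweepSet(
                sweeps=sweeps,
                sampling_rate=sampling_rate,
                capacitance_pF=capacitance_pF,
                condition=cond,
                cell_id=cell["cell_id"],
                step1_window=slice(0, n1),
                step2_peaks=step2,
            )
        out[cell["cell_id"]] = cell_sets
    return out
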