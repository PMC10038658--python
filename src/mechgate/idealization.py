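"""Trace idealization and open-probability estimation.

Two cross-checked estimators of single-channel open probability:

* half-amplitude thresholding — classify each sample open/closed against
  half the open-level amplitude and collapse runs into dwells;
* all-point amplitude histograms fitted with a sum of two Gaussians, with
  Po taken as the relative weight of the open-level component,
  Po = A2/(A1+A2).

Analysis operates on magnitude-inverted currents (inward current is stored
negative; histograms and thresholds use the positive-going open level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .stochastic_sim import TraceRecording, lowpass

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trace conditioning


def subtract_blank(trace: TraceRecording, blanks) -> TraceRecording:
    """Subtract the pointwise mean of blank (eventless) sweeps.

    Removes capacitive and passive leak components shared by all sweeps.
    """
    blanks = list(blanks)
    if not blanks:
        raise ValueError("need at least one blank sweep")
    for b in blanks:
        if len(b.current) != len(trace.current):
            raise ValueError("blank length does not match trace")
    mean_blank = np.mean([b.current for b in blanks], axis=0)
    return replace(trace, current=trace.current - mean_blank)


def refilter(trace: TraceRecording, cutoff_hz: float) -> TraceRecording:
    """Digitally low-pass the trace to a narrower bandwidth (causal Bessel).

    The cutoff must be below the trace's current bandwidth.
    """
    if cutoff_hz >= trace.bandwidth:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below current bandwidth {trace.bandwidth} Hz"
        )
    y = lowpass(trace.current, cutoff_hz, trace.sampling_rate)
    return replace(trace, current=y, bandwidth=cutoff_hz)


# ---------------------------------------------------------------------------
# all-point histograms


@dataclass(frozen=True)
class AllPointHistogram:
    """Histogram of every sample magnitude in a segment."""

    edges: np.ndarray  # pA, len = n_bins + 1
    counts: np.ndarray  # float (density if normalized)
    bin_width: float
    normalized: bool

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _select_samples(trace: TraceRecording, segment) -> np.ndarray:
    """Resolve a segment selector into a sample array.

    segment may be None (all samples), a boolean mask, a slice, or a (V, P)
    pair selecting samples with that commanded stimulus.
    """
    x = trace.current
    if segment is None:
        return x
    if isinstance(segment, slice):
        return x[segment]
    segment = np.asarray(segment) if not isinstance(segment, tuple) else segment
    if isinstance(segment, tuple) and len(segment) == 2:
        V, P = segment
        mask = np.isclose(trace.voltage, V) & np.isclose(trace.pressure, P)
        return x[mask]
    return x[np.asarray(segment)]


def allpoint_histogram(
    trace: TraceRecording,
    segment=None,
    bin_width: float = 0.2,
    normalize: bool = True,
    invert: bool = True,
) -> AllPointHistogram:
    """All-point amplitude histogram of the selected segment.

    bin_width in pA (0.2 pA for single sweeps, 0.05 pA for pooled data are
    the conventional choices).  With ``normalize`` the bin areas sum to 1.
    ``invert`` flips the sign so the open level is positive.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    x = _select_samples(trace, segment)
    if x.size == 0:
        raise ValueError("selected segment contains no samples")
    if invert:
        x = -x
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    counts = counts.astype(float)
    if normalize:
        counts /= counts.sum() * bin_width
    return AllPointHistogram(edges, counts, bin_width, normalize)


# ---------------------------------------------------------------------------
# two-Gaussian mixture fit


def _two_gauss(x, mu1, s1, a1, mu2, s2, a2, c):
    g1 = a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    g2 = a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    return g1 + g2 + c


@dataclass
class TwoGaussianResults:
    """Fitted closed/open amplitude components and the derived Po."""

    mu_closed: float
    sd_closed: float
    weight_closed: float
    mu_open: float
    sd_open: float
    weight_open: float
    baseline: float
    po: float
    converged: bool
    rss: float
    n_bins: int
    method: str

    @property
    def open_amplitude(self) -> float:
        """Open-level amplitude relative to the closed level (pA)."""
        return self.mu_open - self.mu_closed

    def summary(self) -> str:
        lines = [
            "Two-Gaussian amplitude fit (%s)" % self.method,
            "-" * 44,
            f"closed: mu={self.mu_closed:8.4f} pA  sd={self.sd_closed:.4f}  A={self.weight_closed:.4f}",
            f"open:   mu={self.mu_open:8.4f} pA  sd={self.sd_open:.4f}  A={self.weight_open:.4f}",
            f"baseline C = {self.baseline:.5f}",
            f"Po = A2/(A1+A2) = {self.po:.4f}",
            f"converged: {self.converged}   RSS: {self.rss:.4g}   bins: {self.n_bins}",
        ]
        return "\n".join(lines)


class TwoGaussianMixture:
    """Model for the two-level amplitude distribution of a single channel.

    Built from an :class:`AllPointHistogram` (least-squares backend) and
    optionally the raw samples (EM backend).  ``fit`` returns
    :class:`TwoGaussianResults`; Po is the open component's relative weight.
    """

    def __init__(
        self,
        histogram: AllPointHistogram,
        samples: np.ndarray | None = None,
        expected_amplitude: float | None = None,
    ):
        if np.count_nonzero(histogram.counts) < 10:
            raise ValueError("histogram needs at least 10 nonempty bins")
        self.histogram = histogram
        self.samples = None if samples is None else np.asarray(samples, float)
        # Optional open-level amplitude seed (pA): constrains the separation
        # between the two means, which keeps the fit well-posed on (nearly)
        # one-level data where the open component's weight must pin near 0.
        self.expected_amplitude = expected_amplitude

    # -- initial values ----------------------------------------------------

    def _default_init(self):
        h = self.histogram
        c, y = h.centers, h.counts
        # candidate levels: the two largest well-separated local maxima;
        # the closed level is the more negative one (inverted-data scale)
        grad_up = np.r_[True, y[1:] >= y[:-1]]
        grad_dn = np.r_[y[:-1] >= y[1:], True]
        peaks = np.where(grad_up & grad_dn & (y > 0))[0]
        mode = peaks[np.argmax(y[peaks])] if len(peaks) else int(np.argmax(y))
        far = peaks[np.abs(c[peaks] - c[mode]) > 2 * h.bin_width]
        far = far[y[far] >= 0.1 * y[mode]]  # noise bumps don't qualify
        if self.expected_amplitude is not None:
            # only peaks at a plausible open-level separation qualify
            sep = np.abs(c[far] - c[mode])
            far = far[(sep >= 0.4 * self.expected_amplitude)
                      & (sep <= 2.5 * self.expected_amplitude)]
        if len(far):
            second = far[np.argmax(y[far])]
            mu1, mu2 = sorted((c[mode], c[second]))
            delta = mu2 - mu1
        else:
            mu1 = c[mode]
            delta = (
                self.expected_amplitude
                if self.expected_amplitude is not None
                else 5 * h.bin_width
            )
        delta = max(delta, 2 * h.bin_width)
        s0 = max(2 * h.bin_width, 0.05)
        total = y.sum() * h.bin_width
        near1 = y[np.abs(c - mu1) < 2 * s0].sum() * h.bin_width
        a1 = float(np.clip(near1, 0.05 * total, 0.95 * total))
        return [mu1, s0, a1, delta, s0, max(total - a1, 1e-3), 0.0]

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "ls", init=None) -> TwoGaussianResults:
        """Fit the mixture.  ``init`` (optional) is
        [mu_closed, sd_closed, A1, mu_open, sd_open, A2, C]; internally the
        open mean is parametrized as mu_closed + delta with delta bounded
        away from zero (and near the expected amplitude when one is given),
        which keeps the two components from collapsing onto one level."""
        if method == "em":
            return self._fit_em()
        if method != "ls":
            raise ValueError("method must be 'ls' or 'em'")
        h = self.histogram
        if init is not None:
            p0 = [init[0], init[1], init[2], init[3] - init[0], init[4], init[5], init[6]]
        else:
            p0 = self._default_init()
        if self.expected_amplitude is not None:
            dlo, dhi = 0.4 * self.expected_amplitude, 2.5 * self.expected_amplitude
        else:
            dlo, dhi = 2 * h.bin_width, np.inf
        p0[3] = np.clip(p0[3], dlo * 1.001 if np.isfinite(dlo) else dlo, dhi * 0.999 if np.isfinite(dhi) else dhi)
        f = lambda x, mu1, s1, a1, d, s2, a2, c: _two_gauss(x, mu1, s1, a1, mu1 + d, s2, a2, c)
        # sds capped at the histogram span and baseline kept non-negative:
        # rules out the degenerate wide-component-plus-negative-baseline fit
        span = h.edges[-1] - h.edges[0]
        if self.expected_amplitude is not None:
            # with a known amplitude scale, the closed mean stays near its
            # initialization (prevents the components trading places)
            mu_lo = p0[0] - 0.3 * self.expected_amplitude
            mu_hi = p0[0] + 0.3 * self.expected_amplitude
        else:
            mu_lo, mu_hi = -np.inf, np.inf
        lb = [mu_lo, 1e-6, 0.0, dlo, 1e-6, 0.0, 0.0]
        ub = [mu_hi, span, np.inf, dhi, span, np.inf, np.inf]
        # pad zero-count bins so the whole admissible open-level range lies
        # on the fit grid (otherwise an out-of-support open component is
        # unconstrained on one-level data)
        cfit, yfit = h.centers, h.counts
        d_reach = dhi if np.isfinite(dhi) else p0[3]
        pad_to = p0[0] + d_reach + 4 * p0[4]
        if pad_to > cfit[-1]:
            extra = np.arange(cfit[-1] + h.bin_width, pad_to + h.bin_width, h.bin_width)
            cfit = np.concatenate([cfit, extra])
            yfit = np.concatenate([yfit, np.zeros(len(extra))])
        try:
            popt, _ = curve_fit(f, cfit, yfit, p0=p0, bounds=(lb, ub), maxfev=20000)
            converged = True
        except RuntimeError:
            popt, converged = np.array(p0, float), False
        popt = np.array([popt[0], popt[1], popt[2], popt[0] + popt[3],
                         popt[4], popt[5], popt[6]])
        resid = h.counts - _two_gauss(h.centers, *popt)
        a1, a2 = popt[2], popt[5]
        po = a2 / (a1 + a2) if converged and (a1 + a2) > 0 else np.nan
        return TwoGaussianResults(
            mu_closed=popt[0], sd_closed=popt[1], weight_closed=a1,
            mu_open=popt[3], sd_open=popt[4], weight_open=a2,
            baseline=popt[6], po=po, converged=converged,
            rss=float(resid @ resid), n_bins=len(h.counts), method="ls",
        )

    def _fit_em(self, max_iter: int = 500, tol: float = 1e-8) -> TwoGaussianResults:
        """Two-component Gaussian EM on the raw samples (no baseline term)."""
        if self.samples is None:
            raise ValueError("EM backend needs the raw samples")
        x = self.samples
        mu = np.array([np.percentile(x, 25), np.percentile(x, 90)])
        sd = np.full(2, max(x.std() / 2, 1e-3))
        w = np.array([0.5, 0.5])
        ll_old = -np.inf
        converged = False
        for _ in range(max_iter):
            logp = (
                -0.5 * ((x[:, None] - mu) / sd) ** 2
                - np.log(sd * np.sqrt(2 * np.pi))
                + np.log(w)
            )
            m = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - m)
            norm = p.sum(axis=1, keepdims=True)
            r = p / norm
            ll = float((np.log(norm[:, 0]) + m[:, 0]).sum())
            nk = r.sum(axis=0)
            w = nk / len(x)
            mu = (r * x[:, None]).sum(axis=0) / nk
            sd = np.sqrt((r * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
            sd = np.maximum(sd, 1e-6)
            if abs(ll - ll_old) < tol * (1 + abs(ll)):
                converged = True
                break
            ll_old = ll
        order = np.argsort(mu)
        mu, sd, w = mu[order], sd[order], w[order]
        return TwoGaussianResults(
            mu_closed=mu[0], sd_closed=sd[0], weight_closed=w[0],
            mu_open=mu[1], sd_open=sd[1], weight_open=w[1],
            baseline=0.0, po=w[1] / (w[0] + w[1]), converged=converged,
            rss=np.nan, n_bins=len(self.histogram.counts), method="em",
        )


def fit_two_gaussians(
    h: AllPointHistogram, init=None, expected_amplitude: float | None = None
) -> TwoGaussianResults:
    """Least-squares two-Gaussian fit of an all-point histogram."""
    return TwoGaussianMixture(h, expected_amplitude=expected_amplitude).fit(init=init)


# ---------------------------------------------------------------------------
# half-amplitude threshold idealization


@dataclass(frozen=True)
class IdealizedTrace:
    """Two-level event sequence: alternating closed(0)/open(1) dwells."""

    levels: np.ndarray  # 0 closed, 1 open
    starts: np.ndarray  # s
    durations: np.ndarray  # s
    threshold: float  # pA (magnitude-inverted scale)
    source_id: str = ""

    def __post_init__(self):
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be > 0")
        if np.any(self.levels[1:] == self.levels[:-1]):
            raise ValueError("dwell levels must alternate")

    @property
    def n_dwells(self) -> int:
        return len(self.levels)

    def open_fraction(self, t0: float | None = None, t1: float | None = None) -> float:
        """Open-time fraction within [t0, t1] (defaults: full trace)."""
        ends = self.starts + self.durations
        t0 = self.starts[0] if t0 is None else t0
        t1 = ends[-1] if t1 is None else t1
        lo = np.maximum(self.starts, t0)
        hi = np.minimum(ends, t1)
        ov = np.clip(hi - lo, 0.0, None)
        return float(ov[self.levels == 1].sum() / (t1 - t0))


def half_amplitude_idealize(
    trace: TraceRecording,
    open_amplitude: float,
    invert: bool = True,
    noise_sd: float | None = None,
    source_id: str = "",
    window: slice | None = None,
) -> IdealizedTrace:
    """Idealize by half-amplitude thresholding.

    A sample is open iff its (magnitude-inverted) current exceeds half the
    open-level amplitude; samples exactly at threshold keep the previous
    level.  ``open_amplitude`` must be positive (pA, inverted scale).
    """
    if open_amplitude <= 0:
        raise ValueError("open amplitude must be > 0")
    if noise_sd is not None and open_amplitude <= 2 * noise_sd:
        logger.warning(
            "open amplitude %.3g pA <= 2x noise sd %.3g pA: idealization unreliable",
            open_amplitude, noise_sd,
        )
    x = -trace.current if invert else trace.current
    offset = 0
    if window is not None:
        offset = window.start or 0
        x = x[window]
    thr = 0.5 * open_amplitude
    cls = x > thr
    eq = x == thr
    if eq.any():
        idx = np.where(eq)[0]
        for i in idx:  # ties take the previous sample's level
            cls[i] = cls[i - 1] if i > 0 else False
    fs = trace.sampling_rate
    change = np.where(cls[1:] != cls[:-1])[0] + 1
    bounds = np.r_[0, change, len(x)]
    levels = cls[bounds[:-1]].astype(int)
    starts = (bounds[:-1] + offset) / fs
    durations = np.diff(bounds) / fs
    return IdealizedTrace(levels, starts, durations, thr, source_id)


def paired_po_response(
    it: IdealizedTrace,
    episode,
    settle_s: float = 0.0,
    t_offset: float = 0.0,
):
    """Per-half open probabilities of a paired 0-mmHg / test-pressure step.

    ``episode`` must contain exactly two pressure segments at the same
    voltage (the paired-stimulus design); ``t_offset`` is the step's start
    time on the idealized trace's clock.  ``settle_s`` seconds after each
    segment boundary are excluded from the analysis window (filter-edge
    guard).  Returns (po_control, po_pressure, delta_po).
    """
    if len(episode) != 2:
        raise ValueError("episode must have exactly two pressure segments")
    s0, s1 = episode
    t_mid = t_offset + s0.duration
    t_end = t_mid + s1.duration
    po0 = it.open_fraction(t_offset + settle_s, t_mid)
    po1 = it.open_fraction(t_mid + settle_s, t_end)
    return po0, po1, po1 - po0
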