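"""Transient shapes used for simulation and template matching.

The climbing-fiber (CF) calcium event is modelled as a single-exponential
rise multiplied by an exponential decay,

    k(t) = (1 - exp(-t / tau_r)) * exp(-t * ln2 / t_half),   t >= 0,

with ``tau_r`` solved numerically so the kernel peaks exactly at the
requested time-to-peak (~10 ms for CF events) and ``t_half`` the decay
half-time (~74 ms).  The slower non-CF component uses an alpha-like shape
with an adjustable time-to-peak.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

LN2 = float(np.log(2.0))


def rise_tau_for_peak(peak_ms: float, decay_half_ms: float) -> float:
    """Rise time constant such that the rise*decay product peaks at ``peak_ms``."""
    if peak_ms <= 0 or decay_half_ms <= 0:
        raise ValueError("peak_ms and decay_half_ms must be positive")
    lam = LN2 / decay_half_ms
    if peak_ms >= 1.0 / lam:
        raise ValueError("time-to-peak must be shorter than the decay time constant")

    def f(tau: float) -> float:
        return np.exp(-peak_ms / tau) - lam * tau / (1.0 + lam * tau)

    return brentq(f, 1e-9 * peak_ms, 0.999 / lam - 1e-12, xtol=1e-12)


def cf_kernel(t_ms: np.ndarray, rise_ms: float = 10.0,
              decay_half_ms: float = 74.0, amplitude: float = 1.0) -> np.ndarray:
    """CF event kernel evaluated at times ``t_ms`` (0 for t < 0), peak == amplitude."""
    tau = rise_tau_for_peak(rise_ms, decay_half_ms)
    t = np.asarray(t_ms, dtype=float)
    k = np.where(t >= 0.0,
                 (1.0 - np.exp(-np.maximum(t, 0.0) / tau))
                 * np.exp(-np.maximum(t, 0.0) * LN2 / decay_half_ms),
                 0.0)
    peak = (1.0 - np.exp(-rise_ms / tau)) * np.exp(-rise_ms * LN2 / decay_half_ms)
    return amplitude * k / peak


def alpha_kernel(t_ms: np.ndarray, peak_ms: float, shape: float = 2.0) -> np.ndarray:
    """Slow alpha-like transient, unit peak at ``peak_ms``; used for non-CF signals."""
    if peak_ms <= 0 or shape <= 0:
        raise ValueError("peak_ms and shape must be positive")
    t = np.asarray(t_ms, dtype=float)
    x = np.maximum(t, 0.0) / peak_ms
    with np.errstate(over="ignore"):
        k = x ** shape * np.exp(shape * (1.0 - x))
    return np.where(t >= 0.0, k, 0.0)


def event_template(frame_period_ms: float, rise_ms: float = 10.0,
                   decay_half_ms: float = 74.0, n_half_lives: float = 2.0,
                   lead_ms: float = 30.0) -> np.ndarray:
    """CF kernel sampled at frame centres for template matching.

    The template spans ``n_half_lives`` decay half-times (at least 3 samples)
    plus a pre-onset baseline of ``lead_ms`` (at least one sample): the
    baseline-then-rise-then-decay signature is what distinguishes a CF
    transient from a bare decaying stretch (which would otherwise correlate
    near 1 with a monotone template) and from the slowly rising non-CF
    signal.  Kept short so that a neighbouring event's tail (events can be
    as close as the ~200 ms refractory period) does not corrupt the
    correlation window.
    """
    if frame_period_ms <= 0:
        raise ValueError("frame_period_ms must be positive")
    n = max(3, int(round(n_half_lives * decay_half_ms / frame_period_ms)))
    lead = max(1, int(round(lead_ms / frame_period_ms)))
    t = (np.arange(-lead, n) + 0.5) * frame_period_ms
    return cf_kernel(t, rise_ms=rise_ms, decay_half_ms=decay_half_ms)


def post_peak_integral(rise_ms: float, decay_half_ms: float,
                       window_ms: float = 100.0, dt_ms: float = 0.01) -> float:
    """Integral of the unit-peak CF kernel over [t_peak, t_peak + window] (ΔF/F·ms)."""
    t = np.arange(rise_ms, rise_ms + window_ms + dt_ms / 2, dt_ms)
    return float(np.trapezoid(cf_kernel(t, rise_ms, decay_half_ms), dx=dt_ms))


def binned_event_template(frame_period_ms: float, rise_ms: float = 10.0,
                          decay_half_ms: float = 74.0,
                          n_half_lives: float = 2.0, lead_frames: int = 1,
                          phase: float = 0.0) -> np.ndarray:
    """CF kernel integrated over frames, with the onset ``phase`` (in frame
    fractions) into its first frame.

    On coarsely sampled data a frame's value is the average of the kernel
    over that frame, and the shape of the binned transient depends on where
    within a frame the event starts; templates at a few phases together
    cover all alignments.
    """
    if frame_period_ms <= 0:
        raise ValueError("frame_period_ms must be positive")
    n = max(3, int(round(n_half_lives * decay_half_ms / frame_period_ms)))
    total = lead_frames + n
    sub = 64  # sub-samples per frame for the bin average
    t = np.arange(total * sub) * (frame_period_ms / sub)
    k = cf_kernel(t - (lead_frames + phase) * frame_period_ms,
                  rise_ms=rise_ms, decay_half_ms=decay_half_ms)
    return k.reshape(total, sub).mean(axis=1)
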