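"""Synthetic two-photon recording generator.

Emulates awake-animal dendritic calcium imaging of cerebellar Purkinje cells
receiving climbing-fiber (CF) input: spontaneous CF events at ~0.7 Hz,
airpuff-evoked events whose probability/latency/amplitude depend on stimulus
strength, a slower graded non-CF calcium component on stimulated trials,
distance-dependent spontaneous co-activation plus a per-trial shared
facilitation state that produces stimulus-driven extra synchrony, and
additive Gaussian recording noise.  Traces can be rendered densely (1 ms)
or at the imaging frame period (64 ms), and optionally painted into a
pixel movie with ground-truth ROI masks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import condition_order
from .kernels import alpha_kernel, cf_kernel, post_peak_integral
from .latency import get_latency_model


def _duration_map(d1, d2, d3, d4, p1, p2) -> dict[str, float]:
    return {"d1": d1, "d2": d2, "d3": d3, "d4": d4, "p1": p1, "p2": p2}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic recording generator.

    Defaults reproduce the study conditions the analysis is calibrated for:
    32x128-pixel movies at 64 ms/frame, 35 trials per condition at a 4 s
    inter-trial interval, spontaneous CF rate 0.7 Hz, event kinetics with
    10 ms rise and 74 ms decay half-time, and condition-dependent evoked
    probability, latency (median/MAD), amplitude gain and non-CF component.
    Times are ms unless a field name says seconds (``_s``).
    """

    n_experiments: int = 1
    n_dendrites: int = 8
    frame_period_ms: float = 64.0
    movie_shape: tuple[int, int] = (32, 128)
    iti_s: float = 4.0
    trials_per_condition: int = 35
    pre_time_s: float = 2.0
    duration_s: float | None = None     # overrides protocol-derived duration
    include_contra: bool = False
    bilateral_fraction: float = 0.5     # of dendrites, when contra trials exist

    spont_rate_hz: float = 0.7
    refractory_ms: float = 200.0
    kernel_rise_ms: float = 10.0
    kernel_decay_half_ms: float = 74.0
    event_amp: float = 1.0              # ΔF/F at the peak of a unit-gain event
    amp_cv: float = 0.1                 # lognormal amplitude variability (mean 1)

    evoked_prob: dict[str, float] = field(
        default_factory=lambda: _duration_map(0.35, 0.50, 0.65, 0.80, 0.40, 0.70))
    latency_median_ms: dict[str, float] = field(
        default_factory=lambda: _duration_map(67.1, 71.8, 78.8, 80.9, 81.3, 79.6))
    latency_mad_ms: dict[str, float] = field(
        default_factory=lambda: _duration_map(23.3, 21.1, 19.3, 18.0, 21.0, 21.0))
    event_gain: dict[str, float] = field(
        default_factory=lambda: _duration_map(1.0, 1.0, 1.0, 1.15, 1.0, 1.1))
    noncf_integral: dict[str, float] = field(
        default_factory=lambda: _duration_map(0.10, 0.20, 0.30, 0.40, 0.15, 0.35))
    noncf_rise_ms: dict[str, float] = field(
        default_factory=lambda: _duration_map(73.0, 114.0, 130.0, 148.0, 110.0, 140.0))
    noncf_shape: float = 2.0
    shared_drive_prob: dict[str, float] = field(
        default_factory=lambda: _duration_map(0.15, 0.25, 0.35, 0.45, 0.20, 0.40))
    shared_boost: float = 1.25          # evoked-prob multiplier in the shared state

    spont_sync_scale_um: float = 50.0   # distance constant of shared spontaneous events
    spont_sync_strength: float = 0.3    # recruit probability at zero distance
    dendrite_spacing_um: float = 15.0
    graded_fraction: float = 0.58       # dendrites with rank-ordered graded profile
    threshold_low_prob: float = 0.05    # sub-threshold response of step dendrites
    suppress_spont_in_window: bool = True

    f0: float = 100.0                   # baseline fluorescence, arbitrary units
    noise_sd: float = 0.03              # per-sample ΔF/F noise
    pixel_noise_sd: float = 2.0         # per-pixel movie noise, raw units
    render_resolution_ms: float = 1.0
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        pos = {"frame_period_ms": self.frame_period_ms, "iti_s": self.iti_s,
               "spont_rate_hz": self.spont_rate_hz, "refractory_ms": self.refractory_ms,
               "kernel_rise_ms": self.kernel_rise_ms, "event_amp": self.event_amp,
               "kernel_decay_half_ms": self.kernel_decay_half_ms, "f0": self.f0,
               "render_resolution_ms": self.render_resolution_ms,
               "dendrite_spacing_um": self.dendrite_spacing_um}
        for name, v in pos.items():
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("evoked_prob", "shared_drive_prob"):
            for cond, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{cond}] = {p} outside [0, 1]")
        for mode in ("duration", "pressure"):
            order = condition_order(mode)
            probs = [self.evoked_prob[c] for c in order]
            if any(b < a for a, b in zip(probs, probs[1:])):
                raise ValueError(
                    f"evoked_prob must be non-decreasing with strength over {order}")
        if not 0.0 <= self.graded_fraction <= 1.0:
            raise ValueError("graded_fraction must be in [0, 1]")
        if self.refractory_ms >= self.iti_s * 1000.0:
            raise ValueError("refractory must be shorter than the inter-trial interval")
        if self.shared_boost < 1.0:
            raise ValueError("shared_boost must be >= 1")
        for cond, q in self.shared_drive_prob.items():
            if 0.0 < q < 1.0 and self.shared_boost * self.evoked_prob[cond] > 1.0 + 1e-12:
                raise ValueError(
                    f"shared_boost * evoked_prob[{cond}] exceeds 1; "
                    "shared-state calibration infeasible")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["movie_shape"] = list(self.movie_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["movie_shape"] = tuple(d["movie_shape"])
        return cls(**d)


@dataclass
class StimulusProtocol:
    """Trial schedule: one row per trial with onset time and condition label."""

    trials: pd.DataFrame  # trial_id, onset_s, condition, laterality
    iti_s: float

    def __post_init__(self) -> None:
        onsets = self.trials["onset_s"].to_numpy()
        if len(onsets) > 1:
            gaps = np.diff(onsets)
            if (gaps <= 0).any():
                raise ValueError("trial onsets must be strictly increasing")
            if (gaps < self.iti_s - 1e-9).any():
                raise ValueError("consecutive onsets closer than the inter-trial interval")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def onsets_ms(self) -> np.ndarray:
        return self.trials["onset_s"].to_numpy(dtype=float) * 1000.0

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.trials["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def to_csv(self, path: str | Path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, iti_s: float = 4.0) -> "StimulusProtocol":
        return cls(pd.read_csv(path), iti_s=iti_s)


@dataclass
class GroundTruth:
    """Injected activity: the oracle against which recovery is tested."""

    events: pd.DataFrame      # dendrite_id, time_ms, gain, origin, trial_id, condition
    dendrites: pd.DataFrame   # dendrite_id, position_um, graded, threshold_idx, bilateral
    shared_state: pd.DataFrame  # trial_id, shared
    duration_ms: float

    @property
    def roi_positions(self) -> np.ndarray:
        return self.dendrites["position_um"].to_numpy(dtype=float)


@dataclass
class TraceSet:
    """Rendered per-dendrite fluorescence: ΔF/F ground truth and raw F."""

    dff: np.ndarray           # (n_dendrites, n_samples) noisy ΔF/F
    raw_f: np.ndarray         # f0 * (1 + dff)
    dt_ms: float
    positions_um: np.ndarray
    f0: float

    @property
    def n_dendrites(self) -> int:
        return self.dff.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.dff.shape[1] * self.dt_ms


# ---------------------------------------------------------------------------
# Protocol generation
# ---------------------------------------------------------------------------

def make_protocol(config: GeneratorConfig, mode: str,
                  rng: np.random.Generator | None = None) -> StimulusProtocol:
    """Randomized-order trial schedule for one experiment.

    ``mode`` selects the condition family: ``duration`` (d1-d4, airpuff
    durations 8/15/30/45 ms at fixed pressure) or ``pressure`` (p1-p2,
    10/50 psi at fixed duration).  Onsets are spaced by the inter-trial
    interval, starting ``pre_time_s`` after recording start.
    """
    config.validate()
    conds = condition_order(mode)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lateralities = ("ipsi", "contra") if config.include_contra else ("ipsi",)
    labels = [(c, lat) for lat in lateralities for c in conds
              for _ in range(config.trials_per_condition)]
    order = rng.permutation(len(labels))
    rows = []
    for i, j in enumerate(order):
        cond, lat = labels[j]
        rows.append({"trial_id": i, "onset_s": config.pre_time_s + i * config.iti_s,
                     "condition": cond, "laterality": lat})
    df = pd.DataFrame(rows, columns=["trial_id", "onset_s", "condition", "laterality"])
    return StimulusProtocol(df, iti_s=config.iti_s)


def _recording_duration_ms(config: GeneratorConfig, protocol: StimulusProtocol) -> float:
    if config.duration_s is not None:
        return config.duration_s * 1000.0
    if len(protocol) == 0:
        return config.pre_time_s * 1000.0
    return (protocol.trials["onset_s"].iloc[-1] + config.iti_s) * 1000.0


# ---------------------------------------------------------------------------
# Event simulation
# ---------------------------------------------------------------------------

def _amp_jitter(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal amplitude factor with mean 1 and CV ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _spontaneous_times(config: GeneratorConfig, positions: np.ndarray,
                       duration_ms: float, rng: np.random.Generator
                       ) -> list[np.ndarray]:
    """Spontaneous CF event times per dendrite with distance-dependent sharing.

    A Poisson process of population "sources" at uniform mediolateral
    positions recruits each dendrite with probability
    ``strength * exp(-distance / scale)``; independent per-dendrite events
    top the marginal rate up to the target.  The per-dendrite refractory
    period acts as a dead time that thins the process (kept rate =
    lam/(1 + lam*tau)), so the target rate is inflated to
    ``lam0 = rate/(1 - rate*tau)`` to make the *realized* rate match
    ``spont_rate_hz``.
    """
    n = len(positions)
    span = max(float(positions.max() - positions.min()), 1e-9)
    scale, strength = config.spont_sync_scale_um, config.spont_sync_strength
    t_s = duration_ms / 1000.0

    tau_s = config.refractory_ms / 1000.0
    if config.spont_rate_hz * tau_s >= 1.0:
        raise ValueError("spont_rate_hz too high for the refractory period")
    lam0 = config.spont_rate_hz / (1.0 - config.spont_rate_hz * tau_s)

    src_rate = lam0
    shared_rate = np.zeros(n)
    if strength > 0 and scale > 0 and src_rate > 0:
        n_src = rng.poisson(src_rate * t_s)
        src_t = np.sort(rng.uniform(0.0, duration_ms, n_src))
        src_x = positions.min() + rng.uniform(0.0, span, n_src)
        recruit = strength * np.exp(
            -np.abs(positions[:, None] - src_x[None, :]) / scale)  # (n, n_src)
        hit = rng.random(recruit.shape) < recruit
        shared = [src_t[hit[i]] for i in range(n)]
        # marginal shared rate from the uniform-source integral, per dendrite
        x = positions - positions.min()
        shared_rate = src_rate * strength * (scale / span) * (
            2.0 - np.exp(-x / scale) - np.exp(-(span - x) / scale))
    else:
        shared = [np.empty(0) for _ in range(n)]

    out = []
    for i in range(n):
        indep_rate = lam0 - shared_rate[i]
        if indep_rate < -1e-9:
            raise ValueError("spont_sync_strength too large: shared spontaneous "
                             "rate exceeds spont_rate_hz")
        n_ind = rng.poisson(max(indep_rate, 0.0) * t_s)
        times = np.sort(np.concatenate([shared[i],
                                        rng.uniform(0.0, duration_ms, n_ind)]))
        out.append(times)
    return out


def _enforce_refractory(times: np.ndarray, keep_mask_priority: np.ndarray,
                        refractory_ms: float) -> np.ndarray:
    """Boolean keep-mask; on conflicts, priority (evoked) events win."""
    order = np.argsort(times)
    keep = np.zeros(len(times), bool)
    last_t, last_idx = -np.inf, -1
    for idx in order:
        t = times[idx]
        if t - last_t >= refractory_ms:
            keep[idx] = True
            last_t, last_idx = t, idx
        elif keep_mask_priority[idx] and not keep_mask_priority[last_idx]:
            keep[last_idx] = False   # evoked displaces a nearby spontaneous event
            keep[idx] = True
            last_t, last_idx = t, idx
    return keep


def simulate_events(config: GeneratorConfig, protocol: StimulusProtocol,
                    rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw ground-truth CF events (spontaneous + evoked) and trial states.

    Evoked responses use a per-trial shared facilitation state S ~
    Bernoulli(q[condition]): a dendrite with marginal probability p fires
    with ``boost * p`` when S is on and with ``p * (1 - q * boost)/(1 - q)``
    otherwise, so the marginal stays exactly p while pairs acquire extra
    synchrony ``q/(1-q) * (boost-1)^2 * p_i * p_j``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    duration_ms = _recording_duration_ms(config, protocol)
    n = config.n_dendrites
    positions = np.arange(n, dtype=float) * config.dendrite_spacing_um

    graded = rng.random(n) < config.graded_fraction
    threshold_idx = rng.integers(0, 4, size=n)  # step position for non-graded cells
    bilateral = rng.random(n) < (config.bilateral_fraction
                                 if config.include_contra else 0.0)

    lat_lo = max(1e-3, 50.0 - config.kernel_rise_ms)
    lat_hi = 200.0 - config.kernel_rise_ms
    lat_models = {c: get_latency_model(config.latency_median_ms[c],
                                       config.latency_mad_ms[c], lat_lo, lat_hi)
                  for c in protocol.conditions}

    onsets_ms = protocol.onsets_ms
    window_lo, window_hi = onsets_ms + 50.0, onsets_ms + 200.0

    # dendrite x condition marginal probability
    def dprob(i: int, cond: str, laterality: str) -> float:
        if laterality == "contra" and not bilateral[i]:
            return 0.0
        if graded[i]:
            return config.evoked_prob[cond]
        mode = "duration" if cond.startswith("d") else "pressure"
        order = list(condition_order(mode))
        k = min(threshold_idx[i], len(order) - 1)
        high = config.evoked_prob[order[-1]]
        return high if order.index(cond) >= k else config.threshold_low_prob

    rows: list[dict] = []
    shared_rows: list[dict] = []

    spont = _spontaneous_times(config, positions, duration_ms, rng)
    for i in range(n):
        times = spont[i]
        if config.suppress_spont_in_window and len(onsets_ms):
            peak = times + config.kernel_rise_ms
            j = np.searchsorted(onsets_ms + 50.0, peak) - 1
            in_win = (j >= 0) & (peak < np.where(j >= 0, window_hi[np.clip(j, 0, None)],
                                                 -np.inf))
            times = times[~in_win]
        for t in times:
            rows.append({"dendrite_id": i, "time_ms": float(t),
                         "gain": 1.0, "origin": "spontaneous",
                         "trial_id": -1, "condition": "sp"})

    for _, trial in protocol.trials.iterrows():
        cond = trial["condition"]
        q = config.shared_drive_prob[cond]
        shared = bool(rng.random() < q) if q > 0 else False
        shared_rows.append({"trial_id": int(trial["trial_id"]), "shared": shared})
        onset = trial["onset_s"] * 1000.0
        for i in range(n):
            p = dprob(i, cond, trial["laterality"])
            if p <= 0:
                continue
            if 0.0 < q < 1.0:
                p_hi = config.shared_boost * p
                p_lo = p * (1.0 - q * config.shared_boost) / (1.0 - q)
                p_fire = p_hi if shared else p_lo
            else:
                p_fire = p
            if rng.random() < p_fire:
                lat = float(lat_models[cond].sample(rng, 1)[0])
                rows.append({"dendrite_id": i, "time_ms": onset + lat,
                             "gain": config.event_gain[cond],
                             "origin": "evoked", "trial_id": int(trial["trial_id"]),
                             "condition": cond})

    events = pd.DataFrame(rows, columns=["dendrite_id", "time_ms", "gain",
                                         "origin", "trial_id", "condition"])
    events["gain"] = events["gain"] * _amp_jitter(rng, config.amp_cv, len(events))

    # joint refractory pass per dendrite (evoked events take priority)
    keep = np.ones(len(events), bool)
    for i in range(n):
        sel = np.flatnonzero(events["dendrite_id"].to_numpy() == i)
        if len(sel) < 2:
            continue
        t = events["time_ms"].to_numpy()[sel]
        prio = (events["origin"].to_numpy()[sel] == "evoked")
        keep[sel] = _enforce_refractory(t, prio, config.refractory_ms)
    events = events[keep].sort_values(["dendrite_id", "time_ms"]).reset_index(drop=True)
    events = events[events["time_ms"] < duration_ms].reset_index(drop=True)

    dendrites = pd.DataFrame({
        "dendrite_id": np.arange(n), "position_um": positions,
        "graded": graded, "threshold_idx": threshold_idx, "bilateral": bilateral})
    shared_df = pd.DataFrame(shared_rows, columns=["trial_id", "shared"])
    return GroundTruth(events=events, dendrites=dendrites,
                       shared_state=shared_df, duration_ms=duration_ms)


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------

def _noncf_amplitude(config: GeneratorConfig, cond: str, dt: float) -> float:
    """Peak of the non-CF alpha transient giving the target ΔF/F-integral.

    ``noncf_integral`` is expressed in units of the mean spontaneous event's
    post-peak 100 ms integral, so the slow component's own [peak, peak+100 ms]
    integral is scaled to ``noncf_integral * spontaneous_integral``.
    """
    target = config.noncf_integral[cond]
    if target <= 0:
        return 0.0
    spont = config.event_amp * post_peak_integral(
        config.kernel_rise_ms, config.kernel_decay_half_ms)
    tp = config.noncf_rise_ms[cond]
    t = np.arange(tp, tp + 100.0 + dt / 2, dt)
    unit = np.trapezoid(alpha_kernel(t, tp, config.noncf_shape), dx=dt)
    return target * spont / unit


def render_traces(truth: GroundTruth, config: GeneratorConfig,
                  protocol: StimulusProtocol, mode: str = "frame",
                  rng: np.random.Generator | None = None) -> TraceSet:
    """Render ground-truth events to ΔF/F and raw fluorescence traces.

    Components sum linearly: CF kernels (unit peak, scaled by amplitude and
    per-event gain), one slow non-CF transient per stimulated trial, and
    Gaussian noise added at the output resolution.  ``mode='frame'`` bins
    the dense rendering to the frame period (frame value = mean over the
    frame); ``mode='dense'`` keeps the render resolution.
    """
    if mode not in ("frame", "dense"):
        raise ValueError(f"mode must be 'frame' or 'dense', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    dt = config.render_resolution_ms
    n_samp = int(round(truth.duration_ms / dt))
    n = len(truth.dendrites)

    kern_len = int(round(6.0 * config.kernel_decay_half_ms / dt)) + 1
    kern = cf_kernel(np.arange(kern_len) * dt, config.kernel_rise_ms,
                     config.kernel_decay_half_ms, amplitude=config.event_amp)

    noncf_shapes: dict[str, np.ndarray] = {}
    for cond in protocol.conditions:
        amp = _noncf_amplitude(config, cond, dt)
        tp = config.noncf_rise_ms[cond]
        length = int(round((4.0 * tp + 400.0) / dt))
        noncf_shapes[cond] = amp * alpha_kernel(np.arange(length) * dt, tp,
                                                config.noncf_shape)

    ev = truth.events
    if len(ev) and (ev["time_ms"].to_numpy() >= truth.duration_ms).any():
        raise ValueError("ground-truth events extend beyond the trace duration")

    if mode == "frame":
        factor = int(round(config.frame_period_ms / dt))
        n_samp = (n_samp // factor) * factor
        n_out = n_samp // factor
        dt_out = config.frame_period_ms
    else:
        factor, n_out, dt_out = 1, n_samp, dt

    dff = np.empty((n, n_out))
    for i in range(n):
        clean = np.zeros(n_samp)
        sub = ev[ev["dendrite_id"] == i]
        for t_ms, gain in zip(sub["time_ms"].to_numpy(), sub["gain"].to_numpy()):
            i0 = int(round(t_ms / dt))
            seg = kern[: max(0, min(kern_len, n_samp - i0))]
            if len(seg):
                clean[i0:i0 + len(seg)] += gain * seg
        for _, trial in protocol.trials.iterrows():
            shape = noncf_shapes[trial["condition"]]
            i0 = int(round(trial["onset_s"] * 1000.0 / dt))
            seg = shape[: max(0, min(len(shape), n_samp - i0))]
            if len(seg):
                clean[i0:i0 + len(seg)] += seg
        if factor > 1:
            clean = clean[:n_samp].reshape(n_out, factor).mean(axis=1)
        if config.noise_sd > 0:
            clean = clean + rng.normal(0.0, config.noise_sd, n_out)
        dff[i] = clean

    raw = config.f0 * (1.0 + dff)
    return TraceSet(dff=dff, raw_f=raw, dt_ms=dt_out,
                    positions_um=truth.roi_positions, f0=config.f0)


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def render_movie(traces: TraceSet, config: GeneratorConfig,
                 rng: np.random.Generator | None = None,
                 stripe_width: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Paint dendrites as vertical stripes into a pixel movie.

    Each dendrite becomes a ``stripe_width``-pixel-wide vertical band at its
    mediolateral position (dendrites appear as parasagittally aligned,
    tube-like structures under two-photon imaging); pixel value = the
    dendrite's raw fluorescence plus independent per-pixel noise.  Returns
    ``(movie, labels)`` where ``labels`` is a 2-D mask image (0 = background,
    dendrite_id + 1 elsewhere).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    h, w = config.movie_shape
    n = traces.n_dendrites
    pitch = stripe_width + 1
    if n * pitch > w:
        raise ValueError(f"{n} dendrites do not fit as {stripe_width}-pixel "
                         f"stripes in a {h}x{w} field")
    n_frames = traces.raw_f.shape[1]
    movie = np.full((n_frames, h, w), traces.f0, dtype=np.float32)
    labels = np.zeros((h, w), dtype=np.int16)
    start = (w - n * pitch) // 2
    for i in range(n):
        c0 = start + i * pitch
        labels[:, c0:c0 + stripe_width] = i + 1
        movie[:, :, c0:c0 + stripe_width] = traces.raw_f[i][:, None, None]
    if config.pixel_noise_sd > 0:
        movie += rng.normal(0.0, config.pixel_noise_sd,
                            movie.shape).astype(np.float32)
    return movie, labels


def save_movie(movie: np.ndarray, labels: np.ndarray, outdir: str | Path,
               prefix: str = "synthetic") -> tuple[Path, Path]:
    """Write the movie and its labeled ROI masks as multi-frame/2-D TIFFs."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    movie_path = outdir / f"{prefix}_movie.tif"
    mask_path = outdir / f"{prefix}_masks.tif"
    tifffile.imwrite(movie_path, movie.astype(np.float32))
    tifffile.imwrite(mask_path, labels)
    return movie_path, mask_path
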