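"""Event-size analysis: ΔF/F-integrals, jitter-matched spontaneous reference,
stimulus-evoked enhancement, and the slow non-CF signal.

All quantities operate on the spontaneous-peak-normalized ΔF/F trace, so
sizes are expressed in units of the dendrite's mean spontaneous event.  The
size of an event is the integral of the normalized trace over the 100 ms
following its peak; evoked sizes are additionally divided by the dendrite's
mean spontaneous integral, making the spontaneous mean exactly 1.

The 'sp' reference trace answers "what would the evoked average look like
if stimulation merely re-timed ordinary spontaneous events?": each evoked
event is replaced by the dendrite's mean spontaneous event at the same
latency, so the reference carries exactly the same temporal jitter as the
evoked average.  The evoked-minus-reference difference is the calcium-event
enhancement, which is compared per condition against the non-CF signal
measured on trials without any evoked event (additivity / supralinearity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import EVOKED_WINDOW_MS
from .synthgen import StimulusProtocol


def event_integral(dff: np.ndarray, frame_period_ms: float, peak_index: int,
                   window_ms: float = 100.0) -> float:
    """Trapezoidal integral of ΔF/F over [peak, peak + window] (ΔF/F·ms)."""
    n_win = int(round(window_ms / frame_period_ms))
    if peak_index + n_win >= len(dff):
        raise ValueError("integration window extends past the end of the trace")
    seg = dff[peak_index:peak_index + n_win + 1]
    return float(np.trapezoid(seg, dx=frame_period_ms))


def event_integrals(events: pd.DataFrame, dff_by_dendrite: dict[int, np.ndarray],
                    frame_period_ms: float, window_ms: float = 100.0
                    ) -> pd.DataFrame:
    """ΔF/F-integral for every event, normalized to each dendrite's
    mean spontaneous integral; events whose window leaves the trace are
    flagged excluded."""
    rows = []
    for _, e in events.iterrows():
        did = e["dendrite_id"]
        try:
            raw = event_integral(dff_by_dendrite[did], frame_period_ms,
                                 int(e["peak_index"]), window_ms)
            excluded = False
        except ValueError:
            raw, excluded = np.nan, True
        rows.append({"dendrite_id": did, "peak_index": e["peak_index"],
                     "label": e["label"], "trial_id": e["trial_id"],
                     "condition": e["condition"], "integral_raw": raw,
                     "excluded": excluded})
    df = pd.DataFrame(rows)
    df["integral_norm"] = np.nan
    for did, grp in df.groupby("dendrite_id"):
        spont = grp[(grp["label"] == "spontaneous") & ~grp["excluded"]]
        if len(spont) == 0:
            continue
        denom = spont["integral_raw"].mean()
        if denom > 0:
            df.loc[grp.index, "integral_norm"] = grp["integral_raw"] / denom
    return df


def exclude_multi_event_trials(events: pd.DataFrame, min_gap_ms: float = 100.0
                               ) -> tuple[set, float]:
    """Trials with >= 2 evoked-window events closer than ``min_gap_ms``.

    Returns ``(excluded_trial_ids, exclusion_fraction)``; such trials are
    dropped from size analyses (the stimulus is assumed to trigger at most
    one CF burst, and near-coincident transients contaminate the integral).
    """
    evoked = events[events["label"] == "evoked"]
    excluded = set()
    trial_ids = evoked["trial_id"].unique()
    for (did, tid), grp in evoked.groupby(["dendrite_id", "trial_id"]):
        t = np.sort(grp["peak_time_ms"].to_numpy(dtype=float))
        if len(t) >= 2 and np.diff(t).min() < min_gap_ms:
            excluded.add((did, tid))
    frac = (len({t for _, t in excluded}) / len(trial_ids)) if len(trial_ids) else 0.0
    return excluded, frac


def _aligned_segment(trace: np.ndarray, start_idx: int, n_out: int) -> np.ndarray | None:
    if start_idx < 0 or start_idx + n_out > len(trace):
        return None
    return trace[start_idx:start_idx + n_out]


def _pre_stim_baseline(trace: np.ndarray, t_axis_ms: np.ndarray,
                       window: tuple[float, float] = (-150.0, -50.0)) -> float:
    """Mean over a pre-stimulus window of a stimulus-aligned trace.

    Stimulus-aligned averages sit on a stationary background (the ΔF/F
    percentile-baseline offset plus tails of incidental spontaneous events);
    subtracting the pre-stimulus mean removes it in expectation so that
    evoked, reference and non-CF composites share a common zero.
    """
    sel = (t_axis_ms >= window[0]) & (t_axis_ms < window[1])
    if not sel.any():
        return 0.0
    return float(trace[sel].mean())


def condition_mean_traces(events: pd.DataFrame,
                          dff_by_dendrite: dict[int, np.ndarray],
                          frame_period_ms: float, protocol: StimulusProtocol,
                          pre_ms: float = 200.0, post_ms: float = 600.0,
                          excluded: set | None = None,
                          ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Stimulus-aligned mean normalized ΔF/F per condition, over trials with
    an evoked event (excluding flagged multi-event trials).

    Returns ``(time_axis_ms, {condition: mean_trace})``.
    """
    excluded = excluded or set()
    n_pre = int(round(pre_ms / frame_period_ms))
    n_post = int(round(post_ms / frame_period_ms))
    n_out = n_pre + n_post
    t_axis = (np.arange(n_out) - n_pre) * frame_period_ms
    evoked = events[events["label"] == "evoked"]
    onset_of = dict(zip(protocol.trials["trial_id"],
                        protocol.trials["onset_s"] * 1000.0))
    sums: dict[str, list[np.ndarray]] = {}
    for (did, tid), grp in evoked.groupby(["dendrite_id", "trial_id"]):
        if (did, tid) in excluded:
            continue
        cond = grp["condition"].iloc[0]
        start = int(round(onset_of[tid] / frame_period_ms)) - n_pre
        seg = _aligned_segment(dff_by_dendrite[did], start, n_out)
        if seg is not None:
            sums.setdefault(cond, []).append(seg)
    means = {}
    for c, v in sums.items():
        m = np.mean(v, axis=0)
        means[c] = m - _pre_stim_baseline(m, t_axis)
    return t_axis, means


def build_sp_reference(events: pd.DataFrame,
                       mean_spont_events: dict[int, np.ndarray],
                       frame_period_ms: float, protocol: StimulusProtocol,
                       pre_ms: float = 200.0, post_ms: float = 600.0,
                       excluded: set | None = None,
                       conditions: list[str] | None = None) -> np.ndarray:
    """Jitter-matched spontaneous composite trace aligned on stimulus onset.

    For every evoked event, the dendrite's (normalized, peak-aligned) mean
    spontaneous event is placed at the event's peak time relative to the
    stimulus; averaging across events yields a reference whose latency
    jitter is identical to the evoked averages.  The mean spontaneous event
    arrays must be peak-aligned with the peak at the centre index.
    """
    excluded = excluded or set()
    n_pre = int(round(pre_ms / frame_period_ms))
    n_post = int(round(post_ms / frame_period_ms))
    n_out = n_pre + n_post
    onset_of = dict(zip(protocol.trials["trial_id"],
                        protocol.trials["onset_s"] * 1000.0))
    evoked = events[events["label"] == "evoked"]
    if conditions is not None:
        evoked = evoked[evoked["condition"].isin(conditions)]
    segs = []
    me_corrected: dict[int, np.ndarray] = {}
    for did, me in mean_spont_events.items():
        # remove the mean event's own pre-onset floor so the placed
        # composite is zero-baselined like the evoked averages
        pk = int(np.argmax(me))
        stop = max(1, pk - int(round(50.0 / frame_period_ms)))
        me_corrected[did] = me - float(np.mean(me[:stop]))
    for _, e in evoked.iterrows():
        if (e["dendrite_id"], e["trial_id"]) in excluded:
            continue
        me = me_corrected[e["dendrite_id"]]
        peak_in_me = int(np.argmax(me))
        # latency of the event's peak relative to its stimulus onset, frames
        lat_frames = int(round((e["peak_time_ms"] - onset_of[e["trial_id"]])
                               / frame_period_ms))
        out = np.zeros(n_out)
        # place mean event so its peak sits at n_pre + lat_frames
        start = n_pre + lat_frames - peak_in_me
        lo, hi = max(0, start), min(n_out, start + len(me))
        if hi > lo:
            out[lo:hi] = me[lo - start:hi - start]
        segs.append(out)
    if not segs:
        raise ValueError("no evoked events to build the sp reference from")
    return np.mean(segs, axis=0)


def enhancement_trace(evoked_mean: np.ndarray, sp_reference: np.ndarray
                      ) -> np.ndarray:
    """Calcium-event enhancement: evoked mean minus jitter-matched reference."""
    if evoked_mean.shape != sp_reference.shape:
        raise ValueError("traces must share one time base")
    return evoked_mean - sp_reference


def peak_anchored_integral(trace: np.ndarray, frame_period_ms: float,
                           t_axis_ms: np.ndarray, window_ms: float = 100.0,
                           smooth_ms: float = 15.0) -> float:
    """Integral of a stimulus-aligned mean trace over [its peak, peak+window],
    searching the peak within the post-stimulus half.

    The peak is located on a lightly smoothed copy (the raw argmax of a
    noisy trace rides the largest noise excursion, which would bias noisier
    traces upward); the integral itself uses the unsmoothed trace.
    """
    n_smooth = max(1, int(round(smooth_ms / frame_period_ms)))
    sm = (np.convolve(trace, np.ones(n_smooth) / n_smooth, mode="same")
          if n_smooth > 1 else trace)
    post = np.flatnonzero(t_axis_ms >= 0.0)
    pk = post[int(np.argmax(sm[post]))]
    n_win = int(round(window_ms / frame_period_ms))
    hi = min(len(trace), pk + n_win + 1)
    return float(np.trapezoid(trace[pk:hi], dx=frame_period_ms))


def extract_noncf(events: pd.DataFrame, dff_by_dendrite: dict[int, np.ndarray],
                  frame_period_ms: float, protocol: StimulusProtocol,
                  spont_integral_means: dict[int, float],
                  rng: np.random.Generator,
                  pre_ms: float = 200.0, post_ms: float = 600.0,
                  smooth_ms: float = 15.0) -> dict:
    """Non-CF signal from trials without any evoked event.

    For each condition: the stimulus-aligned mean trace over qualifying
    trials (no event peaking in the 50-200 ms window, and no spontaneous
    transient peaking in — or decaying into — the aligned segment, since at
    ~0.7 Hz roughly a quarter of trials carry an incidental CF transient
    that would contaminate the slow non-CF average), its rise time
    (stimulus onset to peak of the lightly smoothed mean trace), and the
    per-trial ΔF/F-integral over [t, t+100 ms] with t drawn uniformly in
    [50, 200) ms of the stimulus (one seeded draw per dendrite-trial),
    normalized to the dendrite's mean spontaneous integral.

    Returns ``{"t_axis_ms", "mean_traces", "rise_times_ms", "integrals",
    "missing"}``; ``missing`` lists (dendrite, condition) combinations with
    no qualifying trial.
    """
    n_pre = int(round(pre_ms / frame_period_ms))
    n_post = int(round(post_ms / frame_period_ms))
    n_out = n_pre + n_post
    t_axis = (np.arange(n_out) - n_pre) * frame_period_ms
    lo, hi = EVOKED_WINDOW_MS
    evoked = events[events["label"] == "evoked"]
    hit_trials = {(d, t) for d, t in zip(evoked["dendrite_id"],
                                         evoked["trial_id"])}
    # any detected event inside (or decaying into) the aligned segment would
    # contaminate the slow non-CF average; index spontaneous peaks per dendrite
    spont_peaks = {did: grp["peak_time_ms"].to_numpy(float)
                   for did, grp in
                   events[events["label"] != "evoked"].groupby("dendrite_id")}

    traces: dict[str, list[np.ndarray]] = {}
    int_rows = []
    missing = []
    dendrite_ids = sorted(dff_by_dendrite)
    qualified: dict[tuple[int, str], int] = {}
    for did in dendrite_ids:
        dff = dff_by_dendrite[did]
        for _, trial in protocol.trials.iterrows():
            tid, cond = trial["trial_id"], trial["condition"]
            if (did, tid) in hit_trials:
                continue
            onset_ms = trial["onset_s"] * 1000.0
            sp = spont_peaks.get(did)
            if sp is not None and np.any(
                    (sp >= onset_ms - pre_ms - 300.0)
                    & (sp < onset_ms + post_ms)):
                continue  # a CF transient (or its tail) overlaps the segment
            start = int(round(onset_ms / frame_period_ms)) - n_pre
            seg = _aligned_segment(dff, start, n_out)
            if seg is None:
                continue
            qualified[(did, cond)] = qualified.get((did, cond), 0) + 1
            traces.setdefault(cond, []).append(seg)
            base = _pre_stim_baseline(seg, t_axis)
            t_rand = rng.uniform(lo, hi)
            i0 = int(round((onset_ms + t_rand) / frame_period_ms))
            n_win = int(round(100.0 / frame_period_ms))
            if i0 + n_win < len(dff):
                raw = float(np.trapezoid(dff[i0:i0 + n_win + 1] - base,
                                         dx=frame_period_ms))
                denom = spont_integral_means.get(did, np.nan)
                int_rows.append({"dendrite_id": did, "trial_id": tid,
                                 "condition": cond,
                                 "integral_norm": raw / denom})
    for did in dendrite_ids:
        for cond in protocol.conditions:
            if qualified.get((did, cond), 0) == 0:
                missing.append((did, cond))

    mean_traces = {}
    for c, v in traces.items():
        m = np.mean(v, axis=0)
        mean_traces[c] = m - _pre_stim_baseline(m, t_axis)
    n_smooth = max(1, int(round(smooth_ms / frame_period_ms)))
    rise = {}
    for cond, tr in mean_traces.items():
        sm = (np.convolve(tr, np.ones(n_smooth) / n_smooth, mode="same")
              if n_smooth > 1 else tr)
        post = np.flatnonzero(t_axis >= 0.0)
        rise[cond] = float(t_axis[post[int(np.argmax(sm[post]))]])
    return {"t_axis_ms": t_axis, "mean_traces": mean_traces,
            "rise_times_ms": rise,
            "integrals": pd.DataFrame(int_rows, columns=[
                "dendrite_id", "trial_id", "condition", "integral_norm"]),
            "missing": missing}


def linearity_comparison(per_dendrite: pd.DataFrame,
                         conditions: list[str]) -> pd.DataFrame:
    """Across-dendrite comparison of enhancement size vs non-CF size.

    ``per_dendrite`` holds one row per (dendrite, condition) with columns
    ``enhancement_integral`` and ``noncf_integral`` — each the peak-anchored
    integral of that dendrite's condition-mean trace, in multiples of the
    dendrite's mean spontaneous-event integral.  Under a purely additive
    model the two sizes agree (unity line); the supralinearity flag fires
    when the across-dendrite mean of the paired difference exceeds twice
    its SEM.
    """
    rows = []
    for cond in conditions:
        grp = per_dendrite[per_dendrite["condition"] == cond].dropna(
            subset=["enhancement_integral", "noncf_integral"])
        diff = (grp["enhancement_integral"]
                - grp["noncf_integral"]).to_numpy(dtype=float)
        n = len(diff)
        mean_diff = float(diff.mean()) if n else np.nan
        sem_diff = float(diff.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({
            "condition": cond,
            "enhancement_integral": float(grp["enhancement_integral"].mean())
            if n else np.nan,
            "noncf_integral": float(grp["noncf_integral"].mean())
            if n else np.nan,
            "difference": mean_diff, "difference_sem": sem_diff,
            "n_dendrites": n,
            "supralinear": bool(n > 1 and np.isfinite(sem_diff)
                                and mean_diff > 2.0 * sem_diff)})
    return pd.DataFrame(rows)
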