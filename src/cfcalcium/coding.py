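"""Per-dendrite stimulus coding: response probability, dendrite categories,
latency statistics and receptive-field laterality.

The calcium-event probability of a dendrite for a condition is the fraction
of that condition's trials containing at least one evoked event; the
spontaneous reference ('sp') is the fraction of matched 150 ms pre-stimulus
windows containing any event.  Dendrites fall into five categories by how
probability varies with airpuff duration: category 1 responds gradedly
(probability shares the duration rank order), categories 2-5 are
threshold-like (a step at d1..d4).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .constants import DURATION_CONDITIONS, LATENCY_WINDOWS_MS, SP_WINDOW_MS
from .synthgen import StimulusProtocol


def event_probability(events: pd.DataFrame, protocol: StimulusProtocol,
                      dendrite_ids: np.ndarray | None = None,
                      lateralities: tuple[str, ...] = ("ipsi",)) -> pd.DataFrame:
    """Per-dendrite event probability for 'sp' and each evoked condition.

    Returns a tidy frame (dendrite_id, condition, probability, n_trials).
    """
    trials = protocol.trials[protocol.trials["laterality"].isin(lateralities)]
    if dendrite_ids is None:
        dendrite_ids = np.sort(events["dendrite_id"].unique())
    onsets_ms = trials["onset_s"].to_numpy(dtype=float) * 1000.0

    rows = []
    for did in dendrite_ids:
        sub = events[events["dendrite_id"] == did]
        evoked = sub[sub["label"] == "evoked"]
        for cond, grp in trials.groupby("condition", sort=False):
            n = len(grp)
            hit = evoked["trial_id"].isin(grp["trial_id"]).to_numpy()
            n_hit = evoked.loc[hit, "trial_id"].nunique()
            rows.append({"dendrite_id": did, "condition": cond,
                         "probability": n_hit / n if n else np.nan, "n_trials": n})
        # spontaneous chance over matched pre-stimulus windows
        t = sub["peak_time_ms"].to_numpy(dtype=float)
        in_pre = ((t[None, :] >= onsets_ms[:, None] - SP_WINDOW_MS)
                  & (t[None, :] < onsets_ms[:, None]))
        rows.append({"dendrite_id": did, "condition": "sp",
                     "probability": in_pre.any(axis=1).mean() if len(onsets_ms)
                     else np.nan,
                     "n_trials": len(onsets_ms)})
    return pd.DataFrame(rows)


def _step_sse(p: np.ndarray, k: int) -> float:
    low, high = p[:k], p[k:]
    sse = 0.0
    if len(low):
        sse += float(((low - low.mean()) ** 2).sum())
    if len(high):
        sse += float(((high - high.mean()) ** 2).sum())
    return sse


def categorize_dendrite(probs: dict[str, float] | pd.Series, sp: float,
                        n_trials: int = 35) -> tuple[int, bool]:
    """Classify a duration-mode dendrite into one of five categories.

    Returns ``(category, responsive)``.  Category 1 = graded (probability,
    corrected for the spontaneous floor, shares the rank order of the
    duration and a same-complexity line fits better than any step);
    categories 2-5 = threshold-like at d1..d4 (step position chosen by least
    squares over the four possible steps).  Unresponsive dendrites (no
    condition above the spontaneous floor) are assigned the highest
    threshold category and flagged.
    """
    p = np.array([float(probs[c]) for c in DURATION_CONDITIONS])
    floor = max(float(sp), 0.0)
    corrected = np.clip(p - floor, 0.0, 1.0)
    if corrected.max() <= 0.0:
        return 5, False

    # rank-order check with one binomial SE of tolerance per comparison;
    # a flat profile (zero span) is threshold-like, not graded
    se = np.sqrt(np.maximum(p * (1.0 - p), 1e-6) / max(n_trials, 1))
    increasing = (all(p[i + 1] - p[i] > -se[i] for i in range(3))
                  and p[3] - p[0] > max(se[0], se[3]))

    # same-complexity model comparison: 2-parameter line vs 2-level step
    x = np.arange(4.0)
    slope, intercept = np.polyfit(x, p, 1)
    sse_line = float(((p - (slope * x + intercept)) ** 2).sum())
    step_sses = [_step_sse(p, k) for k in range(1, 4)]
    if increasing and sse_line <= min(step_sses):
        return 1, True
    # threshold position: best step over the four candidate positions
    # (a step "at d1" is the flat responder: all four conditions high)
    candidates = [_step_sse(p, k) for k in range(0, 4)]
    k_best = int(np.argmin(candidates))
    return 2 + k_best, True


def latency_stats(events: pd.DataFrame) -> pd.DataFrame:
    """Median onset latency and MAD per dendrite per condition.

    Operates on classified evoked events with defined latencies.  Returns a
    tidy frame (dendrite_id, condition, n, latency_median_ms,
    latency_mad_ms); dendrites without any usable latency in a condition
    are simply absent from that condition's rows.
    """
    evoked = events[(events["label"] == "evoked")
                    & events["onset_latency_ms"].notna()]
    rows = []
    for (did, cond), grp in evoked.groupby(["dendrite_id", "condition"]):
        lat = grp["onset_latency_ms"].to_numpy(dtype=float)
        med = float(np.median(lat))
        rows.append({"dendrite_id": did, "condition": cond, "n": len(lat),
                     "latency_median_ms": med,
                     "latency_mad_ms": float(np.median(np.abs(lat - med)))})
    return pd.DataFrame(rows, columns=["dendrite_id", "condition", "n",
                                       "latency_median_ms", "latency_mad_ms"])


def summarize_latency(stats: pd.DataFrame, min_events: int = 5) -> pd.DataFrame:
    """Across-dendrite mean ± SEM of per-dendrite latency median and MAD.

    Dendrites contributing fewer than ``min_events`` latencies to a
    condition are excluded from that condition's summary: a median over one
    or two events is not a latency estimate, and near-unresponsive
    dendrites would otherwise dominate the across-dendrite spread.
    """
    stats = stats[stats["n"] >= min_events]
    rows = []
    for cond, grp in stats.groupby("condition"):
        for col, name in [("latency_median_ms", "median"),
                          ("latency_mad_ms", "mad")]:
            v = grp[col].to_numpy(dtype=float)
            rows.append({"condition": cond, "statistic": name,
                         "mean": float(v.mean()),
                         "sem": float(v.std(ddof=1) / np.sqrt(len(v)))
                         if len(v) > 1 else np.nan,
                         "n_dendrites": len(v)})
    return pd.DataFrame(rows, columns=["condition", "statistic", "mean",
                                       "sem", "n_dendrites"])


def latency_window_counts(events: pd.DataFrame,
                          windows_ms: tuple[tuple[float, float], ...]
                          = LATENCY_WINDOWS_MS) -> pd.DataFrame:
    """Evoked-event counts per dendrite per condition per latency interval."""
    evoked = events[(events["label"] == "evoked")
                    & events["onset_latency_ms"].notna()]
    rows = []
    for (did, cond), grp in evoked.groupby(["dendrite_id", "condition"]):
        lat = grp["onset_latency_ms"].to_numpy(dtype=float)
        for lo, hi in windows_ms:
            rows.append({"dendrite_id": did, "condition": cond,
                         "window": f"[{lo:g},{hi:g})",
                         "count": int(((lat >= lo) & (lat < hi)).sum())})
    return pd.DataFrame(rows, columns=["dendrite_id", "condition",
                                       "window", "count"])


def classify_laterality(events: pd.DataFrame, protocol: StimulusProtocol,
                        dendrite_ids: np.ndarray | None = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Ipsi-specific / bilateral / unresponsive receptive-field labels.

    A dendrite is responsive to a laterality when its evoked response count
    (best condition) exceeds the spontaneous chance probability by a
    one-sided binomial test at ``alpha``, Bonferroni-corrected across
    dendrites.
    """
    lats = set(protocol.trials["laterality"].unique())
    if "contra" not in lats or "ipsi" not in lats:
        raise ValueError("protocol must contain both ipsi and contra trials")
    if dendrite_ids is None:
        dendrite_ids = np.sort(events["dendrite_id"].unique())
    alpha_corr = alpha / max(len(dendrite_ids), 1)

    rows = []
    for did in dendrite_ids:
        responsive = {}
        for side in ("ipsi", "contra"):
            probs = event_probability(events, protocol, np.array([did]),
                                      lateralities=(side,))
            sp = float(probs.loc[probs["condition"] == "sp", "probability"].iloc[0])
            evoked = probs[probs["condition"] != "sp"]
            best = evoked.loc[evoked["probability"].idxmax()]
            k = int(round(best["probability"] * best["n_trials"]))
            p0 = min(max(sp, 1e-9), 1.0 - 1e-9)
            test = binomtest(k, int(best["n_trials"]), p0, alternative="greater")
            responsive[side] = test.pvalue < alpha_corr
        if responsive["ipsi"] and responsive["contra"]:
            label = "bilateral"
        elif responsive["ipsi"]:
            label = "ipsi_specific"
        elif responsive["contra"]:
            label = "contra_specific"
        else:
            label = "unresponsive"
        rows.append({"dendrite_id": did, "laterality": label})
    return pd.DataFrame(rows)
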