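"""Population synchrony: coactivation, joint probabilities, extra synchrony,
and distance-dependent spontaneous correlation.

Coactivation on a trial is the fraction of responsive dendrites with an
airpuff-evoked event (peak in the 150 ms evoked window).  For every
dendrite pair the measured joint probability (fraction of trials with
events in both) is compared to the independent prediction P_i * P_j; the
difference, in percent, is the pair's "extra synchrony" — the synchrony
beyond what the two dendrites' individual response probabilities would
produce if they were independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .constants import SP_WINDOW_MS
from .synthgen import StimulusProtocol

MIN_RESPONSIVE_DENDRITES = 6  # inclusion rule for population analyses


def _evoked_matrix(events: pd.DataFrame, protocol: StimulusProtocol,
                   dendrite_ids: np.ndarray) -> pd.DataFrame:
    """Boolean (trial x dendrite) table: did the dendrite respond on the trial."""
    evoked = events[events["label"] == "evoked"]
    mat = pd.DataFrame(False, index=protocol.trials["trial_id"].to_numpy(),
                       columns=list(dendrite_ids))
    for did in dendrite_ids:
        hit = evoked.loc[evoked["dendrite_id"] == did, "trial_id"].unique()
        mat.loc[mat.index.isin(hit), did] = True
    return mat


def _sp_matrix(events: pd.DataFrame, protocol: StimulusProtocol,
               dendrite_ids: np.ndarray) -> pd.DataFrame:
    """Boolean (trial x dendrite): any event in the matched pre-stimulus window."""
    onsets = protocol.onsets_ms
    mat = pd.DataFrame(False, index=protocol.trials["trial_id"].to_numpy(),
                       columns=list(dendrite_ids))
    for did in dendrite_ids:
        t = events.loc[events["dendrite_id"] == did, "peak_time_ms"].to_numpy(float)
        hit = ((t[None, :] >= onsets[:, None] - SP_WINDOW_MS)
               & (t[None, :] < onsets[:, None])).any(axis=1)
        mat[did] = hit
    return mat


def responsive_dendrites(events: pd.DataFrame, protocol: StimulusProtocol,
                         dendrite_ids: np.ndarray | None = None,
                         alpha: float = 0.05) -> np.ndarray:
    """Dendrites whose best-condition evoked probability beats spontaneous chance.

    One-sided binomial test of the response count for the strongest
    condition against the spontaneous pre-window chance, at ``alpha``.
    """
    from .coding import event_probability

    if dendrite_ids is None:
        dendrite_ids = np.sort(events["dendrite_id"].unique())
    out = []
    probs = event_probability(events, protocol, dendrite_ids)
    for did in dendrite_ids:
        sub = probs[probs["dendrite_id"] == did]
        sp = float(sub.loc[sub["condition"] == "sp", "probability"].iloc[0])
        evoked = sub[sub["condition"] != "sp"]
        best = evoked.loc[evoked["probability"].idxmax()]
        k = int(round(best["probability"] * best["n_trials"]))
        p0 = min(max(sp, 1e-9), 1.0 - 1e-9)
        if binomtest(k, int(best["n_trials"]), p0,
                     alternative="greater").pvalue < alpha:
            out.append(did)
    return np.asarray(out)


def coactivation_fraction(events: pd.DataFrame, protocol: StimulusProtocol,
                          responsive_ids: np.ndarray) -> pd.DataFrame:
    """Per-trial fraction of responsive dendrites with an evoked event.

    Requires at least 6 responsive dendrites (fields of view with fewer are
    excluded from population analyses).  Returns (trial_id, condition,
    fraction).
    """
    if len(responsive_ids) < MIN_RESPONSIVE_DENDRITES:
        raise ValueError(
            f"only {len(responsive_ids)} responsive dendrites; population "
            f"coactivation requires at least {MIN_RESPONSIVE_DENDRITES} — "
            "experiment excluded")
    mat = _evoked_matrix(events, protocol, responsive_ids)
    frac = mat.mean(axis=1)
    return pd.DataFrame({"trial_id": mat.index,
                         "condition": protocol.trials["condition"].to_numpy(),
                         "fraction": frac.to_numpy()})


def pair_joint_probability(events: pd.DataFrame, protocol: StimulusProtocol,
                           dendrite_ids: np.ndarray) -> pd.DataFrame:
    """Measured vs independent joint response probability for every pair.

    Per condition (plus the 'sp' pre-window condition): measured = fraction
    of trials on which both dendrites responded; independent = product of
    the two marginal probabilities.
    """
    ev_mat = _evoked_matrix(events, protocol, dendrite_ids)
    sp_mat = _sp_matrix(events, protocol, dendrite_ids)
    cond_of = protocol.trials.set_index("trial_id")["condition"]
    rows = []
    conds = list(dict.fromkeys(cond_of))
    for label, mat in [("evoked", ev_mat), ("sp", sp_mat)]:
        for cond in (conds if label == "evoked" else ["sp"]):
            sel = (mat if label == "sp"
                   else mat.loc[cond_of.reindex(mat.index).to_numpy() == cond])
            if not len(sel):
                continue
            arr = sel.to_numpy()
            p = arr.mean(axis=0)
            for a in range(len(dendrite_ids)):
                for b in range(a + 1, len(dendrite_ids)):
                    meas = float((arr[:, a] & arr[:, b]).mean())
                    rows.append({"dendrite_i": dendrite_ids[a],
                                 "dendrite_j": dendrite_ids[b],
                                 "condition": cond,
                                 "p_i": float(p[a]), "p_j": float(p[b]),
                                 "measured_joint": meas,
                                 "independent_joint": float(p[a] * p[b])})
    return pd.DataFrame(rows)


def extra_synchrony(pair_stats: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM (across pairs) of 100*(measured - independent) per condition."""
    df = pair_stats.copy()
    df["extra_pct"] = 100.0 * (df["measured_joint"] - df["independent_joint"])
    rows = []
    for cond, grp in df.groupby("condition", sort=False):
        v = grp["extra_pct"].to_numpy(dtype=float)
        rows.append({"condition": cond, "mean_extra_pct": float(v.mean()),
                     "sem": float(v.std(ddof=1) / np.sqrt(len(v)))
                     if len(v) > 1 else np.nan,
                     "n_pairs": len(v)})
    return pd.DataFrame(rows)


def spont_distance_correlation(events: pd.DataFrame, roi_positions_um: dict,
                               duration_ms: float, frame_period_ms: float,
                               n_shuffles: int = 100,
                               bin_um: float = 50.0,
                               rng: np.random.Generator | None = None
                               ) -> pd.DataFrame:
    """Pairwise Pearson correlation of spontaneous event rasters vs distance.

    Each dendrite's spontaneous events are binarized per frame; the Pearson
    r of every pair is binned by mediolateral separation (``bin_um`` wide
    bins).  The control recomputes r after independently permuting each
    dendrite's frame order (destroying alignment while preserving rates),
    averaged over ``n_shuffles`` seeded shuffles.  Pairs where either raster
    has zero variance are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ids = np.sort(np.asarray(list(roi_positions_um.keys())))
    if len(ids) < 2:
        raise ValueError("need at least two dendrites")
    n_frames = int(round(duration_ms / frame_period_ms))
    spont = events[events["label"].isin(["spontaneous", "unlabeled"])]
    rasters = {}
    for did in ids:
        idx = (spont.loc[spont["dendrite_id"] == did, "peak_time_ms"]
               .to_numpy(float) / frame_period_ms).astype(int)
        v = np.zeros(n_frames, dtype=float)
        v[idx[idx < n_frames]] = 1.0
        rasters[did] = v

    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            x, y = rasters[ids[a]], rasters[ids[b]]
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            shuf = []
            for _ in range(n_shuffles):
                xs = x[rng.permutation(n_frames)]
                ys = y[rng.permutation(n_frames)]
                shuf.append(np.corrcoef(xs, ys)[0, 1])
            dist = abs(roi_positions_um[ids[a]] - roi_positions_um[ids[b]])
            rows.append({"dendrite_i": ids[a], "dendrite_j": ids[b],
                         "distance_um": float(dist),
                         "distance_bin_um": bin_um * (dist // bin_um),
                         "pearson_r": r,
                         "shuffled_r": float(np.mean(shuf))})
    return pd.DataFrame(rows)
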