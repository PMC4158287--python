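"""Raw fluorescence to ΔF/F, and normalization to the mean spontaneous event.

ΔF/F is computed frame-by-frame as ``(F - Fb) / Fb`` where the baseline
``Fb`` is the 8th percentile of F within a centered 1-s moving window
(truncated at the trace edges).  For presentation-scale comparisons each
dendrite's ΔF/F trace is divided by the peak of its mean spontaneous
calcium event, so a unit of the normalized trace is "one average
spontaneous event".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DffTrace:
    """Per-dendrite ΔF/F time series."""

    dendrite_id: int
    values: np.ndarray
    frame_period_ms: float
    normalization: str = "raw"        # "raw" | "spont_peak"
    roi_position_um: float = 0.0
    spont_peak: float | None = None   # divisor used for the normalized variant

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ΔF/F values must be finite")
        if self.frame_period_ms <= 0:
            raise ValueError("frame_period_ms must be positive")
        if self.normalization == "spont_peak" and not (self.spont_peak or 0) > 0:
            raise ValueError("normalized trace must record a positive spontaneous peak")


def extract_roi_fluorescence(movie: np.ndarray, masks: np.ndarray | dict
                             ) -> dict[int, np.ndarray]:
    """Mean fluorescence over each ROI's pixels, per frame.

    ``masks`` is either a labeled 2-D image (0 = background, label k =
    dendrite ``k - 1``) or a mapping ``dendrite_id -> boolean mask``.
    Overlapping boolean masks are allowed; shared pixels contribute to both
    means.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, height, width) array")
    if isinstance(masks, dict):
        items = [(int(k), np.asarray(m, bool)) for k, m in masks.items()]
    else:
        labels = np.asarray(masks)
        items = [(int(lab) - 1, labels == lab)
                 for lab in np.unique(labels) if lab != 0]
    out: dict[int, np.ndarray] = {}
    for did, mask in items:
        if mask.shape != movie.shape[1:]:
            raise ValueError(f"mask for dendrite {did} does not match movie frame shape")
        if not mask.any():
            raise ValueError(f"empty ROI mask for dendrite {did}")
        out[did] = movie[:, mask].mean(axis=1)
    return out


def _truncated_window_percentile(f: np.ndarray, idx: np.ndarray, half: int,
                                 q: float) -> np.ndarray:
    n = len(f)
    out = np.empty(len(idx))
    for k, i in enumerate(idx):
        out[k] = np.percentile(f[max(0, i - half):min(n, i + half + 1)], q)
    return out


def compute_dff(f: np.ndarray, frame_period_ms: float, window_ms: float = 1000.0,
                percentile: float = 8.0, baseline_stride: int = 1) -> np.ndarray:
    """ΔF/F = (F - Fb)/Fb with a moving low-percentile baseline.

    Fb at each frame is the ``percentile``-th percentile (linear-interpolation
    definition) of F within a centered window of ``window_ms``, truncated at
    the trace edges.  ``baseline_stride > 1`` evaluates the baseline on a
    subgrid and linearly interpolates between the evaluation points — the
    baseline varies slowly by construction, so this is an accuracy-neutral
    shortcut for densely sampled traces.
    """
    f = np.asarray(f, dtype=float)
    n = len(f)
    half = max(1, int(round(window_ms / 2.0 / frame_period_ms)))
    if n < half + 1:
        raise ValueError("trace shorter than the baseline window")

    if baseline_stride <= 1:
        if n >= 2 * half + 1:
            from numpy.lib.stride_tricks import sliding_window_view
            fb = np.empty(n)
            interior = sliding_window_view(f, 2 * half + 1)
            fb[half:n - half] = np.percentile(interior, percentile, axis=1)
            edges = np.concatenate([np.arange(half), np.arange(n - half, n)])
            fb[edges] = _truncated_window_percentile(f, edges, half, percentile)
        else:
            fb = _truncated_window_percentile(f, np.arange(n), half, percentile)
    else:
        centers = np.arange(0, n, baseline_stride)
        if centers[-1] != n - 1:
            centers = np.append(centers, n - 1)
        fb_c = np.empty(len(centers))
        interior = (centers >= half) & (centers < n - half)
        if interior.any():
            from numpy.lib.stride_tricks import sliding_window_view
            view = sliding_window_view(f, 2 * half + 1)
            fb_c[interior] = np.percentile(view[centers[interior] - half],
                                           percentile, axis=1)
        edges = ~interior
        if edges.any():
            fb_c[edges] = _truncated_window_percentile(f, centers[edges],
                                                       half, percentile)
        fb = np.interp(np.arange(n), centers, fb_c)

    if (fb <= 0).any():
        raise ValueError("non-positive baseline fluorescence; raw F must be positive")
    return (f - fb) / fb


def mean_spontaneous_event(dff: np.ndarray, frame_period_ms: float,
                           peak_indices: np.ndarray,
                           pre_ms: float = 200.0, post_ms: float = 500.0
                           ) -> np.ndarray:
    """Peak-aligned average of the spontaneous events of one dendrite.

    Events whose window would run off either trace edge are skipped; uses the
    detected peak frame with no sub-frame interpolation.
    """
    pre = int(round(pre_ms / frame_period_ms))
    post = int(round(post_ms / frame_period_ms))
    segs = []
    for p in np.asarray(peak_indices, dtype=int):
        if p - pre >= 0 and p + post + 1 <= len(dff):
            segs.append(dff[p - pre:p + post + 1])
    if not segs:
        raise ValueError("no usable spontaneous events: record a longer baseline")
    return np.mean(segs, axis=0)


def normalize_to_spontaneous(dff: np.ndarray, frame_period_ms: float,
                             spont_peak_indices: np.ndarray
                             ) -> tuple[np.ndarray, float, np.ndarray]:
    """Divide a ΔF/F trace by the peak of its mean spontaneous event.

    Returns ``(normalized_trace, spont_peak, mean_event)``.  After
    normalization the dendrite's mean spontaneous event has peak exactly 1.
    """
    if len(np.atleast_1d(spont_peak_indices)) == 0:
        raise ValueError("no spontaneous events for this dendrite: "
                         "record a longer baseline")
    mean_event = mean_spontaneous_event(dff, frame_period_ms, spont_peak_indices)
    peak = float(mean_event.max())
    if peak <= 0:
        raise ValueError("mean spontaneous event has non-positive peak")
    return dff / peak, peak, mean_event / peak
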