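"""Analysis window conventions shared across modules.

All windows are half-open ``[a, b)`` and all times are milliseconds unless a
name says otherwise.  A frame's time is its start time; frames are 0-based.
"""

# Peak-time window (relative to stimulus onset) within which a detected
# calcium event counts as airpuff-evoked.
EVOKED_WINDOW_MS: tuple[float, float] = (50.0, 200.0)

# Pre-stimulus window used to estimate the spontaneous ("sp") chance
# probability on a per-trial basis; matched in span to the evoked window.
SP_WINDOW_MS: float = 150.0

# Latency intervals used for early/late event-count comparisons.
LATENCY_WINDOWS_MS: tuple[tuple[float, float], ...] = ((0.0, 75.0), (75.0, 150.0))

# Condition labels per stimulus family, ordered by increasing strength.
DURATION_CONDITIONS: tuple[str, ...] = ("d1", "d2", "d3", "d4")
PRESSURE_CONDITIONS: tuple[str, ...] = ("p1", "p2")

CONDITION_ORDERS: dict[str, tuple[str, ...]] = {
    "duration": DURATION_CONDITIONS,
    "pressure": PRESSURE_CONDITIONS,
}


def condition_order(mode: str) -> tuple[str, ...]:
    """Ordered condition labels for a stimulus mode (``duration``/``pressure``)."""
    try:
        return CONDITION_ORDERS[mode]
    except KeyError:
        raise ValueError(f"unknown stimulus mode {mode!r}; expected one of "
                         f"{sorted(CONDITION_ORDERS)}") from None
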