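"""Event timelines and per-volume condition arrays.

Subjects report episode on/offsets in continuous time (seconds); the state
sequence lives on the volume grid (one label per TR). This module rounds
episodes to the nearest volume, aligns them with the edge-trimmed phase
series, applies the optional hemodynamic lag shift, selects each subject's
analysis window, and masks state sequences by condition.

Volume convention: volume t covers [t*TR, (t+1)*TR), 0-based; episodes are
marked on half-open index ranges, so a boundary volume between consecutive
episodes is never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EventTimeline",
    "ConditionArray",
    "MaskedStateSequence",
    "events_to_condition_array",
    "rounding_deviation",
    "shift_condition_array",
    "analysis_window",
    "mask_states_by_condition",
]

DEFAULT_SHIFT_TR = 8  # 4.8 s at TR = 0.6 s, centre of the 4-6 s BOLD lag


@dataclass(frozen=True)
class EventTimeline:
    """Sorted, non-overlapping (onset, offset) episode pairs in seconds."""

    episodes: tuple[tuple[float, float], ...]
    truncated: bool = False  # set by generators that could not fit all events

    def __post_init__(self) -> None:
        eps = tuple((float(a), float(b)) for a, b in self.episodes)
        for a, b in eps:
            if not a < b:
                raise ValueError(f"episode ({a}, {b}) has onset >= offset")
            if a < 0:
                raise ValueError(f"episode ({a}, {b}) starts before the scan")
        for (a1, b1), (a2, b2) in zip(eps, eps[1:]):
            if a2 < b1:
                raise ValueError("episodes overlap or are unsorted")
        object.__setattr__(self, "episodes", eps)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.episodes))

    def occupancy(self, scan_dur: float) -> float:
        """Fraction of the scan covered by episodes."""
        return self.total_duration / scan_dur


@dataclass(frozen=True)
class ConditionArray:
    """Per retained volume: 1 = event, 0 = rest; plus bookkeeping.

    ``window`` is the half-open (start, end) analysis window over retained
    volumes once selected (None before selection); ``shift_applied`` records
    the hemodynamic shift in TRs.
    """

    labels: np.ndarray
    shift_applied: int = 0
    window: tuple[int, int] | None = None
    n_dropped_episodes: int = 0
    n_merged_episodes: int = 0
    truncated_by_shift: bool = False

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("condition labels must be 0 or 1")
        if self.window is not None:
            s, e = self.window
            if not (0 <= s < e <= lab.size):
                raise ValueError(f"invalid window {self.window} for {lab.size} volumes")
        object.__setattr__(self, "labels", lab)


@dataclass(frozen=True)
class MaskedStateSequence:
    """State labels within the analysis window, other-condition volumes -> 0."""

    labels: np.ndarray
    condition_of_interest: int
    tr: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if np.any(lab < 0):
            raise ValueError("state labels must be >= 0")
        object.__setattr__(self, "labels", lab)


def _round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (0.5 -> 1, not banker's 0)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def events_to_condition_array(
    timeline: EventTimeline,
    tr: float,
    n_volumes_original: int,
    front_trim: int = 10,
    back_trim: int = 10,
) -> ConditionArray:
    """Rasterise an event timeline onto the retained volume grid.

    Episode boundaries are rounded to the nearest volume index
    (onset_idx = round(onset/tr), offset_idx = round(offset/tr), half away
    from zero) and marked on the half-open range [onset_idx, offset_idx) in
    the original indexing; the array is then cut down to the retained volumes
    (indices shifted by -front_trim). Episodes that round to zero length are
    dropped and counted; overlaps created by rounding are merged and counted.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    scan_dur = n_volumes_original * tr
    n_retained = n_volumes_original - front_trim - back_trim
    if n_retained <= 0:
        raise ValueError("trimming leaves no volumes")
    full = np.zeros(n_volumes_original, dtype=int)
    dropped = 0
    merged = 0
    for onset, offset in timeline.episodes:
        if onset >= scan_dur:
            raise ValueError(
                f"episode ({onset}, {offset}) lies outside the {scan_dur:.1f} s scan"
            )
        i0 = _round_half_away(onset / tr)
        i1 = _round_half_away(offset / tr)
        i0 = max(i0, 0)
        i1 = min(i1, n_volumes_original)
        if i1 <= i0:
            dropped += 1
            continue
        if full[i0:i1].any():
            merged += 1
        full[i0:i1] = 1
    return ConditionArray(
        labels=full[front_trim : n_volumes_original - back_trim],
        n_dropped_episodes=dropped,
        n_merged_episodes=merged,
    )


def rounding_deviation(timeline: EventTimeline, tr: float) -> float:
    """Total |rounded duration - true duration| over episodes, in seconds.

    Diagnostic for the nearest-integer rounding rule; bounded by one TR per
    episode boundary pair.
    """
    dev = 0.0
    for onset, offset in timeline.episodes:
        i0 = _round_half_away(onset / tr)
        i1 = _round_half_away(offset / tr)
        dev += abs((i1 - i0) * tr - (offset - onset))
    return dev


def shift_condition_array(arr: ConditionArray, n_tr: int = DEFAULT_SHIFT_TR) -> ConditionArray:
    """Shift the condition labels ``n_tr`` volumes later in time.

    The BOLD response lags the experience by roughly 4-6 s, so event labels
    are moved later; the vacated head volumes become rest (0) and labels
    pushed past the end are discarded (flagged when any marked volume is
    lost).
    """
    if n_tr < 0:
        raise ValueError("n_tr must be >= 0")
    n = arr.labels.size
    if n_tr >= n:
        raise ValueError(f"shift of {n_tr} TRs exceeds the {n}-volume array")
    if n_tr == 0:
        return arr
    shifted = np.zeros_like(arr.labels)
    shifted[n_tr:] = arr.labels[: n - n_tr]
    lost = bool(arr.labels[n - n_tr :].any())
    return replace(
        arr,
        labels=shifted,
        shift_applied=arr.shift_applied + n_tr,
        truncated_by_shift=arr.truncated_by_shift or lost,
        window=None,
    )


def analysis_window(states: np.ndarray, condition: ConditionArray) -> tuple[int, int]:
    """Select the subject's analysis window from state and condition changes.

    The first and last state of the scan have no definite start/end, so the
    window begins at the earliest volume where either the state label or the
    condition label differs from its predecessor, and ends (half-open) at the
    latest such volume; everything before the first change and from the last
    change onward is discarded.

    Raises on fully constant input (no change anywhere).
    """
    s = np.asarray(states)
    c = condition.labels
    if s.shape[0] != c.shape[0]:
        raise ValueError("states and condition arrays differ in length")
    change = np.flatnonzero((s[1:] != s[:-1]) | (c[1:] != c[:-1])) + 1
    if change.size == 0:
        raise ValueError("no state or condition change: empty analysis window")
    return int(change[0]), int(change[-1])


def mask_states_by_condition(
    states: np.ndarray,
    condition: np.ndarray,
    condition_of_interest: int,
    tr: float = 0.6,
) -> MaskedStateSequence:
    """Zero out volumes of the other condition, keeping state labels otherwise.

    Masking prevents two events separated by a short rest from concatenating
    into one inflated dwell, and gives the transition analysis an explicit
    "0" state marking condition boundaries.
    """
    s = np.asarray(states, dtype=int)
    c = np.asarray(condition, dtype=int)
    if s.shape != c.shape:
        raise ValueError("states and condition must have equal length")
    if condition_of_interest not in (0, 1):
        raise ValueError("condition_of_interest must be 0 or 1")
    out = np.where(c == condition_of_interest, s, 0)
    return MaskedStateSequence(out, condition_of_interest, tr)
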