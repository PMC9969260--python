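"""Per-subject, per-condition characteristics of PL-state dynamics.

Four metrics summarise how a subject moves through phase-locking states
within each condition (event vs rest):

* switching frequency — state transitions per second,
* probability of occurrence (fractional occupancy) — share of condition
  volumes spent in each state,
* mean dwell time — average length of a maximal run of one state, seconds,
* switch probability — row-normalised transition probabilities, including
  the "0" mask state that marks the other condition.

Switching frequency and occupancy are computed on condition-restricted
volumes directly (a transition straddling a condition boundary counts for
neither condition); dwell time and switch probability consume the 0-masked
sequence so that two events separated by rest never concatenate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import ConditionArray, MaskedStateSequence

__all__ = [
    "TransitionCounts",
    "switching_frequency",
    "occurrence_probability",
    "mean_dwell_time",
    "switch_probabilities",
    "subject_condition_metrics",
    "assemble_metrics",
]

METRIC_COLUMNS = [
    "subject_id",
    "group",
    "condition",
    "shift",
    "metric",
    "state",
    "to_state",
    "value",
    "missing",
]


@dataclass
class TransitionCounts:
    """Observed switches between states 0..k (0 = other-condition mask).

    ``counts[i, j]`` is the number of consecutive-volume pairs switching from
    state i to state j (diagonal is structurally zero: a switch requires a
    label change). ``probabilities`` row-normalises over outgoing switches;
    rows with no outgoing switch are NaN and flagged in ``row_observed``.
    """

    counts: np.ndarray  # (k+1, k+1) ints
    probabilities: np.ndarray  # (k+1, k+1) floats, NaN rows possible
    row_observed: np.ndarray  # (k+1,) bool


def _condition_mask(condition: ConditionArray | np.ndarray) -> np.ndarray:
    return condition.labels if isinstance(condition, ConditionArray) else np.asarray(condition)


def switching_frequency(
    states: np.ndarray,
    condition: ConditionArray | np.ndarray,
    condition_of_interest: int,
    tr: float,
) -> float:
    """State transitions per second within one condition.

    Counts consecutive-volume pairs whose two volumes both belong to the
    condition of interest and whose state labels differ, divided by the
    condition's duration (condition volumes x TR). Returns NaN when the
    condition never occurs.
    """
    s = np.asarray(states)
    c = _condition_mask(condition)
    in_cond = c == condition_of_interest
    n_vol = int(in_cond.sum())
    if n_vol == 0:
        return np.nan
    both = in_cond[:-1] & in_cond[1:]
    n_switch = int(np.sum(both & (s[:-1] != s[1:])))
    return n_switch / (n_vol * tr)


def occurrence_probability(
    states: np.ndarray,
    condition: ConditionArray | np.ndarray,
    condition_of_interest: int,
    k: int,
) -> np.ndarray:
    """Fraction of condition volumes spent in each state 1..k (sums to 1).

    Returns an all-NaN vector when the condition never occurs.
    """
    s = np.asarray(states)
    c = _condition_mask(condition)
    sel = s[c == condition_of_interest]
    if sel.size == 0:
        return np.full(k, np.nan)
    return np.bincount(sel, minlength=k + 1)[1 : k + 1] / sel.size


def mean_dwell_time(masked: MaskedStateSequence, k: int) -> np.ndarray:
    """Mean maximal-run length per state 1..k, in seconds.

    Runs are broken by the 0 mask label and by the window edges. States never
    present in the sequence yield NaN.
    """
    s = masked.labels
    sums = np.zeros(k + 1)
    counts = np.zeros(k + 1, dtype=int)
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        if s[i] != 0:
            sums[s[i]] += j - i
            counts[s[i]] += 1
        i = j
    with np.errstate(invalid="ignore"):
        mean_runs = np.where(counts[1:] > 0, sums[1:] / np.maximum(counts[1:], 1), np.nan)
    return mean_runs * masked.tr


def switch_probabilities(masked: MaskedStateSequence, k: int) -> TransitionCounts:
    """Transition counts and row-normalised probabilities over states 0..k.

    Every consecutive pair with differing labels is one switch, including
    pairs entering or leaving the 0 mask state — those transitions mark
    condition on/offsets.
    """
    s = masked.labels
    if np.any(s > k):
        raise ValueError("state label exceeds k")
    counts = np.zeros((k + 1, k + 1), dtype=int)
    frm, to = s[:-1], s[1:]
    diff = frm != to
    np.add.at(counts, (frm[diff], to[diff]), 1)
    row_tot = counts.sum(axis=1)
    observed = row_tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_tot[:, None]
    probs[~observed] = np.nan
    return TransitionCounts(counts=counts, probabilities=probs, row_observed=observed)


def subject_condition_metrics(
    subject_id: str,
    group: str,
    states: np.ndarray,
    condition: ConditionArray,
    k: int,
    tr: float,
    shift: int = 0,
) -> pd.DataFrame:
    """All four metrics for one subject, both conditions, as long-format rows.

    ``states`` and ``condition.labels`` must already be restricted to the
    subject's analysis window. Missing cells (state never visited in a
    condition, or an empty condition) appear as flagged NaN rows so that the
    statistics layer can decide on imputation.
    """
    from .events import mask_states_by_condition  # local: avoid cycle at import

    s = np.asarray(states)
    c = condition.labels
    rows: list[dict] = []
    for cond_val, cond_name in ((1, "event"), (0, "rest")):
        sf = switching_frequency(s, c, cond_val, tr)
        rows.append(
            dict(condition=cond_name, metric="switch_freq", state=0, to_state=None,
                 value=sf, missing=bool(np.isnan(sf)))
        )
        occ = occurrence_probability(s, c, cond_val, k)
        masked = mask_states_by_condition(s, c, cond_val, tr)
        dwell = mean_dwell_time(masked, k)
        trans = switch_probabilities(masked, k)
        for st in range(1, k + 1):
            rows.append(
                dict(condition=cond_name, metric="occupancy", state=st, to_state=None,
                     value=occ[st - 1], missing=bool(np.isnan(occ[st - 1])))
            )
            rows.append(
                dict(condition=cond_name, metric="dwell_time", state=st, to_state=None,
                     value=dwell[st - 1], missing=bool(np.isnan(dwell[st - 1])))
            )
        for frm in range(k + 1):
            for to in range(k + 1):
                if frm == to:
                    continue
                v = trans.probabilities[frm, to]
                rows.append(
                    dict(condition=cond_name, metric="switch_prob", state=frm,
                         to_state=to, value=v, missing=bool(np.isnan(v)))
                )
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", subject_id)
    df.insert(1, "group", group)
    df.insert(3, "shift", shift)
    return df[METRIC_COLUMNS]


def assemble_metrics(per_subject_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject metric tables into one tidy long table.

    Keys (subject, condition, shift, metric, state, to_state) must be unique
    across the input; duplicates raise.
    """
    if not per_subject_tables:
        raise ValueError("no metric tables to assemble")
    df = pd.concat(per_subject_tables, ignore_index=True)[METRIC_COLUMNS]
    keys = ["subject_id", "condition", "shift", "metric", "state", "to_state"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate metric keys:\n{df.loc[dup, keys].head()}")
    return df
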