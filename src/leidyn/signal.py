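"""Band-pass filtering and instantaneous phase extraction for ROI BOLD series.

The dynamic-connectivity analysis downstream is entirely phase based: each
region's band-limited BOLD signal is mapped to its analytic-signal angle
theta(n, t), and all later quantities are functions of phase differences.
Filtering is therefore zero-phase (forward-backward Butterworth), so the
filter contributes no frequency-dependent phase lag of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "SubjectRecording",
    "PhaseSeries",
    "bandpass_filter",
    "instantaneous_phase",
    "trim_edges",
]

#: Default passband (Hz) for resting-state BOLD phase analysis.
DEFAULT_BAND = (0.04, 0.07)
#: Default Butterworth order (per pass; applied forward-backward).
DEFAULT_ORDER = 5
#: Default number of volumes dropped at each end against Hilbert edge effects.
DEFAULT_TRIM = 10


@dataclass(frozen=True)
class SubjectRecording:
    """One subject's ROI x time BOLD matrix with acquisition context.

    Attributes
    ----------
    subject_id : str
    group : str
        Group label (e.g. clinical / non-clinical).
    bold : ndarray, shape (n_regions, n_volumes)
        Region-averaged BOLD amplitude, arbitrary units.
    tr : float
        Repetition time in seconds.
    """

    subject_id: str
    group: str
    bold: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bold, dtype=float)
        if b.ndim != 2:
            raise ValueError("bold must be a 2-D regions x volumes matrix")
        if b.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if b.shape[1] <= 20:
            raise ValueError("need more than 20 volumes")
        if not np.all(np.isfinite(b)):
            raise ValueError(f"non-finite values in BOLD matrix of {self.subject_id}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "bold", b)

    @property
    def n_regions(self) -> int:
        return self.bold.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[1]


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phases theta(n, t) for the retained volumes of a subject.

    ``retained_index_offset`` counts volumes dropped at the front, so retained
    volume ``t`` corresponds to original volume ``t + retained_index_offset``.
    """

    subject_id: str
    phases: np.ndarray
    retained_index_offset: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite phases")
        if np.any(p <= -np.pi) or np.any(p > np.pi):
            raise ValueError("phases must lie in (-pi, pi]")
        object.__setattr__(self, "phases", p)

    @property
    def n_regions(self) -> int:
        return self.phases.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.phases.shape[1]


def bandpass_filter(
    bold: np.ndarray,
    tr: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    A ``order``-th order Butterworth band-pass is designed for sampling rate
    1/tr and applied forward and backward (``sosfiltfilt``), which cancels the
    filter's phase response at the cost of doubling the effective magnitude
    order.

    Parameters
    ----------
    bold : ndarray, shape (n_regions, n_volumes)
    tr : float
        Sampling interval in seconds.
    low, high : float
        Passband edges in Hz; must satisfy 0 < low < high < Nyquist.
    order : int
        Per-pass filter order, >= 1.

    Returns
    -------
    ndarray of the same shape.
    """
    x = np.atleast_2d(np.asarray(bold, dtype=float))
    if order < 1:
        raise ValueError("order must be >= 1")
    nyq = 0.5 / tr
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"invalid band [{low}, {high}] Hz for Nyquist {nyq:.4f} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    min_len = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= min_len:
        raise ValueError(
            f"series of length {x.shape[-1]} too short for order-{order} "
            f"band-pass (needs > {min_len} samples)"
        )
    # maximal odd-extension padding: a narrow band means a long impulse
    # response, and the default pad length leaks edge transients deep into
    # the series
    out = sps.sosfiltfilt(sos, x, axis=-1, padlen=x.shape[-1] - 1)
    return out if np.asarray(bold).ndim == 2 else out[0]


def instantaneous_phase(filtered: np.ndarray) -> np.ndarray:
    """Per-region instantaneous phase via the Hilbert transform.

    Rows are demeaned before the transform (a residual DC offset would bias
    the analytic-signal angle). Output is the angle of the analytic signal,
    wrapped to (-pi, pi].

    Raises
    ------
    ValueError
        If any region's series is identically zero after demeaning (phase
        undefined), naming the offending region index.
    """
    x = np.atleast_2d(np.asarray(filtered, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in filtered signal")
    x = x - x.mean(axis=-1, keepdims=True)
    dead = np.flatnonzero(np.all(x == 0.0, axis=-1))
    if dead.size:
        raise ValueError(f"phase undefined for all-zero region(s) {dead.tolist()}")
    analytic = sps.hilbert(x, axis=-1)
    phases = np.angle(analytic)
    # np.angle returns [-pi, pi]; map -pi onto +pi for the (-pi, pi] contract.
    phases[phases == -np.pi] = np.pi
    return phases if np.asarray(filtered).ndim == 2 else phases[0]


def trim_edges(x: np.ndarray, front: int = DEFAULT_TRIM, back: int = DEFAULT_TRIM):
    """Drop ``front`` and ``back`` volumes along the last (time) axis.

    The Hilbert transform is least reliable near the series edges; the
    transform is computed on the full series and the contaminated ends are
    discarded afterwards (800 volumes with the 10+10 default leaves 780).
    """
    x = np.asarray(x)
    if front < 0 or back < 0:
        raise ValueError("trim counts must be non-negative")
    n = x.shape[-1]
    if n <= front + back:
        raise ValueError(
            f"cannot trim {front}+{back} volumes from a series of length {n}"
        )
    return x[..., front : n - back]


def phases_for_subject(
    rec: SubjectRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
    front_trim: int = DEFAULT_TRIM,
    back_trim: int = DEFAULT_TRIM,
) -> PhaseSeries:
    """Filter, phase-extract and trim one recording (convenience wrapper)."""
    filt = bandpass_filter(rec.bold, rec.tr, low=low, high=high, order=order)
    phases = instantaneous_phase(filt)
    return PhaseSeries(
        subject_id=rec.subject_id,
        phases=trim_edges(phases, front_trim, back_trim),
        retained_index_offset=front_trim,
    )
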