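"""Savitzky–Golay smoothing and derivative estimation.

Position derivatives up to jerk are estimated per axis with a third-order
Savitzky–Golay filter: each sample gets a local cubic least-squares fit over
a ``window_span``-sample window, and the fitted polynomial's derivatives are
evaluated at the sample.  The window span is the smoothing dial studied
throughout this package; the conventional sweep at 100 Hz is
{5, 25, 51, 101, 201} samples — minimum, quarter-second, half-second, one
second and two seconds.

Edges are handled by evaluating the polynomial fitted to the terminal window
(scipy's ``mode="interp"``), not by padding or reflecting the signal:
padding modes distort the jerk estimate at the segment boundaries, which
dominate short cannulation trials.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import savgol_filter

from .io import KinematicSeries
from .segmentation import TaskSegment

__all__ = ["DerivativeSet", "SpanTooLongError", "sg_derivatives", "speed_profile"]

DEFAULT_SPANS = (5, 25, 51, 101, 201)


class SpanTooLongError(ValueError):
    """The segment is shorter than the requested window span.

    Callers sweeping several spans should drop the trial at this span (and
    record why) rather than shrink the window silently.
    """


@dataclasses.dataclass
class DerivativeSet:
    """Smoothed position and derivatives at one window span.

    ``position``, ``velocity``, ``acceleration`` and ``jerk`` are (n, 3)
    arrays aligned to ``t`` in mm, mm/s, mm/s² and mm/s³; ``speed`` is the
    per-sample Euclidean norm of the velocity vector (mm/s).
    """

    window_span: int
    t: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    jerk: np.ndarray
    speed: np.ndarray
    fs: float

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


def sg_derivatives(
    segment: TaskSegment | KinematicSeries,
    window_span: int,
    polyorder: int = 3,
) -> DerivativeSet:
    """Estimate position and derivatives of order 1–3 at one window span.

    Parameters
    ----------
    segment : TaskSegment or KinematicSeries
        The cropped task window (or a bare series, for synthetic studies).
    window_span : int
        Odd number of samples per local fit, ≥ 5 and ≤ the record length.
    polyorder : int
        Local polynomial order; 3 (cubic) is the design default, the lowest
        order that carries a jerk estimate.

    Raises
    ------
    SpanTooLongError
        If the record is shorter than ``window_span``.
    """
    series = segment.series if isinstance(segment, TaskSegment) else segment
    window_span = int(window_span)
    if window_span % 2 == 0 or window_span < 5:
        raise ValueError("window_span must be odd and >= 5")
    if polyorder >= window_span:
        raise ValueError("polyorder must be smaller than window_span")
    n = len(series)
    if n < window_span:
        raise SpanTooLongError(
            f"segment of {n} samples is shorter than window span {window_span}; "
            "drop this trial at this span"
        )
    pos = series.positions
    # true sample interval, not the nominal one, so derivative scaling is exact
    delta = float(np.mean(np.diff(series.t)))
    out = [
        savgol_filter(
            pos, window_span, polyorder, deriv=d, delta=delta, axis=0, mode="interp"
        )
        for d in range(4)
    ]
    velocity = out[1]
    return DerivativeSet(
        window_span=window_span,
        t=series.t,
        position=out[0],
        velocity=velocity,
        acceleration=out[2],
        jerk=out[3],
        speed=np.linalg.norm(velocity, axis=1),
        fs=1.0 / delta,
    )


def speed_profile(dset: DerivativeSet) -> np.ndarray:
    """Per-sample Euclidean norm of the 3-D velocity estimate (mm/s).

    This is the speed of the needle tip — the rotation-invariant scalar
    whose peaks and spectrum the smoothness metrics consume — not the
    derivative of the (origin-dependent) distance from the origin.
    """
    return np.linalg.norm(dset.velocity, axis=1)
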