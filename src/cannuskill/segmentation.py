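"""Task segmentation: entry detection, flashback intervals, cropping.

All process metrics are computed on the *constrained task*: the window from
``t_entry`` — the first timestamp at which the needle tip's z-position drops
below the skin surface — to ``t_end``, the final recorded sample.  Using the
first crossing only means later re-emergences and reinsertion attempts stay
inside one task window rather than splitting the trial.

The flashback channel is converted to closed time intervals with a
sample-and-hold convention: a run of consecutive ``flash == 1`` samples
extends to the timestamp of the first subsequent zero sample, and a run that
reaches the final sample ends exactly at ``t_end``.  This makes the flash
ratio of an uninterrupted flashback exactly 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import KinematicSeries, TrialMeta

__all__ = [
    "TaskSegment",
    "NoEntryError",
    "detect_entry",
    "extract_flash_intervals",
    "segment_task",
]


class NoEntryError(ValueError):
    """The needle never punctured the skin surface; the trial is unusable."""


@dataclasses.dataclass
class TaskSegment:
    """The cropped task window plus its flashback intervals.

    ``t_flash`` is the onset of the first flashback interval, or ``None``
    when the LED never lit inside the window.  ``flash_intervals`` is an
    ordered list of disjoint ``(begin, end)`` pairs, all within
    ``[t_flash, t_end]``.
    """

    t_entry: float
    t_end: float
    t_flash: float | None
    flash_intervals: list[tuple[float, float]]
    series: KinematicSeries

    def __post_init__(self) -> None:
        if not self.t_entry < self.t_end:
            raise ValueError("t_entry must precede t_end")
        prev_end = -np.inf
        for a, b in self.flash_intervals:
            if a > b:
                raise ValueError(f"flash interval ({a}, {b}) reversed")
            if a < prev_end:
                raise ValueError("flash intervals must be disjoint and ordered")
            if b > self.t_end + 1e-12:
                raise ValueError("flash interval extends past t_end")
            prev_end = b
        if self.flash_intervals:
            if self.t_flash != self.flash_intervals[0][0]:
                raise ValueError("t_flash must equal the first interval onset")
        elif self.t_flash is not None:
            raise ValueError("t_flash set but no flash intervals")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_entry


def detect_entry(series: KinematicSeries, skin_z: float) -> float:
    """Timestamp of the first sample whose z lies below the skin surface.

    Later re-emergences do not move the entry time: the segmentation is
    first-crossing, which keeps multiple reinsertion attempts inside one
    task window.

    Raises
    ------
    NoEntryError
        If z never drops below ``skin_z``.
    """
    below = np.flatnonzero(series.z < skin_z)
    if below.size == 0:
        raise NoEntryError(
            f"needle tip never crossed the skin surface (skin_z={skin_z:g} mm, "
            f"min z={series.z.min():g} mm)"
        )
    return float(series.t[below[0]])


def extract_flash_intervals(
    series: KinematicSeries,
) -> tuple[list[tuple[float, float]], float | None]:
    """Maximal runs of ``flash == 1`` as closed time intervals.

    Returns ``(intervals, t_flash)`` where ``t_flash`` is the onset of the
    first interval, or ``(empty list, None)`` when the channel is all zeros.
    """
    flash = series.flash.astype(bool)
    if not flash.any():
        return [], None
    padded = np.concatenate([[0], flash.view(np.int8), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)  # first index after each run
    n = len(series)
    intervals = []
    for i, j in zip(starts, stops):
        end_idx = j if j < n else n - 1  # terminal run holds to the last sample
        intervals.append((float(series.t[i]), float(series.t[end_idx])))
    return intervals, intervals[0][0]


def segment_task(
    series: KinematicSeries,
    meta: TrialMeta | float,
) -> TaskSegment:
    """Crop a trial to ``[t_entry, t_end]`` and attach its flash intervals.

    ``meta`` may be a full :class:`~cannuskill.io.TrialMeta` or just the skin
    height in millimetres.  Flash intervals straddling ``t_entry`` are
    clipped to start at ``t_entry``; intervals entirely before it are
    dropped.  Segmentation is idempotent: re-segmenting the cropped series
    reproduces the same window.
    """
    skin_z = meta.skin_z if isinstance(meta, TrialMeta) else float(meta)
    t_entry = detect_entry(series, skin_z)
    t_end = float(series.t[-1])
    start = int(np.searchsorted(series.t, t_entry))
    cropped = KinematicSeries(
        t=series.t[start:],
        x=series.x[start:],
        y=series.y[start:],
        z=series.z[start:],
        flash=series.flash[start:],
        fs=series.fs,
    )
    raw_intervals, _ = extract_flash_intervals(series)
    intervals = []
    for a, b in raw_intervals:
        a, b = max(a, t_entry), min(b, t_end)
        # A zero-length interval can only be a flash confined to the very
        # last sample; it is kept so flash_ratio reports the degenerate
        # trial instead of silently scoring it 0.
        if b > a or (a == b == t_end):
            intervals.append((a, b))
    t_flash = intervals[0][0] if intervals else None
    return TaskSegment(
        t_entry=t_entry,
        t_end=t_end,
        t_flash=t_flash,
        flash_intervals=intervals,
        series=cropped,
    )
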