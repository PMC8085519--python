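"""Process metrics and the flash-ratio outcome metric.

Five per-trial process metrics quantify how the needle moved between skin
entry and task end:

* ``T`` — task time, ``t_end − t_entry`` (s).
* ``PL`` — path length: summed Euclidean steps of the smoothed tip
  trajectory (mm).
* ``Pks`` — number of strict local maxima of the speed profile; intermittent
  motion composed of many submovements produces many peaks.
* ``LDLJ`` — log dimensionless jerk,
  ``−ln| (T⁵/PL²) ∫ ‖d³x/dt³‖² dt |``.  The T⁵/PL² factor makes the squared
  jerk integral dimensionless, so LDLJ is invariant to the spatial and
  temporal scale of the movement; less negative = smoother.  A single
  minimum-jerk movement attains the maximum, ``−ln 720 ≈ −6.579``.
* ``SPARC`` — spectral arc length: the (negated) arc length of the
  frequency-normalised Fourier magnitude spectrum of the speed profile up to
  an adaptive cutoff.  Smooth movements concentrate spectral mass at low
  frequency, giving a short arc; less negative = smoother.  By construction
  SPARC ≤ −1.

The outcome metric ``FR`` (flash ratio) is the fraction of the time from
first flashback to task end during which flashback was maintained: 1 for an
uninterrupted flashback, 0 if flashback never occurred.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from .derivatives import DEFAULT_SPANS, DerivativeSet, SpanTooLongError, sg_derivatives
from .io import ProcessMetricsRow, TrialMeta
from .segmentation import TaskSegment

__all__ = [
    "SpectrumProfile",
    "UndefinedMetricError",
    "DegenerateTrialError",
    "time_metric",
    "path_length",
    "count_peaks",
    "ldlj",
    "sparc",
    "speed_spectrum",
    "flash_ratio",
    "compute_all",
]

logger = logging.getLogger(__name__)

MINIMUM_JERK_LDLJ = -math.log(720.0)  # analytic optimum for a single movement


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined on this input.

    Raised e.g. for LDLJ of a motion with identically zero jerk (ln 0) or
    SPARC of an identically zero speed profile (V(0) = 0).
    """


class DegenerateTrialError(ValueError):
    """The trial's flashback geometry makes the flash ratio 0/0."""


@dataclasses.dataclass
class SpectrumProfile:
    """Normalised speed spectrum feeding SPARC.

    ``omega`` is the angular-frequency grid (rad/s), ``V`` the Fourier
    magnitude of the speed profile, ``Vhat = V/V(0)`` its DC-normalised
    version (so ``Vhat[0] == 1``), and ``omega_c`` the adaptive cutoff: the
    largest frequency not exceeding the configured maximum at which ``Vhat``
    still reaches the amplitude threshold.
    """

    omega: np.ndarray
    V: np.ndarray
    Vhat: np.ndarray
    omega_c: float


def time_metric(segment: TaskSegment) -> float:
    """Task time T = t_end − t_entry in seconds."""
    return segment.t_end - segment.t_entry


def path_length(dset: DerivativeSet) -> float:
    """Path length PL: summed Euclidean steps of the smoothed trajectory (mm)."""
    steps = np.diff(dset.position, axis=0)
    return float(np.linalg.norm(steps, axis=1).sum())


def count_peaks(dset: DerivativeSet, prominence: float = 0.0) -> int:
    """Number of strict local maxima of the speed profile.

    ``prominence`` (mm/s) is an optional floor for noisy real data; the
    default 0 counts literal local maxima.  A floor at the floating-point
    noise level (1e-12 of the peak speed) is always applied so that
    roundoff wiggles on analytically flat profiles are not counted.
    """
    scale = float(dset.speed.max(initial=0.0))
    floor = max(prominence, 1e-12 * scale)
    kwargs = {"prominence": floor} if floor > 0 else {}
    peaks, _ = find_peaks(dset.speed, **kwargs)
    return int(peaks.size)


def ldlj(dset: DerivativeSet, T: float, PL: float) -> float:
    """Log dimensionless jerk of the segmented movement.

    The squared magnitude of the 3-D jerk vector is integrated over the task
    window by the trapezoidal rule, scaled by T⁵/PL² to remove units, and
    the negative natural log of the absolute value is returned.

    Raises
    ------
    UndefinedMetricError
        If the jerk is identically zero (constant velocity), where ln 0 is
        undefined.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    if not PL > 0:
        raise ValueError("PL must be positive")
    jerk_sq = np.einsum("ij,ij->i", dset.jerk, dset.jerk)
    integral = float(trapezoid(jerk_sq, dset.t))
    dlj = abs(T**5 / PL**2 * integral)
    # physical motion has DLJ >= 720; values at floating-point noise level
    # mean the jerk is identically zero up to roundoff
    if dlj < 1e-15:
        raise UndefinedMetricError(
            "jerk is identically zero; log dimensionless jerk is undefined"
        )
    return -math.log(dlj)


def speed_spectrum(
    speed: np.ndarray,
    fs: float,
    padlevel: int = 4,
    f_max: float = 10.0,
    amp_threshold: float = 0.05,
) -> SpectrumProfile:
    """Zero-padded, DC-normalised magnitude spectrum of a speed profile.

    The FFT length is the record length rounded up to a power of two and
    shifted left by ``padlevel`` bits; padding refines the frequency grid so
    the arc length is resolved on short trials.

    Raises
    ------
    UndefinedMetricError
        If the speed profile is identically zero (V(0) = 0).
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size < 2:
        raise ValueError("speed profile needs at least 2 samples")
    nfft = 2 ** (int(np.ceil(np.log2(speed.size))) + int(padlevel))
    V = np.abs(np.fft.rfft(speed, nfft))
    if V[0] == 0.0:
        raise UndefinedMetricError(
            "speed profile is identically zero; the normalised spectrum is undefined"
        )
    omega = 2.0 * np.pi * np.fft.rfftfreq(nfft, d=1.0 / fs)
    Vhat = V / V[0]
    within = omega <= 2.0 * np.pi * f_max
    candidates = np.flatnonzero(within & (Vhat >= amp_threshold))
    cut = int(candidates[-1])
    if cut == 0:
        raise UndefinedMetricError(
            "spectrum collapses to DC; arc length cutoff is undefined"
        )
    sel = slice(0, cut + 1)
    return SpectrumProfile(
        omega=omega[sel], V=V[sel], Vhat=Vhat[sel], omega_c=float(omega[cut])
    )


def sparc(
    dset: DerivativeSet,
    fs: float | None = None,
    padlevel: int = 4,
    f_max: float = 10.0,
    amp_threshold: float = 0.05,
) -> float:
    """Spectral arc length of the speed profile.

    The arc length of ``Vhat`` over ``[0, omega_c]`` with the frequency axis
    normalised by ``omega_c``:

    ``SPARC = −Σ sqrt((Δω/ω_c)² + (ΔV̂)²)``

    The normalised frequency axis alone contributes arc length 1, so
    SPARC ≤ −1 always, and amplitude scaling of the movement cancels in
    ``Vhat`` exactly.
    """
    if fs is None:
        fs = dset.fs
    prof = speed_spectrum(
        dset.speed, fs, padlevel=padlevel, f_max=f_max, amp_threshold=amp_threshold
    )
    d_omega = np.diff(prof.omega) / prof.omega_c
    d_vhat = np.diff(prof.Vhat)
    return float(-np.sum(np.sqrt(d_omega**2 + d_vhat**2)))


def flash_ratio(segment: TaskSegment) -> float:
    """Flash ratio FR: maintained-flashback time over time since first flashback.

    ``FR = Σ(t_flash_end − t_flash_begin) / (t_end − t_flash)``; 0 when
    flashback never occurred, 1 when it was held continuously from onset to
    task end.

    Raises
    ------
    DegenerateTrialError
        If the only flashback is a single sample at the very end of the
        record (0/0).
    """
    if not segment.flash_intervals:
        return 0.0
    denom = segment.t_end - segment.t_flash
    if denom == 0.0:
        raise DegenerateTrialError(
            "flashback confined to the final sample: flash ratio is 0/0"
        )
    total = sum(b - a for a, b in segment.flash_intervals)
    return total / denom


def compute_all(
    segment: TaskSegment,
    meta: TrialMeta,
    spans=DEFAULT_SPANS,
    polyorder: int = 3,
    prominence: float = 0.0,
    sparc_params: dict | None = None,
) -> list[ProcessMetricsRow]:
    """All process metrics for one trial across a sweep of window spans.

    Emits one row per span.  FR is span-independent and attached to every
    row.  Spans that cannot be computed (segment shorter than the window, or
    a mathematically undefined metric) yield a row whose metric fields are
    NaN with ``missing_reason`` set; per-span failures are recorded, never
    raised.
    """
    sparc_params = sparc_params or {}
    fr = flash_ratio(segment)
    T = time_metric(segment)
    rows: list[ProcessMetricsRow] = []
    for span in spans:
        try:
            dset = sg_derivatives(segment, span, polyorder=polyorder)
            pl = path_length(dset)
            row = ProcessMetricsRow(
                participant_id=meta.participant_id,
                trial_id=meta.trial_id,
                window_span=int(span),
                T=T,
                PL=pl,
                Pks=count_peaks(dset, prominence=prominence),
                LDLJ=ldlj(dset, T, pl),
                SPARC=sparc(dset, **sparc_params),
                FR=fr,
            )
        except (SpanTooLongError, UndefinedMetricError, ValueError) as exc:
            logger.info(
                "trial %s/%s span %d dropped: %s",
                meta.participant_id,
                meta.trial_id,
                span,
                exc,
            )
            row = ProcessMetricsRow(
                participant_id=meta.participant_id,
                trial_id=meta.trial_id,
                window_span=int(span),
                T=np.nan,
                PL=np.nan,
                Pks=np.nan,
                LDLJ=np.nan,
                SPARC=np.nan,
                FR=fr,
                missing_reason=str(exc),
            )
        rows.append(row)
    return rows
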