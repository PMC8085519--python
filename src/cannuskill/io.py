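"""Trial data model and on-disk formats.

A *trial* is one cannulation attempt: a uniformly sampled 3-D needle-tip
trajectory plus a synchronously sampled binary flashback channel, stored as a
CSV (columns ``time_s, x_mm, y_mm, z_mm, flash``) with a JSON metadata sidecar
(participant, fistula, skin height, expert ratings, experience).  Units are
fixed in the column names — seconds and millimetres — to prevent silent unit
drift; window spans elsewhere in the package are expressed in samples.

Derived per-trial metrics travel in a tidy long-format table, one row per
(trial, window span).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KinematicSeries",
    "TrialMeta",
    "ProcessMetricsRow",
    "SkillIndicators",
    "TrialFormatError",
    "TrialValidationError",
    "TRIAL_COLUMNS",
    "GRS_CATEGORIES",
    "METRICS_COLUMNS",
    "read_trial",
    "write_trial",
    "read_metrics_table",
    "write_metrics_table",
    "resample_uniform",
]

TRIAL_COLUMNS = ("time_s", "x_mm", "y_mm", "z_mm", "flash")

#: Expert-rating categories on the 1–7 Likert scale.  Palpation is retained in
#: the file format but excluded from the default skill score, since it is
#: unrelated to needle motion.
GRS_CATEGORIES = (
    "palpation",
    "needle_holding",
    "needle_movement",
    "flashback_quality",
    "overall_quality",
)

METRICS_COLUMNS = (
    "participant_id",
    "trial_id",
    "window_span",
    "T_s",
    "PL_mm",
    "Pks",
    "LDLJ",
    "SPARC",
    "FR",
)

#: Tolerated relative deviation of the median sample interval from 1/fs.
_JITTER_TOL = 0.01


class TrialFormatError(ValueError):
    """A trial file does not conform to the expected schema."""


class TrialValidationError(ValueError):
    """Trial content violates a data-model invariant."""


@dataclasses.dataclass
class KinematicSeries:
    """Uniformly sampled 3-D needle-tip trajectory with flashback channel.

    Parameters
    ----------
    t : ndarray
        Timestamps in seconds, strictly increasing, nominally uniform at
        ``fs``.
    x, y, z : ndarray
        Needle-tip position in millimetres.  ``z`` is vertical (larger =
        higher above the simulator base).
    flash : ndarray
        Per-sample binary flashback indicator (1 while the in-needle LED is
        lit).
    fs : float
        Nominal sampling rate in Hz (100 for the simulator hardware).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    flash: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.flash = np.asarray(self.flash)
        n = len(self.t)
        if n < 2:
            raise TrialValidationError("a trial needs at least 2 samples")
        for name in ("x", "y", "z", "flash"):
            if len(getattr(self, name)) != n:
                raise TrialValidationError(
                    f"channel {name!r} has {len(getattr(self, name))} samples, "
                    f"expected {n}"
                )
        dt = np.diff(self.t)
        if not np.all(dt > 0):
            raise TrialValidationError("timestamps must be strictly increasing")
        if self.fs <= 0:
            raise TrialValidationError("fs must be positive")
        if abs(np.median(dt) * self.fs - 1.0) > _JITTER_TOL:
            raise TrialValidationError(
                "median sample interval deviates more than "
                f"{_JITTER_TOL:.0%} from 1/fs={1.0 / self.fs:g} s; resample "
                "explicitly with resample_uniform() if this is intentional"
            )
        if not np.isin(self.flash, (0, 1)).all():
            raise TrialValidationError("flash values must be 0 or 1")
        self.flash = self.flash.astype(np.int8)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        """Position samples as an (n, 3) array in millimetres."""
        return np.column_stack([self.x, self.y, self.z])

    def replace(self, **changes) -> "KinematicSeries":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class TrialMeta:
    """Per-trial metadata: identity, geometry and skill indicators.

    ``grs`` maps each category in :data:`GRS_CATEGORIES` to an integer expert
    rating on a 1–7 Likert scale.  ``skin_z`` is the height of the simulator
    skin surface in millimetres on the same vertical axis as the trajectory.
    """

    participant_id: str
    trial_id: str
    fistula_id: int
    skin_z: float
    fs: float
    years_experience: float
    grs: dict

    def __post_init__(self) -> None:
        if not 1 <= int(self.fistula_id) <= 4:
            raise TrialValidationError("fistula_id must be in 1..4")
        if self.years_experience < 0:
            raise TrialValidationError("years_experience must be >= 0")
        missing = [c for c in GRS_CATEGORIES if c not in self.grs]
        if missing:
            raise TrialFormatError(f"missing GRS categories: {missing}")
        for cat, score in self.grs.items():
            if not 1 <= int(score) <= 7:
                raise TrialValidationError(
                    f"GRS score {cat}={score} outside the 1..7 Likert scale"
                )


@dataclasses.dataclass
class ProcessMetricsRow:
    """The five process metrics for one trial at one smoothing window span.

    ``T`` (task time, s), ``PL`` (path length, mm), ``Pks`` (speed-profile
    peak count), ``LDLJ`` (log dimensionless jerk, dimensionless, less
    negative = smoother) and ``SPARC`` (spectral arc length, < 0, less
    negative = smoother), plus the span-independent flash ratio ``FR``.

    When a span could not be computed for this trial (e.g. the segmented
    record is shorter than the window) the metric fields are NaN and
    ``missing_reason`` explains why.
    """

    participant_id: str
    trial_id: str
    window_span: int
    T: float
    PL: float
    Pks: float
    LDLJ: float
    SPARC: float
    FR: float
    missing_reason: str | None = None

    def __post_init__(self) -> None:
        if self.missing_reason is not None:
            return
        if not self.T > 0:
            raise TrialValidationError("T must be positive")
        if not self.PL > 0:
            raise TrialValidationError("PL must be positive")
        if self.Pks < 0 or self.Pks != int(self.Pks):
            raise TrialValidationError("Pks must be a nonnegative integer")
        if not np.isfinite(self.LDLJ):
            raise TrialValidationError("LDLJ must be finite")
        if not 0 <= self.FR <= 1:
            raise TrialValidationError("FR must lie in [0, 1]")


@dataclasses.dataclass
class SkillIndicators:
    """Per-trial skill indicators: FR (outcome), GRS sum and years experience."""

    FR: float
    GRS: int
    Exp: float

    def __post_init__(self) -> None:
        if not 0 <= self.FR <= 1:
            raise TrialValidationError("FR must lie in [0, 1]")


# ---------------------------------------------------------------------------
# trial CSV + JSON sidecar


def read_trial(csv_path, meta_path) -> tuple[KinematicSeries, TrialMeta]:
    """Read one trial from its CSV + JSON sidecar and validate it.

    Raises
    ------
    TrialFormatError
        If a required column or sidecar key is absent.
    TrialValidationError
        If the content violates a :class:`KinematicSeries` invariant.
    """
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    for col in TRIAL_COLUMNS:
        if col not in frame.columns:
            raise TrialFormatError(f"trial CSV {csv_path} missing column {col!r}")
    with open(meta_path) as fh:
        raw = json.load(fh)
    for key in ("participant_id", "trial_id", "fistula_id", "skin_z_mm",
                "fs_hz", "years_experience", "grs"):
        if key not in raw:
            raise TrialFormatError(f"sidecar {meta_path} missing key {key!r}")
    meta = TrialMeta(
        participant_id=str(raw["participant_id"]),
        trial_id=str(raw["trial_id"]),
        fistula_id=int(raw["fistula_id"]),
        skin_z=float(raw["skin_z_mm"]),
        fs=float(raw["fs_hz"]),
        years_experience=float(raw["years_experience"]),
        grs={k: int(v) for k, v in raw["grs"].items()},
    )
    series = KinematicSeries(
        t=frame["time_s"].to_numpy(),
        x=frame["x_mm"].to_numpy(),
        y=frame["y_mm"].to_numpy(),
        z=frame["z_mm"].to_numpy(),
        flash=frame["flash"].to_numpy(),
        fs=meta.fs,
    )
    return series, meta


def write_trial(series: KinematicSeries, meta: TrialMeta, csv_path, meta_path) -> None:
    """Write one trial as CSV + JSON sidecar (lossless round trip)."""
    frame = pd.DataFrame(
        {
            "time_s": series.t,
            "x_mm": series.x,
            "y_mm": series.y,
            "z_mm": series.z,
            "flash": series.flash,
        }
    )
    # 17 significant digits round-trip any float64 exactly
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "participant_id": meta.participant_id,
        "trial_id": meta.trial_id,
        "fistula_id": meta.fistula_id,
        "skin_z_mm": meta.skin_z,
        "fs_hz": meta.fs,
        "years_experience": meta.years_experience,
        "grs": dict(meta.grs),
    }
    with open(meta_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# tidy metrics table


def write_metrics_table(rows: Iterable[ProcessMetricsRow], path) -> pd.DataFrame:
    """Write process-metric rows as a tidy long-format CSV.

    Rows are sorted by (participant_id, trial_id, window_span); numeric
    fields are serialised at full double precision.  An empty input is an
    error — no silent empty files.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to write an empty metrics table")
    frame = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "trial_id": [r.trial_id for r in rows],
            "window_span": [r.window_span for r in rows],
            "T_s": [r.T for r in rows],
            "PL_mm": [r.PL for r in rows],
            "Pks": [r.Pks for r in rows],
            "LDLJ": [r.LDLJ for r in rows],
            "SPARC": [r.SPARC for r in rows],
            "FR": [r.FR for r in rows],
            "missing_reason": [r.missing_reason or "" for r in rows],
        }
    )
    frame = frame.sort_values(
        ["participant_id", "trial_id", "window_span"], kind="mergesort"
    ).reset_index(drop=True)
    frame.to_csv(path, index=False, float_format="%.17g")
    return frame


def read_metrics_table(path) -> pd.DataFrame:
    """Read a metrics CSV, checking the schema."""
    frame = pd.read_csv(
        path, keep_default_na=False, na_values=[""], float_precision="round_trip"
    )
    for col in METRICS_COLUMNS:
        if col not in frame.columns:
            raise TrialFormatError(f"metrics table {path} missing column {col!r}")
    if "missing_reason" not in frame.columns:
        frame["missing_reason"] = ""
    frame["missing_reason"] = frame["missing_reason"].fillna("")
    return frame


# ---------------------------------------------------------------------------


def resample_uniform(series: KinematicSeries, fs: float | None = None) -> KinematicSeries:
    """Resample a trial to a strictly uniform grid by linear interpolation.

    Savitzky–Golay differentiation assumes uniform spacing, so trials with
    more than 1% timing jitter are rejected at construction; this utility is
    the deliberate escape hatch.  Positions are interpolated linearly; the
    flash channel uses previous-sample hold so it stays binary.
    """
    if fs is None:
        fs = series.fs
    n = int(np.floor((series.t[-1] - series.t[0]) * fs)) + 1
    t_new = series.t[0] + np.arange(n) / fs
    x = np.interp(t_new, series.t, series.x)
    y = np.interp(t_new, series.t, series.y)
    z = np.interp(t_new, series.t, series.z)
    idx = np.searchsorted(series.t, t_new, side="right") - 1
    flash = series.flash[np.clip(idx, 0, len(series) - 1)]
    return KinematicSeries(t=t_new, x=x, y=y, z=z, flash=flash, fs=fs)
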