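"""Core data types for dynamic myocardial perfusion studies.

A dynamic SPECT flow study is represented here as a set of frame-averaged
time-activity curves (TACs): one for the left-ventricular blood pool (the
arterial input function), one per myocardial segment of the standard AHA
17-segment model, and optionally one extracardiac (hepatic/bowel) curve.
Activity values are relative concentration units — both kinetic models in
:mod:`mfrkit.kinetics` depend only on the blood/myocardium ratio, so no
absolute Bq/ml calibration is carried.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "RegionTAC",
    "SegmentScheme",
    "DynamicStudy",
    "PatientStudyPair",
    "SEGMENT_IDS",
    "default_frame_schedule",
    "frame_average",
    "aha17_scheme",
    "read_tac_csv",
    "write_tac_csv",
]

SEGMENT_IDS: tuple[str, ...] = tuple(f"seg{i:02d}" for i in range(1, 18))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames (seconds)."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.shape != durations.shape or starts.ndim != 1:
            raise ValueError("starts and durations must be equal-length 1-D arrays")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be strictly positive")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + 0.5 * self.durations

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.starts.shape == other.starts.shape
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.durations, other.durations)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.starts.tobytes(), self.durations.tobytes()))


def default_frame_schedule() -> FrameSchedule:
    """The 23-frame dynamic binning: 15 x 6 s, 4 x 30 s, 4 x 60 s (450 s total)."""
    durations = np.concatenate([np.full(15, 6.0), np.full(4, 30.0), np.full(4, 60.0)])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts=starts, durations=durations)


@dataclass(frozen=True)
class RegionTAC:
    """Frame-averaged activity concentration for one region."""

    region_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("TAC values must be a 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"TAC '{self.region_id}' contains non-finite values")


@dataclass(frozen=True)
class SegmentScheme:
    """AHA 17-segment labels with vascular-territory assignment and mass weights."""

    segment_ids: tuple[str, ...]
    territory_of: dict[str, str]
    weight_of: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.segment_ids) != 17:
            raise ValueError("scheme must have exactly 17 segments")
        if set(self.territory_of) != set(self.segment_ids):
            raise ValueError("territory map must cover exactly the segment set")
        if set(self.weight_of) != set(self.segment_ids):
            raise ValueError("weight map must cover exactly the segment set")
        w = np.array([self.weight_of[s] for s in self.segment_ids])
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")

    @property
    def territories(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.territory_of.values()))

    def segments_in(self, territory: str) -> tuple[str, ...]:
        return tuple(s for s in self.segment_ids if self.territory_of[s] == territory)


# Standard AHA territory assignment: LAD gets the anterior/anteroseptal wall and
# apex, LCx the lateral wall, RCA the inferior/inferoseptal wall.
_AHA_TERRITORY = {
    "LAD": (1, 2, 7, 8, 13, 14, 17),
    "LCx": (5, 6, 11, 12, 16),
    "RCA": (3, 4, 9, 10, 15),
}


def aha17_scheme(weights: dict[str, float] | None = None) -> SegmentScheme:
    """Standard AHA 17-segment scheme with LAD/LCx/RCA territories.

    Parameters
    ----------
    weights
        Optional per-segment relative mass weights; defaults to uniform 1/17.
    """
    territory_of = {
        f"seg{i:02d}": terr for terr, idxs in _AHA_TERRITORY.items() for i in idxs
    }
    if weights is None:
        weights = {s: 1.0 / 17.0 for s in SEGMENT_IDS}
    return SegmentScheme(
        segment_ids=SEGMENT_IDS, territory_of=territory_of, weight_of=weights
    )


@dataclass(frozen=True)
class DynamicStudy:
    """One dynamic acquisition: blood pool plus 17 segmental TACs."""

    condition: str  # "rest" | "stress"
    schedule: FrameSchedule
    blood: RegionTAC
    segments: dict[str, RegionTAC]
    extracardiac: RegionTAC | None = None
    truth: object | None = None  # KineticTruth when simulated
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in ("rest", "stress"):
            raise ValueError("condition must be 'rest' or 'stress'")
        n = self.schedule.n_frames
        if self.blood.values.size != n:
            raise ValueError("blood TAC length does not match the schedule")
        if tuple(self.segments) != SEGMENT_IDS:
            raise ValueError("segments must be seg01..seg17 in order")
        for tac in self.segments.values():
            if tac.values.size != n:
                raise ValueError(f"TAC '{tac.region_id}' length mismatch")
        if self.extracardiac is not None and self.extracardiac.values.size != n:
            raise ValueError("extracardiac TAC length mismatch")

    def segment_matrix(self) -> np.ndarray:
        """Segment TACs stacked as a (17, n_frames) array in seg01..seg17 order."""
        return np.vstack([self.segments[s].values for s in SEGMENT_IDS])

    def with_segments(self, matrix: np.ndarray) -> "DynamicStudy":
        """Copy of the study with segment TACs replaced from a (17, n) array."""
        segs = {
            s: RegionTAC(s, np.asarray(matrix[i], dtype=float))
            for i, s in enumerate(SEGMENT_IDS)
        }
        return replace(self, segments=segs)


@dataclass(frozen=True)
class PatientStudyPair:
    """Rest and stress studies of one patient on a common schedule."""

    rest: DynamicStudy
    stress: DynamicStudy
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.rest.condition != "rest" or self.stress.condition != "stress":
            raise ValueError("pair must hold one rest and one stress study")
        if self.rest.schedule != self.stress.schedule:
            raise ValueError("rest and stress schedules must be identical")


def frame_average(
    fine_times: np.ndarray, fine_values: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Bin a continuous curve onto acquisition frames.

    Returns, per frame, the time-average of the curve over [start, end) by
    trapezoidal integration divided by the frame duration.  The fine grid must
    cover the whole schedule with step <= 0.5 s.
    """
    t = np.asarray(fine_times, dtype=float)
    v = np.asarray(fine_values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("fine grid and values must be matching 1-D arrays")
    if t[0] > schedule.starts[0] + 1e-9 or t[-1] < schedule.ends[-1] - 1e-9:
        raise ValueError("fine grid does not cover the frame schedule")
    if np.max(np.diff(t)) > 0.5 + 1e-12:
        raise ValueError("fine grid step must be <= 0.5 s")

    # cumulative trapezoid integral, then interpolate at frame boundaries
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    lo = np.interp(schedule.starts, t, cum)
    hi = np.interp(schedule.ends, t, cum)
    return (hi - lo) / schedule.durations


# ---------------------------------------------------------------------------
# CSV interchange
#
# Dialect: '#'-prefixed metadata lines, then a header row
#   frame,t_start_s,duration_s,blood,seg01,...,seg17[,extracardiac]
# one row per frame in time order; decimal point, comma separator, UTF-8.
# ---------------------------------------------------------------------------

_META_KEYS = ("condition", "patient_id", "schedule_sha1")


def _schedule_hash(schedule: FrameSchedule) -> str:
    h = hashlib.sha1()
    h.update(schedule.starts.tobytes())
    h.update(schedule.durations.tobytes())
    return h.hexdigest()[:12]


def write_tac_csv(study: DynamicStudy, path) -> None:
    """Write a study in the TAC CSV dialect (deterministic column order)."""
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(1, study.schedule.n_frames + 1),
        "t_start_s": study.schedule.starts,
        "duration_s": study.schedule.durations,
        "blood": study.blood.values,
    }
    for s in SEGMENT_IDS:
        cols[s] = study.segments[s].values
    if study.extracardiac is not None:
        cols["extracardiac"] = study.extracardiac.values
    df = pd.DataFrame(cols)
    buf = io.StringIO()
    buf.write(f"# condition={study.condition}\n")
    buf.write(f"# patient_id={study.patient_id}\n")
    buf.write(f"# schedule_sha1={_schedule_hash(study.schedule)}\n")
    df.to_csv(buf, index=False, float_format="%.12g")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_tac_csv(path, schedule: FrameSchedule | None = None) -> DynamicStudy:
    """Read a study from the TAC CSV dialect; validates structure strictly.

    If ``schedule`` is given, the file must match it frame-for-frame.
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    try:
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    except Exception as exc:  # non-numeric cells, ragged rows
        raise ValueError(f"cannot parse TAC CSV {path}: {exc}") from exc

    for col in ("frame", "t_start_s", "duration_s", "blood"):
        if col not in df.columns:
            raise ValueError(f"TAC CSV {path} lacks required column '{col}'")
    missing = [s for s in SEGMENT_IDS if s not in df.columns]
    if missing:
        raise ValueError(f"TAC CSV {path} lacks segment columns {missing}")
    for col in df.columns:
        if col == "frame":
            continue
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda x: isinstance(x, (int, float)))].index
            row = int(bad[0]) + 1 if len(bad) else "?"
            raise ValueError(f"non-numeric cell in column '{col}', data row {row}")
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 1
            raise ValueError(f"missing value in column '{col}', data row {row}")

    file_schedule = FrameSchedule(
        starts=df["t_start_s"].to_numpy(), durations=df["duration_s"].to_numpy()
    )
    if schedule is not None:
        if file_schedule.n_frames != schedule.n_frames:
            raise ValueError(
                f"TAC CSV {path} has {file_schedule.n_frames} frames, "
                f"expected {schedule.n_frames}"
            )
        if file_schedule != schedule:
            raise ValueError(f"TAC CSV {path} frame times differ from the schedule")
    schedule = file_schedule
    condition = meta.get("condition", "rest")
    segments = {s: RegionTAC(s, df[s].to_numpy()) for s in SEGMENT_IDS}
    extracardiac = (
        RegionTAC("extracardiac", df["extracardiac"].to_numpy())
        if "extracardiac" in df.columns
        else None
    )
    return DynamicStudy(
        condition=condition,
        schedule=schedule,
        blood=RegionTAC("blood", df["blood"].to_numpy()),
        segments=segments,
        extracardiac=extracardiac,
        patient_id=meta.get("patient_id", ""),
    )
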