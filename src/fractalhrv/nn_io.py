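"""Reading, cleaning and labelling of NN-interval (normal-to-normal RR) records.

An NN series is the sequence of intervals between consecutive normal
heartbeats extracted from an ambulatory ECG, here handled as a beat-indexed
record: beat times in seconds from record start, interval lengths in
milliseconds, and a per-beat label (``normal``, ``ectopic`` or ``artifact``).
Holter devices quantize intervals — 8 ms at a 125-Hz sampling rate — so the
series carries its quantization step.

Two plain-text file dialects are supported: ``nn`` (one interval in ms per
line, beat times accumulated) and ``t_nn`` (comma-separated
``beat_time_s,nn_ms[,label]``).  Sleep/wake spans come from a diary CSV of
clock times, optionally refined by a change-point search on the NN level
(sleep lengthens NN intervals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SESSIONS = ("Pre", "F01", "F02", "F03", "Post")

NORMAL = "normal"
ECTOPIC = "ectopic"
ARTIFACT = "artifact"

#: hard physiological bounds for an acceptable NN interval, ms
DEFAULT_BOUNDS_MS = (300.0, 2000.0)
#: maximum relative change versus the previous accepted beat
DEFAULT_MAX_REL_CHANGE = 0.2
#: records losing more than this fraction of beats are considered unanalyzable
MAX_EXCLUDED_FRACTION = 0.2

MAX_RECORD_DURATION_S = 26 * 3600.0


class ParseError(ValueError):
    """Malformed RR or diary file."""


class ValidationError(ValueError):
    """Series violates a contract (non-positive interval, bad ordering, ...)."""


class UnanalyzableRecordError(ValueError):
    """Too many beats were excluded for the record to be trusted."""


@dataclass
class NNSeries:
    """A beat-indexed NN-interval record.

    ``beat_times`` are seconds from record start (strictly increasing);
    ``nn_ms`` is the interval ending at each beat.  ``start_clock_h`` is the
    clock time (hours, 0-24) of record start, used to anchor diary entries.
    """

    subject_id: str
    session_id: str
    beat_times: np.ndarray
    nn_ms: np.ndarray
    beat_labels: np.ndarray = None  # type: ignore[assignment]
    quantization_ms: float = 8.0
    start_clock_h: float = 7.0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        if self.beat_labels is None:
            self.beat_labels = np.full(self.nn_ms.size, NORMAL, dtype=object)
        else:
            self.beat_labels = np.asarray(self.beat_labels, dtype=object)
        if self.beat_times.shape != self.nn_ms.shape:
            raise ValidationError("beat_times and nn_ms must have equal length")

    @property
    def n_beats(self) -> int:
        return int(self.nn_ms.size)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0]) if self.n_beats else 0.0

    def normal_mask(self) -> np.ndarray:
        return self.beat_labels == NORMAL

    def validate(self, cleaned: bool = False) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        if self.n_beats == 0:
            raise ValidationError("empty series")
        if np.any(self.nn_ms <= 0):
            raise ValidationError("non-positive NN interval")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat times not strictly increasing")
        if self.duration_s > MAX_RECORD_DURATION_S:
            raise ValidationError("record longer than 26 h")
        if cleaned:
            lo, hi = DEFAULT_BOUNDS_MS
            nn = self.nn_ms[self.normal_mask()]
            if nn.size and (nn.min() < lo or nn.max() > hi):
                raise ValidationError("cleaned series has NN outside [300, 2000] ms")


@dataclass
class SpanLabels:
    """Sleep/wake partition of a record.

    ``sleep_intervals_s`` are (onset, offset) pairs in seconds from record
    start, non-overlapping.  ``wake_reference_s`` — the end of the main sleep
    interval, i.e. the time of arising — serves as circadian phase zero.
    """

    sleep_intervals_s: list[tuple[float, float]]
    wake_reference_s: float
    record_duration_s: float

    def __post_init__(self) -> None:
        iv = sorted((float(a), float(b)) for a, b in self.sleep_intervals_s)
        for (a1, b1), (a2, _) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValidationError("overlapping sleep intervals")
        total = sum(b - a for a, b in iv)
        if iv and not (0.0 < total < 24 * 3600.0):
            raise ValidationError("total sleep duration outside (0, 24) h")
        self.sleep_intervals_s = iv

    @property
    def total_sleep_h(self) -> float:
        return sum(b - a for a, b in self.sleep_intervals_s) / 3600.0

    def label_times(self, times_s: np.ndarray) -> np.ndarray:
        """Label each time as ``asleep`` or ``awake`` (exactly one label each)."""
        t = np.asarray(times_s, dtype=float)
        asleep = np.zeros(t.shape, dtype=bool)
        for a, b in self.sleep_intervals_s:
            asleep |= (t >= a) & (t < b)
        return np.where(asleep, "asleep", "awake").astype(object)


@dataclass
class ExclusionReport:
    n_total: int
    n_out_of_bounds: int
    n_rel_change: int

    @property
    def n_excluded(self) -> int:
        return self.n_out_of_bounds + self.n_rel_change

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# Reading / writing RR files
# ---------------------------------------------------------------------------

def read_rr(
    path: str | Path,
    dialect: str = "auto",
    subject_id: str = "unknown",
    session_id: str = "unknown",
    quantization_ms: float = 8.0,
    start_clock_h: float = 7.0,
) -> NNSeries:
    """Read an RR file in the ``nn`` or ``t_nn`` dialect.

    ``nn``: one NN value (ms) per line; beat times are the cumulative sum of
    the intervals, the first beat falling one interval after time zero.
    ``t_nn``: ``beat_time_s,nn_ms[,label]`` per row.  A single non-numeric
    first line is treated as a header.  ``auto`` sniffs commas.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if rows and not _numeric_lead(rows[0][1]):
        rows = rows[1:]  # header
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if dialect == "auto":
        dialect = "t_nn" if "," in rows[0][1] else "nn"

    times, nn, labels = [], [], []
    for lineno, ln in rows:
        parts = [p.strip() for p in ln.split(",")]
        try:
            if dialect == "nn":
                if len(parts) != 1:
                    raise ValueError("expected a single NN value")
                nn.append(float(parts[0]))
            else:
                if len(parts) < 2:
                    raise ValueError("expected beat_time_s,nn_ms")
                times.append(float(parts[0]))
                nn.append(float(parts[1]))
                labels.append(parts[2] if len(parts) > 2 else NORMAL)
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc

    nn_arr = np.asarray(nn, dtype=float)
    if np.any(nn_arr <= 0):
        bad = int(np.flatnonzero(nn_arr <= 0)[0])
        raise ValidationError(f"{path}: non-positive NN interval at data row {bad + 1}")
    if dialect == "nn":
        times_arr = np.cumsum(nn_arr) / 1000.0
        labels_arr = None
    else:
        times_arr = np.asarray(times, dtype=float)
        labels_arr = np.asarray(labels, dtype=object)
    series = NNSeries(
        subject_id=subject_id,
        session_id=session_id,
        beat_times=times_arr,
        nn_ms=nn_arr,
        beat_labels=labels_arr,
        quantization_ms=quantization_ms,
        start_clock_h=start_clock_h,
    )
    series.validate()
    return series


def write_rr(series: NNSeries, path: str | Path, dialect: str = "t_nn") -> None:
    """Write an RR file; ``t_nn`` keeps beat times and labels exactly."""
    path = Path(path)
    with path.open("w") as fh:
        if dialect == "nn":
            fh.write("nn_ms\n")
            for v in series.nn_ms:
                fh.write(f"{v:.6g}\n")
        elif dialect == "t_nn":
            fh.write("beat_time_s,nn_ms,label\n")
            for t, v, lab in zip(series.beat_times, series.nn_ms, series.beat_labels):
                fh.write(f"{float(t)!r},{float(v)!r},{lab}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Beat cleaning
# ---------------------------------------------------------------------------

def filter_normal_beats(
    series: NNSeries,
    max_rel_change: float = DEFAULT_MAX_REL_CHANGE,
    bounds_ms: tuple[float, float] = DEFAULT_BOUNDS_MS,
    force: bool = False,
) -> tuple[NNSeries, ExclusionReport]:
    """Exclude artifacts and ectopy by interval rules.

    A beat is excluded when its NN lies outside ``bounds_ms`` (labelled
    ``artifact``) or differs from the previous *accepted* NN by more than
    ``max_rel_change`` (labelled ``ectopic``).  Excluded beats are removed —
    not interpolated — and remaining beat times are kept, so gaps stay
    visible to the resampler.  Idempotent: survivors already satisfy both
    rules relative to their accepted predecessor.

    Raises :class:`UnanalyzableRecordError` when more than 20% of beats are
    excluded, unless ``force`` is set.
    """
    if not (0.0 < max_rel_change <= 1.0):
        raise ValueError("max_rel_change must be in (0, 1]")
    lo, hi = bounds_ms
    if not (0.0 < lo < hi < 5000.0):
        raise ValueError("bounds_ms must lie within (0, 5000) ms")

    nn = series.nn_ms
    keep = np.ones(series.n_beats, dtype=bool)
    labels = series.beat_labels.copy()
    n_bounds = n_rel = 0
    prev_accepted = None
    for i, v in enumerate(nn):
        if not (lo <= v <= hi):
            keep[i] = False
            labels[i] = ARTIFACT
            n_bounds += 1
            continue
        if prev_accepted is not None and abs(v - prev_accepted) / prev_accepted > max_rel_change:
            keep[i] = False
            labels[i] = ECTOPIC
            n_rel += 1
            continue
        prev_accepted = v

    report = ExclusionReport(series.n_beats, n_bounds, n_rel)
    if report.fraction_excluded > MAX_EXCLUDED_FRACTION and not force:
        raise UnanalyzableRecordError(
            f"{series.subject_id}/{series.session_id}: "
            f"{report.fraction_excluded:.1%} of beats excluded (> {MAX_EXCLUDED_FRACTION:.0%})"
        )
    cleaned = replace(
        series,
        beat_times=series.beat_times[keep],
        nn_ms=nn[keep],
        beat_labels=labels[keep],
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# Sleep/wake labelling
# ---------------------------------------------------------------------------

def clock_to_seconds(clock_h: float, start_clock_h: float) -> float:
    """Clock time (hours) -> seconds from record start, wrapping midnight."""
    return ((clock_h - start_clock_h) % 24.0) * 3600.0


def label_sleep_wake(
    series: NNSeries,
    diary: Sequence[tuple[float, float]] | None,
    auto_detect: bool = False,
    diary_in_clock_hours: bool = True,
) -> SpanLabels:
    """Build the sleep/wake partition from a diary, optionally refined.

    ``diary`` holds (onset, offset) pairs, as clock hours by default or as
    seconds from record start.  With ``auto_detect`` each diary boundary is
    shifted up to ±30 min to the strongest sustained NN-level change-point
    (sleep onset: NN lengthening; arising: NN shortening), computed from
    15-min running medians on a 5-min grid.  The wake reference (circadian
    phase zero) is the offset of the longest sleep interval.
    """
    if not diary:
        raise ValidationError("empty diary: sleep/wake labels are required")
    intervals: list[tuple[float, float]] = []
    for onset, offset in diary:
        if diary_in_clock_hours:
            a = clock_to_seconds(onset, series.start_clock_h)
            b = clock_to_seconds(offset, series.start_clock_h)
            if b <= a:
                b += 24 * 3600.0
        else:
            a, b = float(onset), float(offset)
        intervals.append((a, b))

    if auto_detect:
        intervals = [
            (
                _refine_boundary(series, a, direction=+1),
                _refine_boundary(series, b, direction=-1),
            )
            for a, b in intervals
        ]

    main = max(intervals, key=lambda iv: iv[1] - iv[0])
    return SpanLabels(
        sleep_intervals_s=intervals,
        wake_reference_s=main[1],
        record_duration_s=series.duration_s,
    )


def _refine_boundary(series: NNSeries, t0: float, direction: int, search_s: float = 1800.0) -> float:
    """Move a diary boundary to the largest sustained NN level shift.

    ``direction`` +1 expects NN to lengthen across the boundary (sleep
    onset), −1 to shorten (arising).  Candidates on a 5-min grid within
    ±``search_s``; the level on each side is the mean of 15-min running
    medians over the adjacent 30 min, so only sustained shifts score.
    """
    step, half_med, flank = 300.0, 450.0, 1800.0
    grid = np.arange(series.beat_times[0], series.beat_times[-1], step)
    med = np.array([
        np.median(series.nn_ms[(series.beat_times >= g - half_med) & (series.beat_times < g + half_med)])
        if np.any((series.beat_times >= g - half_med) & (series.beat_times < g + half_med))
        else np.nan
        for g in grid
    ])
    cands = grid[(grid >= t0 - search_s) & (grid <= t0 + search_s)]
    best_t, best_score = t0, 0.0
    for c in cands:
        before = med[(grid >= c - flank) & (grid < c)]
        after = med[(grid >= c) & (grid < c + flank)]
        if before.size < 3 or after.size < 3:
            continue
        score = direction * (np.nanmean(after) - np.nanmean(before))
        if score > best_score:
            best_t, best_score = float(c), float(score)
    return best_t


def read_diary(path: str | Path) -> pd.DataFrame:
    """Diary CSV: subject_id,session_id,sleep_onset,sleep_offset (ISO clock times)."""
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "session_id", "sleep_onset", "sleep_offset"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: diary missing columns {sorted(missing)}")
    for col in ("sleep_onset", "sleep_offset"):
        df[col + "_h"] = df[col].map(_parse_clock)
    return df


def _parse_clock(s: str) -> float:
    try:
        parts = [float(p) for p in str(s).strip().split(":")]
    except ValueError as exc:
        raise ParseError(f"bad clock time {s!r}") from exc
    while len(parts) < 3:
        parts.append(0.0)
    h, m, sec = parts[:3]
    return h + m / 60.0 + sec / 3600.0


def _json_native(obj):
    """Numpy scalars -> python scalars so JSON and CSV print identical reprs."""
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return str(obj)


def _numeric_lead(line: str) -> bool:
    tok = line.split(",")[0].strip()
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(
    tables: dict[str, pd.DataFrame],
    outdir: str | Path,
    formats: Iterable[str] = ("csv", "json"),
) -> list[Path]:
    """Write each result table as CSV and/or JSON with a deterministic layout.

    JSON and CSV encode identical numbers: both go through Python ``repr``
    of the float values (pandas' default float formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        df = df.reset_index(drop=True)
        if "csv" in formats:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        if "json" in formats:
            p = outdir / f"{name}.json"
            with p.open("w") as fh:
                json.dump(df.to_dict(orient="records"), fh, indent=1, default=_json_native)
            written.append(p)
    return written
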