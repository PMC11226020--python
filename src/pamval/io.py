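"""Reading, writing and filtering of classifier detection tables.

The canonical in-memory container for detections is a :class:`pandas.DataFrame`
with the columns in :data:`DETECTION_COLUMNS`.  Two on-disk dialects are
accepted:

* a *per-recording* tab-delimited result table as emitted by the
  BirdNET-Analyzer GUI, with columns ``Start (s)``, ``End (s)``,
  ``Scientific name``, ``Common name`` and ``Confidence`` — the caller supplies
  the site and the recording's start datetime;
* a *combined* long table (the package's canonical interchange format) that
  additionally carries ``site_id``, ``recording_id`` and ``recording_start``
  columns, so one file can hold a whole deployment.

Detections are 3-s classifier windows; the absolute time of a detection is
``recording_start + segment_start_s`` and is materialised in the ``start_time``
column on read.
"""

from __future__ import annotations

import os
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, MappingError, ValidationError

#: Columns of the canonical detection frame (``start_time`` is derived).
DETECTION_COLUMNS = [
    "site_id",
    "recording_id",
    "recording_start",
    "segment_start_s",
    "segment_end_s",
    "scientific_name",
    "common_name",
    "confidence",
    "start_time",
]

#: Header names of the per-recording classifier output dialect.
BIRDNET_COLUMNS = {
    "Start (s)": "segment_start_s",
    "End (s)": "segment_end_s",
    "Scientific name": "scientific_name",
    "Common name": "common_name",
    "Confidence": "confidence",
}

_COMBINED_EXTRA = ["site_id", "recording_id", "recording_start"]

#: Length of one classifier prediction window, seconds.
SEGMENT_LENGTH_S = 3.0

#: The classifier run's default minimum confidence.
DEFAULT_MIN_CONFIDENCE = 0.10


def _finalize(df: pd.DataFrame, on_bad_rows: str) -> pd.DataFrame:
    """Validate confidences, compute absolute timestamps, order columns."""
    df = df.copy()
    df["segment_start_s"] = df["segment_start_s"].astype(float)
    df["segment_end_s"] = df["segment_end_s"].astype(float)
    df["confidence"] = df["confidence"].astype(float)
    bad = ~df["confidence"].between(0.0, 1.0) | df["confidence"].isna()
    if bad.any():
        rows = df.index[bad].tolist()
        if on_bad_rows == "raise":
            raise ValidationError(
                f"confidence outside [0, 1] at row(s) {rows[:10]}"
                + ("..." if len(rows) > 10 else "")
            )
        df = df.loc[~bad]
    df["recording_start"] = pd.to_datetime(df["recording_start"])
    df["start_time"] = df["recording_start"] + pd.to_timedelta(
        df["segment_start_s"], unit="s"
    )
    return df[DETECTION_COLUMNS].reset_index(drop=True)


def read_detection_table(
    path: str | os.PathLike,
    site_id: str | None = None,
    recording_start=None,
    recording_id: str | None = None,
    on_bad_rows: str = "raise",
) -> pd.DataFrame:
    """Read a tab-delimited detection table into the canonical frame.

    The dialect is sniffed from the header: a file carrying ``site_id``/
    ``recording_id``/``recording_start`` columns is treated as a combined
    table; otherwise it is a per-recording result table and ``site_id`` and
    ``recording_start`` must be given (``recording_id`` defaults to the file's
    base name).

    Parameters
    ----------
    path
        Tab-delimited file to read.
    site_id, recording_start, recording_id
        Provenance for the per-recording dialect; ignored for combined tables.
    on_bad_rows
        ``"raise"`` (default) fails on the first invalid confidence;
        ``"skip"`` drops invalid rows.  Silent row loss biases richness, so
        skipping is opt-in.

    Returns
    -------
    pandas.DataFrame
        One row per detection, file order preserved, with absolute
        ``start_time`` resolved.
    """
    if on_bad_rows not in ("raise", "skip"):
        raise ValueError("on_bad_rows must be 'raise' or 'skip'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in BIRDNET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=BIRDNET_COLUMNS)
    combined = all(c in df.columns for c in _COMBINED_EXTRA)
    if not combined:
        if site_id is None or recording_start is None:
            raise FormatError(
                "per-recording table: site_id and recording_start are required"
            )
        df["site_id"] = site_id
        df["recording_id"] = (
            recording_id
            if recording_id is not None
            else os.path.splitext(os.path.basename(os.fspath(path)))[0]
        )
        df["recording_start"] = pd.Timestamp(recording_start)
    return _finalize(df, on_bad_rows)


def write_detection_table(detections: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write detections as a combined tab-delimited table.

    Emits the same dialect :func:`read_detection_table` accepts;
    ``read(write(df))`` is the identity on all detection fields.  Confidences
    are printed with full precision (well beyond 4 significant digits).
    """
    df = detections.copy()
    out = pd.DataFrame(
        {
            "site_id": df["site_id"],
            "recording_id": df["recording_id"],
            "recording_start": pd.to_datetime(df["recording_start"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "Start (s)": df["segment_start_s"],
            "End (s)": df["segment_end_s"],
            "Scientific name": df["scientific_name"],
            "Common name": df["common_name"],
            "Confidence": [repr(float(c)) for c in df["confidence"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def filter_by_confidence(detections: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain detections with ``confidence >= threshold`` (inclusive), order kept."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold!r} outside [0, 1]")
    return detections.loc[detections["confidence"] >= threshold].copy()


def filter_by_ssc(
    detections: pd.DataFrame,
    ssc_map: Mapping[str, float],
    default: float | None = None,
) -> pd.DataFrame:
    """Retain each detection iff its confidence meets its species' SSC threshold.

    ``ssc_map`` maps scientific name to a per-species threshold.  Species absent
    from the map raise :class:`~pamval.errors.MappingError` unless ``default``
    supplies a fallback threshold.
    """
    species = detections["scientific_name"]
    unknown = sorted(set(species) - set(ssc_map))
    if unknown and default is None:
        raise MappingError(f"no SSC threshold for species: {', '.join(unknown)}")
    thresholds = species.map(lambda s: ssc_map.get(s, default)).astype(float)
    if ((thresholds < 0) | (thresholds > 1)).any():
        raise ValidationError("SSC thresholds must lie in [0, 1]")
    return detections.loc[detections["confidence"].to_numpy() >= thresholds.to_numpy()].copy()


def read_point_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read point-count observations from CSV.

    Required columns: ``site_id``, ``visit_start`` (ISO 8601), ``species``;
    optional: ``behavior``, ``distance_m``, ``sex``.
    """
    df = pd.read_csv(path)
    required = ["site_id", "visit_start", "species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df["visit_start"] = pd.to_datetime(df["visit_start"])
    return df


def read_schedule(path: str | os.PathLike) -> pd.DataFrame:
    """Read a recording schedule from CSV.

    Required columns: ``recording_id``, ``site_id``, ``start`` (ISO 8601),
    ``duration_s``.  Overlapping recordings at one site violate the schedule
    invariant and raise :class:`~pamval.errors.ValidationError`.
    """
    df = pd.read_csv(path)
    required = ["recording_id", "site_id", "start", "duration_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df["start"] = pd.to_datetime(df["start"])
    df["duration_s"] = df["duration_s"].astype(float)
    if (df["duration_s"] <= 0).any():
        raise ValidationError("recording duration_s must be > 0")
    check_schedule_nonoverlap(df)
    return df


def check_schedule_nonoverlap(schedule: pd.DataFrame) -> None:
    """Raise if any two recordings of one site overlap in time."""
    for site, grp in schedule.groupby("site_id"):
        g = grp.sort_values("start")
        ends = g["start"] + pd.to_timedelta(g["duration_s"], unit="s")
        if (g["start"].iloc[1:].to_numpy() < ends.iloc[:-1].to_numpy()).any():
            raise ValidationError(f"overlapping recordings at site {site!r}")


def read_visits(path: str | os.PathLike) -> pd.DataFrame:
    """Read survey visits from CSV (``site_id``, ``visit_start``, ``duration_min``)."""
    df = pd.read_csv(path)
    required = ["site_id", "visit_start"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df["visit_start"] = pd.to_datetime(df["visit_start"])
    if "duration_min" not in df.columns:
        df["duration_min"] = 10.0
    if df.duplicated(["site_id", "visit_start"]).any():
        raise ValidationError("duplicate (site_id, visit_start) visit")
    return df


def detection_times_within_recordings(
    detections: pd.DataFrame, schedule: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: detection lies inside its recording's [start, start+duration]."""
    sched = schedule.set_index("recording_id")
    starts = detections["recording_id"].map(sched["start"])
    durs = detections["recording_id"].map(sched["duration_s"])
    t = pd.to_datetime(detections["start_time"])
    lo = t >= starts
    hi = (t + pd.to_timedelta(SEGMENT_LENGTH_S, unit="s")) <= starts + pd.to_timedelta(
        durs, unit="s"
    )
    return (lo & hi).to_numpy()
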