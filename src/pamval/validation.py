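"""Classifier-performance evaluation for acoustic bird detections.

Implements the validation workflow used to benchmark an automated acoustic
classifier against expert annotation:

* draw a reproducible random sample of detections per species at two
  confidence strata (the classifier default of 0.10 and a filtered 0.25) and
  emit 5-s review-clip coordinates for each;
* precision = TP / (TP + FP) over the annotated sample;
* the maximum confidence observed among annotated false positives,
  an empirical upper bound used as a conservative per-species threshold;
* segment-level recall over random 120-s clips: TP = clips with both a manual
  and a classifier detection of the species, FN = clips with a manual
  detection only, recall = TP / (TP + FN);
* F-score = harmonic mean of precision (default stratum) and recall;
* the species-specific confidence (SSC) threshold decision rule:

  ========================================  ==========================
  precision estimate                        SSC threshold
  ========================================  ==========================
  P_C10 >= 0.85                             0.10 (no extra filter)
  P_C10 < 0.85 and P_C25 >= 0.85            0.25
  P_C10 < 0.85 and P_C25 < 0.85             max false-positive confidence
  ========================================  ==========================

All metrics are stored at full precision; presentation rounds to 3 decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import EmptyPoolError, SSCAssignmentError, UndefinedMetricError
from .io import DEFAULT_MIN_CONFIDENCE, SEGMENT_LENGTH_S

#: Confidence strata at which precision is validated.
STRATA = {"c10": 0.10, "c25": 0.25}

#: Seconds of context added on each side of a detection for review clips.
CLIP_PAD_S = 1.0

TRUE_POSITIVE = "true_positive"
FALSE_POSITIVE = "false_positive"


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (presentation convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


@dataclass
class ValidationSample:
    """A reproducible random sample of one species' detections at one stratum."""

    species: str
    stratum: str
    threshold: float
    seed: int
    detections: pd.DataFrame
    clip_windows: pd.DataFrame
    shortfall: bool = False


@dataclass
class SegmentSample:
    """Random fixed-length segments drawn from the pooled recording time."""

    segments: pd.DataFrame  # segment_id, recording_id, start_s, end_s
    length_s: float
    seed: int


@dataclass
class SegmentAnnotation:
    """Per-segment species sets: expert-heard vs classifier-detected."""

    segment_id: object
    manual_species: frozenset = field(default_factory=frozenset)
    classifier_species: frozenset = field(default_factory=frozenset)


def sample_for_validation(
    detections: pd.DataFrame,
    species: str,
    stratum: str = "c10",
    n: int = 60,
    seed: int = 0,
    recordings: pd.DataFrame | None = None,
) -> ValidationSample:
    """Sample ``n`` detections of ``species`` without replacement at a stratum.

    The stratum filter (``confidence >= 0.10`` for ``"c10"``, ``>= 0.25`` for
    ``"c25"``) is applied before sampling.  If the eligible pool is smaller
    than ``n`` the whole pool is returned and a shortfall warning issued.
    Review-clip windows span the 3-s segment plus 1 s of context each side,
    clamped to the recording bounds (the lower bound always, the upper bound
    when ``recordings`` supplies durations).
    """
    threshold = STRATA[stratum] if stratum in STRATA else float(stratum)
    pool = detections.loc[
        (detections["scientific_name"] == species)
        & (detections["confidence"] >= threshold)
    ]
    if len(pool) == 0:
        raise EmptyPoolError(
            f"no eligible detections of {species!r} at threshold {threshold}"
        )
    shortfall = len(pool) < n
    if shortfall:
        warnings.warn(
            f"{species}: eligible pool ({len(pool)}) smaller than requested "
            f"sample size ({n}); returning the full pool",
            stacklevel=2,
        )
        chosen = pool
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen = pool.iloc[np.sort(idx)]
    chosen = chosen.reset_index(drop=True)
    clip_start = (chosen["segment_start_s"] - CLIP_PAD_S).clip(lower=0.0)
    clip_end = chosen["segment_end_s"] + CLIP_PAD_S
    if recordings is not None:
        durs = chosen["recording_id"].map(
            recordings.set_index("recording_id")["duration_s"]
        )
        clip_end = np.minimum(clip_end, durs)
    clips = pd.DataFrame(
        {
            "recording_id": chosen["recording_id"],
            "clip_start_s": clip_start,
            "clip_end_s": clip_end,
            "species": species,
        }
    )
    return ValidationSample(
        species=species,
        stratum=stratum if stratum in STRATA else f"t{threshold}",
        threshold=threshold,
        seed=seed,
        detections=chosen,
        clip_windows=clips,
        shortfall=shortfall,
    )


def compute_precision(annotations: pd.DataFrame) -> float:
    """Fraction of annotated detections labelled true-positive.

    ``annotations`` must carry a ``label`` column with values
    ``"true_positive"`` / ``"false_positive"``; one label per detection.
    """
    if len(annotations) == 0:
        raise UndefinedMetricError("precision undefined for empty annotations")
    labels = annotations["label"]
    bad = set(labels) - {TRUE_POSITIVE, FALSE_POSITIVE}
    if bad:
        raise ValueError(f"unknown annotation label(s): {sorted(bad)}")
    return float((labels == TRUE_POSITIVE).sum() / len(labels))


def compute_max_fp_confidence(annotations: pd.DataFrame) -> float | None:
    """Maximum confidence among false-positive annotations, or None if none.

    Annotations from both validation strata should be pooled before calling,
    since a single per-species value is reported.
    """
    fp = annotations.loc[annotations["label"] == FALSE_POSITIVE, "confidence"]
    if len(fp) == 0:
        return None
    return float(fp.max())


def sample_segments(
    recordings: pd.DataFrame,
    n: int = 50,
    length_s: float = 120.0,
    seed: int = 0,
) -> SegmentSample:
    """Draw ``n`` random ``length_s`` segments uniformly from pooled recording time.

    Each segment lies fully inside one recording.  Segments are drawn
    independently: the probability a segment starts in a given recording is
    proportional to that recording's eligible start-time measure
    ``duration_s - length_s``.  When every recording is exactly ``length_s``
    long the start is forced to 0 and recordings are chosen uniformly.
    """
    elig = recordings.loc[recordings["duration_s"] >= length_s].reset_index(drop=True)
    if len(elig) == 0:
        raise EmptyPoolError(f"no recording is at least {length_s} s long")
    rng = np.random.default_rng(seed)
    slack = (elig["duration_s"] - length_s).to_numpy(float)
    total = slack.sum()
    if total > 0:
        probs = slack / total
        rec_idx = rng.choice(len(elig), size=n, p=probs)
        starts = rng.uniform(0.0, slack[rec_idx])
    else:  # every eligible recording is exactly length_s long
        rec_idx = rng.choice(len(elig), size=n)
        starts = np.zeros(n)
    seg = pd.DataFrame(
        {
            "segment_id": np.arange(n),
            "recording_id": elig["recording_id"].to_numpy()[rec_idx],
            "start_s": starts,
            "end_s": starts + length_s,
        }
    )
    return SegmentSample(segments=seg, length_s=length_s, seed=seed)


def classifier_species_for_segments(
    detections: pd.DataFrame,
    sample: SegmentSample,
    recordings: pd.DataFrame,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> dict[object, frozenset]:
    """Species the classifier detected in each sampled segment.

    A detection belongs to a segment when its 3-s window overlaps the segment
    by any amount and its confidence is at least ``min_confidence``.
    Segment coordinates are seconds from the start of their recording.
    """
    rec_start = recordings.set_index("recording_id")["start"]
    det = detections.loc[detections["confidence"] >= min_confidence]
    offsets = (
        pd.to_datetime(det["start_time"]) - det["recording_id"].map(rec_start)
    ).dt.total_seconds()
    out: dict[object, frozenset] = {}
    for seg in sample.segments.itertuples(index=False):
        mask = (
            (det["recording_id"] == seg.recording_id).to_numpy()
            & (offsets.to_numpy() + SEGMENT_LENGTH_S > seg.start_s)
            & (offsets.to_numpy() < seg.end_s)
        )
        out[seg.segment_id] = frozenset(det.loc[mask, "scientific_name"])
    return out


def compute_recall(
    segment_annotations: list[SegmentAnnotation],
    species: str,
    undetected_missing: bool = False,
) -> float | None:
    """Segment-level recall TP / (TP + FN) for one species.

    TP counts segments with both a manual and a classifier detection of the
    species; FN counts segments with a manual detection only.  Returns None
    (metric undefined) when the species was never manually detected.  With
    ``undetected_missing=True`` the stricter published exclusion is applied:
    the metric is also None when the classifier never detected the species in
    any segment.
    """
    if not segment_annotations:
        raise UndefinedMetricError("recall undefined for empty segment annotations")
    tp = sum(
        1
        for a in segment_annotations
        if species in a.manual_species and species in a.classifier_species
    )
    fn = sum(
        1
        for a in segment_annotations
        if species in a.manual_species and species not in a.classifier_species
    )
    if tp + fn == 0:
        return None
    if undetected_missing and not any(
        species in a.classifier_species for a in segment_annotations
    ):
        return None
    return tp / (tp + fn)


def compute_f_score(precision_c10: float, recall: float | None) -> float | None:
    """Harmonic mean of precision and recall; None propagates from recall."""
    if recall is None or (isinstance(recall, float) and np.isnan(recall)):
        return None
    p, r = float(precision_c10), float(recall)
    for name, v in (("precision", p), ("recall", r)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v!r} outside [0, 1]")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def assign_ssc(
    precision_c10: float,
    precision_c25: float,
    max_fp_confidence: float | None,
    precision_cutoff: float = 0.85,
) -> float:
    """Species-specific confidence threshold from the decision rule.

    0.10 when P_C10 >= cutoff; else 0.25 when P_C25 >= cutoff; else the
    maximum false-positive confidence.  All comparisons are inclusive (>=).
    """
    if precision_c10 >= precision_cutoff:
        return 0.10
    if precision_c25 >= precision_cutoff:
        return 0.25
    if max_fp_confidence is None or (
        isinstance(max_fp_confidence, float) and np.isnan(max_fp_confidence)
    ):
        raise SSCAssignmentError(
            "both precision strata below cutoff but max_fp_confidence is missing"
        )
    return float(max_fp_confidence)


def summarize_performance(
    per_species: pd.DataFrame,
    precision_cutoff: float = 0.85,
    fp_confidence_cutoff: float = 0.50,
) -> tuple[pd.DataFrame, dict]:
    """Build the per-species performance table and its column summaries.

    ``per_species`` needs one row per species with columns ``scientific_name``,
    ``precision_c10``, ``precision_c25``, ``max_fp_confidence`` and optionally
    ``recall`` (NaN/None where undefined).  ``f_score`` and ``ssc`` are
    recomputed from those inputs.  The returned table reports metrics rounded
    to 3 decimals; the summary dict reports per-column mean and range over
    non-missing entries plus the threshold-exceedance counts
    (``precision_c10 > precision_cutoff`` strictly, ``max_fp_confidence <
    fp_confidence_cutoff`` strictly).
    """
    df = per_species.copy().reset_index(drop=True)
    if "recall" not in df.columns:
        df["recall"] = np.nan
    f = [
        compute_f_score(p, (None if pd.isna(r) else r))
        for p, r in zip(df["precision_c10"], df["recall"])
    ]
    df["f_score"] = [np.nan if v is None else v for v in f]
    df["ssc"] = [
        assign_ssc(p10, p25, (None if pd.isna(m) else m), precision_cutoff)
        for p10, p25, m in zip(
            df["precision_c10"], df["precision_c25"], df["max_fp_confidence"]
        )
    ]
    summary: dict = {"n_species": int(len(df))}
    for col in ("precision_c10", "precision_c25", "max_fp_confidence", "recall", "f_score"):
        vals = df[col].dropna()
        summary[col] = {
            "mean": round3(vals.mean()) if len(vals) else None,
            "min": round3(vals.min()) if len(vals) else None,
            "max": round3(vals.max()) if len(vals) else None,
            "n": int(len(vals)),
        }
    summary["n_precision_c10_above_cutoff"] = int(
        (df["precision_c10"] > precision_cutoff).sum()
    )
    summary["n_max_fp_below_cutoff"] = int(
        (df["max_fp_confidence"] < fp_confidence_cutoff).sum()
    )
    table = df.copy()
    for col in ("precision_c10", "precision_c25", "max_fp_confidence", "recall", "f_score", "ssc"):
        table[col] = [np.nan if pd.isna(v) else round3(v) for v in table[col]]
    return table, summary
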