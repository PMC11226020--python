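"""Species richness from filtered detections and from point counts.

Richness is the number of unique species in a defined unit: per paired survey
visit at the *short* duration (only recordings within a configurable window,
default 1 h, of a point-count survey) or per site at the *long* duration
(all recordings across the survey season).  Detections are first filtered to
a confidence threshold — one of the static thresholds or the per-species SSC
map — and optionally intersected with a focal species list.  Accumulation
curves track cumulative unique species by calendar day, and the top-N
confirmation review ranks each species' highest-confidence detections for
manual confirmation of total (focal and non-focal) richness.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import filter_by_confidence, filter_by_ssc

logger = logging.getLogger(__name__)

#: The threshold ladder used for method comparison.
STATIC_THRESHOLDS = (0.1, 0.25, 0.5, 0.75, 0.9)
SSC_LABEL = "SSC"


def apply_threshold(
    detections: pd.DataFrame,
    threshold,
    ssc_map: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Filter detections by a static threshold or the ``"SSC"`` label."""
    if isinstance(threshold, str) and threshold.upper() == SSC_LABEL:
        if ssc_map is None:
            raise ValidationError("threshold label SSC requires an ssc_map")
        return filter_by_ssc(detections, ssc_map)
    return filter_by_confidence(detections, float(threshold))


def pair_surveys_with_recordings(
    visits: pd.DataFrame,
    recordings: pd.DataFrame,
    window_min: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair each survey visit with recordings within the time window.

    A visit is paired with every same-site recording whose interval intersects
    ``[visit_start - window, visit_end + window]``.  Returns ``(pairs,
    exclusions)``: one pair row per (visit, recording), and the visits with no
    qualifying recording.
    """
    window = pd.Timedelta(minutes=window_min)
    rows = []
    excluded = []
    for visit in visits.itertuples(index=False):
        v_start = pd.Timestamp(visit.visit_start)
        v_end = v_start + pd.Timedelta(minutes=getattr(visit, "duration_min", 10.0))
        recs = recordings.loc[recordings["site_id"] == visit.site_id]
        rec_start = recs["start"]
        rec_end = recs["start"] + pd.to_timedelta(recs["duration_s"], unit="s")
        hit = recs.loc[(rec_end >= v_start - window) & (rec_start <= v_end + window)]
        if len(hit) == 0:
            excluded.append({"site_id": visit.site_id, "visit_start": v_start})
            continue
        for rec in hit.itertuples(index=False):
            rows.append(
                {
                    "site_id": visit.site_id,
                    "visit_start": v_start,
                    "recording_id": rec.recording_id,
                }
            )
    pairs = pd.DataFrame(rows, columns=["site_id", "visit_start", "recording_id"])
    exclusions = pd.DataFrame(excluded, columns=["site_id", "visit_start"])
    return pairs, exclusions


def _richness_rows(groups, method, threshold_label, period):
    rows = []
    for keys, species in groups:
        row = dict(keys)
        row.update(
            {
                "method": method,
                "threshold_label": str(threshold_label),
                "period": period,
                "richness": len(species),
                "species_set": frozenset(species),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def short_duration_richness(
    pairs: pd.DataFrame,
    detections: pd.DataFrame,
    threshold,
    focal_species: Iterable[str] | None = None,
    ssc_map: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Unique species per paired visit from its paired recordings.

    One richness record per (site, visit): detections are restricted to the
    recordings paired with that visit, threshold-filtered, and intersected
    with ``focal_species`` when given.  Visits whose paired recordings contain
    no qualifying detection get richness 0.
    """
    det = apply_threshold(detections, threshold, ssc_map)
    if focal_species is not None:
        det = det.loc[det["scientific_name"].isin(set(focal_species))]
    by_rec = det.groupby("recording_id")["scientific_name"].agg(set)
    groups = []
    for (site, vstart), grp in pairs.groupby(["site_id", "visit_start"]):
        species: set = set()
        for rid in grp["recording_id"]:
            species |= by_rec.get(rid, set())
        groups.append(({"site_id": site, "visit_start": vstart}, species))
    return _richness_rows(groups, "aru", threshold, "short")


def long_duration_richness(
    detections: pd.DataFrame,
    period: tuple,
    threshold,
    focal_species: Iterable[str] | None = None,
    ssc_map: Mapping[str, float] | None = None,
    sites: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Unique species per site over an inclusive date period.

    ``period`` is ``(start_date, end_date)``; detections are assigned to days
    by their segment start time.  ``sites`` forces a record (possibly
    richness 0) for every listed site.
    """
    start, end = (pd.Timestamp(period[0]), pd.Timestamp(period[1]))
    if end < start:
        raise ValidationError("empty period: end date before start date")
    det = apply_threshold(detections, threshold, ssc_map)
    if focal_species is not None:
        det = det.loc[det["scientific_name"].isin(set(focal_species))]
    days = pd.to_datetime(det["start_time"]).dt.normalize()
    det = det.loc[(days >= start.normalize()) & (days <= end.normalize())]
    per_site = det.groupby("site_id")["scientific_name"].agg(set).to_dict()
    site_list = sorted(set(sites)) if sites is not None else sorted(per_site)
    groups = [({"site_id": s}, per_site.get(s, set())) for s in site_list]
    return _richness_rows(groups, "aru", threshold, "long")


def point_count_richness(
    observations: pd.DataFrame,
    scope: str = "focal",
    focal_species: Iterable[str] | None = None,
    period: tuple | None = None,
    per: str = "site",
) -> pd.DataFrame:
    """Unique species per site or per visit from point-count observations.

    ``scope="focal"`` restricts to ``focal_species``; ``scope="all"`` keeps
    every species.  ``per`` is ``"site"`` (season total across visits) or
    ``"visit"``.
    """
    obs = observations.copy()
    if period is not None:
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        days = pd.to_datetime(obs["visit_start"]).dt.normalize()
        obs = obs.loc[(days >= start.normalize()) & (days <= end.normalize())]
    if scope == "focal":
        if focal_species is None:
            raise ValidationError("scope='focal' requires focal_species")
        obs = obs.loc[obs["species"].isin(set(focal_species))]
    elif scope != "all":
        raise ValidationError("scope must be 'focal' or 'all'")
    if per == "site":
        keys = ["site_id"]
    elif per == "visit":
        keys = ["site_id", "visit_start"]
    else:
        raise ValidationError("per must be 'site' or 'visit'")
    groups = [
        (dict(zip(keys, k if isinstance(k, tuple) else (k,))), set(g["species"]))
        for k, g in obs.groupby(keys)
    ]
    period_label = "long" if per == "site" else "short"
    return _richness_rows(groups, "point_count", "pc", period_label)


def accumulation_curve(
    events: pd.DataFrame,
    period: tuple,
    species_col: str = "species",
    time_col: str = "time",
    pool: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Cumulative unique-species count per calendar day, union across sites.

    ``events`` needs a species column and a timestamp column.  Day 1 is the
    period start date; bounds are inclusive.  Events outside the period are
    excluded with a log note.  ``pool`` optionally restricts the species
    considered.
    """
    start, end = pd.Timestamp(period[0]).normalize(), pd.Timestamp(period[1]).normalize()
    if end < start:
        raise ValidationError("empty period: end date before start date")
    ev = events[[species_col, time_col]].copy()
    ev["day"] = pd.to_datetime(ev[time_col]).dt.normalize()
    outside = (ev["day"] < start) | (ev["day"] > end)
    if outside.any():
        logger.info("accumulation_curve: excluded %d events outside period", outside.sum())
        ev = ev.loc[~outside]
    if pool is not None:
        ev = ev.loc[ev[species_col].isin(set(pool))]
    first_day = ev.groupby(species_col)["day"].min()
    n_days = (end - start).days + 1
    dates = pd.date_range(start, end, freq="D")
    first_idx = ((first_day - start).dt.days).to_numpy()
    cumulative = np.array(
        [(first_idx <= d).sum() for d in range(n_days)], dtype=int
    )
    return pd.DataFrame(
        {"day_index": np.arange(1, n_days + 1), "date": dates, "cumulative_richness": cumulative}
    )


def top_confidence_review(detections: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Per species, the ``n`` highest-confidence detections ranked for review.

    Ties at the boundary are broken by earlier timestamp, then lexicographic
    recording id, so the review set is deterministic.  Species with fewer than
    ``n`` detections list them all.
    """
    det = detections.sort_values(
        ["scientific_name", "confidence", "start_time", "recording_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    det = det.groupby("scientific_name", sort=True).head(n).copy()
    det["review_rank"] = det.groupby("scientific_name").cumcount() + 1
    return det.reset_index(drop=True)


def confirmed_total_richness(reviews: pd.DataFrame) -> int:
    """Count species with at least one confirmed detection in their review set.

    ``reviews`` is the output of :func:`top_confidence_review` with an added
    boolean ``confirmed`` column (the manual-review outcome per detection).
    """
    if "confirmed" not in reviews.columns:
        raise ValidationError("reviews must carry a boolean 'confirmed' column")
    per_species = reviews.groupby("scientific_name")["confirmed"].any()
    return int(per_species.sum())
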