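"""Synthetic soundscape-classifier data with known ground truth.

No public dataset accompanies the validation workflow, so this module
generates the three input streams the pipeline consumes — classifier
detection tables, recording schedules and point-count records — from an
explicit statistical model, keeping per-detection truth labels so every
metric can be checked against its generating parameters.

Model
-----
* Each site has a habitat; each species is present (occupied) at a site with
  habitat-specific probability ``psi``, drawn once per dataset.
* Recording effort is fixed clock blocks per day (default four 1-h blocks,
  mirroring a dawn/dusk schedule).
* At an occupied site, true detections of a species arrive as a homogeneous
  Poisson process with rate ``vocal_rate_per_hour``; false positives arrive
  everywhere at ``fp_rate_per_hour``.  Detections occupy non-overlapping 3-s
  windows on the classifier grid within each block.
* Confidences are i.i.d.: true positives from a Beta rescaled to [0.10, 1],
  false positives from a Beta rescaled to [0.10, fp_cap].  ``fp_cap`` is the
  species' true maximum false-positive confidence, so threshold logic can be
  validated against a known bound.
* At each point-count visit an occupied species is recorded with probability
  ``p_point_count``, independently across visits.

All randomness flows from one integer seed through named child streams
(occupancy, detections, point counts, annotation thinning), so outputs are
bit-identical across runs with the same seed and config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapacityError
from .io import DEFAULT_MIN_CONFIDENCE, SEGMENT_LENGTH_S, check_schedule_nonoverlap
from .reference import load_focal_benchmark
from .validation import (
    FALSE_POSITIVE,
    TRUE_POSITIVE,
    SegmentAnnotation,
    SegmentSample,
    classifier_species_for_segments,
)

#: Hours of recording per day in the emulated deployment design.
DEFAULT_BLOCKS = ((5.0, 1.0), (6.0, 1.0), (20.0, 1.0), (21.0, 1.0))


@dataclass
class SpeciesProfile:
    """Generating parameters for one species."""

    scientific_name: str
    common_name: str
    occupancy: dict = field(default_factory=lambda: {"grassland": 0.9, "row_crop": 0.6})
    vocal_rate_per_hour: float = 2.0
    tp_conf_a: float = 1.5
    tp_conf_b: float = 3.0
    fp_rate_per_hour: float = 0.2
    fp_conf_a: float = 1.2
    fp_conf_b: float = 5.0
    fp_cap: float = 0.6
    p_point_count: float = 0.5
    fp_sources: dict | None = None  # optional confusion weights for FP provenance


@dataclass
class SimulationConfig:
    """Full description of one synthetic study."""

    species: list
    n_sites: int = 10
    habitats: list | None = None  # per-site; default alternates grassland/row_crop
    season_start: str = "2022-05-19"
    n_days: int = 60
    daily_blocks: tuple = DEFAULT_BLOCKS
    visits_per_site: int = 3
    visit_duration_min: float = 10.0
    seed: int = 0

    def site_ids(self) -> list:
        return [f"site{i + 1:02d}" for i in range(self.n_sites)]

    def site_habitats(self) -> dict:
        if self.habitats is not None:
            return dict(zip(self.site_ids(), self.habitats))
        return {
            s: ("grassland" if i % 2 == 0 else "row_crop")
            for i, s in enumerate(self.site_ids())
        }


def _streams(config: SimulationConfig) -> dict:
    """Named, independent child RNGs derived from the config seed."""
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("occupancy", "detections", "point_counts", "annotation")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def default_config(seed: int = 0, n_sites: int = 10, n_days: int = 60,
                   rate_scale: float = 0.02) -> SimulationConfig:
    """Study-shaped default: 20 focal species over a 10-site, 60-day season.

    Species rates are proportional to the benchmark's per-species detection
    totals (scaled down by ``rate_scale`` to keep datasets desk-sized) and
    split into true/false rates so each species' expected precision at the
    0.10 stratum equals its benchmark precision; ``fp_cap`` is the species'
    benchmark maximum false-positive confidence.
    """
    bench = load_focal_benchmark()
    total_hours = 5189.0  # recording effort behind the benchmark totals
    species = []
    for row in bench.itertuples(index=False):
        rate = max(row.total_detections / total_hours * rate_scale, 0.02)
        p = row.precision_c10
        species.append(
            SpeciesProfile(
                scientific_name=row.scientific_name,
                common_name=row.common_name,
                vocal_rate_per_hour=rate * p,
                fp_rate_per_hour=rate * (1.0 - p),
                fp_cap=max(row.max_fp_confidence, DEFAULT_MIN_CONFIDENCE),
            )
        )
    return SimulationConfig(species=species, n_sites=n_sites, n_days=n_days, seed=seed)


def simulate_schedule(config: SimulationConfig) -> pd.DataFrame:
    """Recording schedule: one recording per (site, day, block), non-overlapping."""
    start = pd.Timestamp(config.season_start)
    rows = []
    for site in config.site_ids():
        for day in range(config.n_days):
            date = start + pd.Timedelta(days=day)
            for b, (hour, dur_h) in enumerate(config.daily_blocks):
                t0 = date + pd.Timedelta(hours=hour)
                rows.append(
                    {
                        "recording_id": f"{site}_{date.date()}_b{b}",
                        "site_id": site,
                        "start": t0,
                        "duration_s": dur_h * 3600.0,
                    }
                )
    schedule = pd.DataFrame(rows)
    check_schedule_nonoverlap(schedule)
    return schedule


def simulate_occupancy(config: SimulationConfig) -> pd.DataFrame:
    """Site × species presence draws (deterministic in the config seed)."""
    rng = _streams(config)["occupancy"]
    habitats = config.site_habitats()
    rows = []
    for site in config.site_ids():
        hab = habitats[site]
        for sp in config.species:
            psi = sp.occupancy.get(hab, 0.0)
            rows.append(
                {
                    "site_id": site,
                    "scientific_name": sp.scientific_name,
                    "habitat": hab,
                    "occupied": bool(rng.random() < psi),
                }
            )
    return pd.DataFrame(rows)


def _distinct_slots(rng: np.random.Generator, n_slots: int, n: int) -> np.ndarray:
    """n distinct slot indices uniform over range(n_slots)."""
    if n > n_slots:
        raise CapacityError(
            f"{n} non-overlapping segments requested but block holds {n_slots}"
        )
    if n > n_slots // 2:
        return rng.permutation(n_slots)[:n]
    chosen: set = set()
    while len(chosen) < n:
        for s in rng.integers(0, n_slots, size=n - len(chosen)):
            chosen.add(int(s))
    return np.fromiter(chosen, dtype=int, count=n)


def _rescaled_beta(rng, a, b, lo, hi, size):
    if hi <= lo:
        return np.full(size, lo)
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def simulate_detections(
    config: SimulationConfig,
    schedule: pd.DataFrame,
    occupancy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Truth-labelled detection table over a recording schedule.

    Returns the canonical detection frame plus ``truth``
    (``true_positive``/``false_positive``) and ``source_species`` columns;
    dropping those two columns yields a valid detection table.  Counts per
    recording block are Poisson in the block's recorded hours; segments are
    placed without overlap (per species) on the 3-s classifier grid.
    """
    if occupancy is None:
        occupancy = simulate_occupancy(config)
    rng = _streams(config)["detections"]
    occ = {
        (r.site_id, r.scientific_name): r.occupied
        for r in occupancy.itertuples(index=False)
    }
    cols: dict[str, list] = {
        "site_id": [], "recording_id": [], "recording_start": [],
        "segment_start_s": [], "confidence": [], "scientific_name": [],
        "common_name": [], "truth": [], "source_species": [],
    }
    for rec in schedule.itertuples(index=False):
        hours = rec.duration_s / 3600.0
        n_slots = int(rec.duration_s // SEGMENT_LENGTH_S)
        for sp in config.species:
            occupied = occ.get((rec.site_id, sp.scientific_name), False)
            n_tp = rng.poisson(sp.vocal_rate_per_hour * hours) if occupied else 0
            n_fp = rng.poisson(sp.fp_rate_per_hour * hours)
            n = n_tp + n_fp
            if n == 0:
                continue
            slots = _distinct_slots(rng, n_slots, n)
            conf = np.concatenate(
                [
                    _rescaled_beta(rng, sp.tp_conf_a, sp.tp_conf_b,
                                   DEFAULT_MIN_CONFIDENCE, 1.0, n_tp),
                    _rescaled_beta(rng, sp.fp_conf_a, sp.fp_conf_b,
                                   DEFAULT_MIN_CONFIDENCE, sp.fp_cap, n_fp),
                ]
            )
            truth = [TRUE_POSITIVE] * n_tp + [FALSE_POSITIVE] * n_fp
            sources = [sp.scientific_name] * n_tp
            if sp.fp_sources:
                names = list(sp.fp_sources)
                w = np.array([sp.fp_sources[k] for k in names], dtype=float)
                sources += list(rng.choice(names, size=n_fp, p=w / w.sum()))
            else:
                sources += [""] * n_fp
            cols["site_id"] += [rec.site_id] * n
            cols["recording_id"] += [rec.recording_id] * n
            cols["recording_start"] += [rec.start] * n
            cols["segment_start_s"] += list(slots * SEGMENT_LENGTH_S)
            cols["confidence"] += list(conf)
            cols["scientific_name"] += [sp.scientific_name] * n
            cols["common_name"] += [sp.common_name] * n
            cols["truth"] += truth
            cols["source_species"] += sources
    df = pd.DataFrame(cols)
    df["segment_end_s"] = df["segment_start_s"] + SEGMENT_LENGTH_S
    df["recording_start"] = pd.to_datetime(df["recording_start"])
    df["start_time"] = df["recording_start"] + pd.to_timedelta(
        df["segment_start_s"], unit="s"
    )
    order = [
        "site_id", "recording_id", "recording_start", "segment_start_s",
        "segment_end_s", "scientific_name", "common_name", "confidence",
        "start_time", "truth", "source_species",
    ]
    return df[order].sort_values(
        ["recording_id", "segment_start_s", "scientific_name"], kind="mergesort"
    ).reset_index(drop=True)


def simulate_point_counts(
    config: SimulationConfig,
    occupancy: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey visits and their observations.

    Visits are evenly spaced over the season at 07:00 local time; at each
    visit every occupied species is recorded with its ``p_point_count``,
    independently across visits.  Returns ``(observations, visits)``.
    """
    if occupancy is None:
        occupancy = simulate_occupancy(config)
    rng = _streams(config)["point_counts"]
    start = pd.Timestamp(config.season_start)
    day_offsets = np.unique(
        np.round(np.linspace(0, config.n_days - 1, config.visits_per_site)).astype(int)
    )
    occ_by_site = {
        s: g.loc[g["occupied"], "scientific_name"].tolist()
        for s, g in occupancy.groupby("site_id")
    }
    behaviors = np.array(["singing", "calling", "observed"])
    visit_rows, obs_rows = [], []
    for site in config.site_ids():
        for d in day_offsets:
            vstart = start + pd.Timedelta(days=int(d), hours=7)
            visit_rows.append(
                {
                    "site_id": site,
                    "visit_start": vstart,
                    "duration_min": config.visit_duration_min,
                }
            )
            for sp in config.species:
                if sp.scientific_name not in occ_by_site.get(site, []):
                    continue
                if rng.random() < sp.p_point_count:
                    obs_rows.append(
                        {
                            "site_id": site,
                            "visit_start": vstart,
                            "species": sp.scientific_name,
                            "behavior": str(rng.choice(behaviors)),
                            "distance_m": float(np.round(rng.uniform(0, 200), 1)),
                            "sex": "",
                        }
                    )
    visits = pd.DataFrame(visit_rows)
    observations = pd.DataFrame(
        obs_rows,
        columns=["site_id", "visit_start", "species", "behavior", "distance_m", "sex"],
    )
    return observations, visits


def oracle_annotations(detections_with_truth: pd.DataFrame) -> pd.DataFrame:
    """Detection-level annotation records copied from simulation truth.

    Stands in for the expert listener in the precision workflow: each
    detection's label is its generating truth.
    """
    return pd.DataFrame(
        {
            "recording_id": detections_with_truth["recording_id"],
            "clip_start_s": (detections_with_truth["segment_start_s"] - 1.0).clip(lower=0),
            "clip_end_s": detections_with_truth["segment_end_s"] + 1.0,
            "species": detections_with_truth["scientific_name"],
            "label": detections_with_truth["truth"],
            "confidence": detections_with_truth["confidence"],
        }
    )


def oracle_segment_annotations(
    sample: SegmentSample,
    detections_with_truth: pd.DataFrame,
    recordings: pd.DataFrame,
    manual_detection_prob: float = 1.0,
    seed: int = 0,
) -> list[SegmentAnnotation]:
    """Segment-level annotations from truth, optionally thinned.

    The manual species set of a segment is every species with at least one
    true vocalization overlapping it, each independently kept with
    ``manual_detection_prob`` (an imperfect-listener model).  The classifier
    species set is every detection at the run's minimum confidence
    overlapping the segment, derived from the detection table alone.
    """
    rng = np.random.default_rng(seed)
    true_det = detections_with_truth.loc[
        detections_with_truth["truth"] == TRUE_POSITIVE
    ]
    manual = classifier_species_for_segments(
        true_det, sample, recordings, min_confidence=0.0
    )
    classifier = classifier_species_for_segments(
        detections_with_truth, sample, recordings,
        min_confidence=DEFAULT_MIN_CONFIDENCE,
    )
    out = []
    for seg_id in sample.segments["segment_id"]:
        heard = frozenset(
            s for s in sorted(manual[seg_id]) if rng.random() < manual_detection_prob
        )
        out.append(
            SegmentAnnotation(
                segment_id=seg_id,
                manual_species=heard,
                classifier_species=classifier[seg_id],
            )
        )
    return out


def expected_precision(profile: SpeciesProfile, threshold: float) -> float:
    """Analytic expected precision of a species at a threshold (occupied site).

    E[N_tp retained] / (E[N_tp retained] + E[N_fp retained]) under the
    Poisson-count, rescaled-Beta-confidence model.
    """
    lo = DEFAULT_MIN_CONFIDENCE

    def surv(a, b, hi, t):
        if t <= lo:
            return 1.0
        if t >= hi:
            return 0.0
        return float(stats.beta.sf((t - lo) / (hi - lo), a, b))

    tp = profile.vocal_rate_per_hour * surv(profile.tp_conf_a, profile.tp_conf_b, 1.0, threshold)
    fp = profile.fp_rate_per_hour * surv(profile.fp_conf_a, profile.fp_conf_b, profile.fp_cap, threshold)
    if tp + fp == 0:
        return float("nan")
    return tp / (tp + fp)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (streams re-derived)."""
    return replace(config, seed=seed)
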