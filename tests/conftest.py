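"""Shared fixtures: small simulated datasets and the bundled benchmark."""

import pandas as pd
import pytest

from pamval import simulate as sim
from pamval.reference import load_focal_benchmark


@pytest.fixture(scope="session")
def benchmark() -> pd.DataFrame:
    return load_focal_benchmark()


@pytest.fixture(scope="session")
def small_config():
    """4 sites, 10 days: enough structure for every pipeline stage, fast."""
    return sim.default_config(seed=11, n_sites=4, n_days=10)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Schedule, occupancy, labelled detections, point counts, visits."""
    schedule = sim.simulate_schedule(small_config)
    occupancy = sim.simulate_occupancy(small_config)
    detections = sim.simulate_detections(small_config, schedule, occupancy)
    observations, visits = sim.simulate_point_counts(small_config, occupancy)
    return {
        "config": small_config,
        "schedule": schedule,
        "occupancy": occupancy,
        "detections": detections,
        "observations": observations,
        "visits": visits,
    }


@pytest.fixture(scope="session")
def plain_detections(small_dataset) -> pd.DataFrame:
    """The detection table as a consumer would see it (truth columns dropped)."""
    return small_dataset["detections"].drop(columns=["truth", "source_species"])


def build_pairing_fixture():
    """30 survey visits of which exactly 6 lack any recording within 1 h.

    Ten sites, three visits each at 07:00 on separate days.  Sites 1-8 get a
    recording overlapping each visit hour; the two remaining sites' recordings
    all happen three days later, so their 6 visits have nothing within the
    window.
    """
    visit_rows, rec_rows = [], []
    base = pd.Timestamp("2022-06-01 07:00")
    for s in range(10):
        site = f"site{s + 1:02d}"
        for v in range(3):
            vstart = base + pd.Timedelta(days=v)
            visit_rows.append(
                {"site_id": site, "visit_start": vstart, "duration_min": 10.0}
            )
            offset = pd.Timedelta(days=3) if s >= 8 else pd.Timedelta(0)
            rec_rows.append(
                {
                    "recording_id": f"{site}_v{v}",
                    "site_id": site,
                    "start": vstart + offset - pd.Timedelta(minutes=30),
                    "duration_s": 3600.0,
                }
            )
    return pd.DataFrame(visit_rows), pd.DataFrame(rec_rows)


@pytest.fixture()
def pairing_fixture():
    return build_pairing_fixture()
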