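"""Bundled reference benchmark for 20 grassland focal bird species.

The package ships a published validation benchmark table for 20 focal
grassland bird species (Nebraska mixed-grass prairie / row-crop landscape):
per species, the total number of classifier detections, the maximum observed
confidence, precision validated from 60 random detections at the classifier's
default minimum confidence of 0.10 (``precision_c10``) and after filtering to
0.25 (``precision_c25``), the maximum confidence observed among validated
false positives, segment-level recall from 50 random 120-s clips, the F-score,
and the species-specific confidence (SSC) threshold assigned from those
metrics.

Alongside the printed 3-decimal metrics the table carries the underlying
integer counts (``p10_tp``/``p10_n`` for precision at the default stratum,
``recall_tp``/``recall_n`` for segment recall).  The counts are recovered
from the printed decimals: precision denominators are the 60-detection
validation design, and each recall decimal is matched by the smallest
fraction with denominator at most the 50-segment design.  F-scores in the
benchmark were computed from these unrounded fractions, not from the printed
3-decimal values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .species import SpeciesCatalog

_DATA = "focal_species_benchmark.tsv"


def load_focal_benchmark() -> pd.DataFrame:
    """Return the 20-species benchmark table as a DataFrame.

    Missing recall/F entries (species never manually detected in the recall
    clips, or never matched) are NaN.
    """
    with resources.files("pamval.data").joinpath(_DATA).open("rb") as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def focal_species_list() -> list[str]:
    """Scientific names of the 20 focal species."""
    return load_focal_benchmark()["scientific_name"].tolist()


def focal_species_catalog() -> SpeciesCatalog:
    """A :class:`SpeciesCatalog` covering the 20 focal species."""
    df = load_focal_benchmark()
    return SpeciesCatalog(df[["scientific_name", "common_name"]].itertuples(index=False))


def focal_ssc_map() -> dict[str, float]:
    """Published SSC threshold per focal species (scientific name -> threshold)."""
    df = load_focal_benchmark()
    return dict(zip(df["scientific_name"], df["ssc"]))
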