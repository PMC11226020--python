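"""Paired statistical comparison of ARU- and point-count-derived richness.

For each (period, threshold) cell the two methods' richness values are
aligned by analysis unit (visit at the short duration, site at the long
duration) and compared with a two-tailed Student paired t-test on the
differences ARU − point count.  Positive mean deltas mean the acoustic
method found more species.  No multiple-testing correction is applied by
default, matching how such threshold ladders are conventionally reported;
Holm-adjusted p-values are available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, ValidationError


@dataclass
class PairedComparisonResult:
    """One cell of the method-comparison table."""

    period: str
    threshold_label: str
    n_pairs: int
    mean_delta: float
    t_statistic: float
    p_value: float
    significant: bool


def paired_t_test(x, y) -> tuple[float, float, float]:
    """Two-tailed Student paired t-test of ``y − x``.

    Returns ``(t, p, mean_delta)`` with ``mean_delta = mean(y − x)`` and
    ``len(x) − 1`` degrees of freedom.  Degenerate difference vectors follow
    fixed conventions instead of erroring: all-zero differences give
    ``t = 0, p = 1``; zero-variance nonzero differences give ``t = ±inf,
    p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and the same length")
    if len(x) < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    d = y - x
    mean_delta = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(mean_delta, 0.0):
            return 0.0, 1.0, 0.0
        return float(np.sign(mean_delta)) * np.inf, 0.0, mean_delta
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue), mean_delta


def build_delta_table(
    aru_richness: pd.DataFrame,
    pc_richness: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Paired comparison across every (period, threshold) cell.

    ``aru_richness`` holds richness records for the acoustic method (several
    ``threshold_label`` values, ``period`` "short" and/or "long");
    ``pc_richness`` holds the point-count records for the same periods.
    Units are aligned on (site_id, visit_start) for short-period cells and on
    site_id for long-period cells; an ARU unit missing from the point-count
    side (or vice versa) raises :class:`~pamval.errors.PairingError` naming
    the offenders.  Returns one row per cell with t, p, mean delta
    (ARU − point count) and a significance flag at ``alpha``; with
    ``holm=True`` an extra column of Holm-adjusted p-values is added.
    """
    results = []
    for period in sorted(aru_richness["period"].unique()):
        keys = ["site_id", "visit_start"] if period == "short" else ["site_id"]
        pc = pc_richness.loc[pc_richness["period"] == period]
        if len(pc) == 0:
            raise PairingError(f"no point-count records for period {period!r}")
        pc_units = pc.set_index(keys)["richness"]
        for label in sorted(
            aru_richness.loc[aru_richness["period"] == period, "threshold_label"].unique()
        ):
            cell = aru_richness.loc[
                (aru_richness["period"] == period)
                & (aru_richness["threshold_label"] == label)
            ].sort_values(keys)
            aru_units = cell.set_index(keys)["richness"]
            missing = aru_units.index.difference(pc_units.index)
            extra = pc_units.index.difference(aru_units.index)
            if len(missing) or len(extra):
                raise PairingError(
                    f"unmatched analysis units in period {period!r}: "
                    f"ARU-only={list(missing)}, point-count-only={list(extra)}"
                )
            pc_aligned = pc_units.loc[aru_units.index]
            t, p, delta = paired_t_test(pc_aligned.to_numpy(), aru_units.to_numpy())
            results.append(
                PairedComparisonResult(
                    period=period,
                    threshold_label=label,
                    n_pairs=len(aru_units),
                    mean_delta=delta,
                    t_statistic=t,
                    p_value=p,
                    significant=bool(p < alpha),
                )
            )
    table = pd.DataFrame([r.__dict__ for r in results])
    if holm and len(table):
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_value_holm"] = adj
    return table
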