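"""Five-component comparison between the HEI-2005 and RC-DQI scoring schemes.

Both indexes score dairy, fruit, vegetables, total grains, and whole grains.
To put them on a common footing each comparable component is rescaled to a
0-5 range (dairy in both indexes, and RC-DQI fruit and vegetables, are halved
from their native 10-point maxima) and summed into a 0-25 subscore. The
comparison then examines

* within-index Pearson correlations among the five components,
* between-index correlations of the matched components, and
* distribution classes: the proportion of children at a component's minimum
  (0), strictly between, and at its maximum (5; 25 for the subscore), the
  diagnostic for whether a scheme dichotomizes the population.

All analyses run on the total sample and stratified by age, ethnic, and
income group. Correlations are unweighted Pearson r with two-sided
significance flags at 0.05 and 0.01 (no multiple-testing correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hei2005 import HEIComponentScores
from .rcdqi import RCDQIComponentScores

#: The five comparable components, in report order.
COMPARABLE = ("dairy", "fruit", "vegetables", "total_grains", "whole_grains")

COMPONENT_MAX = 5.0
SUBSCORE_MAX = 25.0
_TOL = 1e-9


@dataclass(frozen=True)
class RescaledComponents:
    """One child's five comparable components on the common 0-5 scale."""

    child_id: str
    index: str  # "HEI2005" or "RCDQI"
    dairy: float
    fruit: float
    vegetables: float
    total_grains: float
    whole_grains: float

    @property
    def subscore(self) -> float:
        return sum(getattr(self, c) for c in COMPARABLE)

    def as_dict(self) -> dict[str, float]:
        d = {c: getattr(self, c) for c in COMPARABLE}
        d["subscore"] = self.subscore
        return d


def rescale(
    hei: HEIComponentScores, rcdqi: RCDQIComponentScores
) -> tuple[RescaledComponents, RescaledComponents]:
    """Rescale both indexes' comparable components to the common 0-5 range.

    HEI: milk/2 becomes dairy; fruit (total, juice-inclusive), vegetables
    (total), total grains and whole grains are already 5-point. RC-DQI:
    dairy, fruit, and vegetable are halved; the grain components are already
    5-point.
    """
    hei_re = RescaledComponents(
        child_id=hei.child_id,
        index="HEI2005",
        dairy=hei.milk / 2.0,
        fruit=hei.total_fruit,
        vegetables=hei.total_veg,
        total_grains=hei.total_grains,
        whole_grains=hei.whole_grains,
    )
    rc_re = RescaledComponents(
        child_id=rcdqi.child_id,
        index="RCDQI",
        dairy=rcdqi.dairy / 2.0,
        fruit=rcdqi.fruit / 2.0,
        vegetables=rcdqi.vegetable / 2.0,
        total_grains=rcdqi.total_grains,
        whole_grains=rcdqi.whole_grains,
    )
    return hei_re, rc_re


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p; (nan, nan) when either column is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _sig_flag(p: float) -> str:
    if np.isnan(p):
        return "missing"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def correlation_matrix(
    scores: pd.DataFrame, components: tuple[str, ...] = COMPARABLE, stratum: str = "total"
) -> pd.DataFrame:
    """Pairwise Pearson correlations among components of one index.

    ``scores`` has one row per child and one column per component. Returns a
    tidy frame with one row per unordered pair (upper triangle), carrying r,
    p, a significance flag, n, and the stratum label. A component that is
    constant in the stratum yields missing r for its pairs, never 0.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 children to correlate")
    rows = []
    for i, a in enumerate(components):
        for b in components[i + 1 :]:
            r, p = _pearson(scores[a].to_numpy(), scores[b].to_numpy())
            rows.append(
                {
                    "stratum": stratum,
                    "component_a": a,
                    "component_b": b,
                    "r": r,
                    "p": p,
                    "significance": _sig_flag(p),
                    "n": len(scores),
                }
            )
    return pd.DataFrame(rows)


def cross_index_correlations(
    hei_rescaled: pd.DataFrame,
    rcdqi_rescaled: pd.DataFrame,
    stratum: str = "total",
) -> pd.DataFrame:
    """All 5x5 correlations between HEI and RC-DQI rescaled components.

    Both frames must be row-aligned on the same children. The matched-component
    diagonal (e.g. HEI dairy vs RC-DQI dairy) measures agreement between the
    two scoring schemes on identical intake data.
    """
    if len(hei_rescaled) != len(rcdqi_rescaled):
        raise ValueError("frames must cover the same children")
    if len(hei_rescaled) < 3:
        raise ValueError("need at least 3 children to correlate")
    rows = []
    for a in COMPARABLE:
        for b in COMPARABLE:
            r, p = _pearson(hei_rescaled[a].to_numpy(), rcdqi_rescaled[b].to_numpy())
            rows.append(
                {
                    "stratum": stratum,
                    "hei_component": a,
                    "rcdqi_component": b,
                    "r": r,
                    "p": p,
                    "significance": _sig_flag(p),
                    "n": len(hei_rescaled),
                }
            )
    return pd.DataFrame(rows)


def distribution_classes(
    rescaled: pd.DataFrame, stratum: str = "total"
) -> pd.DataFrame:
    """Proportions at the minimum, strictly between, and at the maximum.

    Computed for each of the five components (max 5) and the subscore
    (max 25); boundary membership is exact up to a 1e-9 tolerance. The three
    proportions sum to 1 for every row.
    """
    if len(rescaled) == 0:
        raise ValueError("empty stratum")
    rows = []
    items = [(c, COMPONENT_MAX) for c in COMPARABLE] + [("subscore", SUBSCORE_MAX)]
    for comp, vmax in items:
        v = rescaled[comp].to_numpy(dtype=float)
        at_min = np.abs(v - 0.0) <= _TOL
        at_max = np.abs(v - vmax) <= _TOL
        n = len(v)
        rows.append(
            {
                "stratum": stratum,
                "component": comp,
                "prop_min": float(at_min.sum()) / n,
                "prop_between": float((~at_min & ~at_max).sum()) / n,
                "prop_max": float(at_max.sum()) / n,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


STRATA_COLUMNS = ("age_group", "ethnic_group", "income_group")


def _iter_strata(scores: pd.DataFrame, strata: tuple[str, ...]):
    yield "total", scores
    for col in strata:
        for level, group in scores.groupby(col, sort=True, observed=True):
            yield f"{col}={level}", group


def stratified_report(
    scores: pd.DataFrame, strata: tuple[str, ...] = STRATA_COLUMNS
) -> dict[str, pd.DataFrame]:
    """Full comparison report over the total sample and every stratum.

    ``scores`` is the per-child table produced by the scoring pipeline, with
    rescaled component columns ``hei_<c>``/``rcdqi_<c>`` (plus ``..._subscore``)
    and the stratum columns. Returns the three report tables: within-index
    correlations, between-index correlations, and distribution classes.
    """
    if "weights" in scores.columns:
        warnings.warn("a 'weights' column is present but survey weights are not applied")
    within, cross, dist = [], [], []
    for label, group in _iter_strata(scores, strata):
        if len(group) == 0:
            continue
        hei = group[[f"hei_{c}" for c in COMPARABLE] + ["hei_subscore"]].rename(
            columns=lambda c: c.removeprefix("hei_")
        )
        rc = group[[f"rcdqi_{c}" for c in COMPARABLE] + ["rcdqi_subscore"]].rename(
            columns=lambda c: c.removeprefix("rcdqi_")
        )
        if len(group) >= 3:
            for index, frame in (("HEI2005", hei), ("RCDQI", rc)):
                m = correlation_matrix(frame, stratum=label)
                m.insert(0, "index", index)
                within.append(m)
            cross.append(cross_index_correlations(hei, rc, stratum=label))
        for index, frame in (("HEI2005", hei), ("RCDQI", rc)):
            d = distribution_classes(frame, stratum=label)
            d.insert(0, "index", index)
            dist.append(d)
    return {
        "within_correlations": pd.concat(within, ignore_index=True),
        "cross_correlations": pd.concat(cross, ignore_index=True),
        "distribution_classes": pd.concat(dist, ignore_index=True),
    }
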