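"""The atmospheric-health composite index and cleanliness zoning.

The per-unit score has three parts:

* **erd** — exposure–response degree.  Signed: with the national
  annual PM2.5 limit of 35 µg/m³ as the threshold, a unit below the
  limit earns a positive "cleanliness benefit" proportional to its
  margin under the limit and its standardized population density; a
  unit above it takes a negative score proportional to the excess.
  The magnitude is ``w_e · (margin/35) · dp_std`` with a single
  criterion-level weight ``w_e`` (0.4 under the published scheme);
  the excess is capped at 35 µg/m³ so |erd| ≤ w_e.
* **rv** — regional vulnerability: weighted sum of the four
  standardized vulnerable-population indicators (range [0, 0.2]).
* **ra** — regional adaptability: weighted sum of the five
  standardized mitigation-capacity indicators (range [0, ~0.4]).
* **ahp** — the composite: ``erd + rv + ra`` on the clean branch
  (erd ≥ 0) and ``erd − rv + ra`` on the polluted branch (erd < 0),
  where vulnerability counts against health once pollution exceeds
  the limit and adaptability always mitigates.

Cleanliness zoning assigns each unit one of seven half-open
concentration classes (A-1 … A-3 clean, B-1 … B-3 within-limit
gradations, C exceeding the limit).  The B-class interior boundaries
(18.6, 21.5) are frozen published constants from a natural-breaks
classification of the source data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from airhealth.ahp import WeightScheme, CRITERION_INDICATORS

PM25_LIMIT = 35.0  # national annual-mean concentration limit, µg/m³

VULNERABILITY_INDICATORS = CRITERION_INDICATORS["regional_vulnerability"]
ADAPTABILITY_INDICATORS = CRITERION_INDICATORS["regional_adaptability"]


@dataclass
class ZoneScheme:
    """Ordered half-open concentration intervals with class labels."""

    labels: tuple[str, ...] = ("A-1", "A-2", "A-3", "B-1", "B-2", "B-3", "C")
    # interior boundaries: label i covers [bounds[i-1], bounds[i])
    bounds: tuple[float, ...] = (5.0, 10.0, 15.0, 18.6, 21.5, 35.0)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.labels) - 1:
            raise ValueError("need one fewer boundary than labels")
        if any(b <= a for a, b in zip(self.bounds, self.bounds[1:])):
            raise ValueError("boundaries must be strictly increasing")


DEFAULT_ZONES = ZoneScheme()


def _check_inputs(acp_raw, dp_std=None):
    acp = np.asarray(acp_raw, dtype=float)
    if (acp < 0).any():
        raise ValueError("concentrations must be non-negative")
    if dp_std is None:
        return acp
    dp = np.asarray(dp_std, dtype=float)
    if ((dp < 0) | (dp > 1)).any():
        raise ValueError("standardized density must lie in [0, 1]")
    if dp.shape != acp.shape:
        raise ValueError("acp_raw and dp_std length mismatch")
    return acp, dp


def compute_erd(
    acp_raw,
    dp_std,
    scheme: WeightScheme,
    threshold: float = PM25_LIMIT,
    erd_weighting: str = "criterion",
) -> np.ndarray:
    """Exposure–response degree of each unit (signed, |erd| ≤ w_e).

    ``erd_weighting`` selects how the exposure weight enters:
    ``"criterion"`` (default) multiplies by the single criterion-level
    weight; ``"indicator_product"`` multiplies by both exposure
    indicator weights (concentration × density), an alternative
    reading of the published formula in which the weight symbol
    appears against each factor.
    """
    acp, dp = _check_inputs(acp_raw, dp_std)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if erd_weighting == "criterion":
        w_e = scheme.criterion_weights["exposure_response"]
    elif erd_weighting == "indicator_product":
        w_e = scheme.indicator_weights["acp"] * scheme.indicator_weights["pop_density"]
    else:
        raise ValueError(f"unknown erd_weighting {erd_weighting!r}")

    margin = (threshold - acp) / threshold  # clean branch, in (0, 1]
    excess = np.minimum(acp - threshold, threshold) / threshold  # capped at 1
    return np.where(acp <= threshold, w_e * margin * dp, -w_e * excess * dp)


def _weighted_sum(indicators_std: pd.DataFrame, names, scheme: WeightScheme) -> np.ndarray:
    missing = [n for n in names if n not in indicators_std.columns]
    if missing:
        raise ValueError(f"missing standardized attributes: {missing}")
    block = indicators_std[list(names)].to_numpy(dtype=float)
    if ((block < 0) | (block > 1)).any():
        raise ValueError("attributes must be standardized to [0, 1]")
    w = np.array([scheme.indicator_weights[n] for n in names])
    return block @ w


def compute_rv(indicators_std: pd.DataFrame, scheme: WeightScheme) -> np.ndarray:
    """Regional vulnerability: weighted standardized sensitive-population load."""
    return _weighted_sum(indicators_std, VULNERABILITY_INDICATORS, scheme)


def compute_ra(indicators_std: pd.DataFrame, scheme: WeightScheme) -> np.ndarray:
    """Regional adaptability: weighted standardized mitigation capacity."""
    return _weighted_sum(indicators_std, ADAPTABILITY_INDICATORS, scheme)


def compute_ahp(erd, rv, ra) -> np.ndarray:
    """The composite health pattern.

    Clean branch (erd ≥ 0): erd + rv + ra — cleanliness benefit,
    vulnerable residents included, adds to the pattern.  Polluted
    branch (erd < 0): erd − rv + ra — exposure and vulnerability count
    against health, adaptability mitigates.
    """
    erd = np.asarray(erd, dtype=float)
    rv = np.asarray(rv, dtype=float)
    ra = np.asarray(ra, dtype=float)
    if not (erd.shape == rv.shape == ra.shape):
        raise ValueError("erd, rv, ra length mismatch")
    return np.where(erd >= 0, erd + rv + ra, erd - rv + ra)


def classify_cleanliness(acp_raw, zones: ZoneScheme = DEFAULT_ZONES) -> np.ndarray:
    """Assign each concentration its half-open cleanliness class."""
    acp = _check_inputs(acp_raw)
    idx = np.searchsorted(np.asarray(zones.bounds), acp, side="right")
    return np.asarray(zones.labels, dtype=object)[idx]


def crosstab_zones(labels, groups, zones: ZoneScheme = DEFAULT_ZONES) -> pd.DataFrame:
    """Two-way (city × cleanliness class) count table with margins.

    Only classes that occur appear as columns; a ``Total`` row and
    column carry the margins, and the grand total equals the number of
    units.
    """
    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(groups, dtype=object)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups length mismatch")
    tab = pd.crosstab(pd.Series(groups, name="group"), pd.Series(labels, name="zone"))
    zone_order = [z for z in zones.labels if z in tab.columns]
    tab = tab[zone_order]
    tab["Total"] = tab.sum(axis=1)
    tab.loc["Total"] = tab.sum(axis=0)
    return tab


def natural_breaks(values, k: int) -> list[float]:
    """Fisher–Jenks optimal class breaks (k−1 interior breakpoints).

    Dynamic program minimising the total within-class sum of squared
    deviations over all partitions of the sorted values into k
    contiguous classes.  Breakpoints are reported as the largest value
    of each of the first k−1 classes; classification is
    ``value ≤ break``.  Deterministic; ties resolved toward the
    earliest feasible split.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if k < 1:
        raise ValueError("k must be at least 1")
    n_distinct = len(np.unique(x))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct values ({n_distinct})")
    if k == 1:
        return []

    # prefix sums for O(1) within-class SSD of x[i..j]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def ssd(i: int, j: int) -> float:  # inclusive indices
        m = j - i + 1
        s = cs[j + 1] - cs[i]
        s2 = cs2[j + 1] - cs2[i]
        return max(s2 - s * s / m, 0.0)

    INF = float("inf")
    # cost[c][j] = best total SSD of x[0..j] split into c classes
    prev = np.array([ssd(0, j) for j in range(n)])
    back = np.zeros((k, n), dtype=int)
    for c in range(2, k + 1):
        cur = np.full(n, INF)
        for j in range(c - 1, n):
            best, arg = INF, c - 1
            for i in range(c - 1, j + 1):
                cost = prev[i - 1] + ssd(i, j)
                if cost < best - 1e-12:
                    best, arg = cost, i
            cur[j] = best
            back[c - 1, j] = arg
        prev = cur

    # recover class boundaries
    breaks = []
    j = n - 1
    for c in range(k, 1, -1):
        i = back[c - 1, j]
        breaks.append(float(x[i - 1]))  # last value of the class below
        j = i - 1
    return sorted(breaks)


def quantile_breaks(values, k: int) -> list[float]:
    """Equal-count class breaks at the i/k empirical quantiles.

    Uses the inclusive linear-interpolation quantile convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if k < 1:
        raise ValueError("k must be at least 1")
    if k == 1:
        return []
    qs = np.arange(1, k) / k
    return [float(q) for q in np.quantile(x, qs, method="linear")]


def build_health_records(
    acp: pd.Series,
    indicators_std: pd.DataFrame,
    scheme: WeightScheme,
    threshold: float = PM25_LIMIT,
    zones: ZoneScheme = DEFAULT_ZONES,
    erd_weighting: str = "criterion",
) -> pd.DataFrame:
    """Full per-unit health table: erd, rv, ra, ahp, cleanliness zone.

    ``acp`` is the raw unit-level annual PM2.5 (µg/m³) indexed by unit
    id; ``indicators_std`` the standardized attribute table on the same
    index, including ``pop_density`` for the exposure term.
    """
    indicators_std = indicators_std.loc[acp.index]
    erd = compute_erd(
        acp.to_numpy(), indicators_std["pop_density"].to_numpy(),
        scheme, threshold=threshold, erd_weighting=erd_weighting,
    )
    rv = compute_rv(indicators_std, scheme)
    ra = compute_ra(indicators_std, scheme)
    return pd.DataFrame(
        {
            "acp_raw": acp.to_numpy(dtype=float),
            "erd": erd,
            "rv": rv,
            "ra": ra,
            "ahp": compute_ahp(erd, rv, ra),
            "zone": classify_cleanliness(acp.to_numpy(), zones),
        },
        index=acp.index,
    )
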