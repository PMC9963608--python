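"""Spatial autocorrelation on township units.

First-order queen contiguity (polygons are neighbours iff their
boundaries share at least one point, edge or corner), row-standardized
weights, global Moran's I with a two-sided permutation test, and local
Moran (LISA) with conditional (hold-one-out) permutation and
HH/LL/HL/LH quadrant labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from shapely import STRtree

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Row-standardized contiguity weights.

    ``neighbors[i]`` lists the unit indices adjacent to unit i;
    non-island rows carry equal weights summing to one.  Unit ids are
    kept for reporting.
    """

    neighbors: list[np.ndarray]
    ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def islands(self) -> np.ndarray:
        return np.array([len(nb) == 0 for nb in self.neighbors])

    def matrix(self) -> sparse.csr_matrix:
        """The row-standardized weight matrix W (islands: zero rows)."""
        rows, cols, vals = [], [], []
        for i, nb in enumerate(self.neighbors):
            k = len(nb)
            if k == 0:
                continue
            rows.extend([i] * k)
            cols.extend(nb.tolist())
            vals.extend([1.0 / k] * k)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def lag(self, z: np.ndarray) -> np.ndarray:
        return self.matrix() @ z


def queen_weights(units: pd.DataFrame, snap: float = 0.0) -> SpatialWeights:
    """First-order queen contiguity from unit polygons.

    Two units are adjacent iff their boundaries share at least one
    point (``snap`` > 0 relaxes this to a distance tolerance for
    imperfectly digitised polygons).  Weights are row-standardized.
    """
    if len(units) == 0:
        raise ValueError("empty unit set")
    geoms = list(units["geometry"])
    tree = STRtree(geoms)
    neighbors: list[np.ndarray] = []
    for i, geom in enumerate(geoms):
        if snap > 0:
            idx = tree.query(geom, predicate="dwithin", distance=snap)
        else:
            idx = tree.query(geom, predicate="intersects")
        nb = np.array(sorted(int(j) for j in idx if int(j) != i), dtype=int)
        neighbors.append(nb)
    w = SpatialWeights(neighbors=neighbors, ids=list(units["unit_id"]))
    if w.islands.any():
        logger.warning("%d island unit(s) with no neighbours", int(w.islands.sum()))
    return w


def _prepare(x, W: SpatialWeights) -> tuple[np.ndarray, np.ndarray, sparse.csr_matrix]:
    x = np.asarray(x, dtype=float)
    if len(x) != W.n:
        raise ValueError("value vector and weights size mismatch")
    keep = ~W.islands
    if not keep.all():
        # islands have undefined spatial lag; exclude and renumber
        logger.warning("excluding %d island unit(s) from Moran statistics",
                       int((~keep).sum()))
        remap = -np.ones(W.n, dtype=int)
        remap[np.flatnonzero(keep)] = np.arange(keep.sum())
        sub = [remap[nb[keep[nb]]] for nb, k in zip(W.neighbors, keep) if k]
        W = SpatialWeights(neighbors=[np.asarray(s, dtype=int) for s in sub])
        x = x[keep]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    z = x - x.mean()
    return z, keep, W.matrix()


def _moran_stat(z: np.ndarray, Wm: sparse.csr_matrix) -> float:
    # row-standardized: S0 = n, so I reduces to z·Wz / z·z
    return float(z @ (Wm @ z) / (z @ z))


def morans_i(
    x, W: SpatialWeights, permutations: int = 999, seed: int = 0
) -> tuple[float, float, float]:
    """Global Moran's I with a two-sided permutation test.

    Returns ``(I, E[I], pseudo_p)`` where E[I] = −1/(n−1) and the
    pseudo p-value counts permutations at least as extreme (in
    |I* − E|) as observed, with the +1 correction.
    """
    if permutations < 99:
        raise ValueError("need at least 99 permutations")
    z, _, Wm = _prepare(x, W)
    n = len(z)
    I_obs = _moran_stat(z, Wm)
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(permutations):
        zp = rng.permutation(z)
        if abs(_moran_stat(zp, Wm) - e_i) >= abs(I_obs - e_i):
            extreme += 1
    p = (extreme + 1) / (permutations + 1)
    return I_obs, e_i, p


def local_morans(
    x,
    W: SpatialWeights,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Local Moran (LISA) with conditional permutation inference.

    Iᵢ = zᵢ·lagᵢ·n/Σz²; quadrants by the signs of (zᵢ, lagᵢ):
    (+,+)=HH, (−,−)=LL, (+,−)=HL, (−,+)=LH.  The pseudo p-value holds
    unit i fixed and permutes the remaining values onto its neighbour
    positions, counting draws with Iᵢ* at least as extreme on the side
    of the observed statistic.  Labels are reported only where the
    significance flag is true.
    """
    if permutations < 99:
        raise ValueError("need at least 99 permutations")
    z, keep, Wm = _prepare(x, W)
    n = len(z)
    m2 = float(z @ z)
    lag = Wm @ z
    Ii = z * lag * n / m2

    quad = np.where(z >= 0, np.where(lag >= 0, "HH", "HL"),
                    np.where(lag >= 0, "LH", "LL"))

    rng = np.random.default_rng(seed)
    pvals = np.empty(n)
    kept_neighbors = [Wm[i].indices for i in range(n)]
    for i in range(n):
        k = len(kept_neighbors[i])
        others = np.delete(z, i)
        # draw k neighbour values per permutation, without replacement
        draws = np.empty((permutations, k))
        for p_ in range(permutations):
            draws[p_] = others[rng.choice(n - 1, size=k, replace=False)]
        Ii_star = z[i] * draws.mean(axis=1) * n / m2
        if Ii[i] >= 0:
            extreme = int((Ii_star >= Ii[i]).sum())
        else:
            extreme = int((Ii_star <= Ii[i]).sum())
        pvals[i] = (extreme + 1) / (permutations + 1)

    sig = pvals < alpha
    out = pd.DataFrame(
        {
            "Ii": Ii,
            "quadrant": quad,
            "p": pvals,
            "significant": sig,
            "label": np.where(sig, quad, "ns"),
        }
    )
    if W.ids:
        out.insert(0, "unit_id", np.asarray(W.ids, dtype=object)[keep])
    return out
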