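"""Land-use regression for PM2.5.

Covariates are aggregated in closed circular buffers around each
monitoring station over a ladder of radii (default 250 m … 16 000 m by
doubling); a multiple linear model is selected by forward-entry /
backward-removal stepwise regression with at most one radius per
covariate; the fitted model is screened by a diagnostic battery
(coefficient t-tests, variance-inflation factors, Durbin–Watson,
residual normality) and then evaluated at every grid cell to invert a
full concentration surface, which is finally averaged over the
township polygons.

Cell membership is by cell-centre inclusion throughout: a grid cell
belongs to a buffer iff its centre lies within ``radius`` of the
station (closed disc), and to a township iff its centre falls inside
the polygon.  Land cover contributes one proportion column per class
(``lc_forest`` etc.); continuous surfaces contribute their buffer mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely import STRtree
from shapely.geometry import Point

from airhealth.gridio import Grid, SurfaceStack, LANDCOVER_CLASSES

logger = logging.getLogger(__name__)

DEFAULT_RADII = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16000.0)

#: separator used in flat buffer-matrix column names, e.g. "elevation@1000"
TERM_SEP = "@"


def term_name(covariate: str, radius: float) -> str:
    r = int(radius) if float(radius).is_integer() else radius
    return f"{covariate}{TERM_SEP}{r}"


def parse_term(name: str) -> tuple[str, float]:
    cov, r = name.rsplit(TERM_SEP, 1)
    return cov, float(r)


def _landcover_proportion_names() -> list[str]:
    return [f"lc_{c}" for c in LANDCOVER_CLASSES]


def _covariate_field(surfaces: SurfaceStack, name: str) -> np.ndarray:
    """Resolve a covariate name to a continuous field on the grid.

    ``lc_<class>`` names become 0/1 indicator fields of the land-cover
    class, whose buffer mean is exactly the class proportion.
    """
    if name.startswith("lc_"):
        cls = name[3:]
        if cls not in LANDCOVER_CLASSES:
            raise KeyError(f"unknown land-cover class {cls!r}")
        if "landcover" not in surfaces:
            raise KeyError("surface stack has no 'landcover' surface")
        return (surfaces["landcover"].data == LANDCOVER_CLASSES.index(cls)).astype(float)
    if name not in surfaces:
        raise KeyError(f"unknown covariate surface {name!r}")
    return np.asarray(surfaces[name].data, dtype=float)


def candidate_covariates(surfaces: SurfaceStack, include_landcover_other: bool = False) -> list[str]:
    """Default candidate covariate names for a stack.

    The residual 'other' land-cover class is excluded by default since
    the class proportions sum to one within each radius.
    """
    names = list(surfaces.continuous_names)
    if "landcover" in surfaces:
        for cls in LANDCOVER_CLASSES:
            if cls == "other" and not include_landcover_other:
                continue
            names.append(f"lc_{cls}")
    return names


def _disc_kernel(radius: float, cell_size: float) -> np.ndarray:
    k = int(np.floor(radius / cell_size))
    di = np.arange(-k, k + 1)
    dd = di[:, None] ** 2 + di[None, :] ** 2
    return (dd * cell_size**2 <= radius**2).astype(float)


def buffer_covariates_grid(
    surfaces: SurfaceStack, radius: float, names: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Buffer aggregate of each covariate at every cell centre.

    Equivalent to placing a station at each cell centre: the mean of a
    continuous covariate (or the class proportion, for ``lc_*``) over
    cells whose centres fall within the closed disc of ``radius``;
    cells beyond the grid edge are ignored (the divisor shrinks).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tpl = surfaces.template
    kernel = _disc_kernel(radius, tpl.cell_size)
    ones = np.ones(tpl.data.shape)
    denom = ndimage.correlate(ones, kernel, mode="constant", cval=0.0)
    if names is None:
        names = candidate_covariates(surfaces)
    out = {}
    for name in names:
        fieldv = _covariate_field(surfaces, name)
        num = ndimage.correlate(fieldv, kernel, mode="constant", cval=0.0)
        out[name] = num / denom
    return out


def build_buffers(
    stations: pd.DataFrame,
    surfaces: SurfaceStack,
    radii: list[float] | tuple[float, ...] = DEFAULT_RADII,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Multi-radius buffer matrix at the stations.

    Returns a DataFrame indexed by station id with one column per
    (covariate, radius) pair, named ``<covariate>@<radius>``.
    """
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing and positive")
    if covariates is None:
        covariates = candidate_covariates(surfaces)

    tpl = surfaces.template
    xc, yc = tpl.cell_centers()
    fields = {name: _covariate_field(surfaces, name) for name in covariates}

    rows = {}
    for _, st in stations.iterrows():
        d2 = (xc - st["x"]) ** 2 + (yc - st["y"]) ** 2
        row = {}
        for radius in radii:
            mask = d2 <= radius**2
            if not mask.any():
                raise ValueError(
                    f"station {st['id']}: buffer radius {radius:g} m covers no grid cells"
                )
            for name in covariates:
                row[term_name(name, radius)] = float(fields[name][mask].mean())
        rows[st["id"]] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class LURModel:
    """A fitted land-use-regression model."""

    terms: list[tuple[str, float]]
    intercept: float
    coefficients: dict[str, float]  # keyed by "<covariate>@<radius>"
    r2: float
    n_obs: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return [term_name(c, r) for c, r in self.terms]

    def passes_gate(self, min_r2: float = 0.90) -> bool:
        """The model-acceptance rule: goodness of fit must exceed min_r2."""
        return self.r2 > min_r2

    def to_json(self, path: str | Path) -> None:
        doc = {
            "terms": [[c, r] for c, r in self.terms],
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "r2": self.r2,
            "n_obs": self.n_obs,
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LURModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            terms=[(c, float(r)) for c, r in doc["terms"]],
            intercept=doc["intercept"],
            coefficients=doc["coefficients"],
            r2=doc["r2"],
            n_obs=doc["n_obs"],
            diagnostics=doc.get("diagnostics", {}),
        )


def _ols(X: np.ndarray, y: np.ndarray) -> dict:
    """Least squares with intercept; coefficient t-tests and R²."""
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    df = n - p - 1
    out = {"beta": beta, "resid": resid, "sse": sse, "sst": sst, "r2": r2, "df": df}
    if df > 0:
        sigma2 = sse / df
        xtx_inv = np.linalg.pinv(design.T @ design)
        se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        out["t"] = tvals
        out["p"] = pvals
    else:
        out["t"] = np.full(p + 1, np.nan)
        out["p"] = np.full(p + 1, np.nan)
    return out


def fit_terms(X: pd.DataFrame, y: np.ndarray, columns: list[str]) -> LURModel:
    """Ordinary least squares on a fixed set of buffer-matrix columns."""
    y = np.asarray(y, dtype=float)
    Xd = X[columns].to_numpy(dtype=float)
    res = _ols(Xd, y)
    beta = res["beta"]
    return LURModel(
        terms=[parse_term(c) for c in columns],
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(columns, beta[1:])},
        r2=float(res["r2"]),
        n_obs=len(y),
    )


def stepwise_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_terms: int | None = None,
) -> LURModel:
    """Forward-entry / backward-removal stepwise selection.

    At each entry step the candidate with the largest absolute partial
    correlation with the current residual enters if its partial-F
    (equivalently t-test) p-value is below ``p_enter``; after every
    entry, any selected term whose p-value has risen above ``p_remove``
    is removed (largest p first).  At most one radius per covariate may
    be in the model at a time; a covariate's other radii become
    candidates again if its term is removed.  Ties in |partial
    correlation| break lexicographically on (covariate, radius).

    Because neighbouring radii of one covariate are strongly
    collinear, a greedy first entry can lock in a slightly wrong
    radius; an exchange phase therefore re-examines each selected
    covariate after every entry and swaps its radius for whichever
    alternative most reduces the residual sum of squares.  Under a
    perfect fit, terms whose removal keeps the fit perfect are pruned
    (parsimony rule).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 stations")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove")
    if max_terms is None:
        max_terms = n - 2

    def sse_of(cols: list[str]) -> float:
        return _ols(X[cols].to_numpy(dtype=float), y)["sse"]

    sst = float(((y - y.mean()) ** 2).sum())
    perfect_sse = 1e-10 * sst

    selected: list[str] = []
    for _ in range(200):  # hard cap against entry/removal cycling
        changed = False
        perfect = bool(selected) and sse_of(selected) <= perfect_sse
        # --- forward entry ---
        in_covs = {parse_term(c)[0] for c in selected}
        candidates = [
            c for c in X.columns
            if c not in selected and parse_term(c)[0] not in in_covs
        ]
        if candidates and not perfect and len(selected) < max_terms and n - len(selected) - 2 > 0:
            best = None
            for cand in sorted(candidates, key=parse_term):
                res = _ols(X[selected + [cand]].to_numpy(dtype=float), y)
                t_c = res["t"][-1]
                if not np.isfinite(t_c):
                    continue
                pcorr = abs(t_c) / np.sqrt(t_c**2 + res["df"]) if res["df"] > 0 else 1.0
                p_c = res["p"][-1]
                if best is None or pcorr > best[0] + 1e-12:
                    best = (pcorr, cand, p_c)
            if best is not None and best[2] < p_enter:
                selected.append(best[1])
                changed = True
        # --- radius exchange: re-pick each covariate's radius given the rest ---
        improved = True
        while improved:
            improved = False
            cur_sse = sse_of(selected) if selected else np.inf
            for pos, term in enumerate(list(selected)):
                cov, _ = parse_term(term)
                for alt in X.columns:
                    a_cov, _ = parse_term(alt)
                    if a_cov != cov or alt == term or alt in selected:
                        continue
                    trial = list(selected)
                    trial[pos] = alt
                    s = sse_of(trial)
                    if s < cur_sse * (1.0 - 1e-9):
                        selected[pos] = alt
                        cur_sse = s
                        improved = True
                        changed = True
        # --- backward removal ---
        while len(selected) > 1:
            if sse_of(selected) <= perfect_sse:
                # parsimony under a perfect fit: drop terms that are
                # not needed to keep it perfect
                drop = next(
                    (c for c in selected if sse_of([t for t in selected if t != c]) <= perfect_sse),
                    None,
                )
                if drop is None:
                    break
                selected.remove(drop)
                changed = True
                continue
            res = _ols(X[selected].to_numpy(dtype=float), y)
            pvals = res["p"][1:]
            worst = int(np.argmax(pvals))
            if np.isfinite(pvals[worst]) and pvals[worst] > p_remove:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        logger.warning("stepwise selection admitted no terms; intercept-only model")
        return LURModel(terms=[], intercept=float(y.mean()), coefficients={},
                        r2=0.0, n_obs=n)
    model = fit_terms(X, y, selected)
    model.diagnostics = diagnose(model, X, y)
    return model


def diagnose(model: LURModel, X: pd.DataFrame, y: np.ndarray) -> dict:
    """Diagnostic battery for a fitted model.

    Per-term t-test p-values, variance-inflation factors, the
    Durbin–Watson statistic of residuals in station order, and a
    Shapiro–Wilk residual-normality p-value (reported as missing when
    the residuals are numerically zero).  Flags follow the usual
    screening thresholds: any p > 0.05, any VIF > 10, DW outside
    [1.5, 2.5].
    """
    from statsmodels.stats.stattools import durbin_watson

    y = np.asarray(y, dtype=float)
    cols = model.column_names
    if not cols:
        raise ValueError("cannot diagnose an intercept-only model")
    res = _ols(X[cols].to_numpy(dtype=float), y)
    if res["df"] <= 0:
        raise ValueError("saturated model: zero residual degrees of freedom")
    p_values = {c: float(p) for c, p in zip(cols, res["p"][1:])}

    vifs = {}
    Xd = X[cols].to_numpy(dtype=float)
    for j, c in enumerate(cols):
        if len(cols) == 1:
            vifs[c] = 1.0
            continue
        others = np.delete(Xd, j, axis=1)
        aux = _ols(others, Xd[:, j])
        r2j = aux["r2"]
        vifs[c] = float("inf") if r2j >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2j))

    resid = res["resid"]
    dw = float(durbin_watson(resid))
    if np.max(np.abs(resid)) < 1e-10 or np.ptp(resid) < 1e-12:
        shapiro_p = None  # degenerate residuals: normality not applicable
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)

    return {
        "p_values": p_values,
        "vif": vifs,
        "durbin_watson": dw,
        "shapiro_p": shapiro_p,
        "flag_p": any(p > 0.05 for p in p_values.values()),
        "flag_vif": any(v > 10 for v in vifs.values()),
        "flag_dw": not (1.5 <= dw <= 2.5),
    }


def predict_surface(model: LURModel, surfaces: SurfaceStack) -> Grid:
    """Evaluate the fitted model at every grid cell (the inversion step).

    Buffers are taken around each cell centre exactly as around the
    stations.  Negative predictions are clipped to zero and counted.
    """
    tpl = surfaces.template
    total = np.full(tpl.data.shape, model.intercept, dtype=float)
    by_radius: dict[float, list[str]] = {}
    for cov, radius in model.terms:
        by_radius.setdefault(radius, []).append(cov)
    for radius, covs in by_radius.items():
        buffered = buffer_covariates_grid(surfaces, radius, names=covs)
        for cov in covs:
            total += model.coefficients[term_name(cov, radius)] * buffered[cov]
    negative = int((total < 0).sum())
    if negative:
        logger.warning("clipped %d negative predicted cells to 0", negative)
    return Grid(np.clip(total, 0.0, None), origin=tpl.origin, cell_size=tpl.cell_size)


def zonal_mean(surface: Grid, units: pd.DataFrame) -> pd.Series:
    """Mean of the surface over each unit polygon (cell-centre rule).

    Returns a Series of µg/m³ indexed by ``unit_id``.  A unit whose
    polygon contains no cell centre is an error, named explicitly.
    """
    xc, yc = surface.cell_centers()
    pts = [Point(x, y) for x, y in zip(xc.ravel(), yc.ravel())]
    tree = STRtree(pts)
    values = surface.data.ravel()
    out = {}
    for _, row in units.iterrows():
        idx = tree.query(row["geometry"], predicate="contains")
        if len(idx) == 0:
            raise ValueError(f"unit {row['unit_id']} contains no grid-cell centres")
        out[row["unit_id"]] = float(values[idx].mean())
    return pd.Series(out, name="acp")
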