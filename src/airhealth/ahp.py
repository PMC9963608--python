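"""Analytic-hierarchy-process weighting.

Weights are the principal right eigenvector of a positive reciprocal
pairwise-comparison matrix, normalised to sum one; consistency is
measured by CI = (λmax − n)/(n − 1) and CR = CI/RI with Saaty's random
index, gated at CR < 0.1.  The module also ships the fixed published
weight scheme used by the index stage (criterion weights 0.4 / 0.2 /
0.4 over exposure–response, regional vulnerability and regional
adaptability, with eleven indicator weights underneath).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Saaty's random consistency index by matrix order
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
                7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

CRITERIA = ("exposure_response", "regional_vulnerability", "regional_adaptability")

#: which indicator feeds which criterion
CRITERION_INDICATORS = {
    "exposure_response": ("acp", "pop_density"),
    "regional_vulnerability": (
        "female_density", "under14_density", "over65_density",
        "residential_neighborhoods",
    ),
    "regional_adaptability": (
        "medical_points", "forest_share", "gdp", "tourist_spots", "research_edu",
    ),
}


@dataclass
class WeightScheme:
    """Criterion- and indicator-level weights with consistency statistics.

    Indicator weights within a criterion sum to that criterion's weight
    (within 5e-4, accommodating the rounding of published four-decimal
    weights); criterion weights sum to one.
    """

    criterion_weights: dict[str, float]
    indicator_weights: dict[str, float]
    consistency_ratio: float | None = None

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.criterion_weights.values()) or any(
            w < 0 for w in self.indicator_weights.values()
        ):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.criterion_weights.values()) - 1.0) > 1e-6:
            raise ValueError("criterion weights must sum to 1")
        for crit, inds in CRITERION_INDICATORS.items():
            if crit not in self.criterion_weights:
                continue
            have = [i for i in inds if i in self.indicator_weights]
            if not have:
                continue
            s = sum(self.indicator_weights[i] for i in have)
            if abs(s - self.criterion_weights[crit]) > 5e-4:
                raise ValueError(
                    f"indicator weights under {crit} sum to {s:.4f}, "
                    f"not {self.criterion_weights[crit]:.4f}"
                )

    def indicator_vector(self, criterion: str) -> dict[str, float]:
        return {i: self.indicator_weights[i] for i in CRITERION_INDICATORS[criterion]}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "criterion_weights": self.criterion_weights,
            "indicator_weights": self.indicator_weights,
            "consistency_ratio": self.consistency_ratio,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightScheme":
        doc = json.loads(Path(path).read_text())
        return cls(
            criterion_weights=doc["criterion_weights"],
            indicator_weights=doc["indicator_weights"],
            consistency_ratio=doc.get("consistency_ratio"),
        )


def weights_from_matrix(A) -> tuple[np.ndarray, float, float]:
    """Principal-eigenvector weights of a pairwise-comparison matrix.

    Returns ``(weights, CI, CR)``.  The matrix must be positive and
    reciprocal (A[i,j]·A[j,i] = 1) of order 2..10.  CR is defined as 0
    for n ≤ 2, where a reciprocal matrix is always consistent.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("judgment matrix must be square")
    n = A.shape[0]
    if not (2 <= n <= 10):
        raise ValueError("matrix order must be between 2 and 10")
    if (A <= 0).any():
        raise ValueError("judgment matrix must be positive")
    if np.abs(A * A.T - 1.0).max() > 1e-9:
        raise ValueError("judgment matrix must be reciprocal (A[i,j]*A[j,i] = 1)")

    eigvals, eigvecs = np.linalg.eig(A)
    k = int(np.argmax(eigvals.real))
    lam_max = float(eigvals[k].real)
    w = np.abs(eigvecs[:, k].real)
    w = w / w.sum()

    if n <= 2:
        return w, 0.0, 0.0
    ci = (lam_max - n) / (n - 1)
    cr = ci / RANDOM_INDEX[n]
    return w, float(ci), float(cr)


def consistency_gate(cr: float, threshold: float = 0.1) -> bool:
    """True iff the consistency ratio passes (strict ``cr < threshold``)."""
    if cr < 0:
        raise ValueError("consistency ratio cannot be negative")
    return cr < threshold


def table3_scheme() -> WeightScheme:
    """The published fixed weight scheme of the evaluation system.

    Criterion weights 0.4000 / 0.2000 / 0.4000; indicator weights as
    printed to four decimals (the adaptability indicators sum to
    0.3999, a rounding artifact the invariant tolerance absorbs).
    The expert judgment matrix behind these weights is not public, so
    no consistency ratio is attached.
    """
    return WeightScheme(
        criterion_weights={
            "exposure_response": 0.4000,
            "regional_vulnerability": 0.2000,
            "regional_adaptability": 0.4000,
        },
        indicator_weights={
            "acp": 0.2667,
            "pop_density": 0.1333,
            "female_density": 0.0327,
            "under14_density": 0.0556,
            "over65_density": 0.0790,
            "residential_neighborhoods": 0.0327,
            "medical_points": 0.0737,
            "forest_share": 0.0358,
            "gdp": 0.2060,
            "tourist_spots": 0.0328,
            "research_edu": 0.0516,
        },
        consistency_ratio=None,
    )
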