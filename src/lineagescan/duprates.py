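"""Duplication-rate analysis: time proxies, regression, influence outliers.

Per family, the number of inferred duplications is regressed on a proxy
for the time the family has had to evolve: the root age in MYA from
reconciliation, or the maximum or median root-to-leaf path length of the
gene tree in substitutions per site.  Root-age runs use untransformed
axes; tree-length runs use log(1 + x) on both axes.  Families below the
fitted line are discarded (they duplicate slowly), as are families whose
proxy falls below its 5th percentile (too little divergence for the
inference to be meaningful).  Highly duplicable outliers among the
survivors are ranked by Cook's distance, and the pathway memberships of
the top quartile are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .reconcile import ReconciledFamily
from .tables import AnnotationMap
from .trees import GeneTree

__all__ = [
    "FamilyStats",
    "RegressionFit",
    "time_proxies",
    "fit_regression",
    "filter_candidates",
    "cooks_distance",
    "outlier_pathway_counts",
]

TRANSFORMS = ("identity", "log1p")


@dataclass
class FamilyStats:
    """Per-family duplication statistics used by the outlier analysis."""

    family_id: str
    n_duplications: int
    root_age: float
    max_length: float
    median_length: float
    proxy: float = float("nan")
    residual: float = float("nan")
    leverage: float = float("nan")
    cooks_d: float = float("nan")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of (transformed) duplication counts on a (transformed) proxy."""

    slope: float
    intercept: float
    pearson_r: float
    s2: float  # residual variance, SSE / (n - p)
    n: int
    p: int = 2
    transform_x: str = "identity"
    transform_y: str = "identity"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _apply_transform(values: np.ndarray, tag: str) -> np.ndarray:
    if tag == "identity":
        return values
    if tag == "log1p":
        return np.log1p(values)
    raise ValueError(f"unknown transform {tag!r}; expected one of {TRANSFORMS}")


def time_proxies(
    gene_tree: GeneTree,
    reconciled: ReconciledFamily,
) -> tuple[float, float, float]:
    """(root age MYA, max root-to-leaf length, median root-to-leaf length).

    Path lengths are in substitutions per site over the multiset of
    root-to-leaf paths; the median of an even count is the midpoint of the
    middle pair.
    """
    depths = gene_tree.root_to_leaf_lengths()
    if not depths:
        raise ValueError("gene tree has no leaves")
    return (
        reconciled.root_age,
        float(np.max(depths)),
        float(np.median(depths)),
    )


def fit_regression(
    x: Sequence[float],
    y: Sequence[float],
    transform_x: str = "identity",
    transform_y: str = "identity",
) -> RegressionFit:
    """Ordinary least squares of y on x after the per-axis transforms.

    Pearson's r is computed on the same transformed axes.  Requires at
    least three points and non-constant x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    tx = _apply_transform(x, transform_x)
    ty = _apply_transform(y, transform_y)
    if np.ptp(tx) == 0:
        raise ValueError("x is constant; regression undefined")
    if np.ptp(ty) == 0:
        raise ValueError("y is constant; Pearson r undefined")
    res = stats.linregress(tx, ty)
    resid = ty - (res.intercept + res.slope * tx)
    s2 = float(resid @ resid) / (x.size - 2)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        s2=s2,
        n=int(x.size),
        transform_x=transform_x,
        transform_y=transform_y,
    )


def residuals(
    x: Sequence[float],
    y: Sequence[float],
    fit: RegressionFit,
) -> np.ndarray:
    """Residuals on the fit's transformed axes."""
    tx = _apply_transform(np.asarray(x, dtype=float), fit.transform_x)
    ty = _apply_transform(np.asarray(y, dtype=float), fit.transform_y)
    return ty - fit.predict(tx)


def filter_candidates(
    stats_list: list[FamilyStats],
    fit: RegressionFit,
    pct: float = 5.0,
) -> list[FamilyStats]:
    """Keep fast-duplicating families with enough accumulated divergence.

    Families strictly below the fitted line (negative residual on the
    transformed axes) are dropped first; among the rest, families whose
    active proxy value lies strictly below its ``pct`` th percentile
    (linear-interpolation convention) are dropped.  Input order is
    preserved.
    """
    x = np.array([s.proxy for s in stats_list], dtype=float)
    y = np.array([s.n_duplications for s in stats_list], dtype=float)
    resid = residuals(x, y, fit)
    for s, r in zip(stats_list, resid):
        s.residual = float(r)
    above = [s for s, r in zip(stats_list, resid) if r >= 0]
    if not above:
        raise ValueError("no families above the regression line")
    # (n+1)-position linear interpolation, so with distinct proxies exactly
    # floor(pct/100 * n) survivors fall strictly below the cutoff
    cutoff = float(np.percentile([s.proxy for s in above], pct, method="weibull"))
    survivors = [s for s in above if s.proxy >= cutoff]
    if not survivors:
        raise ValueError("no families survive the percentile filter")
    return survivors


def cooks_distance(
    x: Sequence[float],
    y: Sequence[float],
    fit: RegressionFit,
) -> np.ndarray:
    """Cook's distance of every point under the simple linear fit.

    D_i = e_i^2 h_ii / (p s^2 (1 - h_ii)^2) with h_ii the hat-matrix
    diagonal, p = 2 parameters and s^2 the residual variance; identical to
    the leave-one-out shift in fitted values Σ_j (ŷ_j − ŷ_j(i))² / (p s²).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= fit.p:
        raise ValueError(f"need more than {fit.p} points, got {x.size}")
    tx = _apply_transform(x, fit.transform_x)
    ty = _apply_transform(y, fit.transform_y)
    e = ty - fit.predict(tx)
    sxx = float(np.sum((tx - tx.mean()) ** 2))
    h = 1.0 / x.size + (tx - tx.mean()) ** 2 / sxx
    if fit.s2 <= 0:
        raise ValueError("perfect fit (zero residual variance); Cook's distance undefined")
    return e**2 * h / (fit.p * fit.s2 * (1.0 - h) ** 2)


def outlier_pathway_counts(
    retained: list[FamilyStats],
    annotations: AnnotationMap,
    quartile: float = 0.25,
    kind: str = "pathway",
) -> list[tuple[str, int]]:
    """Pathway membership counts over the top influence quartile.

    Selects the ceil(quartile * n) families with the largest Cook's
    distance (ties broken by family id for reproducibility) and counts how
    many selected families carry each term, sorted by count descending
    then term id.
    """
    if not retained:
        raise ValueError("empty retained family set")
    k = int(np.ceil(quartile * len(retained)))
    ranked = sorted(retained, key=lambda s: (-s.cooks_d, s.family_id))
    top = ranked[:k]
    counts: dict[str, int] = {}
    terms = annotations.terms(kind)
    for fam in top:
        for term in terms.get(fam.family_id, set()):
            counts[term] = counts.get(term, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
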