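"""Selection classification and term over/under-representation testing.

Branches are first classed by their branch-model dN/dS: strictly above 1
is positive (directional/diversifying) selection, strictly between 0 and
0.5 negative (purifying); a dN/dS of exactly 0 or in the band [0.5, 1] is
ignored, as are branches whose dS does not exceed the configured floor
(ratios on near-zero synonymous divergence are unreliable).

For every annotation term a 2x2 table of (positive vs non-positive) x
(annotated vs not) is tested with the two-sided Fisher exact test and the
p-values are corrected by Benjamini-Hochberg FDR and by Bonferroni.  The
observation unit is the non-ignored gene-tree branch, each carrying its
family's annotations; a config switch instead expands every branch into
its mapped species-lineage path and counts path entries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .tables import AnnotationMap, BranchRecord

__all__ = [
    "SelectionClass",
    "ClassifiedBranch",
    "EnrichmentResult",
    "classify_selection",
    "classify_branches",
    "build_contingency",
    "fisher_exact_two_sided",
    "adjust_pvalues",
    "enrichment_results",
    "enrichment_table",
]


class SelectionClass(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    IGNORED = "ignored"


@dataclass(frozen=True)
class ClassifiedBranch:
    """A branch record with its selection class and weight.

    ``weight`` is 1 for branch-unit counting; under lineage-unit counting
    it is the number of species-tree lineages the branch maps onto.
    """

    record: BranchRecord
    selection: SelectionClass
    weight: int = 1


def classify_selection(
    dnds: float | None,
    ds: float | None,
    config: RunConfig,
) -> SelectionClass:
    """Class of a single branch from its dN/dS and dS.

    Missing dN/dS or dS, dS at or below the floor, dN/dS of exactly 0 and
    dN/dS in [negative threshold, positive threshold] all yield IGNORED.
    """
    if dnds is None or ds is None:
        return SelectionClass.IGNORED
    if dnds < 0 or ds < 0:
        raise ValueError(f"dN/dS and dS must be non-negative, got {dnds}, {ds}")
    if ds <= config.ds_floor:
        return SelectionClass.IGNORED
    if dnds > config.dnds_positive:
        return SelectionClass.POSITIVE
    if 0 < dnds < config.dnds_negative:
        return SelectionClass.NEGATIVE
    return SelectionClass.IGNORED


def classify_branches(
    branches: list[BranchRecord],
    config: RunConfig,
    lineage_weights: dict[tuple[str, str], int] | None = None,
) -> list[ClassifiedBranch]:
    """Classify every branch; IGNORED branches are retained but weightless
    in contingency tables.  ``lineage_weights`` maps (family, branch) to the
    length of the branch's species-lineage path for lineage-unit counting.
    """
    out: list[ClassifiedBranch] = []
    for rec in branches:
        cls = classify_selection(rec.dnds, rec.ds, config)
        weight = 1
        if config.enrichment_unit == "lineage" and lineage_weights is not None:
            weight = lineage_weights.get((rec.family_id, rec.branch_id), 1)
        out.append(ClassifiedBranch(rec, cls, weight))
    return out


@dataclass
class EnrichmentResult:
    """Fisher-test outcome for one annotation term."""

    term_id: str
    a: int  # positive & annotated
    b: int  # positive & not annotated
    c: int  # non-positive & annotated
    d: int  # non-positive & not annotated
    p: float
    q_fdr: float = float("nan")
    p_bonferroni: float = float("nan")

    @property
    def pct_mapped_positive(self) -> float:
        """Percent of term-annotated observations that are positive (100*a/(a+c))."""
        return 100.0 * self.a / (self.a + self.c) if self.a + self.c else 0.0

    @property
    def pct_positive_mapped(self) -> float:
        """Percent of positive observations annotated with the term (100*a/(a+b))."""
        return 100.0 * self.a / (self.a + self.b) if self.a + self.b else 0.0

    @property
    def direction(self) -> str:
        """'over' when positives are annotated more often than non-positives."""
        rate_pos = self.a / (self.a + self.b) if self.a + self.b else 0.0
        rate_neg = self.c / (self.c + self.d) if self.c + self.d else 0.0
        return "over" if rate_pos >= rate_neg else "under"


def build_contingency(
    branches: list[ClassifiedBranch],
    term: str,
    annotations: AnnotationMap,
    kind: str = "pathway",
) -> tuple[int, int, int, int]:
    """Counts (a, b, c, d) for one term over all non-ignored observations.

    a = positive & annotated, b = positive & not, c = non-positive &
    annotated, d = non-positive & not.  "Annotated" means the branch's
    family carries the term.  Raises if the term is absent from the
    annotation universe.
    """
    if term not in annotations.universe(kind):
        raise KeyError(f"term {term!r} not in the {kind} annotation universe")
    terms = annotations.terms(kind)
    a = b = c = d = 0
    for cb in branches:
        if cb.selection is SelectionClass.IGNORED:
            continue
        annotated = term in terms.get(cb.record.family_id, set())
        if cb.selection is SelectionClass.POSITIVE:
            if annotated:
                a += cb.weight
            else:
                b += cb.weight
        else:
            if annotated:
                c += cb.weight
            else:
                d += cb.weight
    return a, b, c, d


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric probabilities no greater than that of the observed
    table (the probability-mass rule).  Probabilities share the common
    denominator C(n, a+c), so inclusion is decided by exact integer
    comparison of numerators — ties are handled exactly.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError(f"counts must be non-negative, got {(a, b, c, d)}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty contingency table")
    r1 = a + b  # positive-row margin
    c1 = a + c  # annotated-column margin
    num_obs = comb(r1, a) * comb(n - r1, c1 - a)
    total = 0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        num = comb(r1, x) * comb(n - r1, c1 - x)
        if num <= num_obs:
            total += num
    # Fraction -> float gives the correctly rounded quotient even when the
    # integers overflow a double
    return float(Fraction(total, comb(n, c1)))


def adjust_pvalues(ps, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment: 'fdr_bh' (step-up) or 'bonferroni'."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("empty p-value list")
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(ps, method=method)[1]


def enrichment_results(
    branches: list[ClassifiedBranch],
    annotations: AnnotationMap,
    kind: str = "pathway",
) -> list[EnrichmentResult]:
    """Fisher-test every term in the universe and attach corrections."""
    universe = sorted(annotations.universe(kind))
    if not universe:
        raise ValueError(f"no {kind} annotations present")
    results = []
    for term in universe:
        a, b, c, d = build_contingency(branches, term, annotations, kind)
        results.append(
            EnrichmentResult(term, a, b, c, d, p=fisher_exact_two_sided(a, b, c, d))
        )
    ps = [r.p for r in results]
    for r, q, pb in zip(results, adjust_pvalues(ps, "fdr_bh"),
                        adjust_pvalues(ps, "bonferroni")):
        r.q_fdr = float(q)
        r.p_bonferroni = float(pb)
    return results


def enrichment_table(
    results: list[EnrichmentResult],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Split significant terms into ranked over/under-represented tables.

    Rows are kept when their BH FDR q is below ``alpha``.  The
    over-represented table is sorted by the percent of positive
    observations mapped to the term, descending; the under-represented
    table by the same column ascending.  Bonferroni significance is left
    to the caller to flag (non-significant values are printed bold in the
    source tables this mirrors).
    """
    if not results:
        raise ValueError("no enrichment results to tabulate")
    kept = [r for r in results if r.q_fdr < alpha]
    over = sorted(
        (r for r in kept if r.direction == "over"),
        key=lambda r: (-r.pct_positive_mapped, r.term_id),
    )
    under = sorted(
        (r for r in kept if r.direction == "under"),
        key=lambda r: (r.pct_positive_mapped, r.term_id),
    )
    return over, under
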