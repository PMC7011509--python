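"""Structural context of substitutions on selected lineages.

Every structure-aligned site carries a DSSP 8-state secondary-structure
code (H, G, I, E, B, T, S, C) and a burial bin: exposed when its relative
solvent accessibility (absolute accessible area over the residue's
maximum) is strictly above 0.20, buried otherwise.  For branches under
positive (dN/dS > 1) and negative (dN/dS < 0.5) selection separately, the
category-by-bin composition of substituted site occurrences is compared
with the composition of all site occurrences on the same branches; a site
substituted on k branches contributes k occurrences, and each branch
contributes all of its family's eligible sites to the background.

Significance per report cell comes from a two-tailed bootstrap null:
replicate datasets of the observed substituted size are drawn from the
all-sites category distribution, and the cell's p-value is twice the
smaller tail (add-one smoothed, capped at 1), judged against the
multiple-comparison-corrected threshold alpha / m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .tables import AMINO_ACIDS, BranchRecord, SiteRecord

__all__ = [
    "DSSP_ORDER",
    "REPORT_ROWS",
    "Profile",
    "StructureCell",
    "relative_solvent_accessibility",
    "filter_sites",
    "classify_lineages",
    "substitution_profile",
    "bootstrap_pvalues",
    "corrected_threshold",
    "structure_report",
]

DSSP_ORDER = ("H", "G", "I", "E", "B", "T", "S", "C")
DSSP_NAMES = {
    "H": "alpha-Helix", "G": "3_10-Helix", "I": "pi-Helix", "E": "beta-Sheet",
    "B": "beta-Bridge", "T": "Turn", "S": "Bend", "C": "Coil",
}
BINS = ("exposed", "buried")
#: Aggregate helix class: all three DSSP helix codes.
HELIX_CODES = ("H", "G", "I")

#: The 29 report rows: the aggregate helix class, the eight exclusive
#: secondary-structure classes (each with total/exposed/buried), and the
#: two overall burial rows.
REPORT_ROWS: list[tuple[str, str]] = (
    [("Helix", "total"), ("Helix", "exposed"), ("Helix", "buried")]
    + [(code, part) for code in DSSP_ORDER
       for part in ("total", "exposed", "buried")]
    + [("All", "buried"), ("All", "exposed")]
)


def relative_solvent_accessibility(
    asa: float,
    residue: str,
    max_table: dict[str, float],
    rsa_cutoff: float = 0.20,
) -> tuple[float, str]:
    """RSA ratio and burial bin for one site.

    The bin is ``exposed`` when rsa is strictly greater than the cutoff,
    ``buried`` otherwise (a site exactly at the cutoff is buried).
    """
    if asa < 0:
        raise ValueError(f"accessibility must be non-negative, got {asa}")
    if residue not in max_table:
        raise KeyError(f"residue {residue!r} missing from the max-ASA table")
    rsa = asa / max_table[residue]
    return rsa, ("exposed" if rsa > rsa_cutoff else "buried")


def filter_sites(
    records: list[SiteRecord],
) -> tuple[list[SiteRecord], set[tuple[str, int]]]:
    """Drop ineligible sites; return (eligible records, dropped keys).

    A family flagged ``membrane`` or ``multimer`` on any site loses all of
    its sites; individually, ``unaligned`` sites and sites whose residue is
    not one of the 20 standard amino acids are dropped.
    """
    excluded_families = {
        r.family_id for r in records if r.flags & {"membrane", "multimer"}
    }
    eligible: list[SiteRecord] = []
    dropped: set[tuple[str, int]] = set()
    for r in records:
        if (
            r.family_id in excluded_families
            or "unaligned" in r.flags
            or r.residue not in AMINO_ACIDS
        ):
            dropped.add((r.family_id, r.site_index))
        else:
            eligible.append(r)
    return eligible, dropped


def classify_lineages(
    branches: list[BranchRecord],
    config: RunConfig,
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """(positive, negative) sets of (family, branch) ids; others ignored."""
    from .enrich import SelectionClass, classify_selection

    positive: set[tuple[str, str]] = set()
    negative: set[tuple[str, str]] = set()
    for rec in branches:
        cls = classify_selection(rec.dnds, rec.ds, config)
        if cls is SelectionClass.POSITIVE:
            positive.add((rec.family_id, rec.branch_id))
        elif cls is SelectionClass.NEGATIVE:
            negative.add((rec.family_id, rec.branch_id))
    return positive, negative


@dataclass
class Profile:
    """Substituted-vs-all site-occurrence counts over category x bin cells."""

    selection: str
    sub_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    all_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_sub(self) -> int:
        return sum(self.sub_counts.values())

    @property
    def n_all(self) -> int:
        return sum(self.all_counts.values())

    @staticmethod
    def _row_cells(row: tuple[str, str]) -> list[tuple[str, str]]:
        label, part = row
        if label == "All":
            return [(code, part) for code in DSSP_ORDER]
        codes = HELIX_CODES if label == "Helix" else (label,)
        bins = BINS if part == "total" else (part,)
        return [(code, b) for code in codes for b in bins]

    def row_count(self, row: tuple[str, str], which: str) -> int:
        counts = self.sub_counts if which == "sub" else self.all_counts
        return sum(counts.get(cell, 0) for cell in self._row_cells(row))

    def percent(self, row: tuple[str, str], which: str) -> float:
        total = self.n_sub if which == "sub" else self.n_all
        if total == 0:
            return float("nan")
        return 100.0 * self.row_count(row, which) / total


def substitution_profile(
    sites: list[SiteRecord],
    branches: list[BranchRecord],
    lineage_set: set[tuple[str, str]],
    max_asa: dict[str, float],
    config: RunConfig,
    selection: str = "",
    known_dropped: set[tuple[str, int]] | None = None,
) -> Profile:
    """Profile of substituted vs all site occurrences on a branch set.

    ``sites`` are the eligible (already filtered) records.  A substituted
    index referencing a site in ``known_dropped`` is skipped (the site was
    excluded from the analysis); one referencing no known site at all is
    an error.
    """
    known_dropped = known_dropped or set()
    by_family: dict[str, dict[int, tuple[str, str]]] = {}
    for r in sites:
        _, burial = relative_solvent_accessibility(
            r.asa_A2, r.residue, max_asa, config.rsa_cutoff
        )
        by_family.setdefault(r.family_id, {})[r.site_index] = (r.dssp, burial)

    profile = Profile(selection=selection)
    for rec in branches:
        if (rec.family_id, rec.branch_id) not in lineage_set:
            continue
        fam_sites = by_family.get(rec.family_id, {})
        for cell in fam_sites.values():
            profile.all_counts[cell] = profile.all_counts.get(cell, 0) + 1
        for idx in rec.substituted_sites:
            cell = fam_sites.get(idx)
            if cell is None:
                if (rec.family_id, idx) in known_dropped:
                    continue
                raise KeyError(
                    f"substituted site {idx} of family {rec.family_id!r} has "
                    "no site record"
                )
            profile.sub_counts[cell] = profile.sub_counts.get(cell, 0) + 1
    return profile


def bootstrap_pvalues(
    profile: Profile,
    n_reps: int = 20_000,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[str, str], float]:
    """Two-tailed bootstrap p-value for every report row of a profile.

    Replicates of size ``n_sub`` are drawn from the all-sites category x
    bin distribution; for each row the p-value is
    ``2 * min(P(X* <= obs), P(X* >= obs))`` with add-one smoothing
    ``(1 + count) / (1 + n_reps)``, capped at 1.  Deterministic given the
    seed.
    """
    if profile.n_sub < 1:
        raise ValueError("profile has no substituted sites")
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cells = [(code, b) for code in DSSP_ORDER for b in BINS]
    p_all = np.array(
        [profile.all_counts.get(c, 0) for c in cells], dtype=float
    )
    p_all /= p_all.sum()
    reps = rng.multinomial(profile.n_sub, p_all, size=n_reps)  # (n_reps, 16)

    cell_index = {c: i for i, c in enumerate(cells)}
    pvals: dict[tuple[str, str], float] = {}
    for row in REPORT_ROWS:
        members = [cell_index[c] for c in Profile._row_cells(row)]
        sim = reps[:, members].sum(axis=1)
        obs = profile.row_count(row, "sub")
        lo = (1 + int(np.count_nonzero(sim <= obs))) / (1 + n_reps)
        hi = (1 + int(np.count_nonzero(sim >= obs))) / (1 + n_reps)
        pvals[row] = min(1.0, 2.0 * min(lo, hi))
    return pvals


def corrected_threshold(alpha: float = 0.05, m: int = 30) -> float:
    """Per-cell significance threshold alpha / m for the structural tests."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


@dataclass(frozen=True)
class StructureCell:
    """One report row for one selection class."""

    selection: str
    label: str
    part: str
    substituted_pct: float
    all_pct: float
    p: float
    flagged: bool


def structure_report(
    profiles: list[Profile],
    pvalues: list[dict[tuple[str, str], float]],
    alpha: float = 0.05,
    m: int = 30,
) -> list[StructureCell]:
    """Assemble the per-class report with corrected significance flags."""
    threshold = corrected_threshold(alpha, m)
    out: list[StructureCell] = []
    for profile, pv in zip(profiles, pvalues):
        for row in REPORT_ROWS:
            p = pv[row]
            out.append(
                StructureCell(
                    selection=profile.selection,
                    label=row[0],
                    part=row[1],
                    substituted_pct=profile.percent(row, "sub"),
                    all_pct=profile.percent(row, "all"),
                    p=p,
                    flagged=p < threshold,
                )
            )
    return out
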