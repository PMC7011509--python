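"""Named validation experiments run by the test suite and the results script.

Each experiment is a pure function of a seed.  They wire the synthetic
generators to the analysis stages and return summary numbers:

* planted-enrichment recovery (odds 4, 3 enriched pathways of 50,
  500 families),
* Fisher null calibration under planted odds 1,
* bootstrap null calibration under buried relative risk 1,
* planted buried-substitution deficit (relative risk 0.7, 20 000 sites),
* fast-duplicator recovery (10x duplication rate) via Cook's distance.

Design notes (power analyses, calibration caveats) live in the methods
document; the sizes used here are fixed study conditions, not knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import duprates, enrich, structure
from .config import RunConfig
from .reconcile import lca_reconcile
from .simulate import (
    SimSpec,
    SiteSpec,
    enrichment_recovery_spec,
    simulate_dataset,
    simulate_gene_tree,
    simulate_site_table,
    simulate_species_tree,
)
from .tables import BranchRecord, default_max_asa

__all__ = [
    "enrichment_recovery",
    "enrichment_null_fpr",
    "structure_null_fpr",
    "structure_planted_deficit",
    "duplication_outlier_recovery",
]


def enrichment_null_spec(seed: int) -> SimSpec:
    """Null-calibration dataset: odds 1, five pathways at prevalence 0.5.

    Prevalence 0.5 maximises the contingency-table margins, minimising the
    discreteness (hence conservativeness) of the exact test; five terms per
    dataset keep the total test count low enough that Monte-Carlo
    resolution exceeds the test's small inherent conservativeness.
    """
    return SimSpec(
        n_families=400,
        n_species=5,
        dup_rate=0.0002,
        loss_rate=0.0,
        n_pathways=5,
        pathway_prob=0.5,
        enrichment_odds=1.0,
        seed=seed,
    )


def calibration_site_spec(rr_buried: float = 1.0) -> SiteSpec:
    """Site spec for bootstrap calibration: uniform categories and burial,
    so every report row has ample expected counts."""
    return SiteSpec(
        category_freqs={c: 0.125 for c in "HGIEBTSC"},
        buried_prob={c: 0.5 for c in "HGIEBTSC"},
        baseline_sub_prob=0.05,
        rr_buried=rr_buried,
    )


@dataclass
class RecoveryResult:
    planted: tuple[str, ...]
    recovered: tuple[str, ...]
    q_values: dict[str, float]

    @property
    def all_recovered(self) -> bool:
        return set(self.planted) <= set(self.recovered)


def enrichment_recovery(seed: int) -> RecoveryResult:
    """Planted pathways (odds 4) must reach the over-represented table at
    BH FDR < 0.05."""
    spec = enrichment_recovery_spec(seed)
    dataset = simulate_dataset(spec)
    config = RunConfig(seed=seed)
    classified = enrich.classify_branches(dataset.branch_records, config)
    results = enrich.enrichment_results(classified, dataset.annotations)
    over, _ = enrich.enrichment_table(results, config.alpha)
    return RecoveryResult(
        planted=spec.enriched_pathways,
        recovered=tuple(r.term_id for r in over),
        q_values={r.term_id: r.q_fdr for r in results
                  if r.term_id in spec.enriched_pathways},
    )


def enrichment_null_fpr(
    seed: int, n_datasets: int = 200, alpha: float = 0.05
) -> tuple[float, int]:
    """Fraction of uncorrected Fisher p-values below alpha under odds 1.

    Returns (false-positive rate, number of tests).
    """
    root = np.random.default_rng(seed)
    dataset_seeds = root.integers(0, 2**31 - 1, size=n_datasets)
    hits = total = 0
    for ds_seed in dataset_seeds:
        spec = enrichment_null_spec(int(ds_seed))
        dataset = simulate_dataset(spec)
        config = RunConfig(seed=int(ds_seed))
        classified = enrich.classify_branches(dataset.branch_records, config)
        results = enrich.enrichment_results(classified, dataset.annotations)
        hits += sum(r.p < alpha for r in results)
        total += len(results)
    return hits / total, total


def _one_branch_profile(
    spec: SiteSpec, n_sites: int, seed: int, config: RunConfig
) -> structure.Profile:
    sites, subs = simulate_site_table(
        spec, n_sites, ["b1"], seed=seed, family_id="fam"
    )
    record = BranchRecord(
        family_id="fam", branch_id="b1", parent_id="root", child_id="b1",
        length=0.1, dn=None, ds=0.5, dnds=2.0,
        substituted_sites=tuple(subs["b1"]),
    )
    return structure.substitution_profile(
        sites, [record], {("fam", "b1")}, default_max_asa(), config,
        selection="positive",
    )


def structure_null_fpr(
    seed: int,
    n_datasets: int = 232,
    n_sites: int = 16_000,
    n_reps: int = 2_000,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Bootstrap false-positive rate under buried relative risk 1.

    Each dataset contributes one designated report row (rotating over all
    29 rows), so the 232 tests are independent across datasets; returns
    (false-positive rate, number of tests).
    """
    root = np.random.default_rng(seed)
    config = RunConfig(seed=seed)
    spec = calibration_site_spec(rr_buried=1.0)
    hits = 0
    for i in range(n_datasets):
        ds_seed = int(root.integers(0, 2**31 - 1))
        profile = _one_branch_profile(spec, n_sites, ds_seed, config)
        pvals = structure.bootstrap_pvalues(profile, n_reps, ds_seed + 1)
        row = structure.REPORT_ROWS[i % len(structure.REPORT_ROWS)]
        hits += pvals[row] < alpha
    return hits / n_datasets, n_datasets


def structure_pooled_null_fpr(
    seed: int,
    n_datasets: int = 200,
    n_sites: int = 16_000,
    n_reps: int = 2_000,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Pooled-over-all-rows bootstrap false-positive rate under risk 1.

    Pooling every report row of every dataset exposes the method's
    built-in conservativeness (the substituted sample is drawn from the
    same sites as its baseline), documented in the methods note.
    """
    root = np.random.default_rng(seed)
    config = RunConfig(seed=seed)
    spec = calibration_site_spec(rr_buried=1.0)
    hits = total = 0
    for _ in range(n_datasets):
        ds_seed = int(root.integers(0, 2**31 - 1))
        profile = _one_branch_profile(spec, n_sites, ds_seed, config)
        pvals = structure.bootstrap_pvalues(profile, n_reps, ds_seed + 1)
        hits += sum(p < alpha for p in pvals.values())
        total += len(pvals)
    return hits / total, total


@dataclass
class DeficitResult:
    substituted_pct: float
    all_pct: float
    p: float
    flagged: bool


def structure_planted_deficit(
    seed: int,
    rr_buried: float = 0.7,
    n_sites: int = 20_000,
    n_reps: int = 20_000,
    alpha: float = 0.05,
    m: int = 30,
) -> DeficitResult:
    """Planted buried-substitution deficit must be flagged at alpha/m.

    Uses the default (empirically shaped) site spec with the buried
    relative risk lowered to ``rr_buried``.
    """
    config = RunConfig(seed=seed)
    spec = SiteSpec(rr_buried=rr_buried)
    profile = _one_branch_profile(spec, n_sites, seed, config)
    pvals = structure.bootstrap_pvalues(profile, n_reps, seed + 1)
    row = ("All", "buried")
    p = pvals[row]
    return DeficitResult(
        substituted_pct=profile.percent(row, "sub"),
        all_pct=profile.percent(row, "all"),
        p=p,
        flagged=p < structure.corrected_threshold(alpha, m),
    )


@dataclass
class OutlierResult:
    fraction_fast_top_quartile: float
    fraction_fast_retained: float
    n_retained: int

    @property
    def representation_ratio(self) -> float:
        if self.fraction_fast_retained == 0:
            return float("inf")
        return self.fraction_fast_top_quartile / self.fraction_fast_retained


def duplication_outlier_recovery(
    seed: int,
    n_families: int = 100,
    fast_fraction: float = 0.10,
    base_rate: float = 0.002,
    fast_multiplier: float = 10.0,
) -> OutlierResult:
    """Families with a 10x duplication rate must crowd the top influence
    quartile of the duplication-count vs root-age regression.

    The species tree spans 100 MY so the fast birth process stays at a
    tractable family size; families originate at random internal nodes to
    spread root ages.
    """
    rng = np.random.default_rng(seed)
    stree = simulate_species_tree(16, 100.0, rng)
    internal = [n.label for n in stree.nodes if not n.is_leaf]
    n_fast = int(round(fast_fraction * n_families))
    stats_list: list[duprates.FamilyStats] = []
    fast_ids: set[str] = set()
    for i in range(n_families):
        fid = f"fam{i:03d}"
        rate = base_rate * fast_multiplier if i < n_fast else base_rate
        if i < n_fast:
            fast_ids.add(fid)
        origin = internal[int(rng.integers(len(internal)))]
        fam = simulate_gene_tree(
            stree, rate, 0.0, rng, origin=origin, family_id=fid
        )
        if fam.gene_tree is None or len(fam.gene_tree.leaves) < 2:
            continue
        rec = lca_reconcile(fam.gene_tree, stree, fid)
        age, max_len, med_len = duprates.time_proxies(fam.gene_tree, rec)
        stats_list.append(
            duprates.FamilyStats(
                family_id=fid,
                n_duplications=rec.duplication_count,
                root_age=age,
                max_length=max_len,
                median_length=med_len,
                proxy=age,
            )
        )
    x = [s.proxy for s in stats_list]
    y = [s.n_duplications for s in stats_list]
    fit = duprates.fit_regression(x, y)
    retained = duprates.filter_candidates(stats_list, fit)
    rx = np.array([s.proxy for s in retained])
    ry = np.array([s.n_duplications for s in retained])
    for s, d in zip(retained, duprates.cooks_distance(rx, ry, fit)):
        s.cooks_d = float(d)
    k = int(np.ceil(0.25 * len(retained)))
    top = sorted(retained, key=lambda s: (-s.cooks_d, s.family_id))[:k]
    return OutlierResult(
        fraction_fast_top_quartile=float(
            np.mean([s.family_id in fast_ids for s in top])
        ),
        fraction_fast_retained=float(
            np.mean([s.family_id in fast_ids for s in retained])
        ),
        n_retained=len(retained),
    )
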