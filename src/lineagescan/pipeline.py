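"""Stage orchestration over a working directory of standard-format files.

Each stage reads the files earlier stages wrote into the run directory and
writes its own outputs there.  Every output carries the configuration hash
and seed in its ``##`` metadata header, and a stage re-run with the same
config and seed reproduces its files byte-for-byte.

Files in a run directory:

* ``species_tree.nwk`` — calibrated species tree (lengths in MY)
* ``gene_trees.tsv`` — one Newick gene tree per family
* ``branches.tsv``, ``annotations.tsv``, ``sites.tsv``, ``max_asa.tsv``
* ``truth.json`` — generator truth (simulate stage only)
* stage outputs: ``reconciled.tsv``, ``branch_lineages.tsv``,
  ``enrichment_{pathway,domain}_{over,under}.tsv``,
  ``family_stats_<proxy>.tsv``, ``pathway_counts_<proxy>.tsv``,
  ``regression_<proxy>.json``, ``structure_profile.tsv``,
  ``top_lineages.tsv``
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import duprates, enrich, reconcile, structure
from .config import RunConfig
from .simulate import SimSpec, SimulatedDataset, simulate_dataset
from .tables import (
    default_max_asa,
    load_annotations,
    load_branches,
    load_max_asa,
    load_sites,
    read_table,
    write_table,
)
from .trees import GeneTree, SpeciesTree

__all__ = [
    "write_simulation",
    "run_simulate",
    "run_reconcile",
    "run_enrich",
    "run_duprates",
    "run_structure",
    "run_report",
]

log = logging.getLogger("lineagescan")

PROXIES = {
    "root_age": ("identity", "identity"),
    "max_length": ("log1p", "log1p"),
    "median_length": ("log1p", "log1p"),
}


def _meta(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# simulate


def write_simulation(
    dataset: SimulatedDataset, outdir: str | Path, config: RunConfig
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _meta(config)

    with open(outdir / "species_tree.nwk", "w", encoding="utf-8") as fh:
        fh.write(dataset.species_tree.to_newick() + "\n")

    write_table(
        outdir / "gene_trees.tsv",
        ["family_id", "newick"],
        [
            (f.family_id, f.gene_tree.to_newick())
            for f in dataset.families
            if f.gene_tree is not None and len(f.gene_tree.leaves) >= 2
        ],
        meta,
    )
    write_table(
        outdir / "branches.tsv",
        ["family_id", "branch_id", "parent_id", "child_id", "length",
         "dN", "dS", "dnds", "substituted_sites"],
        [
            (
                r.family_id, r.branch_id, r.parent_id, r.child_id,
                _fmt(r.length),
                None if r.dn is None else _fmt(r.dn),
                None if r.ds is None else _fmt(r.ds),
                None if r.dnds is None else _fmt(r.dnds),
                ",".join(map(str, r.substituted_sites)) or None,
            )
            for r in dataset.branch_records
        ],
        meta,
    )
    ann_rows = []
    for kind in ("pathway", "domain"):
        for family_id in sorted(dataset.annotations.terms(kind)):
            for term in sorted(dataset.annotations.terms(kind)[family_id]):
                ann_rows.append((family_id, kind, term))
    write_table(outdir / "annotations.tsv",
                ["family_id", "kind", "term_id"], ann_rows, meta)
    write_table(
        outdir / "sites.tsv",
        ["family_id", "site_index", "residue", "asa_A2", "dssp", "flags"],
        [
            (r.family_id, r.site_index, r.residue, _fmt(r.asa_A2), r.dssp,
             ",".join(sorted(r.flags)) or None)
            for r in dataset.site_records
        ],
        meta,
    )
    write_table(
        outdir / "max_asa.tsv",
        ["residue", "max_asa_A2"],
        sorted(default_max_asa().items()),
        {**meta, "source": "Tien et al. 2013 theoretical"},
    )
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump({**meta, **dataset.truth}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_simulate(
    outdir: str | Path, config: RunConfig, spec: SimSpec | None = None
) -> SimulatedDataset:
    spec = spec or SimSpec(seed=config.seed)
    if spec.seed != config.seed:
        spec = SimSpec(**{**spec.__dict__, "seed": config.seed})
    dataset = simulate_dataset(spec)
    write_simulation(dataset, outdir, config)
    return dataset


# ---------------------------------------------------------------------------
# shared loading


def _load_trees(outdir: Path) -> tuple[SpeciesTree, dict[str, GeneTree]]:
    stree_path = outdir / "species_tree.nwk"
    if not stree_path.exists():
        raise FileNotFoundError(f"missing input {stree_path}")
    stree = SpeciesTree.from_newick(stree_path.read_text(encoding="utf-8"))
    rows, _ = read_table(outdir / "gene_trees.tsv")
    gtrees = {
        row["family_id"]: GeneTree.from_newick(row["newick"]) for row in rows
    }
    if not gtrees:
        raise ValueError("no families in gene_trees.tsv")
    return stree, gtrees


def _reconcile_all(
    stree: SpeciesTree, gtrees: dict[str, GeneTree]
) -> dict[str, reconcile.ReconciledFamily]:
    return {
        fid: reconcile.lca_reconcile(gt, stree, family_id=fid)
        for fid, gt in sorted(gtrees.items())
    }


# ---------------------------------------------------------------------------
# reconcile


def run_reconcile(outdir: str | Path, config: RunConfig) -> None:
    outdir = Path(outdir)
    stree, gtrees = _load_trees(outdir)
    recon = _reconcile_all(stree, gtrees)
    meta = _meta(config)

    rows = []
    for fid, rec in recon.items():
        for label in sorted(rec.mapping):
            rows.append(
                (fid, label, rec.mapping[label],
                 int(label in rec.duplication_nodes))
            )
    write_table(outdir / "reconciled.tsv",
                ["family_id", "node_id", "mapped_taxon", "is_duplication"],
                rows, meta)

    lin_rows = []
    for fid, rec in recon.items():
        for node in rec.gene_tree.branches():
            path = reconcile.map_branch_lineage(node, rec)
            start = rec.mapping[node.parent.label]
            end = rec.mapping[node.label]
            lin_rows.append((fid, node.label, start, end, ",".join(path)))
    write_table(outdir / "branch_lineages.tsv",
                ["family_id", "branch_id", "start_taxon", "end_taxon",
                 "lineage_list"],
                lin_rows, meta)


# ---------------------------------------------------------------------------
# enrich


def _lineage_weights(
    stree: SpeciesTree, gtrees: dict[str, GeneTree]
) -> dict[tuple[str, str], int]:
    weights: dict[tuple[str, str], int] = {}
    for fid, rec in _reconcile_all(stree, gtrees).items():
        for node in rec.gene_tree.branches():
            weights[(fid, node.label)] = len(
                reconcile.map_branch_lineage(node, rec)
            )
    return weights


def run_enrich(outdir: str | Path, config: RunConfig) -> None:
    outdir = Path(outdir)
    branches_path = outdir / "branches.tsv"
    ann_path = outdir / "annotations.tsv"
    for p in (branches_path, ann_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input {p}")
    branches = load_branches(branches_path)
    annotations = load_annotations(ann_path)
    weights = None
    if config.enrichment_unit == "lineage":
        weights = _lineage_weights(*_load_trees(outdir))
    classified = enrich.classify_branches(branches, config, weights)
    meta = {**_meta(config), "unit": config.enrichment_unit}

    columns = ["term_id", "a", "b", "c", "d",
               "pct_mapped_positive", "pct_positive_mapped",
               "p", "q_fdr", "p_bonferroni", "bonferroni_significant"]
    for kind in ("pathway", "domain"):
        if not annotations.universe(kind):
            log.warning("no %s annotations; skipping", kind)
            continue
        results = enrich.enrichment_results(classified, annotations, kind)
        over, under = enrich.enrichment_table(results, config.alpha)
        for name, table in (("over", over), ("under", under)):
            write_table(
                outdir / f"enrichment_{kind}_{name}.tsv",
                columns,
                [
                    (r.term_id, r.a, r.b, r.c, r.d,
                     f"{r.pct_mapped_positive:.4f}",
                     f"{r.pct_positive_mapped:.4f}",
                     _fmt(r.p), _fmt(r.q_fdr), _fmt(r.p_bonferroni),
                     int(r.p_bonferroni < config.alpha))
                    for r in table
                ],
                meta,
            )


# ---------------------------------------------------------------------------
# duprates


def run_duprates(
    outdir: str | Path, config: RunConfig, proxies: tuple[str, ...] = None
) -> None:
    outdir = Path(outdir)
    stree, gtrees = _load_trees(outdir)
    annotations = load_annotations(outdir / "annotations.tsv")
    recon = _reconcile_all(stree, gtrees)
    meta = _meta(config)

    base_stats: list[duprates.FamilyStats] = []
    for fid, rec in recon.items():
        age, max_len, med_len = duprates.time_proxies(rec.gene_tree, rec)
        base_stats.append(
            duprates.FamilyStats(
                family_id=fid,
                n_duplications=rec.duplication_count,
                root_age=age,
                max_length=max_len,
                median_length=med_len,
            )
        )

    for proxy in proxies or tuple(PROXIES):
        tx, ty = PROXIES[proxy]
        stats_list = []
        for s in base_stats:
            value = getattr(
                s, {"root_age": "root_age", "max_length": "max_length",
                    "median_length": "median_length"}[proxy]
            )
            stats_list.append(
                duprates.FamilyStats(
                    family_id=s.family_id,
                    n_duplications=s.n_duplications,
                    root_age=s.root_age,
                    max_length=s.max_length,
                    median_length=s.median_length,
                    proxy=value,
                )
            )
        x = [s.proxy for s in stats_list]
        y = [s.n_duplications for s in stats_list]
        fit = duprates.fit_regression(x, y, tx, ty)
        retained = duprates.filter_candidates(stats_list, fit)
        rx = np.array([s.proxy for s in retained])
        ry = np.array([s.n_duplications for s in retained])
        dvals = duprates.cooks_distance(rx, ry, fit)
        for s, d in zip(retained, dvals):
            s.cooks_d = float(d)
        ranked = sorted(retained, key=lambda s: (-s.cooks_d, s.family_id))
        write_table(
            outdir / f"family_stats_{proxy}.tsv",
            ["family_id", "cooks_distance", "proxy_value", "n_duplications"],
            [(s.family_id, _fmt(s.cooks_d), _fmt(s.proxy), s.n_duplications)
             for s in ranked],
            {**meta, "proxy": proxy},
        )
        counts = duprates.outlier_pathway_counts(retained, annotations)
        write_table(
            outdir / f"pathway_counts_{proxy}.tsv",
            ["term_id", "n_mapping_instances"],
            counts,
            {**meta, "proxy": proxy},
        )
        with open(outdir / f"regression_{proxy}.json", "w",
                  encoding="utf-8") as fh:
            json.dump(
                {
                    **meta,
                    "proxy": proxy,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "pearson_r": fit.pearson_r,
                    "transform_x": fit.transform_x,
                    "transform_y": fit.transform_y,
                    "n": fit.n,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


# ---------------------------------------------------------------------------
# structure


def run_structure(outdir: str | Path, config: RunConfig) -> None:
    outdir = Path(outdir)
    for name in ("branches.tsv", "sites.tsv", "max_asa.tsv"):
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing input {outdir / name}")
    branches = load_branches(outdir / "branches.tsv")
    sites = load_sites(outdir / "sites.tsv")
    max_asa = load_max_asa(outdir / "max_asa.tsv")

    eligible, dropped = structure.filter_sites(sites)
    positive, negative = structure.classify_lineages(branches, config)
    profiles, pvalues = [], []
    rng = np.random.default_rng(config.seed)
    for name, lineage_set in (("positive", positive), ("negative", negative)):
        profile = structure.substitution_profile(
            eligible, branches, lineage_set, max_asa, config,
            selection=name, known_dropped=dropped,
        )
        if profile.n_sub == 0:
            log.warning("no substituted sites on %s lineages", name)
            continue
        profiles.append(profile)
        pvalues.append(
            structure.bootstrap_pvalues(profile, config.bootstrap_reps, rng)
        )
    cells = structure.structure_report(
        profiles, pvalues, config.alpha, config.n_structural_tests
    )
    write_table(
        outdir / "structure_profile.tsv",
        ["selection", "category", "part", "substituted_pct", "all_pct",
         "p", "flagged"],
        [
            (c.selection, c.label, c.part,
             f"{c.substituted_pct:.4f}", f"{c.all_pct:.4f}",
             _fmt(c.p), int(c.flagged))
            for c in cells
        ],
        {**_meta(config),
         "threshold": _fmt(structure.corrected_threshold(
             config.alpha, config.n_structural_tests))},
    )


# ---------------------------------------------------------------------------
# report


def run_report(outdir: str | Path, config: RunConfig, top: int = 30) -> None:
    """Ranked table of the highest-dN/dS branches and their lineages."""
    outdir = Path(outdir)
    stree, gtrees = _load_trees(outdir)
    branches = load_branches(outdir / "branches.tsv")
    if not branches:
        raise ValueError("no families")
    recon = _reconcile_all(stree, gtrees)
    rows = []
    for rec in branches:
        if rec.dnds is None or rec.ds is None or rec.ds <= config.ds_floor:
            continue
        fam = recon.get(rec.family_id)
        if fam is None or rec.branch_id not in fam.gene_tree:
            continue
        node = fam.gene_tree[rec.branch_id]
        if node.parent is None:
            continue
        path = reconcile.map_branch_lineage(node, fam)
        rows.append(
            (rec.dnds, rec.family_id, rec.branch_id,
             fam.mapping[node.parent.label], fam.mapping[node.label],
             ",".join(path))
        )
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    write_table(
        outdir / "top_lineages.tsv",
        ["family_id", "branch_id", "dnds", "start_taxon", "end_taxon",
         "mapped_lineages"],
        [(fid, bid, _fmt(d), start, end, path)
         for d, fid, bid, start, end, path in rows[:top]],
        {**_meta(config), "ds_floor": config.ds_floor},
    )
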