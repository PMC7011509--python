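"""Generator contracts: purity, congruence limits, calibration of draws."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lineagescan import (
    MixtureSpec,
    SimSpec,
    SiteSpec,
    simulate_dataset,
    simulate_gene_tree,
    simulate_site_table,
    simulate_species_tree,
)
from lineagescan.simulate import assign_branch_rates, assign_pathway_annotations


class TestSpeciesTree:
    def test_two_leaves_is_cherry_with_root_age(self):
        st = simulate_species_tree(2, 350.0, seed=1)
        assert len(st.leaves) == 2
        assert st.root_age == pytest.approx(350.0)
        assert all(st.age(l.label) == 0.0 for l in st.leaves)

    def test_same_seed_identical(self):
        a = simulate_species_tree(12, 684.0, seed=9)
        b = simulate_species_tree(12, 684.0, seed=9)
        assert a.to_newick() == b.to_newick()

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 100.0)

    def test_ultrametric_with_ordered_ages(self):
        st = simulate_species_tree(20, 500.0, seed=3)
        for node in st.nodes:
            for child in node.children:
                assert st.age(node.label) > st.age(child.label) or child.is_leaf


class TestGeneTree:
    def test_no_events_gives_congruent_tree(self):
        st = simulate_species_tree(9, 300.0, seed=2)
        fam = simulate_gene_tree(st, 0.0, 0.0, seed=5)
        gt = fam.gene_tree
        assert fam.true_duplications == set()
        assert sorted(gt.species_of(l) for l in gt.leaves) == sorted(
            l.label for l in st.leaves
        )
        # topology mirrors the species tree: same leaf-set partitions
        species_clades = {
            frozenset(l.label for l in n.leaves()) for n in st.nodes
        }
        gene_clades = {
            frozenset(gt.species_of(l) for l in n.leaves())
            for n in gt.nodes
        }
        assert gene_clades == species_clades

    def test_fixed_seed_reproducible(self):
        st = simulate_species_tree(8, 200.0, seed=2)
        a = simulate_gene_tree(st, 0.004, 0.001, seed=7)
        b = simulate_gene_tree(st, 0.004, 0.001, seed=7)
        assert a.gene_tree.to_newick() == b.gene_tree.to_newick()
        assert a.true_duplications == b.true_duplications

    def test_duplication_mean_matches_branching_expectation(self):
        """Pure-birth mean duplication count over 2000 replicates is within
        3 standard errors of the closed form sum(e^{la*d_child} -
        e^{la*d_parent}) - 1 over species edges (compound growth of
        lineage number with depth)."""
        lam = 0.1
        st = simulate_species_tree(6, 2.0, seed=10)
        # lineage count at depth d grows as e^{lam d}, so expected events
        # on a species edge (d_top, d_bot) are e^{lam d_bot} - e^{lam d_top}
        closed_form = sum(
            math.exp(lam * c.depth) - math.exp(lam * n.depth)
            for n in st.nodes
            for c in n.children
        )
        counts = []
        rng = np.random.default_rng(77)
        for _ in range(2000):
            fam = simulate_gene_tree(st, lam, 0.0, seed=rng)
            counts.append(len(fam.true_duplications))
        counts = np.array(counts)
        sem = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - closed_form) < 3 * sem

    def test_all_lost_family_flagged_not_error(self):
        st = simulate_species_tree(4, 100.0, seed=1)
        fam = simulate_gene_tree(st, 0.0, 1.0, seed=3)
        assert fam.gene_tree is None
        assert fam.true_duplications == set()


class TestBranchRates:
    def _many_branches(self, mixture, n_families=700, seed=0):
        rng = np.random.default_rng(seed)
        st = simulate_species_tree(8, 300.0, rng)
        values = []
        for _ in range(n_families):
            fam = simulate_gene_tree(st, 0.0, 0.0, seed=rng)
            assign_branch_rates(fam.gene_tree, mixture, rng)
            values.extend(fam.gene_tree.dnds.values())
        return np.array(values)

    def test_pure_positive_mixture(self):
        mix = MixtureSpec(w_zero=0, w_negative=0, w_intermediate=0,
                          w_positive=1.0)
        vals = self._many_branches(mix, n_families=5)
        assert np.all(vals > 1.0)

    def test_weights_recovered_within_three_se(self):
        mix = MixtureSpec(w_zero=0.0, w_negative=0.7, w_intermediate=0.2,
                          w_positive=0.1)
        vals = self._many_branches(mix)
        n = len(vals)
        assert n >= 9000
        for weight, lo, hi in [(0.7, 0.0, 0.5), (0.2, 0.5, 1.0),
                               (0.1, 1.0, np.inf)]:
            frac = np.mean((vals > lo) & (vals < hi) if np.isfinite(hi)
                           else vals > lo)
            se = math.sqrt(weight * (1 - weight) / n)
            assert abs(frac - weight) < 3 * se

    def test_ds_always_positive(self):
        vals_tree_rng = np.random.default_rng(3)
        st = simulate_species_tree(6, 100.0, vals_tree_rng)
        fam = simulate_gene_tree(st, 0.0, 0.0, seed=vals_tree_rng)
        assign_branch_rates(fam.gene_tree, MixtureSpec(), vals_tree_rng)
        assert all(v > 0 for v in fam.gene_tree.ds.values())

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(w_zero=0.5, w_negative=0.6, w_intermediate=0.2,
                        w_positive=0.1)


class TestAnnotations:
    def test_huge_odds_saturates_enriched_term(self):
        families = [(f"f{i}", True) for i in range(200)]
        amap = assign_pathway_annotations(
            families, 10, enriched=("path003",), odds=1e9, seed=1
        )
        assert all("path003" in amap.pathways[f] for f, _ in families)

    def test_seed_reproducible(self):
        families = [(f"f{i}", i % 3 == 0) for i in range(50)]
        a = assign_pathway_annotations(families, 20, ("path001",), 4.0, seed=9)
        b = assign_pathway_annotations(families, 20, ("path001",), 4.0, seed=9)
        assert a.pathways == b.pathways

    def test_enriched_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            assign_pathway_annotations([("f", True)], 5,
                                       enriched=("path999",), odds=2.0)


class TestSiteTable:
    def test_zero_baseline_no_substitutions(self):
        spec = SiteSpec(baseline_sub_prob=0.0)
        _, subs = simulate_site_table(spec, 200, ["b1", "b2"], seed=4)
        assert all(not v for v in subs.values())

    def test_category_proportions_within_three_se(self):
        spec = SiteSpec()
        records, _ = simulate_site_table(spec, 10_000, [], seed=8)
        counts = {}
        for r in records:
            counts[r.dssp] = counts.get(r.dssp, 0) + 1
        for code, freq in spec.category_freqs.items():
            se = math.sqrt(freq * (1 - freq) / 10_000)
            assert abs(counts.get(code, 0) / 10_000 - freq) < 3 * se

    def test_no_effect_null_matches_all_site_profile(self):
        """rr=1 and uniform multipliers: substituted-site category
        fractions track the all-sites fractions within sampling error."""
        spec = SiteSpec(rr_buried=1.0, baseline_sub_prob=0.3)
        records, subs = simulate_site_table(spec, 20_000, ["b1"], seed=6)
        chosen = set(subs["b1"])
        sub_recs = [r for r in records if r.site_index in chosen]
        n = len(sub_recs)
        for code, freq in spec.category_freqs.items():
            frac = sum(r.dssp == code for r in sub_recs) / n
            se = math.sqrt(freq * (1 - freq) / n)
            assert abs(frac - freq) < 4 * se

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            SiteSpec(category_freqs={c: 0.2 for c in "HGIEBTSC"})


class TestDatasetPurity:
    def test_same_spec_and_seed_identical_dataset(self):
        spec = SimSpec(n_families=20, n_species=6, seed=31)
        a = simulate_dataset(spec)
        b = simulate_dataset(spec)
        assert a.species_tree.to_newick() == b.species_tree.to_newick()
        assert a.branch_records == b.branch_records
        assert a.annotations.pathways == b.annotations.pathways
        assert a.site_records == b.site_records
        assert a.truth == b.truth

    def test_truth_carries_planted_parameters(self):
        spec = SimSpec(n_families=5, n_species=4, seed=2,
                       enriched_pathways=("path001",), enrichment_odds=3.0)
        ds = simulate_dataset(spec)
        assert ds.truth["enriched_pathways"] == ["path001"]
        assert ds.truth["enrichment_odds"] == 3.0
        assert set(ds.truth["true_duplication_counts"]) <= {
            f.family_id for f in ds.families
        }
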