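"""RSA binning, site filtering, substitution profiles, bootstrap null."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from lineagescan import (
    bootstrap_pvalues,
    classify_lineages,
    corrected_threshold,
    default_max_asa,
    filter_sites,
    relative_solvent_accessibility,
    structure_report,
    substitution_profile,
)
from lineagescan.structure import REPORT_ROWS, Profile
from lineagescan.tables import BranchRecord, SiteRecord


def _site(fam, idx, dssp, rsa, residue="A", flags=()):
    max_asa = default_max_asa()[residue]
    return SiteRecord(family_id=fam, site_index=idx, residue=residue,
                      asa_A2=rsa * max_asa, dssp=dssp,
                      flags=frozenset(flags))


def _branch(fam, bid, dnds, subs=()):
    return BranchRecord(family_id=fam, branch_id=bid, parent_id="r",
                        child_id=bid, length=0.1, dn=None, ds=0.5,
                        dnds=dnds, substituted_sites=tuple(subs))


class TestRSA:
    def test_ratio_and_bin(self):
        table = {"A": 100.0}
        rsa, bin_ = relative_solvent_accessibility(30.0, "A", table)
        assert rsa == pytest.approx(0.30)
        assert bin_ == "exposed"

    def test_cutoff_is_strictly_greater(self):
        table = {"A": 100.0}
        assert relative_solvent_accessibility(20.0, "A", table)[1] == "buried"
        assert relative_solvent_accessibility(20.0001, "A", table)[1] == "exposed"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            relative_solvent_accessibility(-1.0, "A", {"A": 100.0})
        with pytest.raises(KeyError):
            relative_solvent_accessibility(1.0, "Z", {"A": 100.0})


class TestFilterSites:
    def test_multimer_family_fully_dropped(self):
        records = [
            _site("f1", 1, "H", 0.5, flags=("multimer",)),
            _site("f1", 2, "H", 0.5),
            _site("f2", 1, "H", 0.5),
        ]
        eligible, dropped = filter_sites(records)
        assert [r.family_id for r in eligible] == ["f2"]
        assert dropped == {("f1", 1), ("f1", 2)}

    def test_nonstandard_residue_and_unaligned_dropped(self):
        records = [
            SiteRecord("f1", 1, "X", 10.0, "H"),
            _site("f1", 2, "H", 0.5, flags=("unaligned",)),
            _site("f1", 3, "H", 0.5),
        ]
        eligible, dropped = filter_sites(records)
        assert [r.site_index for r in eligible] == [3]
        assert dropped == {("f1", 1), ("f1", 2)}

    def test_clean_input_is_identity(self):
        records = [_site("f1", i, "H", 0.5) for i in range(1, 4)]
        eligible, dropped = filter_sites(records)
        assert eligible == records and not dropped


class TestClassifyLineages:
    def test_sets_disjoint_and_band_ignored(self, config):
        branches = [_branch("f", "pos", 1.5), _branch("f", "neg", 0.3),
                    _branch("f", "band", 0.7), _branch("f", "zero", 0.0)]
        positive, negative = classify_lineages(branches, config)
        assert positive == {("f", "pos")}
        assert negative == {("f", "neg")}


class TestProfile:
    def test_hand_tabulation(self, config):
        # 10 sites: 6 exposed coil, 4 buried sheet; substitutions at
        # 3 exposed-coil sites and 1 buried-sheet site
        sites = [_site("f", i, "C", 0.5) for i in range(1, 7)]
        sites += [_site("f", i, "E", 0.1) for i in range(7, 11)]
        branch = _branch("f", "b1", 2.0, subs=(1, 2, 3, 7))
        profile = substitution_profile(
            sites, [branch], {("f", "b1")}, default_max_asa(), config, "positive"
        )
        assert profile.percent(("C", "total"), "sub") == pytest.approx(75.0)
        assert profile.percent(("E", "total"), "sub") == pytest.approx(25.0)
        assert profile.percent(("C", "total"), "all") == pytest.approx(60.0)
        assert profile.percent(("E", "total"), "all") == pytest.approx(40.0)

    def test_multiplicity_counts_per_branch_occurrence(self, config):
        sites = [_site("f", 1, "H", 0.5), _site("f", 2, "C", 0.5)]
        branches = [_branch("f", "b1", 2.0, subs=(1,)),
                    _branch("f", "b2", 3.0, subs=(1, 2))]
        profile = substitution_profile(
            sites, branches, {("f", "b1"), ("f", "b2")}, default_max_asa(),
            config, "positive",
        )
        # site 1 substituted on two branches counts twice
        assert profile.row_count(("H", "total"), "sub") == 2
        assert profile.n_all == 4  # 2 sites x 2 branches

    def test_exclusive_categories_sum_to_100(self, config):
        rng = np.random.default_rng(4)
        codes = "HGIEBTSC"
        sites = [
            _site("f", i, codes[int(rng.integers(8))], float(rng.uniform(0, 1)))
            for i in range(1, 200)
        ]
        subs = tuple(int(i) for i in rng.choice(range(1, 200), 40, replace=False))
        branch = _branch("f", "b1", 2.0, subs=subs)
        profile = substitution_profile(
            sites, [branch], {("f", "b1")}, default_max_asa(), config, "positive"
        )
        for which in ("sub", "all"):
            total = sum(profile.percent((c, "total"), which) for c in codes)
            assert total == pytest.approx(100.0, abs=0.01)
            bins = (profile.percent(("All", "buried"), which)
                    + profile.percent(("All", "exposed"), which))
            assert bins == pytest.approx(100.0, abs=0.01)

    def test_profile_invariant_to_site_order(self, config):
        rng = np.random.default_rng(5)
        sites = [_site("f", i, "HGIEBTSC"[i % 8], float(rng.uniform(0, 1)))
                 for i in range(1, 50)]
        branch = _branch("f", "b1", 2.0, subs=(1, 5, 9))
        args = ({("f", "b1")}, default_max_asa(), config, "positive")
        p1 = substitution_profile(sites, [branch], *args)
        shuffled = list(sites)
        rng.shuffle(shuffled)
        p2 = substitution_profile(shuffled, [branch], *args)
        assert p1.sub_counts == p2.sub_counts
        assert p1.all_counts == p2.all_counts

    def test_unknown_substituted_index_is_error(self, config):
        sites = [_site("f", 1, "H", 0.5)]
        branch = _branch("f", "b1", 2.0, subs=(99,))
        with pytest.raises(KeyError):
            substitution_profile(sites, [branch], {("f", "b1")},
                                 default_max_asa(), config, "positive")

    def test_known_dropped_index_is_skipped(self, config):
        sites = [_site("f", 1, "H", 0.5)]
        branch = _branch("f", "b1", 2.0, subs=(1, 2))
        profile = substitution_profile(
            sites, [branch], {("f", "b1")}, default_max_asa(), config,
            "positive", known_dropped={("f", 2)},
        )
        assert profile.n_sub == 1


def _two_cell_profile(n_half: int, n_sub_obs: int) -> Profile:
    """All-sites mass split evenly between two cells; all substitutions in
    the first."""
    profile = Profile(selection="positive")
    profile.all_counts = {("H", "exposed"): n_half, ("C", "exposed"): n_half}
    profile.sub_counts = {("H", "exposed"): n_sub_obs}
    return profile


class TestBootstrap:
    def test_degenerate_distribution_gives_p_one(self):
        profile = Profile(selection="positive")
        profile.all_counts = {("H", "exposed"): 100}
        profile.sub_counts = {("H", "exposed"): 10}
        pvals = bootstrap_pvalues(profile, n_reps=500, seed=1)
        assert pvals[("H", "total")] == 1.0
        assert pvals[("H", "exposed")] == 1.0

    def test_matches_exact_binomial_tail(self):
        """Cell frequency 0.5, n_sub 10, all 10 observed in the cell: the
        bootstrap p at 20 000 replicates sits within 3 Monte-Carlo SE of
        the exact binomial two-tail 2 * 0.5**10."""
        profile = _two_cell_profile(500, 10)
        pvals = bootstrap_pvalues(profile, n_reps=20_000, seed=99)
        exact = 2 * sps.binom.sf(9, 10, 0.5)  # = 2 * P(X >= 10) = 2*0.5^10
        mc_se = 2 * np.sqrt(exact / 2 * (1 - exact / 2) / 20_000)
        assert abs(pvals[("H", "exposed")] - exact) < 3 * mc_se

    def test_same_seed_reproducible(self):
        profile = _two_cell_profile(500, 10)
        p1 = bootstrap_pvalues(profile, n_reps=2_000, seed=5)
        p2 = bootstrap_pvalues(profile, n_reps=2_000, seed=5)
        assert p1 == p2

    def test_empty_substitutions_rejected(self):
        profile = Profile(selection="positive")
        profile.all_counts = {("H", "exposed"): 100}
        with pytest.raises(ValueError):
            bootstrap_pvalues(profile, n_reps=100, seed=1)


class TestReport:
    def test_corrected_threshold_value(self):
        assert corrected_threshold(0.05, 30) == pytest.approx(0.05 / 30)
        assert f"{corrected_threshold(0.05, 30):.5f}" == "0.00167"

    def test_flag_boundary(self, config):
        profile = _two_cell_profile(500, 10)
        pvals = {row: 0.5 for row in REPORT_ROWS}
        pvals[("H", "exposed")] = 0.0016
        pvals[("C", "exposed")] = 0.0017
        cells = structure_report([profile], [pvals], alpha=0.05, m=30)
        by_row = {(c.label, c.part): c for c in cells}
        assert by_row[("H", "exposed")].flagged
        assert not by_row[("C", "exposed")].flagged

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            corrected_threshold(0.05, 0)
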