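"""Synthetic data with the statistical structure the analyses assume.

The generators emulate, at desk scale, the shape of a phylogenetically
indexed gene-family corpus: a calibrated (ultrametric) species tree;
gene families grown inside it by a birth-death process of duplication and
loss, with the true duplication nodes recorded; branch-wise dN/dS drawn
from a mixture with a small positively selected fraction; pathway/domain
annotations with optional planted enrichment among families containing
positive branches; and structure-site tables with specified secondary-
structure frequencies, per-category burial probabilities, and a
buried/exposed substitution relative risk.

Every generator is a pure function of (spec, seed): the same inputs give
identical output, and all planted quantities are returned so downstream
modules can be tested for recovery and null calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tables import AnnotationMap, BranchRecord, SiteRecord, default_max_asa
from .trees import GeneTree, Node, SpeciesTree

__all__ = [
    "MixtureSpec",
    "SiteSpec",
    "SimSpec",
    "SimulatedFamily",
    "SimulatedDataset",
    "simulate_species_tree",
    "simulate_gene_tree",
    "assign_branch_rates",
    "assign_pathway_annotations",
    "simulate_site_table",
    "simulate_dataset",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class MixtureSpec:
    """Branch dN/dS mixture: point mass at 0 plus three uniform classes.

    Defaults put most branches under purifying selection with a small
    positively selected tail, qualitatively matching a corpus where a
    minority of families carry any dN/dS > 1 branch.
    """

    w_zero: float = 0.05
    w_negative: float = 0.65
    w_intermediate: float = 0.20
    w_positive: float = 0.10
    negative_range: tuple[float, float] = (0.01, 0.5)
    intermediate_range: tuple[float, float] = (0.5, 1.0)
    positive_range: tuple[float, float] = (1.0, 5.0)
    #: lognormal parameters (mean of log, sd of log) for per-branch dS
    ds_log_mu: float = math.log(0.1)
    ds_log_sigma: float = 0.5

    def weights(self) -> tuple[float, float, float, float]:
        return (self.w_zero, self.w_negative, self.w_intermediate, self.w_positive)

    def __post_init__(self) -> None:
        if abs(sum(self.weights()) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {self.weights()}")
        if any(w < 0 for w in self.weights()):
            raise ValueError("mixture weights must be non-negative")


# Per-category frequencies and burial probabilities loosely shaped like an
# empirical all-sites profile of globular proteins: helices and coil
# dominate, turns/bends are mostly exposed, sheets mostly buried.
_DEFAULT_FREQS = {
    "H": 0.3276, "G": 0.0322, "I": 0.0065, "E": 0.1984,
    "B": 0.0104, "T": 0.1109, "S": 0.0970, "C": 0.2170,
}
_DEFAULT_BURIED = {
    "H": 0.537, "G": 0.413, "I": 0.575, "E": 0.684,
    "B": 0.596, "T": 0.265, "S": 0.314, "C": 0.411,
}


@dataclass(frozen=True)
class SiteSpec:
    """Generator spec for structure-site tables.

    ``rr_buried`` multiplies the substitution probability of buried sites;
    1.0 means burial has no effect on substitution and the substituted-site
    profile matches the all-sites profile in expectation.
    """

    category_freqs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FREQS)
    )
    buried_prob: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BURIED)
    )
    #: Beta(a, b) shape for RSA within each burial bin (scaled into the bin)
    rsa_beta: tuple[float, float] = (2.0, 2.0)
    rsa_cutoff: float = 0.20
    baseline_sub_prob: float = 0.05
    rr_buried: float = 0.75
    category_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.category_freqs) != set("HGIEBTSC"):
            raise ValueError("category_freqs must cover the 8 DSSP codes")
        if abs(sum(self.category_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("category frequencies must sum to 1")
        if any(f < 0 for f in self.category_freqs.values()):
            raise ValueError("category frequencies must be non-negative")
        if self.rr_buried <= 0:
            raise ValueError("rr_buried must be positive")
        if not 0 <= self.baseline_sub_prob <= 1:
            raise ValueError("baseline_sub_prob must be in [0, 1]")
        if any(m <= 0 for m in self.category_multipliers.values()):
            raise ValueError("category multipliers must be positive")


@dataclass(frozen=True)
class SimSpec:
    """Full study-condition spec for one synthetic dataset."""

    n_species: int = 16
    root_age_mya: float = 684.0
    n_families: int = 100
    #: duplication / loss rates per gene lineage
    dup_rate: float = 0.002
    loss_rate: float = 0.0005
    #: 'MY' runs the birth-death clock per million years along the
    #: calibrated tree; 'subs' runs it per substitutions/site
    rate_unit: str = "MY"
    #: converts MY of branch duration into substitutions per site
    subs_per_my: float = 0.002
    #: families originate at a uniformly chosen species-tree internal node,
    #: giving a spread of family root ages; False pins all roots to the root
    random_origin: bool = True
    mixture: MixtureSpec = field(default_factory=MixtureSpec)
    n_pathways: int = 50
    pathway_prob: float = 0.08
    enriched_pathways: tuple[str, ...] = ()
    enrichment_odds: float = 1.0
    n_domains: int = 30
    domain_prob: float = 0.05
    sites: SiteSpec = field(default_factory=SiteSpec)
    n_sites_per_family: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.rate_unit not in ("MY", "subs"):
            raise ValueError("rate_unit must be 'MY' or 'subs'")
        if self.enrichment_odds <= 0:
            raise ValueError("enrichment_odds must be positive")
        universe = {f"path{i:03d}" for i in range(self.n_pathways)}
        if not set(self.enriched_pathways) <= universe:
            raise ValueError("enriched_pathways must be drawn from the universe")


# ---------------------------------------------------------------------------
# named validation-experiment designs


def enrichment_recovery_spec(seed: int = 0) -> SimSpec:
    """Planted-enrichment recovery experiment: 3 enriched pathways of 50,
    odds 4, 500 families.

    Because enrichment is planted per family (any family containing a
    positively selected branch boosts its enriched-pathway odds) while the
    test counts branches, the branch-level contrast is diluted by the
    branch-weighted fraction of boosted families.  The experiment therefore
    uses small families (5-species tree, low duplication rate, no loss) and
    a base pathway prevalence of 0.2 so the planted odds ratio yields a
    well-powered absolute contrast (z > 5 per term).
    """
    return SimSpec(
        n_families=500,
        n_species=5,
        dup_rate=0.0002,
        loss_rate=0.0,
        pathway_prob=0.2,
        enriched_pathways=("path003", "path017", "path041"),
        enrichment_odds=4.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_leaves: int,
    root_age: float,
    seed: int | np.random.Generator = 0,
) -> SpeciesTree:
    """Random ultrametric species tree with the given root age.

    Internal node ages are uniform on (0, root_age); the topology comes
    from successive random pair merges in order of increasing age (a
    coalescent-style construction).  Leaves are ``S1..Sn`` at age 0,
    internal nodes ``N1..`` in merge order from the root down.
    """
    if n_leaves < 2:
        raise ValueError(f"need at least 2 leaves, got {n_leaves}")
    if root_age <= 0:
        raise ValueError("root age must be positive")
    rng = _as_rng(seed)
    ages = sorted(rng.uniform(0.0, root_age, size=n_leaves - 2).tolist())
    ages.append(float(root_age))

    lineages: list[tuple[Node, float]] = [
        (Node(label=f"S{i + 1}"), 0.0) for i in range(n_leaves)
    ]
    merge_ages = ages  # ascending; the last merge is the root
    label_counter = n_leaves - 1  # root will be N1
    for age in merge_ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False).tolist())
        (node_a, age_a) = lineages[i]
        (node_b, age_b) = lineages[j]
        parent = Node(label=f"N{label_counter}")
        label_counter -= 1
        for child, child_age in ((node_a, age_a), (node_b, age_b)):
            child.length = age - child_age
            child.parent = parent
            parent.children.append(child)
        lineages[i] = (parent, age)
        del lineages[j]
    root = lineages[0][0]
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# gene trees by birth-death inside the species tree


@dataclass
class SimulatedFamily:
    """One simulated gene family with its generator truth."""

    family_id: str
    gene_tree: GeneTree | None  # None when every lineage was lost
    true_duplications: set[str] = field(default_factory=set)
    origin: str = ""  # species node the family originated at


class _GeneSim:
    def __init__(
        self,
        species_tree: SpeciesTree,
        dup_rate: float,
        loss_rate: float,
        rng: np.random.Generator,
        subs_per_my: float,
        rate_unit: str,
    ):
        self.stree = species_tree
        self.lam = dup_rate
        self.mu = loss_rate
        self.rng = rng
        self.subs_per_my = subs_per_my
        self.rate_unit = rate_unit
        self.leaf_counter = 0
        self.node_counter = 0
        self.true_dups: set[str] = set()

    def _clock_scale(self) -> float:
        # event rates are per MY or per substitutions/site of branch length
        return 1.0 if self.rate_unit == "MY" else self.subs_per_my

    def _new_internal(self) -> str:
        self.node_counter += 1
        return f"n{self.node_counter}"

    def evolve_edge(self, target: Node, duration: float) -> Node | None:
        """One gene lineage traversing the species edge into ``target``.

        Returns the surviving gene subtree (its ``length`` covers the MY
        spent on this edge, converted to substitutions/site) or None.
        """
        total_rate = (self.lam + self.mu) * self._clock_scale()
        t = 0.0
        while True:
            wait = (
                float("inf") if total_rate == 0
                else float(self.rng.exponential(1.0 / total_rate))
            )
            if t + wait >= duration:
                node = self.at_species_node(target)
                if node is not None:
                    node.length += (duration - t) * self.subs_per_my
                return node
            t += wait
            if self.rng.uniform() < self.mu / (self.lam + self.mu):
                return None  # loss
            # duplication: two sublineages continue on this same edge
            left = self.evolve_edge(target, duration - t)
            right = self.evolve_edge(target, duration - t)
            if left is not None and right is not None:
                label = self._new_internal()
                dup = Node(label=label, length=t * self.subs_per_my)
                for child in (left, right):
                    child.parent = dup
                    dup.children.append(child)
                self.true_dups.add(label)
                return dup
            survivor = left if left is not None else right
            if survivor is not None:
                survivor.length += t * self.subs_per_my
            return survivor

    def at_species_node(self, snode: Node) -> Node | None:
        """A gene lineage arriving exactly at species node ``snode``."""
        if snode.is_leaf:
            self.leaf_counter += 1
            return Node(label=f"{snode.label}|g{self.leaf_counter}", length=0.0)
        survivors = []
        for child in snode.children:
            sub = self.evolve_edge(child, child.length)
            if sub is not None:
                survivors.append(sub)
        if not survivors:
            return None
        if len(survivors) == 1:
            return survivors[0]
        node = Node(label=self._new_internal(), length=0.0)
        while len(survivors) > 2:  # keep gene trees binary under polytomies
            right = survivors.pop()
            left = survivors.pop()
            joint = Node(label=self._new_internal(), length=0.0)
            for c in (left, right):
                c.parent = joint
                joint.children.append(c)
            survivors.append(joint)
        for c in survivors:
            c.parent = node
            node.children.append(c)
        return node


def simulate_gene_tree(
    species_tree: SpeciesTree,
    dup_rate: float,
    loss_rate: float,
    seed: int | np.random.Generator = 0,
    origin: str | None = None,
    subs_per_my: float = 0.002,
    rate_unit: str = "MY",
    family_id: str = "fam",
) -> SimulatedFamily:
    """Grow one gene family inside the species tree by birth-death.

    With ``dup_rate = loss_rate = 0`` the gene tree is leaf-for-leaf
    congruent with the species tree (below the origin).  A family whose
    lineages are all lost comes back with ``gene_tree=None``.  The labels
    of duplication nodes that survive in the returned tree are the
    generator truth; with ``loss_rate = 0`` these are all events.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = _as_rng(seed)
    sim = _GeneSim(species_tree, dup_rate, loss_rate, rng, subs_per_my, rate_unit)
    origin_node = species_tree[origin] if origin else species_tree.root
    if origin_node.is_leaf:
        raise ValueError("family origin must be an internal species node")
    root = sim.at_species_node(origin_node)
    if root is not None:
        root.length = 0.0
        tree = GeneTree(root)
        true_dups = {d for d in sim.true_dups if d in tree}
    else:
        tree, true_dups = None, set()
    return SimulatedFamily(
        family_id=family_id,
        gene_tree=tree,
        true_duplications=true_dups,
        origin=origin_node.label,
    )


# ---------------------------------------------------------------------------
# branch rates


def assign_branch_rates(
    gene_tree: GeneTree,
    mixture: MixtureSpec,
    seed: int | np.random.Generator = 0,
) -> GeneTree:
    """Draw per-branch dN/dS and dS from the mixture, in place.

    Every branch receives dS > 0 and a dN/dS from one of the four classes
    (zero / negative / intermediate / positive) with the spec weights.
    """
    rng = _as_rng(seed)
    ranges = {
        1: mixture.negative_range,
        2: mixture.intermediate_range,
        3: mixture.positive_range,
    }
    for node in gene_tree.branches():
        cls = int(rng.choice(4, p=mixture.weights()))
        if cls == 0:
            dnds = 0.0
        else:
            lo, hi = ranges[cls]
            dnds = float(rng.uniform(lo, hi))
        gene_tree.dnds[node.label] = dnds
        gene_tree.ds[node.label] = float(
            rng.lognormal(mixture.ds_log_mu, mixture.ds_log_sigma)
        )
    return gene_tree


# ---------------------------------------------------------------------------
# annotations


def assign_pathway_annotations(
    families: list[tuple[str, bool]],
    n_pathways: int,
    enriched: tuple[str, ...] = (),
    odds: float = 1.0,
    seed: int | np.random.Generator = 0,
    base_prob: float = 0.08,
    kind: str = "pathway",
    annotations: AnnotationMap | None = None,
) -> AnnotationMap:
    """Bernoulli pathway memberships with planted enrichment.

    ``families`` pairs each family id with whether it contains at least
    one positively selected branch.  Membership odds for an enriched term
    are multiplied by ``odds`` in positive-containing families, so
    ``odds=1`` plants no association by construction.
    """
    if n_pathways < 1:
        raise ValueError("need at least one term in the universe")
    if odds <= 0:
        raise ValueError("odds multiplier must be positive")
    prefix = "path" if kind == "pathway" else "dom"
    universe = [f"{prefix}{i:03d}" for i in range(n_pathways)]
    if not set(enriched) <= set(universe):
        raise ValueError(f"enriched terms must be a subset of the {kind} universe")
    rng = _as_rng(seed)
    base_odds = base_prob / (1.0 - base_prob)
    boosted = base_odds * odds
    p_boosted = boosted / (1.0 + boosted)
    amap = annotations if annotations is not None else AnnotationMap()
    for family_id, has_positive in families:
        amap.terms(kind).setdefault(family_id, set())
        amap.terms("domain" if kind == "pathway" else "pathway").setdefault(
            family_id, set()
        )
        for term in universe:
            p = p_boosted if (has_positive and term in enriched) else base_prob
            if rng.uniform() < p:
                amap.add(family_id, kind, term)
    return amap


# ---------------------------------------------------------------------------
# structure-site tables


def simulate_site_table(
    spec: SiteSpec,
    n_sites: int,
    branches: list[str],
    seed: int | np.random.Generator = 0,
    family_id: str = "fam",
    max_asa: dict[str, float] | None = None,
) -> tuple[list[SiteRecord], dict[str, list[int]]]:
    """Sites with DSSP codes, accessibilities, and per-branch substitutions.

    Each site draws a DSSP category from the spec frequencies, a burial
    bin from the category's buried probability, an RSA from a Beta
    distribution scaled into the bin, a residue uniformly from the 20
    standard amino acids, and an absolute accessibility rsa * maxASA.
    Substitution indicators are drawn independently per (branch, site)
    with probability baseline * rr_buried^[buried] * category multiplier.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = _as_rng(seed)
    max_asa = max_asa or default_max_asa()
    residues = sorted(max_asa)
    codes = sorted(spec.category_freqs)
    freqs = np.array([spec.category_freqs[c] for c in codes])
    a, b = spec.rsa_beta
    cut = spec.rsa_cutoff

    cat_idx = rng.choice(len(codes), size=n_sites, p=freqs)
    buried_p = np.array([spec.buried_prob[c] for c in codes])[cat_idx]
    buried = rng.uniform(size=n_sites) < buried_p
    frac = rng.beta(a, b, size=n_sites)
    rsa = np.where(buried, frac * cut, cut + frac * (1.0 - cut))
    res_idx = rng.integers(len(residues), size=n_sites)

    mult = np.array(
        [spec.category_multipliers.get(c, 1.0) for c in codes]
    )[cat_idx]
    sub_prob = np.minimum(
        1.0,
        spec.baseline_sub_prob * mult * np.where(buried, spec.rr_buried, 1.0),
    )

    records: list[SiteRecord] = []
    for i in range(n_sites):
        residue = residues[res_idx[i]]
        records.append(
            SiteRecord(
                family_id=family_id,
                site_index=i + 1,
                residue=residue,
                asa_A2=float(rsa[i]) * max_asa[residue],
                dssp=codes[cat_idx[i]],
            )
        )

    substituted: dict[str, list[int]] = {}
    for branch in branches:
        hits = rng.uniform(size=n_sites) < sub_prob
        substituted[branch] = [i + 1 for i in np.flatnonzero(hits)]
    return records, substituted


# ---------------------------------------------------------------------------
# whole datasets


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus the generator truth."""

    spec: SimSpec
    species_tree: SpeciesTree
    families: list[SimulatedFamily]
    branch_records: list[BranchRecord]
    annotations: AnnotationMap
    site_records: list[SiteRecord]
    truth: dict

    def gene_trees(self) -> dict[str, GeneTree]:
        return {
            f.family_id: f.gene_tree
            for f in self.families
            if f.gene_tree is not None
        }


def simulate_dataset(spec: SimSpec, seed: int | None = None) -> SimulatedDataset:
    """Generate a complete dataset under one spec; pure in (spec, seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    stree = simulate_species_tree(spec.n_species, spec.root_age_mya, rng)
    internal = [n.label for n in stree.nodes if not n.is_leaf]

    families: list[SimulatedFamily] = []
    branch_records: list[BranchRecord] = []
    site_records: list[SiteRecord] = []
    family_flags: list[tuple[str, bool]] = []
    true_dup_counts: dict[str, int] = {}

    for i in range(spec.n_families):
        fid = f"fam{i:04d}"
        origin = (
            internal[int(rng.integers(len(internal)))]
            if spec.random_origin
            else stree.root.label
        )
        fam = simulate_gene_tree(
            stree,
            spec.dup_rate,
            spec.loss_rate,
            rng,
            origin=origin,
            subs_per_my=spec.subs_per_my,
            rate_unit=spec.rate_unit,
            family_id=fid,
        )
        families.append(fam)
        if fam.gene_tree is None or len(fam.gene_tree.leaves) < 2:
            family_flags.append((fid, False))
            continue
        true_dup_counts[fid] = len(fam.true_duplications)
        assign_branch_rates(fam.gene_tree, spec.mixture, rng)

        tree = fam.gene_tree
        has_positive = any(v > 1.0 for v in tree.dnds.values())
        family_flags.append((fid, has_positive))

        branch_ids = [n.label for n in tree.branches()]
        sites, subs = simulate_site_table(
            spec.sites,
            spec.n_sites_per_family,
            branch_ids,
            rng,
            family_id=fid,
        )
        site_records.extend(sites)
        tree.substituted_sites.update(subs)
        for node in tree.branches():
            dnds = tree.dnds[node.label]
            ds = tree.ds[node.label]
            branch_records.append(
                BranchRecord(
                    family_id=fid,
                    branch_id=node.label,
                    parent_id=node.parent.label,
                    child_id=node.label,
                    length=node.length,
                    dn=dnds * ds,
                    ds=ds,
                    dnds=dnds,
                    substituted_sites=tuple(subs.get(node.label, [])),
                )
            )

    annotations = assign_pathway_annotations(
        family_flags,
        spec.n_pathways,
        spec.enriched_pathways,
        spec.enrichment_odds,
        rng,
        base_prob=spec.pathway_prob,
    )
    assign_pathway_annotations(
        family_flags,
        spec.n_domains,
        (),
        1.0,
        rng,
        base_prob=spec.domain_prob,
        kind="domain",
        annotations=annotations,
    )

    truth = {
        "seed": spec.seed if seed is None else seed,
        "enriched_pathways": list(spec.enriched_pathways),
        "enrichment_odds": spec.enrichment_odds,
        "rr_buried": spec.sites.rr_buried,
        "true_duplication_counts": true_dup_counts,
        "family_origins": {f.family_id: f.origin for f in families},
    }
    return SimulatedDataset(
        spec=spec,
        species_tree=stree,
        families=families,
        branch_records=branch_records,
        annotations=annotations,
        site_records=site_records,
        truth=truth,
    )
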