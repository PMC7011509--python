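"""Run configuration: analysis thresholds, bootstrap size, seed.

Every output file written by the pipeline carries the configuration hash
and the seed in its header so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and knobs shared across the pipeline stages.

    Parameters
    ----------
    dnds_positive : float
        Branches with dN/dS strictly above this are called positively
        selected (default 1).
    dnds_negative : float
        Branches with 0 < dN/dS strictly below this are called negatively
        selected (default 0.5); values of 0 or in [0.5, 1] are ignored.
    ds_floor : float
        Branches with dS at or below this are ignored regardless of dN/dS;
        guards against unreliable ratios on near-zero synonymous divergence.
    rsa_cutoff : float
        Relative solvent accessibility above which a site is exposed
        (strictly greater than; default 0.20).
    min_identity : float
        Pairwise alignment identity a sequence pair must strictly exceed.
    max_gap : float
        Pairwise gap fraction a pair must stay strictly below.
    bootstrap_reps : int
        Replicates for the structural bootstrap null (default 20 000).
    alpha : float
        Significance level for enrichment and structural tests.
    n_structural_tests : int
        Number of structural comparisons used for the per-cell corrected
        threshold alpha / m (default 30).
    enrichment_unit : str
        ``"branch"`` counts each non-ignored gene-tree branch once;
        ``"lineage"`` expands each branch into its mapped species-tree
        lineage path and counts path entries.
    seed : int
        Base seed for all stochastic operations; no global random state.
    """

    dnds_positive: float = 1.0
    dnds_negative: float = 0.5
    ds_floor: float = 0.01
    rsa_cutoff: float = 0.20
    min_identity: float = 0.80
    max_gap: float = 0.10
    bootstrap_reps: int = 20_000
    alpha: float = 0.05
    n_structural_tests: int = 30
    enrichment_unit: str = "branch"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.dnds_positive, "dnds_positive must be > 0"),
            (0 < self.dnds_negative <= self.dnds_positive,
             "dnds_negative must lie in (0, dnds_positive]"),
            (self.ds_floor >= 0, "ds_floor must be >= 0"),
            (0 <= self.rsa_cutoff <= 1, "rsa_cutoff must be in [0, 1]"),
            (0 <= self.min_identity <= 1, "min_identity must be in [0, 1]"),
            (0 <= self.max_gap <= 1, "max_gap must be in [0, 1]"),
            (self.bootstrap_reps >= 1, "bootstrap_reps must be >= 1"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.n_structural_tests >= 1, "n_structural_tests must be >= 1"),
            (self.enrichment_unit in ("branch", "lineage"),
             "enrichment_unit must be 'branch' or 'lineage'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (seed included)."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def replace(self, **changes) -> "RunConfig":
        data = self.to_dict()
        data.update(changes)
        return RunConfig(**data)
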