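"""Pairwise alignment quality control for gene families.

A family's multiple sequence alignment passes QC when every sequence pair
is strictly more than ``min_identity`` identical in columns where both
members have a residue, and has strictly fewer than ``max_gap`` gapped
columns among columns where at least one member has a residue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .tables import AMINO_ACIDS

__all__ = ["PairQC", "pairwise_alignment_qc"]

GAP = "-"
_ALPHABET = AMINO_ACIDS | {GAP}


@dataclass(frozen=True)
class PairQC:
    """QC verdict for one aligned sequence pair."""

    name_a: str
    name_b: str
    identity: float
    gap_fraction: float
    passed: bool


def _pair_stats(row_a: str, row_b: str) -> tuple[float, float]:
    both = matches = single_gap = any_residue = 0
    for a, b in zip(row_a, row_b):
        a_gap = a == GAP
        b_gap = b == GAP
        if a_gap and b_gap:
            continue
        any_residue += 1
        if a_gap != b_gap:
            single_gap += 1
        else:
            both += 1
            if a == b:
                matches += 1
    if both == 0:
        raise ValueError("pair has no co-aligned residue columns; identity undefined")
    return matches / both, single_gap / any_residue


def pairwise_alignment_qc(
    msa: dict[str, str],
    min_identity: float = 0.80,
    max_gap: float = 0.10,
) -> tuple[list[PairQC], bool]:
    """Score every sequence pair of an alignment and give the family verdict.

    Parameters
    ----------
    msa : mapping of sequence name to aligned row (residues and ``-`` gaps).
    min_identity : identity each pair must strictly exceed.
    max_gap : gap fraction each pair must stay strictly below.

    Returns
    -------
    (pair results, family verdict) — the family passes iff all pairs pass.

    Identity is matches over columns where both rows are non-gap; the gap
    fraction is columns where exactly one row is a gap over columns where
    at least one row is non-gap.  Both statistics are symmetric in the pair.
    """
    if len(msa) < 2:
        raise ValueError("alignment QC needs at least two sequences")
    lengths = {len(row) for row in msa.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned rows have unequal lengths: {sorted(lengths)}")
    for name, row in msa.items():
        bad = set(row) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {name!r} contains non-standard symbols {sorted(bad)}"
            )
    results: list[PairQC] = []
    for name_a, name_b in itertools.combinations(sorted(msa), 2):
        identity, gap_fraction = _pair_stats(msa[name_a], msa[name_b])
        passed = identity > min_identity and gap_fraction < max_gap
        results.append(PairQC(name_a, name_b, identity, gap_fraction, passed))
    return results, all(r.passed for r in results)
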