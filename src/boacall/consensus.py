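"""Consensus calling across windowing scenarios.

Each allele collects one vote per scenario (core length x offset mode).
The consensus call at agreement threshold ``tau`` is the majority breed
among the non-missing votes, accepted only when its share of those votes
reaches ``tau``; ties, empty vote sets, and sub-threshold majorities are
missing.  Missing votes are excluded from the denominator by default; the
``all_votes_denominator`` flag counts them against the leader instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assign import AssignmentTensor
from .haplo import EXOTIC, LOCAL, MISSING

DEFAULT_THRESHOLDS = (0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95)

_EPS = 1e-9  # guards >= comparisons against float rounding of tau * n


@dataclass(frozen=True)
class ThresholdGrid:
    """Agreement thresholds at which consensus calls are produced."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t or any(not 0 < x < 1 for x in t):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")


def consensus_allele(
    votes, threshold: float, all_votes_denominator: bool = False
) -> int:
    """Consensus call for one allele from its multiset of votes.

    ``votes`` is any iterable over {LOCAL, EXOTIC, MISSING} codes.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote set")
    if not 0.5 <= threshold < 1:
        raise ValueError("threshold must lie in [0.5, 1)")
    n_l = sum(1 for v in votes if v == LOCAL)
    n_e = sum(1 for v in votes if v == EXOTIC)
    if n_l + n_e == 0 or n_l == n_e:
        return MISSING
    leader, lead = (LOCAL, n_l) if n_l > n_e else (EXOTIC, n_e)
    denom = len(votes) if all_votes_denominator else n_l + n_e
    if lead + _EPS >= threshold * denom and 2 * lead > denom:
        return leader
    return MISSING


@dataclass
class ConsensusMatrix:
    """Per-allele consensus calls at every threshold."""

    thresholds: tuple[float, ...]
    calls: np.ndarray  # (n_thresholds, n_haplotypes, n_loci) int8

    def at(self, threshold: float) -> np.ndarray:
        return self.calls[self.thresholds.index(threshold)]


def consensus_matrix(
    tensor: AssignmentTensor,
    grid: ThresholdGrid,
    all_votes_denominator: bool = False,
) -> ConsensusMatrix:
    """Vectorized consensus over all alleles of an assignment tensor."""
    n_e, n_l = tensor.vote_counts()
    informative = n_e + n_l
    leader_is_e = n_e > n_l
    lead = np.maximum(n_e, n_l).astype(np.float64)
    denom = (
        np.full(lead.shape, tensor.n_scenarios, dtype=np.float64)
        if all_votes_denominator
        else informative.astype(np.float64)
    )
    base = np.where(leader_is_e, EXOTIC, LOCAL).astype(np.int8)
    undecided = (informative == 0) | (n_e == n_l)

    out = np.empty((len(grid.thresholds),) + lead.shape, dtype=np.int8)
    for i, tau in enumerate(grid.thresholds):
        ok = (lead + _EPS >= tau * denom) & (2 * lead > denom) & ~undecided
        out[i] = np.where(ok, base, MISSING)
    return ConsensusMatrix(tuple(grid.thresholds), out)
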