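"""Consensus miRNA-target prediction and cross-screen convergence.

Target-prediction algorithms disagree wildly; the standard remedy is to
keep a (miRNA, gene) pair only when several independent algorithms call
it.  Here a pair is *consensus* when called by at least ``min_algorithms``
distinct algorithms (default 4).  Convergence then intersects the genes
targeted by candidate miRNAs with an independent siRNA-screen hit list,
yielding genes supported by both screens and the subset of candidate
miRNAs that drive them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PredictionCallSet",
    "ConsensusMap",
    "ConvergenceMap",
    "consensus_targets",
    "converge_with_sirna",
]


@dataclass
class PredictionCallSet:
    """(mirna_id, gene_id, algorithm_id) call triples plus the algorithm universe."""

    calls: pd.DataFrame
    algorithms: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id", "algorithm_id"}
        if not required.issubset(self.calls.columns):
            raise ValueError(f"calls require columns {sorted(required)}")
        self.algorithms = tuple(self.algorithms)
        unknown = set(self.calls["algorithm_id"]) - set(self.algorithms)
        if unknown:
            raise ValueError(f"algorithm_ids outside declared universe: {sorted(unknown)[:5]}")
        if self.calls.duplicated(["mirna_id", "gene_id", "algorithm_id"]).any():
            raise ValueError("duplicate (mirna, gene, algorithm) triples")

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class ConsensusMap:
    """Retained (gene, mirna) pairs with their algorithm support counts."""

    pairs: pd.DataFrame  # columns: gene_id, mirna_id, support
    min_algorithms: int

    def binder_sets(self, universe: Iterable[str] | None = None) -> dict[str, set[str]]:
        """gene_id -> set of consensus-binding miRNAs, optionally restricted
        to a screened miRNA universe."""
        df = self.pairs
        if universe is not None:
            df = df[df["mirna_id"].isin(set(universe))]
        return {g: set(sub["mirna_id"]) for g, sub in df.groupby("gene_id", sort=True)}

    def genes_targeted_by(self, mirnas: Iterable[str]) -> set[str]:
        """Genes with at least one retained pair whose miRNA is in ``mirnas``
        (the putative-target-gene funnel stage)."""
        m = set(mirnas)
        sub = self.pairs[self.pairs["mirna_id"].isin(m)]
        return set(sub["gene_id"])


@dataclass
class ConvergenceMap:
    """Genes supported by both screens and their candidate binder subsets."""

    gene_to_candidates: dict[str, frozenset[str]]
    active_candidates: frozenset[str]
    candidates: frozenset[str]
    sirna_hits: frozenset[str]

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_candidates)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "n_candidate_binders": len(ms),
             "candidate_binders": ",".join(sorted(ms))}
            for g, ms in sorted(self.gene_to_candidates.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "n_candidate_binders", "candidate_binders"])


def consensus_targets(calls: PredictionCallSet, min_algorithms: int = 4) -> ConsensusMap:
    """Retain (mirna, gene) pairs called by >= ``min_algorithms`` distinct algorithms.

    Raising the threshold can only remove pairs (antitone), never add them.
    """
    if min_algorithms < 1 or min_algorithms > len(calls.algorithms):
        raise ValueError(
            f"min_algorithms must be in [1, {len(calls.algorithms)}], got {min_algorithms}"
        )
    support = (
        calls.calls.groupby(["gene_id", "mirna_id"], sort=True)["algorithm_id"]
        .nunique()
        .rename("support")
        .reset_index()
    )
    retained = support[support["support"] >= min_algorithms].reset_index(drop=True)
    return ConsensusMap(pairs=retained, min_algorithms=min_algorithms)


def converge_with_sirna(
    consensus: ConsensusMap,
    candidates: Iterable[str],
    sirna_hits: Iterable[str],
) -> ConvergenceMap:
    """Intersect candidate-miRNA targets with the siRNA-screen hit list.

    A gene is retained iff it is an siRNA hit *and* has at least one
    consensus binder among the candidate miRNAs.  Also reports the set of
    candidates with at least one retained gene (the screen's "active"
    miRNAs).  An empty intersection is a legitimate outcome and only
    warns.
    """
    candidates = frozenset(candidates)
    sirna_hits = frozenset(sirna_hits)
    if not candidates:
        raise ValueError("candidate miRNA set must be nonempty")

    sub = consensus.pairs
    sub = sub[sub["mirna_id"].isin(candidates) & sub["gene_id"].isin(sirna_hits)]
    gene_to_candidates = {
        g: frozenset(s["mirna_id"]) for g, s in sub.groupby("gene_id", sort=True)
    }
    active: frozenset[str] = frozenset().union(*gene_to_candidates.values()) \
        if gene_to_candidates else frozenset()
    if not gene_to_candidates:
        warnings.warn(
            "no genes are both siRNA hits and candidate-miRNA targets",
            stacklevel=2,
        )
    return ConvergenceMap(
        gene_to_candidates=gene_to_candidates,
        active_candidates=active,
        candidates=candidates,
        sirna_hits=sirna_hits,
    )
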