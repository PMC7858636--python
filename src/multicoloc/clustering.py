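"""Branch-and-bound divisive clustering of traits into colocalized groups.

Starting from all traits in one cluster, the algorithm accepts the cluster
when both P_R >= P_R* and P_A >= P_A* (equivalently PPFC >= tau with both
marginals bounded); otherwise it removes the trait whose exclusion branch
carries the most posterior evidence — regional branches (one trait null,
O(kQ)) by default, alignment branches (one trait causal elsewhere, O(kQ^2))
optionally — and recurses on the remainder. A cluster that shrinks to one
trait marks that trait as unclustered and the whole procedure restarts on
everything still unassigned. A pairwise-closure baseline emulating repeated
two-trait analyses is provided for benchmarking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .bayes import CorrelationModel
from .posterior import PosteriorBreakdown, ppfc
from .priors import PriorSpec

__all__ = ["AlgorithmConfig", "ClusterResult", "bb_cluster", "branch_evidence", "pairwise_baseline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlgorithmConfig:
    """Stopping thresholds and branch criterion for the divisive search.

    ``p_r_star``/``p_a_star`` are the acceptance bounds on the regional and
    alignment probabilities (defaults 0.5 each, so tau = 0.25);
    ``report_threshold`` flags clusters whose PPFC clears the reporting bar
    (default 0.7).
    """

    p_r_star: float = 0.5
    p_a_star: float = 0.5
    branch_criterion: str = "regional"
    report_threshold: float = 0.7

    def __post_init__(self) -> None:
        if not (0 < self.p_r_star <= 1 and 0 < self.p_a_star <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.branch_criterion not in ("regional", "alignment"):
            raise ValueError("branch_criterion must be 'regional' or 'alignment'")


@dataclass
class ClusterResult:
    """One emitted cluster: member trait indices (region order), its
    posterior breakdown, the candidate shared SNP and the proportion of the
    colocalization posterior it explains (PPE)."""

    trait_indices: tuple
    breakdown: PosteriorBreakdown
    candidate_snp: str
    ppe: float
    passes_report_threshold: bool


def branch_evidence(region, priors: PriorSpec, criterion: str = "regional",
                    corr: CorrelationModel | None = None) -> np.ndarray:
    """Per-trait branch evidence within a cluster (k >= 2 traits).

    The regional criterion returns the posterior mass of each
    drop-one-trait-null class; the alignment criterion the mass of each
    drop-one-trait-causal-elsewhere class. The argmax names the trait whose
    removal is best supported.
    """
    bd = ppfc(region, priors, corr)
    if criterion == "regional":
        return bd.regional_branch_evidence
    if criterion == "alignment":
        return bd.alignment_branch_evidence
    raise ValueError("criterion must be 'regional' or 'alignment'")


def bb_cluster(
    region,
    priors: PriorSpec,
    config: AlgorithmConfig | None = None,
    corr: CorrelationModel | None = None,
) -> tuple[list[ClusterResult], list[int]]:
    """Partition traits into colocalized clusters by divisive search.

    Returns the accepted clusters (each satisfying P_R >= P_R* and
    P_A >= P_A* by construction) and the list of unclustered trait indices.
    Deterministic: exact evidence ties remove the lowest trait index.
    """
    config = config or AlgorithmConfig()
    clusters: list[ClusterResult] = []
    unclustered: list[int] = []
    remaining = list(range(region.m))

    while len(remaining) >= 2:
        current = list(remaining)
        accepted = False
        while len(current) >= 2:
            sub = region.subset_traits(current)
            sub_corr = corr.subset(current) if corr is not None else None
            bd = ppfc(sub, priors, sub_corr)
            logger.info(
                "cluster %s: P_R=%.4f P_A=%.4f", [region.trait_names[i] for i in current],
                bd.p_r, bd.p_a,
            )
            if bd.p_r >= config.p_r_star and bd.p_a >= config.p_a_star:
                clusters.append(
                    ClusterResult(
                        trait_indices=tuple(current),
                        breakdown=bd,
                        candidate_snp=region.snp_ids[bd.top_snp_index],
                        ppe=bd.ppe,
                        passes_report_threshold=bd.ppfc > config.report_threshold,
                    )
                )
                remaining = [i for i in remaining if i not in current]
                accepted = True
                break
            ev = (
                bd.regional_branch_evidence
                if config.branch_criterion == "regional"
                else bd.alignment_branch_evidence
            )
            logger.debug("branch evidence: %s", ev)
            drop = current[int(np.argmax(ev))]
            current = [i for i in current if i != drop]
        if not accepted:
            # the descent bottomed out at a singleton: that trait does not
            # colocalize with any other; restart on everything else
            unclustered.append(current[0])
            remaining = [i for i in remaining if i != current[0]]
    unclustered.extend(remaining)
    return clusters, sorted(unclustered)


def pairwise_baseline(
    region,
    priors: PriorSpec,
    config: AlgorithmConfig | None = None,
) -> list[ClusterResult]:
    """Pairwise-analysis emulator: run the two-trait posterior for every
    pair and form maximal trait sets in which *every* pair clears the
    report threshold (clique closure). Greedy order: pairs are seeded in
    descending pair posterior, and clusters grow by the candidate trait
    whose weakest link is strongest. Benchmarking aid only.
    """
    config = config or AlgorithmConfig()
    m = region.m
    pair_post: dict[tuple[int, int], float] = {}
    pair_bd: dict[tuple[int, int], PosteriorBreakdown] = {}
    for i, j in itertools.combinations(range(m), 2):
        bd = ppfc(region.subset_traits([i, j]), priors)
        pair_post[(i, j)] = bd.ppfc
        pair_bd[(i, j)] = bd

    def post(a: int, b: int) -> float:
        return pair_post[(min(a, b), max(a, b))]

    passing = [p for p, v in sorted(pair_post.items(), key=lambda kv: -kv[1])
               if v > config.report_threshold]
    assigned: set[int] = set()
    clusters: list[ClusterResult] = []
    for i, j in passing:
        if i in assigned or j in assigned:
            continue
        members = [i, j]
        while True:
            candidates = [
                t for t in range(m)
                if t not in assigned and t not in members
                and all(post(t, u) > config.report_threshold for u in members)
            ]
            if not candidates:
                break
            members.append(max(candidates, key=lambda t: min(post(t, u) for u in members)))
        members.sort()
        bd = ppfc(region.subset_traits(members), priors)
        clusters.append(
            ClusterResult(
                trait_indices=tuple(members),
                breakdown=bd,
                candidate_snp=region.snp_ids[bd.top_snp_index],
                ppe=bd.ppe,
                passes_report_threshold=bd.ppfc > config.report_threshold,
            )
        )
        assigned.update(members)
    return clusters
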