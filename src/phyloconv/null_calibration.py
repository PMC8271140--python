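"""Simulation-based null distribution of the simultaneous score and
significance thresholds with two Bonferroni corrections.

The null keeps the empirical tree and the empirical phenotype events fixed
and re-draws genotype events only: each null site receives a substitution
count drawn from the empirical substitutions-per-site histogram, events are
placed on branches with probability proportional to branch length (at most
one event per branch per site), and event states follow a random walk over
the 20 amino acids (each step moves to one of the 19 other residues,
uniformly).  The same best-foreground maximisation used on real sites is
applied to every null site, so observed and null scores are comparable.

Correction 1 divides the nominal level by the number of sites; Correction 2
additionally divides by the number of test types (3: convergence, GWAS,
all-changes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .ancestral import BranchEvent
from .simultaneous_scores import ApproachKind, SiteScoreRecord
from .trees import Phylogeny

logger = logging.getLogger(__name__)

N_TEST_TYPES = 3


class CorrectionKind(str, Enum):
    CORRECTION1 = "correction1"  # alpha / n_sites
    CORRECTION2 = "correction2"  # alpha / (n_sites * n_tests)


@dataclass
class SubstCountDistribution:
    """Empirical distribution of reconstructed substitutions per site."""

    values: np.ndarray  # distinct substitution counts
    probs: np.ndarray  # frequencies, sum to 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.values) == 0:
            raise ValueError("empty substitution-count distribution")
        if np.any(self.values < 0):
            raise ValueError("substitution counts must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-9 or np.any(self.probs < 0):
            raise ValueError("probabilities must form a simplex")

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))


def empirical_subst_distribution(event_counts) -> SubstCountDistribution:
    """Histogram of per-site event counts (from branch-event extraction)."""
    counts = np.asarray(list(event_counts), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("need at least one site")
    values, n = np.unique(counts, return_counts=True)
    return SubstCountDistribution(values=values, probs=n / n.sum())


@dataclass
class NullScoreDistribution:
    approach: ApproachKind
    scores: np.ndarray  # best score of each simulated null site
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)

    @property
    def n_replicates(self) -> int:
        return len(self.scores)

    def tail_probability(self, s: int) -> float:
        """Monte-Carlo estimate of P(score >= s)."""
        return float((self.scores >= s).mean())


@dataclass
class SignificanceThreshold:
    approach: ApproachKind
    alpha: float
    correction: CorrectionKind
    threshold: int
    corrected_level: float
    resolution_limited: bool = False


def _phenotype_branch_rows(tree: Phylogeny, pheno_events: list[BranchEvent]):
    """Preorder-rank row indices of phenotype gain/loss branches."""
    branch_nodes = tree.branch_nodes()  # preorder
    rank = {int(n): r for r, n in enumerate(branch_nodes)}
    gains, losses = [], []
    for e in pheno_events:
        r = rank[tree.label_to_index[e.branch]]
        (gains if e.to_state == "1" else losses).append(r)
    return branch_nodes, np.array(gains, np.int64), np.array(losses, np.int64)


def simulate_null_sites(
    tree: Phylogeny,
    pheno_events: list[BranchEvent],
    dist: SubstCountDistribution,
    n_sites: int,
    approach: ApproachKind,
    seed: int,
    n_aa: int = 20,
) -> NullScoreDistribution:
    """Null score sample of ``n_sites`` simulated sites (vectorised).

    Deterministic for a given (tree, phenotype events, dist, seed).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    scores = _null_scores_all_approaches(
        tree, pheno_events, dist, n_sites, rng, n_aa=n_aa
    )[approach]
    return NullScoreDistribution(approach=approach, scores=scores, seed=seed)


def _null_scores_all_approaches(
    tree: Phylogeny,
    pheno_events: list[BranchEvent],
    dist: SubstCountDistribution,
    n_sites: int,
    rng: np.random.Generator,
    n_aa: int = 20,
) -> dict[ApproachKind, np.ndarray]:
    """Simulate null sites once and score them under all three approaches.

    One RNG stream drives event placement and the state walk; the three
    scores are pure functions of the same simulated events.
    """
    branch_nodes, gain_rows, loss_rows = _phenotype_branch_rows(tree, pheno_events)
    n_branches = len(branch_nodes)
    weights = tree.blen[branch_nodes]
    inv_w = (1.0 / weights).astype(np.float32)
    gain_mask = np.zeros(n_branches, dtype=bool)
    gain_mask[gain_rows] = True
    loss_mask = np.zeros(n_branches, dtype=bool)
    loss_mask[loss_rows] = True

    k_all = rng.choice(dist.values, size=n_sites, p=dist.probs)
    k_all = np.minimum(k_all, n_branches)

    conv = np.zeros(n_sites, dtype=np.int64)
    gwas = np.zeros(n_sites, dtype=np.int64)
    allc = np.zeros(n_sites, dtype=np.int64)

    # sites with equal substitution count are exchangeable: process them in
    # groups so the weighted sampling without replacement (exponential keys
    # Exp(1)/w_b, k smallest win; Efraimidis-Spirakis) only partitions to
    # the group's own k.
    chunk = max(1, int(2e7) // n_branches)
    for kval in np.unique(k_all):
        if kval == 0:
            continue
        idx = np.flatnonzero(k_all == kval)
        for lo in range(0, len(idx), chunk):
            rows = idx[lo : lo + chunk]
            nk = len(rows)
            keys = rng.standard_exponential(
                size=(nk, n_branches), dtype=np.float32
            )
            keys *= inv_w[None, :]
            if kval < n_branches:
                top = np.argpartition(keys, kval, axis=1)[:, :kval]
            else:
                top = np.broadcast_to(
                    np.arange(n_branches), (nk, n_branches)
                ).copy()
            # events are chained along each site in preorder branch order
            chosen = np.sort(top, axis=1)

            # random walk over amino acids: s_i = (s_0 + sum of deltas) mod
            # n_aa with deltas uniform on 1..n_aa-1, so consecutive states
            # always differ and each event is a real change
            s0 = rng.integers(0, n_aa, size=nk)
            deltas = rng.integers(1, n_aa, size=(nk, kval))
            states = (s0[:, None] + np.cumsum(deltas, axis=1)) % n_aa
            from_states = np.concatenate([s0[:, None], states[:, :-1]], axis=1)

            on_gain = gain_mask[chosen]
            on_loss = loss_mask[chosen]
            allc[rows] = (on_gain | on_loss).sum(axis=1)

            # per-site per-aa coincidence counts, maximised over foreground
            site_idx = np.broadcast_to(np.arange(nk)[:, None], (nk, kval))
            counts = np.zeros((nk, n_aa), dtype=np.int64)
            np.add.at(counts, (site_idx[on_gain], states[on_gain]), 1)
            conv[rows] = counts.max(axis=1)
            np.add.at(counts, (site_idx[on_loss], from_states[on_loss]), 1)
            gwas[rows] = counts.max(axis=1)
    return {
        ApproachKind.CONVERGENCE: conv,
        ApproachKind.GWAS: gwas,
        ApproachKind.ALL_CHANGES: allc,
    }


def significance_threshold(
    null: NullScoreDistribution,
    alpha: float,
    n_sites: int,
    correction: CorrectionKind,
    n_tests: int = N_TEST_TYPES,
) -> SignificanceThreshold:
    """Smallest score whose null tail probability is below the corrected level."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    level = alpha / n_sites
    if correction == CorrectionKind.CORRECTION2:
        level /= n_tests
    max_obs = int(null.scores.max()) if null.n_replicates else 0
    resolution_limited = level < 1.0 / null.n_replicates
    if resolution_limited:
        logger.warning(
            "corrected level %.3g below Monte-Carlo resolution 1/%d; "
            "threshold set beyond the observed null support",
            level,
            null.n_replicates,
        )
        threshold = max_obs + 1
    else:
        threshold = max_obs + 1
        for s in range(0, max_obs + 1):
            if null.tail_probability(s) <= level:
                threshold = s
                break
        if threshold > max_obs:
            # the required quantile lies beyond the simulated support
            resolution_limited = True
    return SignificanceThreshold(
        approach=null.approach,
        alpha=alpha,
        correction=correction,
        threshold=threshold,
        corrected_level=level,
        resolution_limited=resolution_limited,
    )


def classify_sites(
    records: list[SiteScoreRecord],
    threshold1: SignificanceThreshold,
    threshold2: SignificanceThreshold,
) -> list[SiteScoreRecord]:
    """Annotate records in place with significance flags under both corrections."""
    for t in (threshold1, threshold2):
        if records and t.approach != records[0].approach:
            raise ValueError("threshold approach does not match records")
    for r in records:
        r.threshold_correction1 = threshold1.threshold
        r.threshold_correction2 = threshold2.threshold
        r.significant_correction1 = r.score >= threshold1.threshold
        r.significant_correction2 = r.score >= threshold2.threshold
    return records
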