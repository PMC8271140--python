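"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package's
vectorised implementations: likelihoods by explicit enumeration of joint
internal-node assignments, scores by literal set logic, Fisher p-values by
hypergeometric enumeration, and a slow per-site null simulator.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import hypergeom


def enum_likelihood_and_marginals(tree, tip_codes, p_matrices, root_freqs):
    """Joint enumeration over all internal-node state assignments.

    Parameters
    ----------
    tree : Phylogeny
    tip_codes : dict node_index -> state code (or -1 for missing)
    p_matrices : (n_nodes, k, k) transition matrix of the branch above
        each node (per-branch matrices allow class-heterogeneous models)
    root_freqs : (k,) root state distribution

    Returns (log-likelihood, marginals (n_nodes, k)).
    """
    k = len(root_freqs)
    internal = [i for i in range(tree.n_nodes) if not tree.is_tip[i]]
    tips = list(tree.tip_indices)
    total = 0.0
    marg = np.zeros((tree.n_nodes, k))
    tip_choices = {
        i: ([tip_codes[i]] if tip_codes[i] >= 0 else list(range(k))) for i in tips
    }
    for assign in itertools.product(range(k), repeat=len(internal)):
        states = dict(zip(internal, assign))
        for tip_assign in itertools.product(*(tip_choices[i] for i in tips)):
            states.update(zip(tips, tip_assign))
            prob = root_freqs[states[tree.root]]
            for i in range(tree.n_nodes):
                if i == tree.root:
                    continue
                prob *= p_matrices[i][states[tree.parent[i]], states[i]]
            total += prob
            for i in range(tree.n_nodes):
                marg[i, states[i]] += prob
    return np.log(total), marg / total


def brute_convergence(pheno_events, aa_events, fg_aa):
    gains = {e.branch for e in pheno_events if (e.from_state, e.to_state) == ("0", "1")}
    return len([e for e in aa_events if e.to_state == fg_aa and e.branch in gains])


def brute_gwas(pheno_events, aa_events, fg_aa):
    gains = {e.branch for e in pheno_events if (e.from_state, e.to_state) == ("0", "1")}
    losses = {e.branch for e in pheno_events if (e.from_state, e.to_state) == ("1", "0")}
    n = 0
    for e in aa_events:
        if e.branch in gains and e.to_state == fg_aa:
            n += 1
        elif e.branch in losses and e.from_state == fg_aa:
            n += 1
    return n


def brute_all_changes(pheno_events, aa_events):
    return len({e.branch for e in pheno_events} & {e.branch for e in aa_events})


def brute_best(pheno_events, aa_events, scorer):
    aas = {e.from_state for e in aa_events} | {e.to_state for e in aa_events}
    if not aas:
        return 0
    return max(scorer(pheno_events, aa_events, a) for a in aas)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumeration of the hypergeometric support."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def reference_null_scores(tree, pheno_events, dist, n_sites, rng, n_aa=20):
    """Slow, per-site reimplementation of the null-site simulator.

    Same declared scheme (counts from the empirical histogram, placement
    proportional to branch length without replacement, preorder-chained
    uniform random walk over amino acids, best-foreground maximisation)
    but a completely separate code path and RNG stream.
    """
    branch_nodes = tree.branch_nodes()
    w = tree.blen[branch_nodes] / tree.blen[branch_nodes].sum()
    gains, losses = set(), set()
    for e in pheno_events:
        (gains if e.to_state == "1" else losses).add(tree.label_to_index[e.branch])
    out = {"convergence": [], "gwas": [], "all_changes": []}
    for _ in range(n_sites):
        k = int(rng.choice(dist.values, p=dist.probs))
        k = min(k, len(branch_nodes))
        if k == 0:
            for v in out.values():
                v.append(0)
            continue
        rows = rng.choice(len(branch_nodes), size=k, replace=False, p=w)
        chosen = [int(branch_nodes[r]) for r in sorted(rows)]
        state = int(rng.integers(n_aa))
        events = []  # (node, from, to)
        for node in chosen:
            nxt = (state + int(rng.integers(1, n_aa))) % n_aa
            events.append((node, state, nxt))
            state = nxt
        out["all_changes"].append(
            len([1 for node, _, _ in events if node in gains or node in losses])
        )
        best_c = best_g = 0
        for aa in range(n_aa):
            c = len([1 for node, _, to in events if node in gains and to == aa])
            g = c + len([1 for node, fr, _ in events if node in losses and fr == aa])
            best_c, best_g = max(best_c, c), max(best_g, g)
        out["convergence"].append(best_c)
        out["gwas"].append(best_g)
    return {key: np.array(v) for key, v in out.items()}
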