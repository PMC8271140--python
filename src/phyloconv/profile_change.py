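"""Site-specific amino acid profile change between phenotype branch classes.

For each alignment site, asks whether the amino acid propensity profile
differs between the branches whose reconstructed phenotype is foreground
and those whose phenotype is background.  The model space is a fixed finite
library of propensity profiles (a synthetic CAT-C10-like set shipped with
the package; see ``data/profiles_c10_like_synthetic.tsv``): under the
no-change model one library profile governs the whole tree, under the
change model the foreground and background branch classes carry two
different profiles.  With equal prior odds on the two model classes and
the library's prior weights within each class, the reported score is the
posterior probability of the change model.

A quadrant (2x2) Fisher exact test relates the per-site simultaneous score
to the profile-change posterior: sites are dichotomised at a score cutoff
(default: mid-range) and at posterior 0.5, and independence is tested
two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import fisher_exact

from .ancestral import (
    AA_ALPHABET,
    LOGLIK_FLOOR,
    CharacterStateMap,
    SubstitutionModel,
    site_log_likelihoods,
)
from .trees import Phylogeny

logger = logging.getLogger(__name__)


def validate_profile(profile: np.ndarray) -> np.ndarray:
    p = np.asarray(profile, dtype=float)
    if p.shape != (20,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("profile must be a 20-simplex")
    return p / p.sum()


@dataclass
class ProfileLibrary:
    """Finite mixture of amino acid propensity profiles with prior weights."""

    profiles: np.ndarray  # (m, 20)
    weights: np.ndarray  # (m,) simplex
    names: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[1] != 20:
            raise ValueError("profiles must be (m, 20)")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    @classmethod
    def default(cls) -> "ProfileLibrary":
        """The shipped 10-profile synthetic library (uniform prior weights)."""
        path = resources.files("phyloconv.data").joinpath(
            "profiles_c10_like_synthetic.tsv"
        )
        names, rows = [], []
        with path.open() as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("profile\t"):
                    continue
                parts = line.rstrip("\n").split("\t")
                names.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        profiles = np.array(rows)
        m = len(names)
        return cls(profiles=profiles, weights=np.full(m, 1.0 / m), names=names)


@dataclass
class BranchPartition:
    """Foreground/background split of all branches (by child node label)."""

    foreground: set[str]
    background: set[str]
    root_class: int = 0  # phenotype MAP state at the root

    def __post_init__(self) -> None:
        if self.foreground & self.background:
            raise ValueError("foreground and background branches must be disjoint")


@dataclass
class ProfileChangeResult:
    gene: str
    site: int
    posterior: float
    best_foreground_profile: int
    best_background_profile: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError("posterior must lie in [0, 1]")


def partition_branches(tree: Phylogeny, pheno_states: CharacterStateMap) -> BranchPartition:
    """Assign each branch to a class by its child node's MAP phenotype.

    Branches on which the phenotype changes are assigned by the child
    state, i.e. a gain branch already belongs to the foreground class.
    """
    fg, bg = set(), set()
    for i in range(tree.n_nodes):
        if tree.parent[i] < 0:
            continue
        (fg if pheno_states.map_state[tree.labels[i]] == "1" else bg).add(tree.labels[i])
    root_class = int(pheno_states.map_state[tree.labels[tree.root]])
    return BranchPartition(foreground=fg, background=bg, root_class=root_class)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------
def _fg_node_mask(tree: Phylogeny, partition: BranchPartition) -> np.ndarray:
    mask = np.zeros(tree.n_nodes, dtype=bool)
    for lab in partition.foreground:
        mask[tree.label_to_index[lab]] = True
    return mask


def _profile_models(
    library_profiles: np.ndarray, exchangeabilities: np.ndarray | None
) -> list[SubstitutionModel]:
    # CAT-style: shared exchangeabilities (uniform by default), per-profile
    # stationary frequencies; each model normalised to 1 sub/unit length.
    models = []
    for p in library_profiles:
        pi = np.maximum(p, 0.0)
        pi = pi / pi.sum()
        if exchangeabilities is None:
            m = SubstitutionModel.poisson(AA_ALPHABET, freqs=pi)
        else:
            m = SubstitutionModel(AA_ALPHABET, exchangeabilities, pi)
        models.append(m)
    return models


def _tip_codes(tree: Phylogeny, site_states: dict) -> np.ndarray:
    lut = {c: i for i, c in enumerate(AA_ALPHABET)}
    codes = np.empty((tree.n_tips, 1), dtype=np.int64)
    for row, i in enumerate(tree.tip_indices):
        codes[row, 0] = lut.get(str(site_states[tree.labels[i]]), -1)
    return codes


def _pair_logliks(
    tree: Phylogeny,
    codes: np.ndarray,
    fg_mask: np.ndarray,
    models: list[SubstitutionModel],
    pairs: np.ndarray,  # (P, 2) [fg_idx, bg_idx]
    rate: float,
    root_class: int,
) -> np.ndarray:
    """Pruning log-likelihood of one site under P (fg, bg) profile pairs.

    Vectorised over pairs: each branch uses the transition matrix of the
    profile its class points to; the root draws from the profile of the
    root's own class.
    """
    n_pairs = len(pairs)
    k = models[0].n_states
    p_stack = np.stack([m.transition_matrices(tree.blen, rate) for m in models])
    prof_col = np.where(fg_mask[None, :], pairs[:, 0:1], pairs[:, 1:2])  # (P, n_nodes)
    obs = codes[:, 0]
    partials = np.ones((tree.n_nodes, n_pairs, k))
    for row, i in enumerate(tree.tip_indices):
        if obs[row] >= 0:
            partials[i] = 0.0
            partials[i, :, obs[row]] = 1.0
    messages = np.empty_like(partials)
    logscale = np.zeros(n_pairs)
    for i in range(tree.n_nodes):
        if not tree.is_tip[i]:
            prod = np.ones((n_pairs, k))
            for c in tree.children[i]:
                prod = prod * messages[c]
            mx = prod.max(axis=1)
            bad = mx <= 0.0
            if bad.any():
                mx = np.where(bad, 1.0, mx)
                logscale += np.where(bad, LOGLIK_FLOOR / tree.n_nodes, 0.0)
            prod /= mx[:, None]
            logscale += np.log(mx)
            partials[i] = prod
        if i != tree.root:
            pm = p_stack[prof_col[:, i], i]  # (P, k, k)
            messages[i] = np.einsum("pab,pb->pa", pm, partials[i])
    root_prof = pairs[:, 0] if root_class == 1 else pairs[:, 1]
    pi = np.stack([models[j].freqs for j in root_prof])
    lik = np.einsum("pk,pk->p", pi, partials[tree.root])
    out = np.where(lik > 0, np.log(np.maximum(lik, 1e-300)) + logscale, LOGLIK_FLOOR)
    return np.maximum(out, LOGLIK_FLOOR)


def site_profile_likelihood(
    tree: Phylogeny,
    site_states: dict,
    partition: BranchPartition,
    fg_profile: np.ndarray,
    bg_profile: np.ndarray,
    rate: float = 1.0,
    exchangeabilities: np.ndarray | None = None,
) -> float:
    """Pruning log-likelihood of one site with class-dependent profiles.

    With ``fg_profile == bg_profile`` this reduces to a plain single-profile
    pruning likelihood.  A profile with zero mass on an observed residue
    yields the documented floor value instead of ``-inf``.
    """
    fg_profile = validate_profile(fg_profile)
    bg_profile = validate_profile(bg_profile)
    models = _profile_models(np.stack([fg_profile, bg_profile]), exchangeabilities)
    ll = _pair_logliks(
        tree,
        _tip_codes(tree, site_states),
        _fg_node_mask(tree, partition),
        models,
        np.array([[0, 1]]),
        rate,
        partition.root_class,
    )[0]
    if ll <= LOGLIK_FLOOR:
        logger.warning("site likelihood underflow: profile excludes observed residue")
    return float(ll)


def _null_rate_ml(
    tree, codes, fg_mask, models, weights, root_class, bounds=(1e-2, 1e2)
) -> float:
    diag = np.stack([np.arange(len(models))] * 2, axis=1)
    logw = np.log(weights)

    def neg(logr):
        ll = _pair_logliks(tree, codes, fg_mask, models, diag, np.exp(logr), root_class)
        return -logsumexp(ll + logw)

    res = minimize_scalar(
        neg,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 0.1, "maxiter": 18},
    )
    return float(np.exp(res.x))


def profile_change_posterior(
    tree: Phylogeny,
    site_states: dict,
    partition: BranchPartition,
    library: ProfileLibrary | None = None,
    rate: float | str = "ml",
    exchangeabilities: np.ndarray | None = None,
    gene: str = "",
    site: int = 0,
) -> ProfileChangeResult:
    """Posterior probability that the site's profile differs between classes.

    The change model averages over ordered profile pairs (fg != bg), the
    no-change model over single shared profiles; prior odds between the two
    model classes are 1:1.  The site-specific rate is fitted by ML under
    the no-change model and then held fixed, so rate variation is not
    mistaken for a profile change.
    """
    if not partition.foreground:
        raise ValueError("no foreground branches: phenotype never reconstructed as 1")
    if not partition.background:
        raise ValueError("no background branches")
    if library is None:
        library = ProfileLibrary.default()
    m = library.n_profiles
    if m < 2:
        return ProfileChangeResult(gene, site, 0.0, 0, 0)
    codes = _tip_codes(tree, site_states)
    fg_mask = _fg_node_mask(tree, partition)
    models = _profile_models(library.profiles, exchangeabilities)
    if rate == "ml":
        rate = _null_rate_ml(
            tree, codes, fg_mask, models, library.weights, partition.root_class
        )
    f, b = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    pairs = np.stack([f.ravel(), b.ravel()], axis=1)  # all (fg, bg) combos
    ll = _pair_logliks(
        tree, codes, fg_mask, models, pairs, float(rate), partition.root_class
    )
    logw = np.log(library.weights)
    pair_logw = logw[pairs[:, 0]] + logw[pairs[:, 1]]
    same = pairs[:, 0] == pairs[:, 1]
    log_null = logsumexp(ll[same] + logw[pairs[same, 0]])
    log_oc = logsumexp(ll[~same] + pair_logw[~same]) - logsumexp(pair_logw[~same])
    # normalise the null mixture weights too (they already sum to 1)
    posterior = float(1.0 / (1.0 + np.exp(log_null - log_oc)))
    best = pairs[~same][np.argmax(ll[~same])]
    return ProfileChangeResult(
        gene=gene,
        site=site,
        posterior=posterior,
        best_foreground_profile=int(best[0]),
        best_background_profile=int(best[1]),
    )


# ---------------------------------------------------------------------------
# quadrant Fisher cross-test
# ---------------------------------------------------------------------------
@dataclass
class QuadrantTestResult:
    table: np.ndarray  # [[hi/hi, hi/lo], [lo/hi, lo/lo]] (sim x profile-change)
    p_value: float
    sim_cutoff: int
    pc_cutoff: float
    degenerate: bool = False


def quadrant_fisher(
    sim_scores,
    pc_scores,
    sim_cutoff: int | None = None,
    pc_cutoff: float = 0.5,
) -> QuadrantTestResult:
    """Two-sided Fisher exact test of the 2x2 quadrant table.

    Sites are split at ``sim_cutoff`` (default: half the maximum observed
    score, rounded up — mid-range on the discrete score scale) and at
    ``pc_cutoff`` on the profile-change posterior.  A table with an empty
    row or column carries no information: p-value 1 with a warning.
    """
    sim = np.asarray(sim_scores)
    pc = np.asarray(pc_scores, dtype=float)
    if sim.shape != pc.shape:
        raise ValueError("paired score lists must have equal length")
    if sim_cutoff is None:
        sim_cutoff = int(np.ceil(sim.max() / 2)) if sim.size else 0
    hi_sim = sim >= sim_cutoff
    hi_pc = pc > pc_cutoff
    table = np.array(
        [
            [int((hi_sim & hi_pc).sum()), int((hi_sim & ~hi_pc).sum())],
            [int((~hi_sim & hi_pc).sum()), int((~hi_sim & ~hi_pc).sum())],
        ]
    )
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        warnings.warn("degenerate quadrant table (empty row or column); p = 1")
        p = 1.0
    else:
        _, p = fisher_exact(table, alternative="two-sided")
    return QuadrantTestResult(
        table=table,
        p_value=float(p),
        sim_cutoff=int(sim_cutoff),
        pc_cutoff=float(pc_cutoff),
        degenerate=degenerate,
    )


def write_profile_change_table(results: list[ProfileChangeResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsite\tpc_posterior\tbest_fg_profile\tbest_bg_profile\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.site}\t{r.posterior:.6f}\t"
                f"{r.best_foreground_profile}\t{r.best_background_profile}\n"
            )
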