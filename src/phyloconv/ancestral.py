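"""Marginal ancestral state reconstruction for amino acid sites and traits.

Implements continuous-time Markov models of character evolution on a rooted
phylogeny: Felsenstein's pruning algorithm for the likelihood, a two-pass
(inside/outside) computation of per-node marginal posteriors, hard MAP state
assignment, and extraction of branch events (branches whose parent and child
MAP states differ).  These events are the atoms counted by the simultaneous
scores.

The default amino acid model combines the LG empirical exchangeabilities
(Le & Gascuel 2008; shipped as ``data/lg.dat`` in PAML layout) with either
the LG frequencies or alignment-wide observed frequencies.  The binary
phenotype is modelled as a two-state chain with separate gain and loss
rates, fitted by maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .io_formats import AMINO_ACIDS, Alignment
from .trees import Phylogeny

logger = logging.getLogger(__name__)

AA_ALPHABET = AMINO_ACIDS  # PAML ordering, shared with the LG data file

#: Per-site log-likelihood floor used when a character assignment has zero
#: probability under the model (e.g. a profile with zero mass on an
#: observed residue).
LOGLIK_FLOOR = -1e6


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------
@dataclass
class SubstitutionModel:
    """Time-reversible CTMC over a finite character alphabet.

    The rate matrix is assembled as ``Q[i, j] = s[i, j] * pi[j]`` from a
    symmetric exchangeability matrix ``s`` and stationary frequencies
    ``pi``.  When ``normalized`` is True, Q is rescaled to one expected
    substitution per unit branch length at stationarity, so branch lengths
    are in expected-substitution units and ``rate`` acts as a relative
    rate multiplier.
    """

    alphabet: str
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    rate: float = 1.0
    normalized: bool = True
    name: str = "custom"
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if s.shape != (k, k):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be a simplex (sum 1)")
        if self.rate <= 0:
            raise ValueError("rate multiplier must be positive")
        self.exchangeabilities = s
        self.freqs = pi

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def rate_matrix(self) -> np.ndarray:
        """Assembled Q (rows sum to zero), before the ``rate`` multiplier."""
        q = self.exchangeabilities * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        if self.normalized:
            mu = -np.dot(self.freqs, np.diag(q))
            if mu > 0:
                q = q / mu
        return q

    def _eigen(self):
        # reversible Q diagonalised through the symmetric similarity
        # B = D^{1/2} Q D^{-1/2}; guards pi=0 states with a tiny floor.
        if self._eig is None:
            q = self.rate_matrix()
            pi = np.maximum(self.freqs, 1e-300)
            d = np.sqrt(pi)
            b = (q * d[:, None]) / d[None, :]
            b = 0.5 * (b + b.T)
            w, v = np.linalg.eigh(b)
            u = v / d[None, :].T  # rows scaled: U = D^{-1/2} V
            uinv = (v * d[:, None]).T  # U^{-1} = V^T D^{1/2}
            self._eig = (w, u, uinv)
        return self._eig

    def transition_matrices(
        self, t: np.ndarray, rate: float | None = None
    ) -> np.ndarray:
        """P(t_b) for an array of branch lengths; shape (len(t), k, k)."""
        w, u, uinv = self._eigen()
        r = self.rate if rate is None else rate
        t = np.asarray(t, dtype=float)
        e = np.exp(np.outer(t * r, w))  # (B, k)
        p = np.einsum("ij,bj,jk->bik", u, e, uinv)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p

    def encode(self, symbols) -> np.ndarray:
        """Map symbols to state indices; unknown symbols -> -1 (missing)."""
        lut = {c: i for i, c in enumerate(self.alphabet)}
        return np.array([lut.get(s, -1) for s in symbols], dtype=np.int64)

    # -- constructors -------------------------------------------------------
    @classmethod
    def poisson(cls, alphabet: str = AA_ALPHABET, freqs=None) -> "SubstitutionModel":
        k = len(alphabet)
        s = np.ones((k, k)) - np.eye(k)
        pi = np.full(k, 1.0 / k) if freqs is None else np.asarray(freqs, float)
        return cls(alphabet, s, pi, name="poisson")

    @classmethod
    def from_paml(cls, path: str | Path, freqs=None) -> "SubstitutionModel":
        """Load a 20-state empirical model from a PAML-style .dat file
        (19 lower-triangular exchangeability rows, then 20 frequencies)."""
        values: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    values.append([float(x) for x in line.split()])
        rows, file_freqs = values[:19], np.array(values[19])
        s = np.zeros((20, 20))
        for i, row in enumerate(rows, start=1):
            s[i, :i] = row
        s = s + s.T
        pi = file_freqs if freqs is None else np.asarray(freqs, float)
        pi = pi / pi.sum()
        return cls(AA_ALPHABET, s, pi, name=Path(path).stem)

    @classmethod
    def lg(cls, freqs=None) -> "SubstitutionModel":
        with resources.as_file(
            resources.files("phyloconv.data").joinpath("lg.dat")
        ) as p:
            model = cls.from_paml(p, freqs=freqs)
        model.name = "LG"
        return model

    @classmethod
    def binary(cls, gain: float, loss: float) -> "SubstitutionModel":
        """Two-state chain with 0->1 rate ``gain`` and 1->0 rate ``loss``.

        Branch lengths keep the tree's units (the chain is NOT normalised
        to one expected event per unit length).
        """
        if gain <= 0 or loss <= 0:
            raise ValueError("gain and loss rates must be positive")
        pi = np.array([loss, gain]) / (gain + loss)
        s = np.array([[0.0, gain + loss], [gain + loss, 0.0]])
        m = cls("01", s, pi, normalized=False, name="binary")
        m.gain, m.loss = float(gain), float(loss)
        return m


def observed_frequencies(aln: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Alignment-wide amino acid frequencies with a small pseudocount."""
    counts = np.full(20, pseudocount)
    lut = {c: i for i, c in enumerate(AA_ALPHABET)}
    flat, n = np.unique(aln.matrix, return_counts=True)
    for sym, c in zip(flat, n):
        if sym in lut:
            counts[lut[sym]] += c
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# state maps and events
# ---------------------------------------------------------------------------
@dataclass
class CharacterStateMap:
    """Per-node MAP state and marginal posterior for one character."""

    alphabet: str
    map_state: dict[str, str]
    posterior: dict[str, np.ndarray]

    @classmethod
    def from_arrays(
        cls, tree: Phylogeny, alphabet: str, post: np.ndarray
    ) -> "CharacterStateMap":
        codes = map_codes_from_posterior(post)
        return cls(
            alphabet=alphabet,
            map_state={tree.labels[i]: alphabet[codes[i]] for i in range(tree.n_nodes)},
            posterior={tree.labels[i]: post[i] for i in range(tree.n_nodes)},
        )


def map_codes_from_posterior(post: np.ndarray) -> np.ndarray:
    """MAP assignment; ties resolved to the lowest alphabet index."""
    return np.argmax(post, axis=-1)


@dataclass(frozen=True)
class BranchEvent:
    """A reconstructed state change on a branch (identified by child node)."""

    branch: str
    kind: str  # "phenotype" | "aa"
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("branch event requires from_state != to_state")


def extract_branch_events(
    tree: Phylogeny, states: CharacterStateMap, kind: str = "aa"
) -> list[BranchEvent]:
    """One event per branch whose parent and child MAP states differ."""
    events = []
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        a, b = states.map_state[tree.labels[p]], states.map_state[tree.labels[i]]
        if a != b:
            events.append(
                BranchEvent(branch=tree.labels[i], kind=kind, from_state=a, to_state=b)
            )
    return events


# ---------------------------------------------------------------------------
# pruning and marginal reconstruction (vectorised across sites)
# ---------------------------------------------------------------------------
def _tip_code_matrix(tree: Phylogeny, tip_states: dict, model: SubstitutionModel):
    """(n_tips, 1) state codes in tree tip-index order from a label->symbol map."""
    codes = np.empty((tree.n_tips, 1), dtype=np.int64)
    lut = {c: i for i, c in enumerate(model.alphabet)}
    for row, i in enumerate(tree.tip_indices):
        sym = tip_states[tree.labels[i]]
        sym = None if sym in (None, "X", "-", "?") else sym
        if sym is None:
            codes[row, 0] = -1
        else:
            if str(sym) not in lut:
                raise ValueError(f"symbol {sym!r} outside model alphabet")
            codes[row, 0] = lut[str(sym)]
    return codes


def _downward_pass(tree, tip_codes, model, rate, transition=None):
    """Postorder partial likelihoods, per-site log scaling, child messages."""
    k = model.n_states
    n_sites = tip_codes.shape[1]
    p = model.transition_matrices(tree.blen, rate) if transition is None else transition
    partials = np.ones((tree.n_nodes, n_sites, k))
    for row, i in enumerate(tree.tip_indices):
        obs = tip_codes[row]
        m = obs >= 0
        partials[i, m, :] = 0.0
        partials[i, m, obs[m]] = 1.0
    messages = np.empty_like(partials)  # msg[c][s,a] = sum_b P_c[a,b] L_c[s,b]
    logscale = np.zeros(n_sites)
    for i in range(tree.n_nodes):
        if not tree.is_tip[i]:
            prod = np.ones((n_sites, k))
            for c in tree.children[i]:
                prod *= messages[c]
            mx = prod.max(axis=1)
            bad = mx <= 0.0
            if bad.any():
                mx = np.where(bad, 1.0, mx)
                logscale += np.where(bad, LOGLIK_FLOOR / tree.n_nodes, 0.0)
            prod /= mx[:, None]
            logscale += np.log(mx)
            partials[i] = prod
        if i != tree.root:
            messages[i] = partials[i] @ p[i].T
    return partials, messages, logscale, p


def site_log_likelihoods(
    tree: Phylogeny,
    tip_codes: np.ndarray,
    model: SubstitutionModel,
    rate: float | None = None,
    root_freqs: np.ndarray | None = None,
    transition: np.ndarray | None = None,
) -> np.ndarray:
    """Pruning log-likelihood of every site; tip_codes is (n_tips, n_sites)
    in ``tree.tip_indices`` order with -1 for missing data."""
    partials, _, logscale, _ = _downward_pass(tree, tip_codes, model, rate, transition)
    pi = model.freqs if root_freqs is None else np.asarray(root_freqs, float)
    lik = partials[tree.root] @ pi
    out = np.where(lik > 0, np.log(np.maximum(lik, 1e-300)) + logscale, LOGLIK_FLOOR)
    return np.maximum(out, LOGLIK_FLOOR)


def marginal_posteriors(
    tree: Phylogeny,
    tip_codes: np.ndarray,
    model: SubstitutionModel,
    rate: float | None = None,
    root_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Marginal posterior state probabilities at every node, (n_nodes, S, k).

    Down/up two-pass algorithm: the postorder pass collects subtree partial
    likelihoods, the preorder pass propagates the likelihood of the rest of
    the tree; their normalised product is the marginal posterior.
    """
    k = model.n_states
    partials, messages, _, p = _downward_pass(tree, tip_codes, model, rate)
    n_sites = tip_codes.shape[1]
    pi = model.freqs if root_freqs is None else np.asarray(root_freqs, float)
    outside = np.empty((tree.n_nodes, n_sites, k))
    outside[tree.root] = pi[None, :]
    for i in range(tree.n_nodes - 1, -1, -1):  # preorder
        if tree.is_tip[i]:
            continue
        kids = tree.children[i]
        for c in kids:
            sib = outside[i].copy()
            for w in kids:
                if w != c:
                    sib *= messages[w]
            out = sib @ p[c]
            norm = out.sum(axis=1, keepdims=True)
            norm[norm <= 0] = 1.0
            outside[c] = out / norm
    post = outside * partials
    norm = post.sum(axis=2, keepdims=True)
    norm[norm <= 0] = 1.0
    return post / norm


def fit_rate(
    tree: Phylogeny,
    tip_codes: np.ndarray,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> float:
    """Alignment-wide ML rate multiplier (single shared scale factor)."""

    def neg(logr):
        return -site_log_likelihoods(tree, tip_codes, model, rate=np.exp(logr)).sum()

    res = minimize_scalar(
        neg,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 0.05, "maxiter": 20},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# public single-character surface
# ---------------------------------------------------------------------------
def prune_log_likelihood(
    tree: Phylogeny,
    tip_states: dict,
    model: SubstitutionModel,
    root_freqs: np.ndarray | None = None,
) -> float:
    """Felsenstein pruning log-likelihood of one character."""
    codes = _tip_code_matrix(tree, tip_states, model)
    return float(site_log_likelihoods(tree, codes, model, root_freqs=root_freqs)[0])


def marginal_ancestral_states(
    tree: Phylogeny,
    tip_states: dict,
    model: SubstitutionModel,
    root_freqs: np.ndarray | None = None,
) -> CharacterStateMap:
    """Marginal ML reconstruction of one character at every node."""
    codes = _tip_code_matrix(tree, tip_states, model)
    post = marginal_posteriors(tree, codes, model, root_freqs=root_freqs)[:, 0, :]
    return CharacterStateMap.from_arrays(tree, model.alphabet, post)


def fit_binary_phenotype_model(
    tree: Phylogeny,
    phenotypes: dict[str, int],
    bounds: tuple[float, float] = (1e-6, 100.0),
) -> SubstitutionModel:
    """ML gain/loss rates for the binary phenotype chain (equal root prior)."""
    values = {phenotypes[lab] for lab in tree.tip_labels}
    if len(values) < 2:
        raise ValueError("no phenotype variation: all tips share one state")
    codes = np.array(
        [[phenotypes[tree.labels[i]]] for i in tree.tip_indices], dtype=np.int64
    )
    root = np.array([0.5, 0.5])
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def neg(x):
        m = SubstitutionModel.binary(np.exp(x[0]), np.exp(x[1]))
        return -site_log_likelihoods(tree, codes, m, root_freqs=root)[0]

    n_changes = max(_parsimony_changes(tree, phenotypes), 1)
    x0 = np.log(np.full(2, n_changes / tree.total_length()))
    x0 = np.clip(x0, lo, hi)
    res = minimize(neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
    if np.any(np.isclose(res.x, lo, atol=1e-6)) or np.any(
        np.isclose(res.x, hi, atol=1e-6)
    ):
        logger.warning("phenotype rate ML hit an optimisation bound")
    return SubstitutionModel.binary(*np.exp(res.x))


def _parsimony_changes(tree: Phylogeny, phenotypes: dict[str, int]) -> int:
    """Fitch parsimony count for the binary trait (used to seed the ML fit)."""
    sets = [None] * tree.n_nodes
    changes = 0
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            sets[i] = {phenotypes[tree.labels[i]]}
        else:
            inter = set.intersection(*(sets[c] for c in tree.children[i]))
            if inter:
                sets[i] = inter
            else:
                sets[i] = set.union(*(sets[c] for c in tree.children[i]))
                changes += 1
    return changes


def reconstruct_phenotype(
    tree: Phylogeny,
    phenotypes: dict[str, int],
    model: SubstitutionModel | None = None,
) -> tuple[CharacterStateMap, list[BranchEvent], SubstitutionModel]:
    """Fit (unless given) the two-state model, reconstruct, extract events."""
    if model is None:
        model = fit_binary_phenotype_model(tree, phenotypes)
    tip_states = {lab: str(phenotypes[lab]) for lab in tree.tip_labels}
    csm = marginal_ancestral_states(
        tree, tip_states, model, root_freqs=np.array([0.5, 0.5])
    )
    return csm, extract_branch_events(tree, csm, kind="phenotype"), model


def write_state_map(csm: CharacterStateMap, path) -> None:
    """TSV dump: node label, MAP state, posterior of the MAP state."""
    with open(path, "w") as fh:
        fh.write("node\tmap_state\tposterior\n")
        for lab, st in csm.map_state.items():
            p = csm.posterior[lab][csm.alphabet.index(st)]
            fh.write(f"{lab}\t{st}\t{p:.6f}\n")
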