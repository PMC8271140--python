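"""Per-site simultaneous scores: branch coincidences of phenotype and
genotype change under three counting approaches.

All three scores count branches on which a reconstructed phenotype change
and a reconstructed amino acid change co-occur:

* ``CONVERGENCE`` — only gains of the foreground phenotype coinciding with
  gains of a designated foreground amino acid;
* ``GWAS`` — additionally counts branches where both the foreground
  phenotype and the foreground amino acid are lost;
* ``ALL_CHANGES`` — any phenotype change coinciding with any amino acid
  change, direction-blind.

Because an alignment column over 20 amino acids carries no a priori
foreground variant, ``site_best_score`` evaluates every amino acid observed
in the site's events as a candidate foreground and reports the maximum
(ties to the lowest alphabet index).  The null calibration applies the same
maximisation, so the test statistic and its null distribution match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .ancestral import AA_ALPHABET, BranchEvent, CharacterStateMap, extract_branch_events
from .trees import Phylogeny


class ApproachKind(str, Enum):
    CONVERGENCE = "convergence"
    GWAS = "gwas"
    ALL_CHANGES = "all_changes"


@dataclass
class SiteScoreRecord:
    """Per-site result of one counting approach."""

    gene: str
    site: int  # 1-based retained column
    approach: ApproachKind
    foreground_aa: str | None
    score: int
    contributing_branches: list[str] = field(default_factory=list)
    threshold_correction1: int | None = None
    threshold_correction2: int | None = None
    significant_correction1: bool | None = None
    significant_correction2: bool | None = None

    def __post_init__(self) -> None:
        if self.score != len(self.contributing_branches):
            raise ValueError("score must equal the number of contributing branches")


def _split_phenotype(pheno_events: list[BranchEvent]):
    gains = {e.branch for e in pheno_events if e.from_state == "0" and e.to_state == "1"}
    losses = {e.branch for e in pheno_events if e.from_state == "1" and e.to_state == "0"}
    return gains, losses


def convergence_score(
    pheno_events: list[BranchEvent],
    aa_events: list[BranchEvent],
    fg_aa: str,
    gene: str = "",
    site: int = 0,
) -> SiteScoreRecord:
    """Branches carrying both a phenotype gain and a gain of ``fg_aa``."""
    gains, _ = _split_phenotype(pheno_events)
    hits = sorted(e.branch for e in aa_events if e.to_state == fg_aa and e.branch in gains)
    return SiteScoreRecord(
        gene, site, ApproachKind.CONVERGENCE, fg_aa, len(hits), hits
    )


def gwas_score(
    pheno_events: list[BranchEvent],
    aa_events: list[BranchEvent],
    fg_aa: str,
    gene: str = "",
    site: int = 0,
) -> SiteScoreRecord:
    """Coincident gains plus coincident losses of the foreground pair."""
    gains, losses = _split_phenotype(pheno_events)
    hits = sorted(
        e.branch
        for e in aa_events
        if (e.to_state == fg_aa and e.branch in gains)
        or (e.from_state == fg_aa and e.branch in losses)
    )
    return SiteScoreRecord(gene, site, ApproachKind.GWAS, fg_aa, len(hits), hits)


def all_changes_score(
    pheno_events: list[BranchEvent],
    aa_events: list[BranchEvent],
    gene: str = "",
    site: int = 0,
) -> SiteScoreRecord:
    """Branches with any phenotype change and any amino acid change."""
    pheno_branches = {e.branch for e in pheno_events}
    hits = sorted({e.branch for e in aa_events} & pheno_branches)
    return SiteScoreRecord(gene, site, ApproachKind.ALL_CHANGES, None, len(hits), hits)


def site_best_score(
    pheno_events: list[BranchEvent],
    aa_events: list[BranchEvent],
    approach: ApproachKind,
    gene: str = "",
    site: int = 0,
) -> SiteScoreRecord:
    """Best record over candidate foreground amino acids for one site.

    Candidates are the amino acids appearing in the site's events.  Ties are
    broken toward the lowest alphabet index so results are deterministic.
    """
    if approach == ApproachKind.ALL_CHANGES:
        return all_changes_score(pheno_events, aa_events, gene=gene, site=site)
    scorer = convergence_score if approach == ApproachKind.CONVERGENCE else gwas_score
    observed = {e.from_state for e in aa_events} | {e.to_state for e in aa_events}
    candidates = sorted(observed, key=lambda a: (AA_ALPHABET + "?").index(a))
    best = None
    for aa in candidates:
        rec = scorer(pheno_events, aa_events, aa, gene=gene, site=site)
        if best is None or rec.score > best.score:
            best = rec
    if best is None:  # no events at the site
        best = SiteScoreRecord(gene, site, approach, None, 0, [])
    return best


def site_best_score_from_states(
    tree: Phylogeny,
    pheno_events: list[BranchEvent],
    aa_site_states: CharacterStateMap,
    approach: ApproachKind,
    gene: str = "",
    site: int = 0,
) -> SiteScoreRecord:
    """Convenience wrapper taking the site's reconstructed state map."""
    aa_events = extract_branch_events(tree, aa_site_states, kind="aa")
    return site_best_score(pheno_events, aa_events, approach, gene=gene, site=site)


# ---------------------------------------------------------------------------
# vectorised scoring across an alignment (used by the pipeline and the null)
# ---------------------------------------------------------------------------
def score_matrix(
    tree: Phylogeny,
    pheno_events: list[BranchEvent],
    map_codes: np.ndarray,
    approach: ApproachKind,
    n_states: int = 20,
) -> np.ndarray:
    """Best score of every site from a (n_nodes, n_sites) MAP-code matrix.

    Equivalent to looping ``site_best_score`` over sites; kept vectorised
    because the null calibration evaluates 10^5 sites per run.
    """
    gains, losses = _split_phenotype(pheno_events)
    nodes = np.array([i for i in range(tree.n_nodes) if tree.parent[i] >= 0])
    parents = tree.parent[nodes]
    child_c = map_codes[nodes]  # (B, S)
    parent_c = map_codes[parents]
    ev = child_c != parent_c
    n_sites = map_codes.shape[1]
    gain_rows = np.array([tree.label_to_index[b] for b in gains], dtype=np.int64)
    loss_rows = np.array([tree.label_to_index[b] for b in losses], dtype=np.int64)
    node_pos = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_pos[nodes] = np.arange(len(nodes))
    gain_rows = node_pos[gain_rows]
    loss_rows = node_pos[loss_rows]

    if approach == ApproachKind.ALL_CHANGES:
        pheno_rows = np.concatenate([gain_rows, loss_rows]).astype(np.int64)
        if len(pheno_rows) == 0:
            return np.zeros(n_sites, dtype=np.int64)
        return ev[pheno_rows].sum(axis=0).astype(np.int64)

    counts = np.zeros((n_sites, n_states), dtype=np.int64)
    if len(gain_rows):
        e = ev[gain_rows]
        sites, rows = np.nonzero(e.T)
        np.add.at(counts, (sites, child_c[gain_rows][rows, sites]), 1)
    if approach == ApproachKind.GWAS and len(loss_rows):
        e = ev[loss_rows]
        sites, rows = np.nonzero(e.T)
        np.add.at(counts, (sites, parent_c[loss_rows][rows, sites]), 1)
    return counts.max(axis=1)


def score_alignment_records(
    tree: Phylogeny,
    pheno_events: list[BranchEvent],
    map_codes: np.ndarray,
    approach: ApproachKind,
    gene: str = "",
    columns: np.ndarray | None = None,
    alphabet: str = AA_ALPHABET,
) -> list[SiteScoreRecord]:
    """Full per-site records (with contributing branches) for reporting."""
    records = []
    n_sites = map_codes.shape[1]
    cols = columns if columns is not None else np.arange(1, n_sites + 1)
    for s in range(n_sites):
        aa_events = []
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p >= 0 and map_codes[i, s] != map_codes[p, s]:
                aa_events.append(
                    BranchEvent(
                        branch=tree.labels[i],
                        kind="aa",
                        from_state=alphabet[map_codes[p, s]],
                        to_state=alphabet[map_codes[i, s]],
                    )
                )
        records.append(
            site_best_score(
                pheno_events, aa_events, approach, gene=gene, site=int(cols[s])
            )
        )
    return records


def write_score_table(records: list[SiteScoreRecord], path) -> None:
    """Machine-readable per-site score table (TSV)."""
    with open(path, "w") as fh:
        fh.write(
            "gene\tsite\tapproach\tforeground_aa\tscore\tthreshold_correction1\t"
            "threshold_correction2\tsignificant_correction1\t"
            "significant_correction2\tcontributing_branches\n"
        )
        for r in records:
            fh.write(
                f"{r.gene}\t{r.site}\t{r.approach.value}\t"
                f"{r.foreground_aa or '.'}\t{r.score}\t"
                f"{r.threshold_correction1 if r.threshold_correction1 is not None else '.'}\t"
                f"{r.threshold_correction2 if r.threshold_correction2 is not None else '.'}\t"
                f"{_flag(r.significant_correction1)}\t{_flag(r.significant_correction2)}\t"
                f"{';'.join(r.contributing_branches)}\n"
            )


def _flag(x: bool | None) -> str:
    return "." if x is None else ("1" if x else "0")
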