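"""End-to-end scan: alignment + tree + phenotypes -> per-site simultaneous
scores, simulation-calibrated thresholds, and significance calls."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ancestral
from .ancestral import SubstitutionModel, observed_frequencies
from .io_formats import Alignment, drop_gap_columns
from .null_calibration import (
    CorrectionKind,
    NullScoreDistribution,
    SignificanceThreshold,
    SubstCountDistribution,
    _null_scores_all_approaches,
    classify_sites,
    empirical_subst_distribution,
    significance_threshold,
)
from .simultaneous_scores import (
    ApproachKind,
    SiteScoreRecord,
    score_alignment_records,
    score_matrix,
)
from .trees import Phylogeny


@dataclass
class ScanResult:
    """Everything the simultaneous test produces for one gene/phenotype run."""

    approaches: list[ApproachKind]
    scores: dict[ApproachKind, np.ndarray]
    thresholds: dict[tuple[ApproachKind, CorrectionKind], SignificanceThreshold]
    null_distributions: dict[ApproachKind, NullScoreDistribution]
    subst_distribution: SubstCountDistribution
    phenotype_events: list
    phenotype_model: SubstitutionModel
    columns: np.ndarray  # original 1-based coordinates of scored sites
    rate: float
    records: dict[ApproachKind, list[SiteScoreRecord]] = field(default_factory=dict)

    def any_significant(
        self, approach: ApproachKind, correction: CorrectionKind
    ) -> bool:
        t = self.thresholds[(approach, correction)]
        return bool((self.scores[approach] >= t.threshold).any())


def run_scan(
    tree: Phylogeny,
    alignment: Alignment,
    phenotypes: dict[str, int],
    approaches: list[ApproachKind] | None = None,
    alpha: float = 0.05,
    n_null: int = 100_000,
    seed: int = 0,
    model: SubstitutionModel | None = None,
    gene: str = "",
    fit_rate: bool = True,
    filter_gaps: bool = True,
    build_records: bool = True,
) -> ScanResult:
    """Run the full simultaneous test.

    Reconstructs marginal ancestral amino acids per site (LG
    exchangeabilities with alignment-wide frequencies by default, one
    shared ML rate multiplier), reconstructs the phenotype under a fitted
    two-state model, scores every site under the requested approaches,
    simulates ``n_null`` null sites conditioned on the empirical
    substitutions-per-site histogram, and annotates significance under
    both Bonferroni corrections.
    """
    if approaches is None:
        approaches = list(ApproachKind)
    if filter_gaps:
        alignment = drop_gap_columns(alignment)
    if model is None:
        model = SubstitutionModel.lg(freqs=observed_frequencies(alignment))

    order = [alignment.ids.index(lab) for lab in tree.tip_labels]
    codes = model.encode(alignment.matrix[order].ravel()).reshape(
        tree.n_tips, alignment.n_sites
    )
    rate = ancestral.fit_rate(tree, codes, model) if fit_rate else model.rate
    post = ancestral.marginal_posteriors(tree, codes, model, rate=rate)
    map_codes = ancestral.map_codes_from_posterior(post)
    del post

    pheno_csm, pheno_events, pheno_model = ancestral.reconstruct_phenotype(
        tree, phenotypes
    )

    nodes = np.flatnonzero(np.asarray(tree.parent) >= 0)
    event_counts = (map_codes[nodes] != map_codes[tree.parent[nodes]]).sum(axis=0)
    dist = empirical_subst_distribution(event_counts)

    null_all = _null_scores_all_approaches(
        tree, pheno_events, dist, n_null, np.random.default_rng(seed)
    )
    scores, thresholds, nulls, records = {}, {}, {}, {}
    n_sites = alignment.n_sites
    for approach in approaches:
        scores[approach] = score_matrix(tree, pheno_events, map_codes, approach)
        nulls[approach] = NullScoreDistribution(
            approach=approach, scores=null_all[approach], seed=seed
        )
        t1 = significance_threshold(
            nulls[approach], alpha, n_sites, CorrectionKind.CORRECTION1
        )
        t2 = significance_threshold(
            nulls[approach], alpha, n_sites, CorrectionKind.CORRECTION2
        )
        thresholds[(approach, CorrectionKind.CORRECTION1)] = t1
        thresholds[(approach, CorrectionKind.CORRECTION2)] = t2
        if build_records:
            recs = score_alignment_records(
                tree,
                pheno_events,
                map_codes,
                approach,
                gene=gene,
                columns=alignment.columns,
                alphabet=model.alphabet,
            )
            records[approach] = classify_sites(recs, t1, t2)

    return ScanResult(
        approaches=approaches,
        scores=scores,
        thresholds=thresholds,
        null_distributions=nulls,
        subst_distribution=dist,
        phenotype_events=pheno_events,
        phenotype_model=pheno_model,
        columns=alignment.columns,
        rate=rate,
        records=records,
    )
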