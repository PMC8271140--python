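import numpy as np
import pytest

from phyloconv import (
    BranchPartition,
    Phylogeny,
    ProfileLibrary,
    SubstitutionModel,
    marginal_ancestral_states,
    partition_branches,
    profile_change_posterior,
    quadrant_fisher,
    site_profile_likelihood,
)
from phyloconv.ancestral import AA_ALPHABET, LOGLIK_FLOOR, prune_log_likelihood
from phyloconv.profile_change import _fg_node_mask, _pair_logliks, _profile_models

from conftest import random_small_tree
from oracles import enum_likelihood_and_marginals, fisher_two_sided


@pytest.fixture
def library():
    return ProfileLibrary.default()


@pytest.fixture
def fg_clade_tree():
    """Six tips; (T1,T2,T3) is the foreground clade."""
    return Phylogeny.from_newick(
        "(((T1:1,T2:1):1,T3:1):1,((T4:1,T5:1):1,T6:1):1);"
    )


def clade_partition(tree, fg_tips):
    model = SubstitutionModel.binary(0.1, 0.1)
    states = {lab: ("1" if lab in fg_tips else "0") for lab in tree.tip_labels}
    csm = marginal_ancestral_states(
        tree, states, model, root_freqs=np.array([0.5, 0.5])
    )
    return partition_branches(tree, csm)


class TestProfileLibrary:
    def test_default_library_shape(self, library):
        assert library.n_profiles == 10
        assert np.allclose(library.profiles.sum(axis=1), 1.0, atol=1e-9)
        assert (library.profiles > 0).all()


class TestPartitionBranches:
    def test_all_background(self, balanced4):
        part = clade_partition(balanced4, set())
        assert part.foreground == set()
        assert len(part.background) == balanced4.n_branches

    def test_foreground_clade_branches(self, fg_clade_tree):
        part = clade_partition(fg_clade_tree, {"T1", "T2", "T3"})
        # 3 tip branches + the (T1,T2) stem + the clade stem
        assert part.foreground == {"T1", "T2", "T3", "N2", "N4"}

    def test_sizes_sum_to_branch_count(self, fg_clade_tree):
        part = clade_partition(fg_clade_tree, {"T1", "T4"})
        assert len(part.foreground) + len(part.background) == fg_clade_tree.n_branches


class TestSiteProfileLikelihood:
    def test_equal_profiles_reduce_to_plain_pruning(self, fg_clade_tree, library):
        part = clade_partition(fg_clade_tree, {"T1", "T2", "T3"})
        prof = library.profiles[3]
        site = {"T1": "D", "T2": "E", "T3": "D", "T4": "K", "T5": "D", "T6": "A"}
        ll = site_profile_likelihood(fg_clade_tree, site, part, prof, prof, rate=0.7)
        model = SubstitutionModel.poisson(AA_ALPHABET, freqs=prof)
        model.rate = 0.7
        assert ll == pytest.approx(
            prune_log_likelihood(fg_clade_tree, site, model), abs=1e-8
        )

    def test_matches_enumeration_with_heterogeneous_branches(self, rng):
        # class-dependent transition matrices vs joint enumeration, 4-state
        for _ in range(40):
            tree = random_small_tree(rng, n_tips=int(rng.integers(3, 6)))
            fg = {
                tree.labels[int(i)]
                for i in rng.choice(tree.branch_nodes(), size=2, replace=False)
            }
            part = BranchPartition(
                foreground=fg,
                background=set(tree.labels[i] for i in tree.branch_nodes()) - fg,
                root_class=0,
            )
            k = 4
            prof_f = rng.dirichlet(np.full(k, 1.5))
            prof_b = rng.dirichlet(np.full(k, 1.5))
            models = [
                SubstitutionModel("ABCD", np.ones((k, k)) - np.eye(k), p)
                for p in (prof_f, prof_b)
            ]
            codes = rng.integers(0, k, size=(tree.n_tips, 1))
            mask = _fg_node_mask(tree, part)
            ll = _pair_logliks(
                tree, codes, mask, models, np.array([[0, 1]]), 1.0, 0
            )[0]
            p_f = models[0].transition_matrices(tree.blen)
            p_b = models[1].transition_matrices(tree.blen)
            p_per_branch = np.where(mask[:, None, None], p_f, p_b)
            tip_codes = {
                int(i): int(codes[row, 0]) for row, i in enumerate(tree.tip_indices)
            }
            ll_ref, _ = enum_likelihood_and_marginals(
                tree, tip_codes, p_per_branch, models[1].freqs
            )
            assert ll == pytest.approx(ll_ref, abs=1e-8)

    def test_zero_mass_profile_hits_floor(self, fg_clade_tree):
        part = clade_partition(fg_clade_tree, {"T1"})
        prof = np.zeros(20)
        prof[AA_ALPHABET.index("A")] = 1.0  # excludes every other residue
        site = {t: "K" for t in fg_clade_tree.tip_labels}
        ll = site_profile_likelihood(fg_clade_tree, site, part, prof, prof, rate=1e-6)
        assert ll <= LOGLIK_FLOOR * 0.5


class TestProfileChangePosterior:
    def test_constant_site_favours_no_change(self, fg_clade_tree, library):
        part = clade_partition(fg_clade_tree, {"T1", "T2", "T3"})
        site = {t: "A" for t in fg_clade_tree.tip_labels}
        res = profile_change_posterior(fg_clade_tree, site, part, library)
        assert res.posterior < 0.5

    def test_posterior_invariant_to_profile_relabelling(self, fg_clade_tree, library):
        part = clade_partition(fg_clade_tree, {"T1", "T2", "T3"})
        site = {"T1": "K", "T2": "R", "T3": "K", "T4": "D", "T5": "E", "T6": "D"}
        res = profile_change_posterior(fg_clade_tree, site, part, library, rate=1.0)
        perm = np.arange(library.n_profiles)[::-1]
        shuffled = ProfileLibrary(
            profiles=library.profiles[perm],
            weights=library.weights[perm],
            names=[library.names[i] for i in perm],
        )
        res2 = profile_change_posterior(fg_clade_tree, site, part, shuffled, rate=1.0)
        assert res2.posterior == pytest.approx(res.posterior, abs=1e-10)
        assert perm[res2.best_foreground_profile] == res.best_foreground_profile

    def test_single_profile_library_posterior_zero(self, fg_clade_tree, library):
        part = clade_partition(fg_clade_tree, {"T1"})
        single = ProfileLibrary(
            profiles=library.profiles[:1], weights=np.array([1.0]), names=["only"]
        )
        site = {t: "A" for t in fg_clade_tree.tip_labels}
        res = profile_change_posterior(fg_clade_tree, site, part, single)
        assert res.posterior == 0.0

    def test_empty_foreground_is_error(self, fg_clade_tree, library):
        part = clade_partition(fg_clade_tree, set())
        site = {t: "A" for t in fg_clade_tree.tip_labels}
        with pytest.raises(ValueError, match="foreground"):
            profile_change_posterior(fg_clade_tree, site, part, library)

    def test_separated_classes_favour_change(self, fg_clade_tree, library):
        # foreground tips basic (KR profile), background acidic (DE profile)
        part = clade_partition(fg_clade_tree, {"T1", "T2", "T3"})
        site = {"T1": "K", "T2": "R", "T3": "K", "T4": "D", "T5": "E", "T6": "D"}
        res = profile_change_posterior(fg_clade_tree, site, part, library)
        assert res.posterior > 0.5
        assert library.names[res.best_foreground_profile] == "basic"
        assert library.names[res.best_background_profile] == "acidic"


class TestQuadrantFisher:
    def test_perfect_independence(self):
        sim = [5] * 10 + [5] * 10 + [0] * 10 + [0] * 10
        pc = ([0.9] * 10 + [0.1] * 10) * 2
        res = quadrant_fisher(sim, pc, sim_cutoff=3)
        assert res.table.tolist() == [[10, 10], [10, 10]]
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_exact_p(self):
        sim = [5] * 5 + [0] * 5
        pc = [0.9] * 5 + [0.1] * 5
        res = quadrant_fisher(sim, pc, sim_cutoff=3)
        assert res.table.tolist() == [[5, 0], [0, 5]]
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_degenerate_table_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = quadrant_fisher([0, 0, 0], [0.1, 0.2, 0.3], sim_cutoff=2)
        assert res.p_value == 1.0 and res.degenerate

    def test_default_cutoff_is_midrange(self):
        res = quadrant_fisher([0, 1, 2, 7], [0.1, 0.2, 0.9, 0.8])
        assert res.sim_cutoff == 4

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(60):
            table = rng.integers(0, 11, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            sim = [1] * (table[0, 0] + table[0, 1]) + [0] * (table[1, 0] + table[1, 1])
            pc = (
                [0.9] * table[0, 0]
                + [0.1] * table[0, 1]
                + [0.9] * table[1, 0]
                + [0.1] * table[1, 1]
            )
            res = quadrant_fisher(sim, pc, sim_cutoff=1)
            assert res.p_value == pytest.approx(
                fisher_two_sided(res.table), rel=1e-6, abs=1e-12
            )
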