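"""Branch matching, branch-wise lengths, congruence ranking, gene shopping."""

import itertools
import math

import numpy as np
import pytest

from saxshift.congruence import (CongruenceScore, branchwise_lengths,
                                 congruence_rank, congruence_score, gene_shop,
                                 impute_missing_lengths, match_branches)
from saxshift.simulate import SimConfig, simulate_gene_trees
from saxshift.trees import read_newick

from conftest import random_ultrametric_tree


def all_clade_pairs(tree, shared):
    """Brute-force (descendant, parent) restricted clade pairs."""
    clades = tree.clades()
    out = {}
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        out[nd.id] = (clades[nd.id] & shared, clades[nd.parent.id] & shared)
    return out


class TestMatchBranches:
    def test_identical_topology_all_matched(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt = read_newick("((A:.1,B:.2):.3,(C:.4,D:.5):.6);")
        table = match_branches(gt, sp)
        assert len(table.matches) == 6
        out, rep = branchwise_lengths(sp, [gt])
        assert rep.coverage == 1.0
        lens = sorted(nd.length for nd in out.postorder()
                      if nd is not out.root)
        assert lens == pytest.approx([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])

    def test_nni_rearrangement_against_clade_oracle(self):
        """On a 5-taxon NNI pair, the matched set equals a brute-force
        enumeration over all (descendant, parent) clade pairs."""
        sp = read_newick("(((A:1,B:1):1,C:2):1,(D:1,E:1):2);")
        gt = read_newick("(((A:1,C:1):1,B:2):1,(D:1,E:1):2);")
        table = match_branches(gt, sp)
        shared = frozenset(sp.taxa)
        spairs = all_clade_pairs(sp, shared)
        gpairs = set(all_clade_pairs(gt, shared).values())
        expected = {nid for nid, pair in spairs.items() if pair in gpairs}
        assert set(table.matches) == expected
        # the rearranged quartet's internal branches are unmatched
        ab = sp.mrca({"A", "B"})
        assert ab.id not in table.matches

    def test_missing_taxon_parent_clade_disambiguates(self):
        """When a pruned taxon collapses two species-tree branches to the
        same descendant clade, only the branch whose parent clade also
        matches is matched."""
        sp = read_newick("(((A:1,B:1):1,(C:1,X:1):1):1,(D:1,E:1):2);")
        gt = read_newick("(((A:.1,B:.1):.1,C:.2):.1,(D:.1,E:.1):.2);")
        table = match_branches(gt, sp)
        cx = sp.mrca({"C", "X"})       # restricted clade {C}
        c_tip = sp.find_tip("C")       # restricted clade {C} as well
        # branch above C-X ancestor has parent clade {A,B,C}: matched;
        # the C terminal branch has parent {C} after restriction: skipped
        assert cx.id in table.matches
        assert c_tip.id not in table.matches

    def test_too_few_shared_taxa_skipped(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt = read_newick("((A:1,B:1):1,Z:1);")
        assert match_branches(gt, sp) is None


class TestBranchwiseLengths:
    def test_mean_across_loci(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gts = [read_newick(f"((A:{x},B:1):1,(C:1,D:1):1);")
               for x in (0.1, 0.2, 0.3)]
        out, rep = branchwise_lengths(sp, gts)
        assert out.find_tip("A").length == pytest.approx(0.2)
        assert rep.coverage == 1.0

    def test_unmatched_branch_gets_nan_then_imputed(self):
        sp = read_newick("(((A:1,B:1):1,C:2):1,(D:1,E:1):2);")
        gt = read_newick("(((A:.1,C:.1):.1,B:.2):.1,(D:.3,E:.3):.2);")
        out, rep = branchwise_lengths(sp, [gt])
        assert rep.unmatched
        assert any(math.isnan(nd.length) for nd in out.postorder()
                   if nd is not out.root)
        fixed = impute_missing_lengths(out)
        assert all(not math.isnan(nd.length) for nd in fixed.postorder()
                   if nd is not fixed.root)

    def test_simulated_recovery_clt(self):
        """With many congruent-but-noisy loci, per-branch means land
        within 3 standard errors of the generating lengths."""
        sp = random_ultrametric_tree(8, seed=2)
        rate, sd, n_loci = 0.01, 0.2, 120
        rng = np.random.default_rng(0)
        sub = sp.copy()
        for nd in sub.postorder():
            if nd is not sub.root:
                nd.length = rate * (nd.parent.age - nd.age)
            nd.age = None
        sub.units = "subs"
        gts = []
        for _ in range(n_loci):
            g = sub.copy()
            for nd in g.postorder():
                if nd is not g.root:
                    nd.length *= rng.lognormal(0, sd)
            gts.append(g)
        out, rep = branchwise_lengths(sub, gts)
        assert rep.coverage == 1.0
        mean_mult = math.exp(sd ** 2 / 2)
        se_mult = math.sqrt((math.exp(sd**2) - 1) * math.exp(sd**2))
        for nd_o, nd_t in zip(out.postorder(), sub.postorder()):
            if nd_t is sub.root:
                continue
            mu = nd_t.length * mean_mult
            se = nd_t.length * se_mult / math.sqrt(n_loci)
            assert abs(nd_o.length - mu) < 3.5 * se


class TestCongruenceRank:
    def test_identical_and_star(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert congruence_score(sp, sp) == 1.0
        star = read_newick("(A,B,C,D);")
        assert congruence_score(star, sp) == 0.0

    def test_score_equals_one_minus_normalized_rf(self):
        """Node-fraction score equals 1 - normalized rooted RF distance
        computed by an independent clade-set comparison."""
        sp = random_ultrametric_tree(10, seed=5)
        for seed in range(6):
            gt = random_ultrametric_tree(10, seed=50 + seed)
            # relabel so taxa coincide (same tip count, sorted labels)
            mapping = dict(zip(sorted(gt.taxa), sorted(sp.taxa)))
            for leaf in gt.leaves():
                leaf.label = mapping[leaf.label]
            score = congruence_score(gt, sp)

            def nontrivial_clades(t):
                n = t.n_tips()
                return {c for c in t.clades().values() if 1 < len(c) < n}

            cs, cg = nontrivial_clades(sp), nontrivial_clades(gt)
            rf_norm = 1.0 - len(cs & cg) / len(cs)
            assert score == pytest.approx(1.0 - rf_norm)

    def test_rank_stable_sort_ties_by_locus(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gts = [sp.copy(), sp.copy()]
        ranked = congruence_rank(gts, sp, locus_ids=["z", "a"])
        assert [s.locus for s in ranked] == ["a", "z"]
        assert all(s.score == 1.0 for s in ranked)

    def test_tip_permutation_invariance(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt1 = read_newick("((B:1,A:1):1,(D:1,C:1):1);")
        assert congruence_score(gt1, sp) == congruence_score(sp, sp)

    def test_mean_score_decreases_with_discordance(self):
        sp = random_ultrametric_tree(8, seed=9)
        means = []
        for theta in (0.05, 1.0, 5.0):
            gts = simulate_gene_trees(
                sp, SimConfig(max_time=1, seed=13, pop_scale=theta,
                              n_loci=60))
            means.append(np.mean([congruence_score(g, sp) for g in gts]))
        assert means[0] > means[1] > means[2]


class TestGeneShop:
    def test_all_loci_cover_everything(self):
        ranked = [CongruenceScore(f"L{i}", 1 - i / 10) for i in range(5)]
        lt = {f"L{i}": {"A", "B", "C"} for i in range(5)}
        assert gene_shop(ranked, lt, k=2) == ["L0", "L1"]

    def test_rare_taxon_forces_full_ranking(self):
        ranked = [CongruenceScore("L0", 0.9), CongruenceScore("L1", 0.8),
                  CongruenceScore("L2", 0.1)]
        lt = {"L0": {"A", "B"}, "L1": {"A", "B"}, "L2": {"C"}}
        assert gene_shop(ranked, lt, k=1) == ["L0", "L1", "L2"]

    def test_impossible_coverage_names_taxa(self):
        ranked = [CongruenceScore("L0", 0.9)]
        with pytest.raises(ValueError, match="C"):
            gene_shop(ranked, {"L0": {"A"}}, k=1, taxa={"A", "C"})

    @pytest.mark.parametrize("seed", range(5))
    def test_prefix_length_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(8)]
        loci = {}
        for i in range(12):
            n = int(rng.integers(2, 8))
            loci[f"L{i:02d}"] = set(rng.choice(taxa, size=n, replace=False))
        ranked = [CongruenceScore(lid, float(rng.random()))
                  for lid in loci]
        ranked.sort(key=lambda s: (-s.score, s.locus))
        k = 2
        counts = {t: sum(1 for s in loci.values() if t in s) for t in taxa}
        if min(counts.values()) < k:
            with pytest.raises(ValueError):
                gene_shop(ranked, loci, k=k, taxa=set(taxa))
            return
        chosen = gene_shop(ranked, loci, k=k, taxa=set(taxa))
        # brute force: shortest prefix with full k-coverage
        for pref in range(1, len(ranked) + 1):
            cover = {t: 0 for t in taxa}
            for s in ranked[:pref]:
                for t in loci[s.locus]:
                    cover[t] += 1
            if min(cover.values()) >= k:
                break
        assert len(chosen) == pref

    def test_monotone_in_k(self):
        rng = np.random.default_rng(1)
        taxa = [f"t{i}" for i in range(6)]
        loci = {f"L{i}": set(rng.choice(taxa, size=4, replace=False))
                for i in range(15)}
        ranked = sorted([CongruenceScore(lid, float(rng.random()))
                         for lid in loci], key=lambda s: (-s.score, s.locus))
        prev = 0
        for k in (1, 2, 3):
            counts = {t: sum(1 for s in loci.values() if t in s)
                      for t in taxa}
            if min(counts.values()) < k:
                break
            n = len(gene_shop(ranked, loci, k=k, taxa=set(taxa)))
            assert n >= prev
            prev = n
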