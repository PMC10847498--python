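"""ClaSSE generator structure, likelihood oracles, and MCMC behaviour."""

import math

import numpy as np
import pytest

from saxshift.classe import (ClasseParams, build_generator, classe_loglik,
                             mcmc_sample)
from saxshift.simulate import SimConfig, simulate_classe_tree
from saxshift.states import Biome, BiomeRegionState, enumerate_states

from conftest import pure_birth_params, random_ultrametric_tree


# ---------------------------------------------------------------------------
# Independent oracle: scalar fine-grid RK4 over the full E/D system for the
# single-region (biome-only) model, written without the package's vectorised
# machinery.
# ---------------------------------------------------------------------------

def oracle_loglik_biome_only(tree, tip_states, params, rho=1.0,
                             nsteps_per_unit=400):
    """Plain-loop pruning for the 3-state single-region biome model:
    states 0=alpine, 1=non_alpine, 2=both; only sympatric cladogenesis."""
    lam = [params.lambda_alpine, params.lambda_non_alpine, params.lambda_both]
    mu = [params.mu_alpine, params.mu_non_alpine, params.mu_both]
    Q = [[0.0, 0.0, params.q_AB],
         [0.0, 0.0, params.q_NB],
         [params.q_BA, params.q_BN, 0.0]]
    for i in range(3):
        Q[i][i] = -sum(Q[i])

    def deriv(y):
        E, D = y[:3], y[3:]
        dE, dD = [0.0] * 3, [0.0] * 3
        for i in range(3):
            qe = sum(Q[i][j] * E[j] for j in range(3))
            qd = sum(Q[i][j] * D[j] for j in range(3))
            dE[i] = mu[i] - (lam[i] + mu[i]) * E[i] + qe \
                + lam[i] * E[i] * E[i]
            dD[i] = -(lam[i] + mu[i]) * D[i] + qd \
                + 2.0 * lam[i] * D[i] * E[i]
        return dE + dD

    def integrate(y, duration):
        n = max(2, int(math.ceil(duration * nsteps_per_unit)))
        h = duration / n
        for _ in range(n):
            k1 = deriv(y)
            k2 = deriv([y[i] + 0.5 * h * k1[i] for i in range(6)])
            k3 = deriv([y[i] + 0.5 * h * k2[i] for i in range(6)])
            k4 = deriv([y[i] + h * k3[i] for i in range(6)])
            y = [y[i] + h / 6 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
                 for i in range(6)]
        return y

    logc = 0.0
    store = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            E = [1.0 - rho] * 3
            D = [0.0] * 3
            D[tip_states[nd.label]] = rho
        else:
            cl, cr = nd.children
            El, Dl = store[cl.id]
            Er, Dr = store[cr.id]
            E = El
            D = [lam[i] * Dl[i] * Dr[i] for i in range(3)]
        if nd is tree.root:
            pi_states = sorted(set(tip_states.values()))
            pi = [1.0 / len(pi_states) if i in pi_states else 0.0
                  for i in range(3)]
            num = sum(pi[i] * D[i] for i in range(3))
            den = sum(pi[i] * lam[i] * (1 - E[i]) ** 2 for i in range(3))
            return math.log(num) - math.log(den) + logc
        y = integrate(E + D, nd.parent.age - nd.age)
        E, D = y[:3], y[3:]
        c = sum(D)
        store[nd.id] = (E, [d / c for d in D])
        logc += math.log(c)


class TestGenerator:
    def test_single_region_only_sympatric(self, one_region_space):
        params = ClasseParams(lambda_alpine=0.25)
        gen = build_generator(one_region_space, params)
        i = one_region_space.index_of(
            BiomeRegionState(Biome.ALPINE, frozenset({"Asia"})))
        evs = gen.clado_by_state[i]
        assert all(mode == "sympatric" for _, _, _, mode in evs)
        assert sum(w for _, _, w, _ in evs) == pytest.approx(0.25)

    def test_both_single_region_moves(self, full_space):
        """State (both,{Europe}) in the full 5-region space: biome shift to
        alpine and to non-alpine, and dispersal to four regions (Arctic
        allowed) -- six positive off-diagonals."""
        params = ClasseParams()
        gen = build_generator(full_space, params)
        i = full_space.index_of(
            BiomeRegionState(Biome.BOTH, frozenset({"Europe"})))
        offdiag = [(j, r) for j, r in enumerate(gen.Q[i])
                   if j != i and r > 0]
        assert len(offdiag) == 6
        kinds = sorted(gen.move_kind[(i, j)][0] for j, _ in offdiag)
        assert kinds == ["biome_shift", "biome_shift"] + ["dispersal"] * 4

    def test_nonalpine_cannot_reach_arctic(self, full_space):
        params = ClasseParams()
        gen = build_generator(full_space, params)
        for i, st in enumerate(full_space):
            if st.biome != Biome.NON_ALPINE:
                continue
            for j, rate in enumerate(gen.Q[i]):
                if rate > 0 and j != i:
                    assert "Arctic" not in full_space[j].regions or \
                        full_space[j].biome != Biome.NON_ALPINE

    def test_conservation_all_77_states(self, full_space):
        params = ClasseParams(lambda_alpine=0.11, lambda_non_alpine=0.22,
                              lambda_both=0.33)
        gen = build_generator(full_space, params)
        assert np.allclose(gen.Q.sum(axis=1), 0.0, atol=1e-12)
        mass = np.zeros(len(full_space))
        for m in range(len(gen.ev_w)):
            mass[gen.ev_i[m]] += gen.ev_w[m]
        assert np.allclose(mass, gen.lam, atol=1e-12)


class TestLoglik:
    def test_yule_closed_form(self, one_region_space):
        """One effective state, no extinction or moves: matches the
        analytic pure-birth expression with survival conditioning."""
        lam = 0.3
        params = pure_birth_params(lam)
        gen = build_generator(one_region_space, params)
        tree = random_ultrametric_tree(5, seed=2)
        tips = {lb: 0 for lb in tree.taxa}
        ll = classe_loglik(tree, tips, gen, rho=1.0, method="adaptive")
        total_bl = sum(nd.parent.age - nd.age for nd in tree.postorder()
                       if nd is not tree.root)
        n = tree.n_tips()
        analytic = (n - 1) * math.log(lam) - lam * total_bl - math.log(lam)
        assert ll == pytest.approx(analytic, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_rk4_oracle(self, one_region_space, seed):
        """Biome-only model on random 4-tip trees: pruning likelihood
        agrees with an independently coded fine-grid RK4 integrator."""
        rng = np.random.default_rng(seed)
        tree = random_ultrametric_tree(4, seed=300 + seed, rate=0.4)
        params = ClasseParams(
            lambda_alpine=0.1 + 0.3 * rng.random(),
            lambda_non_alpine=0.1 + 0.3 * rng.random(),
            lambda_both=0.1 + 0.3 * rng.random(),
            mu_alpine=0.05 * rng.random(), mu_non_alpine=0.05 * rng.random(),
            mu_both=0.05 * rng.random(),
            q_NB=0.2 * rng.random(), q_BN=0.2 * rng.random(),
            q_BA=0.2 * rng.random(), q_AB=0.2 * rng.random(),
            d=0.0, e=0.0)
        gen = build_generator(one_region_space, params)
        tips = {lb: int(rng.integers(3)) for lb in tree.taxa}
        rho = 0.8
        ll = classe_loglik(tree, tips, gen, rho=rho, method="adaptive")
        # oracle state order matches the package's enumeration order
        order = [s.biome for s in one_region_space]
        assert order == [Biome.ALPINE, Biome.NON_ALPINE, Biome.BOTH]
        ref = oracle_loglik_biome_only(tree, tips, params, rho=rho)
        assert ll == pytest.approx(ref, abs=1e-4)

    def test_fast_path_agrees_with_adaptive(self, one_region_space):
        params = ClasseParams(q_NB=0.1, q_BN=0.1, q_BA=0.1, q_AB=0.1,
                              d=0, e=0)
        gen = build_generator(one_region_space, params)
        tree = random_ultrametric_tree(30, seed=12)
        rng = np.random.default_rng(0)
        tips = {lb: int(rng.integers(3)) for lb in tree.taxa}
        lla = classe_loglik(tree, tips, gen, rho=1.0, method="adaptive")
        llf = classe_loglik(tree, tips, gen, rho=1.0, method="fast",
                            nsteps=20)
        assert llf == pytest.approx(lla, abs=2e-3)

    def test_region_label_permutation_symmetry(self):
        """Swapping the labels of two regions with identical rates leaves
        the likelihood unchanged when tip states are permuted to match."""
        space = enumerate_states(regions=("Asia", "Europe"), max_range=2)
        params = ClasseParams(d=0.05, e=0.05)
        gen = build_generator(space, params)
        res = simulate_classe_tree(
            space, SimConfig(params=params, n_tips=12, seed=41))
        tree, tips = res.tree, res.tip_states

        def swap(idx):
            st = space[idx]
            mapping = {"Asia": "Europe", "Europe": "Asia"}
            return space.index_of(BiomeRegionState(
                st.biome, frozenset(mapping[r] for r in st.regions)))

        tips_swapped = {lb: swap(i) for lb, i in tips.items()}
        ll1 = classe_loglik(tree, tips, gen, rho=1.0, method="adaptive")
        ll2 = classe_loglik(tree, tips_swapped, gen, rho=1.0,
                            method="adaptive")
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_child_reordering_invariance(self, one_region_space):
        params = ClasseParams(q_NB=0.1, q_BN=0.1, q_BA=0.1, q_AB=0.1)
        gen = build_generator(one_region_space, params)
        tree = random_ultrametric_tree(10, seed=14)
        rng = np.random.default_rng(3)
        tips = {lb: int(rng.integers(3)) for lb in tree.taxa}
        ll1 = classe_loglik(tree, tips, gen, rho=1.0)
        flipped = tree.copy()
        for nd in flipped.internal_nodes():
            nd.children = nd.children[::-1]
        ll2 = classe_loglik(flipped, tips, gen, rho=1.0)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_collapsed_birth_death_matches_scalar_pruning(
            self, one_region_space):
        """With shared rates across biomes, no moves, and uniform tips,
        the likelihood equals a scalar constant-rate birth-death pruning
        computed with the closed-form E and D propagators."""
        lam, mu = 0.3, 0.1
        params = ClasseParams(
            lambda_alpine=lam, lambda_non_alpine=lam, lambda_both=lam,
            mu_alpine=mu, mu_non_alpine=mu, mu_both=mu,
            q_NB=0, q_BN=0, q_BA=0, q_AB=0, d=0, e=0)
        gen = build_generator(one_region_space, params)
        tree = random_ultrametric_tree(7, seed=5)
        tips = {lb: 2 for lb in tree.taxa}
        ll = classe_loglik(tree, tips, gen, rho=1.0, method="adaptive")

        r = lam - mu

        def E_of(t):
            return mu * (1 - math.exp(-r * t)) / \
                (lam - mu * math.exp(-r * t))

        def D_factor(t0, t1):
            # D(t1)/D(t0) for the linear BD propagator
            def g(t):
                return math.exp(-r * t) * (lam - mu * math.exp(-r * t))**-2
            return math.exp(-r * (t1 - t0)) * \
                ((lam - mu * math.exp(-r * t0))
                 / (lam - mu * math.exp(-r * t1))) ** 2

        logl = 0.0
        for nd in tree.postorder():
            if nd is tree.root:
                continue
            logl += math.log(D_factor(nd.age, nd.parent.age))
        n = tree.n_tips()
        logl += (n - 1) * math.log(lam)
        logl -= math.log(lam * (1 - E_of(tree.root_age())) ** 2)
        assert ll == pytest.approx(logl, abs=1e-6)

    def test_nonbinary_tree_rejected(self, one_region_space):
        from saxshift.trees import read_newick
        t = read_newick("(A:1,B:1,C:1);", units="myr")
        t.set_ages_from_lengths()
        gen = build_generator(one_region_space, ClasseParams())
        with pytest.raises(ValueError, match="binary"):
            classe_loglik(t, {lb: 0 for lb in t.taxa}, gen)


class TestMcmc:
    def test_prior_only_reproduces_prior_moments(self, one_region_space):
        """With the likelihood switched off, the chain samples the
        exponential(10) prior: mean 0.1, sd 0.1 within MC error."""
        tree = random_ultrametric_tree(4, seed=1)
        tips = {lb: 0 for lb in tree.taxa}
        s = mcmc_sample(tree, tips, one_region_space, n_iter=30_000, seed=7,
                        free=["lambda_both", "q_BA"], thin=5,
                        use_likelihood=False)
        for col in ("lambda_both", "q_BA"):
            assert s[col].mean() == pytest.approx(0.1, abs=0.02)
            assert s[col].std() == pytest.approx(0.1, abs=0.03)

    def test_same_seed_same_chain(self, one_region_space):
        params = ClasseParams(d=0, e=0)
        gen_tree = random_ultrametric_tree(10, seed=31)
        rng = np.random.default_rng(0)
        tips = {lb: int(rng.integers(3)) for lb in gen_tree.taxa}
        kw = dict(n_iter=200, seed=99, rho=1.0, thin=5,
                  free=["lambda_both", "q_BA"], nsteps=6)
        a = mcmc_sample(gen_tree, tips, enumerate_states(
            regions=("Asia",), max_range=1), **kw)
        b = mcmc_sample(gen_tree, tips, enumerate_states(
            regions=("Asia",), max_range=1), **kw)
        assert a.equals(b)
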