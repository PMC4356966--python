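"""Full-data-information sampler: latent draws, partial-conditional CDF
families, the order-statistic proposal, MH correctness against a grid
oracle, and end-to-end recovery on small problems."""

import numpy as np
import pytest
from scipy.special import log_expit

import lowrank_ising.ising_core as ising_core
from lowrank_ising import (
    ChainConfig,
    Dataset,
    Prior,
    PriorSpec,
    draw_theta,
    fit_curie_weiss,
    make_curie_weiss,
    run,
    sample_exact,
)
from lowrank_ising.sampler import (
    LogisticFamily,
    curie_weiss_obs_family,
    log_partial_conditional,
    mh_step,
    obs_cdf_family,
    os_propose,
    read_chains,
    update_parameter,
    write_chains,
)


def random_state(rng, N, n):
    return Dataset(np.where(rng.uniform(size=(N, n)) < 0.5, 1, -1))


class TestDrawTheta:
    def test_zero_loadings_standard_normal(self, rng):
        data = random_state(rng, 20_000, 4)
        theta = draw_theta(np.zeros((4, 2)), data, rng)
        assert theta.shape == (20_000, 2)
        assert np.all(np.abs(theta.mean(axis=0)) < 4 / np.sqrt(20_000))

    def test_mean_is_loading_projection(self, rng):
        E = rng.normal(size=(5, 2))
        data = random_state(rng, 3, 5)
        draws = np.stack([draw_theta(E, data, rng) for _ in range(4000)])
        target = data.states.astype(float) @ E
        assert np.allclose(draws.mean(axis=0), target, atol=4 / np.sqrt(4000))

    def test_seeded_determinism(self, rng):
        E = rng.normal(size=(4, 1))
        data = random_state(rng, 10, 4)
        t1 = draw_theta(E, data, np.random.default_rng(3))
        t2 = draw_theta(E, data, np.random.default_rng(3))
        assert np.array_equal(t1, t2)


class TestObsCdfFamily:
    def test_b_update_zero_theta_gives_identical_cdfs(self, rng):
        data = random_state(rng, 8, 3)
        fam = obs_cdf_family("b", 0, 0, np.zeros((8, 2)), np.zeros((3, 2)), np.zeros(3), data)
        assert np.allclose(fam.loc, 0.0)
        assert np.allclose(fam.scale, 0.5)

    @pytest.mark.parametrize("kind", ["b", "e"])
    def test_bernoulli_product_equals_irt_likelihood(self, kind, rng):
        # Π F^y (1−F)^{1−y} at the current parameter reproduces the product
        # of per-node IRT probabilities, including the θ<0 flipped build
        N, n, r = 9, 5, 2
        theta = rng.normal(size=(N, r))
        E = rng.normal(size=(n, r))
        b = rng.normal(size=n)
        data = random_state(rng, N, n)
        for i in range(n):
            x = theta @ E[i] + b[i]
            direct = log_expit(2.0 * data.states[:, i] * x).sum()
            comps = range(r) if kind == "e" else [0]
            for c in comps:
                fam = obs_cdf_family(kind, i, c, theta, E, b, data)
                w = b[i] if kind == "b" else E[i, c]
                assert fam.log_bernoulli(w, fam.y).sum() == pytest.approx(direct, abs=1e-12)

    def test_zero_theta_component_dropped(self, rng):
        N, n = 6, 3
        theta = rng.normal(size=(N, 1))
        theta[2, 0] = 0.0
        data = random_state(rng, N, n)
        fam = obs_cdf_family("e", 1, 0, theta, rng.normal(size=(n, 1)), np.zeros(n), data)
        assert fam.n_obs == N - 1


class TestOsPropose:
    def test_selected_rank_matches_total_score(self, rng):
        # the proposal is the order statistic of rank y_+ + 1: exactly
        # y_+ of the other draws fall below it
        fam = LogisticFamily(
            loc=rng.normal(size=12), scale=rng.uniform(0.3, 2.0, size=12),
            y=rng.uniform(size=12) < 0.5,
        )
        for y_plus in (0, 3, 12):
            prop = os_propose(Prior(), fam, y_plus, rng)
            below = np.delete(prop.below, prop.source)
            assert int(below.sum()) == y_plus

    def test_no_observations_returns_prior_draw(self, rng):
        fam = LogisticFamily(loc=np.empty(0), scale=np.empty(0), y=np.empty(0, dtype=bool))
        prop = os_propose(Prior(), fam, 0, rng)
        assert prop.source == 0

    def test_full_score_returns_maximum(self, rng):
        fam = LogisticFamily(loc=np.zeros(5), scale=np.ones(5), y=np.ones(5, dtype=bool))
        prop = os_propose(Prior(), fam, 5, rng)
        # rank N+1: every other draw lies below the proposal
        assert np.all(np.delete(prop.below, prop.source))

    def test_invalid_score_rejected(self, rng):
        fam = LogisticFamily(loc=np.zeros(3), scale=np.ones(3), y=np.ones(3, dtype=bool))
        with pytest.raises(ValueError):
            os_propose(Prior(), fam, 4, rng)


class TestMhStep:
    def test_proposal_equal_to_current_always_accepted(self, rng):
        fam = LogisticFamily(loc=np.zeros(4), scale=np.ones(4), y=np.ones(4, dtype=bool))
        prop = os_propose(Prior(), fam, 4, rng)
        from lowrank_ising.sampler import OSProposal

        same = OSProposal(w_star=0.37, source=prop.source, below=prop.below)
        # force current == proposal: ratio is exactly one
        w_new, accepted = mh_step(0.37, Prior(), fam, same, rng)
        assert accepted and w_new == 0.37

    def test_prior_only_target_always_accepts(self, rng):
        # no data: proposal source is the prior itself, target = prior
        fam = LogisticFamily(loc=np.empty(0), scale=np.empty(0), y=np.empty(0, dtype=bool))
        w = 0.0
        n_acc = 0
        for _ in range(2000):
            w, ok = update_parameter(w, Prior(), fam, rng)
            n_acc += ok
        assert n_acc == 2000

    def test_chain_matches_grid_density_for_single_main_effect(self, rng):
        # fixed θ, one b_i: MH samples vs grid-normalised partial conditional
        N, n = 150, 4
        theta = rng.normal(size=(N, 1))
        E = rng.normal(scale=0.4, size=(n, 1))
        b = np.zeros(n)
        data = random_state(rng, N, n)
        fam = obs_cdf_family("b", 0, 0, theta, E, b, data)
        prior = Prior()
        grid = np.linspace(-2.5, 2.5, 20001)
        lp = log_partial_conditional(grid, prior, fam)
        dens = np.exp(lp - lp.max())
        dens /= np.trapezoid(dens, grid)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        w, draws = 0.0, []
        for it in range(4500):
            w, _ = update_parameter(w, prior, fam, rng)
            if it >= 500:
                draws.append(w)
        draws = np.sort(draws)
        emp = np.arange(1, len(draws) + 1) / len(draws)
        interp = np.interp(draws, grid, cdf)
        ks = max(np.abs(emp - interp).max(), np.abs(emp - 1 / len(draws) - interp).max())
        assert ks < 0.08


class TestRun:
    def test_acceptance_rates_valid_and_b_above_e(self, rng):
        data = random_state(rng, 300, 6)
        chains = run(data, 2, config=ChainConfig(iterations=120, burn_in=40, seed=0))
        assert np.all((chains.accept_b >= 0) & (chains.accept_b <= 1))
        assert np.all((chains.accept_E >= 0) & (chains.accept_E <= 1))
        # main effects are typically easier to accept than loadings
        assert chains.accept_b.mean() >= chains.accept_E.mean() - 0.05

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            Dataset(np.empty((0, 4)))

    def test_rank_validation(self, rng):
        data = random_state(rng, 10, 3)
        with pytest.raises(ValueError, match="rank"):
            run(data, 4)

    def test_seeded_reproducibility(self, rng):
        data = random_state(rng, 100, 4)
        cfg = ChainConfig(iterations=60, burn_in=20, seed=5)
        c1 = run(data, 1, config=cfg)
        c2 = run(data, 1, config=cfg)
        assert np.array_equal(c1.b, c2.b)
        assert np.array_equal(c1.E, c2.E)

    def test_never_computes_partition_function(self, rng, monkeypatch):
        def boom(*args, **kwargs):
            raise AssertionError("sampler must not enumerate the partition function")

        monkeypatch.setattr(ising_core, "partition_function", boom)
        monkeypatch.setattr(ising_core, "log_partition_function", boom)
        data = random_state(rng, 80, 4)
        run(data, 1, config=ChainConfig(iterations=30, burn_in=10, seed=0))

    def test_chain_io_round_trip(self, rng, tmp_path):
        data = random_state(rng, 60, 3)
        chains = run(data, 2, config=ChainConfig(iterations=40, burn_in=10, seed=2))
        write_chains(chains, tmp_path / "c.csv", tmp_path / "c.json")
        back = read_chains(tmp_path / "c.csv", tmp_path / "c.json")
        assert np.allclose(back.b, chains.b)
        assert np.allclose(back.E, chains.E)
        assert back.rank == 2


class TestCurieWeissFit:
    def test_independent_coins_concentrate_near_zero(self, rng):
        data = random_state(rng, 800, 10)  # a = 0 ground truth
        chains = fit_curie_weiss(data, config=ChainConfig(iterations=1500, burn_in=300, seed=1))
        assert np.quantile(chains.a, 0.95) < 0.25

    def test_posterior_covers_truth_across_replicates(self):
        # central 95% interval contains the generating coupling in at
        # least 17 of 20 seeded replicates at N = 500
        model = make_curie_weiss(10, 0.5)
        hits = 0
        for k in range(20):
            data = sample_exact(model, 500, seed=100 + k)
            chains = fit_curie_weiss(
                data, config=ChainConfig(iterations=1800, burn_in=400, seed=k)
            )
            lo, hi = np.quantile(chains.a, [0.025, 0.975])
            hits += lo <= 0.5 <= hi
        assert hits >= 17

    def test_curie_weiss_family_matches_rasch_likelihood(self, rng):
        N, n = 12, 6
        data = random_state(rng, N, n)
        theta = rng.normal(size=N)
        e = 0.31
        fam = curie_weiss_obs_family(theta, data)
        direct = log_expit(2.0 * e * theta[:, None] * data.states).sum()
        assert fam.log_bernoulli(e, fam.y).sum() == pytest.approx(direct, abs=1e-10)
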