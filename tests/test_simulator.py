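import numpy as np
import pytest

from bbgp.simulate import (
    ErSimResult,
    SimConfig,
    found_replicate,
    selection_update,
    sequence_sample,
    simulate_experiment,
    wf_step,
)


class TestFounding:
    def test_fixed_endpoints(self, rng):
        assert found_replicate(200, 1000, 0.0, rng) == 0
        assert found_replicate(200, 1000, 1.0, rng) == 2000

    def test_matches_two_stage_sampling_oracle(self, rng):
        """Founding equals explicitly resampling haplotype labels from a
        pool of H founders."""
        H, N, p0, M = 200, 1000, 0.5, 10_000
        counts = np.array([found_replicate(H, N, p0, rng) for _ in range(M)])
        pool = np.zeros(H)
        pool[: round(H * p0)] = 1
        oracle = np.array(
            [pool[rng.integers(0, H, 2 * N)].sum() for _ in range(2000)]
        )
        se_mean = oracle.std() / np.sqrt(2000) + counts.std() / np.sqrt(M)
        assert counts.mean() == pytest.approx(oracle.mean(), abs=4 * se_mean)
        assert counts.var() == pytest.approx(oracle.var(), rel=0.15)


class TestWfStep:
    def test_neutral_martingale(self, rng):
        c = np.full(20_000, 600)  # p = 0.3 at 2N = 2000
        nxt = wf_step(c, 1000, 0.0, 0.5, rng)
        p = nxt / 2000
        assert p.mean() == pytest.approx(0.3, abs=4 * p.std() / np.sqrt(p.size))

    def test_deterministic_selection_update(self):
        assert selection_update(0.5, 0.1, 0.5) == pytest.approx(0.511905, abs=1e-6)

    def test_recessive_allele_initially_shielded(self):
        p = 0.01
        delta_rec = selection_update(p, 0.1, 0.0) - p
        delta_add = selection_update(p, 0.1, 0.5) - p
        assert 0 <= delta_rec < delta_add
        assert delta_rec < 2 * 0.1 * p * p  # O(p^2) differential

    def test_absorbing_boundaries(self, rng):
        assert wf_step(0, 1000, 0.1, 0.5, rng) == 0
        assert wf_step(2000, 1000, 0.1, 0.5, rng) == 2000


class TestSequencing:
    def test_fixed_frequencies(self, rng):
        y, n = sequence_sample(0.0, 45, rng)
        assert y == 0
        y, n = sequence_sample(1.0, 45, rng)
        assert y == n

    def test_poisson_depth_moment(self, rng):
        _, n = sequence_sample(np.full(100_000, 0.5), 45.0, rng)
        se = np.sqrt(45.0 / n.size)
        assert n.mean() == pytest.approx(45.0, abs=4 * se)

    def test_finite_pool_stage(self, rng):
        copies = np.full(1000, 1000)
        y, n = sequence_sample(
            np.full(1000, 0.5), 45.0, rng, N=1000, copies=copies, pool_females=500
        )
        assert ((0 <= y) & (y <= n)).all()


class TestExperiment:
    def test_neutral_mean_conservation(self):
        cfg = SimConfig(L_neutral=2000, L_selected=0, R=1,
                        sample_gens=(0, 60), seed=5)
        res = simulate_experiment(cfg)
        p0 = res.truth["p0"].to_numpy()
        terminal = res.freqs[:, 0, -1]
        se = terminal.std() / np.sqrt(terminal.size)
        assert terminal.mean() == pytest.approx(p0.mean(), abs=3 * se)

    def test_drift_variance_formula(self, rng):
        """Cross-trajectory variance after G generations matches the
        classical p0 q0 (1 - (1 - 1/2N)^G) drift formula."""
        N, G, M, p0 = 1000, 60, 2000, 0.5
        c = np.full(M, int(2 * N * p0))
        for _ in range(G):
            c = wf_step(c, N, 0.0, 0.5, rng)
        f = c / (2 * N)
        expected = p0 * (1 - p0) * (1 - (1 - 1 / (2 * N)) ** G)
        m4 = np.mean((f - f.mean()) ** 4)
        se_var = np.sqrt(max(m4 - f.var() ** 2, 0) / M)
        assert f.var() == pytest.approx(expected, abs=3 * se_var)

    def test_strong_selection_matches_recursion_oracle(self):
        """Mean terminal frequency under s=0.1, h=0.5, p0=0.2 tracks the
        deterministic selection recursion iterated over 60 generations."""
        p = 0.2
        for _ in range(60):
            p = selection_update(p, 0.1, 0.5)
        assert p == pytest.approx(0.8131864, abs=1e-6)
        cfg = SimConfig(L_neutral=0, L_selected=50, sample_gens=(0, 60),
                        p0_range_selected=(0.2, 0.2001), seed=11)
        res = simulate_experiment(cfg)
        assert res.freqs[:, :, -1].mean() == pytest.approx(p, abs=0.03)

    def test_reproducible_from_seed(self):
        cfg = SimConfig(L_neutral=20, L_selected=5, seed=42)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        assert np.array_equal(a.y, b.y) and np.array_equal(a.n, b.n)
        assert a.truth.equals(b.truth)

    def test_replicates_exchangeable(self):
        cfg = SimConfig(L_neutral=500, L_selected=0, seed=9)
        res = simulate_experiment(cfg)
        terminal = res.freqs[:, :, -1]  # (L, R)
        means = terminal.mean(axis=0)
        se = terminal.std() / np.sqrt(terminal.shape[0])
        assert np.ptp(means) < 6 * se

    def test_result_invariants(self):
        cfg = SimConfig(L_neutral=30, L_selected=10, seed=2)
        res = simulate_experiment(cfg)
        assert isinstance(res, ErSimResult)
        assert ((res.freqs >= 0) & (res.freqs <= 1)).all()
        assert (res.y <= res.n).all()
        assert res.truth.shape[0] == 40
        # generation-0 record equals the founded frequency exactly
        assert res.sample_gens[0] == 0

    def test_selected_p0_respects_range(self):
        cfg = SimConfig(L_neutral=0, L_selected=200, seed=3)
        res = simulate_experiment(cfg)
        p0 = res.truth["p0"]
        assert (p0 >= 0.12).all() and (p0 <= 0.8).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(N=0)
        with pytest.raises(ValueError):
            SimConfig(sample_gens=(0, 99))
        with pytest.raises(ValueError):
            SimConfig(p0_range_selected=(0.0, 0.5))
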