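"""Gibbs admixture sampler, Gelman-Rubin diagnostic, chain averaging."""

import numpy as np
import pytest

import gbsconcord as gc
from gbsconcord.admixture import ChainSamples, align_population_labels
from gbsconcord.errors import ConvergenceError, InputError


def _gl_from_dosages(dosages, depth=10, eps=0.01):
    """(N, S) dosage matrix -> (S, N, 3) log-GL with binomial read noise."""
    rng = np.random.default_rng(1234)
    dosages = np.asarray(dosages)
    p_alt = dosages / 2 * (1 - eps) + (1 - dosages / 2) * eps
    alt = rng.binomial(depth, p_alt)
    gl = gc.genotype_likelihood(depth - alt, alt, eps)  # (N, S, 3)
    return np.transpose(gl, (1, 0, 2))


def _noiseless_gl(dosages):
    dosages = np.asarray(dosages)
    n, s = dosages.shape
    gl = np.full((s, n, 3), -50.0)
    for i in range(n):
        for j in range(s):
            gl[j, i, dosages[i, j]] = 0.0
    return gl


class TestGibbs:
    def test_noiseless_likelihood_dominates(self):
        dos = np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1], [0, 2, 0]])
        gl = _noiseless_gl(dos)
        chains = gc.gibbs_admixture(gl, gc.MCMCConfig(iterations=400, burn_in=100, seed=3))
        for ch in chains:
            mode = ch.genoprob.argmax(axis=2)
            assert (mode == dos).all()
            assert ch.genoprob.max(axis=2).min() > 0.95

    def test_deterministic_given_seed(self):
        gl = _gl_from_dosages(np.array([[0, 1], [2, 1], [1, 0]]))
        cfg = gc.MCMCConfig(iterations=200, burn_in=50, seed=9)
        c1 = gc.gibbs_admixture(gl, cfg)
        c2 = gc.gibbs_admixture(gl, cfg)
        assert (c1[0].p == c2[0].p).all() and (c1[1].q == c2[1].q).all()

    def test_k1_beta_binomial_closed_form(self):
        """k=1 noiseless: p posterior mean equals (1 + alt copies)/(2 + 2N)."""
        dos = np.array([[0], [1], [2]])  # 3 alt copies among 6
        gl = _noiseless_gl(dos)
        cfg = gc.MCMCConfig(k=1, iterations=6000, burn_in=500, thin=2, chains=1, seed=4)
        (chain,) = gc.gibbs_admixture(gl, cfg)
        assert (chain.q == 1.0).all()  # degenerate admixture at k=1
        expected = (1 + 3) / (2 + 6)
        assert chain.p.mean() == pytest.approx(expected, abs=0.02)

    def test_posterior_mode_accuracy_at_depth_10(self):
        """>= 98% posterior-mode genotype accuracy at depth 10, eps = 0.01."""
        rng = np.random.default_rng(7)
        n, s = 12, 120
        f = rng.uniform(0.1, 0.5, s)
        dos = rng.binomial(2, f, (n, s))
        gl = _gl_from_dosages(dos, depth=10)
        gp = gc.genotype_probabilities(
            gl, gc.MCMCConfig(iterations=800, burn_in=200, seed=5), override=True
        )
        acc = (gp.probs.argmax(axis=2) == dos).mean()
        assert acc >= 0.98
        assert np.allclose(gp.probs.sum(axis=2), 1.0, atol=1e-9)
        assert gp.mean_dosage.min() >= 0.0 and gp.mean_dosage.max() <= 2.0

    def test_frequency_calibration_credible_interval(self):
        """k=1, f=0.3, 50 individuals at depth 20: the central 95% credible
        interval for p covers the truth in >= 90% of 20 seeded replicates."""
        cover = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            dos = rng.binomial(2, 0.3, (50, 1))
            p_alt = dos / 2 * 0.99 + (1 - dos / 2) * 0.01
            alt = rng.binomial(20, p_alt)
            gl = np.transpose(gc.genotype_likelihood(20 - alt, alt, 0.01), (1, 0, 2))
            cfg = gc.MCMCConfig(k=1, iterations=1200, burn_in=200, thin=2, chains=1, seed=rep)
            (chain,) = gc.gibbs_admixture(gl, cfg)
            lo, hi = np.quantile(chain.p[:, 0, 0], [0.025, 0.975])
            cover += lo <= 0.3 <= hi
        assert cover >= 18

    def test_zero_depth_cells_shrink_to_hw_prior(self):
        """A no-data cell lands near the admixture-weighted HW prior, not a
        confident genotype."""
        rng = np.random.default_rng(21)
        n, s = 20, 40
        dos = rng.binomial(2, 0.5, (n, s))
        gl = _gl_from_dosages(dos, depth=15)
        gl[0, 0, :] = 0.0  # individual 0 has no reads at site 0
        gp = gc.genotype_probabilities(
            gl, gc.MCMCConfig(iterations=600, burn_in=150, seed=2), override=True
        )
        assert gp.probs[0, 0].max() < 0.9
        assert 0.4 < gp.mean_dosage[0, 0] < 1.6  # near 2f = 1, not 0 or 2

    def test_nonfinite_gl_rejected(self):
        gl = np.zeros((2, 2, 3))
        gl[1, 0, 1] = np.nan
        with pytest.raises(InputError, match="site 1"):
            gc.gibbs_admixture(gl, gc.MCMCConfig(iterations=10, burn_in=1))


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        x = np.arange(20.0)
        gr = gc.gelman_rubin(np.stack([x, x]))
        assert gr.rhat == pytest.approx(1.0, abs=0.05)
        assert not gr.degenerate

    def test_separated_chains_hand_computation(self):
        """W = 5/3, B = 20000 -> R-hat = sqrt(5001.25 / (5/3)) ~ 54.78."""
        gr = gc.gelman_rubin([[1, 2, 3, 4], [101, 102, 103, 104]])
        w = 5 / 3
        var_plus = (3 / 4) * w + 20000 / 4
        assert gr.rhat == pytest.approx(np.sqrt(var_plus / w))
        assert gr.rhat > 50

    def test_degenerate_constant_chains(self):
        gr = gc.gelman_rubin([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert gr.rhat == 1.0 and gr.degenerate

    def test_same_distribution_below_1_1(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 500))
        assert gc.gelman_rubin(chains).rhat < 1.1

    def test_shape_validation(self):
        with pytest.raises(InputError):
            gc.gelman_rubin([[1.0, 2.0]])


class TestAveraging:
    def _chain(self, genoprob, p, q):
        return ChainSamples(genoprob=genoprob, p=p, q=q, n_samples=p.shape[0])

    def test_identical_chains_average_is_chain(self):
        rng = np.random.default_rng(3)
        gpb = rng.dirichlet(np.ones(3), size=(2, 4))
        p = rng.uniform(0.2, 0.8, (5, 2, 4))
        q = rng.dirichlet(np.ones(2), size=(5, 2))
        ch = self._chain(gpb, p, q)
        gp = gc.average_genotype_probs([ch, ch])
        assert np.allclose(gp.probs, gpb)

    def test_cell_average_arithmetic(self):
        a = np.zeros((1, 1, 3)); a[0, 0] = [1, 0, 0]
        b = np.zeros((1, 1, 3)); b[0, 0] = [0, 1, 0]
        p = np.full((4, 1, 1), 0.5)
        q = np.full((4, 1, 1), 1.0)
        gp = gc.average_genotype_probs([self._chain(a, p, q), self._chain(b, p, q)])
        assert gp.probs[0, 0] == pytest.approx([0.5, 0.5, 0])
        assert gp.mean_dosage[0, 0] == pytest.approx(0.5)

    def test_label_switched_chains_aligned(self):
        """Permuting population labels changes neither genotype probabilities
        nor (after alignment) the averaged admixture proportions."""
        rng = np.random.default_rng(8)
        gpb = rng.dirichlet(np.ones(3), size=(3, 6))
        p = rng.uniform(0.1, 0.9, (10, 2, 6))
        q = rng.dirichlet(np.ones(2), size=(10, 3))
        ch1 = self._chain(gpb, p, q)
        ch2 = self._chain(gpb, p[:, ::-1], q[:, :, ::-1])  # labels swapped
        aligned = align_population_labels([ch1, ch2])
        assert np.allclose(aligned[1].p, p)
        gp = gc.average_genotype_probs([ch1, ch2])
        assert np.allclose(gp.probs, gpb)
        assert np.allclose(gp.q, q.mean(axis=0))

    def test_convergence_screen_raises_and_overrides(self):
        rng = np.random.default_rng(5)
        gpb = rng.dirichlet(np.ones(3), size=(2, 3))
        p1 = np.full((6, 1, 3), 0.2) + rng.normal(0, 0.01, (6, 1, 3))
        p2 = np.full((6, 1, 3), 0.8) + rng.normal(0, 0.01, (6, 1, 3))
        q = np.full((6, 2, 1), 1.0)
        ch1 = self._chain(gpb, p1, q)
        ch2 = self._chain(gpb, p2, q)
        with pytest.raises(ConvergenceError) as exc:
            gc.average_genotype_probs([ch1, ch2], rhat_threshold=1.2)
        assert any(name.startswith("p[") for name in exc.value.parameters)
        gp = gc.average_genotype_probs([ch1, ch2], rhat_threshold=1.2, override=True)
        assert gp.rhat_max > 1.2
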