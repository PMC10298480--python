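"""Bayesian genotype probabilities via a hierarchical admixture model.

A desk-scale Gibbs sampler for the standard admixture model: each individual
``i`` has admixture proportions ``q_i ~ Dirichlet(1)`` over ``k`` populations;
each population has an alternative-allele frequency ``p_kl ~ Beta(1, 1)`` per
locus; the two allele copies of a genotype draw their ancestry from
``Categorical(q_i)`` and their allele from ``Bernoulli(p_zl)``; the read data
enter through the per-individual genotype likelihoods.  All full conditionals
are conjugate, so the sampler alternates: genotype states given (q, p) and
the likelihoods; allele-copy ancestries given genotypes; Beta updates for p;
Dirichlet updates for q.  Genotype probabilities are Rao-Blackwellised
(the per-sweep conditional posterior over dosage is averaged rather than the
sampled indicator).

This is a simplified stand-in for fuller hierarchical admixture samplers:
there are no hyper-priors on the Dirichlet/Beta parameters and k is fixed.
Genotype probabilities are invariant to population label switching; admixture
proportions are aligned across chains (by matching allele-frequency vectors)
before averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, ConvergenceError, InputError


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  The "field" preset is the full-length field protocol
    (50,000 iterations, burn-in 5,000, thin 10, k = 2, two chains); the
    default is a desk-scale preset with the same shape."""

    k: int = 2
    iterations: int = 5000
    burn_in: int = 500
    thin: int = 10
    chains: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (0 <= self.burn_in < self.iterations):
            raise ConfigError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.chains < 1:
            raise ConfigError("chains must be >= 1")

    @classmethod
    def preset(cls, name: str, **overrides) -> "MCMCConfig":
        presets = {
            "desk": cls(),
            "field": cls(iterations=50_000, burn_in=5_000, thin=10),
        }
        if name not in presets:
            raise ConfigError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        return replace(presets[name], **overrides)


@dataclass
class ChainSamples:
    """Thinned post-burn-in draws from one chain."""

    genoprob: np.ndarray  # (N, S, 3) Rao-Blackwellised posterior genotype probabilities
    p: np.ndarray  # (T, k, S) population allele frequencies
    q: np.ndarray  # (T, N, k) admixture proportions
    n_samples: int


@dataclass
class GenoProbMatrix:
    """Chain-averaged posterior genotype probabilities and mean dosage."""

    sample_ids: list[str]
    site_labels: list[str]
    probs: np.ndarray  # (N, S, 3)
    mean_dosage: np.ndarray  # (N, S)
    q: np.ndarray  # (N, k)
    rhat_max: float
    rhat_flagged: list[str] = field(default_factory=list)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_dosage, index=self.sample_ids, columns=self.site_labels)


def _normalized_likelihood(gl: np.ndarray) -> np.ndarray:
    """(S, N, 3) natural-log GLs -> (N, S, 3) linear likelihoods, max-normalized."""
    gl = np.asarray(gl, dtype=float)
    if gl.ndim != 3 or gl.shape[2] != 3:
        raise InputError("gl must be an (S, N, 3) array")
    bad = ~np.isfinite(gl)
    if bad.any():
        s, n, _ = np.argwhere(bad)[0]
        raise InputError(f"non-finite genotype likelihood at site {s}, individual {n}")
    lik = np.exp(gl - gl.max(axis=2, keepdims=True))
    return np.transpose(lik, (1, 0, 2))


def _sample_categorical(rng: np.random.Generator, w: np.ndarray) -> np.ndarray:
    """Sample indices along the last axis of a (…, k) weight array."""
    c = np.cumsum(w, axis=-1)
    c /= c[..., -1:]
    u = rng.random(w.shape[:-1] + (1,))
    return (u > c[..., :-1]).sum(axis=-1)


def gibbs_admixture(gl: np.ndarray, config: MCMCConfig | None = None) -> list[ChainSamples]:
    """Run the Gibbs sampler; returns one :class:`ChainSamples` per chain.

    ``gl`` is the (S, N, 3) natural-log genotype-likelihood matrix (flat
    triplets for missing data).  Deterministic given ``config.seed`` (chain
    ``c`` uses the stream seeded by ``[seed, c]``).
    """
    config = config or MCMCConfig()
    config.validate()
    lik = _normalized_likelihood(gl)  # (N, S, 3)
    n, s, _ = lik.shape
    k = config.k
    chains: list[ChainSamples] = []
    dosages = np.arange(3.0)
    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        p = rng.beta(1.0, 1.0, size=(k, s))
        q = rng.dirichlet(np.ones(k), size=n)
        gp_accum = np.zeros((n, s, 3))
        p_samples, q_samples = [], []
        n_rec = 0
        for it in range(config.iterations):
            pi = q @ p  # (N, S)
            prior = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1)
            post = prior * lik
            post /= post.sum(axis=-1, keepdims=True)
            g = _sample_categorical(rng, post)  # (N, S) dosages
            a1 = g >= 1  # allele of copy 1 (alt iff dosage >= 1)
            a2 = g == 2
            # ancestry of each copy: w_k = q_ik * p_kl^a * (1-p_kl)^(1-a)
            alt_counts = np.zeros((k, s))
            ref_counts = np.zeros((k, s))
            z_tot = np.zeros((n, k))
            for a in (a1, a2):
                w = q[:, None, :] * np.where(a[..., None], p.T[None], (1 - p.T)[None])
                z = _sample_categorical(rng, w)  # (N, S)
                for kk in range(k):
                    zk = z == kk
                    alt_counts[kk] += (zk & a).sum(axis=0)
                    ref_counts[kk] += (zk & ~a).sum(axis=0)
                    z_tot[:, kk] += zk.sum(axis=1)
            p = rng.beta(1.0 + alt_counts, 1.0 + ref_counts)
            q = _dirichlet_rows(rng, 1.0 + z_tot)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                gp_accum += post
                p_samples.append(p.copy())
                q_samples.append(q.copy())
                n_rec += 1
        chains.append(
            ChainSamples(
                genoprob=gp_accum / max(n_rec, 1),
                p=np.array(p_samples),
                q=np.array(q_samples),
                n_samples=n_rec,
            )
        )
    return chains


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws for an (N, k) concentration matrix."""
    gam = rng.gamma(alpha)
    return gam / gam.sum(axis=1, keepdims=True)


class GelmanRubin(NamedTuple):
    rhat: float
    degenerate: bool


def gelman_rubin(chains) -> GelmanRubin:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (m, n): m >= 2 chains of n >= 2 retained samples.  With the
    within-chain variance W and between-chain variance B (of chain means,
    times n), R-hat = sqrt(((n-1)/n * W + B/n) / W).  If every chain has zero
    within-chain variance the statistic is degenerate and reported as 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("need >= 2 chains of >= 2 samples")
    m, n = x.shape
    w = x.var(axis=1, ddof=1).mean()
    b = n * x.mean(axis=1).var(ddof=1)
    if w == 0:
        return GelmanRubin(1.0, True)
    var_plus = (n - 1) / n * w + b / n
    return GelmanRubin(float(np.sqrt(var_plus / w)), False)


def _rhat_many(stacks: np.ndarray) -> np.ndarray:
    """Vectorized R-hat over the trailing parameter axes of an (m, n, ...) array."""
    m, n = stacks.shape[:2]
    w = stacks.var(axis=1, ddof=1).mean(axis=0)
    b = n * stacks.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / w)
    r[w == 0] = 1.0
    return r


def align_population_labels(chains: list[ChainSamples]) -> list[ChainSamples]:
    """Permute population labels of each chain to best match the first chain.

    The permutation maximizes the agreement (negative squared distance) of
    posterior-mean allele-frequency vectors.  Genotype probabilities are
    label-invariant and untouched.
    """
    if not chains:
        return chains
    ref = chains[0].p.mean(axis=0)  # (k, S)
    k = ref.shape[0]
    out = [chains[0]]
    for ch in chains[1:]:
        mean_p = ch.p.mean(axis=0)
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(k)):
            score = -((ref - mean_p[list(perm)]) ** 2).sum()
            if score > best_score:
                best_perm, best_score = list(perm), score
        out.append(
            ChainSamples(
                genoprob=ch.genoprob,
                p=ch.p[:, best_perm],
                q=ch.q[:, :, best_perm],
                n_samples=ch.n_samples,
            )
        )
    return out


def average_genotype_probs(
    chains: list[ChainSamples],
    sample_ids: list[str] | None = None,
    site_labels: list[str] | None = None,
    rhat_threshold: float = 1.2,
    override: bool = False,
) -> GenoProbMatrix:
    """Average genotype probabilities across chains after a convergence screen.

    Monitored parameters are all population allele frequencies p_kl and all
    admixture proportions q_ik (after label alignment).  Any parameter with
    R-hat above ``rhat_threshold`` raises :class:`ConvergenceError` unless
    ``override`` is set; the offending parameter names are listed either way.
    """
    if not chains:
        raise InputError("no chains given")
    chains = align_population_labels(chains)
    flagged: list[str] = []
    rhat_max = 1.0
    if len(chains) >= 2 and all(c.n_samples >= 2 for c in chains):
        p_stack = np.stack([c.p for c in chains])  # (m, T, k, S)
        q_stack = np.stack([c.q for c in chains])  # (m, T, N, k)
        rp = _rhat_many(p_stack)
        rq = _rhat_many(q_stack)
        rhat_max = float(max(np.nanmax(rp), np.nanmax(rq)))
        for kk, ss in np.argwhere(rp > rhat_threshold):
            flagged.append(f"p[{kk},{ss}]")
        for ii, kk in np.argwhere(rq > rhat_threshold):
            flagged.append(f"q[{ii},{kk}]")
        if flagged and not override:
            raise ConvergenceError(
                f"{len(flagged)} monitored parameters exceed R-hat {rhat_threshold} "
                f"(max {rhat_max:.3f}): {flagged[:10]}{'...' if len(flagged) > 10 else ''}",
                parameters=flagged,
            )
    probs = np.mean([c.genoprob for c in chains], axis=0)
    probs /= probs.sum(axis=-1, keepdims=True)
    q = np.mean([c.q.mean(axis=0) for c in chains], axis=0)
    n, s, _ = probs.shape
    mean_dosage = probs @ np.arange(3.0)
    return GenoProbMatrix(
        sample_ids=list(sample_ids) if sample_ids else [f"ind{i + 1:02d}" for i in range(n)],
        site_labels=list(site_labels) if site_labels else [f"snp{j + 1}" for j in range(s)],
        probs=probs,
        mean_dosage=mean_dosage,
        q=q,
        rhat_max=rhat_max,
        rhat_flagged=flagged,
    )


def genotype_probabilities(
    gl: np.ndarray,
    config: MCMCConfig | None = None,
    sample_ids: list[str] | None = None,
    site_labels: list[str] | None = None,
    rhat_threshold: float = 1.2,
    override: bool = False,
) -> GenoProbMatrix:
    """Convenience: run all chains and average with the convergence screen."""
    chains = gibbs_admixture(gl, config)
    return average_genotype_probs(
        chains,
        sample_ids=sample_ids,
        site_labels=site_labels,
        rhat_threshold=rhat_threshold,
        override=override,
    )
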