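"""Concordance between two sampling arms: PCA, Procrustes, summary statistics.

The headline statistic is the symmetric Procrustes correlation R between the
two arms' PCA ordinations of posterior mean genotype dosage: both score
configurations are centered and scaled to unit sum of squares, the optimal
rotation comes from the SVD of the cross-product, the residual
m^2 = 1 - (sum of singular values)^2, and R = sqrt(1 - m^2).  R is invariant
to translation, rotation, reflection, and uniform scaling of either input,
and symmetric in its arguments.  Supporting statistics mirror the companion
wet-lab comparisons: a paired t-test (e.g. for DNA concentrations of the two
sampling methods) and an ANCOVA of a response on a covariate plus a
two-level group indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass
class PCAResult:
    """Principal-component scores of individuals (column-centered, unscaled)."""

    scores: np.ndarray  # (N, n_axes)
    explained_var: np.ndarray  # fractions, non-increasing
    n_axes: int
    sample_ids: list[str] | None = None


def pca(X, n_axes: int = 2, sample_ids: list[str] | None = None) -> PCAResult:
    """PCA of an individuals x SNPs matrix of mean genotype dosages.

    The matrix is column-centered (no variance scaling) and decomposed by
    SVD; scores are left singular vectors scaled by the singular values.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("pca needs a 2-D matrix with at least 2 individuals")
    if X.shape[1] < 1:
        raise InputError("pca needs at least one SNP column")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    n_axes = min(n_axes, len(s))
    return PCAResult(
        scores=(u * s)[:, :n_axes],
        explained_var=frac[:n_axes],
        n_axes=n_axes,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


@dataclass
class ProcrustesResult:
    """Symmetric Procrustes statistics; r = sqrt(1 - m2) by construction."""

    r: float
    m2: float
    rotation: np.ndarray  # applied to the second configuration
    scale: float
    translation_a: np.ndarray
    translation_b: np.ndarray
    residuals: np.ndarray  # per-individual residual distances


def procrustes(scores_a, scores_b) -> ProcrustesResult:
    """Symmetric Procrustes correlation between two score configurations.

    Both inputs (same individuals in the same order, same axis count) are
    centered and scaled to unit sum of squares; the second is then optimally
    rotated (reflections allowed) and scaled onto the first.
    """
    A = np.asarray(getattr(scores_a, "scores", scores_a), dtype=float)
    B = np.asarray(getattr(scores_b, "scores", scores_b), dtype=float)
    if A.shape != B.shape:
        raise InputError(f"configurations differ in shape: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[0] < 2:
        raise InputError("need at least two rows")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mu_a, B - mu_b
    na = np.sqrt((Ac**2).sum())
    nb = np.sqrt((Bc**2).sum())
    if na == 0 or nb == 0:
        raise InputError("degenerate configuration with zero spread")
    Ac /= na
    Bc /= nb
    u, s, vt = np.linalg.svd(Ac.T @ Bc)
    trace = s.sum()
    rotation = vt.T @ u.T  # maps Bc onto Ac
    scale = trace
    fitted = scale * Bc @ rotation
    m2 = max(0.0, 1.0 - trace**2)
    r = float(np.sqrt(max(0.0, 1.0 - m2)))
    residuals = np.sqrt(((Ac - fitted) ** 2).sum(axis=1))
    return ProcrustesResult(
        r=r,
        m2=float(m2),
        rotation=rotation,
        scale=float(scale),
        translation_a=mu_a,
        translation_b=mu_b,
        residuals=residuals,
    )


def procrustes_permutation_p(scores_a, scores_b, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for the observed Procrustes R (rows of B shuffled)."""
    A = np.asarray(getattr(scores_a, "scores", scores_a), dtype=float)
    B = np.asarray(getattr(scores_b, "scores", scores_b), dtype=float)
    obs = procrustes(A, B).r
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(B.shape[0])
        if procrustes(A, B[perm]).r >= obs:
            hits += 1
    return hits / (n_perm + 1)


@dataclass(frozen=True)
class PairedTTest:
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t(x, y) -> PairedTTest:
    """Two-tailed paired t-test on the differences x - y.

    With all differences zero the test is the degenerate "no difference" case
    (t = 0, p = 1, flagged); zero variance around a non-zero mean leaves t
    undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InputError("paired_t needs two equal-length 1-D samples of size >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTTest(0.0, n - 1, 1.0, degenerate=True)
        return PairedTTest(float("nan"), n - 1, float("nan"), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTTest(float(t), n - 1, float(p))


def t_pvalue(t: float, df: int) -> float:
    """Two-tailed p-value of a t statistic (Student's t survival function)."""
    return float(2.0 * stats.t.sf(abs(t), df=df))


def ancova(response, covariate, group) -> pd.DataFrame:
    """OLS of response on [intercept, covariate, group indicator].

    ``group`` must have exactly two levels.  Returns a per-term table with
    coefficient, standard error, t, and two-sided p (residual df = n - 3).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    g = np.asarray(group)
    if not (y.shape == x.shape == g.shape) or y.ndim != 1:
        raise InputError("response, covariate and group must be equal-length 1-D")
    if y.size < 4:
        raise InputError("need at least 4 observations for residual df >= 1")
    levels = pd.unique(g)
    if len(levels) != 2:
        raise InputError(f"group must have exactly two levels, got {list(levels)}")
    ind = (g == levels[1]).astype(float)
    X = np.column_stack([np.ones_like(y), x, ind])
    names = ["intercept", "covariate", f"group[{levels[1]}]"]
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        # identify the collinear term: drop columns until rank recovers
        for j in (1, 2):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise InputError(f"singular design: term {names[j]!r} is collinear")
        raise InputError("singular design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
    return pd.DataFrame(
        {"term": names, "estimate": beta, "se": se, "t": tvals, "p": pvals, "df": dof}
    )


@dataclass
class ArmSummary:
    label: str
    n_snps: int
    mean_coverage: float  # mean over SNPs of per-SNP mean depth per individual
    sd_coverage: float
    total_reads: int
    ledger: pd.DataFrame | None = None


@dataclass
class ConcordanceResult:
    """Paired ordinations, Procrustes statistics, and per-arm summaries."""

    arm_a: ArmSummary
    arm_b: ArmSummary
    procrustes_r: dict  # design -> R
    procrustes_m2: dict
    threshold: float
    concordant: dict  # design -> bool
    pca: dict = field(default_factory=dict)  # design -> (PCAResult, PCAResult)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "procrustes_r": dict(self.procrustes_r),
            "procrustes_m2": dict(self.procrustes_m2),
            "concordant": dict(self.concordant),
            "arms": {
                a.label: {
                    "n_snps": a.n_snps,
                    "mean_coverage": a.mean_coverage,
                    "sd_coverage": a.sd_coverage,
                    "total_reads": a.total_reads,
                }
                for a in (self.arm_a, self.arm_b)
            },
        }


def _arm_summary(arm) -> ArmSummary:
    """Summarize an ArmResult-like object (see gbsconcord.pipeline)."""
    table = arm.snp_table
    if table.n_sites:
        per_snp = table.total_depth.mean(axis=1)
        mean_cov, sd_cov = float(per_snp.mean()), float(per_snp.std(ddof=1)) if len(per_snp) > 1 else 0.0
    else:
        mean_cov, sd_cov = 0.0, 0.0
    return ArmSummary(
        label=arm.label,
        n_snps=table.n_sites,
        mean_coverage=mean_cov,
        sd_coverage=sd_cov,
        total_reads=int(sum(arm.read_counts.values())),
        ledger=arm.ledger.to_frame() if arm.ledger is not None else None,
    )


def concordance_report(
    arm_a,
    arm_b,
    arm_a_control=None,
    arm_b_control=None,
    n_axes: int = 2,
    threshold: float = 0.95,
) -> ConcordanceResult:
    """Compare two pipeline arms: PCA per arm, Procrustes between arms.

    ``arm_a``/``arm_b`` are own-reference ArmResults; if control-reference
    ArmResults are also given, a second Procrustes comparison is reported
    under the "control" design.  Individuals are matched by sample id and
    must coincide between arms.
    """
    designs = {"own": (arm_a, arm_b)}
    if arm_a_control is not None and arm_b_control is not None:
        designs["control"] = (arm_a_control, arm_b_control)
    r_by, m2_by, ok_by, pca_by = {}, {}, {}, {}
    for design, (a, b) in designs.items():
        ids_a = list(a.gprobs.sample_ids)
        ids_b = list(b.gprobs.sample_ids)
        missing = sorted(set(ids_a) ^ set(ids_b))
        if missing:
            raise InputError(f"arms disagree on individuals: {missing}")
        order_b = [ids_b.index(i) for i in ids_a]
        pa = pca(a.gprobs.mean_dosage, n_axes=n_axes, sample_ids=ids_a)
        pb = pca(b.gprobs.mean_dosage[order_b], n_axes=n_axes, sample_ids=ids_a)
        axes = min(pa.n_axes, pb.n_axes)
        res = procrustes(pa.scores[:, :axes], pb.scores[:, :axes])
        r_by[design] = res.r
        m2_by[design] = res.m2
        ok_by[design] = bool(res.r >= threshold)
        pca_by[design] = (pa, pb)
    return ConcordanceResult(
        arm_a=_arm_summary(arm_a),
        arm_b=_arm_summary(arm_b),
        procrustes_r=r_by,
        procrustes_m2=m2_by,
        threshold=threshold,
        concordant=ok_by,
        pca=pca_by,
    )


def plot_procrustes(pca_a: PCAResult, pca_b: PCAResult, ax=None):
    """Overlay two ordinations with residual arrows (requires matplotlib)."""
    import matplotlib.pyplot as plt

    res = procrustes(pca_a.scores, pca_b.scores)
    A = pca_a.scores - pca_a.scores.mean(axis=0)
    A = A / np.sqrt((A**2).sum())
    B = pca_b.scores - pca_b.scores.mean(axis=0)
    B = res.scale * (B / np.sqrt((B**2).sum())) @ res.rotation
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(A[:, 0], A[:, 1], facecolors="none", edgecolors="k", label="arm A")
    ax.scatter(B[:, 0], B[:, 1], marker="^", color="r", label="arm B")
    for i in range(A.shape[0]):
        ax.annotate("", xy=tuple(B[i]), xytext=tuple(A[i]), arrowprops={"arrowstyle": "->", "lw": 0.6})
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    ax.set_title(f"Procrustes R = {res.r:.3f}")
    return ax
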