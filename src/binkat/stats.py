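"""Bin-level association tests for a covariate-adjusted quantitative trait.

Model
-----
The phenotype is ``y = X b + e`` under the null, with ``X`` the covariate
design (intercept included) and Gaussian errors. Writing ``M = I - X (X'X)^- X'``
for the residual projection and ``r = M y`` for the null residuals, each bin
is scored through its weighted genotype matrix ``Z = G_bin diag(w)``:

* weighted burden: OLS of ``y`` on ``[X, s]`` with the collapsed score
  ``s_i = sum_j w_j g_ij``; two-sided t test on the score coefficient.
* SKAT (dispersion): score statistic ``Q = || Z' r ||^2``, distributed under
  the null as ``sum_k lambda_k chi^2_1`` with
  ``lambda = sigma^2 * eig(Z' M Z)``. The mixture tail is evaluated by
  numerical inversion of the characteristic function (Davies's approach)
  with a moment-matching (Liu) fallback.

The burden test is the more powerful of the two when variant effects share
a direction; SKAT is robust to mixed effect signs and to non-causal
variants inside the bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .binning import Bin
from .variant_io import GenotypeMatrix, VariantRecord

logger = logging.getLogger("binkat.stats")

__all__ = [
    "NullModel",
    "AssociationResult",
    "fit_null_model",
    "burden_score",
    "burden_test",
    "wilcoxon_burden_test",
    "skat_q",
    "skat_lambdas",
    "mixture_pvalue",
    "skat_test",
    "skat_permutation_pvalue",
    "leave_one_out",
    "bh_fdr",
]

P_FLOOR = 1e-300
_EIG_RTOL = 1e-10


@dataclass
class NullModel:
    """Covariate-only OLS fit: residuals, residual variance, projection."""

    design: np.ndarray
    residuals: np.ndarray
    sigma2: float
    rank: int
    _qbasis: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.design.shape[0]

    def project(self, v: np.ndarray) -> np.ndarray:
        """Apply ``M = I - X (X'X)^- X'`` to a vector or column block."""
        return v - self._qbasis @ (self._qbasis.T @ v)


@dataclass
class AssociationResult:
    feature_id: str
    level: str
    n_variants: int
    test: str
    statistic: float
    p_value: float
    p_method: str
    fdr_q: float = float("nan")
    flag: str = ""


def fit_null_model(phenotype: Sequence[float], covariates: np.ndarray) -> NullModel:
    """OLS of the phenotype on the covariate design (intercept included).

    ``sigma2`` uses the unbiased denominator ``n - rank(X)``. Rank-deficient
    designs and degenerate (zero residual variance) phenotypes are fatal.
    """
    y = np.asarray(phenotype, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2:
        raise ValueError("covariates must be a 2-D design matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("phenotype length does not match the design")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("phenotype/covariates contain non-finite values")
    if n <= p:
        raise ValueError(f"need n > p covariate columns (n={n}, p={p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _dependent_columns(X)
        raise ValueError(f"rank-deficient design; dependent columns: {bad}")
    q, _ = np.linalg.qr(X)
    resid = y - q @ (q.T @ y)
    rss = float(resid @ resid)
    sigma2 = rss / (n - rank)
    if sigma2 <= max(1e-12 * float(y @ y) / n, 1e-30):
        raise ValueError("zero residual variance: phenotype lies in the design span")
    return NullModel(design=X, residuals=resid, sigma2=sigma2, rank=rank, _qbasis=q)


def _dependent_columns(X: np.ndarray) -> list[int]:
    kept: list[int] = []
    bad: list[int] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            kept.append(j)
        else:
            bad.append(j)
    return bad


def burden_score(bin: Bin, geno: GenotypeMatrix) -> np.ndarray:
    """Per-sample collapsed score ``s_i = sum_j w_j * dosage_ij``."""
    return geno.dosage[:, bin.variant_indices] @ bin.weights


def burden_test(
    bin: Bin,
    geno: GenotypeMatrix,
    phenotype: Sequence[float],
    covariates: np.ndarray,
) -> AssociationResult:
    """Weighted burden regression: OLS of y on [covariates, score].

    Two-sided p-value for the score coefficient from the t distribution on
    ``n - p - 1`` degrees of freedom. A score with no variation beyond the
    covariate span is uninformative and reported with p = 1.
    """
    y = np.asarray(phenotype, dtype=float)
    X = np.asarray(covariates, dtype=float)
    s = burden_score(bin, geno)
    q, _ = np.linalg.qr(X)
    s_resid = s - q @ (q.T @ s)
    if float(s_resid @ s_resid) <= 1e-12 * max(float(s @ s), 1.0):
        return AssociationResult(
            feature_id=bin.feature_id,
            level=bin.level,
            n_variants=bin.size,
            test="burden",
            statistic=0.0,
            p_value=1.0,
            p_method="exact-t",
            flag="uninformative-bin",
        )
    fit = sm.OLS(y, np.column_stack([X, s])).fit()
    tval = float(fit.tvalues[-1])
    pval = float(fit.pvalues[-1])
    return AssociationResult(
        feature_id=bin.feature_id,
        level=bin.level,
        n_variants=bin.size,
        test="burden",
        statistic=tval,
        p_value=max(pval, P_FLOOR),
        p_method="exact-t",
    )


def wilcoxon_burden_test(
    bin: Bin, geno: GenotypeMatrix, group_labels: Sequence[int]
) -> AssociationResult:
    """Wilcoxon rank-sum burden test between two sample groups.

    The statistic is the rank-sum W of group-1 burden scores (midranks for
    ties). Exact enumeration is used when both groups have <= 8 samples and
    the scores are tie-free; otherwise the tie-corrected normal
    approximation.
    """
    labels = np.asarray(group_labels)
    s = burden_score(bin, geno)
    g1 = s[labels == 1]
    g0 = s[labels == 0]
    if g1.size == 0 or g0.size == 0:
        raise ValueError("both groups must be non-empty for the rank-sum test")
    ties = np.unique(s).size < s.size
    exact = g1.size <= 8 and g0.size <= 8 and not ties
    res = sps.mannwhitneyu(
        g1, g0, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    w = float(res.statistic + g1.size * (g1.size + 1) / 2)  # U1 -> rank-sum W
    return AssociationResult(
        feature_id=bin.feature_id,
        level=bin.level,
        n_variants=bin.size,
        test="wilcoxon",
        statistic=w,
        p_value=max(min(float(res.pvalue), 1.0), P_FLOOR),
        p_method="exact-enum" if exact else "normal-approx",
    )


def _weighted_genotypes(bin: Bin, geno: GenotypeMatrix) -> np.ndarray:
    return geno.dosage[:, bin.variant_indices] * bin.weights


def skat_q(null: NullModel, bin: Bin, geno: GenotypeMatrix) -> float:
    """SKAT score statistic ``Q = || Z' r ||^2`` with ``Z = G_bin diag(w)``."""
    z = _weighted_genotypes(bin, geno)
    u = z.T @ null.residuals
    return float(u @ u)


def skat_lambdas(null: NullModel, bin: Bin, geno: GenotypeMatrix) -> np.ndarray:
    """Mixture weights of the null distribution of Q.

    ``lambda = sigma2 * eig(Z' M Z)`` sorted descending, with eigenvalues
    below ``1e-10 * max`` discarded. Under the Gaussian null,
    ``Q ~ sum_k lambda_k chi^2_1``.
    """
    z = _weighted_genotypes(bin, geno)
    mz = null.project(z)
    a = mz.T @ mz  # Z'MZ, since M is idempotent
    eig = np.linalg.eigvalsh(a)[::-1]
    # "numerically zero" is judged against the pre-projection scale of Z, so
    # a bin annihilated by the design (Z within the covariate span) is empty
    scale = float((z**2).sum())
    if eig.size == 0 or eig[0] <= max(_EIG_RTOL * scale, 1e-30):
        return np.empty(0)
    lam = null.sigma2 * eig[eig > _EIG_RTOL * eig[0]]
    return lam


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Moment-matching approximation to P(sum lambda_k chi2_1 > q).

    Matches the first four cumulants ``c_r = sum lambda^r`` to a scaled
    (possibly noncentral) chi-square.
    """
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    t = (q - c1) / np.sqrt(2.0 * c2)
    x = t * np.sqrt(2.0) * a + df + delta
    if delta > 0:
        return float(sps.ncx2.sf(x, df, delta))
    return float(sps.chi2.sf(x, df))


def _davies_pvalue(
    q: float, lam: np.ndarray, acc: float = 1e-9, lim: int = 1_000_000
) -> tuple[float, bool]:
    """Tail of a positive mixture of chi-squares by CF inversion.

    Implements the real-axis inversion integral
    ``P(Q > q) = 1/2 + (1/pi) int_0^inf sin(theta(u)) / (u rho(u)) du``
    with a midpoint rule whose step is chosen so that the aliasing error is
    below ``acc`` (the mixture is stochastically dominated by
    ``lambda_max * chi2_m``, which bounds both tails) and whose truncation
    error is bounded from the integrand's decay rate. Mixtures with equal
    weights reduce to an exact scaled chi-square. Returns ``(p, converged)``;
    a non-converged evaluation (more than ``lim`` terms needed) leaves the
    caller to fall back to the Liu approximation.
    """
    lam = np.sort(np.asarray(lam, dtype=float))[::-1]
    m = lam.size
    scale = lam[0]
    lam = lam / scale
    q = q / scale
    if q <= 0.0:
        return 1.0, True
    if lam[-1] >= 1.0 - 1e-12:  # all weights equal: Q/lambda ~ chi2_m exactly
        return float(sps.chi2.sf(q, m)), True

    alias_acc = min(0.1 * acc, 1e-11)
    x_up = float(sps.chi2.isf(alias_acc, m))
    if q >= x_up:
        # deeper in the tail than the aliasing budget can resolve
        return float(sps.chi2.sf(q, m)), False
    span = 1.05 * max(x_up - q, q) + 1.0
    delta = 2.0 * np.pi / span

    total = 0.0
    block = 8192
    j0 = 0
    while j0 < lim:
        j = np.arange(j0, min(j0 + block, lim), dtype=float) + 0.5
        u = j * delta
        lu = lam[:, None] * u[None, :]
        theta = 0.5 * np.arctan(lu).sum(axis=0) - 0.5 * q * u
        log_rho = 0.25 * np.log1p(lu**2).sum(axis=0)
        total += float((np.sin(theta) * np.exp(-log_rho) / j).sum())
        u_end = u[-1]
        lu2 = (lam * u_end) ** 2
        decay = 0.5 * float((lu2 / (1.0 + lu2)).sum())  # integrand ~ u^-(1+decay)
        tail_bound = np.exp(-log_rho[-1]) / max(decay, 1e-3)
        if tail_bound / np.pi < 0.5 * acc:
            return 0.5 + total / np.pi, True
        j0 += block
    return 0.5 + total / np.pi, False


def _ruben_pvalue(
    q: float, lam: np.ndarray, acc: float = 1e-9, max_terms: int = 50_000
) -> tuple[float, bool]:
    """Tail of a positive chi-square mixture by Ruben's chi-square series.

    With ``beta = lambda_min`` the mixture sf expands as
    ``P(Q > q) = sum_k c_k P(chi2_{m+2k} > q / beta)`` with non-negative
    coefficients ``c_k`` summing to one, so the truncation error is bounded
    exactly by the undistributed mass ``1 - sum_{k<=K} c_k``. Converges
    geometrically at rate ``1 - lambda_min / lambda_max``; enormously
    spread mixtures exhaust ``max_terms`` and report non-convergence.
    """
    lam = np.asarray(lam, dtype=float)
    if q <= 0.0:
        return 1.0, True
    beta = lam.min()
    x = q / beta
    m = lam.size
    ratio = 1.0 - beta / lam  # in [0, 1)

    # chi-square upper tails SF(x; m + 2k) by upward recurrence in the df
    c0 = float(np.exp(0.5 * np.log(beta / lam).sum()))
    if c0 <= 0.0:
        return np.nan, False

    coeffs = np.empty(max_terms)
    coeffs[0] = c0
    gpow = ratio.copy()  # holds ratio**r
    g = np.empty(max_terms)  # g[r-1] = 0.5 * sum ratio**r
    mass = c0
    block = 1024
    n_done = 1

    from scipy.special import gammaln

    half_m = 0.5 * m
    sf0 = float(sps.chi2.sf(x, m))
    log_half_x = np.log(0.5 * x) if x > 0 else -np.inf

    while n_done < max_terms:
        n_end = min(n_done + block, max_terms)
        for n in range(n_done, n_end):
            g[n - 1] = 0.5 * float(gpow.sum())
            gpow *= ratio
            coeffs[n] = np.dot(coeffs[:n], g[n - 1 :: -1]) / n
        mass = float(coeffs[:n_end].sum())
        if 1.0 - mass < 0.5 * acc:
            k = np.arange(n_end, dtype=float)
            log_terms = (half_m + k[:-1]) * log_half_x - 0.5 * x - gammaln(
                half_m + k[:-1] + 1.0
            )
            sf = np.empty(n_end)
            sf[0] = sf0
            sf[1:] = sf0 + np.cumsum(np.exp(log_terms))
            sf = np.minimum(sf, 1.0)
            p = float(coeffs[:n_end] @ sf) + (1.0 - mass)
            return min(p, 1.0), True
        n_done = n_end
    return np.nan, False


def mixture_pvalue(
    q: float, lambdas: Sequence[float], method: str = "auto"
) -> tuple[float, str]:
    """P(sum_k lambda_k chi2_1 > q) for positive mixture weights.

    ``method="davies"`` uses characteristic-function inversion (absolute
    accuracy target 1e-9, at most 1e6 integration terms); ``"ruben"`` uses
    Ruben's chi-square series (same accuracy target, exact truncation
    bound); ``"liu"`` uses four-cumulant moment matching; ``"auto"`` tries
    the exact evaluations in that order and falls back to Liu only when
    both fail to converge or return a value outside (0, 1]. Returns
    ``(p_value, method_used)`` with p floored at 1e-300.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(lam <= 0.0) or not np.isfinite(lam).all():
        raise ValueError("mixture weights must be positive and finite")
    if method not in ("davies", "ruben", "liu", "auto"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("davies", "auto"):
        p, ok = _davies_pvalue(q, lam)
        if ok and 0.0 < p <= 1.0:
            return max(p, P_FLOOR), "davies"
        if method == "davies":
            raise RuntimeError("Davies CF inversion failed to converge")
    if method in ("ruben", "auto"):
        p, ok = _ruben_pvalue(q, lam)
        if ok and 0.0 < p <= 1.0:
            return max(p, P_FLOOR), "ruben"
        if method == "ruben":
            raise RuntimeError("Ruben series failed to converge")
    p = _liu_pvalue(q, lam)
    return min(max(p, P_FLOOR), 1.0), "liu"


def skat_test(null: NullModel, bin: Bin, geno: GenotypeMatrix) -> AssociationResult:
    """SKAT dispersion test of one bin against the fitted null model."""
    q = skat_q(null, bin, geno)
    lam = skat_lambdas(null, bin, geno)
    if lam.size == 0:
        return AssociationResult(
            feature_id=bin.feature_id,
            level=bin.level,
            n_variants=bin.size,
            test="skat",
            statistic=q,
            p_value=1.0,
            p_method="none",
            flag="uninformative-bin",
        )
    p, used = mixture_pvalue(q, lam, method="auto")
    return AssociationResult(
        feature_id=bin.feature_id,
        level=bin.level,
        n_variants=bin.size,
        test="skat",
        statistic=q,
        p_value=p,
        p_method=used,
    )


def skat_permutation_pvalue(
    null: NullModel,
    bin: Bin,
    geno: GenotypeMatrix,
    n_perm: int = 50_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Residual-permutation reference p-value for the SKAT statistic.

    Permutes the null residuals and recomputes Q; mainly useful as an
    independent calibration check of the analytic mixture tail.
    """
    rng = rng or np.random.default_rng()
    z = _weighted_genotypes(bin, geno)
    r = null.residuals
    q_obs = float((z.T @ r) @ (z.T @ r))
    perms = rng.permuted(np.broadcast_to(r, (n_perm, r.size)).copy(), axis=1)
    q_perm = ((perms @ z) ** 2).sum(axis=1)
    return (1.0 + float((q_perm >= q_obs).sum())) / (n_perm + 1.0)


def leave_one_out(
    null: NullModel,
    bin: Bin,
    geno: GenotypeMatrix,
    variants: Sequence[VariantRecord] | None = None,
) -> list[tuple[str, float]]:
    """Influence analysis: re-test the bin with each variant removed in turn.

    Returns ``(variant_id, p_without_variant)`` pairs sorted ascending by
    p-value; the *last* entry (largest removal p) is the most influential
    variant — dropping it weakens the signal the most.
    """
    if bin.size < 2:
        raise ValueError("leave-one-out requires a bin of size >= 2")
    rows: list[tuple[str, float]] = []
    for k in range(bin.size):
        keep = np.ones(bin.size, dtype=bool)
        keep[k] = False
        sub = Bin(
            feature_id=bin.feature_id,
            level=bin.level,
            variant_indices=bin.variant_indices[keep],
            weights=bin.weights[keep],
        )
        res = skat_test(null, sub, geno)
        j = int(bin.variant_indices[k])
        vid = variants[j].vid if variants is not None else str(j)
        rows.append((vid, res.p_value))
    rows.sort(key=lambda t: (t[1], t[0]))
    return rows


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0.0) or np.any(p > 1.0) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
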