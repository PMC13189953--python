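"""Sum-of-single-effects fine-mapping from z-scores and an LD matrix.

The model decomposes the (standardized) joint effect vector into L
single-effect vectors, each having exactly one nonzero coordinate with a
categorical posterior over variants and a normal slab prior on the effect.
Iterative Bayesian stepwise selection (coordinate ascent on the variational
objective) yields per-variant posterior inclusion probabilities

    PIP_i = 1 - prod_l (1 - alpha_{l,i})

and per-component credible sets: the smallest variant sets holding >= 95%
of a component's posterior mass, kept only when their purity (minimum
pairwise |r|) reaches 0.5.  Inputs are GWAS z-scores with an LD (correlation)
matrix, as produced from summary statistics; variants in near-perfect LD
(r^2 >= 0.99) are thinned first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FineMapResult", "CredibleSet", "ld_filter", "susie_rss"]


def ld_filter(
    variant_ids: list[str],
    ld_matrix: np.ndarray,
    r2_cap: float = 0.99,
) -> list[str]:
    """Greedy thinning of variants in near-perfect LD.

    Scanning in position (input) order, a variant is dropped when its squared
    correlation with an already-retained variant reaches ``r2_cap``.
    """
    R = np.asarray(ld_matrix, dtype=float)
    m = len(variant_ids)
    if R.shape != (m, m):
        raise ValueError("LD matrix does not match variant list")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("LD matrix is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("LD matrix diagonal is not 1")
    kept: list[int] = []
    for j in range(m):
        if all(R[j, k] ** 2 < r2_cap for k in kept):
            kept.append(j)
    return [variant_ids[j] for j in kept]


@dataclass(frozen=True)
class CredibleSet:
    """A level-``coverage`` credible set from one effect component."""

    component: int
    variants: tuple[int, ...]  # indices into the fitted variant list
    coverage: float
    purity: float


@dataclass
class FineMapResult:
    """PIPs, per-component posteriors and credible sets."""

    pip: np.ndarray
    alpha: np.ndarray  # (L, m) posterior inclusion weights per component
    posterior_mean: np.ndarray  # (L, m) conditional posterior effect means
    credible_sets: list[CredibleSet]
    L: int
    converged: bool
    elbo_trace: np.ndarray
    alpha_sums_trace: np.ndarray  # (iterations, L): conservation diagnostic

    def in_any_credible_set(self, index: int) -> bool:
        return any(index in cs.variants for cs in self.credible_sets)


def _credible_set(
    alpha_l: np.ndarray, R: np.ndarray, coverage: float, purity_min: float, component: int
) -> CredibleSet | None:
    order = np.argsort(-alpha_l, kind="stable")
    csum = np.cumsum(alpha_l[order])
    size = int(np.searchsorted(csum, coverage)) + 1
    size = min(size, len(order))
    members = tuple(sorted(int(i) for i in order[:size]))
    if len(members) == 1:
        purity = 1.0
    else:
        sub = np.abs(R[np.ix_(members, members)])
        iu = np.triu_indices(len(members), k=1)
        purity = float(sub[iu].min())
    if purity < purity_min:
        return None
    return CredibleSet(component, members, coverage, purity)


def susie_rss(
    z_scores: np.ndarray,
    ld_matrix: np.ndarray,
    n: int,
    L: int = 5,
    prior_variance: float = 0.04,
    tol: float = 1e-6,
    max_iter: int = 200,
    coverage: float = 0.95,
    purity_min: float = 0.5,
    ridge: float = 1e-6,
) -> FineMapResult:
    """Fit the sum-of-single-effects model to z-scores with LD.

    The z-scores and correlation matrix are converted to sufficient
    statistics on the standardized scale (X'X = (n-1) R, X'y = sqrt(n-1) z,
    y'y = n - 1) with residual variance fixed at 1; ``prior_variance`` is the
    slab variance of each single effect (default 0.2^2).  ``ridge`` is added
    to the LD diagonal for numerical stability.  At least two effect
    components are required.  If ``max_iter`` is reached before the ELBO
    changes by less than ``tol``, the partial result is returned with
    ``converged=False``.
    """
    z = np.asarray(z_scores, dtype=float)
    R = np.asarray(ld_matrix, dtype=float)
    m = len(z)
    if R.shape != (m, m):
        raise ValueError("z-scores and LD matrix are misaligned")
    if L < 2:
        raise ValueError("at least two effect components are required (L >= 2)")
    if n < 2:
        raise ValueError("sample size must be >= 2")
    R = R + ridge * np.eye(m)

    sigma2 = 1.0
    s0 = prior_variance
    XtX_scale = float(n - 1)
    d = XtX_scale * np.diag(R)
    Xty = np.sqrt(n - 1.0) * z
    yty = float(n - 1)
    log_prior = -np.log(m)

    alpha = np.full((L, m), 1.0 / m)
    mu = np.zeros((L, m))
    post_var = np.zeros((L, m))
    b = alpha * mu  # (L, m) per-component posterior mean vectors

    elbo_trace: list[float] = []
    alpha_sums: list[np.ndarray] = []
    converged = False

    def XtXv(v: np.ndarray) -> np.ndarray:
        return XtX_scale * (R @ v)

    for _ in range(max_iter):
        for l in range(L):
            b_others = b.sum(axis=0) - b[l]
            Xtr = Xty - XtXv(b_others)
            s1 = 1.0 / (1.0 / s0 + d / sigma2)
            mu1 = s1 * Xtr / sigma2
            shat2 = sigma2 / d
            bhat = Xtr / d
            lbf = 0.5 * np.log(shat2 / (s0 + shat2)) + 0.5 * (bhat**2 / shat2) * (
                s0 / (s0 + shat2)
            )
            w = lbf + log_prior
            w = w - w.max()
            a = np.exp(w)
            a /= a.sum()
            alpha[l] = a
            mu[l] = mu1
            post_var[l] = s1
            b[l] = a * mu1

        elbo_trace.append(
            _elbo(alpha, mu, post_var, b, Xty, yty, d, R, XtX_scale, sigma2, s0, n, log_prior)
        )
        alpha_sums.append(alpha.sum(axis=1).copy())
        if len(elbo_trace) > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break

    pip = 1.0 - np.prod(1.0 - alpha, axis=0)
    sets = []
    seen = set()
    for l in range(L):
        cs = _credible_set(alpha[l], R, coverage, purity_min, l)
        if cs is not None and cs.variants not in seen:
            seen.add(cs.variants)
            sets.append(cs)
    return FineMapResult(
        pip=pip,
        alpha=alpha,
        posterior_mean=mu,
        credible_sets=sets,
        L=L,
        converged=converged,
        elbo_trace=np.asarray(elbo_trace),
        alpha_sums_trace=np.asarray(alpha_sums),
    )


def _elbo(
    alpha: np.ndarray,
    mu: np.ndarray,
    post_var: np.ndarray,
    b: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    d: np.ndarray,
    R: np.ndarray,
    XtX_scale: float,
    sigma2: float,
    s0: float,
    n: int,
    log_prior: float,
) -> float:
    """Variational objective: E[log-likelihood] minus per-component KL."""
    btot = b.sum(axis=0)
    quad = XtX_scale * float(btot @ (R @ btot))
    quad -= sum(XtX_scale * float(b[l] @ (R @ b[l])) for l in range(b.shape[0]))
    eb2 = alpha * (mu**2 + post_var)  # (L, m) second moments
    quad += float((eb2 * d).sum())
    erss = yty - 2.0 * float(btot @ Xty) + quad
    eloglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * erss / sigma2

    kl = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        for l in range(alpha.shape[0]):
            a = alpha[l]
            nz = a > 0
            kl_cat = float(np.sum(a[nz] * (np.log(a[nz]) - log_prior)))
            kl_norm = 0.5 * (
                np.log(s0 / post_var[l]) + (post_var[l] + mu[l] ** 2) / s0 - 1.0
            )
            kl += kl_cat + float(np.sum(a * kl_norm))
    return float(eloglik - kl)
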