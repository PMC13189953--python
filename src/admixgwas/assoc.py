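"""Two-stage polygenic mixed-model association (GRAMMAR-style).

Stage 1 fits, once, the polygenic model

    y = X beta + g + e,   g ~ N(0, sigma_g^2 * 2*Phi),  e ~ N(0, sigma_e^2 I)

by REML, profiling the single variance ratio delta = sigma_e^2 / sigma_g^2 on
the eigendecomposition of the relationship matrix 2*Phi.  Stage-1 residuals
are decorrelated by the fitted covariance (r = V^-1/2 (y - X beta_hat), the
symmetric square root), rank inverse-normal transformed, and stage 2
regresses them on each variant's dosage with a plain Wald t-test and no
further covariates.  Whitening removes the family covariance from the
residuals, so the per-variant tests stay calibrated at nominal levels
without refitting the random effect per variant; BLUP-subtracted
("conditional") residuals are also available but are conservative under
dense families, because the fitted family effect absorbs part of every
family-shared signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_formats import CohortGenotypes
from .kinship import KinshipMatrix

__all__ = [
    "VarianceComponents",
    "fit_polygenic_model",
    "inverse_normal_transform",
    "AssocResult",
    "test_variants",
    "genomic_control_lambda",
]

_CHI2_1_MEDIAN = float(stats.chi2.median(df=1))


@dataclass
class VarianceComponents:
    """REML variance components and fixed effects of the polygenic model."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    fixed_effects: dict[str, float]
    loglik: float
    delta: float  # sigma_e^2 / sigma_g^2 at the optimum


def _reml_neg_loglik(log10_delta: float, d: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    delta = 10.0**log10_delta
    w = d + delta
    n, p = xr.shape
    xtw = xr.T / w
    xtwx = xtw @ xr
    xtwy = xtw @ yr
    beta = np.linalg.solve(xtwx, xtwy)
    resid = yr - xr @ beta
    rss = float(np.sum(resid**2 / w))
    sigma_g2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma_g2)
        + (n - p)
        + np.sum(np.log(w))
        + logdet_xtwx
    )
    return -ll


def fit_polygenic_model(
    phenotype: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    kinship: KinshipMatrix,
    sample_ids: list[str] | None = None,
    delta_log10_bounds: tuple[float, float] = (-6.0, 6.0),
    tol: float = 1e-6,
    residual_type: str = "decorrelated",
) -> tuple[VarianceComponents, np.ndarray]:
    """REML fit of the polygenic model; returns components and stage-1 residuals.

    ``phenotype`` and the rows of ``covariates`` must align with
    ``sample_ids`` (default: the kinship matrix's ids).  An intercept column
    is added automatically.  The variance ratio delta = sigma_e^2/sigma_g^2
    is profiled by bounded Brent search on log10(delta).

    ``residual_type`` selects the stage-1 residuals: "decorrelated"
    (default) returns V^-1/2 (y - X beta_hat) with the symmetric square root
    of the fitted covariance, which leaves the residuals exchangeable under
    the null; "conditional" returns the BLUP-subtracted residuals
    y - X beta_hat - g_hat, which are conservative in stage 2 when families
    are large.  When 2*Phi is the identity both choices are proportional to
    the OLS residuals.
    """
    y = np.asarray(phenotype, dtype=float)
    if sample_ids is None:
        sample_ids = list(kinship.ids)
    K = kinship.subset(sample_ids)
    A = K.relationship()
    n = len(y)
    if A.shape != (n, n) or len(covariates) != n:
        raise ValueError("phenotype, covariates and kinship are misaligned")

    X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    names = ["intercept"] + list(covariates.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    d, U = np.linalg.eigh(A)
    if d.min() < -1e-8:
        raise np.linalg.LinAlgError(
            f"kinship relationship matrix not PSD (min eigenvalue {d.min():.3g})"
        )
    d = np.clip(d, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=delta_log10_bounds,
        args=(d, yr, Xr),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(
            f"REML profile search failed in log10(delta) "
            f"bracket {delta_log10_bounds}: {res.message}"
        )
    delta = 10.0**res.x
    w = d + delta
    xtw = Xr.T / w
    beta = np.linalg.solve(xtw @ Xr, xtw @ yr)
    resid_r = yr - Xr @ beta
    sigma_g2 = float(np.sum(resid_r**2 / w)) / (n - X.shape[1])
    sigma_e2 = float(delta * sigma_g2)
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)

    if residual_type == "decorrelated":
        # V^-1/2 (y - X beta) up to the sigma_g scale (irrelevant after INT)
        residuals = U @ (resid_r / np.sqrt(w))
    elif residual_type == "conditional":
        # BLUP of g in the rotated basis: g* = D (D + delta I)^-1 (y* - X* beta)
        ghat = U @ (d / w * resid_r)
        residuals = y - X @ beta - ghat
    else:
        raise ValueError(f"unknown residual_type {residual_type!r}")
    vc = VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=float(h2),
        fixed_effects=dict(zip(names, beta)),
        loglik=float(-res.fun),
        delta=float(delta),
    )
    return vc, residuals


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps value of rank r (average rank for ties) among n to
    Phi^-1((r - 3/8) / (n + 1/4)); strictly monotone on distinct values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D array of length >= 2")
    if np.isnan(x).any():
        raise ValueError("missing values cannot be rank transformed")
    if np.all(x == x[0]):
        raise ValueError("all values identical; no ranking possible")
    ranks = stats.rankdata(x, method="average")
    return special.ndtri((ranks - 0.375) / (len(x) + 0.25))


@dataclass
class AssocResult:
    """Per-variant additive association statistics."""

    table: pd.DataFrame  # id, chrom, pos, ref, alt, n, beta, se, stat, p, tested

    def tested(self) -> pd.DataFrame:
        return self.table.loc[self.table["tested"]].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "AssocResult":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
        return cls(df)


def test_variants(
    int_residuals: np.ndarray,
    genotypes: CohortGenotypes,
    min_samples: int = 10,
) -> AssocResult:
    """Simple linear regression of transformed residuals on each dosage.

    Samples with missing dosage are dropped per variant; variants with fewer
    than ``min_samples`` informative samples or zero dosage variance are
    flagged untested.  Two-sided Wald t-test p-values.
    """
    y = np.asarray(int_residuals, dtype=float)
    d = genotypes.dosages
    if len(y) != d.shape[0]:
        raise ValueError("residuals and genotypes are misaligned")
    m = d.shape[1]
    ok = ~np.isnan(d)
    n_used = ok.sum(axis=0)

    yk = np.where(ok, y[:, None], 0.0)
    dk = np.where(ok, d, 0.0)
    sum_x = dk.sum(axis=0)
    sum_y = yk.sum(axis=0)
    sum_xx = (dk * dk).sum(axis=0)
    sum_xy = (dk * yk).sum(axis=0)
    sum_yy = (yk * yk).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        nv = n_used.astype(float)
        sxx = sum_xx - sum_x**2 / nv
        sxy = sum_xy - sum_x * sum_y / nv
        syy = sum_yy - sum_y**2 / nv
        beta = sxy / sxx
        rss = syy - beta * sxy
        df = nv - 2
        sigma2 = np.clip(rss, 0.0, None) / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)

    tested = (n_used >= min_samples) & (sxx > 1e-12) & (df > 0)
    # guard against exact fits: p underflows toward 0 but stays in (0, 1]
    p = np.where(tested, np.clip(p, np.nextafter(0, 1), 1.0), np.nan)
    table = pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "chrom": genotypes.variants["chrom"],
            "pos": genotypes.variants["pos"],
            "ref": genotypes.variants["ref"],
            "alt": genotypes.variants["alt"],
            "n": n_used,
            "beta": np.where(tested, beta, np.nan),
            "se": np.where(tested, se, np.nan),
            "stat": np.where(tested, tstat, np.nan),
            "p": p,
            "tested": tested,
        }
    )
    return AssocResult(table)


def genomic_control_lambda(assoc: AssocResult | np.ndarray) -> float:
    """Genomic-control inflation factor: median chi^2 over the chi^2_1 median."""
    if isinstance(assoc, AssocResult):
        p = assoc.tested()["p"].to_numpy(dtype=float)
    else:
        p = np.asarray(assoc, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 tested variants for lambda")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)
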