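"""Post-imputation quality control and population structure.

Filters follow the usual post-imputation defaults for an imputed family
cohort: per-sample missingness < 10%, per-variant missingness < 10%,
imputation R^2 > 0.8 (strict), MAF >= 1%, and an exact Hardy-Weinberg test
(p >= 1e-6) computed in unrelated individuals only, so that family structure
does not masquerade as HWE departure.  Population structure is summarized by
PCA fitted on LD-pruned variants in the unrelated subset and projected onto
everyone else with the same loadings and standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CohortGenotypes, ValidationError

__all__ = [
    "QCThresholds",
    "QCReport",
    "variant_sample_qc",
    "hwe_exact_test",
    "ld_prune",
    "PCResult",
    "pca_fit_project",
]


@dataclass(frozen=True)
class QCThresholds:
    """Variant/sample filter thresholds (defaults: imputed-cohort standard)."""

    sample_missing_max: float = 0.10  # exclusive: fail if rate >= max
    variant_missing_max: float = 0.10
    imputation_r2_min: float = 0.8  # strict: fail if R2 <= min
    maf_min: float = 0.01  # fail if MAF < min
    hwe_p_min: float = 1e-6  # fail if p < min


@dataclass
class QCReport:
    """Per-variant and per-sample QC statistics with pass flags and reasons."""

    variant_table: pd.DataFrame
    sample_table: pd.DataFrame
    thresholds: QCThresholds

    @property
    def passed_variants(self) -> list[str]:
        t = self.variant_table
        return list(t.loc[t["pass"], "id"])

    @property
    def passed_samples(self) -> list[str]:
        t = self.sample_table
        return list(t.loc[t["pass"], "sample_id"])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the allele counts, the heterozygote count under HWE has
    the (hypergeometric-type) distribution

        P(h) ∝ n! * 2**h / (n_AA! * h! * n_aa!)

    over heterozygote counts h with the parity of the minor-allele count.
    The p-value sums P over all configurations no more probable than the
    observed one.  Computed with exact integer weights, so results agree
    with full enumeration to machine precision.  Monomorphic input returns
    p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa  # minor allele count (either allele works: symmetric)
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    f = [math.factorial(k) for k in range(n + 1)]
    weights: dict[int, int] = {}
    for h in range(rare % 2, rare + 1, 2):
        aa = (rare - h) // 2
        AA = n - aa - h
        if AA < 0:
            continue
        weights[h] = (f[n] * (1 << h)) // (f[AA] * f[h] * f[aa])
    w_obs = weights[n_Aa]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return tail / total


def variant_sample_qc(
    genotypes: CohortGenotypes,
    unrelated_ids: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[QCReport, CohortGenotypes]:
    """Apply sample- then variant-level filters in a fixed order.

    Order: (1) drop samples with missingness >= ``sample_missing_max``;
    (2) variant missingness; (3) imputation R^2 (strict >, variants with no
    score pass); (4) MAF; (5) exact HWE in the unrelated survivors.
    Reason codes record every stage a variant failed among those evaluated
    for it; variants failing an early stage are not evaluated further.
    """
    unrel = set(unrelated_ids)
    missing_unrel = unrel - set(genotypes.samples)
    if missing_unrel:
        raise ValueError(f"unrelated ids not in cohort: {sorted(missing_unrel)[:5]}")

    d = genotypes.dosages
    # stage 1: sample missingness
    sample_miss = np.mean(np.isnan(d), axis=1)
    sample_pass = sample_miss < thresholds.sample_missing_max
    sample_table = pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "missing_rate": sample_miss,
            "pass": sample_pass,
        }
    )
    kept_samples = [s for s, ok in zip(genotypes.samples, sample_pass) if ok]
    if not kept_samples:
        raise ValidationError("all samples fail missingness QC")
    g = genotypes.subset(sample_ids=kept_samples)
    d = g.dosages

    n_samp = d.shape[0]
    variant_miss = np.mean(np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    r2 = g.variants["imputation_r2"].to_numpy(dtype=float)

    unrel_kept = [s for s in kept_samples if s in unrel]
    if not unrel_kept:
        raise ValidationError("no unrelated individuals survive sample QC; HWE stage impossible")
    unrel_idx = np.asarray([kept_samples.index(s) for s in unrel_kept], dtype=int)
    du = d[unrel_idx, :]

    m = g.n_variants
    reasons: list[list[str]] = [[] for _ in range(m)]
    hwe_p = np.full(m, np.nan)
    for j in range(m):
        if variant_miss[j] >= thresholds.variant_missing_max:
            reasons[j].append("missing_rate")
            continue
        if not np.isnan(r2[j]) and r2[j] <= thresholds.imputation_r2_min:
            reasons[j].append("imputation_r2")
            continue
        if np.isnan(maf[j]) or maf[j] < thresholds.maf_min:
            reasons[j].append("maf")
            continue
        col = du[:, j]
        col = col[~np.isnan(col)]
        geno = np.rint(col).astype(int)
        n_AA = int(np.sum(geno == 0))
        n_Aa = int(np.sum(geno == 1))
        n_aa = int(np.sum(geno == 2))
        if n_AA + n_Aa + n_aa == 0:
            reasons[j].append("hwe_no_data")
            continue
        hwe_p[j] = hwe_exact_test(n_AA, n_Aa, n_aa)
        if hwe_p[j] < thresholds.hwe_p_min:
            reasons[j].append("hwe")

    passed = np.asarray([len(r) == 0 for r in reasons])
    variant_table = pd.DataFrame(
        {
            "id": g.variants["id"],
            "chrom": g.variants["chrom"],
            "pos": g.variants["pos"],
            "maf": maf,
            "missing_rate": variant_miss,
            "imputation_r2": r2,
            "hwe_p": hwe_p,
            "pass": passed,
            "reasons": [",".join(r) for r in reasons],
        }
    )
    report = QCReport(variant_table, sample_table, thresholds)
    filtered = g.subset(variant_ids=list(g.variants.loc[passed, "id"]))
    return report, filtered


# --------------------------------------------------------------------------
# LD pruning
# --------------------------------------------------------------------------


def pairwise_complete_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared dosage correlation matrix.

    Each pair's correlation uses only samples observed for both variants;
    pairs involving a zero-variance variant get NaN (excluded from pruning
    decisions).
    """
    mask = (~np.isnan(d)).astype(float)
    x = np.where(np.isnan(d), 0.0, d)
    n = mask.T @ mask
    sx = x.T @ mask  # sum of x over the joint support, per pair
    sxx = (x * x).T @ mask
    sxy = x.T @ x
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        denom = varx * varx.T
        r2 = np.where(denom > 1e-12, cov**2 / denom, np.nan)
        r2 = np.where(n >= 2, r2, np.nan)
    return r2


def ld_prune(
    genotypes: CohortGenotypes,
    window: int = 1000,
    step: int = 50,
    r2_max: float = 0.05,
) -> list[str]:
    """Sliding-window LD pruning in the PLINK ``--indep-pairwise`` style.

    Within each window of ``window`` variants (advancing by ``step``),
    scanning retained pairs in position order, the later-position member of
    any pair with squared dosage correlation > ``r2_max`` is removed.
    Correlations are pairwise-complete over non-missing samples;
    zero-variance variants never trigger removal and are retained.  Variants
    are processed per chromosome in position order; the result is
    deterministic.
    """
    order = np.lexsort(
        (genotypes.variants["pos"].to_numpy(), genotypes.variants["chrom"].to_numpy())
    )
    ids = genotypes.variants["id"].to_numpy()
    chroms = genotypes.variants["chrom"].to_numpy()
    d = genotypes.dosages
    retained = dict.fromkeys(ids[order], True)

    for chrom in pd.unique(chroms[order]):
        cidx = order[chroms[order] == chrom]
        m = len(cidx)
        alive = np.ones(m, dtype=bool)
        start = 0
        while True:
            stop = min(start + window, m)
            widx = np.asarray([k for k in range(start, stop) if alive[k]], dtype=int)
            if len(widx) > 1:
                r2 = pairwise_complete_r2(d[:, cidx[widx]])
                exceed = (r2 > r2_max) & ~np.isnan(r2)
                walive = np.ones(len(widx), dtype=bool)
                for a in range(len(widx)):
                    if not walive[a]:
                        continue
                    hits = exceed[a, a + 1 :] & walive[a + 1 :]
                    walive[a + 1 :][hits] = False
                alive[widx[~walive]] = False
            if stop >= m:
                break
            start += step
        for k in range(m):
            if not alive[k]:
                retained[ids[cidx[k]]] = False
    return [i for i in ids[order] if retained[i]]


# --------------------------------------------------------------------------
# PCA on unrelateds, projection of relatives
# --------------------------------------------------------------------------


@dataclass
class PCResult:
    """PCA loadings/scores with the unrelated fit-set flag per sample."""

    variant_ids: list[str]
    loadings: np.ndarray  # (n_pruned_variants, K)
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, K)
    explained_variance_ratio: np.ndarray
    fit_set: np.ndarray  # bool per sample

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.scores[:, k] for k in range(self.scores.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols, "fit_set": self.fit_set})


def pca_fit_project(
    genotypes: CohortGenotypes,
    pruned_ids: Sequence[str],
    unrelated_ids: Sequence[str],
    k: int = 4,
) -> PCResult:
    """Fit PCA on unrelated individuals and project everyone.

    Dosages are standardized as (x - 2p) / sqrt(2p(1-p)) with allele
    frequency p estimated in the unrelated fit set; missing values are mean
    imputed (zero after centering) inside PCA only.  Components are fitted by
    SVD of the standardized unrelated matrix; all samples (relatives
    included) are projected with the same loadings.  Each component's sign is
    fixed by forcing its largest-magnitude loading positive.
    """
    if len(pruned_ids) == 0:
        raise ValueError("no pruned variants to fit PCA on")
    if len(unrelated_ids) <= k:
        raise ValueError(f"need more than {k} unrelated individuals to fit {k} PCs")
    sub = genotypes.subset(variant_ids=list(pruned_ids))
    pos = {s: i for i, s in enumerate(sub.samples)}
    fit_idx = np.asarray([pos[s] for s in unrelated_ids], dtype=int)

    d = sub.dosages
    du = d[fit_idx, :]
    p = np.nanmean(du, axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    usable = (scale > 0) & ~np.isnan(scale)
    if usable.sum() == 0:
        raise ValueError("all pruned variants are monomorphic in the fit set")
    p, scale = p[usable], scale[usable]
    z = (d[:, usable] - 2.0 * p) / scale
    z = np.where(np.isnan(z), 0.0, z)
    zu = z[fit_idx, :]

    u, s, vt = np.linalg.svd(zu, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if len(s) else 0
    if k > rank:
        raise ValueError(f"requested {k} components but fit-set rank is {rank}")
    loadings = vt[:k, :].T  # (m, k)
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(k):
        jmax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[jmax, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = z @ loadings
    var_ratio = (s[:k] ** 2) / np.sum(s**2)
    kept_ids = list(np.asarray(sub.variants["id"])[usable])
    fit_set = np.zeros(len(sub.samples), dtype=bool)
    fit_set[fit_idx] = True
    return PCResult(kept_ids, loadings, list(sub.samples), scores, var_ratio, fit_set)
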