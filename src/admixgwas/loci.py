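"""Genomic risk loci, catalog cross-referencing, ancestry enrichment.

Variants below the suggestive threshold (p < 1e-4 by default) are grouped
into loci: nearby significant variants (gaps <= 100 kb) cluster together,
each cluster's minimum-p variant becomes the lead, a 100 kb window is
centered on the lead, and overlapping windows are merged (the merged locus
keeps the best lead).  Any significant variant left outside every window
seeds a new cluster and the procedure repeats, so every significant variant
ends up in exactly one locus.

Loci are then tiered: genome-wide (any member p <= 5e-8), or
catalog-supported when an obesity-related catalog association at the same
lenient significance (5e-8 < p < 1e-4) falls inside the locus bounds.  Only
those two tiers are carried into the functional-prioritization stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assoc import AssocResult

__all__ = [
    "GenomicLocus",
    "define_loci",
    "DEFAULT_TRAIT_TERMS",
    "catalog_crossref",
    "retained_loci",
    "ancestry_enrichment",
]


@dataclass(frozen=True)
class GenomicLocus:
    """A merged risk locus: 1-based inclusive bounds, lead variant, members."""

    chrom: str
    start: int
    end: int
    lead_id: str
    lead_p: float
    members: tuple[str, ...]
    tier: str | None = None  # genome_wide | suggestive_catalog_supported | suggestive_unsupported

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _cluster_positions(pos: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Indices grouped so consecutive positions within a group differ <= max_gap."""
    order = np.argsort(pos, kind="stable")
    groups: list[list[int]] = []
    for idx in order:
        if groups and pos[idx] - pos[groups[-1][-1]] <= max_gap:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    return [np.asarray(g) for g in groups]


def define_loci(
    assoc: AssocResult | pd.DataFrame,
    p_threshold: float = 1e-4,
    region_size: int = 100_000,
) -> list[GenomicLocus]:
    """Group significant variants into merged risk loci.

    Per chromosome: (1) significant variants (p < ``p_threshold``) with
    consecutive gaps <= ``region_size`` form clusters; (2) each cluster's
    lead is its minimum-p variant (ties: smaller position, then id);
    (3) a window of ``region_size`` is centered on the lead (floored at
    position 1); (4) overlapping windows merge to a fixpoint, keeping the
    best lead; significant variants not covered by any window seed new
    clusters until all are covered.  Members are the significant variants
    inside the final bounds.  Output is sorted by (chrom, start) and
    invariant to input row order.
    """
    table = assoc.tested() if isinstance(assoc, AssocResult) else assoc
    sig = table.loc[table["p"] < p_threshold, ["id", "chrom", "pos", "p"]]
    loci: list[GenomicLocus] = []
    half = region_size // 2
    for chrom, group in sig.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy(dtype=np.int64)
        pvals = group["p"].to_numpy(dtype=float)
        ids = group["id"].to_numpy()

        # windows as (start, end) 1-based inclusive, with their lead
        windows: list[tuple[int, int, str, float]] = []

        def covered(p_: int) -> bool:
            return any(s <= p_ <= e for s, e, _, _ in windows)

        remaining = np.arange(len(pos))
        while len(remaining):
            for grp in _cluster_positions(pos[remaining], region_size):
                g = remaining[grp]
                lead_order = sorted(g, key=lambda i: (pvals[i], pos[i], ids[i]))
                lead = lead_order[0]
                start = max(1, int(pos[lead]) - half)
                end = int(pos[lead]) + half
                windows.append((start, end, ids[lead], pvals[lead]))
            # merge overlapping windows to fixpoint, keep the best lead
            changed = True
            while changed:
                changed = False
                windows.sort(key=lambda w: w[0])
                merged: list[tuple[int, int, str, float]] = []
                for w in windows:
                    if merged and w[0] <= merged[-1][1]:
                        prev = merged[-1]
                        best = min(
                            [prev, w], key=lambda t: (t[3], _lead_pos(t, pos, ids), t[2])
                        )
                        merged[-1] = (prev[0], max(prev[1], w[1]), best[2], best[3])
                        changed = True
                    else:
                        merged.append(w)
                windows = merged
            remaining = np.asarray([i for i in remaining if not covered(int(pos[i]))])
        for start, end, lead_id, lead_p in windows:
            inside = (pos >= start) & (pos <= end)
            member_ids = tuple(ids[i] for i in np.argsort(pos, kind="stable") if inside[i])
            loci.append(
                GenomicLocus(str(chrom), start, end, lead_id, float(lead_p), member_ids)
            )
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def _lead_pos(w: tuple[int, int, str, float], pos: np.ndarray, ids: np.ndarray) -> int:
    where = np.nonzero(ids == w[2])[0]
    return int(pos[where[0]]) if len(where) else 0


#: Obesity-related trait vocabulary for catalog matching.
DEFAULT_TRAIT_TERMS = (
    "body mass index",
    "BMI",
    "waist-hip ratio",
    "WHR",
    "obese",
    "obesity",
    "weight",
    "body weight",
    "overweight",
    "waist circumference",
    "hip circumference",
    "body fat",
    "fat distribution",
    "fat-free mass",
)


def catalog_crossref(
    loci: list[GenomicLocus],
    assoc: AssocResult | pd.DataFrame,
    catalog: pd.DataFrame,
    trait_terms: tuple[str, ...] = DEFAULT_TRAIT_TERMS,
    gw_threshold: float = 5e-8,
    lenient_low: float = 5e-8,
    lenient_high: float = 1e-4,
) -> list[GenomicLocus]:
    """Assign evidence tiers to loci and return all loci with tiers set.

    genome_wide: any member variant with cohort p <= ``gw_threshold``.
    suggestive_catalog_supported: a catalog record inside the locus bounds
    whose trait matches the vocabulary (case-insensitive exact match) with
    catalog p strictly inside (``lenient_low``, ``lenient_high``).
    Everything else is suggestive_unsupported (dropped downstream).
    Malformed catalog rows are skipped with a warning.
    """
    import logging

    logger = logging.getLogger("admixgwas")
    table = assoc.tested() if isinstance(assoc, AssocResult) else assoc
    p_by_id = dict(zip(table["id"], table["p"]))
    terms = {t.lower() for t in trait_terms}

    cat_rows = []
    for row in catalog.itertuples(index=False):
        try:
            pos = int(row.pos)
            p = float(row.p)
            trait = str(row.trait)
            if not (0 < p <= 1) or pos < 1:
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("skipping malformed catalog row: %r", tuple(row))
            continue
        cat_rows.append((str(row.chrom), pos, trait.lower(), p))

    out: list[GenomicLocus] = []
    for locus in loci:
        member_p = [p_by_id[m] for m in locus.members if m in p_by_id]
        if member_p and min(member_p) <= gw_threshold:
            out.append(replace(locus, tier="genome_wide"))
            continue
        supported = any(
            chrom == locus.chrom
            and locus.start <= pos <= locus.end
            and trait in terms
            and lenient_low < p < lenient_high
            for chrom, pos, trait, p in cat_rows
        )
        tier = "suggestive_catalog_supported" if supported else "suggestive_unsupported"
        out.append(replace(locus, tier=tier))
    return out


def retained_loci(loci: list[GenomicLocus]) -> list[GenomicLocus]:
    """Loci carried into functional prioritization (tiers i and ii)."""
    return [
        l
        for l in loci
        if l.tier in ("genome_wide", "suggestive_catalog_supported")
    ]


def ancestry_enrichment(
    freq_table: pd.DataFrame,
    eur_labels: list[str],
    afr_labels: list[str],
    cohort_label: str,
    rare_max: float = 0.01,
    cohort_min: float = 0.01,
) -> pd.DataFrame:
    """Flag variants rare in European panels but enriched in African ones.

    flag = (max EUR AF < ``rare_max``) and (min AFR AF > max EUR AF) and
    (cohort AF >= ``cohort_min``).  Variants with any missing frequency are
    unflagged with reason "insufficient data".
    """
    for col in [*eur_labels, *afr_labels, cohort_label]:
        if col not in freq_table.columns:
            raise KeyError(f"frequency table lacks population column {col!r}")
    eur = freq_table[list(eur_labels)].to_numpy(dtype=float)
    afr = freq_table[list(afr_labels)].to_numpy(dtype=float)
    coh = freq_table[cohort_label].to_numpy(dtype=float)

    has_data = ~(
        np.isnan(eur).any(axis=1) | np.isnan(afr).any(axis=1) | np.isnan(coh)
    )
    with np.errstate(invalid="ignore"):
        eur_max = np.nanmax(np.where(np.isnan(eur), -np.inf, eur), axis=1)
        afr_min = np.nanmin(np.where(np.isnan(afr), np.inf, afr), axis=1)
        flag = has_data & (eur_max < rare_max) & (afr_min > eur_max) & (coh >= cohort_min)

    reasons = []
    for i in range(len(freq_table)):
        if not has_data[i]:
            reasons.append("insufficient data")
        elif flag[i]:
            reasons.append("")
        else:
            why = []
            if not eur_max[i] < rare_max:
                why.append("not rare in EUR")
            if not afr_min[i] > eur_max[i]:
                why.append("AFR not above EUR")
            if not coh[i] >= cohort_min:
                why.append("cohort AF below minimum")
            reasons.append("; ".join(why))
    return pd.DataFrame(
        {"enriched": flag, "reason": reasons}, index=freq_table.index
    )
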