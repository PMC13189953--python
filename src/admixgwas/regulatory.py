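"""Enhancer overlap, promoter-capture target genes, allele-specific motifs.

Variants retained after locus cross-referencing are intersected with an
18-state chromatin segmentation of adipose nuclei.  EnhA1/EnhA2 count as
active enhancers (H3K4me1 with H3K27ac), EnhG1/EnhG2 as genic enhancers
(H3K4me1 with H3K36me3) and EnhWk as weak; the default retained set is
active-or-genic.  Target genes come from promoter-capture interactions whose
other end overlaps the variant-containing enhancer segment (the bait names
the gene promoter), collected across preadipocyte differentiation
timepoints.  Allele-specific transcription-factor binding is scored with
log2-odds PWM scans of both alleles over both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ChromatinSegment,
    GenomicInterval,
    InteractionRecord,
    PWM,
    position_in_interval,
)

__all__ = [
    "ENHANCER_CLASSES",
    "classify_enhancer_overlap",
    "assign_target_genes",
    "MotifHit",
    "pwm_log_odds",
    "pwm_score_threshold",
    "best_pwm_score",
    "score_allele_motifs",
]

#: Chromatin-state mnemonic -> enhancer class.  Everything else is "none".
ENHANCER_CLASSES: dict[str, str] = {
    "EnhA1": "active",
    "EnhA2": "active",
    "EnhG1": "genic",
    "EnhG2": "genic",
    "EnhWk": "weak",
}

#: Enhancer classes carried into functional prioritization by default.
RETAINED_ENHANCER_CLASSES = ("active", "genic")


def classify_enhancer_overlap(
    variants: pd.DataFrame,
    segments: Sequence[ChromatinSegment],
) -> pd.DataFrame:
    """Assign each variant an enhancer class from its containing segment.

    ``variants`` needs columns id/chrom/pos (1-based).  Returns a frame with
    columns enhancer_class ({active, genic, weak, none}), state and the
    containing segment's coordinates (NaN when uncovered).  Variants on
    chromosomes absent from the segmentation get class "none" with a logged
    warning.
    """
    import logging

    logger = logging.getLogger("admixgwas")
    by_chrom: dict[str, list[ChromatinSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    starts = {
        c: np.asarray([s.interval.start for s in segs])
        for c, segs in by_chrom.items()
    }

    rows = []
    for v in variants.itertuples(index=False):
        chrom, pos = str(v.chrom), int(v.pos)
        segs = by_chrom.get(chrom)
        if segs is None:
            logger.warning("variant %s: chromosome %s absent from segmentation", v.id, chrom)
            rows.append((v.id, "none", None, np.nan, np.nan))
            continue
        # segments are sorted and non-overlapping: binary search the candidate
        k = int(np.searchsorted(starts[chrom], pos, side="left")) - 1
        hit = None
        if k >= 0 and segs[k].interval.contains_position(pos):
            hit = segs[k]
        if hit is None:
            rows.append((v.id, "none", None, np.nan, np.nan))
        else:
            cls = ENHANCER_CLASSES.get(hit.state, "none")
            rows.append((v.id, cls, hit.state, hit.interval.start, hit.interval.end))
    return pd.DataFrame(
        rows, columns=["id", "enhancer_class", "state", "segment_start", "segment_end"]
    )


def assign_target_genes(
    variant_chrom: str,
    variant_pos: int,
    enhancer_segment: GenomicInterval | None,
    interactions: Iterable[InteractionRecord],
    mode: str = "segment",
    include_bait_side: bool = False,
) -> dict[str, list[str]]:
    """Map a variant to target genes via promoter-capture interactions.

    Default ``mode="segment"``: an interaction contributes its bait genes if
    its other end overlaps the variant-containing enhancer segment.
    ``mode="position"`` relaxes this to the other end containing the variant
    position itself.  With ``include_bait_side``, a variant falling inside a
    bait also yields the bait's genes when the other end carries gene
    annotation (the symmetric orientation).  Returns {gene: sorted unique
    timepoints}; the result is independent of interaction order.
    """
    if mode not in ("segment", "position"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "segment" and enhancer_segment is None:
        raise ValueError("segment mode requires the variant's enhancer segment")
    hits: dict[str, set[str]] = {}

    def add(genes: tuple[str, ...], timepoint: str | None) -> None:
        for gene in genes:
            hits.setdefault(gene, set()).add(timepoint or "")

    for rec in interactions:
        if mode == "segment":
            anchored = rec.other_end.overlaps(enhancer_segment)
        else:
            anchored = rec.other_end.chrom == variant_chrom and rec.other_end.contains_position(
                variant_pos
            )
        if anchored:
            add(rec.bait_genes, rec.timepoint)
        if include_bait_side:
            if rec.bait.chrom == variant_chrom and rec.bait.contains_position(variant_pos):
                if rec.other_genes:
                    add(rec.bait_genes, rec.timepoint)
    return {g: sorted(t for t in tps) for g, tps in sorted(hits.items())}


# --------------------------------------------------------------------------
# allele-specific motif scoring
# --------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifHit:
    """Best per-allele scores of one PWM around a variant."""

    motif_id: str
    ref_score: float
    alt_score: float
    delta: float  # alt - ref
    threshold: float
    differential: bool  # exactly one allele exceeds the threshold


def pwm_log_odds(pwm: PWM, prob_floor: float = 1e-4) -> np.ndarray:
    """Per-position log2-odds scores vs the background, (L, 4).

    Probabilities are floored at ``prob_floor`` before the log so motifs with
    structural zeros score very unfavourably instead of -inf.
    """
    mat = np.maximum(pwm.as_array(), prob_floor)
    bg = np.asarray(pwm.background, dtype=float)
    return np.log2(mat / bg)


def pwm_score_threshold(
    pwm: PWM,
    quantile: float = 1.0 - 1e-4,
    exhaustive_max_len: int = 12,
    dp_bin: float = 1e-3,
) -> float:
    """Score threshold at a background quantile of the PWM score distribution.

    For motifs up to ``exhaustive_max_len`` bp the distribution over all 4^L
    sequences (weighted by background probabilities) is enumerated exactly by
    iterated outer sums; longer motifs use a dynamic-programming convolution
    of per-position score distributions discretized to ``dp_bin`` bits.
    """
    lo = pwm_log_odds(pwm)
    bg = np.asarray(pwm.background, dtype=float)
    L = lo.shape[0]
    if L <= exhaustive_max_len:
        scores = np.zeros(1)
        probs = np.ones(1)
        for i in range(L):
            scores = (scores[:, None] + lo[i][None, :]).reshape(-1)
            probs = (probs[:, None] * bg[None, :]).reshape(-1)
        order = np.argsort(scores, kind="stable")
        cdf = np.cumsum(probs[order])
        k = int(np.searchsorted(cdf, quantile, side="left"))
        k = min(k, len(order) - 1)
        return float(scores[order][k])
    # DP on a discretized score grid
    offset = lo.min(axis=1).sum()
    span = (lo.max(axis=1) - lo.min(axis=1)).sum()
    n_bins = int(np.ceil(span / dp_bin)) + 1
    dist = np.zeros(n_bins)
    dist[0] = 1.0
    for i in range(L):
        shifted = np.zeros(n_bins)
        for b in range(4):
            k = int(round((lo[i, b] - lo[i].min()) / dp_bin))
            if k == 0:
                shifted += bg[b] * dist
            else:
                shifted[k:] += bg[b] * dist[:-k]
        dist = shifted
    cdf = np.cumsum(dist)
    k = int(np.searchsorted(cdf, quantile, side="left"))
    return float(offset + min(k, n_bins - 1) * dp_bin)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.asarray([_BASE_INDEX[b] for b in seq], dtype=int)
    except KeyError as exc:
        raise ValueError(f"ambiguous or invalid base {exc.args[0]!r} in sequence") from None


def best_pwm_score(pwm: PWM, sequence: str) -> float:
    """Best log2-odds score over all offsets of both strands of ``sequence``."""
    lo = pwm_log_odds(pwm)
    L = lo.shape[0]
    if len(sequence) < L:
        raise ValueError(f"sequence shorter ({len(sequence)}) than motif ({L})")
    best = -np.inf
    for seq in (sequence, sequence.translate(_COMPLEMENT)[::-1]):
        enc = _encode(seq)
        for off in range(len(enc) - L + 1):
            s = float(lo[np.arange(L), enc[off : off + L]].sum())
            if s > best:
                best = s
    return best


def score_allele_motifs(
    sequence_window: str,
    variant_offset: int,
    ref_allele: str,
    alt_allele: str,
    pwm_set: Sequence[PWM],
    score_threshold_quantile: float = 1.0 - 1e-4,
) -> list[MotifHit]:
    """Score each PWM against the window carrying each allele.

    ``sequence_window`` holds the reference allele at 0-based
    ``variant_offset`` and must span the variant by at least
    (max motif length - 1) on both sides.  For each PWM the best score over
    all offsets and strands is computed per allele; a differential hit is a
    motif where exactly one allele's best score exceeds the PWM's
    background-quantile threshold.  Delta is alt minus ref.
    """
    window = sequence_window.upper()
    if any(b not in _BASE_INDEX for b in window):
        raise ValueError("sequence window contains ambiguous bases")
    if not (0 <= variant_offset < len(window)):
        raise ValueError("variant offset outside window")
    if window[variant_offset] != ref_allele.upper():
        raise ValueError(
            f"window has {window[variant_offset]!r} at the variant offset, "
            f"expected ref allele {ref_allele!r}"
        )
    max_len = max(len(p) for p in pwm_set)
    if variant_offset < max_len - 1 or len(window) - variant_offset < max_len:
        raise ValueError(
            f"window too short: need the variant flanked by {max_len - 1} bases"
        )
    alt_window = window[:variant_offset] + alt_allele.upper() + window[variant_offset + 1 :]

    hits = []
    for pwm in pwm_set:
        thr = pwm_score_threshold(pwm, score_threshold_quantile)
        ref_s = best_pwm_score(pwm, window)
        alt_s = best_pwm_score(pwm, alt_window)
        hits.append(
            MotifHit(
                motif_id=pwm.motif_id,
                ref_score=ref_s,
                alt_score=alt_s,
                delta=alt_s - ref_s,
                threshold=thr,
                differential=(ref_s > thr) != (alt_s > thr),
            )
        )
    return hits
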