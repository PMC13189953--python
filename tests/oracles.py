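"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (enumeration, exact rational
arithmetic, O(n^2) scans) and shares no code with the implementations under
test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np


# -- Hardy-Weinberg: exact rational enumeration ----------------------------


def hwe_exact_fraction(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value via Fraction arithmetic.

    P(h | n, nA) = nA! na! n! / (2n)! * 2^h / (AA! h! aa!), enumerated over
    all heterozygote counts with the right parity; the p-value sums the
    probabilities <= the observed configuration's.
    """
    from math import factorial

    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0
    const = Fraction(
        factorial(nA) * factorial(na) * factorial(n), factorial(2 * n)
    )
    probs = {}
    for h in range(min(nA, na) % 2, min(nA, na) + 1, 2):
        AA = (nA - h) // 2
        aa = (na - h) // 2
        probs[h] = const * Fraction(2**h, factorial(AA) * factorial(h) * factorial(aa))
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


# -- maximum independent set (for unrelated-subset checks) -----------------


def max_independent_set_size(ids: list[str], related_pairs: set[tuple[str, str]]) -> int:
    """Exhaustive maximum subset with no related pair (n <= ~15)."""
    best = 0
    for r in range(len(ids), 0, -1):
        if r <= best:
            break
        for subset in combinations(ids, r):
            s = set(subset)
            if not any(a in s and b in s for a, b in related_pairs):
                best = r
                break
    return best


# -- risk-locus definition: naive reference --------------------------------


def define_loci_reference(
    records: list[tuple[str, str, int, float]],
    p_threshold: float = 1e-4,
    region_size: int = 100_000,
) -> list[tuple[str, int, int, str, tuple[str, ...]]]:
    """Plain-python locus definition over (id, chrom, pos, p) records.

    Returns (chrom, start, end, lead_id, member_ids) sorted by (chrom,
    start).  Same contract as the package: distance clustering (gap <=
    region_size), min-p lead (ties by position then id), window = lead +/-
    region_size/2 floored at 1, overlapping windows merged keeping the best
    lead, uncovered significant variants re-entering until all are covered.
    """
    half = region_size // 2
    out = []
    sig = [r for r in records if r[3] < p_threshold]
    for chrom in sorted({r[1] for r in sig}):
        rows = sorted((r for r in sig if r[1] == chrom), key=lambda r: r[2])
        windows: list[dict] = []  # {start, end, lead_id, lead_p, lead_pos}

        def is_covered(pos):
            return any(w["start"] <= pos <= w["end"] for w in windows)

        todo = list(rows)
        while todo:
            clusters: list[list] = []
            for r in todo:
                if clusters and r[2] - clusters[-1][-1][2] <= region_size:
                    clusters[-1].append(r)
                else:
                    clusters.append([r])
            for cl in clusters:
                lead = min(cl, key=lambda r: (r[3], r[2], r[0]))
                windows.append(
                    {
                        "start": max(1, lead[2] - half),
                        "end": lead[2] + half,
                        "lead_id": lead[0],
                        "lead_p": lead[3],
                        "lead_pos": lead[2],
                    }
                )
            # merge to fixpoint
            merged_any = True
            while merged_any:
                merged_any = False
                windows.sort(key=lambda w: w["start"])
                new: list[dict] = []
                for w in windows:
                    if new and w["start"] <= new[-1]["end"]:
                        prev = new[-1]
                        best = min(
                            [prev, w],
                            key=lambda t: (t["lead_p"], t["lead_pos"], t["lead_id"]),
                        )
                        new[-1] = {
                            "start": prev["start"],
                            "end": max(prev["end"], w["end"]),
                            "lead_id": best["lead_id"],
                            "lead_p": best["lead_p"],
                            "lead_pos": best["lead_pos"],
                        }
                        merged_any = True
                    else:
                        new.append(w)
                windows = new
            todo = [r for r in todo if not is_covered(r[2])]
        for w in windows:
            members = tuple(
                r[0] for r in rows if w["start"] <= r[2] <= w["end"]
            )
            out.append((chrom, w["start"], w["end"], w["lead_id"], members))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


# -- LD pruning / filtering: naive references ------------------------------


def ld_prune_reference(
    dosages: np.ndarray,
    positions: np.ndarray,
    window: int,
    step: int,
    r2_max: float,
) -> list[int]:
    """Greedy window pruning with per-pair loops (single chromosome)."""
    m = dosages.shape[1]
    order = np.argsort(positions, kind="stable")
    alive = {int(j): True for j in order}
    start = 0
    while True:
        stop = min(start + window, m)
        widx = [int(order[k]) for k in range(start, stop) if alive[int(order[k])]]
        for a in range(len(widx)):
            if not alive[widx[a]]:
                continue
            for b in range(a + 1, len(widx)):
                if not alive[widx[b]]:
                    continue
                x, y = dosages[:, widx[a]], dosages[:, widx[b]]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2:
                    continue
                xv, yv = x[ok], y[ok]
                if xv.std() == 0 or yv.std() == 0:
                    continue
                r = np.corrcoef(xv, yv)[0, 1]
                if r * r > r2_max:
                    alive[widx[b]] = False
        if stop >= m:
            break
        start += step
    return [int(j) for j in order if alive[int(j)]]


def ld_filter_reference(R: np.ndarray, r2_cap: float) -> list[int]:
    kept: list[int] = []
    for j in range(R.shape[0]):
        if all(R[j, k] ** 2 < r2_cap for k in kept):
            kept.append(j)
    return kept


# -- interval membership / motif scanning ----------------------------------


def classify_reference(
    chrom: str, pos: int, segments: list[tuple[str, int, int, str]]
) -> str | None:
    """O(n) scan: state of the segment containing 1-based pos, else None."""
    for c, start, end, state in segments:
        if c == chrom and start < pos <= end:
            return state
    return None


_COMP = str.maketrans("ACGT", "TGCA")


def best_score_reference(matrix: np.ndarray, background: np.ndarray, seq: str) -> float:
    """Exhaustive best log2-odds over offsets and strands, plain loops."""
    lo = np.log2(np.maximum(matrix, 1e-4) / background)
    L = lo.shape[0]
    best = -np.inf
    for s in (seq, seq.translate(_COMP)[::-1]):
        for off in range(len(s) - L + 1):
            total = 0.0
            for i in range(L):
                total += lo[i, "ACGT".index(s[off + i])]
            best = max(best, total)
    return best
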