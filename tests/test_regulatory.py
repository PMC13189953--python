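import numpy as np
import pandas as pd
import pytest

from admixgwas.io_formats import ChromatinSegment, GenomicInterval, InteractionRecord, PWM
from admixgwas.regulatory import (
    ENHANCER_CLASSES,
    assign_target_genes,
    best_pwm_score,
    classify_enhancer_overlap,
    pwm_score_threshold,
    score_allele_motifs,
)
from oracles import best_score_reference, classify_reference


def seg(chrom, start, end, state):
    return ChromatinSegment(GenomicInterval(chrom, start, end), state)


def variants_frame(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "pos"])


class TestEnhancerClassification:
    SEGMENTS = [
        seg("chr20", 48_000_000, 48_000_500, "EnhA1"),
        seg("chr20", 48_000_500, 48_001_000, "EnhWk"),
        seg("chr20", 48_002_000, 48_003_000, "EnhG2"),
        seg("chr20", 48_004_000, 48_005_000, "TssA"),
    ]

    def test_active_enhancer_containment(self):
        out = classify_enhancer_overlap(
            variants_frame([("v", "chr20", 48_000_100)]), self.SEGMENTS
        )
        assert out.loc[0, "enhancer_class"] == "active"
        assert out.loc[0, "state"] == "EnhA1"

    def test_half_open_boundary(self):
        """1-based position equal to the BED start is NOT inside the segment
        (it is the last base of whatever precedes it)."""
        out = classify_enhancer_overlap(
            variants_frame([("v", "chr20", 48_000_000)]), self.SEGMENTS
        )
        assert out.loc[0, "enhancer_class"] == "none"
        out2 = classify_enhancer_overlap(
            variants_frame([("v", "chr20", 48_000_500)]), self.SEGMENTS
        )
        assert out2.loc[0, "state"] == "EnhA1"  # end base belongs to [start,end)

    @pytest.mark.parametrize(
        "state,cls",
        [("EnhA1", "active"), ("EnhA2", "active"), ("EnhG1", "genic"),
         ("EnhG2", "genic"), ("EnhWk", "weak"), ("TssA", "none"), ("Quies", "none")],
    )
    def test_state_class_mapping(self, state, cls):
        assert ENHANCER_CLASSES.get(state, "none") == cls

    def test_absent_chromosome_warns_none(self, caplog):
        with caplog.at_level("WARNING", logger="admixgwas"):
            out = classify_enhancer_overlap(
                variants_frame([("v", "chr9", 100)]), self.SEGMENTS
            )
        assert out.loc[0, "enhancer_class"] == "none"
        assert any("absent" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 100_000, 500), size=40, replace=False))
        states = rng.choice(list(ENHANCER_CLASSES) + ["TssA", "Quies"], size=40)
        segments, raw = [], []
        for s, state in zip(starts, states):
            end = int(s + rng.integers(100, 500))
            segments.append(seg("chr1", int(s), end, str(state)))
            raw.append(("chr1", int(s), end, str(state)))
        variants = variants_frame(
            [(f"v{i}", "chr1", int(rng.integers(1, 100_500))) for i in range(200)]
        )
        out = classify_enhancer_overlap(variants, segments).set_index("id")
        for row in variants.itertuples(index=False):
            state = classify_reference(row.chrom, row.pos, raw)
            expected = ENHANCER_CLASSES.get(state, "none") if state else "none"
            assert out.loc[row.id, "enhancer_class"] == expected


class TestTargetGeneAssignment:
    ENH = GenomicInterval("chr20", 48_000_000, 48_000_500)

    def _interactions(self):
        return [
            InteractionRecord(
                bait=GenomicInterval("chr20", 47_980_000, 47_985_000),
                bait_genes=("KCNB1",),
                other_end=self.ENH,
                other_genes=(),
                read_count=12,
                score=5.3,
                timepoint=tp,
            )
            for tp in ("D0", "D8")
        ]

    def test_planted_contact_two_timepoints(self):
        out = assign_target_genes("chr20", 48_000_100, self.ENH, self._interactions())
        assert out == {"KCNB1": ["D0", "D8"]}

    def test_segment_vs_position_overlap_modes(self):
        """An interaction touching the variant but not its enhancer segment
        counts only under position-overlap mode."""
        rec = InteractionRecord(
            bait=GenomicInterval("chr20", 47_000_000, 47_005_000),
            bait_genes=("OTHER",),
            other_end=GenomicInterval("chr20", 48_000_060, 48_000_150),
            other_genes=(),
            read_count=5,
            score=2.0,
            timepoint="D2",
        )
        pos = 48_000_100
        narrow_seg = GenomicInterval("chr20", 48_000_090, 48_000_110)
        far_seg = GenomicInterval("chr20", 48_000_400, 48_000_490)
        assert assign_target_genes("chr20", pos, narrow_seg, [rec]) == {"OTHER": ["D2"]}
        assert assign_target_genes("chr20", pos, far_seg, [rec]) == {}
        assert assign_target_genes("chr20", pos, None, [rec], mode="position") == {
            "OTHER": ["D2"]
        }

    def test_unnamed_bait_assigns_nothing(self):
        rec = InteractionRecord(
            bait=GenomicInterval("chr20", 1000, 2000),
            bait_genes=(),
            other_end=self.ENH,
            other_genes=(),
            read_count=3,
            score=1.0,
        )
        assert assign_target_genes("chr20", 48_000_100, self.ENH, [rec]) == {}

    def test_row_order_independence(self):
        recs = self._interactions()
        a = assign_target_genes("chr20", 48_000_100, self.ENH, recs)
        b = assign_target_genes("chr20", 48_000_100, self.ENH, list(reversed(recs)))
        assert a == b

    def test_bait_side_orientation_opt_in(self):
        rec = InteractionRecord(
            bait=GenomicInterval("chr20", 48_000_000, 48_000_500),
            bait_genes=("BAITGENE",),
            other_end=GenomicInterval("chr20", 49_000_000, 49_000_500),
            other_genes=("ANNOT",),
            read_count=3,
            score=1.0,
            timepoint="D16",
        )
        pos = 48_000_100
        assert assign_target_genes("chr20", pos, self.ENH, [rec]) == {}
        out = assign_target_genes("chr20", pos, self.ENH, [rec], include_bait_side=True)
        assert out == {"BAITGENE": ["D16"]}


def consensus_pwm(consensus, strength=0.94):
    rest = (1 - strength) / 3
    cols = []
    for b in consensus:
        col = [rest] * 4
        col["ACGT".index(b)] = strength
        cols.append(tuple(col))
    return PWM(f"cons_{consensus}", tuple(cols))


UNIFORM6 = PWM("uniform6", tuple(((0.25, 0.25, 0.25, 0.25),) * 6))


class TestMotifScoring:
    def test_uniform_pwm_zero_delta(self):
        window = "ACGTACGTACGTACGTACGTA"
        hits = score_allele_motifs(window, 10, "G", "C", [UNIFORM6])
        assert hits[0].delta == 0.0
        assert not hits[0].differential

    def test_alt_completes_consensus(self):
        """Alt allele completing a 6-mer consensus scores above ref and both
        match an exhaustive scan oracle."""
        pwm = consensus_pwm("TGACTC")
        window = "AAAAAATGAATCAAAAAA"  # ref A breaks consensus at offset 9
        hits = score_allele_motifs(window, 9, "A", "C", [pwm])
        h = hits[0]
        assert h.alt_score > h.ref_score
        mat, bg = pwm.as_array(), np.asarray(pwm.background)
        assert h.ref_score == pytest.approx(best_score_reference(mat, bg, window))
        alt_window = window[:9] + "C" + window[10:]
        assert h.alt_score == pytest.approx(best_score_reference(mat, bg, alt_window))

    def test_swapping_alleles_negates_delta(self):
        pwm = consensus_pwm("TGACTC")
        window = "AAAAAATGAATCAAAAAA"
        fwd = score_allele_motifs(window, 9, "A", "C", [pwm])[0]
        rev = score_allele_motifs(window[:9] + "C" + window[10:], 9, "C", "A", [pwm])[0]
        assert rev.delta == pytest.approx(-fwd.delta)

    def test_reverse_complement_invariance(self):
        pwm = consensus_pwm("TGACTC")
        window = "ATCGGATGACTCAGGTTACA"
        comp = str.maketrans("ACGT", "TGCA")
        rc = window.translate(comp)[::-1]
        assert best_pwm_score(pwm, window) == pytest.approx(best_pwm_score(pwm, rc))

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            score_allele_motifs("ACGTA", 2, "G", "T", [UNIFORM6])

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            score_allele_motifs("ACGTNNACGTACGTACGT", 8, "G", "T", [UNIFORM6])

    def test_ref_mismatch_with_window_rejected(self):
        with pytest.raises(ValueError, match="ref allele"):
            score_allele_motifs("ACGTACGTACGTA", 6, "T", "A", [UNIFORM6])


class TestScoreThreshold:
    def test_exhaustive_and_dp_agree(self):
        pwm = consensus_pwm("TGACTCAG", strength=0.9)
        exact = pwm_score_threshold(pwm, 0.999, exhaustive_max_len=12)
        dp = pwm_score_threshold(pwm, 0.999, exhaustive_max_len=4, dp_bin=1e-4)
        assert dp == pytest.approx(exact, abs=0.01)

    def test_threshold_monotone_in_quantile(self):
        pwm = consensus_pwm("TGACTC")
        t50 = pwm_score_threshold(pwm, 0.5)
        t999 = pwm_score_threshold(pwm, 0.999)
        assert t999 > t50

    def test_uniform_pwm_threshold_is_zero(self):
        assert pwm_score_threshold(UNIFORM6, 0.9999) == pytest.approx(0.0)
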