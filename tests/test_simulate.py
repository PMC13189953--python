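import numpy as np
import pandas as pd
import pytest

from admixgwas.io_formats import FOUNDER, Pedigree
from admixgwas.kinship import pedigree_kinship
from admixgwas.simulate import (
    CausalSpec,
    FamilyShape,
    SimulationConfig,
    build_pedigree,
    default_pipeline_config,
    gene_drop,
    inject_missingness,
    make_variant_table,
    plant_regulatory_fixture,
    simulate_cohort,
    simulate_founder_frequencies,
    simulate_phenotype,
)


class TestConfigValidation:
    def test_bad_fst_rejected(self):
        cfg = SimulationConfig(fst_per_population={"EUR": 1.5, "AFR": 0.1, "NAT": 0.2})
        with pytest.raises(ValueError, match="FST"):
            cfg.validate()

    def test_variance_budget_enforced(self):
        cfg = SimulationConfig(h2=0.8, causal_specs=[CausalSpec(0, 0.3)])
        with pytest.raises(ValueError, match="below 1"):
            cfg.validate()

    def test_family_shape_size(self):
        assert FamilyShape(2, 2).size == 10
        assert SimulationConfig(n_families=60).n_samples == 600


class TestFounderFrequencies:
    def test_low_fst_limit_tracks_ancestral(self):
        cfg = SimulationConfig(
            n_variants=500,
            fst_per_population={"EUR": 0.001, "AFR": 0.001, "NAT": 0.001},
        )
        f = simulate_founder_frequencies(cfg, np.random.default_rng(0))
        for pop in ("EUR", "AFR", "NAT"):
            # Beta variance p(1-p)F -> sd <= 0.016 at F = 0.001
            assert np.std(f[pop] - f["ancestral"]) < 0.025
            np.testing.assert_allclose(f[pop], f["ancestral"], atol=0.12)

    def test_moment_oracle_mean_matches_ancestral(self):
        """Balding-Nichols draws are mean-centered on the ancestral frequency."""
        cfg = SimulationConfig(
            n_variants=10_000,
            fst_per_population={"EUR": 0.15, "AFR": 0.15, "NAT": 0.15},
        )
        f = simulate_founder_frequencies(cfg, np.random.default_rng(1))
        for pop in ("EUR", "AFR", "NAT"):
            # MC error on a mean of 10k beta draws is ~0.003
            assert abs(f[pop].mean() - f["ancestral"].mean()) < 0.01

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_variants=100)
        a = simulate_founder_frequencies(cfg, np.random.default_rng(9))
        b = simulate_founder_frequencies(cfg, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)


def two_parent_pedigree(n_kids=2):
    rows = [("p1", FOUNDER, FOUNDER, 1), ("p2", FOUNDER, FOUNDER, 2)]
    rows += [(f"k{i}", "p1", "p2", 1 + i % 2) for i in range(n_kids)]
    admix = pd.DataFrame(
        {"EUR": [1.0, 1.0], "AFR": [0.0, 0.0], "NAT": [0.0, 0.0]}, index=["p1", "p2"]
    )
    return Pedigree(
        pd.DataFrame(rows, columns=["individual", "father", "mother", "sex"]), admix
    )


class TestGeneDrop:
    def test_fixed_frequency_extremes(self):
        """Founder frequency 0 -> everyone dosage 0; frequency 1 -> dosage 2."""
        cfg = SimulationConfig(n_families=1, n_variants=2)
        ped = two_parent_pedigree()
        freqs = pd.DataFrame(
            {"ancestral": [0.0, 1.0], "EUR": [0.0, 1.0], "AFR": [0.0, 1.0], "NAT": [0.0, 1.0]},
            index=make_variant_table(cfg)["id"],
        )
        g = gene_drop(ped, freqs, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(g.dosages[:, 0], 0.0)
        np.testing.assert_array_equal(g.dosages[:, 1], 2.0)

    def test_mendelian_consistency(self):
        cfg = SimulationConfig(n_families=10, n_variants=200)
        rng = np.random.default_rng(1)
        ped = build_pedigree(cfg, rng)
        freqs = simulate_founder_frequencies(cfg, rng)
        g = gene_drop(ped, freqs, cfg, rng)
        dose = pd.DataFrame(g.dosages, index=g.samples)
        for row in ped.table.itertuples(index=False):
            if row.father == FOUNDER:
                continue
            child = dose.loc[row.individual].to_numpy()
            f = dose.loc[row.father].to_numpy()
            m = dose.loc[row.mother].to_numpy()
            lo = (f == 2).astype(int) + (m == 2).astype(int)
            hi = 2 - (f == 0).astype(int) - (m == 0).astype(int)
            assert np.all(child >= lo) and np.all(child <= hi)

    def test_sib_pair_dosage_correlation(self):
        """Across many variants the centered sib-sib genotype correlation is
        ~0.5.  A near-homogeneous ancestry model isolates the Mendelian
        sharing from admixture structure, and dosages are centered by the
        per-variant cohort mean so frequency variation does not inflate the
        correlation."""
        cfg = SimulationConfig(
            n_families=40,
            family_shape=FamilyShape(2, 2),
            n_variants=5000,
            n_chromosomes=5,
            fst_per_population={"EUR": 0.01, "AFR": 0.01, "NAT": 0.01},
        )
        rng = np.random.default_rng(2)
        ped = build_pedigree(cfg, rng)
        freqs = simulate_founder_frequencies(cfg, rng)
        g = gene_drop(ped, freqs, cfg, rng)
        centered = g.dosages - g.dosages.mean(axis=0)
        dose = pd.DataFrame(centered, index=g.samples)
        cors = [
            np.corrcoef(
                dose.loc[f"F{fam:03d}_C0_G0"], dose.loc[f"F{fam:03d}_C0_G1"]
            )[0, 1]
            for fam in range(cfg.n_families)
        ]
        assert abs(np.mean(cors) - 0.5) < 0.05

    def test_grm_tracks_pedigree_relationship(self):
        """Realized standardized-genotype GRM correlates with 2*Phi."""
        cfg = SimulationConfig(n_families=6, n_variants=2500, n_chromosomes=5)
        rng = np.random.default_rng(3)
        ped = build_pedigree(cfg, rng)
        freqs = simulate_founder_frequencies(cfg, rng)
        g = gene_drop(ped, freqs, cfg, rng)
        kin = pedigree_kinship(ped)
        d = g.dosages
        p = d.mean(axis=0) / 2
        ok = (p > 0.05) & (p < 0.95)
        z = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        grm = z @ z.T / ok.sum()
        iu = np.triu_indices(len(g.samples), k=1)
        r = np.corrcoef(grm[iu], kin.relationship()[iu])[0, 1]
        assert r > 0.8

    def test_ar1_blocks_induce_ld(self):
        cfg = SimulationConfig(
            n_families=30, n_variants=200, ld_block_size=10, ld_rho=0.9
        )
        rng = np.random.default_rng(4)
        ped = build_pedigree(cfg, rng)
        freqs = simulate_founder_frequencies(cfg, rng)
        g = gene_drop(ped, freqs, cfg, rng)
        d = g.dosages
        within = np.corrcoef(d[:, 0], d[:, 1])[0, 1]  # same block
        across = np.corrcoef(d[:, 0], d[:, 50])[0, 1]  # different blocks
        assert within > 0.5
        assert abs(across) < 0.25

    def test_missingness_injection_rate(self):
        cfg = SimulationConfig(n_families=10, n_variants=300)
        c = simulate_cohort(cfg)
        rate = np.isnan(c.genotypes.dosages).mean()
        assert 0.005 < rate < 0.02  # configured 1%
        assert not np.isnan(c.complete_genotypes.dosages).any()


class TestPhenotype:
    def _cohort(self, cfg, seed=0):
        rng = np.random.default_rng(seed)
        ped = build_pedigree(cfg, rng)
        freqs = simulate_founder_frequencies(cfg, rng)
        g = gene_drop(ped, freqs, cfg, rng)
        kin = pedigree_kinship(ped)
        return ped, g, kin, rng

    def test_null_model_variance(self):
        """h2 = 0, no causal variants: residual variance ~ sigma_e^2 = 1 and
        phenotypes of unrelated founders are uncorrelated."""
        cfg = SimulationConfig(n_families=80, n_variants=20, h2=0.0)
        ped, g, kin, rng = self._cohort(cfg)
        phen = simulate_phenotype(ped, g, kin, cfg, rng)
        covars = np.column_stack(
            [np.ones(len(phen)), phen["sex"], phen["age"], phen["age"] ** 2]
        )
        beta, *_ = np.linalg.lstsq(covars, phen["bmi"].to_numpy(), rcond=None)
        resid = phen["bmi"].to_numpy() - covars @ beta
        assert resid.var() == pytest.approx(1.0, rel=0.15)
        gf = phen.set_index("sample_id").loc[
            [f"F{f:03d}_GF" for f in range(cfg.n_families)], "bmi"
        ]
        gm = phen.set_index("sample_id").loc[
            [f"F{f:03d}_GM" for f in range(cfg.n_families)], "bmi"
        ]
        assert abs(np.corrcoef(gf, gm)[0, 1]) < 0.25

    def test_parent_offspring_correlation_tracks_h2(self):
        """h2 = 0.4: covariate-free parent-offspring correlation ~ h2/2."""
        cors = []
        for seed in range(15):
            cfg = SimulationConfig(
                n_families=40,
                n_variants=10,
                h2=0.4,
                covariate_effects={"sex": 0.0, "age": 0.0, "age2": 0.0},
                intercept=0.0,
            )
            ped, g, kin, rng = self._cohort(cfg, seed)
            phen = simulate_phenotype(ped, g, kin, cfg, rng).set_index("sample_id")
            parents = [f"F{f:03d}_C0" for f in range(cfg.n_families)]
            kids = [f"F{f:03d}_C0_G0" for f in range(cfg.n_families)]
            cors.append(np.corrcoef(phen.loc[parents, "bmi"], phen.loc[kids, "bmi"])[0, 1])
        assert abs(np.mean(cors) - 0.2) < 0.06

    def test_causal_variant_variance_share(self):
        cfg = SimulationConfig(
            n_families=100, n_variants=20, h2=0.0, causal_specs=[CausalSpec(5, 0.2)]
        )
        ped, g, kin, rng = self._cohort(cfg)
        phen = simulate_phenotype(ped, g, kin, cfg, rng)
        x = g.dosages[:, 5]
        r2 = np.corrcoef(x, phen["bmi"])[0, 1] ** 2
        assert r2 == pytest.approx(0.2, abs=0.08)

    def test_deterministic_given_config(self):
        cfg = SimulationConfig(n_families=5, n_variants=50, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.phenotype, b.phenotype)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)


class TestRegulatoryFixture:
    def test_planted_variant_passes_every_filter_by_construction(self):
        from admixgwas.loci import ancestry_enrichment
        from admixgwas.regulatory import (
            classify_enhancer_overlap,
            assign_target_genes,
            score_allele_motifs,
        )
        from admixgwas.io_formats import GenomicInterval

        cfg = default_pipeline_config(0)
        fx = plant_regulatory_fixture(cfg)
        variants = make_variant_table(cfg)
        planted = next(v for v, r in fx.roles.items() if r == "planted")
        meta = variants.set_index("id").loc[planted]

        enh = classify_enhancer_overlap(
            pd.DataFrame({"id": [planted], "chrom": [meta["chrom"]], "pos": [meta["pos"]]}),
            fx.segments,
        )
        assert enh.loc[0, "enhancer_class"] == "active"
        seg = GenomicInterval(
            meta["chrom"], int(enh.loc[0, "segment_start"]), int(enh.loc[0, "segment_end"])
        )
        genes = assign_target_genes(meta["chrom"], int(meta["pos"]), seg, fx.interactions)
        assert genes == {"KCNB1": ["D0", "D8"]}
        enr = ancestry_enrichment(
            fx.frequency_table, fx.eur_labels, fx.afr_labels, fx.cohort_label
        )
        assert bool(enr.loc[planted, "enriched"])
        cat = fx.catalog
        assert (
            (cat["trait"] == "body mass index")
            & (cat["chrom"] == meta["chrom"])
            & (cat["pos"].sub(meta["pos"]).abs() < 50_000)
        ).any()
        hits = score_allele_motifs(
            fx.sequence_windows[planted], fx.window_offset, meta["ref"], meta["alt"], fx.pwms
        )
        assert any(h.differential and h.delta > 0 for h in hits)

    def test_each_decoy_violates_exactly_one_criterion(self):
        from admixgwas.loci import ancestry_enrichment
        from admixgwas.regulatory import classify_enhancer_overlap, assign_target_genes
        from admixgwas.io_formats import GenomicInterval

        cfg = default_pipeline_config(0)
        fx = plant_regulatory_fixture(cfg)
        variants = make_variant_table(cfg).set_index("id")
        enr = ancestry_enrichment(
            fx.frequency_table, fx.eur_labels, fx.afr_labels, fx.cohort_label
        )
        for vid, role in fx.roles.items():
            if role == "planted":
                continue
            meta = variants.loc[vid]
            enh = classify_enhancer_overlap(
                pd.DataFrame({"id": [vid], "chrom": [meta["chrom"]], "pos": [meta["pos"]]}),
                fx.segments,
            )
            cls = enh.loc[0, "enhancer_class"]
            seg = GenomicInterval(
                meta["chrom"], int(enh.loc[0, "segment_start"]), int(enh.loc[0, "segment_end"])
            )
            genes = assign_target_genes(meta["chrom"], int(meta["pos"]), seg, fx.interactions)
            has_catalog = (
                (fx.catalog["trait"] == "body mass index")
                & (fx.catalog["chrom"] == meta["chrom"])
                & (fx.catalog["pos"].sub(meta["pos"]).abs() < 50_000)
            ).any()
            checks = {
                "enhancer": cls in ("active", "genic"),
                "hic": bool(genes),
                "catalog": bool(has_catalog),
                "enrichment": bool(enr.loc[vid, "enriched"]),
            }
            failed = [k for k, ok in checks.items() if not ok]
            expected = {
                "decoy_weak_enhancer": ["enhancer"],
                "decoy_no_hic": ["hic"],
                "decoy_no_catalog": ["catalog"],
                "decoy_eur_common": ["enrichment"],
            }[role]
            assert failed == expected, (vid, role, checks)

    def test_fixture_written_formats_round_trip(self, tmp_path):
        from admixgwas import io_formats as io

        cfg = default_pipeline_config(0)
        fx = plant_regulatory_fixture(cfg)
        io.write_segmentation(fx.segments, tmp_path / "seg.bed")
        assert io.read_segmentation(tmp_path / "seg.bed") == fx.segments
        io.write_ibed(fx.interactions, tmp_path / "x.ibed")
        back = io.read_ibed(tmp_path / "x.ibed")
        assert [(r.bait, r.other_end, r.bait_genes) for r in back] == [
            (r.bait, r.other_end, r.bait_genes) for r in fx.interactions
        ]
        io.write_pwms(fx.pwms, tmp_path / "m.pwm")
        pwms = io.read_pwms(tmp_path / "m.pwm")
        np.testing.assert_allclose(
            pwms[0].as_array(), fx.pwms[0].as_array(), atol=1e-6
        )
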