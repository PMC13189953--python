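"""Seeded synthetic admixed family cohorts with planted regulatory evidence.

The generator emulates the statistical structure the analysis assumes: a set
of multi-generation families whose founders are admixed draws from several
ancestral populations (Balding-Nichols allele frequencies around a shared
ancestral frequency, divergence controlled by per-population FST), Mendelian
gene dropping down each pedigree, an optional AR(1)-style haplotype
correlation within blocks, and a quantitative phenotype built from sex, age,
age^2, planted causal variants, a polygenic family effect g ~ N(0, h2 * 2Phi)
and residual noise.

A companion fixture generator plants one causal regulatory variant with a
complete evidence trail (active-enhancer segment, promoter-capture contact
to a named gene, catalog support, African-ancestry frequency enrichment and
an allele-sensitive binding motif) plus decoy variants that each violate
exactly one criterion, so the downstream evidence funnel is testable end to
end.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .io_formats import (
    ChromatinSegment,
    CohortGenotypes,
    FOUNDER,
    GenomicInterval,
    InteractionRecord,
    PWM,
    Pedigree,
    VARIANT_COLUMNS,
)
from .kinship import KinshipMatrix, pedigree_kinship

__all__ = [
    "FamilyShape",
    "CausalSpec",
    "SimulationConfig",
    "build_pedigree",
    "make_variant_table",
    "simulate_founder_frequencies",
    "gene_drop",
    "inject_missingness",
    "simulate_phenotype",
    "SimulatedCohort",
    "simulate_cohort",
    "RegulatoryFixture",
    "plant_regulatory_fixture",
    "default_pipeline_config",
]

DECOY_ROLES = (
    "decoy_weak_enhancer",
    "decoy_no_hic",
    "decoy_no_catalog",
    "decoy_eur_common",
)

#: Per-population frequencies forced onto role variants so the planted
#: variant is rare in Europeans, common in Africans and >= 1% in the admixed
#: cohort; the EUR-common decoy violates only the rare-in-EUR rule.
ROLE_FREQUENCIES = {
    "default": {"EUR": 0.005, "AFR": 0.08, "NAT": 0.01},
    "decoy_eur_common": {"EUR": 0.03, "AFR": 0.08, "NAT": 0.01},
}


@dataclass(frozen=True)
class FamilyShape:
    """Three-generation family: a founder couple, their children (each with a
    married-in founder spouse) and grandchildren per couple."""

    n_children: int = 2
    n_grandchildren: int = 2

    @property
    def size(self) -> int:
        return 2 + 2 * self.n_children + self.n_children * self.n_grandchildren


@dataclass(frozen=True)
class CausalSpec:
    """A planted causal variant: column index, share of phenotypic variance,
    and an optional evidence role for the regulatory fixture."""

    variant_index: int
    variance_fraction: float
    role: str | None = None


@dataclass
class SimulationConfig:
    n_families: int = 60
    family_shape: FamilyShape = field(default_factory=FamilyShape)
    n_variants: int = 2000
    populations: tuple[str, ...] = ("EUR", "AFR", "NAT")
    fst_per_population: dict[str, float] = field(
        default_factory=lambda: {"EUR": 0.16, "AFR": 0.08, "NAT": 0.25}
    )
    admixture_dirichlet: tuple[float, ...] = (6.5, 2.0, 1.5)
    h2: float = 0.3
    causal_specs: list[CausalSpec] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.5, "age": 0.02, "age2": -0.0002}
    )
    intercept: float = 26.0
    n_chromosomes: int = 10
    chrom_start: int = 1_000_000
    variant_spacing: int = 10_000
    missing_rate: float = 0.01
    ld_block_size: int = 1  # variants per AR(1)-correlated block; 1 = independent
    ld_rho: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for pop in self.populations:
            f = self.fst_per_population.get(pop)
            if f is None or not (0.0 < f < 1.0):
                raise ValueError(f"FST for population {pop!r} must be in (0,1), got {f}")
        if len(self.admixture_dirichlet) != len(self.populations):
            raise ValueError("admixture_dirichlet length must match populations")
        fracs = [c.variance_fraction for c in self.causal_specs]
        if any(f < 0 for f in fracs):
            raise ValueError("causal variance fractions must be >= 0")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must be in [0, 1)")
        if self.h2 + sum(fracs) >= 1.0:
            raise ValueError("h2 + causal variance fractions must stay below 1")
        for c in self.causal_specs:
            if not (0 <= c.variant_index < self.n_variants):
                raise ValueError(f"causal variant index {c.variant_index} out of range")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ld_block_size < 1 or not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("invalid LD block configuration")

    @property
    def n_samples(self) -> int:
        return self.n_families * self.family_shape.size


def build_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Three-generation pedigrees with Dirichlet founder admixture."""
    config.validate()
    rows = []
    admix_rows = {}
    shape = config.family_shape
    for fam in range(config.n_families):
        fid = f"F{fam:03d}"

        def founder(tag: str, sex: int) -> str:
            ind = f"{fid}_{tag}"
            rows.append((ind, FOUNDER, FOUNDER, sex))
            admix_rows[ind] = rng.dirichlet(config.admixture_dirichlet)
            return ind

        gp_f = founder("GF", 1)
        gp_m = founder("GM", 2)
        for c in range(shape.n_children):
            child_sex = 1 if c % 2 == 0 else 2
            child = f"{fid}_C{c}"
            rows.append((child, gp_f, gp_m, child_sex))
            spouse = founder(f"S{c}", 2 if child_sex == 1 else 1)
            father, mother = (child, spouse) if child_sex == 1 else (spouse, child)
            for g in range(shape.n_grandchildren):
                rows.append(
                    (f"{fid}_C{c}_G{g}", father, mother, int(rng.integers(1, 3)))
                )
    table = pd.DataFrame(rows, columns=["individual", "father", "mother", "sex"])
    admix = pd.DataFrame.from_dict(
        admix_rows, orient="index", columns=list(config.populations)
    )
    admix.index.name = "individual"
    return Pedigree(table, admix)


def make_variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Variant metadata: contiguous chromosome blocks with even spacing."""
    per_chrom = int(np.ceil(config.n_variants / config.n_chromosomes))
    rows = []
    for j in range(config.n_variants):
        c = j // per_chrom
        k = j % per_chrom
        rows.append(
            (
                f"chr{c + 1}",
                config.chrom_start + k * config.variant_spacing,
                f"var{j:05d}",
                "A",
                "G",
                np.nan,
            )
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def simulate_founder_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Balding-Nichols population frequencies around a shared ancestral one.

    For each variant, ancestral p ~ Uniform(0.05, 0.95); population k draws
    Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k), so E = p and the variance grows
    with F_k.  Variants carrying an evidence role get fixed frequencies from
    ``ROLE_FREQUENCIES`` instead, which is what makes ancestry enrichment
    testable by construction.
    """
    config.validate()
    m = config.n_variants
    p = rng.uniform(0.05, 0.95, size=m)
    cols = {"ancestral": p}
    for pop in config.populations:
        f = config.fst_per_population[pop]
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        cols[pop] = rng.beta(a, b)
    freq = pd.DataFrame(cols, index=make_variant_table(config)["id"])
    for spec in config.causal_specs:
        if spec.role is None:
            continue
        fixed = ROLE_FREQUENCIES.get(spec.role, ROLE_FREQUENCIES["default"])
        for pop in config.populations:
            if pop in fixed:
                freq.iloc[spec.variant_index, freq.columns.get_loc(pop)] = fixed[pop]
    return freq


def _block_ids(config: SimulationConfig) -> np.ndarray:
    """Block label per variant; AR(1) correlation acts within a block."""
    per_chrom = int(np.ceil(config.n_variants / config.n_chromosomes))
    j = np.arange(config.n_variants)
    chrom = j // per_chrom
    within = j % per_chrom
    return chrom * per_chrom + within // config.ld_block_size


def _ar1_uniforms(
    n_haps: int, block: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniforms with Gaussian-copula AR(1) dependence within blocks.

    The copula preserves each variant's marginal frequency exactly while
    inducing positive correlation between adjacent variants of a block.
    """
    m = len(block)
    eps = rng.standard_normal((n_haps, m))
    if rho == 0.0:
        return special.ndtr(eps)
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        if block[j] == block[j - 1]:
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        else:
            z[:, j] = eps[:, j]
    return special.ndtr(z)


def gene_drop(
    pedigree: Pedigree,
    founder_freqs: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CohortGenotypes:
    """Drop alleles down the pedigree; returns complete (no-missing) dosages.

    Founder alleles draw their population of origin from the founder's
    admixture proportions independently per variant, then the allele from
    that population's frequency (through the AR(1) copula when configured).
    Offspring inherit one allele per parent, choosing the transmitted
    parental haplotype per LD block.  Imputation quality scores are drawn
    Uniform(0.5, 1] so a strict R^2 > 0.8 filter has bite; variants carrying
    an evidence role get R^2 = 0.95 (they are meant to survive QC by
    construction).
    """
    config.validate()
    order = pedigree.topological_order()
    parents = pedigree.parents()
    pos = {ind: k for k, ind in enumerate(order)}
    m = config.n_variants
    block = _block_ids(config)
    n_blocks_labels, block_index = np.unique(block, return_inverse=True)

    pop_freq = founder_freqs[list(config.populations)].to_numpy(dtype=float)  # (m, P)
    admix = pedigree.founder_admixture
    if admix is None:
        raise ValueError("pedigree lacks founder admixture proportions")

    hap = np.zeros((len(order), 2, m), dtype=np.int8)
    founders = [ind for ind in order if parents[ind][0] == FOUNDER]
    fidx = {ind: i for i, ind in enumerate(founders)}
    n_f_haps = 2 * len(founders)
    # population of origin per founder haplotype per variant
    adx = admix.loc[founders, :].to_numpy(dtype=float)  # (F, P)
    cum = np.cumsum(adx, axis=1)
    u_pop = rng.random((n_f_haps, m))
    pop_choice = np.empty((n_f_haps, m), dtype=np.int64)
    for i in range(len(founders)):
        for h in range(2):
            pop_choice[2 * i + h] = np.searchsorted(cum[i], u_pop[2 * i + h])
    pop_choice = np.minimum(pop_choice, len(config.populations) - 1)
    freqs = pop_freq[np.arange(m)[None, :], pop_choice]  # (n_f_haps, m)
    u_allele = _ar1_uniforms(n_f_haps, block, config.ld_rho, rng)
    founder_alleles = (u_allele < freqs).astype(np.int8)

    for ind in order:
        k = pos[ind]
        f, mth = parents[ind]
        if f == FOUNDER:
            i = fidx[ind]
            hap[k, 0] = founder_alleles[2 * i]
            hap[k, 1] = founder_alleles[2 * i + 1]
        else:
            for h, parent in enumerate((f, mth)):
                pick_block = rng.integers(0, 2, size=len(n_blocks_labels))
                pick = pick_block[block_index]
                hap[k, h] = hap[pos[parent], pick, np.arange(m)]

    dosages = hap.sum(axis=1).astype(float)
    variants = make_variant_table(config)
    r2 = 1.0 - 0.5 * rng.random(m)  # (0.5, 1]
    for spec in config.causal_specs:
        if spec.role is not None:
            r2[spec.variant_index] = 0.95
    variants["imputation_r2"] = r2

    want = pedigree.individuals
    idx = np.asarray([pos[i] for i in want], dtype=int)
    return CohortGenotypes(want, variants, dosages[idx])


def inject_missingness(
    genotypes: CohortGenotypes, rate: float, rng: np.random.Generator
) -> CohortGenotypes:
    """Set dosages missing at a uniform per-entry rate (NaN-coded)."""
    d = genotypes.dosages.copy()
    if rate > 0:
        mask = rng.random(d.shape) < rate
        d[mask] = np.nan
    return CohortGenotypes(list(genotypes.samples), genotypes.variants.copy(), d)


def simulate_phenotype(
    pedigree: Pedigree,
    genotypes: CohortGenotypes,
    kinship: KinshipMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """BMI-like phenotype: covariates + planted effects + family effect + noise.

    y = intercept + b_sex sex + b_age age + b_age2 age^2 + sum_j b_j x_j
        + g + e,  g ~ N(0, h2 * 2Phi), e ~ N(0, sigma_e^2),

    with sigma_e^2 = 1 - h2 - sum of causal variance fractions, and each b_j
    scaled by the realized dosage variance so variant j explains its
    configured share of the unit random variance.  Requires complete dosages
    (inject missingness afterwards).
    """
    config.validate()
    K = kinship.subset(genotypes.samples)
    A = K.relationship()
    eigmin = np.linalg.eigvalsh(A).min()
    if eigmin < -1e-8:
        raise np.linalg.LinAlgError("kinship relationship matrix is not PSD")
    n = len(genotypes.samples)
    sex = (
        pedigree.table.set_index("individual").loc[genotypes.samples, "sex"]
        .to_numpy(dtype=float)
    )
    age = rng.uniform(18.0, 80.0, size=n)
    eff = config.covariate_effects
    y = (
        config.intercept
        + eff.get("sex", 0.0) * sex
        + eff.get("age", 0.0) * age
        + eff.get("age2", 0.0) * age**2
    )
    for spec in config.causal_specs:
        x = genotypes.dosages[:, spec.variant_index]
        if np.isnan(x).any():
            raise ValueError("phenotype simulation needs complete dosages")
        v = x.var()
        if v <= 0:
            raise ValueError(
                f"causal variant {spec.variant_index} is monomorphic in this cohort"
            )
        beta = np.sqrt(spec.variance_fraction / v)
        y = y + beta * (x - x.mean())
    sigma_e2 = 1.0 - config.h2 - sum(c.variance_fraction for c in config.causal_specs)
    if config.h2 > 0:
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        y = y + np.sqrt(config.h2) * (L @ rng.standard_normal(n))
    y = y + np.sqrt(sigma_e2) * rng.standard_normal(n)
    return pd.DataFrame(
        {"sample_id": genotypes.samples, "sex": sex.astype(int), "age": age, "bmi": y}
    )


@dataclass
class SimulatedCohort:
    """Everything one seeded simulation produces."""

    config: SimulationConfig
    pedigree: Pedigree
    kinship: KinshipMatrix
    complete_genotypes: CohortGenotypes
    genotypes: CohortGenotypes  # with missingness injected
    phenotype: pd.DataFrame
    founder_freqs: pd.DataFrame

    @property
    def cohort_allele_frequency(self) -> pd.Series:
        af = np.nanmean(self.genotypes.dosages, axis=0) / 2.0
        return pd.Series(af, index=self.genotypes.variants["id"])


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Deterministic full simulation from (config, config.seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pedigree = build_pedigree(config, rng)
    kin = pedigree_kinship(pedigree)
    freqs = simulate_founder_frequencies(config, rng)
    complete = gene_drop(pedigree, freqs, config, rng)
    phen = simulate_phenotype(pedigree, complete, kin, config, rng)
    observed = inject_missingness(complete, config.missing_rate, rng)
    return SimulatedCohort(config, pedigree, kin, complete, observed, phen, freqs)


# --------------------------------------------------------------------------
# planted regulatory evidence
# --------------------------------------------------------------------------

_TIMEPOINTS = ("D0", "D2", "D8", "D16")
PLANTED_TARGET_GENE = "KCNB1"


@dataclass
class RegulatoryFixture:
    """Matched regulatory evidence for the planted variant and its decoys."""

    segments: list[ChromatinSegment]
    interactions: list[InteractionRecord]
    catalog: pd.DataFrame
    frequency_table: pd.DataFrame
    pwms: list[PWM]
    sequence_windows: dict[str, str]
    window_offset: int  # 0-based position of the variant in every window
    roles: dict[str, str]  # variant id -> role
    target_genes: dict[str, str]  # variant id -> planted bait gene
    eur_labels: list[str] = field(default_factory=lambda: ["EUR_1KG", "EUR_gnomAD"])
    afr_labels: list[str] = field(default_factory=lambda: ["AFR_1KG", "AFR_gnomAD"])
    cohort_label: str = "cohort"


def _consensus_pwm(
    consensus: str, motif_id: str, strengths: tuple[float, ...] | None = None
) -> PWM:
    """Consensus motif with per-column information content.

    Column strengths are deliberately heterogeneous so no two single-mismatch
    sequences tie in score: the background-quantile threshold then falls
    strictly between score levels instead of exactly on one.
    """
    if strengths is None:
        strengths = (0.95, 0.92, 0.90, 0.96, 0.94, 0.91, 0.93, 0.97)[: len(consensus)]
    cols = []
    for base, s in zip(consensus, strengths):
        rest = (1.0 - s) / 3.0
        col = [rest] * 4
        col["ACGT".index(base)] = s
        cols.append(tuple(col))
    return PWM(motif_id, tuple(cols))


def plant_regulatory_fixture(
    config: SimulationConfig,
    cohort_af: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> RegulatoryFixture:
    """Build the evidence layers around the configured role variants.

    The planted variant sits inside an EnhA1 segment contacted (other end)
    by a bait named with the target gene at two differentiation timepoints,
    has an in-locus catalog record for "body mass index" at suggestive
    significance, is rare in the European frequency columns, common in the
    African ones and >= 1% in the cohort column, and its alternate allele
    completes a planted binding-motif consensus.  Each decoy violates
    exactly one of these criteria:

    * decoy_weak_enhancer: its segment is EnhWk instead of EnhA1;
    * decoy_no_hic: no interaction touches its enhancer;
    * decoy_no_catalog: its catalog record is for "height";
    * decoy_eur_common: its European frequency is 3%.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    variants = make_variant_table(config)
    role_specs = [s for s in config.causal_specs if s.role is not None]
    # configs without planted evidence still get a valid (mostly empty)
    # fixture, so the pipeline runs on purely polygenic simulations too

    segments: list[ChromatinSegment] = []
    interactions: list[InteractionRecord] = []
    catalog_rows: list[tuple] = []
    freq_rows: dict[str, dict[str, float]] = {}
    windows: dict[str, str] = {}
    roles: dict[str, str] = {}
    targets: dict[str, str] = {}

    # planted 8-mer; its single G sits at the most informative column, so the
    # ref allele (A) breaks the consensus where the mismatch penalty is largest
    motif_consensus = "ATCACTCG"
    half_motif = len(motif_consensus) - 1
    window_offset = 15  # variant position inside each window sequence
    window_len = 2 * window_offset + 1

    eur_labels = ["EUR_1KG", "EUR_gnomAD"]
    afr_labels = ["AFR_1KG", "AFR_gnomAD"]

    for spec in role_specs:
        v = variants.iloc[spec.variant_index]
        vid, chrom, pos = v["id"], v["chrom"], int(v["pos"])
        roles[vid] = spec.role
        state = "EnhWk" if spec.role == "decoy_weak_enhancer" else "EnhA1"
        enh = GenomicInterval(chrom, pos - 250, pos + 250)
        segments.append(ChromatinSegment(enh, state))
        # flanking background states (abutting, never overlapping)
        segments.append(
            ChromatinSegment(GenomicInterval(chrom, pos - 2250, pos - 250), "Quies")
        )
        segments.append(
            ChromatinSegment(GenomicInterval(chrom, pos + 250, pos + 2250), "TxWk")
        )

        if spec.role != "decoy_no_hic":
            gene = PLANTED_TARGET_GENE if spec.role == "planted" else f"GENE_{vid}"
            targets[vid] = gene
            bait = GenomicInterval(chrom, pos + 40_000, pos + 45_000)
            tps = ("D0", "D8") if spec.role == "planted" else ("D0",)
            for tp in tps:
                interactions.append(
                    InteractionRecord(
                        bait=bait,
                        bait_genes=(gene,),
                        other_end=enh,
                        other_genes=(),
                        read_count=int(rng.integers(8, 40)),
                        score=float(np.round(rng.uniform(5.0, 12.0), 2)),
                        timepoint=tp,
                    )
                )

        trait = "height" if spec.role == "decoy_no_catalog" else "body mass index"
        catalog_rows.append((f"rs_cat_{vid}", chrom, pos + 1_000, trait, 8e-6))

        fixed = ROLE_FREQUENCIES.get(spec.role, ROLE_FREQUENCIES["default"])
        eur_f = fixed["EUR"]
        afr_f = fixed["AFR"]
        if cohort_af is not None and vid in cohort_af.index:
            coh = float(cohort_af.loc[vid])
        else:
            coh = 0.02
        freq_rows[vid] = {
            "EUR_1KG": round(eur_f * 0.9, 6),
            "EUR_gnomAD": round(eur_f * 1.1, 6),
            "AFR_1KG": round(afr_f * 0.85, 6),
            "AFR_gnomAD": round(afr_f * 1.05, 6),
            "cohort": coh,
        }

        # sequence window: alt allele 'G' completes the consensus motif
        bases = np.array(list("ACGT"))
        seq = list(rng.choice(bases, size=window_len))
        g_at = motif_consensus.rindex("G")
        start = window_offset - g_at
        for k, base in enumerate(motif_consensus):
            seq[start + k] = base
        seq[window_offset] = str(v["ref"])  # ref allele breaks the consensus
        windows[vid] = "".join(seq)

    catalog = pd.DataFrame(
        catalog_rows, columns=["variant_id", "chrom", "pos", "trait", "p"]
    )
    # an irrelevant record far from every locus, exercising the vocabulary
    catalog.loc[len(catalog)] = ("rs_noise", "chr99", 5_000_000, "body mass index", 2e-6)

    freq_cols = [*eur_labels, *afr_labels, "cohort"]
    freq = pd.DataFrame.from_dict(freq_rows, orient="index", dtype=float)
    freq = freq.reindex(columns=freq_cols)
    freq.index.name = "variant_id"

    pwms = [
        _consensus_pwm(motif_consensus, "MOTIF_PLANTED_synthetic"),
        PWM("MOTIF_UNIFORM_synthetic", tuple((0.25, 0.25, 0.25, 0.25) for _ in range(8))),
    ]
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return RegulatoryFixture(
        segments=segments,
        interactions=interactions,
        catalog=catalog,
        frequency_table=freq,
        pwms=pwms,
        sequence_windows=windows,
        window_offset=window_offset,
        roles=roles,
        target_genes=targets,
        eur_labels=eur_labels,
        afr_labels=afr_labels,
    )


def default_pipeline_config(seed: int = 0) -> SimulationConfig:
    """The default end-to-end study conditions: 60 ten-member families
    (n = 600), 2,000 variants on 10 chromosomes, h2 = 0.3, one planted
    regulatory variant and four single-violation decoys, each on its own
    chromosome.  The planted variant and the catalog decoy explain 4% of
    phenotypic variance (aimed at the suggestive band between 5e-8 and
    1e-4); the remaining decoys get 5.5% so they clear the suggestive
    threshold regardless of tier."""
    per_chrom = 200
    specs = [CausalSpec(0 * per_chrom + 100, 0.04, "planted")]
    fractions = {"decoy_no_catalog": 0.04}
    for k, role in enumerate(DECOY_ROLES, start=1):
        specs.append(CausalSpec(k * per_chrom + 100, fractions.get(role, 0.055), role))
    return SimulationConfig(causal_specs=specs, seed=seed)
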