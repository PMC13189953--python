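import numpy as np
import pandas as pd
import pytest

from admixgwas.io_formats import CohortGenotypes, Pedigree, VARIANT_COLUMNS


def make_genotypes(dosages, chrom=None, pos=None, r2=None, ids=None):
    """Build a CohortGenotypes from an (n_samples, n_variants) array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "imputation_r2": r2 if r2 is not None else [np.nan] * m,
        }
    )[VARIANT_COLUMNS]
    return CohortGenotypes([f"s{i}" for i in range(n)], variants, d)


@pytest.fixture
def nuclear_family():
    """Two founder parents and two children."""
    return Pedigree(
        pd.DataFrame(
            {
                "individual": ["dad", "mom", "kid1", "kid2"],
                "father": ["0", "0", "dad", "dad"],
                "mother": ["0", "0", "mom", "mom"],
                "sex": [1, 2, 1, 2],
            }
        )
    )


@pytest.fixture
def three_generation_pedigree():
    """A 12-member, three-generation pedigree (two sibships, one inbred-free)."""
    rows = [
        ("gf", "0", "0", 1),
        ("gm", "0", "0", 2),
        ("c1", "gf", "gm", 1),
        ("c2", "gf", "gm", 2),
        ("c3", "gf", "gm", 1),
        ("s1", "0", "0", 2),
        ("s2", "0", "0", 1),
        ("g1", "c1", "s1", 1),
        ("g2", "c1", "s1", 2),
        ("g3", "s2", "c2", 1),
        ("g4", "s2", "c2", 2),
        ("g5", "s2", "c2", 1),
    ]
    return Pedigree(
        pd.DataFrame(rows, columns=["individual", "father", "mother", "sex"])
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 200-sample, 300-variant cohort reused across read-only tests."""
    from admixgwas.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_families=20, n_variants=300, seed=11)
    return simulate_cohort(cfg)
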