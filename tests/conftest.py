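import numpy as np
import pandas as pd
import pytest

from apygwas import (
    GenotypePanel,
    allele_frequencies,
    blend_grm,
    build_grm,
    center_genotypes,
    simulate_genotypes,
)


def make_panel(codes, chroms=None, positions=None):
    """Hand-build a panel from a code matrix (rows = animals)."""
    codes = np.asarray(codes, dtype=np.int8)
    n_snps = codes.shape[1]
    chroms = chroms if chroms is not None else [1] * n_snps
    positions = positions if positions is not None else [
        (i + 1) * 1000 for i in range(n_snps)
    ]
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{i + 1}" for i in range(n_snps)],
            "chrom": chroms,
            "pos_bp": positions,
        }
    )
    ids = [f"A{i + 1}" for i in range(codes.shape[0])]
    return GenotypePanel(codes=codes, animal_ids=ids, snp_map=snp_map)


def blended_grm_from_sim(n_animals, n_snps, seed, beta=0.05):
    """Simulated panel → centered genotypes → blended GRM (shared helper)."""
    panel = simulate_genotypes(
        n_animals, n_snps, n_chromosomes=3, maf_low=0.1, maf_high=0.5,
        n_families=max(n_animals // 10, 1), seed=seed,
    )
    p = allele_frequencies(panel)
    zc = center_genotypes(panel, p)
    return panel, zc, blend_grm(build_grm(zc), beta=beta)


@pytest.fixture(scope="session")
def sim_panel():
    """Medium panel with family structure, shared across read-only tests."""
    return simulate_genotypes(
        n_animals=120, n_snps=400, n_chromosomes=3, maf_low=0.1, maf_high=0.5,
        n_families=10, seed=42,
    )


@pytest.fixture(scope="session")
def sim_zc(sim_panel):
    return center_genotypes(sim_panel, allele_frequencies(sim_panel))


@pytest.fixture(scope="session")
def sim_grm_blended(sim_zc):
    return blend_grm(build_grm(sim_zc), beta=0.05)
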