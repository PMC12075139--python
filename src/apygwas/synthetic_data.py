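"""Synthetic genotype / phenotype / GEBV generator.

Emulates the statistical structure a large single-step beef-cattle
evaluation hands to a back-solving GWAS: multi-chromosome biallelic
genotypes with family relatedness, a sparse set of QTL whose effects sum to
a stated additive variance, phenotypes with a stated heritability, and
GEBVs obtained by an actual GBLUP solve so that downstream SNP-effect
back-solving sees realistic shrinkage.

Family structure is a two-generation half/full-sib design: each family has
one sire and a few dam founders drawn from the base population, and
non-founders are produced by gene-dropping (one allele from each parent per
locus). This guarantees non-trivial off-diagonal structure in the genomic
relationship matrix, which is what makes APY core selection meaningful.

All simulators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .panel import MISSING, GenotypePanel

#: Dam founders per family in the half/full-sib design (plus one sire).
DAMS_PER_FAMILY = 3


@dataclass
class TruthSet:
    """Ground truth of one simulated trait.

    ``true_bv`` is exactly ``Z @ true_effects`` for the centered genotype
    matrix of the companion panel; ``sigma_e2`` follows from ``sigma_a2``
    and the heritability.
    """

    true_effects: np.ndarray
    qtl_indices: np.ndarray
    true_bv: np.ndarray
    sigma_a2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class GebvTable:
    """Per-animal genomic estimated breeding values for one or more traits."""

    animal_ids: list[str]
    gebv: np.ndarray  # (n_animals, n_traits)
    trait_names: list[str]
    sigma_a2_per_trait: np.ndarray

    def __post_init__(self) -> None:
        self.gebv = np.atleast_2d(np.asarray(self.gebv, dtype=float))
        if self.gebv.shape[0] == 1 and len(self.animal_ids) > 1:
            self.gebv = self.gebv.T
        if self.gebv.shape[0] != len(self.animal_ids):
            raise ValueError(
                f"{len(self.animal_ids)} animal ids for {self.gebv.shape[0]} GEBV rows"
            )
        if self.gebv.shape[1] != len(self.trait_names):
            raise ValueError("trait_names length must match GEBV columns")
        self.sigma_a2_per_trait = np.asarray(self.sigma_a2_per_trait, dtype=float)

    def column(self, trait: str) -> np.ndarray:
        return self.gebv[:, self.trait_names.index(trait)]


def simulate_genotypes(
    n_animals: int,
    n_snps: int,
    n_chromosomes: int,
    maf_low: float,
    maf_high: float,
    n_families: int,
    seed: int,
    missing_rate: float = 0.0,
) -> GenotypePanel:
    """Simulate a genotype panel with family structure.

    Per-locus base allele frequencies are drawn uniformly on
    [maf_low, maf_high]. Founders are sampled binomially at those
    frequencies; non-founders are gene-dropped from two founder parents of
    their family (one allele from each parent per locus). SNPs are split as
    evenly as possible across chromosomes on a uniform 1-based position
    grid.

    Parameters
    ----------
    missing_rate
        Fraction of calls replaced by the missing sentinel, to exercise
        call-rate filtering. Default 0 (complete data).
    """
    if n_animals <= 0 or n_snps <= 0 or n_chromosomes <= 0:
        raise ValueError("n_animals, n_snps and n_chromosomes must be positive")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_snps)

    # Assign animals to families round-robin; first members are founders.
    fam = np.arange(n_animals) % n_families
    codes = np.empty((n_animals, n_snps), dtype=np.int8)
    founders_per_family = 1 + DAMS_PER_FAMILY  # sire + dams
    for f in range(n_families):
        members = np.flatnonzero(fam == f)
        n_found = min(len(members), founders_per_family)
        founders = members[:n_found]
        # founders: two independent binomial allele draws per locus
        codes[founders] = rng.binomial(2, p, size=(n_found, n_snps)).astype(np.int8)
        offspring = members[n_found:]
        if len(offspring) == 0:
            continue
        sire = founders[0]
        dams = founders[1:] if n_found > 1 else founders[:1]
        dam_choice = dams[rng.integers(0, len(dams), size=len(offspring))]
        for child, dam in zip(offspring, dam_choice):
            codes[child] = _gamete(codes[sire], rng) + _gamete(codes[dam], rng)

    if missing_rate > 0:
        miss = rng.random(codes.shape) < missing_rate
        codes[miss] = MISSING

    snp_map = _uniform_map(n_snps, n_chromosomes)
    ids = [f"A{i + 1:06d}" for i in range(n_animals)]
    return GenotypePanel(codes=codes, animal_ids=ids, snp_map=snp_map)


def _gamete(parent_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Drop one allele per locus from a parent: 0 -> 0, 2 -> 1, 1 -> coin flip."""
    out = (parent_codes > 0).astype(np.int8)
    het = parent_codes == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def _uniform_map(n_snps: int, n_chromosomes: int) -> pd.DataFrame:
    base, extra = divmod(n_snps, n_chromosomes)
    rows = []
    idx = 0
    for c in range(1, n_chromosomes + 1):
        n_on_chrom = base + (1 if c <= extra else 0)
        for k in range(n_on_chrom):
            idx += 1
            rows.append((f"snp{idx:06d}", c, (k + 1) * 10_000))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])


def simulate_truth(
    panel: GenotypePanel,
    n_qtl: int,
    sigma_a2: float,
    h2: float,
    seed: int,
) -> TruthSet:
    """Plant sparse QTL effects and scale them to the target additive variance.

    QTL positions are sampled without replacement; raw effects are standard
    normal at QTL and zero elsewhere, then rescaled so the population
    variance of the true breeding values Z·effects equals ``sigma_a2``
    exactly. ``sigma_e2`` is set from the heritability identity
    sigma_e2 = sigma_a2·(1−h2)/h2.
    """
    if not (1 <= n_qtl <= panel.n_snps):
        raise ValueError(f"n_qtl must be in [1, {panel.n_snps}], got {n_qtl}")
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must be in (0, 1)")

    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(panel.n_snps, size=n_qtl, replace=False))
    effects = np.zeros(panel.n_snps)
    effects[qtl] = rng.standard_normal(n_qtl)

    z = _centered(panel)
    bv = z @ effects
    v = bv.var()
    if v <= 0:
        raise ValueError("QTL landed only on monomorphic loci; cannot scale variance")
    scale = np.sqrt(sigma_a2 / v)
    effects *= scale
    bv *= scale
    sigma_e2 = sigma_a2 * (1.0 - h2) / h2
    return TruthSet(
        true_effects=effects,
        qtl_indices=qtl,
        true_bv=bv,
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_e2),
    )


def _centered(panel: GenotypePanel) -> np.ndarray:
    """Centered dosage matrix with mean-imputed missing calls (local helper)."""
    codes = panel.codes
    obs = codes != MISSING
    counts = obs.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("panel has an all-missing SNP column")
    p = np.where(obs, codes, 0).sum(axis=0) / (2.0 * counts)
    z = np.where(obs, codes, 2.0 * p) - 2.0 * p
    return z


def simulate_phenotypes(truth: TruthSet, seed: int, mu: float = 0.0) -> np.ndarray:
    """y_i = mu + true_bv_i + e_i with e ~ Normal(0, sigma_e2)."""
    rng = np.random.default_rng(seed)
    n = len(truth.true_bv)
    e = rng.standard_normal(n) * np.sqrt(truth.sigma_e2)
    return mu + truth.true_bv + e


def solve_gblup(
    grm,  # Grm; not annotated to avoid a circular import at type-check time
    phenotypes: np.ndarray,
    sigma_a2: float,
    sigma_e2: float,
    animal_ids: list[str] | None = None,
    trait_name: str = "trait",
) -> GebvTable:
    """BLUP of breeding values under an animal model with a single mean.

    Solves û = σ²a·G_b·(σ²a·G_b + σ²e·I)⁻¹·(y − ȳ) on the blended genomic
    relationship matrix, i.e. plain GBLUP on genotyped animals only. The
    shrinkage this induces is exactly what SNP-effect back-solving assumes.
    """
    y = np.asarray(phenotypes, dtype=float)
    g = grm.G
    n = g.shape[0]
    if y.shape != (n,):
        raise ValueError(f"phenotype length {y.shape} does not match G dimension {n}")
    if sigma_a2 <= 0 or sigma_e2 < 0:
        raise ValueError("sigma_a2 must be positive and sigma_e2 non-negative")
    yc = y - y.mean()
    lhs = sigma_a2 * g + sigma_e2 * np.eye(n)
    try:
        sol = scipy.linalg.solve(lhs, yc, assume_a="pos")
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"GBLUP system singular (sigma_a2={sigma_a2}, sigma_e2={sigma_e2}); "
            "blend G before solving"
        ) from err
    u = sigma_a2 * (g @ sol)
    ids = animal_ids if animal_ids is not None else [f"A{i + 1:06d}" for i in range(n)]
    return GebvTable(
        animal_ids=list(ids),
        gebv=u.reshape(-1, 1),
        trait_names=[trait_name],
        sigma_a2_per_trait=np.array([sigma_a2]),
    )


# ---------------------------------------------------------------------------
# Fixture writers — all round-trip through the readers in genotype_qc.


def write_genotypes_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Animals in rows, header = SNP ids, first column = animal_id. Missing -> NA."""
    df = pd.DataFrame(
        panel.codes, index=pd.Index(panel.animal_ids, name="animal_id"),
        columns=panel.snp_map["snp_id"].tolist(),
    ).astype(object)
    df[panel.codes == MISSING] = "NA"
    df.to_csv(path, sep="\t")


def write_snp_map_tsv(panel: GenotypePanel, path: str | Path) -> None:
    panel.snp_map.to_csv(path, sep="\t", index=False)


def write_gebv_tsv(table: GebvTable, path: str | Path) -> None:
    df = pd.DataFrame(
        table.gebv, index=pd.Index(table.animal_ids, name="animal_id"),
        columns=table.trait_names,
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_truth_tsv(truth: TruthSet, panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": panel.snp_map["snp_id"],
            "true_effect": truth.true_effects,
            "is_qtl": np.isin(np.arange(panel.n_snps), truth.qtl_indices).astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gebv_tsv(path: str | Path, sigma_a2_per_trait=None) -> GebvTable:
    """Read a GEBV TSV (animal_id + one column per trait, header row)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    traits = [c for c in df.columns if c != id_col]
    if not traits:
        raise ValueError(f"{path}: no trait columns found")
    s = (
        np.asarray(sigma_a2_per_trait, dtype=float)
        if sigma_a2_per_trait is not None
        else np.full(len(traits), np.nan)
    )
    return GebvTable(
        animal_ids=df[id_col].tolist(),
        gebv=df[traits].to_numpy(dtype=float),
        trait_names=traits,
        sigma_a2_per_trait=s,
    )
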