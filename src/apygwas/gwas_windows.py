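"""SNP-effect back-solving and sliding-window variance ranking.

Given GEBVs û, SNP effects are recovered as

    â = (1−β) · b · (σ²_u / σ²_a) · Zᵀ · G_APY⁻¹ · û

where β is the GRM blending weight, b a tuning parameter, σ²_u the per-SNP
variance and σ²_a the additive genetic variance. The product G_APY⁻¹·û goes
through the factored APY inverse, never a dense n × n matrix.

The additive variance attributed to SNP i is σ²_ai = â_i² · 2p_i(1−p_i).
Regions are scored by moving windows of adjacent SNPs within a chromosome
(default step 1); window variance is the sum of member σ²_ai, expressed as
a percentage of the additive genetic variance (or of the total SNP
variance), ranked descending, and the top fraction or count retained for
annotation. Window size in SNPs can be derived from effective population
size via the expected independent-chromosome-segment length 1/(4·Ne)
Morgans, with eight such segments spanning the region that captures most
QTL variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm_apy import ApyInverse, CenteredGenotypes, apy_matvec

WINDOW_COLUMNS = (
    "window_id",
    "chromosome",
    "start_bp",
    "end_bp",
    "first_snp_index",
    "n_snps",
    "variance",
    "pct_of_additive",
    "rank",
)


@dataclass(frozen=True)
class BacksolveParams:
    """Scalars of the back-solving equation.

    beta
        GRM blending weight; the (1−β) factor of the equation. Default 0.05.
    b
        Tuning parameter, default 1.
    sigma_a2
        Additive genetic variance of the trait.
    sigma_u2
        Per-SNP variance; when None it defaults to sigma_a2 / 2Σp(1−p),
        the standard relation between SNP and genetic variance.
    """

    sigma_a2: float
    sigma_u2: float | None = None
    beta: float = 0.05
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.sigma_a2 <= 0:
            raise ValueError("sigma_a2 must be positive")
        if self.sigma_u2 is not None and self.sigma_u2 <= 0:
            raise ValueError("sigma_u2 must be positive when supplied")


@dataclass
class SnpEffects:
    """Back-solved per-SNP effects and variances for one trait."""

    effects: np.ndarray
    per_snp_variance: np.ndarray
    trait_name: str
    p: np.ndarray = field(repr=False)


@dataclass
class WindowSizeSpec:
    """Window sizing derived from effective population size.

    The expected independent chromosome segment has mean length 1/(4·Ne)
    Morgans; ``n_segments`` of them (default 8) span the window. Rounded
    values mirror the precision such numbers are customarily printed at
    (5, 4, 2 decimals); full precision is retained alongside.
    """

    ne: int
    n_segments: int
    segment_length_morgans: float
    span_morgans: float
    span_mb: float
    window_snps: int

    @property
    def segment_length_rounded(self) -> float:
        return round(self.segment_length_morgans, 5)

    @property
    def span_morgans_rounded(self) -> float:
        return round(self.span_morgans, 4)

    @property
    def span_mb_rounded(self) -> float:
        return round(self.span_mb, 2)


def backsolve_snp_effects(
    zc: CenteredGenotypes,
    apy: ApyInverse,
    gebv: np.ndarray,
    params: BacksolveParams,
    trait_name: str = "trait",
) -> SnpEffects:
    """â = (1−β)·b·(σ²_u/σ²_a)·Zᵀ·(G_APY⁻¹·û), matvec through the APY factors."""
    u = np.asarray(gebv, dtype=float)
    n_animals = zc.Z.shape[0]
    if u.shape != (n_animals,):
        raise ValueError(f"GEBV length {u.shape} != n_animals {n_animals}")
    if apy.n_total != n_animals:
        raise ValueError(
            f"APY inverse built on {apy.n_total} animals, Z has {n_animals}"
        )
    sigma_u2 = params.sigma_u2 if params.sigma_u2 is not None else (
        params.sigma_a2 / zc.scale_k
    )
    coef = (1.0 - params.beta) * params.b * sigma_u2 / params.sigma_a2
    a_hat = coef * (zc.Z.T @ apy_matvec(apy, u))
    return SnpEffects(
        effects=a_hat,
        per_snp_variance=snp_variances(a_hat, zc.p),
        trait_name=trait_name,
        p=zc.p,
    )


def snp_variances(effects: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Additive variance attributed to each SNP: v_i = â_i² · 2p_i(1−p_i)."""
    a = np.asarray(effects, dtype=float)
    p = np.asarray(p, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"effects shape {a.shape} != p shape {p.shape}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return a**2 * 2.0 * p * (1.0 - p)


def window_scan(
    variances: np.ndarray,
    snp_map: pd.DataFrame,
    window_size: int,
    step: int = 1,
    denominator: str = "sigma_a2",
    sigma_a2: float | None = None,
) -> pd.DataFrame:
    """Score moving windows of adjacent SNPs within each chromosome.

    Window j on a chromosome covers ``window_size`` consecutive SNPs
    starting at offsets 0, step, 2·step, …; chromosomes with fewer SNPs
    than ``window_size`` contribute no windows. ``first_snp_index`` is the
    0-based column index of the window's first SNP in the panel.
    pct_of_additive = 100 × variance / D with D = sigma_a2 or the total SNP
    variance, per ``denominator``. Ranks are 1-based by descending
    variance; ties break by (chromosome, start_bp).
    """
    v = np.asarray(variances, dtype=float)
    if len(v) != len(snp_map):
        raise ValueError("variance vector and SNP map lengths differ")
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if denominator == "sigma_a2":
        if sigma_a2 is None or sigma_a2 <= 0:
            raise ValueError("denominator 'sigma_a2' requires a positive sigma_a2")
        denom = sigma_a2
    elif denominator == "snp_sum":
        denom = v.sum()
        if denom <= 0:
            denom = np.nan
    else:
        raise ValueError("denominator must be 'sigma_a2' or 'snp_sum'")

    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    rows = []
    offset = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = len(idx)
        if m >= window_size:
            csum = np.concatenate([[0.0], np.cumsum(v[idx])])
            for j in range(0, m - window_size + 1, step):
                rows.append(
                    (
                        chrom,
                        int(pos[idx[j]]),
                        int(pos[idx[j + window_size - 1]]),
                        int(idx[j]),
                        window_size,
                        csum[j + window_size] - csum[j],
                    )
                )
        offset += m
    if not rows:
        warnings.warn(
            f"window size {window_size} exceeds every chromosome's SNP count; "
            "empty window table",
            stacklevel=2,
        )
        return pd.DataFrame(columns=list(WINDOW_COLUMNS))

    table = pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "first_snp_index", "n_snps", "variance"],
    )
    table["pct_of_additive"] = 100.0 * table["variance"] / denom
    order = table.sort_values(
        ["variance", "chromosome", "start_bp"], ascending=[False, True, True]
    ).index.to_numpy()
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    table.insert(0, "window_id", np.arange(len(table)))
    return table[list(WINDOW_COLUMNS)]


def select_top_windows(
    table: pd.DataFrame,
    mode: str = "fraction",
    value: float = 0.01,
    overlap_policy: str = "greedy-nonoverlap",
) -> pd.DataFrame:
    """Keep the best-ranked windows by fraction or count.

    fraction mode keeps ceil(value × n_windows) windows; count mode keeps
    exactly ``value``. With ``greedy-nonoverlap`` (the default reporting
    policy, since step-1 windows overlap heavily), ranks are walked in
    order and any window sharing a SNP with an already-kept window is
    discarded, until the quota of kept windows is met or ranks run out.
    """
    n = len(table)
    if n == 0:
        return table.copy()
    if mode == "fraction":
        if not (0.0 < value <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        quota = math.ceil(value * n)
    elif mode == "count":
        quota = int(value)
        if not (1 <= quota <= n):
            raise ValueError(f"count must be in [1, {n}]")
    else:
        raise ValueError("mode must be 'fraction' or 'count'")
    if overlap_policy not in ("keep-all", "greedy-nonoverlap"):
        raise ValueError("overlap_policy must be 'keep-all' or 'greedy-nonoverlap'")

    ranked = table.sort_values("rank")
    if overlap_policy == "keep-all":
        return ranked.head(quota).reset_index(drop=True)

    kept_rows = []
    kept_spans: dict[object, list[tuple[int, int]]] = {}
    for _, row in ranked.iterrows():
        lo = int(row["first_snp_index"])
        hi = lo + int(row["n_snps"]) - 1
        spans = kept_spans.setdefault(row["chromosome"], [])
        if any(lo <= e and s <= hi for s, e in spans):
            continue
        spans.append((lo, hi))
        kept_rows.append(row)
        if len(kept_rows) >= quota:
            break
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def window_size_from_ne(
    ne: int,
    n_segments: int = 8,
    mb_per_morgan: float = 100.0,
    snps_per_mb: float = 0.0,
) -> WindowSizeSpec:
    """Derive window span (and SNP count, given density) from effective population size.

    segment_length = 1/(4·Ne) Morgans; span = n_segments × segment_length;
    span_mb = span × mb_per_morgan (default 100, i.e. 1 cM = 1 Mb);
    window_snps = round(span_mb × snps_per_mb), or 0 when no density given.
    """
    if ne < 1 or n_segments < 1:
        raise ValueError("ne and n_segments must be >= 1")
    if mb_per_morgan <= 0:
        raise ValueError("mb_per_morgan must be positive")
    if snps_per_mb < 0:
        raise ValueError("snps_per_mb must be non-negative")
    seg = 1.0 / (4.0 * ne)
    span = n_segments * seg
    span_mb = span * mb_per_morgan
    return WindowSizeSpec(
        ne=ne,
        n_segments=n_segments,
        segment_length_morgans=seg,
        span_morgans=span,
        span_mb=span_mb,
        window_snps=int(round(span_mb * snps_per_mb)) if snps_per_mb > 0 else 0,
    )
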