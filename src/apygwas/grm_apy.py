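"""Genomic relationship matrix, blending, and the APY inverse.

The GRM follows VanRaden's first method, G = ZZᵀ / 2Σp(1−p), with Z the
dosage matrix centered by twice the allele frequency. A convex blend
G_b = (1−β)·G + β·T (T = identity by default) guarantees invertibility.

The Algorithm for Proven and Young (APY) splits animals into a core set c
and noncore set n and represents the inverse as

    G_APY⁻¹ = [[G_cc⁻¹, 0], [0, 0]]
            + [[−G_cc⁻¹ G_cn], [I]] · M_nn⁻¹ · [[−G_nc G_cc⁻¹, I]]

with M_nn the diagonal matrix of noncore conditional variances
m_jj = g_jj − g_jcᵀ G_cc⁻¹ g_jc. Only the core block is inverted densely;
everything else is linear in the noncore count, which is what makes the
inverse tractable for hundreds of thousands of genotyped animals. The core
size is chosen from the singular values of Z: eigenvalues of G are the
squared singular values, and the core is the smallest k whose leading
eigenvalues explain the requested fraction (default 98%) of the variance
in G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .panel import MISSING, GenotypePanel


@dataclass
class CenteredGenotypes:
    """Dosage matrix centered by 2p, with the VanRaden scale 2Σp(1−p)."""

    Z: np.ndarray
    p: np.ndarray
    scale_k: float


@dataclass
class Grm:
    """Dense symmetric genomic relationship matrix with blending metadata."""

    G: np.ndarray
    beta: float = 0.0
    blend_target: str = "identity"
    is_blended: bool = False

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass
class ApyInverse:
    """Factored APY inverse: core block inverse, core–noncore block, M_nn diagonal.

    Supports matrix–vector products against G_APY⁻¹ without materializing
    the n × n inverse. Indices refer to the animal order of the GRM the
    factorization was built from; results of :func:`apy_matvec` are
    returned in that original order.
    """

    core_indices: np.ndarray
    noncore_indices: np.ndarray
    Gcc_inv: np.ndarray = field(repr=False)
    Gcn: np.ndarray = field(repr=False)
    Mnn_diag: np.ndarray = field(repr=False)
    n_total: int = 0

    @property
    def n_core(self) -> int:
        return len(self.core_indices)

    def save(self, npz_path: str | Path) -> None:
        np.savez(
            npz_path,
            core_indices=self.core_indices,
            noncore_indices=self.noncore_indices,
            Gcc_inv=self.Gcc_inv,
            Gcn=self.Gcn,
            Mnn_diag=self.Mnn_diag,
            n_total=np.array(self.n_total),
        )

    @classmethod
    def load(cls, npz_path: str | Path) -> "ApyInverse":
        with np.load(npz_path) as z:
            return cls(
                core_indices=z["core_indices"],
                noncore_indices=z["noncore_indices"],
                Gcc_inv=z["Gcc_inv"],
                Gcn=z["Gcn"],
                Mnn_diag=z["Mnn_diag"],
                n_total=int(z["n_total"]),
            )


def center_genotypes(panel: GenotypePanel, p: np.ndarray) -> CenteredGenotypes:
    """Z[i,j] = codes[i,j] − 2p_j; missing calls become 0 after centering."""
    p = np.asarray(p, dtype=float)
    if p.shape != (panel.n_snps,):
        raise ValueError(f"p has shape {p.shape}, expected ({panel.n_snps},)")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    codes = panel.codes
    z = np.where(codes != MISSING, codes, 2.0 * p) - 2.0 * p
    scale_k = float(2.0 * np.sum(p * (1.0 - p)))
    return CenteredGenotypes(Z=z, p=p, scale_k=scale_k)


def build_grm(zc: CenteredGenotypes) -> Grm:
    """VanRaden method-I GRM: G = Z·Zᵀ / 2Σp(1−p), symmetric, unblended."""
    if zc.scale_k <= 0:
        raise ValueError("scale 2Σp(1−p) is zero: every locus is fixed")
    g = (zc.Z @ zc.Z.T) / zc.scale_k
    g = (g + g.T) / 2.0  # kill round-off asymmetry
    return Grm(G=g)


def blend_grm(grm: Grm, beta: float = 0.05, target: np.ndarray | None = None) -> Grm:
    """G_b = (1−β)·G + β·T with T the identity unless a matrix is supplied."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must be in [0, 1]")
    n = grm.n
    if target is None:
        gb = (1.0 - beta) * grm.G + beta * np.eye(n)
        name = "identity"
    else:
        target = np.asarray(target, dtype=float)
        if target.shape != (n, n):
            raise ValueError(f"blend target shape {target.shape} != ({n}, {n})")
        gb = (1.0 - beta) * grm.G + beta * target
        name = "supplied-matrix"
    return Grm(G=gb, beta=beta, blend_target=name, is_blended=True)


def select_core_size(zc: CenteredGenotypes, variance_threshold: float = 0.98) -> int:
    """Smallest k such that the top-k squared singular values of Z reach the threshold.

    Squaring the singular values of Z gives the eigenvalues of ZZᵀ, hence of
    G up to the positive scale 2Σp(1−p), so the cumulative-variance rule on
    s² is the eigenvalue rule on G.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    s = scipy.linalg.svdvals(zc.Z)
    ev = s**2
    total = ev.sum()
    if total <= 0:
        raise ValueError("Z is all zero; no variance to explain")
    cum = np.cumsum(ev) / total
    # tiny numerical eigenvalues never force extra core animals at threshold 1.0
    return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)


def select_core_animals(n_total: int, n_core: int, seed: int) -> np.ndarray:
    """Uniform random core subset without replacement, sorted, seed-deterministic."""
    if not (1 <= n_core <= n_total):
        raise ValueError(f"n_core must be in [1, {n_total}], got {n_core}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_total, size=n_core, replace=False))


def build_apy_inverse(grm_blended: Grm, core_indices: np.ndarray) -> ApyInverse:
    """Factor the APY inverse of a blended GRM for the given core set.

    Stores the dense inverse of the core block, the core × noncore block,
    and the noncore conditional variances m_jj = g_jj − g_jcᵀ G_cc⁻¹ g_jc.
    A non-positive m_jj means the core does not span the noncore animal's
    relationships (core too small, or G not positive definite) and raises.
    """
    core = np.unique(np.asarray(core_indices, dtype=np.int64))
    n = grm_blended.n
    if core.size == 0:
        raise ValueError("core set must be non-empty")
    if core[0] < 0 or core[-1] >= n:
        raise ValueError("core indices out of range")
    noncore = np.setdiff1d(np.arange(n), core)
    g = grm_blended.G

    gcc = g[np.ix_(core, core)]
    try:
        gcc_inv = scipy.linalg.inv(gcc)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("core block of G is singular; blend G first") from err
    gcc_inv = (gcc_inv + gcc_inv.T) / 2.0

    gcn = g[np.ix_(core, noncore)]
    if noncore.size:
        # m_jj = g_jj − g_jc' Gcc⁻¹ g_jc for every noncore j, vectorized
        mnn = g[noncore, noncore] - np.sum(gcn * (gcc_inv @ gcn), axis=0)
    else:
        mnn = np.empty(0)
    tol = 1e-10 * max(g.diagonal().max(), 1.0)
    if (mnn <= tol).any():
        j = int(np.argwhere(mnn <= tol)[0, 0])
        raise np.linalg.LinAlgError(
            f"non-positive APY diagonal m_jj={mnn[j]:.3e} for noncore animal index "
            f"{noncore[j]}: core too small or G not positive definite"
        )
    return ApyInverse(
        core_indices=core,
        noncore_indices=noncore,
        Gcc_inv=gcc_inv,
        Gcn=gcn,
        Mnn_diag=mnn,
        n_total=n,
    )


def apy_matvec(apy: ApyInverse, v: np.ndarray) -> np.ndarray:
    """G_APY⁻¹ · v from the stored factors, in the original animal order.

    Cost is O(n_core² + n_core · n_noncore) per product; the full inverse is
    never formed.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (apy.n_total,):
        raise ValueError(f"vector length {v.shape} != n_total {apy.n_total}")
    vc = v[apy.core_indices]
    vn = v[apy.noncore_indices]

    w = apy.Gcc_inv @ vc
    t = (vn - apy.Gcn.T @ w) / apy.Mnn_diag if apy.Mnn_diag.size else vn
    rc = w - apy.Gcc_inv @ (apy.Gcn @ t) if apy.Mnn_diag.size else w

    out = np.empty(apy.n_total)
    out[apy.core_indices] = rc
    out[apy.noncore_indices] = t
    return out


def assemble_apy_inverse(apy: ApyInverse) -> np.ndarray:
    """Materialize the dense G_APY⁻¹ from the block formula (small instances only)."""
    n = apy.n_total
    nc = apy.n_core
    perm = np.concatenate([apy.core_indices, apy.noncore_indices])
    top = np.zeros((n, n))
    top[:nc, :nc] = apy.Gcc_inv
    nn = n - nc
    lower = np.vstack([-apy.Gcc_inv @ apy.Gcn, np.eye(nn)])
    full = top + lower @ np.diag(1.0 / apy.Mnn_diag) @ lower.T if nn else top
    out = np.empty((n, n))
    out[np.ix_(perm, perm)] = full
    return out
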