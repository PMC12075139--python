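"""Core genotype container shared by every stage of the pipeline.

A :class:`GenotypePanel` holds an animals × SNPs matrix of allele-dosage
codes (0/1/2, with ``MISSING`` for no-calls), the animal identifiers, and a
SNP map giving each marker's chromosome and base-pair position. The map is
kept sorted by (chromosome, position) and its row order always matches the
column order of the code matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the integer code matrix.
MISSING: int = -1

MAP_COLUMNS = ("snp_id", "chrom", "pos_bp")


class PanelFormatError(ValueError):
    """Raised when genotype/map inputs violate the panel invariants."""


@dataclass
class GenotypePanel:
    """Animals × SNPs dosage codes plus marker map.

    Parameters
    ----------
    codes
        Integer matrix of shape (n_animals, n_snps) with entries in
        {0, 1, 2, MISSING}.
    animal_ids
        One identifier per row of ``codes``.
    snp_map
        DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp`` (1-based),
        one row per column of ``codes``, sorted by (chrom, pos_bp).
    """

    codes: np.ndarray
    animal_ids: list[str]
    snp_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.validate()

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def validate(self) -> None:
        if self.codes.ndim != 2:
            raise PanelFormatError("genotype codes must be a 2-D matrix")
        if len(self.animal_ids) != self.codes.shape[0]:
            raise PanelFormatError(
                f"{len(self.animal_ids)} animal ids for {self.codes.shape[0]} rows"
            )
        if len(self.snp_map) != self.codes.shape[1]:
            raise PanelFormatError(
                f"SNP map has {len(self.snp_map)} rows but genotype matrix has "
                f"{self.codes.shape[1]} columns"
            )
        for col in MAP_COLUMNS:
            if col not in self.snp_map.columns:
                raise PanelFormatError(f"SNP map missing column {col!r}")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelFormatError(
                f"invalid genotype code {self.codes[i, j]} at animal row {i}, "
                f"SNP column {j} ({self.snp_map['snp_id'].iloc[j]})"
            )
        # positions strictly increase within each chromosome
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if (np.diff(pos) <= 0).any():
                k = int(np.argwhere(np.diff(pos) <= 0)[0, 0])
                raise PanelFormatError(
                    f"non-increasing positions on chromosome {chrom} near "
                    f"{grp['snp_id'].iloc[k + 1]} (pos {pos[k + 1]})"
                )

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        """Return a new panel keeping SNP columns where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            codes=self.codes[:, mask].copy(),
            animal_ids=list(self.animal_ids),
            snp_map=self.snp_map.loc[mask].reset_index(drop=True),
        )

    def sorted_by_map(self) -> "GenotypePanel":
        """Return a panel with columns ordered by (chromosome, position)."""
        order = np.lexsort(
            (self.snp_map["pos_bp"].to_numpy(), self.snp_map["chrom"].to_numpy())
        )
        if np.array_equal(order, np.arange(len(order))):
            return self
        return GenotypePanel(
            codes=self.codes[:, order].copy(),
            animal_ids=list(self.animal_ids),
            snp_map=self.snp_map.iloc[order].reset_index(drop=True),
        )
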