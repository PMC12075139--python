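"""Genotype readers and marker quality control.

Filters SNPs (never animals) by autosome membership, call rate, minor
allele frequency, and deviation from Hardy–Weinberg equilibrium measured as
the absolute difference between observed and expected heterozygote
frequencies. Each removed SNP is attributed to the FIRST filter it fails,
in the fixed order autosome → call-rate → MAF → HWE, so reports are
reproducible; the underlying rules are order-independent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelFormatError

#: Bovine autosomes; the default chromosome set treated as autosomal.
BOVINE_AUTOSOMES = frozenset(range(1, 30))

FILTER_ORDER = ("non_autosome", "call_rate", "maf", "hwe_deviation")


@dataclass(frozen=True)
class QcThresholds:
    """Marker QC thresholds.

    maf_min
        SNPs with minor allele frequency below this are removed (default 0.05).
    hwe_dev_max
        Maximum |observed − expected| heterozygote frequency (default 0.15).
    call_rate_min
        Minimum fraction of non-missing calls per SNP (default 0.90).
    autosomes
        Chromosome identifiers treated as autosomal; anything else is removed.
    """

    maf_min: float = 0.05
    hwe_dev_max: float = 0.15
    call_rate_min: float = 0.90
    autosomes: frozenset = BOVINE_AUTOSOMES

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0.0 <= self.hwe_dev_max <= 1.0):
            raise ValueError("hwe_dev_max must be in [0, 1]")
        if not (0.0 <= self.call_rate_min <= 1.0):
            raise ValueError("call_rate_min must be in [0, 1]")


@dataclass
class QcReport:
    """Audit of one qc_filter run: counts per filter plus a per-SNP fate table."""

    n_input_snps: int
    removed_by_filter: dict[str, int]
    n_retained_snps: int
    fate: pd.DataFrame = field(repr=False)  # columns: snp_id, fate

    def __post_init__(self) -> None:
        total = self.n_retained_snps + sum(self.removed_by_filter.values())
        if total != self.n_input_snps:
            raise ValueError(
                f"fate table does not partition the input: {total} != {self.n_input_snps}"
            )

    def summary_json(self) -> str:
        return json.dumps(
            {
                "n_input_snps": self.n_input_snps,
                "n_retained_snps": self.n_retained_snps,
                "removed_by_filter": self.removed_by_filter,
                "filter_order": list(FILTER_ORDER),
            }
        )

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.fate.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(self.summary_json() + "\n")


def read_genotypes(
    genotype_path: str | Path,
    map_path: str | Path,
    format_name: str = "matrix-tsv",
) -> GenotypePanel:
    """Read a genotype panel from disk.

    ``matrix-tsv``: animals in rows, first column animal_id, header = SNP ids.
    ``plink-raw``: PLINK .raw dialect — header row, six leading metadata
    columns (FID IID PAT MAT SEX PHENOTYPE), then one dosage column per SNP
    (allele suffix after the last ``_`` is stripped); IID is the animal id.

    The map TSV has columns snp_id, chrom, pos_bp (1-based). Columns are
    reordered to the (chromosome, position) sort of the map.
    """
    if format_name == "matrix-tsv":
        df = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
        ids = [str(i) for i in df.index]
        snp_ids = list(df.columns)
        codes = _codes_from_strings(df, genotype_path)
    elif format_name == "plink-raw":
        df = pd.read_csv(genotype_path, sep=r"\s+", dtype=str)
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_meta = [c for c in meta if c not in df.columns]
        if missing_meta:
            raise PanelFormatError(
                f"{genotype_path}: not PLINK-RAW, missing columns {missing_meta}"
            )
        ids = df["IID"].tolist()
        dosage = df.drop(columns=meta)
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in dosage.columns]
        codes = _codes_from_strings(dosage, genotype_path)
    else:
        raise ValueError(f"unknown format {format_name!r}; use matrix-tsv or plink-raw")

    snp_map = pd.read_csv(map_path, sep="\t")
    for col in ("snp_id", "chrom", "pos_bp"):
        if col not in snp_map.columns:
            raise PanelFormatError(f"{map_path}: map missing column {col!r}")
    snp_map["chrom"] = _coerce_chrom(snp_map["chrom"])
    if len(snp_map) != len(snp_ids):
        raise PanelFormatError(
            f"map has {len(snp_map)} rows but genotype file has {len(snp_ids)} SNP columns"
        )
    if list(snp_map["snp_id"]) != snp_ids:
        by_id = {s: k for k, s in enumerate(snp_map["snp_id"])}
        unknown = [s for s in snp_ids if s not in by_id]
        if unknown:
            raise PanelFormatError(
                f"SNP ids in genotype header not found in map: {unknown[:5]}"
            )
        order = [by_id[s] for s in snp_ids]
        snp_map = snp_map.iloc[order].reset_index(drop=True)

    panel = GenotypePanel(
        codes=codes, animal_ids=ids,
        snp_map=snp_map[["snp_id", "chrom", "pos_bp"]].reset_index(drop=True),
    )
    return panel.sorted_by_map()


def _codes_from_strings(df: pd.DataFrame, path) -> np.ndarray:
    vals = df.to_numpy(dtype=object)
    codes = np.full(vals.shape, MISSING, dtype=np.int8)
    ok = {"0": 0, "1": 1, "2": 2}
    na = {"NA", "nan", "", "NaN", "-1"}
    for (i, j), v in np.ndenumerate(vals):
        s = str(v).strip() if v is not None and v == v else "NA"
        if s in ok:
            codes[i, j] = ok[s]
        elif s not in na:
            raise PanelFormatError(
                f"{path}: invalid genotype code {s!r} at row {i}, column {df.columns[j]!r}"
            )
    return codes


def _coerce_chrom(col: pd.Series) -> pd.Series:
    """Store chromosome ids as int where possible, else string (X, MT, ...)."""

    def one(v):
        try:
            return int(v)
        except (TypeError, ValueError):
            return str(v)

    return col.map(one)


def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Counted-allele frequency p per SNP: allele copies / (2 × non-missing calls)."""
    codes = panel.codes
    obs = codes != MISSING
    counts = obs.sum(axis=0)
    if (counts == 0).any():
        j = int(np.argwhere(counts == 0)[0, 0])
        raise ValueError(
            f"SNP {panel.snp_map['snp_id'].iloc[j]} (column {j}) has no called genotypes"
        )
    return np.where(obs, codes, 0).sum(axis=0) / (2.0 * counts)


def qc_filter(
    panel: GenotypePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypePanel, QcReport]:
    """Apply marker QC; returns the retained panel and an audit report.

    Filters, in attribution order: (1) non-autosome, (2) call rate below
    ``call_rate_min``, (3) MAF = min(p, 1−p) below ``maf_min``,
    (4) |het_obs − 2p(1−p)| above ``hwe_dev_max``. Frequencies for MAF and
    HWE are computed from non-missing calls only. Retained SNP order is
    preserved.
    """
    codes = panel.codes
    n = panel.n_snps
    obs = codes != MISSING
    n_called = obs.sum(axis=0)

    chrom = panel.snp_map["chrom"]
    autosomal = chrom.isin(list(thresholds.autosomes)).to_numpy()
    call_rate = n_called / panel.n_animals

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, codes, 0).sum(axis=0) / (2.0 * np.maximum(n_called, 1))
        het_obs = np.where(obs, codes == 1, False).sum(axis=0) / np.maximum(n_called, 1)
    maf = np.minimum(p, 1.0 - p)
    hwe_dev = np.abs(het_obs - 2.0 * p * (1.0 - p))

    fails = {
        "non_autosome": ~autosomal,
        "call_rate": call_rate < thresholds.call_rate_min,
        "maf": maf < thresholds.maf_min,
        "hwe_deviation": hwe_dev > thresholds.hwe_dev_max,
    }
    # SNPs with zero calls have undefined p; they always fail call_rate first
    fails["maf"] = fails["maf"] & (n_called > 0)
    fails["hwe_deviation"] = fails["hwe_deviation"] & (n_called > 0)

    fate = np.full(n, "kept", dtype=object)
    for name in FILTER_ORDER:
        hit = fails[name] & (fate == "kept")
        fate[hit] = name

    keep = fate == "kept"
    removed = {name: int((fate == name).sum()) for name in FILTER_ORDER}
    report = QcReport(
        n_input_snps=n,
        removed_by_filter=removed,
        n_retained_snps=int(keep.sum()),
        fate=pd.DataFrame({"snp_id": panel.snp_map["snp_id"], "fate": fate}),
    )
    if not keep.any():
        warnings.warn("QC removed every SNP; output panel is empty", stacklevel=2)
    return panel.subset_snps(keep), report
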