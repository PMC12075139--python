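"""End-to-end orchestration: QC → GRM → blend → APY → back-solve → windows → genes.

A :class:`PipelineConfig` (loadable from YAML or JSON) names the inputs,
thresholds and seeds; :func:`run_pipeline` executes the stages in order,
writes per-trait TSV outputs under ``outdir`` and a manifest JSON recording
seeds, thresholds and per-stage row counts. Reruns with the same config and
inputs are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_windows, read_gene_intervals, write_annotation_tables
from .genotype_qc import QcThresholds, allele_frequencies, qc_filter, read_genotypes
from .grm_apy import (
    blend_grm,
    build_apy_inverse,
    build_grm,
    center_genotypes,
    select_core_animals,
    select_core_size,
)
from .gwas_windows import (
    BacksolveParams,
    backsolve_snp_effects,
    select_top_windows,
    window_scan,
    window_size_from_ne,
)
from .synthetic_data import read_gebv_tsv


class ConfigError(ValueError):
    """Raised when a pipeline configuration is inconsistent."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one core-sizing and one
    window-sizing option must be set."""

    genotypes: str
    snp_map: str
    gebvs: str
    outdir: str
    genes: str | None = None
    gene_format: str = "bed"
    genotype_format: str = "matrix-tsv"
    # QC
    maf_min: float = 0.05
    hwe_dev_max: float = 0.15
    call_rate_min: float = 0.90
    autosomes: list = field(default_factory=lambda: list(range(1, 30)))
    # GRM / APY
    beta: float = 0.05
    b: float = 1.0
    core_size: int | None = None
    core_variance_threshold: float | None = None
    seed: int = 0
    # windows
    window_snps: int | None = None
    ne: int | None = None
    n_segments: int = 8
    mb_per_morgan: float = 100.0
    step: int = 1
    top_mode: str = "fraction"
    top_value: float = 0.01
    overlap_policy: str = "greedy-nonoverlap"
    denominator: str = "sigma_a2"
    # traits
    traits: list = field(default_factory=list)
    sigma_a2: dict = field(default_factory=dict)  # trait -> additive variance
    sigma_u2: dict = field(default_factory=dict)  # optional per-trait SNP variance

    def validate(self) -> None:
        if (self.core_size is None) == (self.core_variance_threshold is None):
            raise ConfigError(
                "set exactly one of core_size / core_variance_threshold"
            )
        if (self.window_snps is None) == (self.ne is None):
            raise ConfigError("set exactly one of window_snps / ne")
        for path_attr in ("genotypes", "snp_map", "gebvs"):
            if not Path(getattr(self, path_attr)).exists():
                raise ConfigError(f"{path_attr} file not found: {getattr(self, path_attr)}")
        if self.genes is not None and not Path(self.genes).exists():
            raise ConfigError(f"genes file not found: {self.genes}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to outdir/manifest.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "apygwas_version": __version__,
        "seed": config.seed,
        "stages": {},
        "config": {k: v for k, v in vars(config).items()},
    }

    # --- QC -----------------------------------------------------------------
    panel = read_genotypes(config.genotypes, config.snp_map, config.genotype_format)
    thresholds = QcThresholds(
        maf_min=config.maf_min,
        hwe_dev_max=config.hwe_dev_max,
        call_rate_min=config.call_rate_min,
        autosomes=frozenset(config.autosomes),
    )
    panel_qc, report = qc_filter(panel, thresholds)
    report.write(outdir / "qc_report.tsv", outdir / "qc_summary.json")
    manifest["stages"]["qc"] = {
        "n_input_snps": report.n_input_snps,
        "n_retained_snps": report.n_retained_snps,
        "removed_by_filter": report.removed_by_filter,
        "n_animals": panel_qc.n_animals,
    }
    if panel_qc.n_snps == 0:
        raise RuntimeError("stage qc: no SNPs survived quality control")

    # --- GRM / APY ----------------------------------------------------------
    p = allele_frequencies(panel_qc)
    zc = center_genotypes(panel_qc, p)
    grm = build_grm(zc)
    grm_b = blend_grm(grm, beta=config.beta)
    if config.core_size is not None:
        n_core = int(config.core_size)
        realized = None
    else:
        n_core = select_core_size(zc, config.core_variance_threshold)
        realized = config.core_variance_threshold
    core = select_core_animals(panel_qc.n_animals, n_core, seed=config.seed)
    apy = build_apy_inverse(grm_b, core)
    manifest["stages"]["grm_apy"] = {
        "n_animals": grm_b.n,
        "beta": config.beta,
        "n_core": int(n_core),
        "core_variance_threshold": realized,
        "core_seed": config.seed,
    }

    # --- per-trait back-solve + windows + annotation --------------------------
    gebv_table = read_gebv_tsv(config.gebvs)
    order = _match_animals(gebv_table.animal_ids, panel_qc.animal_ids)
    traits = config.traits or gebv_table.trait_names
    if config.window_snps is not None:
        window_size = int(config.window_snps)
        ws_spec = None
    else:
        total_mb = _panel_span_mb(panel_qc)
        density = panel_qc.n_snps / total_mb if total_mb > 0 else 0.0
        ws_spec = window_size_from_ne(
            config.ne, config.n_segments, config.mb_per_morgan, density
        )
        window_size = max(ws_spec.window_snps, 1)
    genes = (
        read_gene_intervals(config.genes, config.gene_format)
        if config.genes is not None
        else None
    )

    trait_stats = {}
    for trait in traits:
        u = gebv_table.column(trait)[order]
        sigma_a2 = float(config.sigma_a2[trait])
        params = BacksolveParams(
            sigma_a2=sigma_a2,
            sigma_u2=config.sigma_u2.get(trait),
            beta=config.beta,
            b=config.b,
        )
        eff = backsolve_snp_effects(zc, apy, u, params, trait_name=trait)
        _write_effects(eff, panel_qc, outdir / f"snp_effects_{trait}.tsv")
        table = window_scan(
            eff.per_snp_variance,
            panel_qc.snp_map,
            window_size=window_size,
            step=config.step,
            denominator=config.denominator,
            sigma_a2=sigma_a2,
        )
        table.to_csv(outdir / f"windows_{trait}.tsv", sep="\t", index=False,
                     float_format="%.10g")
        top = select_top_windows(
            table, mode=config.top_mode, value=config.top_value,
            overlap_policy=config.overlap_policy,
        )
        top.to_csv(outdir / f"top_windows_{trait}.tsv", sep="\t", index=False,
                   float_format="%.10g")
        stats = {
            "n_windows": int(len(table)),
            "n_top_windows": int(len(top)),
            "top_pct_of_additive_sum": float(top["pct_of_additive"].sum())
            if len(top)
            else 0.0,
        }
        if genes is not None:
            ann = annotate_windows(top, genes, trait=trait)
            write_annotation_tables(
                ann,
                outdir / f"annotation_{trait}.tsv",
                outdir / f"annotation_summary_{trait}.tsv",
            )
            stats["n_annotated_windows"] = int(ann["window_id"].nunique()) if len(ann) else 0
            stats["n_candidate_genes"] = int(ann["gene_id"].nunique()) if len(ann) else 0
        trait_stats[trait] = stats
    manifest["stages"]["gwas"] = {
        "window_snps": window_size,
        "step": config.step,
        "traits": trait_stats,
    }
    if ws_spec is not None:
        manifest["stages"]["gwas"]["window_sizing"] = {
            "ne": ws_spec.ne,
            "segment_length_morgans": ws_spec.segment_length_rounded,
            "span_morgans": ws_spec.span_morgans_rounded,
            "span_mb": ws_spec.span_mb_rounded,
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _match_animals(gebv_ids: list[str], panel_ids: list[str]) -> np.ndarray:
    by_id = {a: k for k, a in enumerate(gebv_ids)}
    missing = [a for a in panel_ids if a not in by_id]
    if missing:
        raise ConfigError(
            f"{len(missing)} genotyped animals have no GEBV (first: {missing[:3]})"
        )
    return np.array([by_id[a] for a in panel_ids])


def _panel_span_mb(panel) -> float:
    spans = panel.snp_map.groupby("chrom")["pos_bp"].agg(lambda s: s.max() - s.min() + 1)
    return float(spans.sum()) / 1e6


def _write_effects(eff, panel, path: Path) -> None:
    pd.DataFrame(
        {
            "snp_id": panel.snp_map["snp_id"],
            "chrom": panel.snp_map["chrom"],
            "pos_bp": panel.snp_map["pos_bp"],
            "effect": eff.effects,
            "p": eff.p,
            "variance": eff.per_snp_variance,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
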