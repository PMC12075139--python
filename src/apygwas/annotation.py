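"""Positional gene annotation of top GWAS windows.

Maps ranked windows to candidate genes by interval overlap against a
user-supplied gene annotation (BED or GFF3). A gene is reported for a
window when their 1-based inclusive intervals intersect on the same
chromosome by at least 1 bp, so genes partially inside a window are
included; a --containment style strict mode restricts to genes fully
inside the window. Functional enrichment is out of scope — this module is
purely positional.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

GENE_COLUMNS = ("gene_id", "gene_name", "biotype", "chromosome", "start_bp", "end_bp", "strand")

ANNOTATION_COLUMNS = (
    "trait",
    "window_id",
    "chrom",
    "window_start",
    "window_end",
    "gene_id",
    "gene_name",
    "biotype",
    "overlap_bp",
)


class GeneFormatError(ValueError):
    """Raised on malformed BED/GFF3 input."""


def read_gene_intervals(path: str | Path, format_name: str) -> pd.DataFrame:
    """Read gene records into a DataFrame with 1-based inclusive coordinates.

    BED (half-open, 0-based) is converted to 1-based inclusive; GFF3 is
    already 1-based inclusive and is restricted to type ``gene`` records,
    with biotype taken from the ``gene_biotype``/``biotype`` attribute when
    present, else "unknown".
    """
    path = Path(path)
    if format_name == "bed":
        return _read_bed(path)
    if format_name == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene format {format_name!r}; use 'bed' or 'gff3'")


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GeneFormatError(f"{path}:{ln}: BED line has fewer than 3 fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise GeneFormatError(f"{path}:{ln}: non-integer BED coordinates") from err
            if end0 < start0:
                raise GeneFormatError(f"{path}:{ln}: end < start")
            name = parts[3] if len(parts) > 3 and parts[3] else f"bed_{ln}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            rows.append(
                (name, name, "unknown", _chrom(parts[0]), start0 + 1, end0, strand)
            )
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS))


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    saw_feature = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GeneFormatError(f"{path}:{ln}: GFF3 line has {len(parts)} fields, expected 9")
            saw_feature = True
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as err:
                raise GeneFormatError(f"{path}:{ln}: non-integer GFF3 coordinates") from err
            if end < start:
                raise GeneFormatError(f"{path}:{ln}: end < start")
            attrs = _gff3_attributes(parts[8])
            gene_id = attrs.get("ID", attrs.get("gene_id", f"gene_{ln}"))
            gene_id = gene_id.removeprefix("gene:")
            name = attrs.get("Name", attrs.get("gene_name", gene_id))
            biotype = attrs.get("gene_biotype", attrs.get("biotype", "unknown"))
            strand = parts[6] if parts[6] in "+-" else "."
            rows.append((gene_id, name, biotype, _chrom(parts[0]), start, end, strand))
    if not rows and saw_feature:
        warnings.warn(f"{path}: no 'gene' features found; empty gene set", stacklevel=3)
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS))


def _gff3_attributes(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def _chrom(v: str):
    v = v.removeprefix("chr")
    try:
        return int(v)
    except ValueError:
        return v


def annotate_windows(
    top: pd.DataFrame,
    genes: pd.DataFrame,
    trait: str = "trait",
    containment: bool = False,
) -> pd.DataFrame:
    """Report every (window, gene) pair whose intervals intersect.

    overlap_bp is the length of the 1-based inclusive intersection. With
    ``containment=True`` only genes fully inside a window are reported.
    Output is sorted by (trait, window rank, gene start). Raises when the
    two inputs share no chromosome name at all, which almost always means a
    naming-convention mismatch rather than a biological absence.
    """
    if len(top) == 0 or len(genes) == 0:
        return pd.DataFrame(columns=list(ANNOTATION_COLUMNS))
    win_chroms = set(top["chromosome"])
    gene_chroms = set(genes["chromosome"])
    if not win_chroms & gene_chroms:
        raise ValueError(
            f"no chromosome shared between windows ({sorted(map(str, win_chroms))[:5]}) "
            f"and genes ({sorted(map(str, gene_chroms))[:5]}); "
            "supply a chromosome rename map"
        )

    trees: dict[object, IntervalTree] = {}
    for chrom, grp in genes.groupby("chromosome", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            # +1: intervaltree is half-open, our coordinates inclusive
            (int(s), int(e) + 1, k)
            for k, (s, e) in enumerate(zip(grp["start_bp"], grp["end_bp"]))
        )
        trees[chrom]._rows = grp.reset_index(drop=True)  # type: ignore[attr-defined]

    rows = []
    for _, win in top.sort_values("rank").iterrows():
        tree = trees.get(win["chromosome"])
        if tree is None:
            continue
        ws, we = int(win["start_bp"]), int(win["end_bp"])
        hits = []
        for iv in tree.overlap(ws, we + 1):
            g = tree._rows.iloc[iv.data]  # type: ignore[attr-defined]
            gs, ge = int(g["start_bp"]), int(g["end_bp"])
            if containment and not (ws <= gs and ge <= we):
                continue
            record = (
                trait,
                int(win["window_id"]),
                win["chromosome"],
                ws,
                we,
                g["gene_id"],
                g["gene_name"],
                g["biotype"],
                min(we, ge) - max(ws, gs) + 1,
            )
            hits.append((gs, str(g["gene_id"]), record))
        hits.sort(key=lambda t: (t[0], t[1]))  # gene start, then id for determinism
        seen = set()
        for _, gid, record in hits:
            if gid in seen:  # one row per (window, gene) pair
                continue
            seen.add(gid)
            rows.append(record)
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def write_annotation_tables(
    df: pd.DataFrame, long_path: str | Path, wide_path: str | Path | None = None
) -> None:
    """Long-format TSV plus an optional per-window summary table.

    The summary mirrors the customary reporting layout: one row per window
    with chromosome, position span and the comma-joined candidate genes.
    """
    df.to_csv(long_path, sep="\t", index=False)
    if wide_path is None:
        return
    if len(df) == 0:
        pd.DataFrame(
            columns=["trait", "chrom", "start_bp", "end_bp", "candidate_genes", "n_genes"]
        ).to_csv(wide_path, sep="\t", index=False)
        return
    wide = (
        df.groupby(["trait", "window_id", "chrom", "window_start", "window_end"], sort=False)
        .agg(candidate_genes=("gene_name", lambda s: ",".join(map(str, s))),
             n_genes=("gene_id", "nunique"))
        .reset_index()
        .rename(columns={"window_start": "start_bp", "window_end": "end_bp"})
        .drop(columns=["window_id"])
    )
    wide.to_csv(wide_path, sep="\t", index=False)
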