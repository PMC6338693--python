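"""Readers and writers for the pipeline's interchange formats.

Formats and conventions:

* GWAS summary statistics — TSV with columns ``snp, chr, pos, z`` (or
  ``p`` instead of ``z``); positions 1-based.
* Gene annotation — BED (chrom, start, end, name); 0-based half-open.
* LD — one square TSV per gene (SNP ids as header and index).
* Expression — TSV, genes as rows, samples as columns.
* Marker sets — GMT (name, description, then gene ids, tab-separated).
* Burst traces — CSV with columns ``bin_index, donor_counts,
  acceptor_counts``.
* Configuration — YAML; unknown keys are rejected.

Gene-id matching across files is case-insensitive (ids are compared
uppercased).  Every writer emits a ``#`` header comment documenting the
column schema, which every reader skips.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrichment import MarkerSet
from .gene_assoc import GeneAnnotation, GwasSummary, LdBlock

__all__ = [
    "read_gwas",
    "write_gwas",
    "read_bed",
    "write_bed",
    "read_ld",
    "write_ld",
    "read_ld_dir",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_trace",
    "write_trace",
    "read_config",
    "write_config",
    "read_modules",
    "write_modules",
]


class FormatError(ValueError):
    """Malformed record; message cites file, line and violated rule."""


def _read_table(path: str | Path, sep: str, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def read_gwas(path: str | Path) -> GwasSummary:
    t = _read_table(path, "\t")
    try:
        return GwasSummary(t)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# GWAS summary statistics: snp, chr, pos (1-based), z\n")
        gwas.table.to_csv(fh, sep="\t", index=False)


def read_bed(path: str | Path) -> GeneAnnotation:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{ln}: BED record needs >= 4 fields "
                    f"(chrom, start, end, name), got {len(parts)}"
                )
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer interval") from None
            if start_i >= end_i:
                raise FormatError(
                    f"{path}:{ln}: start >= end ({start_i} >= {end_i})"
                )
            rows.append((name, chrom, start_i, end_i))
    try:
        return GeneAnnotation(
            pd.DataFrame(rows, columns=["gene", "chr", "start", "end"])
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_bed(annot: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# BED gene annotation: chrom, start (0-based), end, name\n")
        for r in annot.table.itertuples(index=False):
            fh.write(f"{r.chr}\t{r.start}\t{r.end}\t{r.gene}\n")


def read_ld(path: str | Path) -> LdBlock:
    t = _read_table(path, "\t", index_col=0)
    snps = list(t.columns)
    if list(t.index) != snps:
        raise FormatError(f"{path}: LD matrix row and column SNP ids differ")
    try:
        return LdBlock(snp_ids=snps, R=t.to_numpy(dtype=float))
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_ld(block: LdBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# square SNP x SNP Pearson correlation matrix\n")
        pd.DataFrame(block.R, index=block.snp_ids, columns=block.snp_ids).to_csv(
            fh, sep="\t"
        )


def read_ld_dir(path: str | Path) -> dict[str, LdBlock]:
    """Read ``<gene>.ld.tsv`` files from a directory into a gene->block map."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"LD directory not found: {path}")
    out = {}
    for f in sorted(path.glob("*.ld.tsv")):
        out[f.name.removesuffix(".ld.tsv")] = read_ld(f)
    if not out:
        raise FormatError(f"{path}: no *.ld.tsv files found")
    return out


def read_expression(path: str | Path) -> pd.DataFrame:
    t = _read_table(path, "\t", index_col=0)
    if t.isna().any().any():
        raise FormatError(f"{path}: expression matrix contains missing values")
    t.index.name = "gene"
    return t.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# expression matrix: genes (rows) x samples (columns)\n")
        expr.to_csv(fh, sep="\t")


def read_gmt(path: str | Path) -> list[MarkerSet]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{ln}: GMT line needs name, description and "
                    f">= 1 gene, got {len(parts)} fields"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{ln}: marker set {name!r} is empty")
            sets.append(MarkerSet(name=name, genes=frozenset(genes)))
    return sets


def write_gmt(sets: list[MarkerSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ms in sets:
            fh.write("\t".join([ms.name, "na", *sorted(ms.genes)]) + "\n")


def read_trace(path: str | Path) -> pd.DataFrame:
    t = _read_table(path, ",")
    missing = {"bin_index", "donor_counts", "acceptor_counts"} - set(t.columns)
    if missing:
        raise FormatError(f"{path}: trace missing columns {sorted(missing)}")
    if (t[["donor_counts", "acceptor_counts"]] < 0).any().any():
        raise FormatError(f"{path}: negative photon counts")
    return t


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# binned two-channel trace: bin_index, donor_counts, acceptor_counts\n")
        trace.to_csv(fh, sep=",", index=False)


def read_modules(path: str | Path) -> dict[str, str]:
    t = _read_table(path, "\t")
    missing = {"gene", "module"} - set(t.columns)
    if missing:
        raise FormatError(f"{path}: module table missing columns {sorted(missing)}")
    return dict(zip(t["gene"], t["module"]))


def write_modules(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# module assignment: gene, module ('grey' = unassigned)\n")
        pd.DataFrame(
            {"gene": list(labels), "module": list(labels.values())}
        ).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


KNOWN_CONFIG_KEYS = {
    "seed",
    "out_dir",
    "log_level",
    "gwas_sim",
    "expr_sim",
    "burst_sim",
    "gene_test",
    "modules",
    "enrichment",
    "smfret",
}


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
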