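"""Gene-based GWAS association testing.

Implements a VEGAS-style gene test: the per-gene statistic is the sum of
the top-k squared SNP z-scores within the gene window, and its null
distribution is simulated by drawing SNP z-vectors from a multivariate
normal with the gene's LD (SNP-SNP correlation) matrix.  The empirical
p-value uses the add-one convention ``(r + 1) / (n_sims + 1)`` so it is
never exactly zero.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GwasSummary",
    "GeneAnnotation",
    "LdBlock",
    "GeneAssociation",
    "assign_snps_to_genes",
    "gene_statistic",
    "gene_pvalue",
    "gene_test",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10
DEFAULT_N_SIMS = 10_000
DEFAULT_FLANK = 50_000


@dataclass
class GwasSummary:
    """GWAS summary statistics: one row per SNP (snp, chr, pos, z).

    Positions are 1-based.  If a ``p`` column is supplied instead of ``z``,
    it is converted to ``|z|`` via the standard normal quantile of ``p/2``;
    the statistic only uses squared z so the sign is immaterial.
    """

    table: pd.DataFrame
    annotation: "GeneAnnotation | None" = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = self.table
        if "z" not in t.columns and "p" in t.columns:
            p = t["p"].to_numpy(dtype=float)
            if np.any((p <= 0) | (p > 1)):
                raise ValueError("p-values must lie in (0, 1]")
            t = t.assign(z=-stats.norm.ppf(p / 2.0))
        missing = {"snp", "chr", "pos", "z"} - set(t.columns)
        if missing:
            raise ValueError(f"GWAS summary missing columns: {sorted(missing)}")
        if t["snp"].duplicated().any():
            dup = t.loc[t["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup}")
        if (t["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1 (1-based)")
        if not np.all(np.isfinite(t["z"].to_numpy(dtype=float))):
            raise ValueError("non-finite z-score in GWAS summary")
        self.table = t.reset_index(drop=True)

    def z_for(self, snp_ids: list[str]) -> np.ndarray:
        sub = self.table.set_index("snp").loc[snp_ids, "z"]
        return sub.to_numpy(dtype=float)


@dataclass
class GeneAnnotation:
    """Gene intervals (gene, chr, start, end); 0-based half-open."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"gene", "chr", "start", "end"} - set(t.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        bad = t["start"] >= t["end"]
        if bad.any():
            g = t.loc[bad, "gene"].iloc[0]
            raise ValueError(f"gene {g} has start >= end")
        if t["gene"].duplicated().any():
            dup = t.loc[t["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene id: {dup}")
        self.table = t.reset_index(drop=True)


@dataclass
class LdBlock:
    """Ordered SNP ids with their Pearson correlation matrix.

    Matrices estimated from finite reference panels can be marginally
    indefinite; eigenvalues above ``-1e-8`` are repaired by clipping to a
    small positive floor and renormalising the diagonal to 1.
    """

    snp_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("LD matrix must be square")
        if R.shape[0] != len(self.snp_ids):
            raise ValueError("LD matrix dimension does not match snp_ids")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-8:
            raise ValueError(
                f"LD matrix not positive semidefinite (min eigenvalue {w.min():.3g})"
            )
        if w.min() < 1e-10:  # repair marginal indefiniteness
            vals, vecs = np.linalg.eigh(R)
            vals = np.clip(vals, 1e-10, None)
            R = (vecs * vals) @ vecs.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        self.R = R

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.R)


@dataclass(frozen=True)
class GeneAssociation:
    """Per-gene test result."""

    gene: str
    n_snps: int
    k_used: int
    statistic: float
    pval: float
    n_sims: int

    def __post_init__(self) -> None:
        if not 0.0 < self.pval <= 1.0:
            raise ValueError("pval must lie in (0, 1]")
        if self.statistic < 0:
            raise ValueError("statistic must be >= 0")


def assign_snps_to_genes(
    gwas: GwasSummary,
    genes: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
) -> dict[str, list[str]]:
    """Map each gene to the SNPs within its flanked window.

    A SNP (1-based position) belongs to every gene whose window
    ``[start - flank + 1, end + flank]`` (the 0-based half-open interval
    widened by ``flank`` on both sides, expressed 1-based inclusive)
    contains it; SNPs in overlapping windows are assigned to all such
    genes.  Genes with no SNPs are dropped with a warning.
    """
    snp_chroms = set(gwas.table["chr"])
    gene_chroms = set(genes.table["chr"])
    if not snp_chroms & gene_chroms:
        raise ValueError(
            f"no shared chromosomes between GWAS ({sorted(snp_chroms)}) "
            f"and annotation ({sorted(gene_chroms)})"
        )
    out: dict[str, list[str]] = {}
    by_chr = {c: t.sort_values("pos") for c, t in gwas.table.groupby("chr")}
    for row in genes.table.itertuples(index=False):
        snps = by_chr.get(row.chr)
        if snps is None:
            continue
        lo = row.start - flank + 1  # first 1-based position inside the window
        hi = row.end + flank
        pos = snps["pos"].to_numpy()
        mask = (pos >= lo) & (pos <= hi)
        if not mask.any():
            logger.warning("gene %s has no SNPs in its window; excluded", row.gene)
            continue
        out[row.gene] = snps.loc[mask, "snp"].tolist()
    return out


def gene_statistic(z: np.ndarray, k: int = DEFAULT_TOP_K) -> float:
    """Sum of the ``min(k, n)`` largest squared z-scores."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty z vector")
    if k < 1:
        raise ValueError("k must be >= 1")
    z2 = z**2
    k = min(k, z2.size)
    if k == z2.size:
        return float(z2.sum())
    return float(np.partition(z2, -k)[-k:].sum())


def _gene_rng(seed: int, gene: str) -> np.random.Generator:
    # named substream per gene: identical under serial or parallel execution
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(gene.encode())])
    )


def _null_statistics(
    block: LdBlock, k: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    m = block.R.shape[0]
    L = block.cholesky()
    draws = rng.standard_normal((n_sims, m)) @ L.T
    z2 = draws**2
    kk = min(k, m)
    if kk == m:
        return z2.sum(axis=1)
    return np.partition(z2, -kk, axis=1)[:, -kk:].sum(axis=1)


def gene_pvalue(
    z: np.ndarray,
    block: LdBlock,
    gene: str = "gene",
    k: int = DEFAULT_TOP_K,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> GeneAssociation:
    """Simulated p-value for one gene's top-k statistic under its LD null.

    Null z-vectors are MVN(0, R) scored with the same statistic; the
    p-value is ``(r + 1) / (n_sims + 1)`` with r the number of null
    statistics >= the observed one.
    """
    z = np.asarray(z, dtype=float)
    if z.size != block.R.shape[0]:
        raise ValueError(
            f"z has {z.size} entries but LD block has {block.R.shape[0]} SNPs"
        )
    obs = gene_statistic(z, k)
    null = _null_statistics(block, k, n_sims, _gene_rng(seed, gene))
    r = int(np.count_nonzero(null >= obs))
    return GeneAssociation(
        gene=gene,
        n_snps=int(z.size),
        k_used=min(k, z.size),
        statistic=obs,
        pval=(r + 1) / (n_sims + 1),
        n_sims=n_sims,
    )


def gene_test(
    gwas: GwasSummary,
    genes: GeneAnnotation,
    ld: dict[str, LdBlock],
    k: int = DEFAULT_TOP_K,
    n_sims: int = DEFAULT_N_SIMS,
    flank: int = DEFAULT_FLANK,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the gene-based test for every annotated gene with SNPs and LD.

    ``ld`` maps gene id to its LD block; SNP order in the block must match
    the window's SNP order.  Returns a tidy table, one row per gene.
    """
    mapping = assign_snps_to_genes(gwas, genes, flank=flank)
    rows = []
    for gene, snp_ids in mapping.items():
        block = ld.get(gene)
        if block is None:
            logger.warning("gene %s has no LD block; excluded", gene)
            continue
        if list(block.snp_ids) != list(snp_ids):
            # allow the block to carry the same SNPs in a different order
            order = {s: i for i, s in enumerate(block.snp_ids)}
            if set(block.snp_ids) != set(snp_ids):
                raise ValueError(f"LD block for {gene} does not cover its SNPs")
            snp_ids = sorted(snp_ids, key=order.__getitem__)
        res = gene_pvalue(
            gwas.z_for(snp_ids), block, gene=gene, k=k, n_sims=n_sims, seed=seed
        )
        rows.append(
            (res.gene, res.n_snps, res.k_used, res.statistic, res.pval, res.n_sims)
        )
    return pd.DataFrame(
        rows, columns=["gene", "n_snps", "k_used", "statistic", "pval", "n_sims"]
    )
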