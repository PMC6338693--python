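"""Randomization-based GWAS enrichment of co-expression modules.

For a network G of n genes with gene-based p-values, a module m of size k
is scored by

    x = (1/k) * sum_i -log10(pval(g_i))        over the module's genes
    z = (x - Xbar) / sigma(X)

where Xbar and sigma(X) are the mean and population standard deviation of
the -log10 p-values over ALL network genes.  Significance of the observed
z is assessed against a null of 10,000 random same-size gene modules
sampled uniformly from G, with the add-one empirical p-value
``(r + 1) / (n_random + 1)``; enrichment is one-sided (large z).  Final
p-values are Bonferroni-corrected across the modules tested.  Marker-set
overlap uses the hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "MarkerSet",
    "module_score",
    "observed_z",
    "empirical_p",
    "bonferroni",
    "marker_enrichment",
    "enrich_modules",
]

DEFAULT_N_RANDOM = 10_000


@dataclass(frozen=True)
class EnrichmentResult:
    module: str
    k: int
    x: float
    network_mean: float
    network_sd: float
    z: float
    emp_p: float
    bonf_p: float
    n_random: int


@dataclass(frozen=True)
class MarkerSet:
    """Named cell-type marker gene set; ids uppercased for matching."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


def _neglog10(gene_p: dict[str, float], genes: list[str]) -> np.ndarray:
    p = np.array([gene_p[g] for g in genes], dtype=float)
    if np.any(p <= 0):
        raise ValueError(
            "p-value of 0 encountered; use an add-one empirical p upstream"
        )
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return -np.log10(p)


def module_score(gene_p: dict[str, float], members: list[str]) -> float:
    """Mean -log10 gene p-value over the module members."""
    if not members:
        raise ValueError("empty module")
    missing = [g for g in members if g not in gene_p]
    if missing:
        raise ValueError(f"module genes without p-values: {missing[:5]}")
    return float(_neglog10(gene_p, list(members)).mean())


def observed_z(
    gene_p: dict[str, float],
    members: list[str],
    network_genes: list[str],
) -> tuple[float, float, float, float]:
    """Module z-score against the whole-network score distribution.

    Returns ``(z, x, network_mean, network_sd)``; the standard deviation
    is the population SD (divisor n) over all network genes.
    """
    network_genes = list(network_genes)
    if len(network_genes) < 2:
        raise ValueError("network must contain >= 2 genes")
    member_set = set(members)
    if not member_set <= set(network_genes):
        raise ValueError("module members must be network genes")
    vals = _neglog10(gene_p, network_genes)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate network: all gene p-values identical")
    x = module_score(gene_p, list(members))
    return (x - mean) / sd, x, mean, sd


def empirical_p(
    gene_p: dict[str, float],
    members: list[str],
    network_genes: list[str],
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical p of the observed module z against random same-size modules.

    Draws ``n_random`` gene sets of size k uniformly without replacement
    (within a draw) from the network, scores each with the same z, and
    returns ``((r + 1) / (n_random + 1), z_obs)`` with r the count of null
    z >= observed z.  One-sided: large z means enrichment.
    """
    k = len(members)
    if k == 0:
        raise ValueError("empty module")
    network_genes = list(network_genes)
    n = len(network_genes)
    if k > n:
        raise ValueError("module larger than network")
    z_obs, _, mean, sd = observed_z(gene_p, members, network_genes)

    vals = _neglog10(gene_p, network_genes)
    rng = np.random.default_rng(seed)
    if k == n:
        null_means = np.full(n_random, vals.mean())
    else:
        # vectorized sampling without replacement within each draw:
        # the k smallest random keys per row index a uniform k-subset
        keys = rng.random((n_random, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_means = vals[idx].mean(axis=1)
    null_z = (null_means - mean) / sd
    r = int(np.count_nonzero(null_z >= z_obs))
    return (r + 1) / (n_random + 1), z_obs


def bonferroni(emp_p: float, n_modules: int) -> float:
    """Bonferroni correction: ``min(1, emp_p * n_modules)``."""
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    return min(1.0, emp_p * n_modules)


def marker_enrichment(
    members: list[str],
    markers: MarkerSet,
    universe: list[str],
) -> float:
    """Hypergeometric upper-tail p for module / marker-set overlap.

    Gene-id matching is case-insensitive.  The tail includes the observed
    overlap, so zero overlap gives p = 1.
    """
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty gene universe")
    mem = {g.upper() for g in members} & uni
    mark = markers.genes & uni
    overlap = len(mem & mark)
    # P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|markers|, n=|module|)
    return float(stats.hypergeom.sf(overlap - 1, len(uni), len(mark), len(mem)))


def enrich_modules(
    gene_p: dict[str, float],
    modules: dict[str, list[str]],
    network_genes: list[str] | None = None,
    marker_sets: list[MarkerSet] | None = None,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    exclude_grey: bool = False,
) -> pd.DataFrame:
    """Score every module and Bonferroni-correct across them.

    ``network_genes`` defaults to all genes with a p-value; with
    ``exclude_grey`` the background genes are dropped from G before
    scoring.  Marker p-values (one column per marker set) use the network
    genes as the universe.
    """
    if network_genes is None:
        network_genes = list(gene_p)
    if exclude_grey:
        in_module = {g for gs in modules.values() for g in gs}
        network_genes = [g for g in network_genes if g in in_module]
    names = sorted(modules)
    n_modules = len(names)
    if n_modules == 0:
        raise ValueError("no modules to test")
    rows = []
    for i, name in enumerate(names):
        members = modules[name]
        # independent named substream per module
        sub_seed = np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31)
        p_emp, z = empirical_p(
            gene_p, members, network_genes, n_random=n_random, seed=int(sub_seed)
        )
        x = module_score(gene_p, members)
        row = {
            "module": name,
            "k": len(members),
            "x": x,
            "z": z,
            "emp_p": p_emp,
            "bonf_p": bonferroni(p_emp, n_modules),
            "n_random": n_random,
        }
        if marker_sets:
            for ms in marker_sets:
                row[f"marker_p::{ms.name}"] = marker_enrichment(
                    members, ms, network_genes
                )
        rows.append(row)
    return pd.DataFrame(rows)
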