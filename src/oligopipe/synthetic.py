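"""Synthetic data generators for the two analysis arms of the pipeline.

Three generators stand in for the study data that cannot be redistributed:

* GWAS summary statistics with AR(1) linkage-disequilibrium blocks and
  planted causal genes (in place of consortium summary statistics plus a
  reference-panel LD estimate);
* modular gene expression matrices with planted co-expression blocks
  (in place of brain microarray expression);
* two-channel photon-burst time traces containing monomers, FRET-active
  oligomers of known size, and multi-bin dust artifacts (in place of
  confocal instrument traces).

Every generator is deterministic given its config seed and returns a
:class:`GroundTruth`-style record alongside the data so downstream stages
can be scored against the planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_assoc import GwasSummary, GeneAnnotation, LdBlock

__all__ = [
    "GwasSimConfig",
    "ExprSimConfig",
    "BurstSimConfig",
    "GwasGroundTruth",
    "ExprGroundTruth",
    "BurstGroundTruth",
    "simulate_ld_blocks",
    "simulate_gwas",
    "simulate_expression",
    "simulate_bursts",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class GwasSimConfig:
    """Configuration for summary-statistic simulation.

    Each simulated gene carries ``snps_per_gene`` SNPs whose z-scores are
    drawn from a multivariate normal with an AR(1) correlation matrix
    (entries ``ld_rho**|i-j|``).  Causal genes receive a mean shift of
    ``effect_size`` on every SNP (a noncentrality on the z scale); all
    other genes are null.
    """

    n_genes: int
    snps_per_gene: int = 10
    ld_rho: float = 0.5
    causal_gene_ids: frozenset[str] = field(default_factory=frozenset)
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.snps_per_gene < 1:
            raise ValueError("n_genes and snps_per_gene must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        known = set(self.gene_ids())
        unknown = set(self.causal_gene_ids) - known
        if unknown:
            raise ValueError(f"causal_gene_ids not simulated: {sorted(unknown)}")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class ExprSimConfig:
    """Configuration for modular expression simulation.

    Genes in a module share a latent per-sample profile; observed
    expression is the latent profile scaled so the expected within-module
    Pearson correlation is ``within_module_cor``, plus independent Gaussian
    noise of ``noise_sd``.  ``background_genes`` are pure noise.
    """

    module_sizes: tuple[int, ...] = (40, 40, 40)
    n_samples: int = 60
    within_module_cor: float = 0.8
    noise_sd: float = 1.0
    background_genes: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("all module sizes must be >= 2")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must lie in (0, 1)")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd < 0 or self.background_genes < 0:
            raise ValueError("noise_sd and background_genes must be >= 0")


@dataclass(frozen=True)
class BurstSimConfig:
    """Configuration for two-channel photon-burst trace simulation.

    The model is intentionally simple: Poisson background in both channels,
    donor-only monomer events, FRET-active oligomer events whose channel
    means follow the intensity equations used downstream, and bright dust
    artifacts spanning >= 2 consecutive bins.  An oligomer of size ``s``
    with efficiency ``true_E`` contributes Poisson signal with mean
    ``(s/2) * monomer_brightness * (1 - true_E)`` in the donor channel and
    ``gamma * (s/2) * monomer_brightness * true_E`` in the acceptor
    channel, so efficiency and apparent size are recovered in expectation.

    ``oligomer_mass_fraction`` is the expected fraction of all
    monomer-equivalents (free monomers count 1, an s-mer counts s) that
    sit in oligomers; the oligomer event rate is derived from it.
    """

    n_bins: int = 100_000
    bin_width_time: float = 1e-3
    background_mean: float = 2.0
    monomer_brightness: float = 100.0
    monomer_event_rate: float = 0.05
    oligomer_mass_fraction: float = 0.015
    oligomer_size_dist: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.25, 4: 0.25, 6: 0.25, 10: 0.25}
    )
    true_E: float = 0.65
    dust_rate: float = 1e-5
    gamma: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not 0.0 <= self.true_E <= 1.0:
            raise ValueError("true_E must lie in [0, 1]")
        if not 0.0 <= self.oligomer_mass_fraction < 1.0:
            raise ValueError("oligomer_mass_fraction must lie in [0, 1)")
        for name in ("background_mean", "monomer_event_rate", "dust_rate",
                     "monomer_brightness", "bin_width_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        sizes = dict(self.oligomer_size_dist)
        if not sizes:
            raise ValueError("oligomer_size_dist must be non-empty")
        if any((int(s) != s or s < 2) for s in sizes):
            raise ValueError("oligomer sizes must be integers >= 2")
        if any(w < 0 for w in sizes.values()) or sum(sizes.values()) <= 0:
            raise ValueError("oligomer size weights must be >= 0 and sum > 0")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass(frozen=True)
class GwasGroundTruth:
    """Per-gene causal flag for a simulated GWAS."""

    causal: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.causal), "causal": [int(v) for v in self.causal.values()]}
        )


@dataclass(frozen=True)
class ExprGroundTruth:
    """Per-gene true module label; background genes labelled ``grey``."""

    module: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": list(self.module), "module": list(self.module.values())})


@dataclass(frozen=True)
class BurstGroundTruth:
    """One record per planted fluorescence event.

    ``species`` is ``monomer``, ``oligomer`` or ``dust``; ``size`` is the
    true stoichiometry in monomer units (1 for monomers, 0 for dust);
    ``bin`` is the event's first bin and ``n_bins`` its bin span.
    ``isolated`` marks events whose bin span neither touches nor is
    adjacent to any other planted event, i.e. events a single-bin burst
    detector sees unconfounded.
    """

    events: pd.DataFrame  # columns: bin, n_bins, species, size, isolated

    @property
    def n_monomers(self) -> int:
        return int((self.events["species"] == "monomer").sum())

    @property
    def n_oligomers(self) -> int:
        return int((self.events["species"] == "oligomer").sum())

    @property
    def n_dust(self) -> int:
        return int((self.events["species"] == "dust").sum())

    def mass_fraction(self) -> float:
        """Planted oligomer mass fraction in percent (exact accounting)."""
        olig = self.events.loc[self.events["species"] == "oligomer", "size"].sum()
        total = olig + self.n_monomers
        if total == 0:
            raise ValueError("no monomer or oligomer events planted")
        return 100.0 * float(olig) / float(total)


# ---------------------------------------------------------------------------
# generators


def simulate_ld_blocks(config: GwasSimConfig) -> list[LdBlock]:
    """One AR(1) correlation matrix per gene, entries ``rho**|i-j|``.

    AR(1) matrices with ``|rho| < 1`` are positive definite, so every block
    admits a Cholesky factorization.
    """
    m = config.snps_per_gene
    idx = np.arange(m)
    R = config.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    blocks = []
    for g in range(config.n_genes):
        snp_ids = [f"G{g:04d}_snp{j}" for j in range(m)]
        blocks.append(LdBlock(snp_ids=snp_ids, R=R.copy()))
    return blocks


def simulate_gwas(
    config: GwasSimConfig, blocks: Sequence[LdBlock]
) -> tuple[GwasSummary, GwasGroundTruth]:
    """Draw per-gene SNP z-vectors from MVN(shift, R).

    Genes are laid out on a single synthetic chromosome, one SNP per
    kilobase, with 100 kb between consecutive genes so default flanking
    windows do not overlap.  Returns the summary table together with the
    per-gene causal flags.
    """
    if len(blocks) != config.n_genes:
        raise ValueError(
            f"expected {config.n_genes} LD blocks, got {len(blocks)}"
        )
    m = config.snps_per_gene
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xB10C]))
    genes = config.gene_ids()
    causal = {g: (g in config.causal_gene_ids) for g in genes}

    records = []
    annot = []
    gene_spacing = 100_000
    for gi, (gene, block) in enumerate(zip(genes, blocks)):
        if block.R.shape[0] != m:
            raise ValueError(
                f"LD block for {gene} has {block.R.shape[0]} SNPs, expected {m}"
            )
        L = np.linalg.cholesky(block.R)
        z = L @ rng.standard_normal(m)
        if causal[gene]:
            z = z + config.effect_size
        start = 1 + gi * gene_spacing
        for j in range(m):
            records.append((block.snp_ids[j], "chr1", start + j * 1000, z[j]))
        annot.append((gene, "chr1", start - 1, start + (m - 1) * 1000 + 1))

    summary = GwasSummary(
        pd.DataFrame(records, columns=["snp", "chr", "pos", "z"])
    )
    summary.annotation = GeneAnnotation(
        pd.DataFrame(annot, columns=["gene", "chr", "start", "end"])
    )
    return summary, GwasGroundTruth(causal=causal)


def simulate_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, ExprGroundTruth]:
    """Latent-factor expression matrix with planted modules.

    Each module m has a latent sample profile ``f_m ~ N(0, 1)``; member
    genes are ``a * f_m + noise_sd * eps`` with ``a`` chosen so the
    expected within-module Pearson correlation equals ``within_module_cor``
    (``cor = a^2 / (a^2 + noise_sd^2)``).  Background genes are pure noise.
    Returns a genes x samples DataFrame and the true labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xE0A]))
    n = config.n_samples
    r = config.within_module_cor
    # a^2/(a^2 + sd^2) = r  =>  a = sd * sqrt(r / (1 - r))
    a = config.noise_sd * np.sqrt(r / (1.0 - r)) if config.noise_sd > 0 else 1.0

    rows, ids, labels = [], [], {}
    for mi, size in enumerate(config.module_sizes):
        label = f"M{mi + 1}"
        latent = rng.standard_normal(n)
        block = a * latent[None, :] + config.noise_sd * rng.standard_normal((size, n))
        rows.append(block)
        for j in range(size):
            gid = f"{label}_g{j:03d}"
            ids.append(gid)
            labels[gid] = label
    if config.background_genes:
        sd = config.noise_sd if config.noise_sd > 0 else 1.0
        block = sd * rng.standard_normal((config.background_genes, n))
        rows.append(block)
        for j in range(config.background_genes):
            gid = f"BG_g{j:03d}"
            ids.append(gid)
            labels[gid] = "grey"
    X = np.vstack(rows)
    expr = pd.DataFrame(X, index=ids, columns=[f"S{j:03d}" for j in range(n)])
    expr.index.name = "gene"
    return expr, ExprGroundTruth(module=labels)


def _draw_sizes(rng: np.random.Generator, dist: Mapping[int, float], n: int) -> np.ndarray:
    sizes = np.array(sorted(dist), dtype=int)
    w = np.array([dist[s] for s in sizes], dtype=float)
    return rng.choice(sizes, size=n, p=w / w.sum())


def simulate_bursts(config: BurstSimConfig) -> tuple[pd.DataFrame, BurstGroundTruth]:
    """Simulate a binned two-channel fluorescence time trace.

    Returns a trace DataFrame (``bin_index``, ``donor_counts``,
    ``acceptor_counts``) and the planted-event ground truth.  Events are
    scheduled per bin with at most one planted species starting per bin
    (monomer beats oligomer beats dust on collision, each drawn
    independently); dust spans 2-3 consecutive bins with a large flat
    signal in both channels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xF8E7]))
    n = config.n_bins
    donor = rng.poisson(config.background_mean, size=n).astype(float)
    acceptor = rng.poisson(config.background_mean, size=n).astype(float)

    mono_mask = rng.random(n) < config.monomer_event_rate
    f = config.oligomer_mass_fraction
    sizes = np.array(sorted(config.oligomer_size_dist), dtype=float)
    w = np.array([config.oligomer_size_dist[int(s)] for s in sizes])
    mean_size = float(np.sum(sizes * w) / np.sum(w))
    olig_rate = (
        (f / (1.0 - f)) * config.monomer_event_rate / mean_size if f > 0 else 0.0
    )
    olig_mask = (rng.random(n) < olig_rate) & ~mono_mask
    dust_mask = (rng.random(n) < config.dust_rate) & ~mono_mask & ~olig_mask

    B = config.monomer_brightness
    events: list[tuple[int, int, str, int]] = []

    mono_bins = np.flatnonzero(mono_mask)
    donor[mono_bins] += rng.poisson(B, size=mono_bins.size)
    events.extend((int(b), 1, "monomer", 1) for b in mono_bins)

    olig_bins = np.flatnonzero(olig_mask)
    if olig_bins.size:
        s = _draw_sizes(rng, config.oligomer_size_dist, olig_bins.size).astype(float)
        d_mean = (s / 2.0) * B * (1.0 - config.true_E)
        a_mean = config.gamma * (s / 2.0) * B * config.true_E
        donor[olig_bins] += rng.poisson(d_mean)
        acceptor[olig_bins] += rng.poisson(a_mean)
        events.extend(
            (int(b), 1, "oligomer", int(si)) for b, si in zip(olig_bins, s)
        )

    for b in np.flatnonzero(dust_mask):
        span = int(rng.integers(2, 4))
        span = min(span, n - int(b))
        if span < 2:
            continue  # dust must cover >= 2 bins; skip truncated trace edge
        amp = 400.0 * B
        sl = slice(int(b), int(b) + span)
        donor[sl] += rng.poisson(amp, size=span)
        acceptor[sl] += rng.poisson(amp, size=span)
        events.append((int(b), span, "dust", 0))

    gt = pd.DataFrame(events, columns=["bin", "n_bins", "species", "size"])
    gt = gt.sort_values("bin", kind="stable").reset_index(drop=True)
    gt["isolated"] = _mark_isolated(gt)

    trace = pd.DataFrame(
        {
            "bin_index": np.arange(n),
            "donor_counts": donor.astype(int),
            "acceptor_counts": acceptor.astype(int),
        }
    )
    trace.attrs["bin_width_time"] = config.bin_width_time
    return trace, BurstGroundTruth(events=gt)


def _mark_isolated(gt: pd.DataFrame) -> np.ndarray:
    """True for events whose bin span is >= 2 bins away from every other event."""
    if gt.empty:
        return np.zeros(0, dtype=bool)
    starts = gt["bin"].to_numpy()
    ends = starts + gt["n_bins"].to_numpy() - 1
    iso = np.ones(len(gt), dtype=bool)
    for i in range(len(gt)):
        others = np.arange(len(gt)) != i
        iso[i] = bool(
            np.all((starts[others] > ends[i] + 1) | (ends[others] < starts[i] - 1))
        )
    return iso
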