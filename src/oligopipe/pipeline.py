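"""Top-level pipeline runners composing the analysis stages.

Each runner takes a plain config mapping (the YAML layout of
:func:`oligopipe.io.read_config`), derives every random stream from the
single global seed via named substreams, writes its intermediates to the
output directory and logs record counts per stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression as cx
from . import enrichment as en
from . import gene_assoc as ga
from . import io as oio
from . import smfret as sf
from . import synthetic as syn

__all__ = ["run_simulate", "run_genetics", "run_smfret"]

logger = logging.getLogger(__name__)


def _sub_seed(seed: int, stream: str) -> int:
    import zlib

    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def run_simulate(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Generate synthetic GWAS, expression and burst-trace inputs.

    Writes the same formats the analysis readers consume, plus ground
    truth tables.  Returns a name -> path map of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    written: dict[str, Path] = {}

    gcfg = dict(config.get("gwas_sim") or {})
    gcfg.setdefault("seed", _sub_seed(seed, "gwas"))
    if "causal_gene_ids" in gcfg:
        gcfg["causal_gene_ids"] = frozenset(gcfg["causal_gene_ids"])
    gwas_cfg = syn.GwasSimConfig(**gcfg)
    blocks = syn.simulate_ld_blocks(gwas_cfg)
    gwas, gwas_gt = syn.simulate_gwas(gwas_cfg, blocks)
    oio.write_gwas(gwas, out / "gwas.tsv")
    oio.write_bed(gwas.annotation, out / "genes.bed")
    ld_dir = out / "ld"
    ld_dir.mkdir(exist_ok=True)
    for gene, block in zip(gwas_cfg.gene_ids(), blocks):
        oio.write_ld(block, ld_dir / f"{gene}.ld.tsv")
    gwas_gt.to_frame().to_csv(out / "gwas_truth.tsv", sep="\t", index=False)
    written.update(
        gwas=out / "gwas.tsv", genes=out / "genes.bed", ld=ld_dir,
        gwas_truth=out / "gwas_truth.tsv",
    )
    logger.info("simulated GWAS: %d genes x %d SNPs", gwas_cfg.n_genes,
                gwas_cfg.snps_per_gene)

    ecfg = dict(config.get("expr_sim") or {})
    ecfg.setdefault("seed", _sub_seed(seed, "expr"))
    if "module_sizes" in ecfg:
        ecfg["module_sizes"] = tuple(ecfg["module_sizes"])
    expr_cfg = syn.ExprSimConfig(**ecfg)
    expr, expr_gt = syn.simulate_expression(expr_cfg)
    # share one gene namespace across the two arms: the first expression
    # genes (module genes first, background last) take the GWAS gene ids,
    # so planted causal genes land in the first expression module
    shared = min(len(expr), gwas_cfg.n_genes)
    rename = dict(zip(expr.index[:shared], gwas_cfg.gene_ids()[:shared]))
    expr = expr.rename(index=rename)
    expr_gt = syn.ExprGroundTruth(
        module={rename.get(g, g): m for g, m in expr_gt.module.items()}
    )
    oio.write_expression(expr, out / "expression.tsv")
    expr_gt.to_frame().to_csv(out / "expr_truth.tsv", sep="\t", index=False)
    written.update(expression=out / "expression.tsv", expr_truth=out / "expr_truth.tsv")
    logger.info("simulated expression: %d genes x %d samples", len(expr),
                expr_cfg.n_samples)

    bcfg = dict(config.get("burst_sim") or {})
    bcfg.setdefault("seed", _sub_seed(seed, "burst"))
    if "oligomer_size_dist" in bcfg:
        bcfg["oligomer_size_dist"] = {
            int(k): float(v) for k, v in bcfg["oligomer_size_dist"].items()
        }
    burst_cfg = syn.BurstSimConfig(**bcfg)
    trace, burst_gt = syn.simulate_bursts(burst_cfg)
    oio.write_trace(trace, out / "trace.csv")
    burst_gt.events.to_csv(out / "burst_truth.tsv", sep="\t", index=False)
    written.update(trace=out / "trace.csv", burst_truth=out / "burst_truth.tsv")
    logger.info("simulated trace: %d bins, %d planted events",
                burst_cfg.n_bins, len(burst_gt.events))
    return written


def run_genetics(config: dict, out_dir: str | Path,
                 inputs: dict[str, Path] | None = None) -> pd.DataFrame:
    """Gene-based test -> module detection -> enrichment, end to end.

    ``inputs`` names the files (gwas, genes, ld, expression, optional
    markers); defaults to the layout :func:`run_simulate` writes under
    ``out_dir``.  Returns the enrichment table (also written as TSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs = inputs or {}

    def _path(name: str, default: str) -> Path:
        p = Path(inputs.get(name, out / default))
        if not p.exists():
            raise FileNotFoundError(f"stage input missing: {name} ({p})")
        return p

    gwas = oio.read_gwas(_path("gwas", "gwas.tsv"))
    genes = oio.read_bed(_path("genes", "genes.bed"))
    ld = oio.read_ld_dir(_path("ld", "ld"))
    expr = oio.read_expression(_path("expression", "expression.tsv"))

    gt_cfg = config.get("gene_test") or {}
    gene_tab = ga.gene_test(
        gwas, genes, ld,
        k=int(gt_cfg.get("top_k", ga.DEFAULT_TOP_K)),
        n_sims=int(gt_cfg.get("n_sims", ga.DEFAULT_N_SIMS)),
        flank=int(gt_cfg.get("flank", ga.DEFAULT_FLANK)),
        seed=_sub_seed(seed, "gene_test"),
    )
    gene_tab.to_csv(out / "gene_pvals.tsv", sep="\t", index=False)
    logger.info("gene-based test: %d genes", len(gene_tab))

    m_cfg = config.get("modules") or {}
    net = cx.build_network(expr, beta=float(m_cfg.get("beta", cx.DEFAULT_BETA)))
    min_size = int(m_cfg.get("min_size", cx.DEFAULT_MIN_SIZE))
    assign = cx.detect_modules(
        net,
        min_size=min_size,
        cut_height=float(m_cfg.get("cut_height", cx.DEFAULT_CUT_HEIGHT)),
    )
    assign = cx.kmeans_refine(
        expr, assign,
        iters=int(m_cfg.get("kmeans_iters", cx.DEFAULT_KMEANS_ITERS)),
        min_size=min_size,
    )
    oio.write_modules(assign.labels, out / "modules.tsv")
    logger.info("modules: %d non-grey", len(assign.modules()))

    e_cfg = config.get("enrichment") or {}
    gene_p = dict(zip(gene_tab["gene"], gene_tab["pval"]))
    # the enrichment universe is the intersection of tested and networked genes
    upper = {g.upper(): g for g in gene_p}
    modules = {
        m: [g for g in gs if g.upper() in upper]
        for m, gs in assign.modules().items()
    }
    modules = {m: gs for m, gs in modules.items() if gs}
    network_genes = [g for g in assign.genes if g.upper() in upper]
    marker_sets = None
    if "markers" in inputs:
        marker_sets = oio.read_gmt(inputs["markers"])
    result = en.enrich_modules(
        gene_p,
        modules,
        network_genes=network_genes,
        marker_sets=marker_sets,
        n_random=int(e_cfg.get("n_random", en.DEFAULT_N_RANDOM)),
        seed=_sub_seed(seed, "enrichment"),
        exclude_grey=bool(e_cfg.get("exclude_grey", False)),
    )
    result = result.sort_values("bonf_p", kind="stable").reset_index(drop=True)
    with open(out / "enrichment.tsv", "w") as fh:
        fh.write("# module GWAS enrichment: module, k, x, z, emp_p, bonf_p, ...\n")
        result.to_csv(fh, sep="\t", index=False)
    logger.info("enrichment: %d modules tested", len(result))
    return result


def run_smfret(config: dict, out_dir: str | Path,
               trace_path: str | Path | None = None) -> sf.TraceAnalysis:
    """Full burst pipeline on one trace; writes burst log, histogram, fit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_cfg = config.get("smfret") or {}
    trace = oio.read_trace(trace_path or out / "trace.csv")
    params = sf.InstrumentParams(
        gamma=float(s_cfg.get("gamma", sf.DEFAULT_GAMMA)),
        donor_background=float(s_cfg.get("donor_background", 0.0)),
        acceptor_background=float(s_cfg.get("acceptor_background", 0.0)),
        burst_threshold_sd=float(s_cfg.get("burst_threshold_sd", 5.0)),
    )
    res = sf.analyze_trace(trace, params)
    with open(out / "bursts.tsv", "w") as fh:
        fh.write("# per-burst log: bin, I_D, I_A, run_length, coincident, "
                 "apparent_size, reason\n")
        res.burst_log.to_csv(fh, sep="\t", index=False)
    hist = pd.DataFrame(
        {
            "bin_left": res.histogram.edges[:-1],
            "bin_right": res.histogram.edges[1:],
            "count": res.histogram.counts,
        }
    )
    with open(out / "fret_histogram.tsv", "w") as fh:
        fh.write("# FRET efficiency histogram, bin width 0.05\n")
        hist.to_csv(fh, sep="\t", index=False)
    fit_info: dict = {
        "I_monomer": float(res.mono.I_monomer),
        "n_oligomer_bursts": res.summary.n_oligomer_bursts,
        "n_monomer_bursts": res.summary.n_monomer_bursts,
        "oligomer_mass_fraction_pct": float(res.summary.mass_fraction),
        "mean_apparent_size": float(res.summary.mean_apparent_size),
    }
    if res.fit is not None:
        fit_info["gaussamp"] = {
            "y0": res.fit.y0, "A": res.fit.A, "x_c": res.fit.x_c,
            "w": res.fit.w, "converged": res.fit.converged,
        }
    with open(out / "smfret_summary.yaml", "w") as fh:
        yaml.safe_dump(fit_info, fh, sort_keys=True)
    logger.info("smfret: %d bursts, %d retained oligomeric",
                len(res.bursts), res.summary.n_oligomer_bursts)
    return res
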