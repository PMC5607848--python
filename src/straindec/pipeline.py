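"""End-to-end orchestration: filter → variants → haplotype scan → genes.

`run_pipeline` wires the library stages together for a single target
species bin: core-gene coverage filtering, LR-test variant calling with
error-matrix refinement, a G-scan of replicate NTF-initialised Gibbs runs
with automatic selection of the strain number, assignment of bases at all
variant positions, and (when gene data are supplied) accessory-genome
inference and pairwise strain divergence. Each stage's outputs are written
before the next begins and every seed and threshold lands in a JSON
manifest, so a run is reproducible from config + inputs + seed.

Replicates and G values do not communicate, so the scan is trivially
parallelisable; execution order never changes results because each
(G, replicate) pair derives its own seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence as dv
from . import filtering, genes, variants
from .haplotypes import (
    MIN_VARIANTS_FOR_DECONVOLUTION,
    GibbsChain,
    assign_all_positions,
    gibbs_run,
    select_haplotype_number,
    snv_uncertainty,
)
from .io import BaseCountTable, CoverageMatrix

logger = logging.getLogger("straindec")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with study defaults."""

    p_min: float = 0.01
    fdr: float = 1e-3
    t: float = 2.5
    f: float = 0.8
    min_cov: float = 5.0
    g_min: int = 1
    g_max: int = 7
    replicates: int = 5
    burn: int = 100
    samples: int = 100
    subset_size: int = 1000
    alpha: float = 1.0
    delta: float = 0.1
    d: float = 0.05
    u_max: float = 0.10
    a_min: float = 0.05
    eta_prior: float = 1.0
    gene_burn: int = 20
    gene_samples: int = 20
    seed: int = 1

    def validate(self) -> None:
        if not 0 < self.p_min < 0.5:
            raise ValueError("p_min must be in (0, 0.5)")
        if not 0 < self.f <= 1:
            raise ValueError("f must be in (0, 1]")
        if self.g_min < 1 or self.g_max < self.g_min:
            raise ValueError("need 1 <= g_min <= g_max")
        if self.replicates < 1 or self.burn < 1 or self.samples < 1:
            raise ValueError("replicates, burn and samples must be >= 1")


@dataclass
class PipelineResult:
    kept_genes: list[str]
    variant_table: pd.DataFrame
    error_matrix: np.ndarray
    selected_g: int
    deviances: dict[int, list[float]]
    uncertainties: dict[int, np.ndarray]
    abundances: dict[int, np.ndarray]
    best_chain: GibbsChain | None
    tau_full: np.ndarray | None  # (V, G) over all variant positions
    gene_assignment: genes.GeneAssignment | None
    divergence: np.ndarray | None
    manifest: dict


def _haplotype_scan(
    tensor: np.ndarray, cfg: RunConfig
) -> tuple[dict[int, list[float]], dict[int, np.ndarray], dict[int, np.ndarray], dict[tuple[int, int], GibbsChain]]:
    deviances: dict[int, list[float]] = {}
    chains: dict[tuple[int, int], GibbsChain] = {}
    for G in range(cfg.g_min, cfg.g_max + 1):
        deviances[G] = []
        for rep in range(cfg.replicates):
            seed = cfg.seed + 1000 * G + rep
            chain = gibbs_run(
                tensor, G, burn=cfg.burn, samples=cfg.samples,
                alpha=cfg.alpha, delta=cfg.delta, seed=seed,
            )
            chains[(G, rep)] = chain
            deviances[G].append(chain.posterior_mean_deviance(tensor))
            logger.info("G=%d replicate %d: posterior mean deviance %.1f", G, rep, deviances[G][-1])
    uncertainties: dict[int, np.ndarray] = {}
    abundances: dict[int, np.ndarray] = {}
    for G in deviances:
        best = int(np.argmin(deviances[G]))
        run_tau = chains[(G, best)].tau_map
        reps = [chains[(G, r)].tau_map for r in range(cfg.replicates) if r != best]
        uncertainties[G] = snv_uncertainty(run_tau, reps)
        abundances[G] = chains[(G, best)].pi_mean.mean(axis=1)
    return deviances, uncertainties, abundances, chains


def run_pipeline(
    core_counts: BaseCountTable,
    core_coverage: CoverageMatrix,
    cfg: RunConfig,
    outdir: str | Path,
    gene_coverage: CoverageMatrix | None = None,
    gene_variant_tensor: np.ndarray | None = None,
) -> PipelineResult:
    """Run every stage on a target-species bin; write outputs under ``outdir``."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}
    t_start = time.time()

    # --- stage 1: core-gene filtering -------------------------------------
    kept, flags = filtering.mad_filter_genes(
        core_coverage, filtering.FilterConfig(cfg.t, cfg.f, cfg.min_cov)
    )
    pd.DataFrame(flags, index=core_coverage.gene_ids, columns=core_coverage.samples).to_csv(
        outdir / "core_gene_flags.tsv", sep="\t"
    )
    (outdir / "kept_core_genes.txt").write_text("\n".join(kept) + "\n")
    keep_mask = np.isin(core_counts.ids.astype(str), kept)
    counts = core_counts.subset(keep_mask)
    manifest["stages"]["filter"] = {"kept_genes": len(kept), "elapsed_s": time.time() - t_start}
    logger.info("kept %d/%d core genes", len(kept), len(core_coverage.gene_ids))

    # --- stage 2: variant detection ---------------------------------------
    t0 = time.time()
    agg = counts.aggregate_over_samples()
    call = variants.fit_error_matrix(agg, p_min=cfg.p_min, fdr=cfg.fdr)
    table = call.table.copy()
    table.insert(0, "position", counts.positions + 1)
    table.insert(0, "id", counts.ids)
    table.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(call.error_matrix, index=list("ACGT"), columns=list("ACGT")).to_csv(
        outdir / "error_matrix.csv"
    )
    manifest["stages"]["variants"] = {
        "n_positions": int(len(agg)),
        "n_variants": int(call.is_variant.sum()),
        "iterations": call.n_iterations,
        "elapsed_s": time.time() - t0,
    }
    logger.info("called %d variant positions", int(call.is_variant.sum()))

    var_mask = call.is_variant
    n_var = int(var_mask.sum())
    if n_var < MIN_VARIANTS_FOR_DECONVOLUTION:
        manifest["stages"]["haplotypes"] = {"skipped": f"only {n_var} variants (<{MIN_VARIANTS_FOR_DECONVOLUTION}); single consensus haplotype reported"}
        _write_manifest(outdir, manifest)
        return PipelineResult(kept, table, call.error_matrix, 1, {}, {}, {}, None, None, None, None, manifest)

    full_tensor = counts.counts[var_mask]
    rng = np.random.default_rng(cfg.seed)
    if n_var > cfg.subset_size:
        subset_idx = np.sort(rng.choice(n_var, size=cfg.subset_size, replace=False))
    else:
        subset_idx = np.arange(n_var)
    tensor = full_tensor[subset_idx]

    # --- stage 3: haplotype scan and selection -----------------------------
    t0 = time.time()
    deviances, uncertainties, abundances, chains = _haplotype_scan(tensor, cfg)
    selected = select_haplotype_number(
        deviances, uncertainties, abundances, d=cfg.d, u_max=cfg.u_max, a_min=cfg.a_min
    )
    pd.DataFrame(
        [(g, r, dev) for g, devs in deviances.items() for r, dev in enumerate(devs)],
        columns=["G", "replicate", "posterior_mean_deviance"],
    ).to_csv(outdir / "deviance.csv", index=False)
    best_rep = int(np.argmin(deviances[selected]))
    best = chains[(selected, best_rep)]
    pd.DataFrame(best.pi_mean, columns=core_counts.samples).to_csv(outdir / "pi.csv", index=False)
    pd.DataFrame(best.eps_mean, index=list("ACGT"), columns=list("ACGT")).to_csv(outdir / "epsilon.csv")
    pd.DataFrame(
        {f"G{g}": uncertainties[g] for g in uncertainties if g == selected}
    ).to_csv(outdir / "snv_uncertainty.csv", index=False)
    manifest["stages"]["haplotypes"] = {
        "selected_g": selected,
        "best_replicate": best_rep,
        "subset_size": int(len(subset_idx)),
        "elapsed_s": time.time() - t0,
    }
    logger.info("selected G=%d", selected)

    # --- stage 4: assign all variant positions ------------------------------
    t0 = time.time()
    tau_full = assign_all_positions(
        full_tensor, best, burn=cfg.burn, samples=cfg.samples, seed=cfg.seed + 7
    )
    var_ids = counts.ids[var_mask]
    var_pos = counts.positions[var_mask]
    tau_df = pd.DataFrame(tau_full, columns=[f"strain_{g}" for g in range(selected)])
    tau_df.insert(0, "position", var_pos + 1)
    tau_df.insert(0, "id", var_ids)
    tau_df.to_csv(outdir / "haplotypes.tsv", sep="\t", index=False)
    manifest["stages"]["assign_all"] = {"n_positions": n_var, "elapsed_s": time.time() - t0}

    # --- stage 5: gene assignment (optional) --------------------------------
    assignment = None
    div = None
    if gene_coverage is not None and gene_variant_tensor is not None:
        t0 = time.time()
        core_len = {g: int(l) for g, l in zip(core_coverage.gene_ids, core_coverage.lengths) if g in set(kept)}
        Y = genes.total_core_coverage(counts, core_len)
        gamma = genes.strain_coverage(best.pi_mean, Y)
        assignment = genes.eta_gibbs(
            gene_variant_tensor, gene_coverage.values, best.pi_mean, best.eps_mean,
            gamma, burn=cfg.gene_burn, samples=cfg.gene_samples,
            eta_prior=cfg.eta_prior, seed=cfg.seed + 11,
        )
        pd.DataFrame(
            assignment.eta_call, index=gene_coverage.gene_ids,
            columns=[f"strain_{g}" for g in range(selected)],
        ).to_csv(outdir / "eta.csv")
        profiles = assignment.eta_call.T.astype(float)  # strains × genes as cluster proxy
        div = dv.divergence_matrix(profiles)
        pd.DataFrame(div).to_csv(outdir / "divergence.csv", index=False)
        manifest["stages"]["genes"] = {"elapsed_s": time.time() - t0}

    manifest["elapsed_s"] = time.time() - t_start
    _write_manifest(outdir, manifest)
    return PipelineResult(
        kept, table, call.error_matrix, selected, deviances, uncertainties,
        abundances, best, tau_full, assignment, div, manifest,
    )


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
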