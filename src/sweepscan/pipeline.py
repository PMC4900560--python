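"""End-to-end scan orchestration: simulate/load, F_ST, PBS, XP-EHH, CSS,
candidates, sweep characterization, with a machine-readable run manifest.

Outputs are deterministic for a fixed config: rerunning with the same
seed and inputs writes byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .candidates import candidate_genes, group_into_sweeps, top_snps_near_genes
from .css import css_genes, css_snps, css_windows
from .differentiation import (allele_counts, fixed_differences, fst_wc_per_snp,
                              local_pbs_per_snp, pbs_scan, windowed_reynolds)
from .ehh import mean_xpehh_window, xpehh_scan
from .io import (read_genes, read_genetic_map, read_phased_vcf,
                 write_genetic_map, write_phased_vcf, write_stats_table)
from .simulate import SimulationConfig, simulate_panel, write_truth
from .sweeps import characterize_sweep, delta_pi_background, delta_pi_profile, \
    partition_haplotypes, pick_core_snp

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_scan", "make_report", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs and thresholds of a full scan."""

    out_dir: str = "sweepscan_out"
    seed: int = 0
    # inputs: either paths ...
    vcf: str | None = None
    genetic_map: str | None = None
    genes: str | None = None
    populations: dict = field(default_factory=dict)   # sample -> label
    # ... or a simulation
    simulate: SimulationConfig | None = None
    # population labels
    focal: str = "focal"
    background: str = "background"
    outgroup: str = "outgroup"
    # thresholds (the scan's printed defaults)
    maf: float = 0.02
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 10_000
    top_n: int = 1000
    gene_dist_bp: int = 8000
    fst_min: float = 0.8
    merge_dist_bp: int = 50_000
    css_mode: str = "literal"
    sweep_mode: str = "genetic"

    def __post_init__(self):
        if len({self.focal, self.background, self.outgroup}) != 3:
            raise ValueError("focal/background/outgroup labels must be distinct")
        for name in ("maf", "ehh_cutoff", "max_gap_bp", "top_n",
                     "gene_dist_bp", "merge_dist_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                log.info("stage %s", name)
                return fn(*a, **k)
            except Exception as e:          # noqa: BLE001 - stage boundary
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_scan(config: RunConfig) -> dict:
    """Execute the full scan; returns a result bundle of DataFrames.

    Writes TSVs for every stage plus ``manifest.json`` under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # ---- inputs ----------------------------------------------------------
    @_stage("input")
    def _load():
        if config.simulate is not None:
            panel, gmap, truth = simulate_panel(config.simulate)
            write_phased_vcf(panel, out / "panel.vcf")
            write_genetic_map(gmap, out / "genetic_map.tsv")
            write_truth(truth, out / "truth.tsv")
            genes = read_genes(config.genes) if config.genes else []
            return panel, gmap, genes
        if not config.vcf or not config.genetic_map:
            raise ValueError("need either a simulation config or VCF + map paths")
        panel = read_phased_vcf(config.vcf, config.populations)
        gmap = read_genetic_map(config.genetic_map)
        genes = read_genes(config.genes) if config.genes else []
        return panel, gmap, genes

    panel, gmap, genes = _load()
    extent = gmap.chrom_length

    # ---- per-SNP F_ST and fixed differences ------------------------------
    @_stage("fst")
    def _fst():
        c_f, n_f = allele_counts(panel, config.focal)
        c_b, n_b = allele_counts(panel, config.background)
        snps = pd.DataFrame({
            "chrom": panel.chromosome,
            "position": panel.positions,
            "freq_focal": c_f / n_f,
            "freq_background": c_b / n_b,
            "fst_wc": fst_wc_per_snp(c_f, n_f, c_b, n_b),
            "fixed_difference": fixed_differences(c_f, n_f, c_b, n_b),
        })
        return snps

    snps = _fst()

    # ---- windowed Reynolds + PBS -----------------------------------------
    @_stage("pbs")
    def _pbs():
        w1k = pbs_scan(panel, config.focal, config.background, config.outgroup,
                       window_bp=1000, extent_bp=extent)
        w100k = pbs_scan(panel, config.focal, config.background, config.outgroup,
                         window_bp=100_000, extent_bp=extent)
        return w1k, w100k

    windows_1k, windows_100k = _pbs()
    snps["pbs_local"] = local_pbs_per_snp(windows_1k, snps["position"])

    # ---- XP-EHH ----------------------------------------------------------
    @_stage("xpehh")
    def _xpehh():
        rec = xpehh_scan(panel, config.focal, config.background, gmap,
                         maf=config.maf, cutoff=config.ehh_cutoff,
                         max_gap=config.max_gap_bp)
        return rec

    xp = _xpehh()
    snps["maf"] = xp["maf"]
    snps["xpehh_raw"] = xp["xpehh_raw"]
    snps["xpehh_norm"] = xp["xpehh_norm"]
    snps["maf_filtered"] = xp["maf_filtered"]
    snps["gap_discarded"] = xp["gap_discarded"]
    for df, wsize in ((windows_1k, 1000), (windows_100k, 100_000)):
        mw = mean_xpehh_window(xp, wsize, extent)
        df["mean_xpehh"] = mw["mean_xpehh"]
        df["n_cores"] = mw["n_cores"]

    # ---- CSS -------------------------------------------------------------
    @_stage("css")
    def _css():
        s = css_snps(snps, mode=config.css_mode)
        w1 = css_windows(windows_1k, fst_col="fst12", mode=config.css_mode)
        w100 = css_windows(windows_100k, fst_col="fst12", mode=config.css_mode)
        g = css_genes(w1, genes) if genes else pd.DataFrame()
        return s, w1, w100, g

    snps, windows_1k, windows_100k, gene_css = _css()
    write_stats_table(snps, out / "snps.tsv")
    write_stats_table(windows_1k, out / "windows_1kb.tsv")
    write_stats_table(windows_100k, out / "windows_100kb.tsv")
    if len(gene_css):
        write_stats_table(gene_css, out / "genes_css.tsv")

    # ---- candidates ------------------------------------------------------
    @_stage("candidates")
    def _candidates():
        if not genes:
            return None, None, None
        top = top_snps_near_genes(snps, genes, n=config.top_n,
                                  max_dist=config.gene_dist_bp)
        cand = candidate_genes(top, fst_threshold=config.fst_min)
        groups = group_into_sweeps(cand, top, merge_dist=config.merge_dist_bp,
                                   fst_threshold=config.fst_min)
        write_stats_table(top, out / "top_snps.tsv")
        write_stats_table(cand, out / "candidate_genes.tsv")
        if len(groups):
            write_stats_table(groups, out / "sweep_groups.tsv")
        return top, cand, groups

    top, cand, groups = _candidates()

    # ---- sweep characterization ------------------------------------------
    @_stage("sweep_char")
    def _sweeps():
        if groups is None or not len(groups):
            return [], np.nan
        regions = []
        profiles = []
        for label, g in groups.groupby("sweep_group"):
            accs = set(g["accession"])
            sub = top[(top["nearest_gene"].isin(accs))
                      & (top["fst_wc"] > config.fst_min)]
            if sub.empty:
                continue
            core = pick_core_snp(sub)
            sel, unsel = partition_haplotypes(
                panel, int(core["position"]), config.focal, config.background)
            prof = delta_pi_profile(panel, int(core["position"]), sel, unsel,
                                    mode=config.sweep_mode, gmap=gmap)
            profiles.append((label, sub, prof))
        if not profiles:
            return [], np.nan
        dp_b = delta_pi_background([p for _, _, p in profiles])
        for label, sub, _ in profiles:
            r = characterize_sweep(panel, gmap, sub, config.focal,
                                   config.background, delta_pi_b=dp_b,
                                   mode=config.sweep_mode)
            r.label = label
            regions.append(r)
        return regions, dp_b

    regions, dp_b = _sweeps()
    if regions:
        sweep_df = pd.DataFrame([{
            "sweep": r.label, "chrom": r.chromosome,
            "core_position": r.core_position,
            "delta_pi_core_pct": r.delta_pi_core_pct, "kind": r.kind,
            "length_cm": r.length_cm, "length_bp": r.length_bp,
            "start_bp": r.start_bp, "stop_bp": r.stop_bp,
            "flagged": r.flagged} for r in regions])
        write_stats_table(sweep_df, out / "sweeps.tsv")
        bundle["sweep_table"] = sweep_df

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "maf": config.maf, "ehh_cutoff": config.ehh_cutoff,
            "max_gap_bp": config.max_gap_bp, "top_n": config.top_n,
            "gene_dist_bp": config.gene_dist_bp, "fst_min": config.fst_min,
            "merge_dist_bp": config.merge_dist_bp, "css_mode": config.css_mode,
            "sweep_mode": config.sweep_mode,
        },
        "populations": {"focal": config.focal, "background": config.background,
                        "outgroup": config.outgroup},
        "n_snps": int(len(snps)),
        "simulated": config.simulate is not None,
    }
    if config.simulate is not None:
        sim = asdict(config.simulate)
        sim["sweeps"] = [asdict(s) for s in config.simulate.sweeps]
        manifest["simulation"] = sim
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    bundle.update({
        "panel": panel, "gmap": gmap, "genes": genes, "snps": snps,
        "windows_1kb": windows_1k, "windows_100kb": windows_100k,
        "gene_css": gene_css, "top_snps": top, "candidate_genes": cand,
        "sweep_groups": groups, "sweeps": regions,
        "delta_pi_background": dp_b, "manifest": manifest,
    })
    return bundle


def make_report(bundle: dict, percentiles=(99.99, 99.9, 99.5)) -> dict:
    """Summary tables: empirical per-chromosome percentile thresholds for
    each statistic, the top-gene table and the sweep table."""
    snps = bundle["snps"]
    rows = []
    for chrom, g in snps.groupby("chrom"):
        for stat in ("fst_wc", "xpehh_norm", "css"):
            v = g[stat].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            for p in percentiles:
                thr = float(np.percentile(v, p))
                rows.append({"chrom": chrom, "stat": stat, "percentile": p,
                             "threshold": thr, "n_above": int((v > thr).sum())})
    report = {"percentiles": pd.DataFrame(rows)}
    if bundle.get("candidate_genes") is not None:
        report["gene_table"] = bundle["candidate_genes"]
    if "sweep_table" in bundle:
        report["sweep_table"] = bundle["sweep_table"]
    return report
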