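"""Outlier-SNP selection, gene association, enrichment and profile summaries.

Implements the post-scan procedures: pick the top-CSS SNPs near genes,
reduce them to candidate genes anchored by highly differentiated SNPs,
cluster nearby candidates into putative sweeps, test feature-class
enrichment of top SNPs, and build binned-mean / linked-decay profiles
with bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "nearest_gene_distance", "top_snps_near_genes", "candidate_genes",
    "group_into_sweeps", "assign_feature_classes", "feature_enrichment",
    "binned_mean_bootstrap", "decay_profile",
]

FEATURE_PRECEDENCE = ("CDS", "UTR", "intron", "intergenic")


def nearest_gene_distance(positions, chrom, genes):
    """Per-SNP distance (bp) to the nearest gene body and its accession.

    Distance is 0 inside the gene body; strand is ignored.  Positions on
    chromosomes without genes get distance -1 and accession ''.
    """
    positions = np.asarray(positions, dtype=np.int64)
    cand = [g for g in genes if g.chromosome == chrom]
    dist = np.full(positions.size, -1, dtype=np.int64)
    acc = np.full(positions.size, "", dtype=object)
    if not cand:
        return dist, acc
    starts = np.array([g.start for g in cand])
    stops = np.array([g.stop for g in cand])
    # distance to interval [start, stop): 0 inside, else bp to nearest base
    d = np.where(positions[:, None] < starts[None, :],
                 starts[None, :] - positions[:, None],
                 np.where(positions[:, None] >= stops[None, :],
                          positions[:, None] - stops[None, :] + 1, 0))
    best = np.argmin(d, axis=1)
    dist = d[np.arange(positions.size), best]
    acc = np.array([cand[j].accession for j in best], dtype=object)
    return dist, acc


def top_snps_near_genes(snp_css: pd.DataFrame, genes, n: int = 1000,
                        max_dist: int = 8000,
                        fst_col: str = "fst_wc") -> pd.DataFrame:
    """Top-``n`` CSS SNPs among those within ``max_dist`` bp of a gene body.

    Sorted by CSS descending; ties broken by F_ST descending, then
    position ascending.  Returns fewer rows (with a warning) when fewer
    SNPs are eligible.
    """
    df = snp_css[snp_css["css"].notna()].copy()
    parts = []
    for chrom, g in df.groupby("chrom"):
        dist, acc = nearest_gene_distance(g["position"].to_numpy(), chrom, genes)
        g = g.assign(gene_distance=dist, nearest_gene=acc)
        parts.append(g)
    df = pd.concat(parts) if parts else df.assign(gene_distance=-1, nearest_gene="")
    eligible = df[(df["gene_distance"] >= 0) & (df["gene_distance"] <= max_dist)]
    eligible = eligible.sort_values(
        ["css", fst_col, "position"], ascending=[False, False, True])
    if len(eligible) < n:
        warnings.warn(f"only {len(eligible)} eligible SNPs for requested top {n}")
    return eligible.head(n).reset_index(drop=True)


def candidate_genes(top_snps: pd.DataFrame, fst_threshold: float = 0.8,
                    fst_col: str = "fst_wc") -> pd.DataFrame:
    """Genes with at least one linked top SNP whose F_ST exceeds the threshold.

    One row per linked gene with its top-SNP count and max F_ST; the
    ``kept`` column marks the candidate subset.
    """
    per_gene = top_snps.groupby("nearest_gene").agg(
        chrom=("chrom", "first"),
        n_top_snps=("position", "size"),
        max_fst=(fst_col, "max"),
        max_css=("css", "max"),
        first_pos=("position", "min"),
    ).reset_index().rename(columns={"nearest_gene": "accession"})
    per_gene["kept"] = per_gene["max_fst"] > fst_threshold
    return per_gene.sort_values(["chrom", "first_pos"]).reset_index(drop=True)


def _labels(k):
    out = []
    for i in range(k):
        lab = ""
        j = i
        while True:
            lab = chr(ord("A") + j % 26) + lab
            j = j // 26 - 1
            if j < 0:
                break
        out.append(lab)
    return out


def group_into_sweeps(cand: pd.DataFrame, top_snps: pd.DataFrame,
                      merge_dist: int = 50_000,
                      fst_threshold: float = 0.8,
                      fst_col: str = "fst_wc") -> pd.DataFrame:
    """Single-linkage clustering of candidate genes into putative sweeps.

    Two genes join the same group when any of their linked outlier SNPs
    (top SNPs above the F_ST threshold) lie within ``merge_dist`` bp on
    the same chromosome.  Groups are labelled A, B, ... in genomic order.
    """
    kept = set(cand.loc[cand["kept"], "accession"])
    out = top_snps[(top_snps["nearest_gene"].isin(kept))
                   & (top_snps[fst_col] > fst_threshold)]
    out = out.sort_values(["chrom", "position"])

    # union-find over run ids: consecutive outlier SNPs within merge_dist on
    # one chromosome share a run; runs sharing a gene are fused
    parent: dict = {}

    def _find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def _union(a, b):
        ra, rb = _find(a), _find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    run = -1
    prev_chrom, prev_pos = None, None
    run_of_gene: dict = {}
    for chrom, pos, gene in zip(out["chrom"], out["position"], out["nearest_gene"]):
        if chrom != prev_chrom or pos - prev_pos > merge_dist:
            run += 1
            parent[run] = run
        if gene in run_of_gene:
            _union(run_of_gene[gene], run)
        else:
            run_of_gene[gene] = run
        prev_chrom, prev_pos = chrom, pos
    rows = [{"accession": g, "group_raw": _find(r)} for g, r in run_of_gene.items()]
    df = pd.DataFrame(rows).merge(
        cand[["accession", "chrom", "first_pos", "max_css", "max_fst"]],
        on="accession")
    order = (df.groupby("group_raw")
               .agg(chrom=("chrom", "first"), pos=("first_pos", "min"))
               .sort_values(["chrom", "pos"]).index.tolist())
    labels = dict(zip(order, _labels(len(order))))
    df["sweep_group"] = df["group_raw"].map(labels)
    return (df.drop(columns="group_raw")
              .sort_values(["sweep_group", "first_pos"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# Feature-class enrichment
# ---------------------------------------------------------------------------

def assign_feature_classes(positions, chrom, features: pd.DataFrame) -> np.ndarray:
    """Assign one feature class per SNP with CDS > UTR > intron > intergenic
    precedence.  ``features`` needs columns chrom/start/stop/feature
    (0-based half-open); unannotated positions are intergenic."""
    positions = np.asarray(positions, dtype=np.int64)
    classes = np.full(positions.size, "intergenic", dtype=object)
    f = features[features["chrom"] == chrom]
    for feat in reversed(FEATURE_PRECEDENCE[:-1]):   # apply low -> high precedence
        sub = f[f["feature"] == feat]
        for start, stop in zip(sub["start"], sub["stop"]):
            classes[(positions >= start) & (positions < stop)] = feat
    return classes


def feature_enrichment(top_classes, all_classes) -> pd.DataFrame:
    """Per-class enrichment of top SNPs: fold = (b/n)/(B/N) with a
    two-sided Fisher's exact test on the 2x2 table (b, n-b, B-b, N-n-B+b).

    b/B are the class counts among top/all SNPs, n/N the set sizes (the
    top set is a subset of the full set).  Classes absent from the full
    set get a NaN fold.
    """
    top_classes = np.asarray(top_classes, dtype=object)
    all_classes = np.asarray(all_classes, dtype=object)
    n, N = top_classes.size, all_classes.size
    rows = []
    for cls in FEATURE_PRECEDENCE:
        b = int((top_classes == cls).sum())
        B = int((all_classes == cls).sum())
        if B == 0 or n == 0:
            fold, p = np.nan, np.nan
        else:
            fold = (b / n) / (B / N)
            table = [[b, n - b], [B - b, N - n - B + b]]
            _, p = fisher_exact(table, alternative="two-sided")
        rows.append({"feature": cls, "b": b, "n": n, "B": B, "N": N,
                     "fold": fold, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binned means and decay profiles with bootstrap CIs
# ---------------------------------------------------------------------------

def binned_mean_bootstrap(snp_table: pd.DataFrame, bin_stat: str = "fst_wc",
                          value_stat: str = "pbs", bin_width: float = 0.05,
                          reps: int = 200, min_snps: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """Mean of ``value_stat`` per ``bin_stat`` bin of ``bin_width`` with 95%
    percentile-bootstrap CIs (``reps`` replicates resampling SNPs within
    the bin).  Bins with fewer than ``min_snps`` SNPs are suppressed."""
    rng = np.random.default_rng(seed)
    x = snp_table[bin_stat].to_numpy(dtype=float)
    y = snp_table[value_stat].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    idx = np.floor(x / bin_width).astype(np.int64)
    rows = []
    for b in np.unique(idx):
        vals = y[idx == b]
        if vals.size < min_snps:
            continue
        boot = np.empty(reps)
        for r in range(reps):
            boot[r] = vals[rng.integers(0, vals.size, vals.size)].mean()
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({"bin_start": b * bin_width, "bin_stop": (b + 1) * bin_width,
                     "n_snps": int(vals.size), "mean": float(vals.mean()),
                     "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows,
                        columns=["bin_start", "bin_stop", "n_snps",
                                 "mean", "ci_low", "ci_high"])


def decay_profile(anchor_positions, window_values: pd.DataFrame,
                  value_col: str, max_dist: int = 500_000,
                  window_bp: int = 1000, reps: int = 200,
                  seed: int = 0) -> pd.DataFrame:
    """Mean windowed statistic versus distance from a set of anchor SNPs.

    For every anchor, window values are collected at each offset up- and
    downstream (the two sides averaged per offset; one-sided at
    chromosome edges), then averaged across anchors; 95% CIs come from
    ``reps`` bootstrap resamplings of the anchors.
    """
    rng = np.random.default_rng(seed)
    anchors = np.asarray(anchor_positions, dtype=np.int64)
    vals = window_values[value_col].to_numpy(dtype=float)
    n_win = vals.size
    n_off = max_dist // window_bp + 1
    k0 = anchors // window_bp
    per = np.full((anchors.size, n_off), np.nan)
    for i, k in enumerate(k0):
        off = np.arange(n_off)
        up = k - off
        dn = k + off
        u = np.where((up >= 0) & (up < n_win), vals[np.clip(up, 0, n_win - 1)], np.nan)
        d = np.where((dn >= 0) & (dn < n_win), vals[np.clip(dn, 0, n_win - 1)], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per[i] = np.nanmean(np.stack([u, d]), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per, axis=0)
        boot = np.empty((reps, n_off))
        for r in range(reps):
            pick = rng.integers(0, anchors.size, anchors.size)
            boot[r] = np.nanmean(per[pick], axis=0)
    lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "distance_bp": np.arange(n_off) * window_bp,
        "mean": mean, "ci_low": lo, "ci_high": hi,
        "n_anchors": np.sum(np.isfinite(per), axis=0),
    })
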