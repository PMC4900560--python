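"""Composite Selection Score (CSS): rank-combine F_ST and XP-EHH.

Each statistic is converted to a fractional rank r = (rank - 0.5)/n over
the items where both statistics are defined (average ranks for ties), the
ranks to normal quantiles z = Phi^-1(r), and the mean z-bar of the two
z-scores to an upper-tail p-value; CSS = -log10 p.  Two standardisations
of z-bar are supported:

* ``literal`` (default): p = 1 - Phi(z-bar) -- z-bar read against a
  standard normal, reproducing the scale of CSS thresholds reported with
  this scoring (top SNPs ~ 3.0).
* ``exact``: p = 1 - Phi(z-bar * sqrt(2)) -- the exact null distribution
  of a mean of two independent standard normals.

High F_ST together with high XP-EHH gives a high CSS; CSS is invariant to
any strictly monotone transform of either input statistic.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["fractional_ranks", "css", "css_snps", "css_windows", "css_genes"]

_LN10 = math.log(10.0)


def fractional_ranks(values) -> np.ndarray:
    """Fractional ranks r_i = (rank_i - 0.5)/n, average ranks for ties.

    Strictly inside (0, 1); all-equal input gives all r = 0.5.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to rank")
    if not np.all(np.isfinite(v)):
        raise ValueError("only finite values may be ranked")
    ranks = stats.rankdata(v, method="average")
    return (ranks - 0.5) / v.size


def css(r_fst, r_xpehh, mode: str = "literal"):
    """CSS from two fractional ranks (both strictly inside (0, 1)).

    CSS = -log10 P(Z > z-bar / sigma) with z_s = Phi^-1(r_s),
    z-bar = (z_fst + z_xpehh)/2 and sigma = 1 (``literal``) or 1/sqrt(2)
    (``exact``).  Computed via the log survival function, so large scores
    do not underflow.
    """
    r1 = np.asarray(r_fst, dtype=float)
    r2 = np.asarray(r_xpehh, dtype=float)
    if np.any((r1 <= 0) | (r1 >= 1) | (r2 <= 0) | (r2 >= 1)):
        raise ValueError("fractional ranks must lie strictly inside (0, 1)")
    z = (special.ndtri(r1) + special.ndtri(r2)) / 2.0
    if mode == "literal":
        zz = z
    elif mode == "exact":
        zz = z * math.sqrt(2.0)
    else:
        raise ValueError(f"unknown CSS mode {mode!r}")
    out = -stats.norm.logsf(zz) / _LN10
    return float(out) if np.isscalar(r_fst) and np.isscalar(r_xpehh) else out


def _css_table(df: pd.DataFrame, fst_col: str, xpehh_col: str,
               mode: str) -> pd.DataFrame:
    """Shared SNP/window CSS machinery: mask, rank, score, flag."""
    out = df.copy()
    fst = out[fst_col].to_numpy(dtype=float)
    xp = out[xpehh_col].to_numpy(dtype=float)
    ok = np.isfinite(fst) & np.isfinite(xp)
    cssv = np.full(len(out), np.nan)
    if ok.sum() >= 2:
        # negative F_ST estimates are ranked as-is: flooring them at 0 would
        # tie ~half of a neutral genome and distort the z-bar null
        r_f = fractional_ranks(fst[ok])
        r_x = fractional_ranks(xp[ok])
        cssv[ok] = css(r_f, r_x, mode=mode)
        out["rank_fst"] = np.nan
        out["rank_xpehh"] = np.nan
        out.loc[ok, "rank_fst"] = r_f
        out.loc[ok, "rank_xpehh"] = r_x
    out["css"] = cssv
    out["css_defined"] = ok
    return out


def css_snps(snp_table: pd.DataFrame, fst_col: str = "fst_wc",
             xpehh_col: str = "xpehh_norm", mode: str = "literal") -> pd.DataFrame:
    """Per-SNP CSS.  SNPs lacking either statistic (NaN F_ST, MAF-filtered
    or gap-discarded XP-EHH) are excluded from ranking and flagged."""
    return _css_table(snp_table, fst_col, xpehh_col, mode)


def css_windows(window_table: pd.DataFrame, fst_col: str = "fst_reynolds",
                xpehh_col: str = "mean_xpehh", mode: str = "literal") -> pd.DataFrame:
    """Per-window CSS over windowed Reynolds F_ST and mean XP-EHH."""
    return _css_table(window_table, fst_col, xpehh_col, mode)


def css_genes(windows_1kb_css: pd.DataFrame, genes, flank_bp: int = 2000) -> pd.DataFrame:
    """Per-gene CSS: mean CSS of the scored 1 kb windows overlapping the
    gene body extended by ``flank_bp`` to either side.

    Genes on chromosomes without scored windows, or with no scored
    overlapping window, get NaN (flagged).
    """
    w = windows_1kb_css
    rows = []
    by_chrom = {c: g for c, g in w.groupby("chrom")} if "chrom" in w else {None: w}
    for gene in genes:
        g = by_chrom.get(gene.chromosome if "chrom" in w else None)
        val, n_win = np.nan, 0
        if g is not None:
            lo = gene.start - flank_bp
            hi = gene.stop + flank_bp
            sel = g[(g["stop"] > lo) & (g["start"] < hi) & g["css"].notna()]
            n_win = len(sel)
            if n_win:
                val = float(sel["css"].mean())
        rows.append({"accession": gene.accession, "chrom": gene.chromosome,
                     "start": gene.start, "stop": gene.stop,
                     "n_windows": n_win, "css_gene": val,
                     "css_defined": bool(n_win)})
    return pd.DataFrame(rows)
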