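"""Allele-frequency differentiation: Weir-Cockerham per-SNP F_ST, windowed
Reynolds F_ST (ratio-of-sums), fixed differences, divergence times and the
Population Branch Statistic (PBS).

Phased haplotypes are treated as sampled alleles: the two-population
variance components are the haploid reduction of the Weir & Cockerham
(1984) ANOVA, which is also the component form of the Reynolds, Weir &
Cockerham (1983) coancestry estimator.  Per-SNP estimates are per-site
ratios a/(a+b); window estimates are ratio-of-sums over sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

__all__ = [
    "allele_counts", "wc_components", "fst_wc_per_snp",
    "fst_reynolds_window", "fixed_differences",
    "divergence_time", "pbs_window",
    "tile_windows", "windowed_reynolds", "pbs_scan", "local_pbs_per_snp",
]

# F_ST >= 1 is clamped below 1 so T = -ln(1-F) stays finite
_FST_CEIL = 1.0 - 1e-6


def allele_counts(panel: HaplotypePanel, *populations: str):
    """Per-site ``(count_allele1, count_total)`` for the given population(s)."""
    idx = panel.haplotype_indices(*populations)
    if idx.size == 0:
        raise ValueError(f"empty population(s): {populations}")
    sub = panel.alleles[idx, :]
    c1 = sub.sum(axis=0, dtype=np.int64)
    total = np.full(panel.n_sites, idx.size, dtype=np.int64)
    return c1, total


def wc_components(c_a, n_a, c_b, n_b):
    """Two-population haploid variance components (a, b) per site.

    ``a`` is the between-population component, ``b`` the within-population
    component; the per-site estimator is ``a/(a+b)`` and the windowed
    Reynolds estimator is ``sum(a)/sum(a+b)``.
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    n_a = np.broadcast_to(np.asarray(n_a, dtype=float), c_a.shape)
    n_b = np.broadcast_to(np.asarray(n_b, dtype=float), c_b.shape)
    if np.any(n_a < 2) or np.any(n_b < 2):
        raise ValueError("both samples must contain at least 2 alleles")
    p1, p2 = c_a / n_a, c_b / n_b
    n_tot = n_a + n_b
    nbar = n_tot / 2.0
    nc = n_tot - (n_a ** 2 + n_b ** 2) / n_tot          # r - 1 = 1
    pbar = (n_a * p1 + n_b * p2) / n_tot
    s2 = (n_a * (p1 - pbar) ** 2 + n_b * (p2 - pbar) ** 2) / nbar
    inner = pbar * (1.0 - pbar) - s2 / 2.0
    a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * inner
    return a, b


def fst_wc_per_snp(c_a, n_a, c_b, n_b):
    """Per-SNP Weir-Cockerham theta-hat; NaN where both samples are
    monomorphic for the same allele.  Negative estimates are reported
    as-is (they are floored at 0 only for rank-based scoring)."""
    a, b = wc_components(c_a, n_a, c_b, n_b)
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0.0, a / np.where(denom == 0, 1.0, denom), np.nan)
    return theta


def fst_reynolds_window(c_a, n_a, c_b, n_b, site_index=None):
    """Ratio-of-sums Reynolds F_ST over the sites in one window.

    ``site_index`` optionally selects a subset of sites; NaN when the
    window holds no polymorphic site (zero denominator).
    """
    a, b = wc_components(c_a, n_a, c_b, n_b)
    if site_index is not None:
        a, b = a[site_index], b[site_index]
    if a.size == 0:
        return np.nan
    denom = np.nansum(a + b)
    if denom == 0.0:
        return np.nan
    return float(np.nansum(a) / denom)


def fixed_differences(c_a, n_a, c_b, n_b):
    """Boolean mask of sites monomorphic for opposite alleles in A and B."""
    c_a, c_b = np.asarray(c_a), np.asarray(c_b)
    return ((c_a == n_a) & (c_b == 0)) | ((c_a == 0) & (c_b == n_b))


def divergence_time(fst):
    """Divergence time T = -ln(1 - F_ST).

    Window F_ST below 0 is clamped to 0 and values at or above 1 are
    clamped just below 1 so T stays finite; NaN propagates.
    """
    f = np.clip(np.asarray(fst, dtype=float), 0.0, _FST_CEIL)
    out = -np.log1p(-f)
    return float(out) if np.isscalar(fst) else out


def pbs_window(t12, t13, t23):
    """PBS = (T12 + T13 - T23) / 2; positive values mark divergence on the
    focal (population 1) branch.  NaN in any input yields NaN."""
    out = (np.asarray(t12, dtype=float) + np.asarray(t13, dtype=float)
           - np.asarray(t23, dtype=float)) / 2.0
    return float(out) if np.isscalar(t12) and np.isscalar(t13) else out


# ---------------------------------------------------------------------------
# Window machinery (fixed-origin, non-overlapping tiles from position 0)
# ---------------------------------------------------------------------------

def tile_windows(extent_bp: int, window_bp: int):
    """Half-open tiles [k*w, (k+1)*w) covering [0, extent_bp)."""
    n = int(np.ceil(extent_bp / window_bp))
    starts = np.arange(n, dtype=np.int64) * window_bp
    return starts, starts + window_bp


def windowed_reynolds(panel: HaplotypePanel, pop_a, pop_b, window_bp: int,
                      extent_bp: int | None = None) -> pd.DataFrame:
    """Reynolds F_ST per non-overlapping window of ``window_bp``.

    ``pop_a`` / ``pop_b`` may be a single label or a tuple of labels
    (pooled).  Returns one row per tile with NaN for empty windows.
    """
    pa = (pop_a,) if isinstance(pop_a, str) else tuple(pop_a)
    pb = (pop_b,) if isinstance(pop_b, str) else tuple(pop_b)
    c_a, n_a = allele_counts(panel, *pa)
    c_b, n_b = allele_counts(panel, *pb)
    a, b = wc_components(c_a, n_a, c_b, n_b)

    if extent_bp is None:
        extent_bp = int(panel.positions[-1]) + 1
    starts, stops = tile_windows(extent_bp, window_bp)
    widx = panel.positions // window_bp
    num = np.bincount(widx, weights=np.nan_to_num(a), minlength=starts.size)
    den = np.bincount(widx, weights=np.nan_to_num(a + b), minlength=starts.size)
    nsites = np.bincount(widx, minlength=starts.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den != 0.0, num / np.where(den == 0, 1.0, den), np.nan)
    return pd.DataFrame({
        "chrom": panel.chromosome, "start": starts, "stop": stops,
        "n_sites": nsites, "fst_reynolds": fst,
    })


def pbs_scan(panel: HaplotypePanel, focal, background, outgroup,
             window_bp: int = 1000, extent_bp: int | None = None) -> pd.DataFrame:
    """Windowed PBS of the focal population from three pairwise window F_STs.

    Each pairwise Reynolds window F_ST is transformed to a divergence time
    T = -ln(1-F); PBS = (T12 + T13 - T23)/2 where 1=focal, 2=background,
    3=outgroup.  Windows where any pairwise F_ST is undefined get NaN.
    """
    if extent_bp is None:
        extent_bp = int(panel.positions[-1]) + 1
    w12 = windowed_reynolds(panel, focal, background, window_bp, extent_bp)
    w13 = windowed_reynolds(panel, focal, outgroup, window_bp, extent_bp)
    w23 = windowed_reynolds(panel, background, outgroup, window_bp, extent_bp)
    t12 = divergence_time(w12["fst_reynolds"].to_numpy())
    t13 = divergence_time(w13["fst_reynolds"].to_numpy())
    t23 = divergence_time(w23["fst_reynolds"].to_numpy())
    out = w12.rename(columns={"fst_reynolds": "fst12"})
    out["fst13"] = w13["fst_reynolds"]
    out["fst23"] = w23["fst_reynolds"]
    out["T12"], out["T13"], out["T23"] = t12, t13, t23
    out["pbs"] = pbs_window(t12, t13, t23)
    return out


def local_pbs_per_snp(pbs_windows: pd.DataFrame, positions) -> np.ndarray:
    """Each SNP inherits the PBS of its containing window (half-open tiles).

    SNPs falling in NaN windows (or outside the tiled extent) get NaN.
    """
    positions = np.asarray(positions, dtype=np.int64)
    window_bp = int(pbs_windows["stop"].iloc[0] - pbs_windows["start"].iloc[0])
    pbs = pbs_windows["pbs"].to_numpy()
    idx = positions // window_bp
    out = np.full(positions.size, np.nan)
    ok = idx < pbs.size
    out[ok] = pbs[idx[ok]]
    return out
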