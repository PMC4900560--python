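"""Selective-sweep characterization around a core SNP.

Given a sweep region, pick the core SNP (highest F_ST, ties by XP-EHH,
then leftmost), split haplotypes into the putatively selected group
(focal haplotypes carrying the focal-major allele at the core) and the
unselected group (remaining focal plus all background haplotypes), and
trace the relative diversity deficit

    delta-pi = (pi_selected - pi_unselected) / pi_unselected

in non-overlapping windows away from the core: 0.01 cM windows to 20 cM
per side (genetic mode) or 1 kb windows to 2 Mb per side (physical mode).
The two sides are folded into a one-sided profile (pi averaged across the
up/downstream windows at each distance index; one-sided at chromosome
edges).  The sweep extent is the first distance interval whose folded
delta-pi recovers to the genomic background level delta-pi_B, reported at
half-window resolution via a midpoint rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GeneticMap, HaplotypePanel

__all__ = [
    "pick_core_snp", "partition_haplotypes", "pi_window", "delta_pi",
    "delta_pi_profile", "delta_pi_background", "sweep_length",
    "classify_sweep", "SweepRegion", "characterize_sweep",
]


def pick_core_snp(region_snps: pd.DataFrame, fst_col: str = "fst_wc",
                  xpehh_col: str = "xpehh_norm") -> pd.Series:
    """Core SNP of a sweep region: argmax F_ST, ties broken by the highest
    XP-EHH, remaining ties by leftmost position."""
    df = region_snps[region_snps[fst_col].notna() & region_snps[xpehh_col].notna()]
    if df.empty:
        raise ValueError("region holds no SNP with both statistics")
    df = df.sort_values([fst_col, xpehh_col, "position"],
                        ascending=[False, False, True])
    return df.iloc[0]


def partition_haplotypes(panel: HaplotypePanel, core_position: int,
                         focal, background):
    """Split haplotypes at the core into (selected, unselected) row indices.

    Selected: focal haplotypes carrying the focal-major allele at the
    core.  Unselected: remaining focal haplotypes plus all background
    haplotypes.  An exact 50/50 focal split is an error (no major allele).
    """
    fpops = (focal,) if isinstance(focal, str) else tuple(focal)
    bpops = (background,) if isinstance(background, str) else tuple(background)
    j = int(np.searchsorted(panel.positions, core_position))
    if j >= panel.n_sites or panel.positions[j] != core_position:
        raise ValueError(f"no site at core position {core_position}")
    f_idx = panel.haplotype_indices(*fpops)
    b_idx = panel.haplotype_indices(*bpops)
    col = panel.alleles[f_idx, j]
    freq1 = col.mean()
    if freq1 == 0.5:
        raise ValueError(
            "focal allele frequency is exactly 0.5 at the core; "
            "choose the selected allele manually")
    major = 1 if freq1 > 0.5 else 0
    selected = f_idx[col == major]
    unselected = np.concatenate([f_idx[col != major], b_idx])
    return selected, unselected


def pi_window(alleles: np.ndarray, site_index=None) -> float:
    """Nucleotide diversity of a haplotype group over a window: the mean
    pairwise count of differing sites (per-window sum, not per-bp; the
    normalisation cancels in delta-pi).  NaN for < 2 haplotypes."""
    H = np.asarray(alleles)
    if site_index is not None:
        H = H[:, site_index]
    n = H.shape[0]
    if n < 2:
        return np.nan
    c = H.sum(axis=0, dtype=np.int64)
    # sum over sites of (# pairs differing) / (# pairs)
    return float(np.sum(c * (n - c)) / (n * (n - 1) / 2))


def delta_pi(pi_selected: float, pi_unselected: float) -> float:
    """(pi_sel - pi_unsel) / pi_unsel; NaN when the unselected group has
    no diversity in the window (or either input is undefined)."""
    if not np.isfinite(pi_selected) or not np.isfinite(pi_unselected) \
            or pi_unselected == 0.0:
        return np.nan
    return (pi_selected - pi_unselected) / pi_unselected


def _window_bounds(panel, gmap, core_position, mode, window, n_windows):
    """Per (side, k) site masks for the profile windows.

    Window 0 is centred on the core (contains the core variant); window k
    on each side spans distances ((k-0.5)w, (k+0.5)w] from the core.
    """
    pos = panel.positions
    if mode == "genetic":
        if gmap is None:
            raise ValueError("genetic mode needs a genetic map")
        coord = gmap.bp_to_cm(pos)
        c0 = gmap.bp_to_cm(core_position)
    elif mode == "physical":
        coord = pos.astype(float)
        c0 = float(core_position)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d = coord - c0
    # signed window index: round(d / w) puts window 0 symmetric on the core
    k = np.rint(d / window).astype(np.int64)
    k[np.abs(k) > n_windows] = n_windows + 1   # beyond profile range
    return k


def delta_pi_profile(panel: HaplotypePanel, core_position: int,
                     selected, unselected, mode: str = "genetic",
                     gmap: GeneticMap | None = None,
                     window: float | None = None,
                     max_dist: float | None = None) -> pd.DataFrame:
    """Folded delta-pi profile around the core.

    Defaults: genetic mode 0.01 cM windows to 20 cM per side (2000
    windows); physical mode 1000 bp windows to 2 Mb per side.  Returns
    one row per distance index k = 0..2000 with per-side pi values, the
    folded pi of each group and the folded delta-pi (NaN where undefined).
    """
    if window is None:
        window = 0.01 if mode == "genetic" else 1000.0
    if max_dist is None:
        max_dist = 20.0 if mode == "genetic" else 2_000_000.0
    n_windows = int(round(max_dist / window))
    k = _window_bounds(panel, gmap, core_position, mode, window, n_windows)

    H_sel = panel.alleles[np.asarray(selected), :]
    H_un = panel.alleles[np.asarray(unselected), :]
    ks = np.arange(0, n_windows + 1)
    rows = []
    for kk in ks:
        sides = {}
        for side, mask in (("up", k == -kk), ("down", k == kk)):
            if kk == 0 and side == "up":
                continue
            if mask.any():
                idx = np.flatnonzero(mask)
                sides[side] = (pi_window(H_sel, idx), pi_window(H_un, idx))
            else:
                sides[side] = (np.nan, np.nan)
        if kk == 0:
            pi_sel, pi_un = sides["down"]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pi_sel = np.nanmean([sides["up"][0], sides["down"][0]])
                pi_un = np.nanmean([sides["up"][1], sides["down"][1]])
        rows.append({
            "k": kk, "distance": kk * window,
            "pi_selected": pi_sel, "pi_unselected": pi_un,
            "delta_pi": delta_pi(pi_sel, pi_un),
        })
    return pd.DataFrame(rows)


def delta_pi_background(profiles, n_windows: int = 1000) -> float:
    """Genomic background delta-pi_B: the mean delta-pi over each profile's
    ``n_windows`` most distant defined windows, pooled across sweeps.
    Uses whatever is available (with a warning) when profiles are short."""
    pool = []
    for prof in profiles:
        ok = prof[np.isfinite(prof["delta_pi"])]
        tail = ok.nlargest(n_windows, "k")["delta_pi"].to_numpy()
        if tail.size < n_windows:
            warnings.warn(
                f"only {tail.size} defined distant windows (wanted {n_windows})")
        pool.append(tail)
    if not pool:
        raise ValueError("need at least one profile")
    return float(np.concatenate(pool).mean())


def sweep_length(profile: pd.DataFrame, delta_pi_b: float,
                 window: float | None = None):
    """Sweep extent from the folded profile: distance from the core to the
    midpoint between the first recovered window (delta-pi >= delta-pi_B)
    and the previous one, i.e. length = (k + 0.5) * w.

    Returns ``(length, k_recover, flagged)``; ``flagged`` is True when the
    profile never recovers inside the scanned range (length = scan range)
    or recovery is degenerate at the core window itself.
    """
    if window is None:
        window = float(profile["distance"].iloc[1] - profile["distance"].iloc[0]) \
            if len(profile) > 1 else 1.0
    ok = profile[np.isfinite(profile["delta_pi"])]
    rec = ok[ok["delta_pi"] >= delta_pi_b]
    if rec.empty:
        k_max = int(profile["k"].max())
        return (k_max + 0.5) * window, k_max, True
    k = int(rec["k"].iloc[0])
    return (k + 0.5) * window, k, k == 0


def classify_sweep(panel: HaplotypePanel, core_position: int, selected,
                   unselected, gmap: GeneticMap,
                   core_halfwidth_cm: float = 0.01):
    """Hard/soft call over the +/- ``core_halfwidth_cm`` core region.

    Hard: the selected haplotypes carry zero diversity over the core
    region (a single core haplotype); soft otherwise.  Also reports the
    core-region delta-pi (as a percentage).
    """
    cm = gmap.bp_to_cm(panel.positions)
    c0 = gmap.bp_to_cm(core_position)
    idx = np.flatnonzero(np.abs(cm - c0) <= core_halfwidth_cm)
    pi_sel = pi_window(panel.alleles[np.asarray(selected), :], idx)
    pi_un = pi_window(panel.alleles[np.asarray(unselected), :], idx)
    dp = delta_pi(pi_sel, pi_un)
    kind = "hard" if pi_sel == 0.0 else "soft"
    return kind, (dp * 100.0 if np.isfinite(dp) else np.nan)


@dataclass
class SweepRegion:
    """Summary of one characterized sweep (one row of the sweep table)."""

    chromosome: str
    core_position: int
    core_fst: float
    core_xpehh: float
    n_selected: int
    n_unselected: int
    kind: str
    delta_pi_core_pct: float
    delta_pi_background: float
    length_cm: float
    length_bp: float
    start_bp: int
    stop_bp: int
    flagged: bool
    profile: pd.DataFrame = field(repr=False, default=None)


def characterize_sweep(panel: HaplotypePanel, gmap: GeneticMap,
                       region_snps: pd.DataFrame, focal, background,
                       delta_pi_b: float | None = None,
                       mode: str = "genetic") -> SweepRegion:
    """End-to-end characterization of one sweep region.

    When ``delta_pi_b`` is None the region's own profile tail defines the
    background level (single-sweep convenience; for a genome scan compute
    it once over all sweeps with :func:`delta_pi_background`).
    """
    core = pick_core_snp(region_snps)
    core_pos = int(core["position"])
    selected, unselected = partition_haplotypes(panel, core_pos, focal, background)
    prof = delta_pi_profile(panel, core_pos, selected, unselected,
                            mode=mode, gmap=gmap)
    if delta_pi_b is None:
        delta_pi_b = delta_pi_background([prof])
    w = 0.01 if mode == "genetic" else 1000.0
    length, k_rec, flagged = sweep_length(prof, delta_pi_b, window=w)
    kind, dp_core = classify_sweep(panel, core_pos, selected, unselected, gmap)
    if mode == "genetic":
        length_cm = length
        c0 = gmap.bp_to_cm(core_pos)
        start_bp = gmap.cm_to_bp(c0 - length)
        stop_bp = gmap.cm_to_bp(c0 + length)
    else:
        start_bp, stop_bp = core_pos - length, core_pos + length
        length_cm = (gmap.bp_to_cm(min(stop_bp, gmap.chrom_length))
                     - gmap.bp_to_cm(max(start_bp, 0))) / 2.0
    # reported rounded to 1 kb
    start_bp = int(round(max(start_bp, 0) / 1000.0) * 1000)
    stop_bp = int(round(min(stop_bp, gmap.chrom_length) / 1000.0) * 1000)
    return SweepRegion(
        chromosome=panel.chromosome, core_position=core_pos,
        core_fst=float(core["fst_wc"]), core_xpehh=float(core["xpehh_norm"]),
        n_selected=int(len(selected)), n_unselected=int(len(unselected)),
        kind=kind, delta_pi_core_pct=dp_core, delta_pi_background=delta_pi_b,
        length_cm=float(length_cm), length_bp=float(stop_bp - start_bp),
        start_bp=start_bp, stop_bp=stop_bp, flagged=bool(flagged),
        profile=prof)
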