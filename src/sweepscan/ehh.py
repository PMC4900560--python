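"""Extended haplotype homozygosity: EHH curves, integrated EHH (iHH) and the
normalized cross-population XP-EHH scan.

EHH at a boundary site is the probability that two haplotypes drawn at
random from the sample are identical over the closed site interval from
the core to the boundary: EHH = sum_g C(n_g, 2) / C(n, 2) with haplotypes
grouped by exact allele-string identity.  At zero extension the groups are
the two core allele classes.  iHH is the trapezoid integral of the EHH
curve over genetic distance (cM), per flank, stopped with a partial
trapezoid at the linear-interpolated crossing of the decay cutoff.

Filters mirror the scan the statistics come from: cores need minor allele
frequency >= 0.02 (joint focal+background sample by default), and a core
whose EHH curve meets a physical gap > 10,000 bp to the next variable site
before decaying below the cutoff is discarded in either population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .panel import GeneticMap, HaplotypePanel

__all__ = ["ehh_at", "ehh_curve", "ihh", "xpehh_scan", "mean_xpehh_window"]


# ---------------------------------------------------------------------------
# Reference-definition EHH (pure python; also the tests' entry point)
# ---------------------------------------------------------------------------

def ehh_at(panel: HaplotypePanel, populations, core_index: int,
           boundary_index: int) -> float:
    """EHH of the closed interval [core, boundary] for the given population(s).

    ``populations`` may be a label or tuple of labels (pooled sample).
    """
    pops = (populations,) if isinstance(populations, str) else tuple(populations)
    H = panel.population_alleles(*pops)
    n = H.shape[0]
    if n < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    lo, hi = sorted((core_index, boundary_index))
    groups = {}
    for row in H[:, lo:hi + 1]:
        key = row.tobytes()
        groups[key] = groups.get(key, 0) + 1
    num = sum(c * (c - 1) // 2 for c in groups.values())
    return num / (n * (n - 1) // 2)


def ehh_curve(panel: HaplotypePanel, populations, core_index: int,
              gmap: GeneticMap, direction: str, cutoff: float = 0.05):
    """(genetic distance cM, EHH) points of one flank, starting at (0, EHH0),
    truncated after the first point below ``cutoff``."""
    step = 1 if direction == "downstream" else -1
    cm = gmap.bp_to_cm(panel.positions)
    points = [(0.0, ehh_at(panel, populations, core_index, core_index))]
    j = core_index
    while 0 <= j + step < panel.n_sites:
        j += step
        e = ehh_at(panel, populations, core_index, j)
        points.append((abs(cm[j] - cm[core_index]), e))
        if e < cutoff:
            break
    return points


# ---------------------------------------------------------------------------
# Numba scan kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _flank_ihh(H, pos, cm, core, step, cutoff, max_gap):
    """Integrate one EHH flank.  Returns (ihh, hit_gap, hit_edge)."""
    n, S = H.shape
    npairs = 0.5 * n * (n - 1)
    gid = np.empty(n, np.int64)
    for i in range(n):
        gid[i] = H[i, core]
    counts = np.zeros(2 * n + 2, np.int64)
    relabel = np.empty(2 * n + 2, np.int64)

    # compact labels, retire singletons, compute EHH
    def _compact(gid):
        for v in range(counts.size):
            counts[v] = 0
        for i in range(n):
            if gid[i] >= 0:
                counts[gid[i]] += 1
        num = 0.0
        nxt = 0
        for v in range(counts.size):
            c = counts[v]
            if c >= 2:
                num += 0.5 * c * (c - 1)
                relabel[v] = nxt
                nxt += 1
            else:
                relabel[v] = -1
        for i in range(n):
            if gid[i] >= 0:
                gid[i] = relabel[gid[i]]
        return num / npairs

    prev_ehh = _compact(gid)
    prev_x = 0.0
    ihh = 0.0
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= S:
            return ihh, False, True            # chromosome edge, EHH >= cutoff
        gap = pos[jn] - pos[j] if step == 1 else pos[j] - pos[jn]
        if gap > max_gap:
            return ihh, True, False            # long-gap rule
        for i in range(n):
            if gid[i] >= 0:
                gid[i] = 2 * gid[i] + H[i, jn]
        e = _compact(gid)
        x = abs(cm[jn] - cm[core])
        if e < cutoff:
            if prev_ehh > cutoff:
                frac = (prev_ehh - cutoff) / (prev_ehh - e)
                xc = prev_x + frac * (x - prev_x)
                ihh += 0.5 * (prev_ehh + cutoff) * (xc - prev_x)
            return ihh, False, False
        ihh += 0.5 * (prev_ehh + e) * (x - prev_x)
        prev_ehh = e
        prev_x = x
        j = jn


@njit(cache=True)
def _scan_pop(H, pos, cm, cores, cutoff, max_gap):
    m = cores.size
    ihh_tot = np.zeros(m)
    hit_gap = np.zeros(m, np.bool_)
    hit_edge = np.zeros(m, np.bool_)
    for c in range(m):
        core = cores[c]
        up, g1, e1 = _flank_ihh(H, pos, cm, core, -1, cutoff, max_gap)
        dn, g2, e2 = _flank_ihh(H, pos, cm, core, 1, cutoff, max_gap)
        ihh_tot[c] = up + dn
        hit_gap[c] = g1 or g2
        hit_edge[c] = e1 or e2
    return ihh_tot, hit_gap, hit_edge


def ihh(panel: HaplotypePanel, populations, core_index: int, gmap: GeneticMap,
        cutoff: float = 0.05, max_gap: int = 10_000):
    """Integrated EHH (both flanks summed, cM units) for one core.

    Returns ``(ihh, hit_gap, hit_edge)``; ``hit_gap`` is True when a
    physical gap > ``max_gap`` bp was met while EHH was still at or above
    ``cutoff``; ``hit_edge`` when a chromosome edge was reached first.
    """
    pops = (populations,) if isinstance(populations, str) else tuple(populations)
    H = np.ascontiguousarray(panel.population_alleles(*pops))
    if H.shape[0] < 2:
        raise ValueError("iHH needs at least 2 haplotypes")
    cm = gmap.bp_to_cm(panel.positions)
    tot, gap, edge = _scan_pop(H, panel.positions, cm,
                               np.array([core_index], dtype=np.int64),
                               cutoff, max_gap)
    return float(tot[0]), bool(gap[0]), bool(edge[0])


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def xpehh_scan(panel: HaplotypePanel, focal, background, gmap: GeneticMap,
               maf: float = 0.02, cutoff: float = 0.05, max_gap: int = 10_000,
               min_cores_for_norm: int = 50,
               maf_joint: bool = True) -> pd.DataFrame:
    """Per-SNP XP-EHH between the focal and background populations.

    raw = ln(iHH_focal / iHH_background); positive values mark long
    haplotypes in the focal population.  Cores below the MAF filter or
    with a gap hit in either population are discarded from normalization;
    norm = (raw - mean)/sd over retained cores, left NaN when fewer than
    ``min_cores_for_norm`` cores are retained.
    """
    fpops = (focal,) if isinstance(focal, str) else tuple(focal)
    bpops = (background,) if isinstance(background, str) else tuple(background)
    Hf = np.ascontiguousarray(panel.population_alleles(*fpops))
    Hb = np.ascontiguousarray(panel.population_alleles(*bpops))
    cm = gmap.bp_to_cm(panel.positions)
    pos = panel.positions

    if maf_joint:
        joint = np.concatenate([Hf, Hb], axis=0)
        f1 = joint.mean(axis=0)
    else:
        f1 = Hf.mean(axis=0)
    maf_val = np.minimum(f1, 1.0 - f1)
    maf_ok = maf_val >= maf

    cores = np.flatnonzero(maf_ok).astype(np.int64)
    ihh_f = np.full(panel.n_sites, np.nan)
    ihh_b = np.full(panel.n_sites, np.nan)
    gap_f = np.zeros(panel.n_sites, dtype=bool)
    gap_b = np.zeros(panel.n_sites, dtype=bool)
    edge = np.zeros(panel.n_sites, dtype=bool)
    if cores.size:
        tf, gf, ef = _scan_pop(Hf, pos, cm, cores, cutoff, max_gap)
        tb, gb, eb = _scan_pop(Hb, pos, cm, cores, cutoff, max_gap)
        ihh_f[cores], ihh_b[cores] = tf, tb
        gap_f[cores], gap_b[cores] = gf, gb
        edge[cores] = ef | eb

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log(ihh_f / ihh_b)
    raw[~np.isfinite(raw)] = np.nan

    gap_discarded = gap_f | gap_b
    retained = maf_ok & ~gap_discarded & np.isfinite(raw)
    norm = np.full(panel.n_sites, np.nan)
    if retained.sum() >= min_cores_for_norm:
        r = raw[retained]
        sd = r.std()
        if sd > 0:
            norm[retained] = (r - r.mean()) / sd

    return pd.DataFrame({
        "chrom": panel.chromosome,
        "position": pos,
        "maf": maf_val,
        "maf_filtered": ~maf_ok,
        "ihh_focal": ihh_f,
        "ihh_background": ihh_b,
        "xpehh_raw": raw,
        "xpehh_norm": norm,
        "gap_discarded": gap_discarded,
        "edge_flag": edge,
        "retained": retained,
    })


def mean_xpehh_window(records: pd.DataFrame, window_bp: int,
                      extent_bp: int | None = None) -> pd.DataFrame:
    """Arithmetic mean of normalized XP-EHH over fixed-origin windows.

    Empty windows (no retained core) get NaN.
    """
    if extent_bp is None:
        extent_bp = int(records["position"].max()) + 1
    n_win = int(np.ceil(extent_bp / window_bp))
    starts = np.arange(n_win, dtype=np.int64) * window_bp
    ok = records["retained"].to_numpy() & np.isfinite(records["xpehh_norm"].to_numpy())
    widx = records.loc[ok, "position"].to_numpy() // window_bp
    vals = records.loc[ok, "xpehh_norm"].to_numpy()
    s = np.bincount(widx, weights=vals, minlength=n_win)
    c = np.bincount(widx, minlength=n_win)
    with np.errstate(invalid="ignore"):
        mean = np.where(c > 0, s / np.where(c == 0, 1, c), np.nan)
    return pd.DataFrame({"start": starts, "stop": starts + window_bp,
                         "n_cores": c, "mean_xpehh": mean})
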